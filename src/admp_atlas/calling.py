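"""Per-tissue epigenome-wide linear age modelling and aDMP calling.

Each probe's beta value (methylation fraction in [0, 1]) is regressed on
chronological age plus covariates by ordinary least squares; a probe is an
age-related differentially methylated position (aDMP) when the age slope
passes an effect-size cut-off (default 2% per 10 years on the beta scale) and
the Bonferroni-adjusted P value passes significance (default <= 0.05).  An
effect-size-only mode and an equal-N subsampler support power-control
re-analyses.

Percent convention: beta is a fraction, so %/10yr = per-year beta slope x 1000.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as _t

log = logging.getLogger(__name__)

#: class labels emitted by :func:`call_admps`
CLASS_GAIN, CLASS_LOSS, CLASS_NONE, CLASS_UNTESTED = "gain", "loss", "none", "untested"


class DatasetError(ValueError):
    """Invalid methylation dataset (misalignment, bad ages, duplicates)."""


class CollinearDesignError(ValueError):
    """Rank-deficient design matrix; names the offending column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank-deficient; column {column!r} "
                         "is collinear with the others")


@dataclass
class MethylationDataset:
    """One tissue's beta matrix with aligned sample metadata.

    ``betas`` is probes x samples (fractions in [0,1], NaN = missing);
    ``samples`` has one row per matrix column, in the same order, with at
    least an ``age`` column (years) plus covariate columns.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    tissue: str

    def __post_init__(self) -> None:
        if "age" not in self.samples.columns:
            raise DatasetError("sample metadata must contain an 'age' column")
        if len(self.samples) != self.betas.shape[1]:
            raise DatasetError(
                f"{self.tissue}: {self.betas.shape[1]} matrix columns but "
                f"{len(self.samples)} metadata rows"
            )
        if not (self.samples.index.astype(str) == self.betas.columns.astype(str)).all():
            raise DatasetError(f"{self.tissue}: matrix columns and metadata "
                               "rows disagree (order and identity must match)")
        if self.samples.index.has_duplicates:
            raise DatasetError(f"{self.tissue}: duplicate sample ids")
        ages = self.samples["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or np.any(ages < 0):
            raise DatasetError(f"{self.tissue}: ages must be finite and >= 0")
        vals = self.betas.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise DatasetError(f"{self.tissue}: beta values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]


@dataclass(frozen=True)
class RegressionFit:
    """Age-coefficient summary of one probe's OLS fit."""

    slope_per_year: float
    se: float
    p: float
    n_used: int
    p_bonf: float = np.nan

    @property
    def slope_per_decade_pct(self) -> float:
        """% per 10 years; exactly 1000x the per-year beta slope."""
        return self.slope_per_year * 1000.0


@dataclass(frozen=True)
class CallingCriteria:
    """The dual aDMP cut-offs: effect size and Bonferroni significance."""

    slope_threshold_pct_per_decade: float = 2.0
    p_bonf_max: float = 0.05
    mode: str = "dual"  # "dual" | "effect_only"
    strict_inequality: bool = False

    def __post_init__(self) -> None:
        if self.slope_threshold_pct_per_decade <= 0:
            raise ValueError("slope threshold must be > 0")
        if not (0 < self.p_bonf_max <= 1):
            raise ValueError("p_bonf_max must be in (0, 1]")
        if self.mode not in ("dual", "effect_only"):
            raise ValueError(f"unknown calling mode {self.mode!r}")


@dataclass
class ADMPTable:
    """Per-probe regression fits and gain/loss/none calls for one tissue."""

    tissue: str
    table: pd.DataFrame  # slope_per_year, slope_per_decade_pct, se, p, p_bonf, n_used, class
    m_tested: int
    criteria: CallingCriteria = field(default_factory=CallingCriteria)

    def probes(self, direction: str) -> pd.Index:
        """Probe ids called in the given direction ('gain' or 'loss')."""
        if direction not in (CLASS_GAIN, CLASS_LOSS):
            raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
        return self.table.index[self.table["class"] == direction]

    @property
    def tested_probes(self) -> pd.Index:
        return self.table.index[self.table["class"] != CLASS_UNTESTED]

    def counts(self) -> dict[str, int]:
        c = self.table["class"].value_counts()
        return {k: int(c.get(k, 0)) for k in
                (CLASS_GAIN, CLASS_LOSS, CLASS_NONE, CLASS_UNTESTED)}


def bonferroni(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` over m tested probes."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


def build_design(samples: pd.DataFrame,
                 covariates: list[str] | None = None) -> pd.DataFrame:
    """Design matrix: intercept + untransformed age + encoded covariates.

    Binary/numeric covariates enter as-is; categorical (non-numeric) columns
    are reference-coded indicators dropping the first level.  If the selected
    covariates include a simplex of cell fractions (columns summing to ~1 per
    sample), the last fraction column is dropped to preserve full rank.
    Samples with any missing covariate are the caller's responsibility
    (see :func:`call_admps`, which drops them globally with a logged count).
    """
    cols = [c for c in (covariates if covariates is not None
                        else [c for c in samples.columns if c != "age"])]
    X = pd.DataFrame({"intercept": 1.0, "age": samples["age"].astype(float)},
                     index=samples.index)
    frac_cols = [c for c in cols
                 if pd.api.types.is_numeric_dtype(samples[c])
                 and samples[c].between(0, 1).all()
                 and not samples[c].isin([0, 1]).all()]  # exclude 0/1 binaries
    if len(frac_cols) >= 2 and np.allclose(samples[frac_cols].sum(axis=1), 1.0):
        dropped = frac_cols[-1]
        cols = [c for c in cols if c != dropped]
        log.info("build_design: cell fractions sum to 1; dropped %r", dropped)
    for c in cols:
        col = samples[c]
        if pd.api.types.is_numeric_dtype(col):
            X[c] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            for dc in dummies.columns:
                X[dc] = dummies[dc].astype(float)
    return X


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify a column whose removal does not reduce rank
    for j in range(X.shape[1] - 1, -1, -1):
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
            raise CollinearDesignError(names[j])
    raise CollinearDesignError(names[-1])


def _ols_age_batch(Y: np.ndarray, X: np.ndarray,
                   age_col: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS of many response columns on a shared full-rank design.

    Y is n x p (no NaN), X is n x k.  Returns (slopes, ses, pvals) for the
    age column.  Zero-residual-variance fits report se = 0, p = 0.
    """
    n, k = X.shape
    # pinv-based solve; the brute-force oracle in the tests goes through the
    # explicit normal equations instead
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - k
    xtx_inv_aa = float((pinv @ pinv.T)[age_col, age_col])
    sigma2 = rss / df
    # numerically-zero residual variance (exact linear response)
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    degenerate = rss <= 1e-24 * scale * n
    se = np.sqrt(sigma2 * xtx_inv_aa)
    se[degenerate] = 0.0
    slopes = B[age_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slopes / np.where(se > 0, se, 1.0), np.inf)
    p = np.where(se > 0, 2.0 * _t.sf(np.abs(np.where(se > 0, tstat, 0.0)), df), 0.0)
    return slopes, se, p


def fit_age_model(
    beta_values: np.ndarray | pd.Series,
    ages: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    m: int = 1,
) -> RegressionFit:
    """OLS fit of one probe: beta ~ intercept + age + covariates.

    Missing betas are dropped (complete-case); the slope, SE and two-sided P
    (t distribution, ``n_used - k`` df) refer to the age coefficient, with age
    entered untransformed.  ``m`` is the Bonferroni family size used for
    ``p_bonf``.
    """
    y = np.asarray(beta_values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if covariates is None:
        C = np.empty((len(a), 0))
        names = ["intercept", "age"]
    elif isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(dtype=float)
        names = ["intercept", "age", *covariates.columns.astype(str)]
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = ["intercept", "age", *[f"cov{i}" for i in range(C.shape[1])]]
    keep = ~np.isnan(y)
    y, a, C = y[keep], a[keep], C[keep]
    X = np.column_stack([np.ones_like(a), a, C])
    n_used, k = X.shape
    if n_used < k + 2:
        raise DatasetError(
            f"insufficient samples after dropping missing betas "
            f"(n_used={n_used}, need >= {k + 2})"
        )
    _check_full_rank(X, names)
    slopes, se, p = _ols_age_batch(y[:, None], X)
    pv = float(p[0])
    return RegressionFit(slope_per_year=float(slopes[0]), se=float(se[0]),
                         p=pv, n_used=n_used, p_bonf=bonferroni(pv, m))


def _classify(slope_pct: np.ndarray, p_bonf: np.ndarray,
              criteria: CallingCriteria) -> np.ndarray:
    thr = criteria.slope_threshold_pct_per_decade
    if criteria.strict_inequality:
        big_gain, big_loss = slope_pct > thr, slope_pct < -thr
    else:
        big_gain, big_loss = slope_pct >= thr, slope_pct <= -thr
    if criteria.mode == "dual":
        sig = p_bonf <= criteria.p_bonf_max
        big_gain, big_loss = big_gain & sig, big_loss & sig
    out = np.full(len(slope_pct), CLASS_NONE, dtype=object)
    out[big_gain] = CLASS_GAIN
    out[big_loss] = CLASS_LOSS
    return out


def call_admps(
    dataset: MethylationDataset,
    criteria: CallingCriteria | None = None,
    covariates: list[str] | None = None,
) -> ADMPTable:
    """Fit every probe and classify gain/loss/none under the calling criteria.

    Probes are fit independently with complete-case handling of missing
    betas; probes whose usable sample count falls below ``k + 2`` are marked
    ``untested`` and excluded from the Bonferroni family ``m_tested``.
    Samples with any missing covariate are dropped globally (logged).
    """
    criteria = criteria or CallingCriteria()
    if dataset.n_probes == 0:
        raise DatasetError(f"{dataset.tissue}: empty dataset")
    X_df = build_design(dataset.samples, covariates)
    cov_ok = X_df.notna().all(axis=1)
    if not cov_ok.all():
        log.info("call_admps[%s]: dropped %d sample(s) with missing covariates",
                 dataset.tissue, int((~cov_ok).sum()))
    X_df = X_df.loc[cov_ok]
    Y_full = dataset.betas.loc[:, cov_ok.to_numpy()].to_numpy(dtype=float)
    X = X_df.to_numpy(dtype=float)
    names = list(X_df.columns.astype(str))
    n, k = X.shape
    min_n = k + 2

    p_count = Y_full.shape[0]
    slopes = np.full(p_count, np.nan)
    se = np.full(p_count, np.nan)
    pv = np.full(p_count, np.nan)
    n_used = np.zeros(p_count, dtype=np.int64)

    nan_mask = np.isnan(Y_full)
    n_used[:] = n - nan_mask.sum(axis=1)
    complete = ~nan_mask.any(axis=1)
    testable = n_used >= min_n

    if complete.any():
        _check_full_rank(X, names)
        s, e, p = _ols_age_batch(Y_full[complete].T, X)
        slopes[complete], se[complete], pv[complete] = s, e, p

    # group probes with missing entries by missingness pattern and batch each
    todo = np.flatnonzero(~complete & testable)
    if len(todo):
        patterns: dict[bytes, list[int]] = {}
        for i in todo:
            patterns.setdefault(nan_mask[i].tobytes(), []).append(i)
        for key, idxs in patterns.items():
            keep = ~np.frombuffer(key, dtype=bool)
            Xs = X[keep]
            _check_full_rank(Xs, names)
            s, e, p = _ols_age_batch(Y_full[np.ix_(idxs, keep)].T, Xs)
            ii = np.asarray(idxs)
            slopes[ii], se[ii], pv[ii] = s, e, p

    m_tested = int(testable.sum())
    if m_tested == 0:
        raise DatasetError(f"{dataset.tissue}: no probe passed the sample-count "
                           "precondition; nothing tested")
    p_bonf = np.full(p_count, np.nan)
    p_bonf[testable] = bonferroni(pv[testable], m_tested)

    slope_pct = slopes * 1000.0
    cls = np.full(p_count, CLASS_UNTESTED, dtype=object)
    cls[testable] = _classify(slope_pct[testable], p_bonf[testable], criteria)

    table = pd.DataFrame(
        {
            "slope_per_year": slopes,
            "slope_per_decade_pct": slope_pct,
            "se": se,
            "p": pv,
            "p_bonf": p_bonf,
            "n_used": n_used,
            "class": cls,
        },
        index=dataset.betas.index,
    )
    log.info("call_admps[%s]: m_tested=%d gain=%d loss=%d (mode=%s)",
             dataset.tissue, m_tested,
             int((cls == CLASS_GAIN).sum()), int((cls == CLASS_LOSS).sum()),
             criteria.mode)
    return ADMPTable(tissue=dataset.tissue, table=table, m_tested=m_tested,
                     criteria=criteria)


def subsample_equal_n(
    datasets: dict[str, MethylationDataset], n: int, seed: int
) -> dict[str, MethylationDataset]:
    """Draw n samples per tissue without replacement (equal-N power control).

    Deterministic per (seed, tissue label); a tissue with exactly n samples is
    returned with all its samples (original order).
    """
    out: dict[str, MethylationDataset] = {}
    for tissue, ds in datasets.items():
        if ds.n_samples < n:
            raise DatasetError(
                f"{tissue}: cannot draw {n} of {ds.n_samples} samples")
        rng = np.random.default_rng([seed, zlib.crc32(tissue.encode())])
        sel = np.sort(rng.choice(ds.n_samples, size=n, replace=False))
        out[tissue] = MethylationDataset(
            betas=ds.betas.iloc[:, sel],
            samples=ds.samples.iloc[sel],
            tissue=tissue,
        )
    return out
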