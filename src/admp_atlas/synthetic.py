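"""Synthetic multi-tissue 450k-like methylome generator with planted effects.

Builds an annotation-structured genome (CpG probes clustered into CpG
islands, an EZH2 union track enriched at islands, per-tissue 15-state
chromatin segmentations, gene models), plants ground-truth linear age effects
with configurable cross-tissue sharing and annotation-biased placement
(gain effects at polycomb-bound CpG islands, loss effects at enhancer-state
non-CGI probes), and simulates per-tissue cohorts:

    beta(probe, sample) = clip(intercept + slope * age + covariates + noise, [0, 1])

Probes are simulated independently; local co-methylation of neighbouring
CpGs in real arrays is not emulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import nchypergeom_fisher

from .annotation import (
    STATE_VOCABULARY,
    GenomicInterval,
    assign_state,
    classify_cgi,
    ezh2_flag,
)
from .calling import MethylationDataset

SHARING_SPECIFIC = "tissue-specific"
SHARING_KSHARED = "k-shared"
SHARING_UNIVERSAL = "universal"

# rough genome-wide state frequencies: quiescent/weak states dominate
_STATE_WEIGHTS = {
    "TssA": 5, "TssAFlnk": 4, "TxFlnk": 1, "Tx": 6, "TxWk": 12, "EnhG": 2,
    "Enh": 8, "ZNF/Rpts": 1, "Het": 5, "TssBiv": 2, "BivFlnk": 1,
    "EnhBiv": 2, "ReprPC": 5, "ReprPCWk": 8, "Quies": 30,
}


class SimulationError(ValueError):
    """Invalid generator configuration."""


@dataclass(eq=False)
class SyntheticGenome:
    """Annotation universe for one synthetic cohort.

    ``probes``: DataFrame(chrom, pos) indexed by probe id, positions strictly
    increasing within a chromosome.  ``segmentations`` cover every probe of
    every tissue exactly once with labels from the 15-state vocabulary.
    """

    probes: pd.DataFrame
    cgi: list[GenomicInterval]
    ezh2: list[GenomicInterval]
    segmentations: dict[str, list[GenomicInterval]]
    genes: pd.DataFrame
    tissues: tuple[str, ...]
    chrom_sizes: dict[str, int]

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def cgi_class(self) -> pd.Series:
        return classify_cgi(self.probes, self.cgi)

    def ezh2_flags(self) -> pd.Series:
        return ezh2_flag(self.probes, self.ezh2)

    def states(self, tissue: str) -> pd.Series:
        return assign_state(self.probes, self.segmentations[tissue])

    def equals(self, other: "SyntheticGenome") -> bool:
        return (
            self.probes.equals(other.probes)
            and self.cgi == other.cgi
            and self.ezh2 == other.ezh2
            and self.segmentations == other.segmentations
            and self.genes.equals(other.genes)
            and self.tissues == other.tissues
            and self.chrom_sizes == other.chrom_sizes
        )


def generate_genome(
    n_probes: int,
    n_genes: int,
    tissues: Sequence[str],
    seed: int,
    *,
    cgi_fraction: float = 0.30,
    ezh2_island_prob: float = 0.5,
    ezh2_background_rate: float = 0.05,
    n_chromosomes: int = 4,
    mean_island_run: float = 5.0,
    mean_segment_run: float = 8.0,
) -> SyntheticGenome:
    """Generate a deterministic annotation-structured genome.

    ``cgi_fraction`` of probes (exactly, up to rounding) sit inside CpG
    islands, realised as runs of consecutive probes so that island/shore
    geometry is meaningful.  A fraction ``ezh2_island_prob`` of islands is
    EZH2-bound versus a ``ezh2_background_rate`` per-probe background, making
    EZH2 overlap islands far more often than chance.
    """
    if n_probes < 100:
        raise SimulationError("n_probes must be >= 100")
    if n_genes < 2:
        raise SimulationError("n_genes must be >= 2")
    tissues = tuple(tissues)
    if not tissues or len(set(tissues)) != len(tissues):
        raise SimulationError("tissues must be non-empty and unique")
    if not (0 < cgi_fraction <= 0.45):
        raise SimulationError("cgi_fraction must be in (0, 0.45] "
                              "(islands need non-island buffer probes)")

    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    counts = np.full(n_chromosomes, n_probes // n_chromosomes)
    counts[: n_probes % n_chromosomes] += 1

    probe_rows = []
    cgi_ivs: list[GenomicInterval] = []
    ezh2_ivs: list[GenomicInterval] = []
    seg_ivs: dict[str, list[GenomicInterval]] = {t: [] for t in tissues}
    chrom_sizes: dict[str, int] = {}
    state_labels = list(_STATE_WEIGHTS)
    state_p = np.array(list(_STATE_WEIGHTS.values()), dtype=float)
    state_p /= state_p.sum()
    pid = 0

    for chrom, n_c in zip(chroms, counts):
        gaps = rng.integers(300, 5001, size=n_c)
        pos = 1000 + np.cumsum(gaps)
        for p in pos:
            probe_rows.append((f"cg{pid:07d}", chrom, int(p)))
            pid += 1
        chrom_sizes[chrom] = int(pos[-1] + 1000)

        # exact-count island placement as probe runs with 1-probe buffers
        target = int(round(cgi_fraction * n_c))
        in_island = np.zeros(n_c, dtype=bool)
        blocked = np.zeros(n_c, dtype=bool)
        order = rng.permutation(n_c)
        remaining = target
        for start in order:
            if remaining <= 0:
                break
            if blocked[start]:
                continue
            want = min(remaining, 1 + rng.poisson(mean_island_run - 1))
            end = start
            while end < n_c and not blocked[end] and end - start < want:
                end += 1
            run = end - start
            if run == 0:
                continue
            in_island[start:end] = True
            blocked[max(0, start - 1):min(n_c, end + 1)] = True
            remaining -= run
        if remaining > 0:  # pathological density; fall back to any free probe
            free = np.flatnonzero(~blocked)
            take = free[:remaining]
            in_island[take] = True
            remaining -= len(take)
        if remaining > 0:
            raise SimulationError("could not realise the requested cgi_fraction")

        # island runs -> intervals, EZH2 binding per island
        idx = np.flatnonzero(in_island)
        if len(idx):
            splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in splits:
                iv = GenomicInterval(chrom, int(pos[run[0]] - 200),
                                     int(pos[run[-1]] + 200))
                cgi_ivs.append(iv)
                if rng.random() < ezh2_island_prob:
                    ezh2_ivs.append(iv)
        for i in np.flatnonzero(~in_island):
            if rng.random() < ezh2_background_rate:
                ezh2_ivs.append(GenomicInterval(chrom, int(pos[i] - 100),
                                                int(pos[i] + 100)))

        # per-tissue segmentation: probe runs, boundaries at gap midpoints
        for t in tissues:
            bounds = [0]
            labels = []
            i = 0
            while i < n_c:
                run = min(n_c - i, 1 + rng.poisson(mean_segment_run - 1))
                j = i + run
                if j < n_c:
                    bounds.append(int((pos[j - 1] + pos[j]) // 2))
                else:
                    bounds.append(chrom_sizes[chrom])
                labels.append(state_labels[rng.choice(len(state_labels), p=state_p)])
                i = j
            for (s, e), lab in zip(zip(bounds, bounds[1:]), labels):
                seg_ivs[t].append(GenomicInterval(chrom, s, e, lab))

    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos"]
    ).set_index("probe_id")

    total_len = sum(chrom_sizes.values())
    gene_rows = []
    for gi in range(n_genes):
        r = rng.random() * total_len
        acc = 0
        chrom = chroms[0]
        for c in chroms:
            acc += chrom_sizes[c]
            if r < acc:
                chrom = c
                break
        length = int(rng.integers(5_000, 100_001))
        start = int(rng.integers(0, max(1, chrom_sizes[chrom] - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"G{gi:05d}", chrom, start, start + length, strand))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )

    return SyntheticGenome(
        probes=probes, cgi=cgi_ivs, ezh2=ezh2_ivs, segmentations=seg_ivs,
        genes=genes, tissues=tissues, chrom_sizes=chrom_sizes,
    )


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SharingSpec:
    """Proportions of planted effects by cross-tissue sharing class."""

    specific: float = 0.85
    k_shared: float = 0.13
    universal: float = 0.02

    def __post_init__(self) -> None:
        total = self.specific + self.k_shared + self.universal
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"sharing proportions sum to {total}, not 1")


@dataclass(frozen=True)
class EffectConfig:
    """Planted-effect design: counts, sharing, slope magnitudes, placement.

    Slope magnitudes are drawn uniformly from ``slope_range_pct`` (% per 10
    years on the beta scale; 2%/10yr = 0.002 beta/year).  ``*_placement_or``
    are the odds with which gain effects prefer CGI&EZH2 probes and loss
    effects prefer enhancer-state non-CGI probes (home tissue's segmentation).
    """

    n_gain: int = 150
    n_loss: int = 100
    gain_sharing: SharingSpec = field(default_factory=SharingSpec)
    loss_sharing: SharingSpec = field(
        default_factory=lambda: SharingSpec(0.974, 0.026, 0.0))
    slope_range_pct: tuple[float, float] = (2.0, 8.0)
    gain_placement_or: float = 5.0
    loss_placement_or: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.slope_range_pct
        if lo <= 0 or hi < lo:
            raise SimulationError("slope_range_pct must satisfy 0 < lo <= hi")
        if self.n_gain < 0 or self.n_loss < 0:
            raise SimulationError("effect counts must be non-negative")


@dataclass(eq=False)
class EffectMap:
    """Ground truth: per-(probe, tissue) age slope and sharing metadata.

    ``slopes`` is probes x tissues in beta units per year (0 for null
    probes); ``info`` (indexed by planted probe id) records direction,
    sharing class, member tissues and the slope magnitude in %/10yr.
    """

    slopes: pd.DataFrame
    info: pd.DataFrame

    def planted(self, direction: str | None = None) -> pd.Index:
        if direction is None:
            return self.info.index
        return self.info.index[self.info["direction"] == direction]

    def specific_fraction(self, direction: str) -> float:
        sub = self.info[self.info["direction"] == direction]
        if sub.empty:
            raise SimulationError(f"no planted {direction} effects")
        return float((sub["n_tissues"] == 1).mean())


def _sharing_counts(n: int, sharing: SharingSpec,
                    force_universal: bool) -> dict[str, int]:
    """Largest-remainder rounding of sharing proportions into exact counts."""
    props = {
        SHARING_SPECIFIC: sharing.specific,
        SHARING_KSHARED: sharing.k_shared,
        SHARING_UNIVERSAL: sharing.universal,
    }
    raw = {k: v * n for k, v in props.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    if force_universal and sharing.universal > 0 and n >= 1 \
            and counts[SHARING_UNIVERSAL] == 0:
        counts[SHARING_UNIVERSAL] = 1
        donor = SHARING_SPECIFIC if counts[SHARING_SPECIFIC] > 0 else SHARING_KSHARED
        counts[donor] -= 1
    return counts


def _biased_draw(rng: np.random.Generator, pool: np.ndarray,
                 in_cat: np.ndarray, n_draw: int, odds: float) -> np.ndarray:
    """Draw ``n_draw`` probes from ``pool`` with odds ``odds`` for the category.

    The in-category count follows Fisher's noncentral hypergeometric
    distribution, so the realised placement 2x2 odds ratio concentrates at
    ``odds``; members are then sampled uniformly within each stratum.
    """
    cat = pool[in_cat[pool]]
    out = pool[~in_cat[pool]]
    if n_draw > len(pool):
        raise SimulationError("requested more effects than available probes")
    if odds != 1.0 and len(cat) == 0:
        raise SimulationError("placement bias impossible: no eligible probes "
                              "in the target category")
    lo = max(0, n_draw - len(out))
    hi = min(n_draw, len(cat))
    if lo == hi:
        a = lo
    else:
        a = int(nchypergeom_fisher.rvs(len(pool), len(cat), n_draw, odds,
                                       random_state=rng))
        a = min(max(a, lo), hi)
    chosen_in = rng.choice(cat, size=a, replace=False) if a else np.empty(0, int)
    chosen_out = (rng.choice(out, size=n_draw - a, replace=False)
                  if n_draw - a else np.empty(0, int))
    return np.concatenate([chosen_in, chosen_out]).astype(int)


def plant_effects(genome: SyntheticGenome, config: EffectConfig,
                  seed: int) -> EffectMap:
    """Plant gain/loss age effects with annotation-biased placement.

    Gain effects prefer probes that are both in a CpG island and EZH2-bound;
    loss effects prefer enhancer-state (home tissue) non-CGI probes.  Sharing
    proportions are realised exactly by largest-remainder rounding; at least
    one universal gain effect is planted whenever the gain sharing spec gives
    the universal class positive mass.
    """
    rng = np.random.default_rng(seed)
    T = len(genome.tissues)
    n_p = genome.n_probes
    if config.n_gain + config.n_loss > n_p:
        raise SimulationError("requested more effects than probes")

    cgi_class = genome.cgi_class().to_numpy()
    ez = genome.ezh2_flags().to_numpy()
    gain_cat = (cgi_class == "island") & ez
    probe_ids = genome.probes.index.to_numpy()

    slopes = pd.DataFrame(0.0, index=genome.probes.index,
                          columns=list(genome.tissues))
    rows: list[tuple] = []

    available = np.ones(n_p, dtype=bool)

    # ---- gains: placement is tissue-independent (CGI & EZH2) -------------
    if config.n_gain:
        pool = np.flatnonzero(available)
        gain_idx = _biased_draw(rng, pool, gain_cat, config.n_gain,
                                config.gain_placement_or)
        available[gain_idx] = False
        gain_idx = rng.permutation(gain_idx)
        counts = _sharing_counts(config.n_gain, config.gain_sharing,
                                 force_universal=True)
        cursor = 0
        tissue_cycle = rng.permutation(T)
        for cls, cnt in counts.items():
            for j in range(cnt):
                i = gain_idx[cursor]
                cursor += 1
                if cls == SHARING_SPECIFIC:
                    members = [genome.tissues[tissue_cycle[(cursor - 1) % T]]]
                elif cls == SHARING_UNIVERSAL or T <= 2:
                    members = list(genome.tissues)
                else:
                    k = int(rng.integers(2, T))
                    members = [genome.tissues[m]
                               for m in rng.choice(T, size=k, replace=False)]
                mag = rng.uniform(*config.slope_range_pct)
                slope = mag / 1000.0
                for t in members:
                    slopes.iloc[i, slopes.columns.get_loc(t)] = slope
                rows.append((probe_ids[i], "gain", cls, len(members),
                             ",".join(sorted(members)), mag))

    # ---- losses: placement per home tissue (Enh & non-CGI) ---------------
    if config.n_loss:
        counts = _sharing_counts(config.n_loss, config.loss_sharing,
                                 force_universal=False)
        # assign member tissues first (home = first member, used for placement)
        assignments: list[tuple[str, list[str]]] = []
        tissue_cycle = rng.permutation(T)
        ci = 0
        for cls, cnt in counts.items():
            for _ in range(cnt):
                if cls == SHARING_SPECIFIC:
                    members = [genome.tissues[tissue_cycle[ci % T]]]
                    ci += 1
                elif cls == SHARING_UNIVERSAL or T <= 2:
                    members = list(genome.tissues)
                else:
                    k = int(rng.integers(2, T))
                    members = [genome.tissues[m]
                               for m in rng.choice(T, size=k, replace=False)]
                assignments.append((cls, members))
        by_home: dict[str, list[int]] = {}
        for ai, (_, members) in enumerate(assignments):
            by_home.setdefault(members[0], []).append(ai)
        state_cache = {t: genome.states(t).to_numpy() for t in by_home}
        for home, ais in by_home.items():
            loss_cat = (state_cache[home] == "Enh") & (cgi_class == "non_CGI")
            pool = np.flatnonzero(available)
            idxs = _biased_draw(rng, pool, loss_cat, len(ais),
                                config.loss_placement_or)
            available[idxs] = False
            for ai, i in zip(ais, idxs):
                cls, members = assignments[ai]
                mag = rng.uniform(*config.slope_range_pct)
                slope = -mag / 1000.0
                for t in members:
                    slopes.iloc[i, slopes.columns.get_loc(t)] = slope
                rows.append((probe_ids[i], "loss", cls, len(members),
                             ",".join(sorted(members)), mag))

    info = pd.DataFrame(
        rows, columns=["probe_id", "direction", "sharing_class", "n_tissues",
                       "tissues", "slope_pct"]
    ).set_index("probe_id")
    return EffectMap(slopes=slopes, info=info)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueDesign:
    """One tissue's cohort: size, age range, covariate structure."""

    name: str
    n_samples: int
    age_range: tuple[float, float]
    sex_proportion: float = 0.5
    n_batches: int = 1
    n_cell_fracs: int = 0
    missingness: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not hi > lo:
            raise SimulationError(f"{self.name}: degenerate age range")
        n_cov = 1 + max(0, self.n_batches - 1) + self.n_cell_fracs
        if self.n_samples < 3 + n_cov:
            raise SimulationError(
                f"{self.name}: need >= {3 + n_cov} samples for {n_cov} covariates")
        if not (0 <= self.missingness < 0.5):
            raise SimulationError(f"{self.name}: missingness must be in [0, 0.5)")


def default_cohort() -> list[TissueDesign]:
    """The study conditions emulated by default: 7 tissues, unequal sizes
    (96-1202) and unequal age ranges; subcutaneous fat is female-only, liver
    is a multi-study merge (batch covariate), blood-cell tissues carry
    residual cell-fraction covariates."""
    return [
        TissueDesign("brain", 380, (0, 97), n_cell_fracs=2),
        TissueDesign("buccal", 96, (1, 28)),
        TissueDesign("liver", 147, (15, 86), n_batches=4),
        TissueDesign("kidney", 171, (15, 86)),
        TissueDesign("fat", 648, (39, 85), sex_proportion=0.0),
        TissueDesign("monocytes", 1202, (44, 83), n_cell_fracs=2),
        TissueDesign("th_cells", 214, (45, 79), n_cell_fracs=2),
    ]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise and nuisance structure of the simulated beta values.

    ``baseline_by_cgi`` gives (mean, sd) of the per-probe methylation level
    per CGI class, truncated to ``baseline_clip`` — islands hypomethylated,
    non-CGI hypermethylated, the 450k bimodality.  ``effect_anchor`` fixes
    the age at which a planted probe sits at its drawn level: ``"mid"``
    (tissue mid-cohort age; keeps multi-decade effects inside [0,1]) or
    ``"zero"`` (level is the literal age-0 intercept).  ``logit_normal``
    switches the additive Gaussian residual from the beta scale to the logit
    scale (default off).
    """

    baseline_by_cgi: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "island": (0.15, 0.10),
            "shore": (0.35, 0.12),
            "non_CGI": (0.72, 0.10),
        })
    baseline_clip: tuple[float, float] = (0.1, 0.9)
    residual_sd: float = 0.03
    sex_effect_sd: float = 0.005
    batch_effect_sd: float = 0.01
    cellfrac_effect_sd: float = 0.01
    effect_anchor: str = "mid"
    logit_normal: bool = False
    missing_cap: float = 0.10

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise SimulationError("residual sd must be >= 0")
        if self.effect_anchor not in ("mid", "zero"):
            raise SimulationError("effect_anchor must be 'mid' or 'zero'")


def simulate_cohort(
    genome: SyntheticGenome,
    effects: EffectMap,
    designs: Sequence[TissueDesign],
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> dict[str, MethylationDataset]:
    """Simulate per-tissue methylation datasets from planted ground truth.

    Ages are uniform within each tissue's range; covariate effects are
    additive with per-probe coefficients; missing entries are inserted
    completely at random, capped so every probe keeps >= 90% of samples
    (``noise.missing_cap``).  Deterministic per (seed, tissue name).
    """
    noise = noise or NoiseConfig()
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        raise SimulationError("duplicate tissue names in cohort design")
    unknown = set(names) - set(genome.tissues)
    if unknown:
        raise SimulationError(f"tissues not in genome: {sorted(unknown)}")

    # per-probe baseline level, shared across tissues
    base_rng = np.random.default_rng([seed, 0xBA5E])
    cgi_class = genome.cgi_class()
    level = np.empty(genome.n_probes)
    for cls, (mu, sd) in noise.baseline_by_cgi.items():
        mask = (cgi_class == cls).to_numpy()
        level[mask] = base_rng.normal(mu, sd, size=int(mask.sum()))
    level = np.clip(level, *noise.baseline_clip)

    out: dict[str, MethylationDataset] = {}
    for design in designs:
        rng = np.random.default_rng([seed, zlib.crc32(design.name.encode())])
        n = design.n_samples
        p = genome.n_probes
        ages = rng.uniform(*design.age_range, size=n)
        sex = (rng.random(n) < design.sex_proportion).astype(int)
        batch = rng.integers(0, design.n_batches, size=n)
        cf = (rng.dirichlet(np.full(design.n_cell_fracs + 1, 5.0), size=n)
              [:, :design.n_cell_fracs] if design.n_cell_fracs else None)

        slope = effects.slopes[design.name].to_numpy()
        anchor = (np.mean(design.age_range)
                  if noise.effect_anchor == "mid" else 0.0)
        intercept = level - slope * anchor

        mu = intercept[:, None] + slope[:, None] * ages[None, :]
        mu += rng.normal(0, noise.sex_effect_sd, size=p)[:, None] * sex[None, :]
        if design.n_batches > 1:
            offsets = np.zeros((p, design.n_batches))
            offsets[:, 1:] = rng.normal(0, noise.batch_effect_sd,
                                        size=(p, design.n_batches - 1))
            mu += offsets[:, batch]
        if cf is not None:
            coefs = rng.normal(0, noise.cellfrac_effect_sd,
                               size=(p, design.n_cell_fracs))
            mu += coefs @ cf.T

        if noise.logit_normal:
            eps = 1e-3
            lin = logit(np.clip(mu, eps, 1 - eps))
            if noise.residual_sd > 0:
                lin = lin + rng.normal(0, 4.0 * noise.residual_sd, size=(p, n))
            betas = expit(lin)
        else:
            if noise.residual_sd > 0:
                mu = mu + rng.normal(0, noise.residual_sd, size=(p, n))
            betas = np.clip(mu, 0.0, 1.0)

        if design.missingness > 0:
            cap = int(np.floor(noise.missing_cap * n))
            mask = rng.random((p, n)) < design.missingness
            excess = np.flatnonzero(mask.sum(axis=1) > cap)
            for i in excess:
                flagged = np.flatnonzero(mask[i])
                keep = rng.choice(flagged, size=cap, replace=False)
                mask[i] = False
                mask[i, keep] = True
            betas = betas.copy()
            betas[mask] = np.nan

        sample_ids = [f"{design.name}_s{i:04d}" for i in range(n)]
        meta = pd.DataFrame({"age": ages, "sex": sex}, index=sample_ids)
        if design.n_batches > 1:
            meta["batch"] = pd.Series([f"b{b}" for b in batch],
                                      index=sample_ids, dtype=object)
        if cf is not None:
            for k in range(design.n_cell_fracs):
                meta[f"cf_{k + 1}"] = cf[:, k]
        out[design.name] = MethylationDataset(
            betas=pd.DataFrame(betas, index=genome.probes.index,
                               columns=sample_ids),
            samples=meta,
            tissue=design.name,
        )
    return out


def null_effects(genome: SyntheticGenome) -> EffectMap:
    """An EffectMap with every slope exactly zero (pure-null simulation)."""
    slopes = pd.DataFrame(0.0, index=genome.probes.index,
                          columns=list(genome.tissues))
    info = pd.DataFrame(
        columns=["direction", "sharing_class", "n_tissues", "tissues",
                 "slope_pct"],
        index=pd.Index([], name="probe_id"))
    return EffectMap(slopes=slopes, info=info)
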