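"""Shared fixtures: a small annotated genome and a simulated 3-tissue cohort."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import admp_atlas as aa

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

TISSUES3 = ("brain", "liver", "kidney")


@pytest.fixture(scope="session")
def genome3() -> aa.SyntheticGenome:
    return aa.generate_genome(2000, 60, TISSUES3, seed=11)


@pytest.fixture(scope="session")
def effects3(genome3) -> aa.EffectMap:
    return aa.plant_effects(
        genome3,
        aa.EffectConfig(n_gain=80, n_loss=50, slope_range_pct=(3.0, 8.0)),
        seed=12,
    )


@pytest.fixture(scope="session")
def cohort3(genome3, effects3) -> dict[str, aa.MethylationDataset]:
    designs = [
        aa.TissueDesign("brain", 200, (20, 90), n_cell_fracs=2),
        aa.TissueDesign("liver", 150, (15, 86), n_batches=2),
        aa.TissueDesign("kidney", 180, (15, 86), missingness=0.02),
    ]
    return aa.simulate_cohort(genome3, effects3, designs,
                              aa.NoiseConfig(residual_sd=0.03), seed=13)


@pytest.fixture(scope="session")
def admps3(cohort3) -> dict[str, aa.ADMPTable]:
    return {t: aa.call_admps(ds) for t, ds in cohort3.items()}


def ols_oracle(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """Brute-force age-slope OLS: explicit normal equations + t survival fn.

    Independent of the package's pinv-based batched solver.
    """
    from scipy.stats import t as tdist

    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    rss = float(resid @ resid)
    if rss <= 1e-24 * len(y) * max(1.0, float(y @ y)):
        # exact linear (or constant) response: zero residual variance
        return float(beta[1]), 0.0, 0.0
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtx)
    slope = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    p = 2.0 * float(tdist.sf(abs(slope) / se, df)) if se > 0 else 0.0
    return slope, se, p


def make_admp_table(tissue: str, rows: dict[str, dict]) -> aa.ADMPTable:
    """Hand-built ADMPTable for specificity tests.

    ``rows``: probe_id -> partial fit dict; unspecified fields get neutral
    defaults (class none, p 1, slope 0).
    """
    defaults = {"slope_per_year": 0.0, "se": 0.001, "p": 1.0, "p_bonf": 1.0,
                "n_used": 100, "class": "none"}
    recs = {}
    for probe, spec in rows.items():
        rec = {**defaults, **spec}
        rec["slope_per_decade_pct"] = rec["slope_per_year"] * 1000.0
        recs[probe] = rec
    df = pd.DataFrame.from_dict(recs, orient="index")
    df.index.name = "probe_id"
    m = int((df["class"] != "untested").sum())
    return aa.ADMPTable(tissue=tissue, table=df, m_tested=max(m, 1))
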