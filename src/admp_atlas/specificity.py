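"""Cross-tissue sharing versus specificity of aDMPs, CGIs and genes.

Given per-tissue aDMP call tables (same probe universe, identical criteria),
these operations quantify how often an age-related position recurs across
tissues: per-probe tissue sets and sharing histograms, pairwise overlap
matrices, relaxed-significance cross-tissue checks, cross-tissue slope
matrices, and region-level (CpG island / nearest gene) aggregation.

Gain and loss aDMPs are stratified throughout; a probe gaining in one tissue
and losing in another appears once in each direction's table and is flagged
discordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .calling import CLASS_GAIN, CLASS_LOSS, ADMPTable

log = logging.getLogger(__name__)

DIRECTIONS = (CLASS_GAIN, CLASS_LOSS)


class SpecificityError(ValueError):
    """Invalid inputs to a specificity computation."""


def round_pct(x: float, ndigits: int = 1) -> float:
    """Half-up rounding for reported percentages (85.15 -> 85.2)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SpecificityTable:
    """Direction-stratified probe -> tissue-set mapping.

    ``table`` is indexed by probe id with columns ``tissues`` (frozenset),
    ``n_tissues`` and ``discordant`` (also called in the opposite direction
    somewhere).
    """

    direction: str
    table: pd.DataFrame
    all_tissues: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.table)


def _check_tables(admp_tables: dict[str, ADMPTable]) -> None:
    if len(admp_tables) < 2:
        raise SpecificityError("need aDMP tables for at least 2 tissues")
    labels = [t.tissue for t in admp_tables.values()]
    if len(set(labels)) != len(labels):
        raise SpecificityError("duplicate tissue labels")


def build_specificity(admp_tables: dict[str, ADMPTable],
                      direction: str) -> SpecificityTable:
    """Map each probe called in >= 1 tissue (given direction) to its tissues."""
    _check_tables(admp_tables)
    if direction not in DIRECTIONS:
        raise SpecificityError(f"direction must be one of {DIRECTIONS}")
    other = CLASS_LOSS if direction == CLASS_GAIN else CLASS_GAIN
    sets: dict[str, set[str]] = {}
    opposite: set[str] = set()
    for tissue, tab in admp_tables.items():
        for p in tab.probes(direction):
            sets.setdefault(p, set()).add(tissue)
        opposite.update(tab.probes(other))
    probes = sorted(sets)
    table = pd.DataFrame(
        {
            "tissues": [frozenset(sets[p]) for p in probes],
            "n_tissues": [len(sets[p]) for p in probes],
            "discordant": [p in opposite for p in probes],
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return SpecificityTable(direction=direction, table=table,
                            all_tissues=tuple(sorted(admp_tables)))


def percent_tissue_specific(table: SpecificityTable) -> float:
    """Percentage of aDMPs called in exactly one tissue (full precision).

    Use :func:`round_pct` for 1-decimal reporting.
    """
    if len(table) == 0:
        raise SpecificityError("empty specificity table")
    return 100.0 * float((table.table["n_tissues"] == 1).mean())


def sharing_histogram(table: SpecificityTable) -> pd.Series:
    """Counts of aDMPs by the number of tissues they were identified in."""
    T = len(table.all_tissues)
    counts = table.table["n_tissues"].value_counts()
    return pd.Series([int(counts.get(k, 0)) for k in range(1, T + 1)],
                     index=pd.RangeIndex(1, T + 1, name="n_tissues"),
                     name="n_admps")


@dataclass
class OverlapMatrix:
    """Pairwise aDMP overlap between tissues.

    ``counts``: diagonal = aDMPs unique to that tissue (against ALL other
    tissues), off-diagonal (i, j) = aDMPs shared by the pair.  ``percent``:
    diagonal = percent of tissue i's aDMPs that are unique; off-diagonal
    (i, j) = percent of tissue i's aDMPs also called in j (row-normalised).
    ``totals``: per-tissue aDMP counts.
    """

    direction: str
    counts: pd.DataFrame
    percent: pd.DataFrame
    totals: pd.Series


def overlap_matrix(admp_tables: dict[str, ADMPTable],
                   direction: str) -> OverlapMatrix:
    """Unique/shared aDMP counts for every tissue pair."""
    _check_tables(admp_tables)
    tissues = list(admp_tables)
    sets = {t: set(admp_tables[t].probes(direction)) for t in tissues}
    counts = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
    pct = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    totals = pd.Series({t: len(sets[t]) for t in tissues}, name="total")
    for i, ti in enumerate(tissues):
        others = set().union(*(sets[t] for t in tissues if t != ti))
        counts.loc[ti, ti] = len(sets[ti] - others)
        if totals[ti]:
            pct.loc[ti, ti] = 100.0 * counts.loc[ti, ti] / totals[ti]
        for tj in tissues[i + 1:]:
            shared = len(sets[ti] & sets[tj])
            counts.loc[ti, tj] = counts.loc[tj, ti] = shared
            if totals[ti]:
                pct.loc[ti, tj] = 100.0 * shared / totals[ti]
            if totals[tj]:
                pct.loc[tj, ti] = 100.0 * shared / totals[tj]
    return OverlapMatrix(direction=direction, counts=counts, percent=pct,
                         totals=totals)


def cross_tissue_significance(
    admps: SpecificityTable,
    all_fits: dict[str, ADMPTable],
    p_relaxed: float = 0.001,
) -> tuple[pd.DataFrame, float, int]:
    """Relaxed-significance check of aDMPs in tissues where they were NOT called.

    For each (aDMP, other-tissue) pair, the indicator is true when the raw
    (unadjusted) P value is below ``p_relaxed`` with a same-sign slope.
    Returns (indicator frame with NaN for skipped pairs, summary fraction
    over evaluable pairs, number of skipped pairs).
    """
    tissues = list(all_fits)
    ind = pd.DataFrame(np.nan, index=admps.table.index, columns=tissues)
    sign = 1.0 if admps.direction == CLASS_GAIN else -1.0
    n_skipped = 0
    for t in tissues:
        fit = all_fits[t].table
        for probe, row in admps.table.iterrows():
            if t in row["tissues"]:
                continue  # home tissue(s) excluded from the denominator
            if probe not in fit.index or fit.at[probe, "class"] == "untested" \
                    or not np.isfinite(fit.at[probe, "p"]):
                n_skipped += 1
                continue
            ok = (fit.at[probe, "p"] < p_relaxed
                  and sign * fit.at[probe, "slope_per_year"] > 0)
            ind.at[probe, t] = float(ok)
    if n_skipped:
        log.info("cross_tissue_significance: %d pair(s) skipped "
                 "(probe untested or absent)", n_skipped)
    evaluable = ind.notna().to_numpy().sum()
    frac = float(np.nansum(ind.to_numpy()) / evaluable) if evaluable else np.nan
    return ind, frac, n_skipped


def cross_tissue_slope_matrix(admps: SpecificityTable,
                              all_fits: dict[str, ADMPTable]) -> pd.DataFrame:
    """Slopes (%/10yr) of each aDMP in every tissue; NaN where untested."""
    tissues = list(all_fits)
    out = pd.DataFrame(np.nan, index=admps.table.index, columns=tissues)
    for t in tissues:
        fit = all_fits[t].table
        common = out.index.intersection(fit.index)
        tested = fit.loc[common, "class"] != "untested"
        out.loc[common[tested], t] = fit.loc[common[tested],
                                             "slope_per_decade_pct"]
    return out


@dataclass
class RegionSpecificity:
    """Tissue sharing aggregated to CGI or gene level.

    ``table``: per unit, the union of member-probe tissue sets and its size.
    ``counts``: per (unit, tissue) aDMP counts (a probe counts towards every
    tissue it was called in).  ``n_unmapped``: aDMP probes without a unit.
    """

    unit: str
    direction: str
    table: pd.DataFrame
    counts: pd.DataFrame
    n_unmapped: int

    def percent_unique(self) -> float:
        if len(self.table) == 0:
            raise SpecificityError("empty region table")
        return 100.0 * float((self.table["n_tissues"] == 1).mean())


def aggregate_to_regions(admps: SpecificityTable, mapping: pd.Series,
                         unit: str = "region") -> RegionSpecificity:
    """Aggregate probe-level tissue sets to regions (CGIs or nearest genes).

    ``mapping`` maps probe id -> unit id; aDMP probes missing from the
    mapping are excluded with a logged count.  A unit's tissue set is the
    union over its member probes' tissue sets, so region-level sharing can
    exceed probe-level sharing.
    """
    if len(mapping) == 0:
        raise SpecificityError("empty probe-to-region mapping")
    mapping = mapping.dropna()
    probes = admps.table.index
    mapped = probes.intersection(mapping.index)
    n_unmapped = len(probes) - len(mapped)
    if n_unmapped:
        log.info("aggregate_to_regions[%s]: %d aDMP probe(s) unmapped",
                 unit, n_unmapped)
    units: dict[str, set[str]] = {}
    counts: dict[tuple[str, str], int] = {}
    for probe in mapped:
        u = mapping.loc[probe]
        tset = admps.table.at[probe, "tissues"]
        units.setdefault(u, set()).update(tset)
        for t in tset:
            counts[(u, t)] = counts.get((u, t), 0) + 1
    ids = sorted(units)
    table = pd.DataFrame(
        {
            "tissues": [frozenset(units[u]) for u in ids],
            "n_tissues": [len(units[u]) for u in ids],
        },
        index=pd.Index(ids, name=f"{unit}_id"),
    )
    cmat = pd.DataFrame(0, index=pd.Index(ids, name=f"{unit}_id"),
                        columns=list(admps.all_tissues), dtype=int)
    for (u, t), c in counts.items():
        cmat.at[u, t] = c
    return RegionSpecificity(unit=unit, direction=admps.direction,
                             table=table, counts=cmat, n_unmapped=n_unmapped)


def external_overlap(admp_probes: pd.Index | set,
                     external: pd.Index | set) -> dict[str, float]:
    """Overlap of an aDMP catalogue with an externally published CpG list.

    Reports the shared count and the percentage under both natural
    denominators (the aDMP catalogue and the external list).
    """
    admp = set(admp_probes)
    ext = set(external)
    shared = len(admp & ext)
    return {
        "n_shared": shared,
        "n_admps": len(admp),
        "n_external": len(ext),
        "pct_of_admps": 100.0 * shared / len(admp) if admp else np.nan,
        "pct_of_external": 100.0 * shared / len(ext) if ext else np.nan,
    }
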