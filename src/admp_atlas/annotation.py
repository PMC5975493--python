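"""Probe-level genomic annotation and enrichment statistics.

Maps CpG probes to CpG-island geometry (island / shore / non-CGI), chromatin
states from a 15-state segmentation, EZH2 (PRC2) binding sites and nearest
genes, and computes odds-ratio enrichment of probe sets against a tested-probe
background with a 1-df chi-squared test.

Coordinate convention: all intervals are 0-based half-open ``[start, end)``;
probe positions are 0-based point coordinates (1-based manifest positions are
converted on ingestion in :mod:`admp_atlas.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

log = logging.getLogger(__name__)

#: The fixed 15-state chromatin vocabulary (Roadmap core model).
STATE_VOCABULARY: tuple[str, ...] = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

#: Width of the island-flanking "shore" band, in bp (inclusive at exactly 2 kb).
SHORE_FLANK_BP = 2000

CGI_CLASSES = ("island", "shore", "non_CGI")


class AnnotationError(ValueError):
    """Raised on invalid annotation inputs (bad intervals, unknown states...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with an optional label."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns a mapping ``chrom -> (starts, ends)`` of sorted, disjoint arrays.
    Labels are discarded (merging is only used for label-free membership).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in pairs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts, dtype=np.int64),
                      np.asarray(ends, dtype=np.int64))
    return out


def _point_in_merged(
    pos: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Boolean membership of point positions in merged sorted intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(len(pos), dtype=bool)
    hit[ok] = pos[ok] < ends[idx[ok]]
    return hit


def _distance_to_merged(
    pos: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Distance (bp) from each point to the nearest merged interval.

    0 inside an interval; outside, the offset to the nearest boundary
    coordinate (``start`` or ``end``), so a point exactly at ``end`` (the
    first position past a half-open interval) has distance 0 while being
    outside — callers distinguish membership separately.
    """
    n = len(pos)
    if len(starts) == 0:
        return np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    dist = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    has_left = idx >= 0
    inside = np.zeros(n, dtype=bool)
    inside[has_left] = pos[has_left] < ends[idx[has_left]]
    dist[inside] = 0
    # offset past the previous interval's end coordinate
    left = has_left & ~inside
    dist[left] = pos[left] - ends[idx[left]]
    # gap to the next interval's first base
    nxt = idx + 1
    has_right = nxt < len(starts)
    right = has_right & ~inside
    dist[right] = np.minimum(dist[right], starts[nxt[right]] - pos[right])
    return dist


def classify_cgi(
    positions: pd.DataFrame, islands: Sequence[GenomicInterval]
) -> pd.Series:
    """Classify probes as ``island`` / ``shore`` / ``non_CGI``.

    A probe inside a (merged) CpG island is ``island``; otherwise, within
    ``SHORE_FLANK_BP`` (2 kb, inclusive) of an island boundary it is ``shore``;
    everything else is ``non_CGI``.  Probes on chromosomes absent from the
    island set are ``non_CGI`` (logged).

    Parameters
    ----------
    positions
        DataFrame with columns ``chrom`` and ``pos`` (0-based), indexed by
        probe id.
    islands
        CpG-island intervals; overlaps are merged internally.
    """
    merged = merge_intervals(islands)
    out = pd.Series("non_CGI", index=positions.index, dtype=object, name="cgi_class")
    missing_chroms = set()
    for chrom, sub in positions.groupby("chrom", sort=False):
        if chrom not in merged:
            missing_chroms.add(chrom)
            continue
        starts, ends = merged[chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        inside = _point_in_merged(pos, starts, ends)
        dist = _distance_to_merged(pos, starts, ends)
        cls = np.where(
            inside, "island",
            np.where(dist <= SHORE_FLANK_BP, "shore", "non_CGI"))
        out.loc[sub.index] = cls
    if missing_chroms:
        log.info(
            "classify_cgi: %d chromosome(s) absent from island set, probes "
            "classified non_CGI: %s", len(missing_chroms), sorted(missing_chroms)
        )
    return out


def cgi_membership(
    positions: pd.DataFrame, islands: Sequence[GenomicInterval]
) -> pd.Series:
    """Map probes inside a (merged) island to a stable island id.

    Ids are ``CGI_<chrom>_<start>_<end>`` of the merged island; probes not
    inside any island map to NaN.  Used for CGI-level specificity.
    """
    merged = merge_intervals(islands)
    out = pd.Series(pd.NA, index=positions.index, dtype=object, name="cgi_id")
    for chrom, sub in positions.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0)
        inside = np.zeros(len(pos), dtype=bool)
        inside[ok] = pos[ok] < ends[idx[ok]]
        ids = np.array([f"CGI_{chrom}_{starts[i]}_{ends[i]}" if hit else None
                        for i, hit in zip(idx, inside)], dtype=object)
        out.loc[sub.index[inside]] = ids[inside]
    return out


def classify_cgi_point(
    chrom: str, pos: int, islands: Sequence[GenomicInterval]
) -> str:
    """Single-probe convenience wrapper around :func:`classify_cgi`."""
    df = pd.DataFrame({"chrom": [chrom], "pos": [pos]}, index=["_probe"])
    return classify_cgi(df, islands).iloc[0]


def assign_state(
    positions: pd.DataFrame, segmentation: Sequence[GenomicInterval]
) -> pd.Series:
    """Assign each probe the chromatin state of the covering interval.

    Segmentation intervals must be non-overlapping within a chromosome; a
    probe sitting exactly on a boundary belongs to the interval beginning
    there (half-open convention).  Uncovered probes get the explicit label
    ``"unassigned"`` and are logged; they are excluded from state enrichment.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in segmentation:
        if iv.name is None or iv.name not in STATE_VOCABULARY:
            raise AnnotationError(f"segmentation interval has invalid state {iv.name!r}")
        by_chrom.setdefault(iv.chrom, []).append(iv)

    out = pd.Series("unassigned", index=positions.index, dtype=object, name="state")
    for chrom, sub in positions.groupby("chrom", sort=False):
        ivs = sorted(by_chrom.get(chrom, []), key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping segmentation intervals on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if not ivs:
            continue
        starts = np.asarray([iv.start for iv in ivs], dtype=np.int64)
        ends = np.asarray([iv.end for iv in ivs], dtype=np.int64)
        labels = np.asarray([iv.name for iv in ivs], dtype=object)
        pos = sub["pos"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        vals = np.where(ok, labels[np.clip(idx, 0, None)], "unassigned")
        out.loc[sub.index] = vals
    n_un = int((out == "unassigned").sum())
    if n_un:
        log.info("assign_state: %d probe(s) uncovered by the segmentation", n_un)
    return out


def ezh2_flag(
    positions: pd.DataFrame, ezh2_intervals: Sequence[GenomicInterval]
) -> pd.Series:
    """True where the probe overlaps ANY interval of the (union) EZH2 track."""
    merged = merge_intervals(ezh2_intervals)
    out = pd.Series(False, index=positions.index, name="ezh2")
    for chrom, sub in positions.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        out.loc[sub.index] = _point_in_merged(pos, starts, ends)
    return out


def nearest_gene(positions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per probe, by distance to the closer gene end.

    The distance to a gene is ``min(|pos - start|, |pos - end|)`` over the
    gene's two ends (5'/3' in genomic coordinates; strand only relabels which
    end is which, so the minimum is strand-invariant).  A probe inside a gene
    body is still measured to the nearer end.  Ties break by smaller distance,
    then lexicographically smaller gene id.  Probes on chromosomes with no
    gene are flagged unmapped (gene id ``NaN``).

    Parameters
    ----------
    positions : DataFrame(chrom, pos) indexed by probe id
    genes : DataFrame(gene_id, chrom, start, end, strand)
    """
    out = pd.DataFrame(
        {"nearest_gene": pd.Series(pd.NA, index=positions.index, dtype=object),
         "gene_distance": pd.Series(np.nan, index=positions.index)}
    )
    for chrom, sub in positions.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            log.info("nearest_gene: no gene on %s, %d probe(s) unmapped",
                     chrom, len(sub))
            continue
        gid = g["gene_id"].to_numpy(dtype=object)
        order = np.argsort(gid, kind="stable")  # lexicographic tie-break base
        gid = gid[order]
        gs = g["start"].to_numpy(dtype=np.int64)[order]
        ge = g["end"].to_numpy(dtype=np.int64)[order]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        # distance matrix probes x genes; gene counts are small (<= few 1000)
        best_d = np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
        best_i = np.zeros(len(pos), dtype=np.int64)
        chunk = max(1, 4_000_000 // max(len(gid), 1))
        for lo in range(0, len(pos), chunk):
            p = pos[lo:lo + chunk, None]
            d = np.minimum(np.abs(p - gs[None, :]), np.abs(p - ge[None, :]))
            i = np.argmin(d, axis=1)  # first minimum = lexicographically least
            best_i[lo:lo + chunk] = i
            best_d[lo:lo + chunk] = d[np.arange(len(i)), i]
        out.loc[sub.index, "nearest_gene"] = gid[best_i]
        out.loc[sub.index, "gene_distance"] = best_d.astype(float)
    return out


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """A 2x2 enrichment of a probe set in an annotation category.

    Cells: ``a`` aDMP & in-category, ``b`` aDMP & out, ``c`` non-aDMP & in,
    ``d`` non-aDMP & out.  The odds ratio is ``(a*d)/(b*c)`` with a
    Haldane-Anscombe +0.5 on every cell iff any cell is zero; the chi-squared
    statistic is the 1-df Pearson statistic on the raw counts, without
    continuity correction.
    """

    category: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = field(default=np.nan)
    chi2: float = field(default=np.nan)
    p: float = field(default=np.nan)
    p_adj: float = field(default=np.nan)
    significant: bool = False
    degenerate: bool = False


def enrichment_from_counts(a: int, b: int, c: int, d: int,
                           category: str = "") -> EnrichmentResult:
    """Odds ratio + 1-df Pearson chi-squared from explicit 2x2 counts."""
    for x in (a, b, c, d):
        if x < 0:
            raise AnnotationError("negative cell count in 2x2 table")
    res = EnrichmentResult(category=category, a=a, b=b, c=c, d=d)
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins) or n == 0:
        # category empty or universal, or one group empty: OR undefined
        res.degenerate = True
        return res
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        res.odds_ratio = (aa * dd) / (bb * cc)
    else:
        res.odds_ratio = (a * d) / (b * c)
    num = n * (a * d - b * c) ** 2
    den = float(margins[0]) * margins[1] * margins[2] * margins[3]
    res.chi2 = num / den
    res.p = float(_chi2.sf(res.chi2, df=1))
    return res


def enrichment_test(
    admp_probes: Iterable[str],
    background: Iterable[str],
    in_category: Iterable[str] | Mapping[str, bool] | pd.Series,
    category: str = "",
) -> EnrichmentResult:
    """Enrichment of ``admp_probes`` in a category over the tested background.

    ``admp_probes`` must be a subset of ``background``.  ``in_category`` is
    either a collection of category-member probe ids or a boolean Series over
    (at least) the background.
    """
    bg = pd.Index(background)
    if bg.has_duplicates:
        bg = bg.unique()
    admp = pd.Index(admp_probes).unique()
    if not admp.isin(bg).all():
        raise AnnotationError("aDMP probes must be a subset of the background")
    if len(bg) < 4:
        raise AnnotationError("background must contain at least 4 probes")
    if isinstance(in_category, pd.Series):
        cat = pd.Index(in_category.index[in_category.astype(bool)])
    elif isinstance(in_category, Mapping):
        cat = pd.Index([k for k, v in in_category.items() if v])
    else:
        cat = pd.Index(in_category)
    cat = cat.unique().intersection(bg)
    a = int(admp.isin(cat).sum())
    b = len(admp) - a
    c = len(cat) - a
    d = len(bg) - len(admp) - c
    return enrichment_from_counts(a, b, c, d, category=category)


def state_enrichment_profile(
    admp_probes: Iterable[str],
    background: Iterable[str],
    states: pd.Series,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One enrichment test per chromatin state (15 results).

    ``states`` maps probe id -> state label; probes labelled ``unassigned``
    are excluded (logged).  Significance flags are Bonferroni-corrected within
    the 15-test profile; raw P values are always reported.
    """
    states = states.astype(object)
    assigned = states.index[states.isin(STATE_VOCABULARY)]
    n_dropped = len(states) - len(assigned)
    if n_dropped:
        log.info("state_enrichment_profile: %d unassigned probe(s) excluded",
                 n_dropped)
    bg = pd.Index(background).unique().intersection(assigned)
    admp = pd.Index(admp_probes).unique().intersection(bg)
    results = []
    for state in STATE_VOCABULARY:
        members = states.index[states == state].intersection(bg)
        res = enrichment_test(admp, bg, members, category=state)
        if not res.degenerate:
            res.p_adj = min(1.0, res.p * len(STATE_VOCABULARY))
            res.significant = res.p_adj <= alpha
        results.append(res)
    return results


def cgi_ezh2_joint_enrichment(
    admp_probes: Iterable[str],
    background: Iterable[str],
    cgi_class: pd.Series,
    ezh2: pd.Series,
    alpha: float = 0.05,
) -> dict[str, EnrichmentResult]:
    """Are CGI and EZH2 enrichments independent, or one underlying signal?

    Restricts the background to probes carrying at least one of the two
    annotations (CGI membership = ``island`` class; EZH2 = union-track
    overlap) and tests the doubly-annotated stratum against (i) CGI-only,
    (ii) EZH2-only, and (iii) either-single stratum.
    """
    bg = pd.Index(background).unique()
    is_cgi = cgi_class.reindex(bg).eq("island").to_numpy()
    is_ez = ezh2.reindex(bg).fillna(False).astype(bool).to_numpy()
    both = pd.Index(bg[is_cgi & is_ez])
    cgi_only = pd.Index(bg[is_cgi & ~is_ez])
    ez_only = pd.Index(bg[~is_cgi & is_ez])
    admp = pd.Index(admp_probes).unique()

    def _vs(stratum: pd.Index, label: str) -> EnrichmentResult:
        restricted = both.union(stratum)
        if len(both) == 0 or len(stratum) == 0:
            res = EnrichmentResult(category=label, a=0, b=0, c=0, d=0,
                                   degenerate=True)
            return res
        res = enrichment_test(admp.intersection(restricted), restricted, both,
                              category=label)
        if not res.degenerate:
            res.p_adj = res.p
            res.significant = res.p <= alpha
        return res

    return {
        "both_vs_cgi_only": _vs(cgi_only, "CGI&EZH2 vs CGI-only"),
        "both_vs_ezh2_only": _vs(ez_only, "CGI&EZH2 vs EZH2-only"),
        "both_vs_either": _vs(cgi_only.union(ez_only), "CGI&EZH2 vs single"),
    }


def annotate_probes(
    positions: pd.DataFrame,
    islands: Sequence[GenomicInterval],
    ezh2_intervals: Sequence[GenomicInterval],
    segmentations: Mapping[str, Sequence[GenomicInterval]],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Full per-probe annotation table.

    Columns: ``chrom, pos, cgi_class, ezh2, state_<tissue>..., nearest_gene,
    gene_distance``; indexed by probe id.
    """
    out = positions[["chrom", "pos"]].copy()
    out["cgi_class"] = classify_cgi(positions, islands)
    out["ezh2"] = ezh2_flag(positions, ezh2_intervals)
    for tissue, seg in segmentations.items():
        out[f"state_{tissue}"] = assign_state(positions, seg)
    ng = nearest_gene(positions, genes)
    out["nearest_gene"] = ng["nearest_gene"]
    out["gene_distance"] = ng["gene_distance"]
    return out
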