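"""End-to-end orchestration: simulate -> call -> specificity -> enrich -> report.

A single YAML config drives the whole run.  One global seed fans out to
per-stage seeds through a fixed hash schedule, so each stage is individually
reproducible; every stage writes its outputs before the next stage begins
and the report is recomputable from the persisted tables alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, annotation, io, specificity
from .calling import (
    ADMPTable,
    CallingCriteria,
    MethylationDataset,
    call_admps,
    subsample_equal_n,
)
from .synthetic import (
    EffectConfig,
    NoiseConfig,
    SharingSpec,
    TissueDesign,
    default_cohort,
    generate_genome,
    plant_effects,
    simulate_cohort,
)

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


@dataclass
class SyntheticSpec:
    """Config block for the synthetic-cohort stage."""

    n_probes: int = 20_000
    n_genes: int = 300
    cgi_fraction: float = 0.30
    effects: EffectConfig = field(default_factory=EffectConfig)
    cohort: list[TissueDesign] = field(default_factory=default_cohort)
    noise: NoiseConfig = field(default_factory=NoiseConfig)


@dataclass
class TissueInput:
    """User-supplied per-tissue files and covariate selection."""

    name: str
    betas: str
    metadata: str
    covariates: list[str] | None = None


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    tissues: list[TissueInput] = field(default_factory=list)
    criteria: CallingCriteria = field(default_factory=CallingCriteria)
    effect_only: bool = True
    equal_n: int | None = 96
    enrichment: bool = True
    p_relaxed: float = 0.001
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if "out_dir" not in raw:
            raise PipelineConfigError("config must set out_dir")
        kw: dict[str, Any] = {"out_dir": str(raw["out_dir"])}
        for key in ("seed", "effect_only", "equal_n", "enrichment",
                    "p_relaxed", "figures"):
            if key in raw:
                kw[key] = raw[key]
        if "criteria" in raw:
            kw["criteria"] = CallingCriteria(**raw["criteria"])
        if "synthetic" in raw and raw["synthetic"] is not None:
            s = dict(raw["synthetic"])
            if "effects" in s:
                e = dict(s["effects"])
                for sk in ("gain_sharing", "loss_sharing"):
                    if sk in e:
                        e[sk] = SharingSpec(**e[sk])
                if "slope_range_pct" in e:
                    e["slope_range_pct"] = tuple(e["slope_range_pct"])
                s["effects"] = EffectConfig(**e)
            if "cohort" in s:
                s["cohort"] = [
                    TissueDesign(**{**d, "age_range": tuple(d["age_range"])})
                    for d in s["cohort"]
                ]
            if "noise" in s:
                n = dict(s["noise"])
                for tk in ("baseline_clip",):
                    if tk in n:
                        n[tk] = tuple(n[tk])
                if "baseline_by_cgi" in n:
                    n["baseline_by_cgi"] = {
                        k: tuple(v) for k, v in n["baseline_by_cgi"].items()}
                s["noise"] = NoiseConfig(**n)
            kw["synthetic"] = SyntheticSpec(**s)
        if "tissues" in raw:
            kw["tissues"] = [TissueInput(**d) for d in raw["tissues"]]
        cfg = cls(**kw)
        if cfg.synthetic is None and not cfg.tissues:
            raise PipelineConfigError(
                "config needs a 'synthetic' block or a 'tissues' list")
        return cfg

    def canonical(self) -> str:
        def _default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))
        return json.dumps(asdict(self), sort_keys=True, default=_default)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Headline numbers of one pipeline run, traceable to persisted tables."""

    provenance: dict[str, Any]
    per_tissue_counts: dict[str, dict[str, int]]
    percent_tissue_specific: dict[str, float]
    sharing_histograms: dict[str, dict[str, int]]
    power_controls: dict[str, Any]
    enrichment_summary: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _auto_covariates(samples: pd.DataFrame) -> list[str]:
    """Default covariate selection: every non-age column with > 1 level."""
    return [c for c in samples.columns
            if c != "age" and samples[c].nunique(dropna=True) > 1]


def _load_tissue(spec: TissueInput) -> MethylationDataset:
    for path in (spec.betas, spec.metadata):
        if not Path(path).exists():
            raise PipelineConfigError(
                f"tissue {spec.name!r}: file not found: {path}")
    ds = io.read_matrix(spec.betas, spec.metadata, tissue=spec.name)
    return ds


def _call_all(datasets: dict[str, MethylationDataset],
              criteria: CallingCriteria,
              covariates: dict[str, list[str] | None]) -> dict[str, ADMPTable]:
    out = {}
    for tissue, ds in datasets.items():
        cov = covariates.get(tissue)
        if cov is None:
            cov = _auto_covariates(ds.samples)
        out[tissue] = call_admps(ds, criteria, covariates=cov)
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; every stage persists before the next runs."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = None
    effects = None
    covariates: dict[str, list[str] | None] = {}

    # ---- stage: simulate (optional) --------------------------------------
    stage = "simulate"
    try:
        if config.synthetic is not None:
            s = config.synthetic
            tissues = [d.name for d in s.cohort]
            genome = generate_genome(
                s.n_probes, s.n_genes, tissues,
                seed=stage_seed(config.seed, "genome"),
                cgi_fraction=s.cgi_fraction)
            effects = plant_effects(genome, s.effects,
                                    seed=stage_seed(config.seed, "effects"))
            datasets = simulate_cohort(genome, effects, s.cohort, s.noise,
                                       seed=stage_seed(config.seed, "cohort"))
            simdir = outdir / "synthetic"
            io.write_genome(genome, simdir)
            io.write_effect_map(effects, simdir / "effect_map.tsv")
            for tissue, ds in datasets.items():
                io.write_matrix(ds, simdir / f"{tissue}_betas.tsv")
                io.write_metadata(ds.samples, simdir / f"{tissue}_meta.tsv")
            log.info("simulate: %d probes, %d tissues, %d planted effects",
                     genome.n_probes, len(tissues), len(effects.info))
        else:
            datasets = {t.name: _load_tissue(t) for t in config.tissues}
            covariates = {t.name: t.covariates for t in config.tissues}
            log.info("load: %d tissues", len(datasets))
    except PipelineConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- stage: call -----------------------------------------------------
    stage = "call"
    try:
        calldir = outdir / "calls"
        calldir.mkdir(exist_ok=True)
        admps = _call_all(datasets, config.criteria, covariates)
        for tissue, tab in admps.items():
            io.write_admp_table(tab, calldir / f"{tissue}_admps.tsv")
        power: dict[str, Any] = {}
        admps_eo = None
        admps_en = None
        if config.effect_only:
            crit_eo = CallingCriteria(
                slope_threshold_pct_per_decade=(
                    config.criteria.slope_threshold_pct_per_decade),
                p_bonf_max=config.criteria.p_bonf_max,
                mode="effect_only",
                strict_inequality=config.criteria.strict_inequality)
            admps_eo = _call_all(datasets, crit_eo, covariates)
            for tissue, tab in admps_eo.items():
                io.write_admp_table(tab, calldir / f"{tissue}_admps_effect_only.tsv")
        if config.equal_n is not None:
            sizes = {t: ds.n_samples for t, ds in datasets.items()}
            n_eq = min(min(sizes.values()), config.equal_n)
            sub = subsample_equal_n(datasets, n_eq,
                                    seed=stage_seed(config.seed, "equal_n"))
            admps_en = _call_all(sub, config.criteria, covariates)
            for tissue, tab in admps_en.items():
                io.write_admp_table(tab, calldir / f"{tissue}_admps_equal_n.tsv")
            power["equal_n"] = n_eq
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: specificity ----------------------------------------------
    stage = "specificity"
    try:
        specdir = outdir / "specificity"
        specdir.mkdir(exist_ok=True)
        pct: dict[str, float] = {}
        hists: dict[str, dict[str, int]] = {}
        spec_tables = {}
        for direction in ("gain", "loss"):
            try:
                st = specificity.build_specificity(admps, direction)
            except specificity.SpecificityError:
                raise
            if len(st) == 0:
                pct[direction] = float("nan")
                hists[direction] = {}
                continue
            spec_tables[direction] = st
            pct[direction] = specificity.round_pct(
                specificity.percent_tissue_specific(st))
            hist = specificity.sharing_histogram(st)
            # string keys keep the report JSON-round-trippable
            hists[direction] = {str(int(k)): int(v) for k, v in hist.items()}
            export = st.table.copy()
            export["tissues"] = export["tissues"].map(
                lambda s: ",".join(sorted(s)))
            export.to_csv(specdir / f"{direction}_specificity.tsv", sep="\t")
            hist.to_csv(specdir / f"{direction}_sharing_histogram.tsv", sep="\t")
            om = specificity.overlap_matrix(admps, direction)
            om.counts.to_csv(specdir / f"{direction}_overlap_counts.tsv", sep="\t")
            om.percent.to_csv(specdir / f"{direction}_overlap_percent.tsv", sep="\t")
            ind, frac, skipped = specificity.cross_tissue_significance(
                st, admps, config.p_relaxed)
            power[f"{direction}_relaxed_p_fraction"] = frac
            power[f"{direction}_relaxed_p_skipped"] = skipped
            slopes = specificity.cross_tissue_slope_matrix(st, admps)
            slopes.to_csv(specdir / f"{direction}_slope_matrix.tsv",
                          sep="\t", na_rep="NA")
        for label, extra in (("effect_only", admps_eo), ("equal_n", admps_en)):
            if extra is None:
                continue
            for direction in ("gain", "loss"):
                st = specificity.build_specificity(extra, direction)
                if len(st):
                    power[f"{label}_{direction}_pct_specific"] = (
                        specificity.round_pct(
                            specificity.percent_tissue_specific(st)))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: annotate/enrich ------------------------------------------
    stage = "enrich"
    enrich_summary: dict[str, Any] = {}
    try:
        if config.enrichment and genome is not None:
            anndir = outdir / "annotation"
            anndir.mkdir(exist_ok=True)
            ann = annotation.annotate_probes(
                genome.probes, genome.cgi, genome.ezh2,
                genome.segmentations, genome.genes)
            ann.to_csv(anndir / "probe_annotation.tsv", sep="\t", na_rep="NA")
            cgi_ids = annotation.cgi_membership(genome.probes, genome.cgi)
            rows = []
            for direction in ("gain", "loss"):
                for tissue, tab in admps.items():
                    called = tab.probes(direction)
                    bg = tab.tested_probes
                    if len(called) == 0:
                        continue
                    for cls in annotation.CGI_CLASSES:
                        res = annotation.enrichment_test(
                            called, bg, ann.index[ann["cgi_class"] == cls],
                            category=f"cgi:{cls}")
                        if not res.degenerate:
                            res.p_adj = res.p
                            res.significant = res.p <= 0.05
                        rows.append((direction, tissue, res))
                    res = annotation.enrichment_test(
                        called, bg, ann.index[ann["ezh2"]], category="ezh2")
                    if not res.degenerate:
                        res.p_adj = res.p
                        res.significant = res.p <= 0.05
                    rows.append((direction, tissue, res))
                    for res in annotation.state_enrichment_profile(
                            called, bg, ann[f"state_{tissue}"]):
                        rows.append((direction, tissue, res))
                st = spec_tables.get(direction)
                if st is not None and len(st):
                    for unit, mapping in (("cgi", cgi_ids),
                                          ("gene", ann["nearest_gene"])):
                        reg = specificity.aggregate_to_regions(st, mapping, unit)
                        enrich_summary[f"{direction}_{unit}_pct_unique"] = (
                            specificity.round_pct(reg.percent_unique()))
                        reg.counts.to_csv(
                            anndir / f"{direction}_{unit}_counts.tsv", sep="\t")
            table = pd.DataFrame(
                [{
                    "direction": d, "tissue": t, "category": r.category,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "odds_ratio": r.odds_ratio, "chi2": r.chi2, "p": r.p,
                    "p_adj": r.p_adj, "significant": r.significant,
                    "degenerate": r.degenerate,
                } for d, t, r in rows])
            table.to_csv(anndir / "enrichment.tsv", sep="\t", index=False,
                         na_rep="NA")
            sig = table[table["significant"] == True]  # noqa: E712
            enrich_summary["n_significant"] = int(len(sig))
            enrich_summary["n_tests"] = int(len(table))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: report ---------------------------------------------------
    stage = "report"
    try:
        report = RunReport(
            provenance={
                "version": __version__,
                "seed": config.seed,
                "config_hash": config.config_hash(),
            },
            per_tissue_counts={t: tab.counts() for t, tab in admps.items()},
            percent_tissue_specific=pct,
            sharing_histograms=hists,
            power_controls=power,
            enrichment_summary=enrich_summary,
        )
        (outdir / "report.json").write_text(report.to_json())
        if config.figures:
            _write_figures(outdir, hists, admps)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return report


def _write_figures(outdir: Path, hists: dict[str, dict[str, int]],
                   admps: dict[str, ADMPTable]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    for direction, hist in hists.items():
        if not hist:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar([int(k) for k in hist], list(hist.values()), color="#4878b0")
        ax.set_xlabel("number of tissues identified in")
        ax.set_ylabel(f"{direction}-aDMPs")
        fig.tight_layout()
        fig.savefig(figdir / f"sharing_{direction}.png", dpi=120)
        plt.close(fig)
    for direction in ("gain", "loss"):
        try:
            om = specificity.overlap_matrix(admps, direction)
        except specificity.SpecificityError:
            continue
        fig, ax = plt.subplots(figsize=(5, 4.5))
        im = ax.imshow(om.counts.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(om.counts)), om.counts.columns, rotation=45,
                      ha="right")
        ax.set_yticks(range(len(om.counts)), om.counts.index)
        fig.colorbar(im, ax=ax, label="aDMPs")
        fig.tight_layout()
        fig.savefig(figdir / f"overlap_{direction}.png", dpi=120)
        plt.close(fig)
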