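# admp-atlas

Tissue-specific analysis of age-related DNA methylation change on Illumina
450k-style beta-value matrices.

Chronological age leaves a measurable imprint on the methylome: at some CpG
sites the methylation fraction (beta value, in [0, 1]) drifts linearly with
age. Such sites are called **age-related differentially methylated positions
(aDMPs)**. A central question for building methylation-based age predictors —
and for understanding the mechanism of epigenetic ageing — is whether aDMPs
found in one tissue recur in others, or whether each tissue ages at its own
loci. `admp-atlas` implements the complete analysis for a multi-tissue panel:

1. **aDMP calling** (`admp_atlas.calling`). Per probe and tissue, ordinary
   least squares of beta on untransformed age plus covariates (sex, batch,
   cell fractions). A probe is a gain-aDMP when the age slope is at least
   +2% per 10 years (beta scale; 2%/10yr = 0.002 beta·year⁻¹) **and** its
   Bonferroni-adjusted P value `min(1, p·m)` over the `m` tested probes is
   at most 0.05; loss-aDMPs mirror the criterion with a negative slope.
   Power-control variants: effect-size-only calling (no P cut-off) and
   equal-N subsampling (every tissue drawn down to the smallest cohort,
   default N = 96, without replacement).
2. **Cross-tissue specificity** (`admp_atlas.specificity`). Per-probe tissue
   sets and sharing histograms, percent tissue-specific, pairwise overlap
   matrices (diagonal = unique against *all* other tissues), a relaxed
   significance check (raw P < 0.001, same-sign slope) in tissues where an
   aDMP was not called, cross-tissue slope matrices, and aggregation of
   sharing to CpG islands and nearest genes.
3. **Functional annotation and enrichment** (`admp_atlas.annotation`).
   CpG-island geometry (island / 2-kb shore / non-CGI), 15-state chromatin
   segmentations (TssA … Quies), EZH2 (polycomb/PRC2) binding overlap and
   strand-aware nearest-gene mapping. Enrichment of an aDMP set in a
   category is the odds ratio `(a·d)/(b·c)` of the 2×2 table aDMP-status ×
   category over the tested-probe background, with a 1-df Pearson
   chi-squared P value (no continuity correction; Haldane–Anscombe +0.5 only
   when a cell is zero).
4. **Synthetic cohorts** (`admp_atlas.synthetic`). A generator that builds
   an annotation-structured genome, plants ground-truth age effects with
   configurable cross-tissue sharing (tissue-specific / k-shared /
   universal, the last emulating the ELOVL2-like CpGs that gain methylation
   in every tissue) and annotation-biased placement (gain effects prefer
   polycomb-bound CpG islands, loss effects enhancer-state non-CGI probes),
   and simulates per-tissue cohorts
   `beta = clip(intercept + slope·age + covariates + noise, [0, 1])`.
   Every downstream claim is testable against this planted truth.
5. **Pipeline & I/O** (`admp_atlas.pipeline`, `admp_atlas.io`). TSV/BED
   dialects, a YAML-driven orchestrator and the `admp-atlas` CLI
   (`simulate | call | specificity | annotate | enrich | report | run`).

## Worked example

Run the full pipeline on a simulated 4-tissue cohort (5 000 probes, 150
planted gain and 100 planted loss effects, 85% / 97.4% of them
tissue-specific by construction):

```python
from admp_atlas.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({
    "out_dir": "demo_run",
    "seed": 7,
    "synthetic": {
        "n_probes": 5000, "n_genes": 100,
        "effects": {"n_gain": 150, "n_loss": 100,
                    "slope_range_pct": [3.0, 8.0]},
        "cohort": [
            {"name": "brain",  "n_samples": 380, "age_range": [0, 97]},
            {"name": "buccal", "n_samples": 96,  "age_range": [1, 28]},
            {"name": "liver",  "n_samples": 147, "age_range": [15, 86],
             "n_batches": 4},
            {"name": "kidney", "n_samples": 171, "age_range": [15, 86]},
        ],
    },
})
print(run_pipeline(cfg).to_json())
```

Key lines of the printed report (abridged):

```json
{
  "percent_tissue_specific": {"gain": 85.3, "loss": 97.0},
  "per_tissue_counts": {"brain": {"gain": 46, "loss": 26, "...": "..."}},
  "sharing_histograms": {"gain": {"1": 128, "2": 10, "3": 9, "4": 3}},
  "power_controls": {
    "effect_only_gain_pct_specific": 85.3,
    "equal_n": 96, "equal_n_gain_pct_specific": 85.3
  },
  "enrichment_summary": {"gain_cgi_pct_unique": 77.9, "n_significant": 14}
}
```

Reading it: 85.3% of the called gain-aDMPs occur in exactly one tissue
(the generator planted 85%), and the tissue-specificity survives both power
controls — effect-size-only calling and equal-N (96 samples) recalling —
so it is not an artefact of unequal statistical power. The sharing histogram
shows the expected long tail, with 3 universal (all-tissue) gain-aDMPs.
Region-level sharing is looser than probe-level (77.9% of CpG islands are
single-tissue versus 85.3% of probes) because an island is "shared" as soon
as any of its probes is called in another tissue. Per-stage tables (aDMP
calls, specificity, overlap matrices, enrichment) are written under
`demo_run/`.

The same stages are available from the shell:

```bash
admp-atlas simulate --config config.yaml --out run --seed 7
admp-atlas call --betas run/synthetic/brain_betas.tsv \
    --meta run/synthetic/brain_meta.tsv --tissue brain \
    --slope 2.0 --pbonf 0.05 --mode dual --out run/brain_admps.tsv
admp-atlas run --config config.yaml --seed 7
```

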