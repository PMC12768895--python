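# plasmacna

Copy-number aberration analysis of low-pass whole-genome sequencing (LP-WGS)
of plasma cell-free DNA, plus a synthetic cohort simulator for testing every
stage without real patient data.

Pipeline stages:

1. **genome** — hg19-like binned coordinate frame (200-kb bins, chromosome-arm
   labels; autosomes by default).
2. **coverage** — read/bin counting (SAM/BAM or bin-count TSV), per-sample
   depth normalization, a control-panel baseline (per-bin mean/SD with a
   usability mask), and per-bin Z-scores
   `z = (norm − mean_controls) / sd_controls` plus log2 ratios.
3. **segment** — from-scratch circular binary segmentation: maximal circular
   two-sample t-statistic, permutation significance at p < 0.05 (seeded,
   with statistically safe sequential stopping), recursive splitting, and a
   standard-error-scaled merge-undo. numba-accelerated with a numpy fallback.
4. **tfx** — tumor DNA fraction (TFx) from segment-level CNA burden: a
   diploid/tumor mixture grid search over fractions with integer copy states,
   per-segment penalties calibrated so flat genomes estimate exactly 0, and a
   0.2% detectability threshold.
5. **scars** — HRD score as the count of large genomic alterations (LGAs):
   copy-level breaks between adjacent same-arm segments, both flanks ≥ 10 Mb.
6. **diagnostics** — arm-level aberration calls (Stouffer-aggregated Z at
   |Z| ≥ 3), Wilcoxon rank-sum / signed-rank comparisons, ROC with the
   Mann-Whitney AUC identity and stratified bootstrap CI, Youden-index
   cutoffs, and confusion-matrix metrics (sensitivity/specificity/PPV/NPV/
   accuracy).
7. **simulate** — negative-binomial bin counts with shared per-bin bias,
   tumor/diploid mixtures at arbitrary tumor fraction, neuroblastoma-typical
   event presets (17q/7/2p gains, 1p/3p/11q/14q losses, focal high-copy 2p
   amplification, hyperdiploid trisomies), and paired pre/post-chemotherapy
   cohorts.
8. **pipeline / cli** — end-to-end orchestration with YAML config, decision
   flags (follow-up when TFx ≥ 0.2% AND an arm |Z| ≥ 3), and a run manifest
   with digests for reproducibility.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property/invariant tests, and
`tests/test_acceptance.py` with simulation-based end-to-end criteria
(a few minutes of compute). One breakpoint-localization test documents a
target that exceeds the information-theoretic limit of changepoint
estimation at its stated signal-to-noise and is expected to fail; the
comment above it explains the bound.

## CLI

```bash
plasmacna simulate --preset-cohort demo --out data/ --seed 7   # cohort TSVs + truth
plasmacna normalize --controls 'data/control_*.counts.tsv' \
    --sample data/nb_a.counts.tsv --out norm/
plasmacna segment --input norm/nb_a.counts.ztable.tsv --out segs.tsv \
    --alpha 0.05 --n-perm 1000 --seed 7
plasmacna tfx --segments segs.tsv --out tfx.json
plasmacna hrd --segments segs.tsv --min-size 10000000
plasmacna classify --cohort run/results.tsv --out perf/ --seed 7
plasmacna run --out run/ --seed 7          # full demo pipeline
plasmacna report --results run/results.tsv --out report/
```

Exit codes: 0 success, 2 validation problem, 3 runtime failure.

## Library example

```python
import numpy as np
from plasmacna import genome, simulate, coverage, segment, tfx, scars, diagnostics

kt = genome.load_default_karyotype()
bins = genome.make_bins(kt, 200_000)

bias = simulate.draw_bias(len(bins), 0.1, np.random.default_rng(0))
controls = [
    coverage.depth_normalize(
        simulate.simulate_sample(
            simulate.SimSampleSpec(sample_id=f"hc{i}", seed=i), bins, bias)[0])
    for i in range(11)
]
baseline = coverage.build_baseline(controls)

spec = simulate.SimSampleSpec(sample_id="tumor", tumor_fraction=0.2,
                              events="nb_17q_1p", seed=99)
profile, truth = simulate.simulate_sample(spec, bins, bias)
zp = coverage.zscore(coverage.depth_normalize(profile), baseline)

segs = segment.segment_profile(zp, bins, segment.SegmentationParams(seed=1))
est = tfx.estimate_tfx(segs)            # ~0.20
score = scars.lga_count(segs, kt)       # LGA/HRD score
calls = diagnostics.arm_calls(zp, bins) # 17q gain, 1p loss, ...
```
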