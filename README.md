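# danseq

Analysis pipeline for lateralized SNc dopamine-neuron activity during
single-forelimb lever-press sequences.

## Scientific problem

Dopaminergic neurons of the substantia nigra pars compacta (SNc) are thought
to carry movement-related signals that are lateralized — stronger for
movements of the forelimb contralateral to the recorded hemisphere — and to
scale with movement vigor. Testing this requires a task in which mice produce
self-paced press *sequences* with one forelimb at a time (a fast fixed-ratio
schedule: 4 presses within 1 s earn a reward), simultaneous single-photon
calcium imaging of SNc neurons, and a set of analyses that:

1. segment presses into sequence bouts from snout-ROI occupancy and compute
   session-level behavior metrics;
2. classify each neuron from peri-event time histograms (PETHs) into
   movement-initiation, execution, reward, and magazine-approach classes with
   a consecutive-bin percentile rule;
3. re-identify the same cells across days from ROI centroids and quantify
   the functional stability of matched pairs against shuffle and
   different-cell controls;
4. test population-level laterality (class proportions and peak amplitudes,
   contra vs ipsi), sequence-length coding (per-neuron Spearman and a
   population linear-trend contrast across grouped lengths), and
   movement/reward population overlap against independent-membership chance;
5. quantify the behavioral effect of a unilateral dopamine depletion
   (before/after × forelimb repeated-measures ANOVA on sequence length).

The package implements these analyses plus a synthetic-data generator that
emulates the full study design with known ground truth, so every statistical
claim can be exercised end to end (parameter recovery, power, and
false-positive calibration). See `docs/methods.md` for the model and all
parameter calibrations.

## Worked example

Simulate the default cohort (6 mice, 101 neurons, one session per forelimb),
classify every neuron, and run the population statistics:

```python
from danseq import default_paper_config, run_pipeline, report_frame

report = run_pipeline(default_paper_config(), seed=0,
                      stages=("behavior", "classify", "population"))
print(report_frame(report).to_string(index=False))
```

Output (≈10 s on one CPU):

```text
     stage                     statistic     value            p
  behavior     mean_presses_per_sequence  4.057262          NaN
  behavior                      mean_ipi  0.313656          NaN
  behavior                 mean_ipi_fano  0.029422          NaN
population             fraction_movement  0.356436          NaN
population               fraction_reward  0.242574          NaN
population    fraction_magazine_approach  0.178218          NaN
population proportion_contrast_statistic  1.018111 3.553320e-01
population  amplitude_contrast_statistic  3.949910 1.841566e-04
population             overlap_statistic  9.000000 1.000000e+00
population   length_proportion_statistic  5.120000 1.906030e-02
population length_trend_contra_statistic 28.393374 2.482943e-07
population   length_trend_ipsi_statistic  0.370640 5.433330e-01
```

This single synthetic cohort reproduces the qualitative findings the
analyses target: movement-initiation neurons are common (planted fraction
0.39); their peak pre-press amplitudes are higher for contralateral
sequences (unpaired t = 3.95, p < 0.001) while per-mouse proportions are
not reliably asymmetric; the movement/reward overlap is consistent with
independent membership (p = 1.0); and sequence-length coding is
contralateral-specific — the population linear trend across length groups
is strong for contra (F = 28.4) and absent for ipsi (F = 0.37).

The same stages run from the command line on files:

```bash
danseq simulate --out cohort/ --seed 0        # events, traces, ROIs, truth
danseq segment  --events cohort/events.csv --manifest cohort/manifest.csv --out seg/
danseq classify --traces-dir cohort/ --events cohort/events.csv \
                --manifest cohort/manifest.csv --out cls/
danseq match    --rois cohort/rois.csv --out matches.csv
danseq run      --seed 0 --out report/        # full pipeline + flat report
```

`danseq simulate --config config.yaml` accepts YAML overrides for any
`SimulationConfig` field.

## Layout

```
src/danseq/
  stats.py       statistical primitives (t tests, exact Spearman, Fisher
                 exact, RM-ANOVA 2x2, trend contrast, Fisher-Z, overlap test)
  behavior.py    event logs, bout segmentation, reward rule, session metrics
  neural.py      trace z-scoring, PETHs, modulation rule, neuron classes
  roi.py         cross-session centroid matching and stability controls
  population.py  proportions, laterality, length coding, overlap
  lesion.py      before/after x forelimb depletion contrast
  simulate.py    synthetic cohorts and fast calibration samplers
  pipeline.py    stage orchestration and flat reporting
  cli.py         click-based command line (danseq ...)
docs/methods.md  model, calibrations, numerical conventions
scripts/acceptance.py  seeded recomputation of headline quantities
tests/           unit + acceptance suites
```
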