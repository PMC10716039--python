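# Methods

This note documents the models implemented in `probepanel`, the defaults
and why they hold, the synthetic-data generator's scope, and the numerical
and design choices that were genuinely open.

## Signal model and event detection

A trace is a sampled ionic current (pA). The open pore sits at a noisy
baseline; a translocating probe produces a square blockade to a fraction of
the open-pore current; returning to baseline ends the event.

**Baseline tracking.** The trace is cut into windows of
`baseline_window_s` (default 1 s); each window contributes a robust level
estimate, and the per-sample baseline is the linear interpolation through
the window centres. Two safeguards make this robust to heavy blockade
occupancy:

1. *Global reference gating.* Blockades only lower the current, so a high
   trace-wide quantile (97th percentile) sits on the open-pore level. Window
   estimates deviating from it by more than 10% are discarded and bridged by
   interpolation. This saves the rare windows that are ~90% blocked by an
   event cluster, where any per-window statistic fails. Traces with more
   than ~10% slow drift would need the gate disabled
   (`reference_level=0`); drift correction beyond the windowed median is
   out of scope.
2. *Iterated masking.* Detection runs up to three estimation passes: a
   90th-percentile first pass locates candidate blockades; these runs are
   bridged across gaps up to `min_duration_s`, padded by 5 ms, and masked;
   masked medians then give the final baseline and noise. Iteration stops
   as soon as the mask stops growing.

**Noise scale.** `noise_sd` is 1.4826·MAD of the baseline-subtracted,
unmasked samples (the Gaussian-consistent MAD), subsampled above 400k
samples; a naive SD would be inflated by residual event samples.

**Event rule.** An event is a maximal run of samples more than
`k_sigma · noise_sd` *below* baseline (one-sided; blockades are current
drops). `k_sigma` defaults to 35, the midpoint of the recommended 30–40
band; values outside the band warn but are honoured. Runs separated by less
than `min_event_separation_s` (1 ms) are merged, then runs strictly shorter
than `min_duration_s` (100 ms) are excluded — an event of exactly 100 ms is
retained. Whether the cutoff applies to raw or baseline-subtracted current
is not fixed by convention; here the deviation is measured from the tracked
baseline, which is equivalent to thresholding baseline-subtracted current
at −k·σ.

Event samples are normalized by the local baseline mean
(`norm = raw / open_pore_estimate`), giving the unitless scale on which the
delay threshold is defined.

## Delay classification

Each event's normalized samples are partitioned into `n_bins = 75`
contiguous segments whose lengths differ by at most one; bin SDs use
ddof=1. A bin is *quiet* iff its SD is strictly below
`sd_threshold = 0.003`; an event is *delayed* iff the longest run of
consecutive quiet bins strictly exceeds `min_run_bins = 10`. Both strict
inequalities follow the rule's wording; the boundary case (exactly 10 quiet
bins) is not delayed.

Choices worth noting:

- The 0.003 threshold is applied to open-pore-normalized current. The
  alternative readings (pA, baseline-subtracted pA) would make the
  threshold hardware-dependent; normalization makes it portable and is the
  package's central calibration decision. It is exposed as a parameter
  (`--sd-threshold`) for recalibration against real instruments.
- "Moving standard deviation … bins" is implemented as disjoint per-bin SDs
  with runs counted over consecutive bins (the bins are counted discretely).
  A true sliding-window variant (`mode="sliding"`, window = bin width, quiet
  span measured in bin widths) ships behind a flag; the two agree on
  clear-cut events.
- A single-sample bin has no defined variability; its SD is NaN and NaN is
  never quiet. This prevents very short events (bins of one sample, SD
  trivially 0) from being classified as wall-to-wall quiet.

With the simulator's defaults (in-event noise 1.5 pA on a 220 pA open pore
→ normalized SD ≈ 0.0068; sojourn SD 0.001) the rule's operating point is
benign: a 10-sample bin is falsely quiet with probability ≈ 0.3%, so a
false 11-bin run is vanishingly rare, while sojourn bins are quiet with
probability ≈ 1. Measured on 10,000 labeled events, sensitivity and
specificity are both > 99%.

Group comparisons of percent-delayed use Welch's unequal-variance t-test
(the robust default when replicate variances differ); the one-tailed
variant tests for an increase in the second sample. For tiny replicate
counts the Welch p agrees with the exact permutation distribution only to
the granularity of that distribution (1/56 for n = 3 vs 5), which the test
suite asserts explicitly.

## Alignment and the threshold cascade

Reads are aligned to each barcode with unit scoring (match +1, mismatch −1,
gap −1) and **free end gaps on both sequences**: unaligned prefixes and
suffixes of read and barcode cost nothing, gaps inside the aligned span are
penalized. Under unit scores this is realised exactly by the zero-floored
(local-alignment) recurrence with the score read off the best cell. This
mode was chosen over one-sided overlap alignment because (a) base-called
events carry adapter/binding-region sequence beyond the barcode, (b) it
makes the raw score symmetric in its arguments, and (c) it coincides with
exhaustive enumeration over all monotone alignments with free ends — the
oracle the tests check against. The normalized score is
`raw_score / barcode_length ∈ [0, 1]`.

Counts come from the optimal path with deterministic tie-breaking
(diagonal > vertical > horizontal; among equal-scoring end cells the first
in row-major order). `mismatches_total` counts substitutions plus all
in-span gap columns; the first-10-bases window is measured in barcode
coordinates and counts substitutions and read gaps. `N` never matches
anything. The `GGG` prefix criterion is evaluated on the read's first three
called bases, not on the alignment — it is a basecall-quality check.

The cascade evaluates its four criteria independently (no short-circuit)
and accepts on their conjunction. Ties in the best normalized score resolve
to the lexicographically smallest probe id and flag the read ambiguous —
reproducibility over optimism. Because each criterion only removes reads,
adding criteria can only lower the false-positive rate; the suite checks
this over all 16 criterion subsets.

ROC curves threshold the normalized score over a grid (default: every
distinct score); AUC is trapezoidal with (0,0) and (1,1) anchors, verified
against scikit-learn.

## Quantification

The standard curve is the Hill equation with n_H fixed at 1 (first-order
binding): `D(C) = B0 + Vmax·C/(Kd + C)`, with B0 the percent delay at zero
analyte, Vmax the saturating rise (percentage points), Kd the
half-saturation concentration (nM). Fitting uses bounded least squares
(`Kd > 0`, `0 ≤ Vmax, B0 ≤ 100`) with initializer Vmax₀ = span of the data,
Kd₀ = concentration nearest the half-rise, B0₀ = minimum delay. When a
0 nM standard exists B0 is a free parameter; otherwise it must be supplied.
R² = 1 − SS_res/SS_tot is reported on the [0, 1] scale. Flat data fit
Vmax = 0 with a warning; non-convergence raises with residual diagnostics.

Inversion is closed-form, `C = Kd·(D−B0)/(Vmax−(D−B0))`. The curve is
treated as calibrated only within the fitted concentration range:

- readings below B0 clamp to 0 nM (a blinded sample may contain none of an
  analyte);
- readings at/above saturation, or inverting beyond the top standard,
  report the top of the calibrated range (`saturated` / `above_range`
  flags). Near saturation dD/dC → 0 and the inverse is numerically
  explosive; a one-SE noise excursion would otherwise turn a top-standard
  sample into an arbitrarily large estimate. Reporting "at least the top
  standard" is the standard-curve convention adopted here.

Sequence similarity (for the selectivity expectation mask) is
100 · matches / longer-length, with matches taken from the optimal global
alignment under unit scoring; among equal-scoring alignments the one with
most matches is used (the DP carries (score, matches) lexicographically,
exact for additive objectives). Selectivity classification calls a
probe–analyte pair positive at p ≤ 0.01 (raw p-values, mirroring the
single-threshold readout; Benjamini–Hochberg is available but off by
default) and expects positives exactly where similarity ≥ 90% (self-pairs
always expected); TP/FP/FN/TN are reported as percentages of all n² cells.

## The synthetic-data generator

The generator emulates what the analysis chain consumes, not pore physics:

- Open-pore baseline 220 pA with 1.5 pA Gaussian noise at 1 kHz.
- Blockades to 30% ± 2% of open pore, arriving as a Poisson process at
  2 /s of open-pore time; durations normal(300 ms, 60 ms) floored at
  160 ms. The floor keeps every retained event ≥ 160 samples so all 75 bins
  hold ≥ 2 samples; the arrival rate puts event occupancy near one third,
  which deliberately stresses the baseline tracker.
- Delay sojourns: one contiguous segment per delayed event, normalized SD
  `delay_sd_frac = 0.001`, length uniform in 20–60% of the event, start
  uniform within the middle 80% so binning always captures it. The per-event
  delay probability is the Hill occupancy
  `(B0 + Vmax·C/(Kd+C))/100`; defaults Kd = 1.09 nM, Vmax = 38.69,
  B0 = 12.32 — the multiplexed-scale dose–response regime — overridable per
  probe.
- Spurious sub-100 ms blockades (50–99 ms uniform, probe-less) superposed
  at 0.1 /s to exercise the duration filter boundary.
- Basecalls: one read per event; substitution rate linear in position from
  1% (5′) to 15% (3′) — a linear profile is the simplest shape consistent
  with a 5′-better-than-3′ accuracy gradient — plus symmetric
  insertion/deletion at 1% total. The indel profile of real basecallers is
  uncharacterized here; 1% symmetric is a free-parameter choice. Spurious
  events yield uniform-random sequence, providing realistic cascade
  negatives. Qualities are derived from the local substitution rate.
- Seeding: one master seed; per-trace and per-read substreams derive by
  SHA-256 hashing of string ids, so adding a probe or trace never
  reshuffles the draws of others, and all outputs are bit-reproducible.

What it does **not** emulate — and hence what passing tests do not show
about real data: sequence-dependent k-mer current levels (blockade depth is
sequence-independent by default), motor-protein dwell-time variation
within events, pore fouling/blockage, open-pore drift, serum matrix
effects, and analyte-class-specific signal differences (proteins and small
molecules are modeled identically to miRNA through their occupancy
parameters). The delay rule's thresholds would need recalibration on real
instruments precisely because these features are absent.

## Evaluation studies and problem sizes

`probepanel.study` packages three deterministic benchmarks (all sizes are
the package's chosen defaults, balancing statistical resolution against a
single-CPU run):

- *Delay classifier*: 10,000 standalone labeled events at p(delay) = 0.5;
  reports sensitivity/specificity.
- *Event filter*: 3 traces × 600 probe events salted with spurious
  blockades; reports ≥150 ms recall (at ≥90% interval overlap) and the
  count of retained sub-100 ms events.
- *Blinded quantification*: 40 probes; standard curves from multiplexed
  runs at {0, 0.25, 1, 3, 10, 20} nM with 300 events/probe/concentration;
  a blinded run with per-probe concentrations log-uniform in 0.25–20 nM and
  700 events/probe; the whole chain (simulate → detect → demux → delay →
  fit → predict) runs end to end. ~300 events per probe puts the
  percent-delay standard error near 2 percentage points, which is what the
  curve fits and the order-of-magnitude prediction check need; the blinded
  run uses more events because inversion is least stable near the range
  ends.

## Pipeline and reproducibility

The file-based pipeline (`RunConfig` → `run_pipeline`) processes every
sample of a design table through detect → demux → delay → quantify, writes
fixed-column TSVs (`events.tsv`, `demux.tsv`, `delay_calls.tsv`,
`percent_delay.tsv`, `curves.tsv`, `predictions.tsv`), an exclusion log
with one reason-coded row per dropped record, and a JSON run report with
per-stage counts and wall-clock times. Samples with known concentrations
calibrate the curves; samples with blank concentrations are predicted.
Reads are joined to detected events through the ground-truth interval
table — the simulator's stand-in for per-event base calling, which is out
of scope. Config files are YAML (chosen over a bespoke key=value dialect;
round-trip identity holds); all randomness flows from the single config
seed; reruns are byte-identical, and a non-empty output directory is
refused without `force`.

## Known limitations

- The baseline tracker assumes blockades are downward and open-pore level
  is within ±10% of the trace-wide 97th percentile; strong drift breaks
  the gate (disable via `reference_level=0`).
- Demultiplexing requires base-called reads; signal-space (basecall-free)
  matching is out of scope.
- Translocation duration is reported but never used for delay calling —
  the classifier rests entirely on the moving-SD rule, by design.
- `n_H` is fixed at 1 by default; cooperative binding would need the
  `fix_nH_to_1=False` path, which is fitted but not exercised by the
  default studies.
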