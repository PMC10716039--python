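# probepanel

Analytics for highly multiplexed nanopore sensing with barcoded molecular
probes. A probe is a DNA construct — adapter, a unique 35-base barcode
beginning `GGG`, and a target-binding region (a complementary sequence for a
miRNA, or an aptamer for a protein or small molecule). When a probe
translocates a nanopore it produces a current blockade event; if its analyte
is bound, translocation stalls and the event contains a low-variance
"delay" sojourn. Sequencing the barcode identifies *which* analyte a probe
targets; the fraction of delayed events measures *how much* of it is
present.

The package implements the full analysis chain for such experiments, for
people building or evaluating probe panels:

- **Event detection** — baseline tracking on the raw current trace, a
  k·σ cutoff (default 35, recommended range 30–40), and exclusion of
  blockades shorter than 100 ms.
- **Barcode demultiplexing** — free-end-gap alignment of base-called reads
  against the barcode library with a four-criterion threshold cascade:
  ≤ 5 total mismatches, ≤ 1 mismatch in the first 10 barcode bases,
  ≥ 15 aligned bases, read starts with `GGG`. ROC/AUC and confusion-matrix
  evaluation included.
- **Delay classification** — each event's normalized signal is split into
  75 bins; the event is *delayed* iff the per-bin SD stays below 0.003
  (fraction of open-pore current) for a run of more than 10 consecutive
  bins. Welch t-tests compare percent-delayed between conditions.
- **Quantification** — percent delayed D versus concentration C follows the
  Hill equation with n_H = 1,

  ```
  D(C) = B0 + Vmax · C / (Kd + C)
  ```

  fitted per probe by least squares and inverted,
  `C = Kd·(D−B0)/(Vmax−(D−B0))`, to predict unknown concentrations.
  Selectivity is scored per probe–analyte pair: a significant rise in
  percent delay (p ≤ 0.01) is *expected* exactly where target sequence
  similarity is ≥ 90%.
- **Synthetic data** — a simulator that generates barcode libraries, raw
  traces with Poisson-spaced blockades and labeled delay sojourns,
  sub-100 ms spurious blockades, and base-called reads whose substitution
  rate rises from the 5′ to the 3′ end. Every downstream stage is testable
  against known ground truth without instrument data.

## Worked example

`examples/04_delay_and_quantification.py` simulates events at five
concentrations, classifies delays, fits the standard curve, and quantifies
an "unknown" sample:

```
  0.00 nM -> 12.75% delayed (occupancy model: 12.32%)
  0.25 nM -> 22.25% delayed (occupancy model: 19.54%)
  1.00 nM -> 33.25% delayed (occupancy model: 30.83%)
  3.00 nM -> 40.00% delayed (occupancy model: 40.70%)
 10.00 nM -> 48.25% delayed (occupancy model: 47.21%)

Hill fit (n_H=1): Kd = 0.88 nM, Vmax = 36.9%, B0 = 13.2%, R^2 = 0.993
(simulator truth: Kd = 1.09, Vmax = 38.69, B0 = 12.32)

unknown sample: 37.00% delayed -> 1.59 nM estimated (true concentration 2.00 nM)
```

Each line pairs the observed percent-delayed (400 events) with the binding
occupancy the simulator drew from; the fitted Kd/Vmax/B0 recover the
generating parameters to within sampling noise, and inverting the curve
places the unknown within a factor of ~1.3 of truth at this event count.

The other examples cover library design and simulation (`01`), event
detection against ground truth (`02`), demultiplexing and the cascade
(`03`), and the file-based pipeline with its TSV outputs (`05`). The same
pipeline is scriptable from a shell:

```bash
probepanel simulate --out exp --n-probes 8 --seed 1
probepanel run --config exp/config.yaml
```

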