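# censtab

Quantification toolkit for centromere-stability assays: the bespoke
measurements used to study how homologous-recombination factors (BRCA2,
PALB2, RAD51) protect centromeres and keep chromosomes from being lost.

It is written for bench scientists and image analysts who run these assays
and want the quantification scripted, seeded and testable instead of living
in interactive point-and-click image- and flow-analysis sessions:

* **HAC-loss rate** — a human artificial chromosome (HAC) carrying a
  destabilized GFP reporter is lost at some probability per division;
  comparing the GFP+ fraction of live cells before (P0) and after (P_si) a
  treatment over n divisions gives the per-division loss rate

      R = 2 − 2 · (P_si / P0)^(1/n)

* **Division index (DI)** — n is estimated from a dye-dilution assay: a
  proliferation dye halves per division, so log-fluorescence is a mixture of
  equally spaced peaks (peak ratio 0.5). A constrained mixture fit (peak
  positions and width fixed, generation weights free) yields
  DI = Σ g·(w_g/2^g) / Σ (w_g/2^g) (precursor-weighted; event-weighted
  Σ g·w_g also available).

* **Median-focus FISH/IF quantification** — per cell, fixed-size boxes
  around detected foci are reduced to a pixel-wise *median focus*; the
  median of its outer ring estimates background, and the background-
  subtracted sum is one robust per-cell signal capturing both focus
  intensity and size. Anchored mode defines boxes on a reference channel
  (e.g. CENP-B) and quantifies other channels (e.g. CENP-A) in the same
  boxes.

* **3D volume-overlap colocalization** — Otsu nuclear segmentation,
  max-Z individualization, reason-coded QC (edge, area > 300 µm², manual
  flags), seeded selection of 100 nuclei per condition, seeded-region-
  growing spot segmentation, and object-based scoring of each reference
  focus by the fraction of its volume overlapped by a partner focus
  (events < 10% discarded as false positives).

* **Colony counting** — particle analysis on thresholded 8-bit plates with
  a 0.01–1.00 circularity filter (4π·area/perimeter²) that drops scratches
  and streaks.

A first-class synthetic-data module generates every input the pipeline
consumes — 2D focus fields, 3D stacks with engineered overlap fractions,
dye-dilution and GFP/viability flow tables, colony plates — with exact
ground truth, so the whole pipeline is testable with no raw data.

## Worked example

```python
import numpy as np
from censtab import synthetic as syn, hacloss

# simulate a control-like dye-dilution experiment (true DI = 3.33)
spec = syn.DyeDilutionSpec.from_division_index(3.33, n_events=10_000, cv=0.10, seed=1)
events, truth = syn.make_dye_dilution(spec)
reference, _ = syn.make_dye_dilution(
    syn.DyeDilutionSpec(n_events=10_000, cv=0.10, generation_weights=(1.0,), seed=2))

fit = hacloss.fit_dye_dilution(events, reference, n_peaks=7)
print(fit.summary())

# GFP-reporter flow: baseline vs treated
base, _ = syn.make_hac_flow(syn.HacFlowSpec(gfp_positive_fraction=0.90, seed=3))
treated, _ = syn.make_hac_flow(syn.HacFlowSpec(gfp_positive_fraction=0.60, seed=4))
p0 = hacloss.gfp_positive_fraction(hacloss.gate_live(base))
p_si = hacloss.gfp_positive_fraction(hacloss.gate_live(treated))
print(hacloss.hac_loss_rate(p_si, p0, fit.division_index().value).summary())
```

prints

```
Dye-dilution halving-peak mixture fit
==============================================
events:            10000
peaks (G+1):       7
peak ratio:        0.500
log anchor mu0:    10.8184
log sigma (fixed): 0.0988
log-likelihood:    2039.86
EM iterations:     7 (converged)
----------------------------------------------
gen   weight    peak mean (a.u.)
  0    0.0000        49932.7
  1    0.0000        24966.4
  2    0.0000        12483.2
  3    0.4998         6241.6
  4    0.5002         3120.8
  5    0.0000         1560.4
  6    0.0000          780.2
----------------------------------------------
DI (precursor-weighted): 3.3335
DI (event-weighted):     3.5002

P0 = 0.9005, P_si = 0.6014, n = 3.334 divisions
rate of HAC loss R = 0.228085 per division
```

The fit puts the population in generations 3–4 (weights ≈ 0.5/0.5), whose
precursor-weighted mean recovers the simulated DI = 3.33 to 0.001. With the
GFP+ fraction dropping from 0.90 to 0.60 over 3.33 divisions, the HAC is
lost in about 23% of divisions — a strongly destabilized state (a stable
line shows R in the low percent range).

The imaging side works the same way from the shell:

```
censtab simulate --what coloc --seed 8 --outdir out
censtab coloc --seed 8 --outdir out       # events, per-nucleus and summary CSVs
censtab simulate --what colonies --seed 5 --outdir out
censtab colonies --seed 5 --outdir out    # "colonies: 10"
```

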