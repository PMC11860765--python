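# Methods

This note documents the models and numerical conventions behind `censtab`,
the assumptions its synthetic data make, and the design choices taken where
the underlying assay descriptions left the details open.

## 1. Rate of HAC loss

A human artificial chromosome (HAC) carrying a destabilized GFP reporter is
non-essential: a cell that loses it survives but turns GFP-negative. If the
HAC is lost with probability R per division, then after n divisions the
GFP+ fraction decays from P0 to

    P_si = P0 * (1 - R/2)^n,   hence   R = 2 - 2 * (P_si / P0)^(1/n).

(The factor 2 reflects that a missegregation event at mitosis deprives one of
the two daughters of the HAC.) The function `hacloss.hac_loss_rate` evaluates
the closed form; it satisfies R = 0 exactly at P_si = P0, R → 2 as P_si → 0,
and is strictly decreasing in P_si. P_si > P0 is allowed but flagged (a
formally negative rate; in practice measurement noise). Inputs may be
fractions or percentages — the ratio P_si/P0 is scale-invariant, and mixed
scales are rejected.

GFP+ fractions are computed among *live* events only: the viability dye
(DRAQ7/DAPI-like) enters dead cells, so live events are those below a
viability threshold. When no threshold is given, the valley of a
two-component Gaussian mixture in log10 intensity is used, mimicking the
valley gates drawn by hand in flow software. Gating always partitions the
table: live + dead = total.

## 2. Division index from dye dilution

A proliferation dye halves per division, so log-fluorescence is a mixture of
equally spaced normal peaks: generation g has mean mu0 + g·log(r) with peak
ratio r = 0.5 and a common SD sigma. `DyeDilutionModel` fixes sigma from the
log-domain SD of an undivided reference population, fixes the peak spacing,
and fits only the generation weights w_g (EM over the simplex — a concave
subproblem) plus a refinement of mu0 within ±0.5·sigma of the reference
mean (its M-step is the responsibility-weighted mean, clipped). Events are
sorted before fitting, so the fit is exactly invariant to event order. The
default is 7 peaks (generations 0–6); 6–8 is the conventional range.

Two division-index conventions are exposed, because the fitted w_g count
cells *present at analysis* while later generations are overrepresented by
their 2^g-fold expansion:

* event-weighted: DI = Σ g·w_g
* precursor-weighted: DI = Σ g·(w_g/2^g) / Σ (w_g/2^g)  (default)

The precursor-weighted form is the convention of common proliferation-fit
software and is the package default; both coincide for a synchronously
dividing population. The synthetic generator records truth under both.

Synthetic dye-dilution events draw a generation from w_g and a log-normal
intensity with sigma = sqrt(log(1+CV²)), CV defaulting to 0.10 — a typical
width for a well-stained undivided population. `DyeDilutionSpec.
from_division_index` places mass on the two generations bracketing the
target DI and solves the two-point identity exactly, so the generated truth
equals the requested DI to machine precision.

## 3. Median-focus quantification

Per cell: threshold the channel inside the nucleus mask, take 8-connected
components of area ≥ `min_area` (default 2 px, suppressing single-pixel
noise), and cut an even-sided square box (10–20 px, default 14) around each
focus centroid. The box convention is pinned: centroid rounded to the
nearest pixel (r, c), box rows r−s/2 … r+s/2−1 (half-open), columns
likewise; boxes crossing the image border are dropped and logged rather
than padded, because padding would bias the ring background. The *median
focus* is the pixel-wise median of the boxes (even counts use the mean of
the two central order statistics); its background is the median of the
outermost 1-px ring (4(s−1) values); the per-cell signal is the sum of the
background-subtracted median focus, negatives retained — subtract-then-sum
with no clamp, so the statistic is exactly invariant to adding a constant
to the whole image. Cells without usable foci are skipped with a reason
code, never imputed.

Anchored mode detects foci on a reference channel only (e.g. CENP-B, which
marks centromeres regardless of treatment) and quantifies every channel in
those same boxes, emitting per-cell ratios such as CENP-A/CENP-B.
Condition normalization divides per-cell values by the mean of the control
condition, which therefore maps to 1 (exactly, up to float summation
order).

The synthetic 2D fields place disjoint circular nuclei (flat background
inside, zero outside) with isotropic Gaussian foci — the diffraction-limited
puncta model — plus additive Gaussian noise clipped at 0. They do not model
a PSF, camera noise statistics, uneven illumination, or clustered/variable
focus morphologies; passing tests demonstrate the *procedure* is correct
and monotone in true amplitude, not that thresholds generalize to any real
microscope's intensity scale (the detection threshold is a free parameter
for exactly that reason).

## 4. 3D volume-overlap colocalization

Nuclei are segmented by a global Otsu threshold (256-bin histogram) on the
DNA channel in 3D; all channels are zeroed outside the mask. Because Otsu
always splits a histogram, a signal-free stack would otherwise yield a
half-volume "nucleus": the mask is kept only when the foreground/background
mean ratio reaches 2, else it is empty. Segmenting an already-masked stack
reproduces the same mask.

Individualization labels the hole-filled max-Z projection (8-connected) and
crops each label's padded (2 px) bounding box across all Z; footprints under
16 px are discarded as threshold specks. Projected area (um²) comes from
the footprint and the lateral pixel size — the projection, not a single
plane. QC exclusions are reason-coded: automatic `edge` (footprint touches
a lateral border; Z truncation is inherent to stacks and not penalized) and
`too_large` (projected area > 300 um², the conventional cutoff for doublets
and spread S-phase nuclei); `mitotic`, `overlapping`, `out_of_focus`,
`apoptotic`, `bad_segmentation` are honored from annotations because they
are human judgments, deliberately not heuristically automated. Cohort
selection shuffles eligible nuclei with a seeded generator and keeps the
first 100 per condition (all, with a warning, when fewer pass).

Spots are segmented by seeded region growing: Gaussian smoothing (sigma
1 voxel default), local maxima above a seed threshold, then growth down to
an include threshold implemented as marker-controlled watershed on the
negated smoothed intensity with full 26-connectivity — contended voxels are
assigned by intensity descent, and spots are disjoint by construction.
Volume bounds discard debris and merged blobs. There are no universal
threshold values; they are tuned per dataset on reference images, so the
synthetic tests pin the pipeline's behavior, not a particular threshold.

Colocalization is object-based: for every reference-channel focus (e.g.
CENP-B or RAD51) and every intersecting partner focus (e.g. Halo-tagged
BRCA2/PALB2), the event's score is |ref ∩ partner| / |ref| — the fraction
of the reference focus volume overlapped. Events under 10% are discarded
as false positives; the boundary is inclusive (exactly 10% is kept, since
only *less than* 10% is excluded). Summaries report the fraction of nuclei
with ≥1 surviving event, mean events per nucleus, the overlap-fraction
distribution, and per-channel focus counts.

Synthetic stacks use the acquisition geometry of a spinning-disk 60x
dataset: 15 Z-sections spanning 10.65 um (0.71 um spacing) and 0.1 um
lateral pixels, both configurable. Nuclei are ellipsoids; spots are
spheres with a logistic intensity edge (half-amplitude exactly at the
nominal radius) so threshold segmentation recovers approximately the true
ball. Engineered overlaps shift the partner sphere laterally in whole
voxels and record the voxel-counted achieved fraction as truth — overlap of
digitized balls is a step function of the shift, so the generator reports
what it achieved rather than pretending to hit an arbitrary target exactly.
Anisotropy matters: with 0.71 um sections, a 0.25 um spot spans one
Z-plane, as in the real acquisition.

## 5. Colony counting

Plates are thresholded (8-bit convention, default 128), 8-connected
components are measured, and circularity 4π·area/perimeter² filters objects
to [0.01, 1.00]. The perimeter estimator is pinned, because circularity
depends on it entirely: the boundary is traced by marching squares at the
0.5 level on the padded mask and polyline lengths summed (holes included) —
the traced-outline convention of particle analysis. Under it a 1-px streak
of length L measures ~2(L+1) (circularity ≈ 0.0031 at L = 1000, excluded)
while a rasterized disk measures close to 2πr (circularity ≈ 0.89–1.0,
kept). Digital circularity of small regular objects can slightly exceed 1,
so the filter tolerates an overshoot of 0.10 above the upper bound; objects
with zero traced perimeter (a single pixel) get infinite circularity and
are excluded.

## 6. Reproducibility and orchestration

Every generator and every stochastic stage is a pure function of its spec
and seed (NumPy `default_rng`); identical config + seed reruns produce
byte-identical CSVs (floats written at 6 significant digits). Runs are
described by a flat key=value config; each stage logs machine-parsable
key=value lines including items in/kept/excluded at every filter, and any
stage failure aborts with the stage name. Significance testing is left out
deliberately: condition tables expose per-replicate means precisely so that
standard tools can run paired tests downstream.

## 7. Problem sizes used in the checks

The bundled checks run at desk scale by choice: division-index recovery
uses 10 simulated experiments of 10,000 events per condition (binomial and
EM error at that size is well under the ±0.05 acceptance band); the
end-to-end colocalization cohort uses 52 nuclei across 13 stacks of
300×300×15 voxels; exo-FISH monotonicity uses three 55-cell fields. These
sizes match or exceed the per-condition cell counts of typical imaging
experiments while keeping the full suite under a minute of compute.

## 8. Known limitations

* The synthetic data are idealized (no PSF, no uneven illumination, no
  autofluorescence, perfectly disjoint nuclei); threshold parameters tuned
  here do not transfer to real images.
* The dye-dilution fit fixes the peak ratio at 0.5; dye efflux or catabolism
  that breaks exact halving would bias DI slightly low or high.
* The valley-based default gates assume clearly bimodal channels; dim
  reporters need explicit thresholds.
* Manual QC criteria are annotation-driven; the package does not attempt to
  recognize mitotic or apoptotic morphology.
* Overlap fractions from segmented spots inherit segmentation error at the
  spot boundary (~1 voxel), so engineered fractions are recovered to within
  a few voxels' worth of volume, while event *presence/absence* — what the
  summaries report — is recovered exactly for well-separated spots.
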