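# Methods

## Scope and coordinate conventions

`puncta` quantifies 2-D fields of view: a nuclear counterstain (DAPI) channel
and one channel per probe, all on a [0, 1] intensity scale, with a known pixel
size in µm. Confocal z-stacks are reduced by per-pixel maximum projection
before analysis. Pixel indices are 0-based (row, col); physical coordinates
use the pixel-centre convention, `x_um = (col + 0.5) · s`,
`y_um = (row + 0.5) · s` with `s` the pixel size (default 0.2 µm/px, matching
a 1024-px field imaged with a 40× objective). Intensity normalization on load
is deliberately conservative: float data already inside [0, 1] is passed
through unchanged so that fixed intensity thresholds mean the same thing in
every field; only out-of-range data (integer camera counts, arbitrary float
scales) is min-max rescaled per channel. Blanket per-field min-max rescaling
would silently redefine the pixel threshold and the 0.15 copy-intensity
criterion on every field and destroy cross-field comparability.

## Nuclear segmentation

Commercial digital-pathology segmenters expose tuning dials without
disclosing the algorithm, so the segmenter here is a standard, reproducible
construction exposing the same six features: global threshold = Otsu ×
(`contrast_threshold` / 0.5) (0.5 is neutral), hole filling, then
marker-controlled watershed on the Gaussian-smoothed Euclidean distance
transform. The h-maxima suppression depth is
`h = max(0.5 px, (1 − aggressiveness) · h_scale_um / s)` with
`h_scale_um = 2 µm`; `aggressiveness = 0` disables splitting entirely (one
object per connected component), and because `h` is non-increasing in
`aggressiveness` the number of segmented objects is monotone non-decreasing
in it. Candidates are filtered on area (default 15–250 µm²), roundness
4πA/P² (default ≥ 0.3; perimeter from the standard weighted contour estimate,
clipped at 1.0 because rasterized disks can exceed the continuum bound by a
percent), and mean counterstain intensity (default ≥ 0.05). The numeric
filter defaults are configuration, not algorithm: the source workflow tuned
them interactively per batch. Ids are assigned in row-major centroid order so
re-runs are stable.

## Puncta detection and copy decomposition

Candidate spot pixels are those above the effective pixel threshold
`max(pixel_intensity_threshold, median + 3 · 1.4826 · MAD)` of the channel;
the robust floor keeps detection stable if a channel's noise scale shifts,
and on the default synthetic conditions it coincides with the configured
0.05. Components may be split by a watershed seeded at h-maxima of intensity
(depth `(1 − spot_aggressiveness) · split_depth`, defaults 0.5 and 0.2);
components below the minimum signal area, 0.45 µm², are discarded.

Per spot we record the thresholded footprint area, the raw peak intensity,
and the background-subtracted integrated intensity measured over the
footprint dilated by 2 px — the thresholded footprint alone captures only
~70 % of a diffraction-limited Gaussian's flux, and the dilation ring (which
never eats into other spots' cores) recovers the wings; background is the
median intensity outside all (dilated) spot masks. Copy counting follows the
cluster rule: a spot whose raw peak is at or below the copy intensity
threshold (default 0.15) is a physically separated punctum and counts as one
copy; above it, the spot is a cluster contributing
`round(integrated / unit)` copies, rounded half away from zero and floored
at 1. The unit copy intensity is the median integrated intensity of the
isolated (below-criterion) puncta in the same field — the internal positive
controls; at least 5 are required, otherwise the per-probe unit must be set
in the configuration. Applying the 0.15 criterion to the *peak* (rather than
mean or integrated) intensity is a documented assumption; it is the reading
that keeps singles and clusters commensurable.

## Assignment, lineage, binning, scores

Each spot is assigned to the nucleus with the nearest centroid (Voronoi
rule; exact ties to the lowest id) iff that distance is ≤ 25 µm — about the
soma diameter of the largest cortical neuron; otherwise it is excluded from
scoring. A cell is positive for a lineage when its marker-probe count is
≥ 2; cells positive for more than one marker are labelled `multiple` and are
excluded from lineage-restricted scores (the underlying workflow never
defines this case), and cells positive for none are `unclassified`.

Test-probe counts map to classes via half-open intervals at the copy minima
{1+: 1, 2+: 4, 3+: 10, 4+: 16} (class 0 ⇔ 0 copies; the half-open reading is
the only one consistent with all four minima). The H-score over a chosen
denominator cell set is `Σ_k k · %(class k)`, k = 1..4, hence 0–400. The
denominator is configurable — `all`, `probe_positive` (default, matching how
per-probe scores are usually reported) or `lineage:<label>` — because
published usage mixes them. Sample-level scores pool cells across the
sample's fields before scoring (the H-score is defined over the entire area
analysed), rather than averaging per-field scores.

For probes too abundant to resolve single puncta the intensity mode reports
total above-background channel intensity divided by the number of
lineage-positive cells. With an explicit background it is the plain clipped
sum (exactly linear in signal); with background self-estimated it sums
`value − median` over pixels above `median + 4 · MAD-sigma`, in components of
≥ 3 px, dilated by 2 px — a plain above-median sum over a 1-Mpx field would
be dominated by noise, and a 3σ cut still leaves a double-digit-percent bias
from isolated noise pixels.

## Statistics

Small-group comparisons use an exact two-sided Mann-Whitney U: pooled
observations get mid-ranks, U is computed for every one of the
C(n_a + n_b, n_a) group assignments, the one-sided tail at least as extreme
as observed is doubled and capped at 1. Exact mode is automatic for
n_a + n_b ≤ 12 (so 4-vs-4 complete separation gives p = 2/70 ≈ 0.0286);
larger problems use the tie-corrected normal approximation. Pearson
correlation reports r and the two-sided p from t = r·√((n−2)/(1−r²)) against
Student-t(n−2). The outlier filter removes values beyond 1.5 × IQR outside
Q1/Q3 with type-7 (linear-interpolation) quartiles, in a single pass with
fences computed once on the input; the 1.5 multiplier is exposed in the API
because the conventional "extreme" fence is 3 × IQR, but 1.5 is implemented
as the workflow states it. Fewer than 4 values pass through unchanged with a
warning.

## Synthetic fields

The generator emulates the study conditions: 1024 × 1024 px at 0.2 µm/px,
20 nuclei of radius 3–5 µm (non-overlapping by rejection sampling, rendered
as mildly eccentric ellipses with per-nucleus brightness 0.5–0.8 and light
smoothing), one probe with every cell positive at a mean of 5 copies,
constant background 0.02, Gaussian noise σ = 0.01, all channels clipped to
[0, 1]. Copies per positive cell are 1 + NB(mean − 1, dispersion 4) — the
true per-cell copy distribution is unknown, so the negative-binomial form is
an explicit modelling choice flagged in the configuration. Copies are
deposited as single puncta or, with probability 0.3 per batch, as cluster
sites of 2 + Poisson(1.5) copies; every site is a sum of unit Gaussians
(σ = 0.3 µm, integrated intensity exactly `copies × unit_copy_intensity`
with `unit_copy_intensity = 1.5`, so a single punctum peaks near 0.13 — below
the 0.15 cluster criterion — and clusters above it). Owned sites are placed
uniformly within 6 µm of the owner nucleus centroid: within the hard 25 µm
cap required for consistency with the assignment rule, and tight enough to
reflect the perinuclear signal concentration seen in tissue. Optional
extras: unowned stray spots, and large (≫ 0.45 µm²) dim autofluorescent
blobs in one configurable channel emulating aggregate-rich (e.g. green)
channels. Everything drawn is recorded in the ground truth, with the
invariant that spot copies per (cell, probe) sum to the cell's recorded
total.

What the generator does **not** emulate: 3-D structure (beyond what maximum
projection would remove), realistic PSFs (no Airy rings), uneven
illumination, tissue autofluorescence texture, chromatin substructure,
touching/overlapping nuclei, or cytoplasmic segmentation targets. Passing
the ground-truth recovery tests therefore demonstrates the pipeline's
internal consistency under idealised imaging, not its performance on real
tissue, where the tunable parameters exist precisely because these effects
vary.

## Degradation model

Probe detectability under RNA fragmentation is modelled at probe-pair
granularity: `n_pairs` (default 20) sites, breaks at the `n_pairs − 1`
junctions only, Poisson(`expected_breaks`) breaks per molecule placed
uniformly with replacement, detectable iff some fragment keeps
≥ `min_intact_run` (default 3) consecutive sites. Two exact companions to
the Monte-Carlo simulator serve as independent cross-checks: exhaustive
enumeration over junction placements for a fixed break count, and a
closed-form mixture using the observation that Poisson breaks thinned over
junctions make each junction an independent Bernoulli(1 − e^(−λ/J)) cut,
after which a run-length recursion gives the exact detectable probability.
Base-pair-resolution breakage and probe-binding kinetics are out of scope.

## Problem sizes and numerical notes

Tests and the acceptance script run on one 1024² default field (shared as a
session fixture), 256² fields for pipeline bookkeeping, 10⁵ molecules per
Monte-Carlo point, 100 random layouts for assignment-oracle equivalence, and
full enumeration for all exact statistics — sizes chosen so the whole suite
completes in well under a minute after the shared field is built. Numerical
choices worth knowing: rounding of cluster copies is half-away-from-zero;
assignment ties are exact float equality (by construction in tests);
watershed depth floors at 0.5 px to avoid fragmenting on distance-transform
plateaus; empty images, empty masks, empty groups and empty denominators all
raise `ValueError` rather than returning degenerate scores; calibration with
fewer than 5 isolated puncta raises a dedicated `CalibrationError`
instructing manual unit configuration.

## Known limitations

- 2-D only; puncta from out-of-plane cell processes are mis-attributed or
  dropped exactly as in any single-plane analysis.
- The segmenter is a disclosed stand-in with the same tuning surface as the
  commercial tool, not a reimplementation of it; absolute parameter values
  do not transfer.
- H-scores of highly expressed probes saturate once single puncta merge
  (use the intensity mode); sparsely expressed probes suffer field-selection
  bias that no per-field score can remove.
- The exact Mann-Whitney enumerates C(n_a + n_b, n_a) arrangements and is
  intended for the small cohort sizes it defaults to (≤ 12 pooled).
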