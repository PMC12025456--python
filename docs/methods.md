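# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the `fenestra` package. Units
are nm, pN, and Pa internally (1 Pa = 10⁻⁶ pN/nm²); spring constants are
consumed in N/m as instrument metadata and converted at the boundary.

## Contact mechanics (`mechanics`)

Approach curves only are analyzed; retract branches (adhesion,
viscoelastic hysteresis) are out of scope. The indentation is
δ = (z − z_c) − F/k, clipped at zero before contact.

Two indenter laws are provided. The sphere law is the Hertz form
F = (4/3)·E/(1−ν²)·√R·δ^{3/2}; its closed-form inverse is used for the
imaging-depth sanity check (100 pN / 0.8 kPa / 20 nm tip → ≈0.63 µm,
i.e. 0.6 µm at one decimal). The pyramid law uses the four-sided-pyramid
prefactor 0.7453·tanθ·E/(1−ν²)·δ²; the constant is stored on every fit
result so a different convention can be audited or substituted. ν
defaults to 0.5 (incompressible) everywhere, matching the assumption
used both for AFM fits and for the rheological conversion.

**Baseline.** A straight line fitted to the leading fraction (default
30%) of the approach is subtracted. The fraction must be chosen below
the contact point; tall features on short ramps need a smaller fraction.

**Contact point.** Two estimators:

- `threshold` (default): first crossing of n_sigma×(baseline noise SD)
  that persists for m consecutive samples (defaults 3σ, 5 samples). The
  raw crossing is systematically late on compliant samples — the force
  reaches 3σ only after tens of nm of indentation — so the estimate is
  refined by regressing F^{2/3} (linear in z for a Hertz sphere when the
  deflection is small) on the ~25 samples above the crossing and
  extrapolating to zero force. `extrapolate=False` returns the raw
  crossing.
- `residual_search` (the oracle): exhaustive scan of candidate contact
  points, fitting the closed-form least-squares modulus at each. The
  score is evaluated on a *fixed* curve segment — from the ramp start to
  one fit-window depth past the noise crossing — with the baseline
  modelled as zero force. Anchoring the segment to the curve rather than
  to the candidate is essential: a window that slides with the candidate
  lets pre-contact candidates fit pure baseline noise and win.

On noiseless curves the search recovers the contact point to within one
sample spacing; on noisy phantom curve populations the two methods agree
to ≈1 sample spacing in the median.

**Modulus fitting.** E enters both laws linearly, so for a given z_c the
least-squares modulus is closed-form. `fit_apparent_modulus` (and the
vectorised `fit_force_volume`) refine z_c by a local residual-search
grid seeded by the threshold estimate (coarse pass at one sample
spacing, fine pass at 0.2 samples); without this joint z_c/E refinement
the contact-point bias propagates into double-digit modulus errors on
soft pixels. Fit windows are indentation ranges in nm and must be chosen
per regime (e.g. 20–250 nm for the cell phantom, 300–900 nm for soft
gels probed with large spheres, 800–1400 nm for stiff gels); fewer than
8 samples in the window is an error. No finite-thickness
("bottom-effect") correction is applied — the modulus is *apparent* by
design.

## Synthetic force-volume phantoms (`synthetic`)

The phantom emulates what a QI scan of a fenestrated cell records:

- substrate plane at height 0 with modulus `substrate_modulus`
  (default 52 kPa, a stiff-gel support);
- an elliptical cell membrane (0.45×field semi-axes) of height
  `cell_height` (400 nm) and modulus `cell_modulus` (8 kPa, the regime
  measured on these cells);
- a flat-topped quartic nuclear dome (`nucleus_height`, `nucleus_radius`)
  whose footprint defines the nuclear-exclusion mask;
- pores of truncated-normal diameter (defaults 200±50 nm clipped to the
  physiological 50–350 nm) placed by rejection sampling inside randomly
  seated elliptical sieve plates, with full rim footprints kept inside
  the cell, outside the nucleus, and non-overlapping. Optional
  `labyrinth_pores` are placed inside the nuclear dome to exercise the
  exclusion rule.

**Per-pixel force law.** Every pixel follows a membrane-over-substrate
composite: Hertz loading of the local membrane, capped at a critical
force, then (once the tip has passed the membrane thickness) Hertz
loading of the substrate in series. Cell pixels have cap =
A·h^{3/2} (no plateau — they simply bottom out, which is why fit windows
stay below ~250 nm); open pore interiors have zero cap (the tip falls
through to the substrate).

**Rim model.** The mechanics of fenestration deformability are not
established; the generator uses a deliberately minimal stand-in. The rim
is an annulus of width w = rim_compliance·r₀ whose collapse force rises
linearly outward, F_crit(r) = F_c·(r−r₀)/w with F_c =
`rim_collapse_force` (400 pN, above the 350 pN imaging maximum). A rim
pixel's curve loads to F_crit, plateaus while the tip passes to the
substrate, then stiffens. Consequently the apparent pore radius at
imaging force F is exactly r₀ + w·clip(F/F_c, 0, 1): non-decreasing in
load, strictly increasing in rim_compliance, identical in fold change
for every pore (since w ∝ r₀), and invertible —
`calibrate_rim_compliance(fold)` = (fold−1)/(t_hi − fold·t_lo) with
t = F/F_c. The reachable fold change is bounded by t_hi/t_lo (≈1.76 for
300/170 pN at F_c = 400 pN). A smooth graded-stiffness rim was evaluated
first and rejected: under the half-depth diameter criterion its
300/170 pN level-set ratio is capped near 1.1, far below the ~1.3–1.45
regime of interest.

The piezo ramp places z_offset = h_max + 0.3·(z_range − h_max), i.e. 30%
of the headroom above the tallest feature is pre-contact baseline and
the rest is post-contact travel; `z_range` is validated against
cell-plus-nucleus height. Forces are solved per sample by vectorised
bisection of the force balance F(δ) = k(s−δ) (monotone on both sides;
48 iterations ≈ 10⁻¹² nm resolution), and Gaussian noise of
`force_noise_sd` (default 15 pN, the tens-of-pN instrument scale) is
added to every sample. Identical specs (including the seed) produce
bit-identical maps. Retract curves, adhesion, creep, and lateral drift
are not simulated.

The hidden `GroundTruth` records the resting height map, modulus map,
masks (cell / nucleus / pore / rim), the pore table with per-load
diameter functions, porosity, and the 300/170 pN enlargement.
`pure_phase_mask` marks pixels whose curve is a single Hertz law — rim
pixels follow the composite law and have no defined single modulus, so
modulus-recovery comparisons exclude them.

**Preset regimes.** `control_like_spec` (~1.5 fen./µm²: 2 plates × 5
pores on a 128² map), `ko_like_spec` (~0.4: 1 plate × 3 pores), and
`deformability_spec` (192² map, 8 larger pores, rim compliance
calibrated to the requested enlargement, default 40%). These presets
*are* the study conditions for the recovery tests; they are not tuned
per run.

**Other generators.** Amplitude sweeps: G′ = plateau below the yield
strain, power-law decay beyond, G″ = loss_factor·G′, multiplicative
Gaussian noise; grids default to 31 log-spaced strains over 0.01–100%.
Nuclei images: non-overlapping disks by rejection sampling (an error
suggests lowering the count when placement is infeasible). Endocytosis
tables: per-well cell-associated and degraded activities with a
3-bioreplicate × 2-technical-replicate six-well default layout.

## QI reconstruction (`reconstruction`)

Height at force F = (z_max − z_cross) + F/k, where z_cross is the first
crossing of F that persists for 2 samples, linearly interpolated between
the bracketing samples. Reporting the *tip* position (deflection added
back) makes rigid and compliant pixels comparable and renders the
monotonicity property exact: since z(F) = z_c + δ(F) + F/k, the height
difference between two forces is just the indentation difference, so
heights can only decrease as load increases. Pixels whose peak force
falls short of the target are masked invalid; above 50% invalid a
warning is logged and the map still returned. Heights carry an arbitrary
global offset (levelling fixes the reference).

## Morphometry (`morphometry`)

**Flattening.** Scan-line levelling in three steps: (1) row offsets
aligned by cumulative medians of row-to-row differences (robust to pores
and to gradually curved cell boundaries, though a full-width abrupt step
would be treated as a scan-line artifact — a known tradeoff of
line-by-line levelling); (2) for order ≥ 1, a per-line polynomial fitted
only to the line's dominant plateau (±40 nm window around the histogram
mode, iterated three times) and subtracted minus its constant, so
multi-level structure cannot tilt the fit, followed by re-alignment of
offsets; (3) the substrate median (the Otsu low cluster, or the global
median if no low plateau exists) set to zero.

**Segmentation.** Cell: largest connected component above a height
threshold, holes filled — the projected area therefore includes sieve
plate holes. The pipeline's automatic threshold is Otsu's; tests show it
recovers phantom cell areas within 3%. Nuclear region: largest component
above a bulge threshold (auto: cell level + 0.3× the bulge amplitude),
morphologically closed; an empty mask is valid (flat cells).

**Pore detection.** Local surface = grey-scale closing wide enough to
bridge the largest admissible pore; candidate pixels are deeper than a
threshold below it (default: half the local membrane height, a relative
criterion that transfers across phantoms), restricted to the cell mask.
Components are filtered by fast-axis diameter (default 50–350 nm, the
fenestration range; widen it for micron-scale hydrogel pores or for
strongly enlarged rims) and circularity (4πA/P² ≥ 0.3). The diameter is
read along the fast axis on the scan line through the component's
centroid — the level-crossing columns are interpolated sub-pixel — at a
configurable criterion: `half-depth` (default; stable under noise
because the pore walls are steep there), `fixed-depth`, or `full-width`
at the detection threshold. The criterion is recorded on every record.
On noiseless single-pore grids the measured diameter is within one pixel
of truth for all diameters in 50–350 nm at 20–27 nm pixels.

**Porosity.** Count of non-nuclear pores over the filled cell area in
µm². Pores whose centroid falls in the nuclear mask are counted
separately as excluded labyrinths; exclusion can only lower porosity.

**Deformability.** Pores from the 170 pN and 300 pN reconstructions of
the same scan are matched greedily by ascending centroid distance
(one-to-one, default radius 3 pixels — order-stable because candidate
pairs are sorted). Each pair's fold change is d_high/d_low; the summary
reports mean ± SD and percent enlargement (mean − 1)×100. Sieve-plate
membership (single-linkage clustering of centroids at 1.5 µm) is
reporting-only metadata.

## Rheology (`rheology`)

The plateau is estimated in two passes — median of the leading quarter,
then the mean of all points within the deviation band (a constant fit;
the "linear function" of common practice is ambiguous between a constant
and a sloped line, and the constant is the reproducible choice — the
band membership it implies is reported via `n_points_in_lver`). The LVER
is the closed interval from the first strain to the last strain with
G′ ≥ (1−deviation)·plateau, deviation 0.10 by default. A sweep whose
leading half decays monotonically by more than the deviation has no
plateau and raises `NoLverError`. Mean ± SD of G′ over the LVER converts
to E = 2G′(1+ν); at ν = 0.5 the ratio E/G′ is exactly 3 by construction.
The loss factor is the mean pointwise G″/G′ over the LVER. Replicates
are combined at the result level (mean ± SD across sweeps), not by
pooling points.

## Assays and statistics (`assay`, `stats`)

Nuclei are counted by global threshold (fixed value, or Otsu when not
given), connected components, and a minimum-area filter; touching nuclei
merge — a documented limitation of plain threshold segmentation (no
watershed splitting). Blank or saturated images warn and count zero.
Endocytosis: normalized total = (cell_associated + degraded)/n_cells per
well; zero-cell wells are excluded with a warning; normalization is
linear in the activity scale.

`compare_groups` is the equal-variance two-sample t-test with Welch
behind a flag, annotated with stars at 0.05/0.01/0.001. Two identical
constant groups give t = 0, p = 1; two different constants give p = 0
(zero pooled variance). Type-I error is calibrated on null simulations
to [0.03, 0.07] at α = 0.05. `summarize_group` reports mean, SD
(ddof = 1; a single observation reports SD 0 with a flag), and 5th/95th
percentiles by linear interpolation between order statistics — the
convention is stated in the output.

## Pipeline and problem sizes

`run_pipeline` chains phantom (or loaded HDF5 scan) → per-pixel modulus
fits → 170/300 pN reconstructions → flattening → segmentation → pore
tables → porosity → deformability → summaries, writing TIFF maps, CSV
tables, and a `report.json` whose provenance block echoes the full
configuration plus every derived threshold; reruns with the same
configuration are byte-identical (no timestamps). Stage failures
propagate as `StageError` with the stage name and the config echo; the
CLI maps configuration errors to exit code 2 and stage failures to 3.

Default problem sizes — 64² maps with 256-sample curves for
modulus/porosity work, 128² for the porosity regimes, 192² for
deformability, 100-seed Monte-Carlo for rheology, 1000 null simulations
for calibration — keep a full test-plus-acceptance cycle within a few
minutes on one CPU while leaving every recovery criterion with a
comfortable margin.

## What passing tests do and do not show

The phantoms have sharp pore edges, a single membrane modulus, additive
Gaussian force noise, and no drift, adhesion, or viscoelasticity; real
scans have gradual membrane slopes, lateral drift, and correlated noise.
Recovery results therefore validate the *algorithms* (the estimators
recover the truth their input model encodes) — they do not certify
accuracy on any particular instrument's data. The rim-collapse model is
a calibration device for the deformability statistic, not a claim about
the physical mechanism of fenestration enlargement; the thresholds that
real analyses must choose (depth criterion, diameter range, matching
radius) are explicit parameters recorded in every output.
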