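# Methods

## What the package models

After traumatic nerve injury (partial ligation of the sciatic nerve),
stromal cells expressing the platelet-derived growth factor receptor beta
(Pdgfrb) increase in number. In cleared whole nerves these cells are
visualised with a genetic tdTomato reporter; vessels are filled by
intravascular FITC-albumin gelatin perfusion; nuclei are stained with DAPI.
Reporter-positive cells then split into two populations by vessel proximity:
**mural cells** (pericytes and vascular smooth muscle cells, wrapped onto
vessel walls) and **Pdgfrb+ fibroblasts** (scattered through the
endoneurium). `periquant` implements the quantification used on such
volumes, a synthetic-volume generator that makes every stage testable
against exact ground truth, the nonparametric statistics applied to the
resulting per-animal counts, and a ligand–receptor communication analysis
for the transcriptomic arm of such studies.

## Synthetic volumes (`periquant.simulate`)

A scene is a set of vessels (tubes of constant radius around polyline
centerlines) plus a Poisson-distributed cell roster:

* mural cell count ~ Poisson(`mural_density`/100 µm × total vessel length ×
  effect multiplier); somata sit on the vessel wall with their centre at
  most `wall_offset_um` (default 2 µm) outside the lumen, nuclei elongated
  1.3× along the vessel axis;
* fibroblast count ~ Poisson(`fibroblast_density`/10⁵ µm³ × non-vessel
  tissue volume × multiplier); positions uniform in tissue, rejected within
  `exclusion_margin_um` (default 10 µm) of any vessel surface so the
  ground-truth class boundary is unambiguous.

Placement uses rejection resampling of *positions only* — counts are drawn
once — so empirical means stay within Monte-Carlo error of the analytic
Poisson means (property-tested). A minimum centroid separation (default
8 µm) keeps nuclei from overlapping, matching the premise of the exact
recovery tests; when a draw cannot satisfy it the separation (and only the
separation) is waived.

**Default scene geometry.** Two arteriole-calibre vessels (radius 8 µm)
cross the 48 × 99 × 99 µm field, tilted through the stack (z 18→30 µm over
the field). Vessels in a mounted nerve are never perfectly parallel to the
imaging plane, and the tilt means successive analysis planes sample
different wall segments rather than re-imaging one plane of a horizontal
tube. Baseline mural density is 15 cells per 100 µm of vessel — roughly
nuclear-contact spacing halved, so that even a doubled (injured) density
stays below geometric packing and remains measurable; an early draft with a
single horizontal vessel at 25/100 µm saturated the plane-based readout and
was replaced before the defaults were frozen. Fibroblast density is 5 per
10⁵ µm³.

Mural somata are restricted to the lateral band of the lumen
(`mural_axial_band`: axial offset ≤ 0.5 × radius). A plane-based overlap
rule is geometrically blind to somata directly above or below the lumen —
their nuclei live in z-planes that contain no vessel cross-section — so the
generator models the population the published counting rule can resolve.
Widening the band degrades mural recall for reasons inherent to the 2-D
analysis, not to any implementation.

**Injury design.** Per-(condition, region) density multipliers encode the
experimental outcome structure: after ligation, mural cells double in the
distal (Wallerian degeneration) stump, fibroblasts double at the lesion and
increase 1.5× distally; sham and contralateral nerves stay at baseline.
Groups are simulated with counter-split seed sequences, so any sample is
reproducible in isolation.

**Rendering.** FITC = rasterized lumens, tdTomato = somata (nucleus
ellipsoid scaled 1.5×), DAPI = nuclear ellipsoids; each channel gets a
constant background, a Gaussian PSF (σ_xy 0.3 µm, σ_z 1.0 µm — a cleared-
tissue 20×/0.8 NA point spread), Poisson shot noise at `photon_gain`
(default 10 photons per intensity unit) and Gaussian read noise (SD 2).
Blur and noise are independently disableable; rendering is linear in
amplitude and blur conserves channel totals (normalized kernel), both
property-tested. Voxels default to 0.62 × 0.62 µm in-plane with a 2 µm z
step (the acquisition protocol allows 2–8 µm).

## Quantification (`periquant.quantify`)

The counting rules mirror the manual workflow on real volumes:

1. **Thresholds.** `auto` is IsoData (iterative intermeans: t ← mean of the
   below-t and above-t means until the fixed point), the default of
   histogram-based imaging software; `cross-channel` copies the FITC
   threshold verbatim onto tdTomato — the convention adopted when
   software-recommended reporter thresholds drift between experimental
   conditions. The pipeline default is IsoData on FITC, cross-channel on
   tdTomato, IsoData on the whole DAPI stack.
2. **Vessel mask** = FITC > threshold; per-plane area in µm².
3. **Broadening.** In-plane dilation by a disk of ⌈radius/pixel⌉ pixels;
   default radius 5 µm (the mural-soma offset scale; the broadening extent
   used in the original software workflow is not recoverable, so the value
   is a required-reported parameter echoed into every output log).
4. **Nucleus segmentation** per z-plane: Gaussian smoothing (0.5 µm),
   IsoData threshold, Euclidean distance transform, watershed from its
   local maxima (every connected component is guaranteed a seed). This is a
   deterministic classical stand-in for the star-convex CNN segmenter used
   in the original analysis; the counting contract only consumes labelled
   ROIs, so any segmenter with the same interface can be swapped in.
5. **Counting.** ROIs under 10 µm² are discarded before anything else.
   `n_nuclei` = surviving ROIs; `n_tdtomato` = ROIs overlapping the
   tdTomato mask; `n_mural` = ROIs overlapping tdTomato ∩ broadened FITC.
   Overlap means ≥ 1 shared pixel (configurable minimum fraction).
   `n_mural ≤ n_tdtomato ≤ n_nuclei` holds structurally and is
   property-tested. A derived fibroblast estimate (`n_tdtomato − n_mural`)
   is labelled as such and never reported as a direct count.
6. **Aggregation.** Five planes 8 µm apart (centred in the stack by
   default), averaged per image; when a region was imaged twice, the
   per-image averages are averaged. The order — planes within image, then
   images within region — is fixed here because derived ratios depend on it.

**Evaluation.** Predicted nuclei are matched one-to-one (greedy by in-plane
distance, 5 µm radius) against true cells whose analytic nuclear
cross-section in that plane clears the same 10 µm² floor; mural predictions
score against true mural cells, tdTomato+ predictions against all labelled
cells. On default noisy volumes both classes recover with F1 ≥ 0.9;
residual errors are grazing cross-sections near the area floor (analytic
vs. rasterized area disagree by a pixel or two) and occasional watershed
merges.

The mural criterion tests *nucleus* pixels against the co-expression mask.
Whether the original workflow tested the nucleus or the whole soma is not
decidable from its description; nucleus-pixel overlap is implemented, and
since every simulated nucleus sits inside its soma the choice only matters
at mask edges.

## Group statistics (`periquant.group_stats`)

Two-sided tests throughout. The exact Mann-Whitney path convolves the null
distribution of U (the standard interleaving recurrence) and is checked
against full enumeration for all group sizes ≤ 8; `auto` uses it for
n₁+n₂ ≤ 16 tie-free data and otherwise the tie-corrected normal
approximation (exact mode with ties is an input error, not a silent
approximation). Kruskal-Wallis is the tie-corrected H with a χ² p on k−1
degrees of freedom, with the all-identical degenerate case defined as H = 0,
p = 1. Dunn's post-hoc z uses pooled mean ranks with tie correction;
the family adjustment is Bonferroni over the requested comparisons —
conservative and order-independent; the flavour is switchable.

**Sensitivity analysis.** `minimum_detectable_effect` estimates, by
simulation under normal shift alternatives N(0,1) vs N(d,1), the smallest d
at which the two-sided Mann-Whitney test reaches the target power. Common
random numbers are shared across the d grid (step 0.02, ≥ 10⁴ replicates
per point), which makes the estimated power curve monotone by construction;
the crossing point is reported with a binomial Monte-Carlo CI. Two test
calibrations are available:

* `asymptotic` (default): reject at the nominal-α critical value of the
  normal-approximation U test. At n = 10 per group, α = 0.05, power = 0.80
  this returns d = 1.36, agreeing with the asymptotic-relative-efficiency
  closed form d_t/√(3/π) = 1.356 (tested against the t-test power solver).
* `exact`: reject from the discrete exact null. The attainable two-sided α
  at n = 10 is 0.0433, so this calibration is conservative and returns the
  larger d ≈ 1.40.

Published sensitivity figures from standard power tools correspond to the
nominal-α calibration, hence the default.

## Ligand–receptor analysis (`periquant.ligand_receptor`, `.tables`)

The DE table (gene, log2FC, adjusted p, per-condition means) is consumed,
never recomputed. Sender ligands are genes with adjusted p < 0.05 in the
requested direction; the volcano convention flags |log2FC| > 3, i.e. an
eightfold linear change. A database row is (ligand, receptor subunits,
family); a pair matches a receiver iff the ligand is selected and **every**
receptor subunit is expressed strictly above the threshold (default 0: any
positive expression) — a receptor complex needs all of its chains, so the
gp130-family cytokines require Il6st plus their private alpha chains.

The communication score is a documented stand-in for package-specific
scores in this family of tools: per pair, scaled sender ligand expression ×
the minimum over subunits of scaled receiver expression, summed per family
(ECM, cytokine, growth factor, adhesion, chemokine, other). With the
default min-max scaling each gene is mapped to [0, 10] across the
population panel, making scores invariant to global rescaling of the
expression units. Scores are monotone in the pair set and invariant to row
order (property-tested).

Enabled-interaction counts before vs after injury are compared with a
two-sided Fisher exact test on the 2×2 table (matched/unmatched ×
pre/post), reported with its direction. The statistic behind the original
in-text comparison is unstated, so this test is an interpretation and the
package treats the result as directional.

The toy tables emulate the structure of the real inputs — injury-responsive
ligands (Il6, Lif, Clcf1, Ccl2, Ngf, Tnc, Spp1, Mmp9) upregulated above the
eightfold cutoff against null genes, and three receiver subtypes (NF,
nociceptor, cLTMR) all expressing Il6st — but the values are synthetic and
carry no information about any sequencing dataset.

## Problem sizes and numerical choices

Defaults are desk-scale by design: 24 × 160 × 160 voxel volumes, five
analysis planes, 5–6 animals per simulated group, 10⁴ power-simulation
replicates per grid point, 50 pipeline repeats in the end-to-end power
check. Degenerate inputs are defined rather than crashed into where a
convention exists (empty vessel masks are valid; blank planes segment to
zero ROIs; identical groups give p = 1) and errored where none does
(constant image under auto-threshold; exact test with ties; plane spacing
not representable at the stack's z step). Ties in ranks use midranks with
the standard corrections everywhere.

## What passing tests do and do not show

The generator makes shape, noise and class geometry explicit, so the tests
demonstrate that the counting rules recover a *known* composition under the
stated imaging model. Real cleared-nerve volumes add vessel branching and
calibre variation, clearing artefacts, depth-dependent attenuation,
reporter-negative nuclei, segmentation-hostile nuclear clusters and
non-Poisson cell clustering — none of which are modelled. Passing F1 and
power checks therefore validate the implementation of the method, not the
biological effect sizes; the per-(condition, region) multipliers are a
design to exercise the statistics, not estimates.
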