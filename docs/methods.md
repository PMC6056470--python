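# Methods

This note documents the models behind `thymoquant`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a user should know before trusting a number.

## Tissue model and stage presets

A section is modelled as an elliptical tissue profile whose outer shell is
cortex and whose interior is medulla, separated by a smooth, randomly
perturbed radial boundary (four low-frequency cosine modes, ~10 % relative
amplitude) calibrated so the realized medullary area fraction matches the
stage preset within 0.5 %. Nuclei are placed by hard-core thinning of a
Poisson process: the realized count is Poisson with mean density × area, and
points are rejection-placed with a minimum separation equal to the nuclear
diameter (6 µm for TEC nuclei, 3.5 µm for thymocytes). Placement refuses
densities beyond ~55 % of the circle-packing limit rather than stalling.
Nuclei render as Gaussian blobs (σ = diameter/4) peaking at 10× a uniform
background of 100 intensity units, with Poisson shot noise; this gives a
realistic signal-to-noise ratio without modelling optics. Sections default
to 0.645 µm/pixel; 3D stacks to 0.229 µm/pixel laterally and 0.589 µm/pixel
axially, with the axial blur doubled relative to the lateral blur to emulate
the light-sheet point-spread elongation that merges nuclei in z.

Stage presets carry the published quantities where they exist: compartment
TEC densities (E15.5 cortex ~13 and medulla ~23 per 10⁴ µm², falling to
<1 and ~5 at P10), organ volumes by displacement (E16.5 2.1 µl, P0 10.6 µl,
P10 55.5 µl, P28 130.3 µl), 8 µm section thickness, and the residual
reporter-positive fraction at P28 (81.1 %, i.e. 18.9 % of TECs dark in the
reporter channel). Cortex area fractions are set so the cortical/medullary
TEC number ratio matches the reported trajectory (~3 at E15.5, ~1 at P10).
The E15.5 organ volume is not published and is extrapolated (1.1 µl) from
the later growth curve; no headline quantity depends on it.

Two preset families deserve explicit caveats:

* **Thymocyte densities are image-realism parameters, not TI-derived.**
  Back-deriving per-compartment thymocyte densities as TI × TEC density
  would make the P10 medulla (TI ≈ 20 × 5 TECs) as DAPI-dense as the cortex
  (TI ≈ 100 × 0.9), contradicting the dense-cortex/sparse-medulla appearance
  on which DAPI-based compartment delineation rests in the first place. The
  presets therefore use section-level densities with a ≥4× cortical excess
  (250 vs 60 nuclei per 10⁴ µm² postnatally), and carry the per-compartment
  reference TIs as separate fields consumed by the morphometry and
  reconciliation steps.
* **Compartment reference TIs.** Only the P10 cortical TI (~100), the ~5×
  cortical/medullary TI ratio, and the whole-organ values (~23 at P0, ~61 at
  P10) are published. P0 compartment TIs are back-solved from the published
  whole-organ value and the 5× ratio under TEC-number weighting; embryonic
  and P28 values are interpolations/extrapolations on the same pattern.

## Spot detection

Images are robustly rescaled (1st–99.9th percentile, denominator floored at
half the median so structure-free images are not noise-amplified), then
filtered with scale-normalized Laplacian-of-Gaussian operators at three
scales (0.8×, 1×, 1.25×) bracketing the expected diameter (default 6 µm,
relative threshold 0.2 of the maximum response). Local maxima pass a
threshold that is the larger of the relative threshold and a noise floor of
8× the robust standard deviation (1.4826 × MAD) of the response field — the
extreme value of the smoothed noise field stays below ~6.5σ at these field
sizes, so empty fields yield zero spots without sacrificing blob
sensitivity. Greedy non-maximum suppression at half the expected diameter
follows, strongest response first, ties broken by lexicographic pixel order
for determinism. Centroids are geometric maxima at pixel centres; match
radii of half a nuclear diameter make sub-pixel refinement unnecessary for
every quantity computed here.

In 3D the axial scale is the lateral scale × 2 (the blur elongation),
expressed in voxels through the stack's z spacing. Candidates in the first
two voxels of each z face are discarded (reflect-padding inflates noise
curvature there). The undercount-risk flag is raised when the measured
axial FWHM of detected spots reaches the expected nuclear diameter — the
resolution-limited regime in which closely apposed nuclei merge along z —
or when nearest-neighbour axial gaps of laterally close spots cluster below
that extent. The merge direction is strictly downward: crowding can only
reduce counts, never inflate them.

## Compartment segmentation

The DAPI channel is smoothed with a Gaussian of σ = window/3 (window
default 50 µm, several nuclear spacings) to form a nuclear-density field.
Otsu's threshold splits the two dominant modes (background vs cortex);
hole-filling recovers the medulla, which always lies inside the cortical
shell. The smoothing roll-off at the tissue edge is compensated by dividing
the background-subtracted field by the blurred tissue indicator, removing
the dim rim that would otherwise masquerade as medulla. Within tissue a
second Otsu split separates medulla from cortex; the threshold is refined
to the midpoint of the two class-core medians (cores eroded by 2σ) so the
blurred boundary ring cannot skew it. Components smaller than 10³ µm² are
removed and their pixels reassigned to the nearest surviving class. A
relative class contrast below 0.3 is declared unimodal: the section is
returned as a single compartment with a warning rather than an arbitrary
split. The procedure is seed-free and exactly invariant under 90°
rotations.

Boundary fidelity is information-limited: with ~0.025 vs ~0.006 nuclei/µm²,
deciding compartment membership below ~15 µm scales is statistically
impossible, so fine lobes of the cortico-medullary junction are smoothed
over. Density estimation therefore supports **guard zones** (default 25 µm
in the pipeline): counting restricted to compartment cores further than the
guard distance from any boundary, with the core area as denominator. For
the uniform within-compartment point process this is unbiased while
excluding exactly the band where segmentation errors concentrate — the
standard boundary-exclusion logic of stereological counting frames. The
plain whole-compartment count (guard 0) remains the default of
`compartment_density`.

## Stereology and reconciliation

Areal densities convert to volumetric ones by dividing by an effective
thickness = section thickness + mean nuclear diameter (Abercrombie: a
nucleus is counted in every section its profile touches). A `correction=
"none"` mode (bare thickness) is provided for sensitivity analysis, and the
nuclear diameter can be overridden per compartment because medullary TEC
nuclei are larger; the default uses a single 6 µm diameter. Compartment
totals are volumetric density × area fraction × organ volume; whole-organ
TIs combine compartment TIs weighted by TEC totals (not areas).

The reconciliation defines `correction_factor = TI_flow / TI_hist` and
`corrected_total = flow TEC count × correction_factor` (an exact identity).
When no in-situ count is supplied, `recovery_rate = TI_hist / TI_flow`,
which assumes equal thymocyte recovery across preparations; the assumption
is recorded in the report. Because the published correction is ambiguous
between the rounded factor 13 and the unrounded 810/61, the acceptance
script reports both (1.456 × 10⁶ vs 1.487 × 10⁶ from 1.12 × 10⁵ flow TECs).

## Dissociation and flow simulation

Four classes — thymocytes, outer and inner cortical TECs, medullary TECs —
survive digestion as independent binomial draws and receive log₁₀-normal
marker intensities: negative populations at mean 2.0, positive at 3.0
(one decade apart), sd 0.15. The sd was set so that fixed quadrant
thresholds at the decade midpoint gate essentially exactly despite the
~800:1 thymocyte:TEC imbalance (at sd 0.25 the 2.3 % per-marker tails would
contaminate the TEC gate by ~40 %); broader overlap studies simply pass a
larger sd. Survival defaults are calibrated to the published
order-of-magnitude discrepancy, not measured: thymocytes 1.0, cortical TECs
0.045, medullary TECs 0.105, giving a weighted TEC recovery of ~0.075 at
P10 and hence a simulated flow TI of ~810 against the reconstructed
histological ~61. The cortical/medullary survival asymmetry (~2.3×)
reproduces the preferential cortical loss qualitatively; note that the
published ~20× whole-vs-purified Cxcl12/Foxn1 expression fold would require
a ~39× asymmetry, which would contradict the near-unity flow Ly51/UEA1
ratios reported at the same ages — the tension is in the source data, and
per-subset survival is exposed so both regimes can be explored.

Default population counts are 1:100 of the organ scale (all gated outputs
are ratios and scale-free; totals always use unscaled counts). Bulk
expression is the exact expectation Σ count × survival × per-cell level
(whole-organ mode uses pre-survival counts of all classes, purified-TEC
mode post-survival TEC counts only), so the ratio-fold-change identities —
exactly 1 for co-localized gene pairs, (s_c + s_m)/(2 s_c) for a cortical
gene over a pan-TEC gene at equal counts — hold to machine precision. The
cortical split into outer/inner subsets exists solely to express the
outer-cortex bias of Cxcl12 relative to the cortex-wide Ccl25.

## Reproduction runs and problem sizes

`run_reproduction` drives every stage from one master seed through named,
order-stable substreams, making reports byte-identical for a fixed
configuration. The default P10 configuration measures 12 sections of
800 × 800 µm: postnatal TEC densities are sparse (~30 medullary nuclei per
section core), and this pooling brings the sampling error of the
reconstructed histological TI to a few percent — the dominant residual
error being a small (~5 %) density transfer across the smoothed
cortico-medullary boundary. The acceptance script uses 20 fields of
800 × 800 µm for the E15.5 density recovery, 10 fields for detection
quality, 3 for segmentation quality, and 5 dissociation replicates for the
flow TI; the whole script completes in a couple of minutes on one CPU.

## What the synthetic data does not show

The generator has uniform within-compartment densities, circularly
symmetric nuclei of a single size per population, no reticular
membrane-reporter morphology, no vasculature or capsule, no epithelial-free
zones, and no spatial correlation between TECs and thymocytes beyond
compartment membership. Passing tests therefore demonstrate that the
counting, segmentation and reconciliation machinery is correct and
well-calibrated under the stated densities and noise — not that the
detector would match expert counts on real sections with uneven
illumination, nuclear size heterogeneity (medullary TEC nuclei are visibly
larger), or genuine boundary ambiguity. The dissociation model likewise has
no digestion kinetics and no ablation pharmacology; recovery timelines are
composition scenarios, not mechanistic predictions.
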