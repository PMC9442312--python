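# Methods

`angioquant` quantifies tumour vascular networks from 3D two-channel
microscopy stacks and tumour perfusion from DCE-MRI, and ships a
synthetic-data subsystem that generates every input it analyzes with
exact ground truth. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Synthetic vascular networks

**Generative model.** Junction sites are drawn as a Poisson process on
the projected (x–y) area at `target_node_density_per_mm2`, with a
hard-core minimum x–y separation (default: half the mean
nearest-neighbour distance of a Poisson process at that intensity, i.e.
`0.25 / sqrt(lambda)`). Each junction greedily connects to its nearest
neighbours until it reaches degree three. A candidate tube is rejected
when (a) its surface would come closer than `clearance_margin_um`
(default 6 µm) to a non-adjacent tube, or (b) it would leave a shared
junction within `min_branch_angle_deg` (default 30°) of an existing
branch. Both rules exist so that the *rendered* tube union has exactly
the topology of the graph: touching tubes create spurious loops, and
near-parallel departures fuse outside the junction blob. Clearance is
evaluated on centerline samples ~6 µm apart through a KD-tree; the
margin absorbs the sampling error.

Because rejections can leave a site below junction grade, a **repair
loop** re-samples replacement sites until the realized junction count
matches the Poisson draw. For networks that are not destined for
rendering (`repair_relax=True`, the default), late repair rounds
progressively relax the clearance margin and angle gate; the
render-validation protocols disable this so their topology guarantee
holds. The realized count still falls ~4 % short of the draw in very
crowded configurations; the Monte-Carlo consistency test bounds this
against 3 standard errors of the seed ensemble.

**Branch geometry.** Centerlines are straight chords displaced by a
sinusoid of amplitude `tortuosity_amplitude × chord` with 1–3 periods
and zero displacement at the ends, so arc length (hence tortuosity) is
known from the polyline itself. Diameters are lognormal per branch
(default median 30 µm, σ_log 0.4, clipped to 4–45 µm). Terminal
branches are grown from junctions after the core graph: a fraction
terminates on a lateral domain face, the rest end blind in the interior
(sprouts, drawn thinner by `sprout_diameter_scale = 0.65` — immature
vessels are thin). The blind/boundary split is chosen so the expected
sprout count equals `sprout_fraction ×` total branches. Merged branches
whose centerline re-approaches itself within one tube diameter are
removed: such a tube would fuse with itself when rendered and cannot
serve as ground truth.

**Perfusion rule.** Each branch is non-perfused with probability
`1 / (1 + exp((d − d0)/s))`, `d0 = 25 µm`, `s = 5 µm` by default, which
makes small-calibre vessels the predominantly unperfused ones. `s = 0`
is defined as "rule disabled" (all branches perfused). Two presets fix
the study conditions used throughout the validation suite:

* `mc38_like` — dense colon-carcinoma-like bed: 220 junctions/mm²,
  branch lengths ~90 µm, diameters median 28 µm with a heavy small-
  vessel tail, 25 % sprouts; ≈ 50–60 % of branches non-perfused.
* `b16f10_like` — sparser melanoma-like bed: 110 junctions/mm², branch
  lengths ~140 µm, diameters median 33 µm, 12 % sprouts; ≈ 30 %
  non-perfused.

## Rendering

Branches are rasterized as tubes (voxel centre within d/2 of the
centerline) on a grid whose default voxel size is the two-photon
acquisition geometry, 0.83 × 0.83 × 5 µm. The endothelium channel
contains every branch; the perfusion channel only branches flagged
perfused — the synthetic analogue of a genetic endothelial label imaged
together with an intravascular tracer. The binary tubes are scaled to
`signal_level` over `background_level`, blurred by a Gaussian PSF, and
optionally noised (Gaussian or Poisson, seeded).

## Segmentation

The endothelium channel is linearly resampled to an isotropic grid
(default 2 µm; 3D thinning assumes near-cubic voxels), smoothed, and
binarized by hysteresis thresholding with the high threshold from Otsu
and the low threshold at half of it. Otsu is a detector, not a boundary
locator: on sparse-foreground images it sits well below the tubes'
half-maximum and dilates them, so a refinement step re-thresholds
midway between the background median and the 95th percentile of the
detected foreground, which places the surface at the half-maximum of a
blurred tube — where its true boundary is. Components below
`min_volume_um3` (default 500 µm³) are removed. Multiscale Hessian
tubularity enhancement (`enhance="sato"`) is available for low-SNR data
but is not the default: it sharpens detection at the cost of diameter
fidelity. The tracer channel is binarized the same way and intersected
with the vessel mask; tracer signal outside vessels is reported as a
leakage fraction.

## Graph extraction and measurement

Masks are thinned to one-voxel 26-connected centerlines
(topology-preserving 3D thinning). Skeleton voxels with ≥ 3 neighbours
form junction clusters (adjacent junction voxels merged to their
centroid); branches are maximal junction-free paths. Four cleaning
steps address known thinning artifacts, each with a length parameter
tied to tube calibre:

* spur pruning — degree-1 branches shorter than `prune_um` (default
  5 µm for real data; the validation protocols use 14 µm because their
  tubes are up to 28 µm thick and end-erosion scales with radius);
* junction merging — junction–junction branches shorter than
  `merge_junction_um` are contracted (thick junction blobs thin into
  split junctions up to one blob diameter apart);
* self-loop removal — loops shorter than twice the merge length are
  blob artifacts, never real cycles;
* degree-2 dissolution — non-junction waypoints are merged away, with
  arc-length-weighted diameters and the longer segment's perfusion flag.

When the source mask is supplied, branch polylines are refined against
it: the skeleton's meander inside each junction blob is replaced by a
straight exit from the node (removing a systematic arc inflation of
short branches), polylines get two passes of 1-2-1 smoothing to damp
the voxel staircase, and degree-1 endpoints are marched along their
final direction to the mask boundary, compensating the end-erosion of
thinning (about one tube radius).

Diameters are twice the Euclidean distance transform of the mask
sampled along the centerline, arc-length-weighted per branch, with
points within one local radius of either end excluded (there the EDT
measures the junction blob, not the vessel). A branch is a sprout iff
it has a degree-1 end farther than `boundary_margin_um` from every
stack face, and perfused iff ≥ `coverage_threshold` (default 0.5) of
its centerline points fall inside the perfusion mask.

## Network metrics

Per stack: tortuosity (arc/chord per branch, arc-length-weighted by
default; per-branch averaging selectable), directional coherence
((3λmax − 1)/2 of the length-weighted second-moment orientation tensor
of unit chords — 0 for isotropic networks, 1 for parallel ones),
junction density per mm² of projected footprint, count-weighted
fractions of branches shorter than 80 µm and longer than 400 µm (300 µm
preset for the sparser melanoma-like networks; the 0.5 mm validation
stacks use 200 µm since no branch can span 400 µm in that field of
view), mean branch length and diameter, length-to-diameter ratio (ratio
of means by default; mean of per-branch ratios also reported — the two
differ on heterogeneous networks), sprout count, and the arc-length-
weighted perfused fraction. Longitudinal series are normalized per
metric to the first imaging day; a zero baseline yields a missing value
rather than an error. Caliper tumour volume uses the ellipsoid
approximation L×W×D×π/6 (mm³).

## DCE-MRI quantification

Signals follow the SPGR steady state `S = M0 sin α (1−E1)/(1−E1 cos α)`
with `E1 = exp(−TR/T1)`. The actual flip angle is recovered voxel-wise
from a two-TR AFI pair via `cos α = (rn − 1)/(n − r)` (r = S2/S1,
n = TR2/TR1 = 10); T1 and M0 from the linearized VFA regression of
S/sin α on S/tan α over 16 angles (1–8°); concentration by inverting
the SPGR equation against the mean pre-injection baseline signal,
`C = (R1(t) − R1,0)/r1`. T2* effects are neglected (TE = 0.632 ms).
Defaults follow a preclinical 7 T protocol: TR 1.7 ms, dynamic flip 5°,
50 frames ~13 s apart, injection at the start of the 11th frame
(0-based index 10), baseline = all pre-injection frames. The relaxivity
default is 3.3 s⁻¹mM⁻¹ (gadodiamide-class agent at high field) and is
echoed in all outputs since it rescales C linearly.

Summary metrics are model-free: iAUC90 (trapezoidal integral of C over
the 90 s after injection, with interpolation to the exact window
endpoints), MRT (first temporal moment of C normalized by its area,
injection to last frame, no extrapolation), and perfused tumour volume
as the fraction of tumour voxels whose iAUC90 strictly exceeds the
median over a muscle reference region. "End-of-session" perfusion
applies the same muscle-median rule to the AUC over the full
post-injection window, since only the initial window is otherwise
defined. The digital phantom forward-simulates all three acquisitions
(dynamic SPGR with gamma-variate concentration curves, VFA, exact
two-TR AFI steady state) and returns closed-form ground truth: plugging
the true maps into the forward model reproduces the stored noiseless
signals bit-for-bit, and true iAUC90/MRT come from fine-grid quadrature
of the analytic curves.

## Section analysis

Vessel cross-sections are classed by area with half-open intervals
(two-class split at 250 µm²; the three-class default adds 1000 µm², a
configurable choice since only the 250 µm² boundary is established).
Apoptosis is scored per class as the fraction of vessels containing at
least one cleaved-caspase-3⁺ endothelial cell; proliferation as the
EdU⁺ fraction of endothelial cells. Local caspase⁺ cell density around
reference cells uses a 100 µm disc with analytic edge correction (disc
∩ section rectangle, computed by polygonal intersection with error
< 10⁻⁴ relative); on homogeneous Poisson input the estimator is
unbiased. The synthetic section generator places 1 + Poisson(4)
endothelial cells per vessel, marks a vessel apoptotic with a per-class
probability, draws EdU per cell with per-class rates, and adds a
homogeneous Poisson background of caspase⁺ non-endothelial cells.

## Validation protocols and problem sizes

`angioquant.benchmarks` pins three end-to-end protocols, sized so the
whole suite runs in minutes on one core:

* **topology** — ≤ 50-branch networks (400 × 400 × 120 µm, tubes
  6–16 µm) rendered noiselessly at 2 µm isotropic; extracted (junction,
  endpoint, branch, cycle) counts must equal ground truth exactly,
  checked over 20 seeds.
* **recovery** — 256 × 256 × 64 voxel stacks (2 µm isotropic, 0.5 mm
  field of view, tubes 8–28 µm); metrics recovered within 10 %
  noiseless and 15 % at Gaussian SNR 10 (tortuosity 5 %), scored on the
  pooled branch population of three stacks because count-sensitive
  metrics (sprouts, tail fractions) are unstable per-stack at this
  field of view.
* **pruning** — deleting non-perfused branches below 25 µm from the
  dense preset must decrease junction density, the short-branch
  fraction and the sprout count and increase the long-branch fraction,
  l/d and the perfused fraction; the sparse preset must show strictly
  smaller relative changes. Averaged over 3 seeds on a 700 µm domain;
  the long-branch threshold is the 95th percentile of the baseline
  length distribution so the baseline fraction is nonzero and
  comparable between presets.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis measures —
branching topology, length/diameter statistics, sprouts,
diameter-linked perfusion, sinusoidal tortuosity — and the acquisition
physics the DCE pipeline inverts. It does not emulate scattering depth
attenuation, motion, vessel-wall signal profiles, pericyte/stromal
background, flow heterogeneity within a vessel, or real segmentation
confounds such as touching non-vascular structures. Passing the
recovery suite therefore demonstrates correctness of the measurement
chain, not robustness to every property of real tissue. Known
limitations: realized branch lengths track junction spacing rather than
the nominal lognormal (which mainly controls sprout lengths and
connection cut-offs); the realized junction count runs a few percent
below the Poisson draw in crowded regimes; and tubes below ~2 voxels in
radius are not measured reliably (sub-resolution vessels trigger a
warning at render time).
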