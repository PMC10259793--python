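# Methods

## The deformity score

A hypha's medial axis is reduced to a set of turn angles: the junction
(emergence) angle between the mother cell's long axis and the initial
hypha direction, plus the deflection of every kink. The deformity value is
the mean sine of these angles, d_h = (sin junction + Σ sin αᵢ) / N with
N = 1 + number of kinks. Properties that the implementation and tests rely
on:

* d_h ∈ [0, 1]; it is 0 exactly when every measured angle has sine 0.
* sin(180° − α) = sin α, so the interior-angle and deflection-angle reading
  of a kink give the same score; angles are stored as deflections in
  [0°, 180°] because 0-means-straight reads naturally.
* d_h is invariant under rotation, translation, reflection and uniform
  scaling (with the simplification tolerance scaled along).
* The junction angle always counts as one of the N angles: the measurement
  scheme treats the emergence angle as a measured angle, so a kink-free
  hypha has N = 1 and d_h = sin(junction). A config flag
  (`include_junction=False`) divides by the kink count only, for users who
  prefer the alternative reading; it refuses kink-free hyphae.
* Angles are computed as atan2(|cross|, dot) of the adjacent segment
  vectors, which is well conditioned near 0° and 180° where arccos is not.

**Eligibility.** Only budding cells (bud initiated or finished) with exactly
one unbranched hypha are scored. Budding indicates that hyphal elongation
has finished, so the scored population is morphologically comparable;
branched cells and cells with a second hypha are excluded with a recorded
reason. Hyphae shorter than twice the simplification tolerance are rejected
as unmeasurable rather than scored 0.

## Kink detection

Manual angle measurement has no single automatic equivalent, so kinks are
defined operationally: the trace is simplified with recursive
maximum-deviation (Douglas–Peucker) simplification, then every interior
vertex of the simplified polyline with deflection ≥ `min_kink_deg`
(default 10°) is a kink. The simplification tolerance default is 0.1 µm,
about 1.5 px at the default 0.065 µm pixel size. The tolerance was chosen
from the behaviour of traced (rasterized) medial axes: sub-pixel skeleton
extraction rounds a sharp corner over roughly two pixels, and at a 1-px
tolerance the simplifier keeps two vertices inside the rounded corner,
splitting one large kink into two smaller ones; at 0.1 µm the corner
collapses to a single vertex while raster jitter (≲ 0.5 px) is still far
below tolerance. On round-trip benchmarks (75 cells, σ ∈ {5°, 20°, 40°})
recovery of the analytic d_h improves from r ≈ 0.92 at 0.05 µm to
r ≈ 0.95 at 0.1 µm. Both parameters are exposed in the config and CLI.
Sub-threshold turns are treated as micro-bends, not kinks, everywhere —
including in the synthetic ground truth, so truth and measurement share one
convention.

## Tracing masks

Segmentation is out of scope: the tracer consumes label masks from any
segmenter (the original measurements this pipeline mechanizes were manual).
Per labelled component:

1. **Skeleton.** `skimage` skeletonization; per-pixel local width = twice
   the Euclidean distance transform. The skeleton pixel graph's longest
   endpoint-to-endpoint geodesic is the medial path. Side branches shorter
   than `prune_len_um` (default 0.2 µm) are pruned as spurs; longer ones
   mark the cell branched → excluded. Components under 20 px, touching the
   image border, or with cyclic/ambiguous skeletons are excluded with a
   reason.
2. **Tip extension.** Skeletons retract from tube ends by about the local
   radius; each path end is extended along its local direction to the mask
   boundary. The path is then smoothed (Gaussian, σ = 1 px, endpoints
   pinned) to sub-pixel precision.
3. **Partition.** On the (lightly smoothed) width profile, the contiguous
   region with width ≥ 0.6 × maximum width containing the global maximum is
   the cell body; a thin terminal path is the hypha; a terminal region with
   width ≥ 0.5 × body width at the distal end is the bud. Both ratios are
   config parameters; where exactly the hypha begins and ends has no
   canonical definition, so the delimitation here is our construction.
   Threshold crossings are refined to
   sub-sample positions, and corrected for cap geometry: along the medial
   line the distance transform falls off linearly into a spherical cap
   (r − t), so a width threshold thr is crossed r − thr/2 before the body
   surface (and, mirrored, past the bud neck). Without this correction the
   traced hypha is systematically ~0.5 µm too long.
4. **Stage.** No thin extension → `no_hypha`; hypha without terminal
   swelling → `hypha_no_bud`; with swelling → `budding`. Thin paths on both
   body poles mean a second hypha → excluded. A bud wider than the mother
   cell would misorient the partition; such cells do not occur at the
   default geometry and the limitation is accepted.
5. **Profiles.** Intensity is sampled along the concatenated pole → body →
   hypha → bud path at uniform 0.05 µm arc steps, bilinearly interpolated
   and averaged over a 3-pixel window perpendicular to the path. Paths
   leaving the image flag the cell as truncated.

Accounting is conservative throughout: every input label ends up either
measured or listed in the QC table with an exclusion reason.

## Demographs and peak distances

Demographs stack per-cell profiles as heatmap rows, cells sorted ascending
by length, per stage group (`no_hypha`, `hypha_no_bud`, `budding`) and
channel. Profiles are aligned at the non-hyphal pole (column 0) on an
absolute-length bin grid (default 0.05 µm) — with tip-localized signals
this makes the bright band track the growing cell length, which is the
pattern of interest; a centered alignment is available but off by default.
Rows are min–max normalized per cell (constant rows map to zeros), so
within-cell localization is preserved and absolute brightness discarded.
The normalization method and alignment are deliberate choices; nothing in
the underlying measurements forces them.

The peak-to-tip distance of a channel is tip arc position minus the arc
position of the profile maximum, restricted to the hypha (+ bud; the bud
can be excluded by flag), after smoothing with a 0.15 µm moving average.
Ties break toward the tip, and the maximum is refined by parabolic
interpolation of the three samples around the argmax, which removes the
0.05 µm sampling-grid bias. A centroid-based peak was considered and
rejected: with two bright regions (tip + emerging bud) the centroid lands
between them.

## Group statistics

Samples are screened with the D'Agostino–Pearson omnibus test (K², n ≥ 20
required) — per-cell d_h distributions are generally non-normal, which
motivates the rank-based comparison. Groups are compared with the
Kruskal–Wallis test, tie-corrected (d_h values tie at 0 for perfectly
straight hyphae), p from χ²(k−1); literally identical groups return the
H = 0, p = 1 boundary rather than failing. p-values map to asterisks:
\*\*\*\* < 0.0001, \*\*\* < 0.001, \*\* < 0.01, \* < 0.1, n.s. otherwise.
The printed-threshold scheme this mirrors leaves a gap between 0.1 and
0.9999; everything in [0.1, 1] is labelled n.s. here. For more than two
groups, pairwise Kruskal–Wallis comparisons with Bonferroni correction are
offered as a post-hoc — an implementation choice, no particular post-hoc
procedure being canonical for this design.

## Synthetic data

The generator emulates the single-cell morphotypes the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `body_length_um` / `body_width_um` | 2.0 / 1.0 | mother-cell capsule |
| `hypha_width_um` | 0.25 | hypha tube width |
| `bud_diameter_um` | 0.9 | bud sphere |
| `hypha_length_um` | (4.0, 0.8) | Normal mean, SD |
| `kink_count_mean` | 3.0 | Poisson rate |
| `deflection_sigma_deg` | 5.0 | half-normal scale of kink and junction angles, truncated to [0°, 180°] |
| `min_segment_um` | 0.2 | shortest inter-kink segment |
| `stage_weights` | (0, 0, 1) | stage mixture; deformity studies use budding only |
| pixel size / PSF σ | 0.065 / 0.08 µm | typical 100× epifluorescence values |
| noise | Poisson shot + Gaussian read (SD 10) on background 100, fill 150, spot 400 | gives image SNR ≈ 8 |

σ = 5° stands in for the straight wild-type-like phenotype and σ = 40° for
the buckled mutant-like one; the half-normal model was chosen for its
single interpretable spread parameter, not taken from any measured angle
distribution. Segment lengths partition the hyphal length by a Dirichlet
draw above the minimum segment length. Impossible draws (hypha too short
for its kink count) and tube layouts that would self-overlap — a hypha
folding back within one tube width of itself or the body, whose rasterized
mask would merge into a branched skeleton — are regenerated with a logged
retry (hard error after 100). This rejection slightly thins the extreme
tail of the σ = 40° angle distribution; the distributional unit tests
therefore target the angle sampler directly.

Rasterization draws tube supports (exact, noiseless → the label mask),
adds a uniform cytoplasmic fill plus one Gaussian spot per channel at the
channel's true arc offset from the tip, blurs with the PSF and adds noise.
Ground truth records kink angles, analytic d_h, hyphal length, stage and
true peak offsets, and every cell derives from the single spec seed.

**What passing synthetic tests does not show.** The generator produces
clean single cells with ideal masks: no segmentation errors, no touching
cells, no uneven illumination or photobleaching, no out-of-focus signal,
and a bud that is always a terminal sphere. Recovery numbers (deformity
correlation r ≈ 0.93, hyphal length error ≈ 2.5%, stage accuracy ≈ 97%,
paired peak offset within 0.05 µm at SNR ≈ 8) are therefore upper bounds on
real-data performance, and the width-ratio partition defaults will need
checking against real morphology.

## Problem sizes and reproducibility

The shipped benchmarks use 100 cells per σ ∈ {5°, 20°, 40°} for the image
round trip, 200 cells for peak recovery, 100 replicates of n = 100 + 100
for power and 1000 resampled replicates for type-I calibration — sizes at
which the Monte-Carlo error of each reported rate is well below the margin
being checked. All randomness flows from explicit seeds; identical config +
seed reproduces byte-identical CSV outputs, and each CLI run writes its
effective config and a hashed-input manifest for replay.

## Known limitations

* 2D only — projections are measured, as in the epifluorescence/DIC data
  this mechanizes; no 3D correction.
* No curvature/sinuosity/angularity metrics: smooth-curve metrics do not
  resolve multiple discrete kinks well, which is what d_h is for.
* No automatic segmentation, deconvolution, time-lapse tracking or
  multicellular-array lineage analysis.
* Whether kinks inside the nascent bud should count is genuinely open; by
  default the hypha is measured up to the bud neck only (the bud is still
  included in the peak-to-tip search window, where the signal of interest
  often sits).
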