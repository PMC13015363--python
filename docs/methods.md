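# Methods

This note documents the models and numerical choices behind
`embryotrack`, what the synthetic scenes do and do not emulate, and the
design decisions taken where the design was genuinely open.

## Detection

**Curvature scoring.** For each scale σ (µm) the volume is smoothed with
per-axis Gaussian sigmas σ/voxel_size (handling anisotropy; sigmas are
clamped at 0.7 voxels with a warning when a scale is sub-voxel along an
axis). Second derivatives are taken with Gaussian-derivative kernels
(mirror boundary — zero padding would fabricate strong edge curvature),
divided by the voxel-size products to give the physical-space Hessian,
and scale-normalised by σ². With eigenvalues λ₁ ≥ λ₂ ≥ λ₃, the score is
(∏ max(0, −λᵢ))^⅓: positive only where all three principal curvatures
are negative (a bright blob in every direction). The cube root makes the
score scale linearly with detector gain while leaving maxima unmoved;
the pointwise maximum over scales combines the multiscale responses.
Default scales are {0.5, 0.75, 1.0, 1.5} × the nominal nucleus radius.

**Significance test.** Candidate seeds are connected plateaus of local
score maxima. Each is tested on the *raw* intensities:
z = (mean(interior) − mean(shell)) / (σ_n·√(1/nᵢ + 1/nₛ)), with σ_n the
global noise SD estimated once per frame as MAD(first spatial
differences)/√2 × 1.4826. Two robustness choices matter here. The
interior never shrinks below 2 voxels per axis: with a handful-of-voxel
interior, conditioning on a local maximum inflates the statistic enough
to let pure noise through z_thr = 4. And seeds undergo scale-aware
non-maximum suppression (drop the weaker of two seeds closer than
0.8·(σ_a+σ_b)): a coarse scale responds to a *pair* of adjacent nuclei
with a saddle maximum between them, which would otherwise become a
phantom third cell. On pure-noise volumes these defaults produce well
under one seed per 10⁵ voxels.

**Boundary refinement.** Seeds grow to instance masks by a per-seed
binary min-cut on the voxel grid of the seed group's dilated bounding
box: 6-neighbour capacities exp(−ΔI²/2σ_g²), soft terminal capacities
from seed/background intensity likelihoods, hard constraints at the seed
(source) and at competing seeds (sink). The solver is
`scipy.sparse.csgraph.maximum_flow` on integer-scaled capacities; the
source side is the residual-reachable set. Contested voxels go to the
seed with the higher foreground affinity, ties to the nearer centroid.
Volume gates (defaults 0.2× and 10× the nominal nucleus volume) drop
implausible masks.

## Linking

The association graph has a pre and a post node per detection plus one
dummy node. Observation arcs (pre→post, capacity 1) cost
−log(p/(1−p)) with p = logistic(z − z_thr) clamped to [10⁻³, 1−10⁻³] —
negative for confident detections, so explaining them pays. Appear and
disappear arcs cost C_border = 4, discounted 4× at the temporal ends of
the span and within one nucleus radius of the volume border. Transition
arcs (k-nearest candidates, default 4) cost
d²/2σ_m² + log(vol_b/vol_a)² with d measured against the motion-flow
prediction when a flow field is supplied; arcs beyond R·gap are omitted
(R defaults to 3 nominal radii per unit gap, σ_m to one radius).
Frame-skip arcs up to g_max = 2 add (gap−1)·C_skip. One-to-two matchings
are a normal parent→child transition plus a discounted dummy→second-child
arc priced by the parent geometry; two-to-one matchings are the mirror
image on the exit side; both are restricted to the 3 nearest neighbours.

Solving: the circulation LP (conservation at every node, integer bounds)
is totally unimodular, so the HiGHS dual-simplex vertex solution is
integral; costs are scaled by 10⁶ and rounded to integers first, the
returned flows are verified integral and conservative, and
`networkx.network_simplex` stands by as an exact integer fallback. A
dynamic program that exhaustively enumerates all feasible track
decompositions over the same arc set (feasible up to 18 detections)
serves as an independent oracle; solver and oracle agree integer-exactly
on randomized instances.

The first, conservative pass uses a strict gate of 1.5 nominal radii;
this produces the high-confidence tracklets consumed by error
correction. Relaxed, wide-motion association happens only later at the
tracklet level.

## Iterative error correction

Per iteration: strict-gate link → missing-cell redetection →
segmentation correction → re-link; the loop stops when an iteration
accepts nothing or after `max_iterations` (default 5).

**Missing cells.** Every skip arc with flow yields interpolated
centroids for its skipped frames. Detection reruns in a window of 3
nucleus diameters with the threshold relaxed to ρ·z_thr (ρ = 0.5).
Acceptance gates: the new seed must not duplicate an existing detection
(within one radius, or overlapping existing labels by more than 30%);
the mask is clipped to the seed's own neighbourhood (1.8 radii) and to
its above-half-peak core so its volume convention matches the
surrounding segmentation; volume gates apply; and the candidate's mean
intensity must reach at least half way from background to the skip
endpoints' mean intensity — a missing cell should look like its track
neighbours, which is what separates dim true nuclei from the bright
noise clusters that survive the relaxed threshold.

**Segmentation conflicts.** The flow localises suspects, but every
acceptance test is purely geometric and volumetric — evidence the
optimal flow cannot change. This matters: degenerate circulation optima
may differ between a whole-scene and a truncated-batch instance, and
flow-dependent corrections would then break batch invariance. The
under-segmentation pattern for detection u at frame t: both adjacent
frames hold two detections within the gate whose paired volume sums
match vol(u) within τ = ±30%, and vol(u) exceeds γ = 1.6 × the median of
those four singles. Split seeds are midpoints of the distance-matched
(previous, next) pairs. The over-segmentation pattern for a same-frame
pair (u, v): exactly one detection within the strict gate of their
midpoint on each adjacent side, and vol(u)+vol(v) matching the sides'
mean within τ.

**Applying corrections.** Splits partition the voxel set exactly: by
connected component when the lobes are disconnected (orphan components
to the nearer seed), otherwise by a two-seed min-cut with hard ball
seeds (≥ half a nucleus radius — single-voxel seeds would let the
minimum cut isolate the seed itself) and no soft terminals, since both
sides are equally bright and only the intensity valley is informative.
Merges union the voxels; both operations retire the old ids and
re-measure. Two memoisation rules prevent oscillation: a region that
took part in an accepted correction is never corrected again in the
opposite direction (kind-agnostic voxel-hash memo), and proposals whose
region overlaps an already-corrected region by more than 30% are
skipped. Proposals are re-validated against the live state immediately
before application, because a split applied earlier in the same
iteration can dissolve a neighbouring merge pattern (under- and
over-segmentation patterns are mutually mimicking on alternating
frames).

Note on preprocessing: deconvolution and registration produce a *new*
series (different content / coordinate frame), so they only combine with
detections computed from that same preprocessed series; precomputed
label volumes from the raw frames must not be mixed with a registered
image stack. The motion-flow field, by contrast, only offsets the
linking costs and composes with any detection source.

## Lineage assembly

Tracklets become nodes of a second circulation (keep-reward observation
arcs force every tracklet to be used; end→start arcs allowed for frame
gaps 1..3 within R·gap·2.0, priced as ordinary transitions). Gap frames
inside merged tracks are filled with interpolated virtual nodes, flagged
as such, so exported lineages have per-frame nodes.

Batches (overlapping frame spans, processed independently through
correction and association) are stitched at the middle overlap frame by
mutual nearest neighbour within the gating radius; the earlier batch
wins conflicting topology; unmatched tracks end or begin as they did in
their own batch.

Division detection runs once, after stitching, so its track-length gate
sees full-length tracks (a batch-local gate would treat divisions near
batch boundaries differently from a whole-scene run). Candidate children
are track roots — and nodes reached only through an interpolated gap
bridge, since the relaxed association sometimes bridges an ended track
onto a genuine daughter; a fitting division pattern wins that
competition and cuts the bridge. For each candidate the 3 nearest
previous-frame nodes are tried as parents; gates, in order: parent chain
length ≥ 5 frames back to the previous division or root (tracks rooted
at the scene's first frame are left-censored — the cell predates the
recording — and always pass); daughters roughly equidistant from the
parent (within 3×); each daughter's share of the combined daughter
volume in [0.3, 0.7] plus 0.5 ≤ (v₁+v₂)/v_parent ≤ 2.0; the pair are the
parent's two mutual-nearest next-frame nodes; and a daughter that dies
immediately (an over-segmentation mimic that re-merges) is rejected. The
volume share, rather than the child/parent ratio, is used because
apparent (half-peak) label volumes are PSF-compressed: true half-volume
daughters show label-volume ratios of 0.55–0.75, while the share of the
combined daughter volume centres on 0.5 regardless of the compression.

## Evaluation metrics

Ground truth and prediction are matched per frame by optimal one-to-one
assignment within a radius. A GT edge is correct iff both endpoints are
matched and the predictions are linked the same way; errors are missed
GT edges + wrong-target GT edges + false predicted edges between matched
nodes, normalised by the GT edge count. Error-free statistics treat each
root-to-leaf GT path as a track; the error-free length is the prefix of
consecutive correct edges from the track start (a `longest_run`
alternative is exposed, since "the longest correct stretch" is an
equally defensible reading).

The mixing index fits a soft-margin linear SVM (C = 1) on jointly
centred, isotropically scaled coordinates — isotropic rather than
per-axis scaling keeps the index invariant under rigid motions — takes
only the hyperplane *direction* from it, and then chooses the offset
along that direction by exact enumeration of all thresholds between
projected points, minimising the index. (A hyperplane that exactly
minimises misclassification is NP-hard in general; fixing the direction
reduces the offset search to a 1-D exact problem.) Both published
variants are exposed: the mean of the two per-class misclassified
fractions, and their sum. Identical point sets give exactly 0.5 (mean
mode) at every threshold; fully degenerate input is flagged.

Dispersion is the mean pairwise Euclidean distance. Velocities are
central differences over ±half_window frames along each cell's own track
(one-sided at ends and across divisions), in µm/min; local statistics
use the k = 50 nearest same-frame neighbours (clamped to the
population), the local variance being the trace of the neighbourhood's
velocity covariance. Expression/speed association is per-gene Pearson
correlation, NaN for zero-variance genes. Point-cloud matching first
aligns by centroid, RMS-radius scale and principal axes (signs fixed by
third moments, reflections removed), then solves the exact linear
assignment with per-point dummy alternatives.

## The synthetic scenes

The simulator emulates an early-embryo recording: nuclei on a spherical
cap, tangential drift toward the vegetal pole (epiboly-like, 1 µm/frame
by default), Brownian jitter (σ = 0.5 µm/frame), soft pairwise repulsion
keeping centroids ≥ 2 radii apart, and divisions at 1%/cell/frame into
half-volume daughters displaced ±1 radius, with a 10-frame post-birth
refractory period (blastomere cycles span many frames at 60 s/frame;
memoryless immediate re-division would be a biological artifact that no
tracker could attribute) — initial cells are exempt, being at random
cycle phases. Rendering: per-nucleus Gaussian blob (σ = r/1.5) convolved
analytically with a Gaussian PSF (σ = 1.5, 0.5, 0.5 µm in z, y, x),
uniform background, Poisson shot noise, then Gaussian read noise with
SNR ≡ (peak − background)/read-noise SD = 10 by default. Ground-truth
labels assign each above-half-peak voxel to the nearest nucleus centre,
guaranteeing disjoint labels; everything is byte-reproducible from the
seed.

The standard test scene is 200 cells, 50 frames, voxels 2×1×1 µm over
32×224×224 voxels; corruption manifests sample mid-track nodes away from
divisions and scene ends, at most one corruption per cell per ±2-frame
window, merge partners within 12 µm. The canonical worked example is a
deterministic two-lineage scene (20 frames, radius 3 µm — large enough
that voxel-grid aliasing of the small half-peak masks stays within the
±30% volume tests) carrying exactly 2 deletions, 2 over- and 6
under-segmentations.

What the simulator does *not* emulate — and hence what passing tests do
not certify on real data: non-blob nuclear morphologies and mitotic
chromatin condensation, intensity variation across cells and time
(photobleaching, depth attenuation), anisotropic and spatially varying
PSFs, uneven background, apoptosis, and cells entering or leaving the
imaged volume mid-recording. Real light-sheet data will also show
textured cytoplasmic background that the uniform-background noise model
does not produce.

## Problem sizes and runtime choices

The default test and acceptance workloads are sized for a single CPU:
the standard scene links ~12,700 detections per pass (~115,000 arcs;
HiGHS solves each in a few seconds), the correction loop converges in
two to three iterations, and a full pipeline run takes well under a
minute. The brute-force oracle is exercised on instances of at most 15
detections over 3 frames, where the enumeration DP is exact and fast.

## Known limitations

Exact batch invariance holds on scenes where no track is lost in the
overlaps and corrections are pattern-unambiguous; heavily entangled
corruption patterns at batch boundaries could still resolve differently.
Division detection needs five frames of parent history (except at the
recording start), so divisions within the first frames of a cell's
appearance mid-scene go undetected by design. The detector assumes
roughly convex bright blobs; elongated or lobed nuclei will be
over-split. The CTC export renders interpolated nodes as small cubes
(they own no voxels); batched runs re-measure labels per batch, so CTC
export after stitching falls back to centroid cubes for imported
nodes.
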