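# Methods

## Model and assumptions

A population of N scalar images on one common voxel grid is treated as a
point cloud on an image manifold.  Groupwise registration is posed as
*graph shrinkage*: a connected graph over the images (nodes) with
geodesic edges is contracted until all nodes coincide at the hidden
population center.  No image is ever designated the template, which
avoids template-selection bias.

Assumptions inherited from this formulation:

- Images are **affinely pre-aligned** and share grid shape and spacing.
  The tool refuses mixed grids rather than resampling silently.
- The pairwise distance is **SSD over the full grid** (no mask, no
  intensity normalization), so intensities must be comparable across the
  cohort — the situation after standard preprocessing (inhomogeneity
  correction, skull stripping) of a single-modality dataset.  Mutual
  information (negated joint-histogram MI, 32 equal-width bins) is
  available for graph construction, but the pairwise *registration*
  forces remain SSD-driven.
- Deformations are **diffeomorphic**: every warp is the exponential of a
  stationary velocity field, composed in the group.

## The two-level graph

Affinity propagation clusters the images using similarities s_ij = −d_ij
and one shared preference p = mean(s).  The message-passing solver is
implemented in-repo (damping 0.9, ≤ 1000 iterations, convergence after 50
stable iterations, no noise injection, ties to the lowest index) so
results are bit-reproducible; scikit-learn's implementation is used only
as a cross-check in the tests.  Degenerate outcomes are handled
conservatively: all-singleton clusterings fall back to a single subgroup
centred on the global center.

The graph connects each subgroup's members to its representative (the
member nearest the global center; the center itself in its own subgroup)
and all representatives to the center.  Σ_α (n_α − 1) + (Ω − 1) = N − 1
edges, connected by construction, for every partition — property-tested
over random partitions up to N = 300.

## Pairwise engine

Edge velocities are estimated by a log-domain diffeomorphic-demons-style
method: classic SSD demons forces u = (F − M∘φ)∇(M∘φ) / (|∇(M∘φ)|² +
(F − M∘φ)²), "fluid" Gaussian smoothing of each update (σ = 2 voxels),
additive velocity accumulation, "diffusion" Gaussian smoothing of the
field (σ = 1 voxel), over a 3-level pyramid with 30 iterations per level.
The best-SSD velocity seen is carried forward, so the returned field
never does worse than the identity.  Edges are estimated once per
undirected pair with v_ji = −v_ij (the stationary-field inverse is the
negation).

The exponential map uses scaling and squaring with the scaled step
bounded by 0.25 voxel (empirically halves the inverse-consistency error
relative to a 0.5-voxel bound at negligible cost; interior error of
exp(v)∘exp(−v) stays below 0.1 voxel for smooth fields of a few voxels'
amplitude).  Composition is a single linear-interpolation resampling;
warped intensities use linear interpolation with nearest-border
extension, labels nearest-neighbour with background outside the grid.

## Shrinkage loop

Per outer iteration: distances on the current images → clustering →
graph → velocity estimation on every edge → energy
F = Σ_ij e_ij ‖v_ij‖² (both orientations; ‖·‖ defaults to the sup voxel
magnitude, which caps each node's per-step displacement at one voxel and
protects the diffeomorphism; an l2 mode exists).  Then one low-level pass
(subgroups shrink onto their representatives) and one high-level pass
(representatives move toward the center and their incremental warp is
composed onto every member, so subgroups travel as wholes).  Inter-edge
velocities are re-estimated after the intra pass because the
representatives have moved.  Images are always resampled once from the
originals through the cumulative warp, never from previous resamplings.

The Δt bound guarantees descent only for exact geodesics; discrete
registration is approximate, so descent is *verified*, not assumed, with
three safeguards (each a design choice of this implementation, since the
formulation leaves the numerics open):

1. **Per-level acceptance** — a pass is accepted only if the energy of
   its own edges, re-measured by re-registering them on the moved images,
   does not increase; otherwise Δt is halved (≤ 5 times).
2. **Whole-iteration acceptance** — after both passes the full-graph
   energy is re-measured; on regression the iteration is retried with all
   time steps halved (≤ 2 global halvings), and as a last resort a
   *joint* pass over all edges is attempted, whose step acceptance is
   exactly the global measurement.  Only accepted measurements enter the
   energy trace, which is therefore non-increasing by construction.
3. **Monotone re-clustering** — if rebuilding the graph on unchanged
   images *raises* the measured energy (re-clustering optimizes SSD, not
   the velocity energy), the previous graph is kept for that iteration.

Cumulative warps must keep a positive interior Jacobian determinant at
every accepted iteration; a step that would break topology is treated
like an energy regression.  Convergence: relative energy decrease below
1e−3, zero energy, or no admissible step; hard cap 20 outer iterations.

`--freeze-graph` builds the graph once; `--schedule joint` runs the pure
single-level dynamics on the hierarchical edge set; `--mode star`
bypasses clustering entirely (group-mean-style baseline with identical
dynamics).

## Evaluation and atlas

Dice uses the majority-vote label map of all aligned segmentations as the
common-space ground truth (background votes; ties go to the lowest label
code).  The per-image "overall" value is the unweighted mean over tissue
classes; a tissue absent from both masks is reported missing rather
than 0.  The atlas is the voxelwise mean intensity plus per-label
frequency maps (probabilities sum to 1 including background).  Atlas
sharpness is the RMS gradient magnitude — the plain mean |gradient| is
invariant to blurring of monotone edges and cannot rank atlases, so the
quadratic mean is used instead.

## Synthetic populations

The generator emulates a heterogeneous single-modality cohort: each
template is a nested-ellipse head phantom (CSF rim, rippled cortical GM
band, WM core, CSF ventricle) with exact labels; subjects are random
smooth diffeomorphic warps of their template (Gaussian-smoothed white
noise velocities, sup amplitude 1.5 voxels, smoothness 6 voxels,
Jacobian-checked, redrawn up to 10 times) plus 2 % Gaussian noise and a
10 % smooth multiplicative bias.  Default: 2 templates × 6 subjects on a
64×64 grid.

Two design choices matter for interpreting results:

- **Heterogeneity is geometric, not radiometric, by default.**  The
  templates differ in head size, ventricle size and cortical fold phase
  under one shared contrast.  SSD demons forces across *different*
  tissue-intensity mappings systematically drag boundaries toward
  intensity matches (measured on this fixture: WM/GM Dice falls after
  registration when the clusters differ in contrast), which is a
  limitation of SSD itself, not of the graph dynamics; real cohorts mix
  contrasts only after modality-aware preprocessing.  Multi-contrast
  styles (including a T2-like WM/GM inversion) remain available via
  explicit `styles` and are exercised with the MI distance in tests.
- **The misphased cortical folds make direct cross-cluster registration
  genuinely unreliable** (fold-locking local minima), which is the regime
  the hierarchical graph targets.  On the default fixture the star
  baseline stalls at ~44 % of the initial energy while the hierarchical
  mode reaches ~15 % and higher Dice; on an *easy* heterogeneous fixture
  the two modes are indistinguishable — passing tests therefore show the
  mechanism works where direct registration fails, not that it always
  dominates group-mean registration.

With the default parameters the between-template SSD exceeds the
within-template SSD by ~13×, making the planted 2-partition the
within-SSD-optimal one (verified by brute force at small N), so
clustering recovery is well-posed.

What the phantoms do **not** model: MR acquisition physics (k-space,
partial volume), non-brain anatomy, topology differences between
subjects, and 3-D cortical folding patterns (the ripple is driven by the
in-plane angle).  Results on the fixture bound what can be claimed about
real data accordingly.

## Numerical choices and degenerate inputs

- Ties everywhere (center, representatives, AP messages, majority votes)
  break toward the lowest index/label for determinism.
- Identical inputs short-circuit: zero energy at iteration 0, identity
  warps, no registration performed.
- Constant images have zero entropy; their MI distance is defined as 0.
- Dice of two empty masks is 0 by convention (logged).
- Problem sizes in tests and the acceptance script (64×64 populations of
  12; 32×32 populations of 80 and 285) were chosen so the full suite
  runs in minutes on one CPU; all operations are dimension-agnostic
  (2-D/3-D) and 3-D templates are covered by unit tests.

## Known limitations

- Alternating level passes are a heuristic; the descent guarantee holds
  per accepted measurement, and runs can terminate at a local plateau of
  the sup-norm energy (the joint-pass fallback mitigates but does not
  eliminate this).
- SSD forces limit the pairwise engine to comparable intensity scales;
  MI-driven forces are deliberately out of scope.
- No groupwise affine stage: inputs must be pre-aligned.
- Two graph levels only; deeper hierarchies are not implemented.
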