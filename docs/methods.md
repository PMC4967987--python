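# Methods

## Problem setting

Candidate-nodule ROI detection in thoracic CT is the stage of a CAD
pipeline that reduces a 512×512 slice (or a whole helical volume) to a
small set of regions that *might* be nodules, before a classifier makes
the final call. `fuzzyroi` implements the family of fuzzy clustering
algorithms used for this stage and the voxel-wise TP/FP methodology used
to compare them. The only feature clustered is the scalar attenuation
value in Hounsfield Units (HU): nodules sit at midrange HU between
air-filled lung parenchyma (≈ −850 HU) and soft tissue (≈ 40 HU), which
is what makes intensity clustering informative and also what makes the
problem hard — vessels occupy the same range.

## The five solvers

All solvers partition the in-mask voxels into `c` fuzzy clusters with
memberships `u_ik ∈ [0,1]`, `Σ_i u_ik = 1`, and scalar centroids `v_i`,
alternating a membership update and a centroid update until the max-norm
centroid change falls to `epsilon` or `max_iter` is reached.

* **FCM** minimizes `J_m = Σ_ik u_ik^m (x_k − v_i)²`:
  `u_ik ∝ |x_k − v_i|^(−2/(m−1))`, `v_i = Σ u^m x / Σ u^m`.
* **KFCM** replaces the squared distance with the kernel-induced
  distance `1 − K(x_k, v_i)`: `u_ik ∝ (1 − K)^(−1/(m−1))`,
  `v_i = Σ u^m K x / Σ u^m K` with `K` evaluated against the previous
  centroids. A Gaussian RBF bounds the influence of outliers (for
  `|x − v| ≫ σ`, `K → 0` and the voxel's pull on the centroid
  vanishes), which is why KFCM survives extreme corruption that drags
  FCM centroids away.
* **SFCM** computes one (non-iterated) FCM membership pass per outer
  iteration, then the spatial function `h_ij = Σ_{k∈NB(x_j)} u_ik`
  (sum of neighbors' memberships over the window), reweights
  `u′ ∝ u^p h^q`, and updates centroids from `u′` with the FCM rule.
* **SKFCM** adds to the kernel distance an additive neighborhood
  penalty `(α/N_R) Σ_{r∈N_k} (1 − K(x_r, v_i))` in both updates, with
  the window *excluding* the center voxel and `0 < α < 1`.
* **MSKFCM** combines KFCM and SFCM: kernelized memberships, the same
  `u^p h^q` spatial reweighting, and the kernelized centroid update
  driven by the spatial memberships. Final labels for SFCM/MSKFCM come
  from the spatial memberships.

After convergence every solver recomputes memberships from the final
centroids, so the returned state is an exact fixed point of its
membership rule (this is also what the fixed-point tests assert).

### Exact reductions

The family is internally consistent and the test suite pins this down
exactly: `SFCM(p=1, q=0) ≡ FCM` and `MSKFCM(p=1, q=0) ≡ KFCM` bitwise
(the spatial step short-circuits to an identity at `p=1, q=0`
specifically so renormalization rounding cannot break the identity);
`SKFCM(α→0) ≡ KFCM` to 1e-9; `KFCM(σ→∞) → FCM` since
`1 − K ≈ d²/(2σ²)` rescales all distances uniformly. The SKFCM→KFCM
fixed-point gap is *linear* in α (measured: ≈0.074 HU at α=1e-3 on a
16×16 random slice with a 900-HU spread), so continuity is tested as a
slope, not as a fixed tolerance.

## Kernels

A single Gaussian spec carries an explicit `variance_scale` because both
denominator conventions, `2σ²` and `σ²`, are common; they coincide under
`σ′ = σ√2` (tested). KFCM/MSKFCM default to `2σ²`; SKFCM uses `σ²`
(its formulation only considers that convention, and `run_skfcm`
normalizes a `2σ²` spec accordingly). The polynomial kernel
`(xy + b)^d` is provided for completeness; all CT defaults are Gaussian
with `σ = 300` HU (useful range ≈ 150–750 HU for thoracic contrast).
The Gaussian may underflow to exactly 0 in float64 at extreme
`|x−y|/σ`; the solvers' singularity handling covers that case.

## Neighborhoods

Windows are squares (2D, never crossing slice boundaries) or rectangular
prisms (3D, spanning `size` voxels per axis — a 3×3×3 window covers the
voxel's slice plus the previous and following one). Sizes are odd so
windows are centered. Boundary handling is truncation: windows are
clipped at volume edges and at the lung mask, and `N_R` is the actual
in-bounds in-mask neighbor count — no padding, so spatial sums never
reference voxels that do not exist. The SFCM/MSKFCM spatial window
includes the center by default (`include_center` is exposed for
sensitivity analysis); the SKFCM penalty window always excludes it.
Spatial sums are computed by scatter → `scipy.ndimage.convolve`
(`mode="constant"`) → gather, which is equivalent to the truncated
per-voxel double loop (oracle-tested).

## Numerical choices

* Fuzzifier default `m = 2`; `epsilon = 1e-3` HU on the max-norm
  centroid change; `max_iter = 200`. All overridable.
* Singularities (`x_k = v_i`, or a vanishing SKFCM bracket): membership
  1 split equally among the coinciding clusters, 0 elsewhere — the
  standard convention that preserves the sum-to-1 invariant.
* A vanishing `u^p h^q` normalizer at a voxel falls back to the
  unweighted memberships there, with a logged warning.
* Random initialization draws `c` intensities uniformly from the
  in-mask range with an explicit seed; duplicate centroids (any mode)
  are perturbed by the smallest representable step so distinctness is
  guaranteed. Operator initialization averages the supplied per-cluster
  sample intensities.
* Objective traces: FCM records `J_m` (provably non-increasing, and
  asserted so); KFCM and SKFCM record their kernelized objectives;
  SFCM/MSKFCM record the analogous diagnostic computed with the spatial
  memberships (no monotonicity is claimed for these — their update is
  not a coordinate descent on a single functional).

## Nodule-cluster selection

With an operator hint (sample nodule intensities) the cluster whose
centroid is nearest the hint mean is selected. Without a hint and with
`c = 3` the middle cluster by centroid intensity is selected — the
lung / nodule / vessel-or-tissue ordering puts nodules in the middle,
and `c = 3` is the configuration under which the combined algorithm
assigns the nodule to a consistent cluster. Any other `c` without a
hint is an explicit error rather than a guess. Note the middle-cluster
rule presumes three *distinct* intensity populations: on data with only
two populations, a three-cluster run splits the dominant one and the
rule is meaningless — supply a hint there.

## Evaluation

Per slice: `TP% = 100·|predicted ∩ truth| / |truth|` and
`FP% = 100·|predicted \ truth| / |predicted|` (the complement of
precision — with a tiny nodule inside a large lung, normalizing FP by
the non-nodule area would make every FP% microscopic and useless for
ranking). The alternative denominator `|domain \ truth|` is available
behind `fp_denominator="domain"` and the choice is recorded in every
record. Slices with empty truth report TP% as missing, not zero.
Consensus masks score each voxel 0–1000 by radiologist agreement;
thresholding at ≥ 800 keeps strong-consensus voxels. Parameter sweeps
run a solver over a grid and emit one record per (combination, slice),
deterministically ordered, with per-combination failures recorded
rather than aborting; the tradeoff table sorts by FP% then −TP%, the
tabular form of a TP-vs-FP tradeoff curve.

## The phantom generator

`PhantomSpec` renders the intensity structure that matters to these
algorithms: an elliptical "lung" of −850 HU parenchyma inside a 40 HU
wall, spherical nodules at −50 HU, axis-aligned vessel tubes at 30 HU,
additive Gaussian noise (default sd 20 HU), clipped to the 12-bit HU
range [−1024, 3071]. The default phantom is 3 slices of 64×64 with one
radius-4 nodule and two vessels — big enough for 3×3×3 windows and
distinct vessel/nodule/lung populations, small enough that the whole
test suite runs in seconds. With sd 20 the nodule/lung separation is
40 σ, so centroid recovery failures indicate algorithmic defects, not
ambiguity. Consensus masks are emulated by grading each nodule from its
eroded core (1000) outward in 250-point shells.

What the phantom does **not** emulate: real parenchymal texture,
partial-volume blur at structure boundaries, juxtapleural attachment,
scanner artifacts, or the intensity overlap between faint nodules and
vessels that makes real LIDC slices hard. Passing the phantom tests
shows the solvers implement their update rules correctly and behave as
designed under controlled separations — not that they reach any
particular accuracy on clinical data.

## Problem sizes used

Unit oracles run on ≤ 8×8 images; limit/recovery checks on 32×32
two-population images (500–512 voxels per population); end-to-end
checks on the 3×64×64 phantom (~7300 in-mask voxels); the CLI pipeline
check runs all five solvers in 2D and 3D twice. The acceptance script
reruns the full pipeline on the standard phantom: centroid recovery
(operator-sample init, the stable mode — random init can legitimately
fall into a background-splitting local minimum, which is a property of
FCM-family objectives, not a defect), per-algorithm ROI TP/FP, the
salt-and-pepper robustness comparison (5% of in-mask voxels flipped to
the volume's own min/max, mislabels counted under the best
cluster-to-class bijection so the measure ignores index permutations),
and a five-point σ sweep.

## Known limitations

* Scalar intensities only — no multifeature/vector clustering.
* Lung isolation is out of scope; the toolkit consumes a precomputed
  lung mask (all voxels participate without one).
* 3D neighborhoods are rectangular prisms only.
* LIDC XML consensus scaling (votes × 1000/readers) is an emulation of
  the 0–1000 consensus convention, labeled as such; the original
  consensus-mask construction is not publicly specified.
* No ROC/FROC analysis: this stage reduces the search space; it is not
  the final classifier.
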