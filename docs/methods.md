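# Methods

## The robustness procedure

The framework assesses whether a delta-radiomics feature's ability to
separate two biological groups survives changes in CT acquisition settings.
It operates on two tables per feature:

* a **cohort table** — one row per patient, annotated wildtype/mutant, with
  n_r = 20 and n_s = 26 by default;
* a **phantom table** — one row per (lesion, scan condition), n_p = 24
  lesions under n_c = 8 conditions by default.

The biological signal BS is the multiset of all n_r·n_s cross-group absolute
differences of the feature. For every unordered condition pair (i, j) the
noise signal NS_ij is the multiset of n_p per-lesion absolute differences
between the two conditions. BS and every NS_ij are divided by the single
constant μ_BS + σ_BS — the noise sets are deliberately *not* self-normalised,
so their normalised means are directly comparable to the normalised
biological mean μ_BS/(μ_BS + σ_BS) ∈ (0, 1]. Each NS_ij is compared to BS
with a two-sided pooled-variance two-sample t-test; the pair is robust iff
p < α (default 0.05) and the normalised biological mean exceeds the
normalised noise mean. The direction condition matters: a significant
difference with noise *above* biology indicates the feature is dominated by
acquisition effects and must not count as robust. A feature is robust
overall when a strict majority of its n_c(n_c−1)/2 pairs are robust.

Assumptions worth stating: the t-test treats the n_r·n_s pairwise
differences as a sample, although they are built from only n_r + n_s
independent measurements; with |BS| = 520 against |NS| = 24 the test is
powerful and its p-values should be read as a screening heuristic, not as
calibrated error rates. No multiple-testing correction is applied across the
28 cells by default (each cell answers its own question — "can a model
trained at condition i transfer to j?"); Bonferroni/Benjamini–Hochberg are
available as an option on `RobustnessModel`, as is Welch's t-test and the
sample (1/(n−1)) moment convention. The default uses population (1/n)
moments everywhere, matching Lin's original concordance formula used in the
screen.

## Screening and selection

* **Reproducibility**: Lin's CCC with 1/n moments between a table and its
  retest replicate; features with CCC < 0.85 are excluded (the comparison is
  inclusive at the threshold). The screen accepts single-timepoint or delta
  tables — it only needs matched sample ids.
* **Redundancy**: average-linkage hierarchical clustering on distance
  1 − |ρ_Spearman|, tree cut at 1 − 0.85. The absolute value treats
  anti-correlated features as redundant; average linkage is the common
  default for correlation-based feature clustering. A constant feature has
  undefined correlations; they are treated as 0 (logged), isolating the
  feature in its own cluster.
* **Informativeness**: orientation-free AUC, max(A, 1−A) with A = U/(n₁n₂)
  and ties counted ½, so no positive class needs designating. Per cluster
  the max-AUC feature is selected iff its AUC > 0.7; AUC ties break
  lexicographically. CIs, when requested, are percentile bootstrap
  (2000 resamples) — a pragmatic choice, not a claim of exactness.

## Synthetic data: what it emulates, what it does not

The generators define the default study conditions:

* **Cohort**: 20 wildtype / 26 mutant subjects; per-feature Gaussian group
  means with common spread (lognormal optional), plus "duplicate" features
  (noisy copies) for planting redundancy. Default planted effects: a
  size-style feature at separation 2.0 SD, boundary-style at 1.6, two
  texture-style at 1.5/1.4, one null feature, one informative feature with
  test–retest CCC 0.3 that the screen must remove.
* **Retest**: retest = base + N(0, σ_e²) with σ_e² = 2σ_x²(1−c)/c, which
  makes the expected CCC equal the target c; recovered within ±0.03 at
  n = 1000.
* **Phantom images**: 24 digital lesions — {10, 20} mm volume-equivalent
  diameter × {spherical, elliptical (axis ratios 1:0.7:0.5), lobular
  (4 smooth radial bumps), spiculated (12 narrow spikes)} × {−630, −10,
  +100} HU on −850 HU background, rendered as star-convex surfaces whose
  base radius is normalised so the enclosed volume matches the
  volume-equivalent sphere (numerical quadrature over 4096 directions;
  voxelised volume within 5%, typically < 1%). Grid 0.7 × 0.7 mm in-plane,
  1.25 mm slices. Acquisition is additive zero-mean Gaussian noise with
  σ = 20 HU · sqrt(276.5 / effective mAs), i.e. quantum noise scaling as
  1/sqrt(dose), plus a scanner-specific Gaussian blur (0 vs 0.4 mm) standing
  in for reconstruction-kernel differences. Not modelled: sinogram physics,
  beam hardening, kernel frequency responses, lesion placement inside
  anatomy, motion. Consequently, passing tests demonstrate that the
  *pipeline machinery* behaves correctly under a controlled noise law — not
  that any particular real feature is robust on a physical scanner.
* **Phantom tables**: the tabular shortcut used by the robustness stage in
  tests draws per-lesion base values and adds condition-scaled noise
  (per-condition scale ∝ sqrt(mas_ref/mas) in the default pipeline), so the
  injected noise is exactly recoverable from per-lesion differences.

Default scan conditions are two scanners at four tube currents (395/195/
100/50 mA × 0.7 s and 480/260/130/65 mA × 0.5 s), chosen so effective mAs
roughly matches across scanners; this yields the 8 conditions and 28 pairs
used throughout.

## Feature extractors

* **Tumor mass**: Σ over mask voxels of (HU + 1000)/1000 mg/mm³ × voxel
  volume, floored at air = 0. The water-equivalent conversion is the
  standard single-energy CT density surrogate.
* **Sigmoid boundary offset**: HU profiles sampled by trilinear
  interpolation along outward surface normals (smoothed-mask gradient),
  half-length 6 mm at 0.35 mm steps; least-squares fit of
  A/(1 + exp((t − offset)/slope)) + B with offset initialised at 0, slope at
  1 mm, A/B from the profile ends, offset bounded to ±6 mm and slope to
  [10⁻³, 6] mm. Up to 200 surface points (deterministic even subsample);
  failed fits are dropped and > 50 % failures raise rather than return a
  silent value. The mean offset localises the density transition relative to
  the mask surface; a +1.5 mm planted shift is recovered within 2 %.
* **Gabor energy**: 4 orientations × wavelengths of 4 and 8 in-plane voxels,
  real Gabor kernels recentred to exactly zero mean, applied per axial slice
  (CT anisotropy); outside-mask pixels are replaced by the slice's in-mask
  mean so background cannot leak in; energy = mean squared response over
  mask voxels and bank elements. Zero on constants; exactly quadratic under
  intensity scaling.
* **DWT energy**: Daubechies-4, 2-level separable 3D transform of the mask
  bounding box (outside-mask filled with the in-mask mean, short axes
  edge-padded to 2²); energy = Σ squared detail coefficients / mask voxels.
  Symmetric extension makes a constant region contribute exactly zero.
* **Size**: volume = voxel count × voxel volume; largest diameter is the
  max pairwise boundary-voxel distance within axial slices (RECIST-style
  convention; a 3D variant is available via `diameter_plane="3d"`).
* Empty and single-voxel masks raise errors instead of returning zeros —
  silent zeros would contaminate downstream signal sets.

Absolute energy/offset values depend on these parameterisations; only
signs, orderings and pipeline behaviour are meaningful across
implementations.

## Numerical and design choices

* Population (1/n) moments are the package-wide default (CCC, σ_BS);
  `ddof=1` is a switch on the robustness model and signal sets.
* Degenerate t-test (both sets zero-variance): p defined as 1 when means are
  equal, else 0, and logged.
* An all-zero biological signal cannot be normalised and raises.
* Every generator takes one integer seed; condition-level sub-seeds are
  derived deterministically as (seed, condition index), so tables are
  bit-reproducible and lesion identity is preserved across conditions.
* Problem sizes in the test-suite and acceptance script (n = 1000 retest
  pairs, 20 seeds × 28 cells for recovery curves, 100 brute-force oracle
  instances) were chosen to keep Monte-Carlo error well below the asserted
  margins while running on a single CPU in seconds.

## Known limitations

* With the default cohort size (46), AUC estimates carry sampling noise of
  roughly ±0.06; a planted feature whose true AUC sits near the 0.7 gate can
  fall on either side for a given seed. The default effects were chosen so
  this is rare, but it is a real property of small-cohort univariate
  selection, not a defect of the gate.
* The t-test independence caveat above; a variance-component model would be
  the statistically stricter alternative and is out of scope.
* The phantom renderer produces isolated lesions on homogeneous background;
  features sensitive to surrounding anatomy (e.g. boundary offset against
  structured parenchyma) are exercised only in their idealised regime.
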