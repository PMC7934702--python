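# radrobust

Robustness screening for delta-radiomics features: does a feature's
*biological* signal outweigh the *acquisition noise* introduced by scanning
the same object on a different scanner or at a different tube current?

Radiomics models are notoriously fragile across CT acquisition settings.
Test–retest reproducibility alone only says a feature agrees with itself; it
says nothing about whether the feature can still separate two biological
classes once scanner noise is added. `radrobust` implements a framework that
closes that gap for delta features (baseline minus follow-up): it screens
features for reproducibility, redundancy and informativeness on a two-group
cohort, then tests each survivor's biological signal against phantom-derived
acquisition noise, condition pair by condition pair.

## The statistic at its core

For a feature, with wildtype values `x_r` (r = 1…n_r) and mutant values
`x_s` (s = 1…n_s), the **biological signal** is the set of all cross-group
absolute differences:

```
BS = { |x_r − x_s| : r = 1…n_r, s = 1…n_s }          (n_r·n_s values)
```

With phantom lesion values `p_si` measured under scan condition *i*, the
**noise signal** for an unordered condition pair (i, j) is the per-lesion
set:

```
NS_ij = { |p_si − p_sj| : s = 1…n_p }                 (n_p values)
```

Both sets are divided by the single constant `μ_BS + σ_BS` (mean and standard
deviation of BS), and each NS_ij is compared with BS by a two-sided pooled
two-sample t-test. A feature is **robust at (i, j)** iff `p < 0.05` *and*
`mean(BS) > mean(NS_ij)` after normalisation; it is robust overall when a
strict majority of the `n_c(n_c−1)/2` condition pairs are robust. With the
default 8 conditions (2 scanners × 4 tube currents) that is 28 pairwise
cells per feature.

Upstream of this test, the standard selection chain is: Lin's concordance
correlation ≥ 0.85 on a test–retest replicate, average-linkage hierarchical
clustering of Spearman correlations at |ρ| > 0.85, and one AUC > 0.7
representative per cluster.

The package ships a synthetic-data module — a 24-lesion digital phantom
(2 sizes × 4 shapes × 3 densities, mAs-dependent Gaussian noise), a 20/26
two-group cohort generator and a retest generator with controllable CCC — so
the whole pipeline runs with fully known ground truth. Feature extractors
(tumor mass, sigmoid boundary offset, Gabor energy, wavelet detail energy,
volume, largest diameter) operate on NIfTI volume+mask pairs.

## Worked example

```python
import radrobust as rr
from radrobust.pipeline import _build_tables

cohort, retest, phantom = _build_tables(rr.default_config(), seed=0)

for r in rr.screen_reproducible(cohort, retest):
    print(f"{r.feature:22s} ccc={r.ccc:.3f} kept={r.kept}")

model = rr.RobustnessModel(cohort, phantom, features=[
    "delta_volume", "delta_sigmoid_offset", "delta_gabor_energy", "delta_dwt_energy"])
print(model.fit().summary())
```

prints

```
delta_volume           ccc=0.975 kept=True
delta_tumor_mass       ccc=0.983 kept=True
delta_sigmoid_offset   ccc=0.960 kept=True
delta_gabor_energy     ccc=0.954 kept=True
delta_dwt_energy       ccc=0.948 kept=True
delta_compactness      ccc=0.950 kept=True
delta_skewness         ccc=0.466 kept=False

Radiomics feature robustness: biological vs acquisition-noise signal
cohort n = 46; phantom lesions x conditions = 24 x 8; alpha = 0.05

feature                       mean BS  robust cells  fraction  robust
---------------------------------------------------------------------
delta_volume                    0.671         28/28     1.000     yes
delta_sigmoid_offset            0.645         28/28     1.000     yes
delta_gabor_energy              0.607         28/28     1.000     yes
delta_dwt_energy                0.593          0/28     0.000      no
```

Reading it: `delta_skewness` was planted with a low test–retest reliability
and falls to the CCC screen. Of the selected features, the size-, boundary-
and Gabor-texture-style features have normalised biological means around
0.6–0.7 that significantly exceed the phantom noise in all 28 condition
pairs; the wavelet-energy-style feature was planted with acquisition noise
on the scale of its biological signal, so no condition pair is robust — the
model keeps the feature out of any cross-scanner use.

The same pipeline is available from the shell:

```bash
radrobust run-all --out results/run --seed 0
radrobust simulate-phantom --out phantom/ --seed 1      # NIfTI volumes + masks
radrobust assess-robustness --cohort cohort.csv --phantom phantom.csv --out robustness.csv
```

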