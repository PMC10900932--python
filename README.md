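# spsd — stochastic parametric skeletal dosimetry

`spsd` estimates the radiation dose rate to **active bone marrow (AM)** from
the bone-seeking beta emitters **⁸⁹Sr** and **⁹⁰Sr(+⁹⁰Y)** incorporated in
trabecular (*TBV*) and cortical (*CBV*) bone, together with a full
uncertainty budget.  It is aimed at dose-reconstruction work for
epidemiological cohorts, where what matters is not a patient-specific dose
but an unbiased population-average **dose factor**

&nbsp;&nbsp;&nbsp;&nbsp;*DF*(AM←s)  [10⁻¹¹ Gy s⁻¹ per Bq g⁻¹ of parent nuclide],  s ∈ {TBV, CBV}

with an honest split of its uncertainty into a **shared** (systematic,
population-common) and an **unshared** (individual-variability) part — the
two inputs a two-dimensional Monte Carlo dose-reconstruction system needs.

## What the toolkit does

* **Stochastic stylized phantoms.** Hematopoietic bone segments are stylized
  solids (boxes, elliptic and deformed cylinders, ellipsoids, pyramids,
  tubes) carrying a cortical shell of thickness *Ct.Th* and a rod-like
  trabecular lattice parameterized by *Tb.Th*, *Tb.Sp* and the bone volume
  fraction *BV/TV*.  Individual variability is sampled from correlated
  truncated normal (macro) and lognormal (micro) distributions via a
  Gaussian copula; phantoms are voxelized (center-point membership) and
  exported as raw grids + JSON sidecars for transport codes.
* **Analytic dose-factor surrogates.** For segments larger than two electron
  mean pathlengths, λ(Ē) = 0.112 + 0.099·e^(−1.526·BV/TV) cm,

  &nbsp;&nbsp;*DF*(AM←TBV) = a·(1 − e^(−b·BV/TV)),  (a, b) = (28, 0.897) for ⁹⁰Sr, (13.9, 1.06) for ⁸⁹Sr

  &nbsp;&nbsp;*DF*(AM←CBV) = *DF*(AM←TBV) · F꜀(Ct.Th) · V_CBV/V_TBV,  F꜀ = a_F·e^(−b_F·Ct.Th)

  with residual-uncertainty laws attached, a crossfire adjustment
  (SS_ext/SS)^0.28 for small segments, and size-class logic that decides
  which uncertainty components apply.
* **Uncertainty engine and skeletal averaging.** Component budgets
  (stylization, voxelization, restriction, cortical uniformity — shared;
  micro/macro architecture, density, chemical composition, AM distribution —
  unshared) combine in quadrature; segment→site→skeleton averaging uses
  marrow-mass and AM-fraction weights with inter-site correlation ρ = 0.5;
  bootstrap variance-of-variance (VOV) logic sizes the random phantom sets;
  a two-dimensional Monte Carlo (shared: normal; unshared: lognormal)
  produces individual dose-factor realizations and credible intervals.

## Worked example

```python
from spsd import (build_solid, add_cortical_shell, derive_geometry,
                  classify_segment, df_tbv_analytic, df_cbv_analytic,
                  two_dim_mc)
from spsd.fixtures import small_phantom_specs, media_basic

bone, marrow = media_basic()                 # 1.9 / 0.98 g/cm3
spec = small_phantom_specs()[2]              # 0.6 x 0.6 x 3.0 cm cylinder,
                                             # BV/TV 0.28, Ct.Th 0.13 cm
part = add_cortical_shell(build_solid(spec.shape), spec.ct_th,
                          spec.cortical_coverage)
geom = derive_geometry(part, bone, marrow, bvtv=spec.micro.bvtv)
print(geom.v_s, geom.ss, geom.v_cbv)         # 0.272 cm3, 3.39 cm2, 0.576 cm3
print(classify_segment(geom))                # (TBV4, CBV5)

df_t = df_tbv_analytic(spec.micro.bvtv, "Sr90")
df_c = df_cbv_analytic(spec.micro.bvtv, spec.ct_th,
                       geom.v_cbv, geom.v_tbv, "Sr90")
print(df_t.value, df_t.delta)                # 6.219e-11 Gy/s per Bq/g, 7.3%
print(df_c.value, df_c.delta)                # 10.691e-11, 12.4%

res = two_dim_mc(1.54, 0.11, 0.36, n_outer=600, n_inner=400, seed=1)
print(res.cv, res.ci90)                      # 0.376, (0.78, 2.61)
```

The spongiosa volume 0.272 cm³ and cortical volume 0.576 cm³ match the
reference tables for this phantom; the segment is "small" for both source
tissues (its spongiosa volume sits below the 1.1 cm³ / between the 0.2 and
1.6 cm³ cuts), so stylization, restriction and the small-segment density
components enter its budget.  The two-dimensional Monte Carlo run shows that
an adult-male ⁹⁰Sr *DF*(AM←CBV) of 1.54×10⁻¹¹ with an 11%/36%
shared/unshared split spreads individuals over roughly 0.8–2.6×10⁻¹¹
(90% interval).

A command-line interface mirrors the library
(`spsd generate-phantom | sample-population | compute-df | skeletal-average |
uncertainty-budget | two-dim-mc | min-sample-size`); every run logs its
resolved configuration and seeds, and identical configurations reproduce
byte-identical outputs.

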