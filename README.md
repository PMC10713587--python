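# sparsectp

Surrogate CT perfusion maps and DEFUSE-3 target-mismatch classification from
sparse dynamic CT.

Standard CT perfusion (CTP) requires a dedicated dynamic acquisition that many
stroke-receiving hospitals cannot run routinely.  A pragmatic alternative is
to treat the scans that *are* universal — a non-contrast CT (NCCT) plus a
multiphase CT angiogram (mCTA: arterial-peak phase and two delayed phases at
8 s intervals) — as a four-frame dynamic study ("mCTA-P") and compute
perfusion maps from it.  `sparsectp` implements that workflow end to end for
researchers evaluating sparse-protocol perfusion imaging:

* **Kinetic model.**  Tissue enhancement is modelled as
  `Q(t) = F · (Ca ⊛ R)(t)` with the Johnson–Wilson–Lee impulse residue
  `R(t) = 0` for `t < T0`, `1` on `[T0, T0+W)`, and `E·exp(−k(t−T0−W))`
  afterwards, with the clearance `k` fixed at 0.  Summary maps follow from
  the residue: `CBV = ∫ F·R dt`, `MTT = CBV/CBF` (Central Volume Principle),
  and `Tmax = T0 + MTT/2`.
* **Fitting.**  Voxelwise least squares by exhaustive search over a `(T0, W)`
  grid with the two linear amplitudes `(F, F·E)` solved in closed form under
  `0 ≤ E ≤ 1` — deterministic and immune to local minima even on 4-frame
  data.  Sparse studies additionally restore the arterial input with a
  gamma-variate bolus fit and compare model and data through the same
  sampling operator.
* **Lesion analysis.**  Hypoperfusion (`Tmax > 4 s`, ipsilateral), ischemic
  core (relative CBF `< 15 %` of the contralateral mean for CTP, `< 25 %` for
  the 4-frame studies), penumbra (`Tmax > 6 s` / `> 5 s`), morphological
  cleanup with a 1 ml minimum component size, and the DEFUSE-3 profile
  (favourable iff core `< 70` ml, penumbra `≥ 15` ml, penumbra/core `≥ 1.8`).
* **Agreement statistics.**  Cohen's κ with delta-method CIs,
  sensitivity/specificity/accuracy, Pearson R, Bland–Altman limits of
  agreement, and a lesion-threshold calibrator.
* **Digital phantoms.**  A 4-D dynamic brain with known `(T0, W, F, E)`
  ground truth per region, and a head phantom (skull annulus + plexiglass
  interior) for the CT-number ring analysis that quantifies the NCCT↔mCTA
  scatter bias (~4 HU at 40 mm collimation).

## Worked example

```python
import sparsectp as sp

spec = sp.DigitalBrainSpec(noise_sd=0.0)                 # 64x64x8 @ 2x2x5 mm
series, truth, _ = sp.generate_digital_brain(spec, sp.AcquisitionProtocol.mcta_p())

maps = sp.perfusion_pipeline(series, fwhm_mm=0.0, bias_hu=4.0)
result = sp.analyze_lesions(maps, series, sp.SPARSE_THRESHOLDS)
print(f"core {result.core_ml:.1f} ml, penumbra {result.penumbra_ml:.1f} ml, "
      f"ratio {result.mismatch_ratio:.1f}, {result.profile}")
```

prints

```
core 2.1 ml, penumbra 21.3 ml, ratio 10.2, favourable
```

i.e. the 4-frame surrogate pipeline (with the +4 HU mCTA bias corrected)
segments a 2.1 ml core and 21.3 ml penumbra on the default phantom, a
favourable target mismatch — matching the profile computed from the phantom's
ground-truth maps (2.2 ml / 21.1 ml).

The same workflow is available from a shell:

```
sparsectp simulate --protocol mcta-p --seed 7 --out run/
sparsectp maps --series run/series --bias-hu 4 --out run/maps
sparsectp lesions --maps run/maps --series run/series --preset sparse --out run/report.json
```

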