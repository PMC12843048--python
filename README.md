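# uteqsm

Quantitative susceptibility mapping (QSM) for ultrashort-echo-time (UTE)
multi-echo MRI, with **separation of paramagnetic and diamagnetic
susceptibility sources**.

## The problem

Magnetic susceptibility χ reveals tissue composition: iron-containing
deposits (e.g. hemosiderin in hemophilic arthropathy) are paramagnetic
(χ > 0), while bone mineral and most connective tissue are diamagnetic
(χ < 0). Conventional QSM estimates only the *net* χ per voxel, so a voxel
containing both sources shows near-zero susceptibility — the two
contributions cancel and the iron is invisible. Musculoskeletal imaging adds
two further complications: many joint tissues have very short T2\* (hence
UTE acquisitions and echo times down to tens of microseconds), and fat is
abundant, whose chemical shift corrupts field maps unless modeled.

`uteqsm` implements the full processing chain for this setting:

1. **Multi-echo water/fat fitting** (IDEAL-style, `uteqsm.ideal`) — the
   complex signal at echo time *t* is modeled as

   S(t) = ( S_W e^(−t/T2\*) + S_F Σ_k α_k e^(i2πf_k t) ) · e^(i(φ₀ + 2πf_B0 t))

   with water and fat amplitudes S_W, S_F, a six-peak fat spectrum
   (α_k, f_k), water T2\*, initial phase φ₀ and B0 off-resonance f_B0.
   A variable-projection solver (closed-form amplitudes/phase per candidate
   (f_B0, R2\*), global grid + pattern search + Newton polish) avoids
   fat–water swaps.
2. **Background-field removal** (`uteqsm.pdf`) — projection onto dipole
   fields: the field of sources outside the tissue mask is fitted by
   weighted least squares and subtracted, leaving the tissue local field.
3. **χ-separation** (`uteqsm.chisep`) — the local field b and the
   reversible relaxation rate R2′ = R2\* − R2 are jointly inverted for a
   nonnegative paramagnetic map χ⁺ and nonpositive diamagnetic map χ⁻:

   min λ_f‖W(b − D⊛(χ⁺+χ⁻))‖² + λ_r‖W′(R2′ − D_r(χ⁺−χ⁻))‖² + λ_reg R(χ⁺,χ⁻),
   s.t. χ⁺ ≥ 0, χ⁻ ≤ 0

   where D is the dipole kernel D(k) = 1/3 − (k·b̂₀)²/|k|² and D_r a
   relaxometric constant (s⁻¹/ppm). The solver is an alternating projected
   gradient method with backtracking (monotone, sign-feasible iterates).
4. **Synthetic phantom** (`uteqsm.phantom`) — a three-tube mixed-source
   phantom (CaCO₃-proxy 522/347/174 mg/mL + Fe₃O₄-proxy 12/8/4 mg/mL in an
   agarose container) with linear concentration→χ and concentration→R2\*
   calibration, forward-simulated to complex multi-echo images with seeded
   complex Gaussian noise.

## Worked example

```python
import numpy as np
import uteqsm as u
from uteqsm.phantom import TE_PHANTOM_S

spec = u.PhantomSpec()                      # 522/347/174 + 12/8/4 mg/mL design
gt = u.make_tube_phantom(spec, u.phantom_geometry(64))
series = u.simulate_acquisition(gt, TE_PHANTOM_S, snr=50.0, seed=1,
                                external_sources=[u.ExternalSphere()])
result = u.process_series(series)           # IDEAL -> PDF -> chi-separation

for i in (1, 2, 3):
    roi = gt.tube_rois == i
    print(f"tube {i}: chi_total {result.susceptibility.chi_total[roi].mean():+.3f}  "
          f"chi_para {result.susceptibility.chi_para[roi].mean():+.3f}  "
          f"chi_dia {result.susceptibility.chi_dia[roi].mean():+.3f} ppm")
```

Output (seed 1):

```
tube 1: chi_total +0.116  chi_para +0.874  chi_dia -0.758 ppm
tube 2: chi_total +0.078  chi_para +0.596  chi_dia -0.518 ppm
tube 3: chi_total +0.037  chi_para +0.320  chi_dia -0.284 ppm
```

The total map barely distinguishes the tubes (mixed sources cancel), while
the separated maps recover both components: ground truth χ⁺ is
0.84/0.56/0.28 ppm and χ⁻ is −0.70/−0.47/−0.23 ppm, so each component is
recovered with the correct ordering and a small uniform bias from the
assumed R2–R2\* proportionality (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
uteqsm simulate --preset phantom3t --snr 50 --seed 7 --out phantom/
uteqsm run --config pipeline.json
uteqsm report --maps out/ --rois phantom/tube_rois.nii.gz --out summary.csv
```

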