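# dcequant

Quantitative dynamic contrast-enhanced MRI (DCE-MRI) of rim-enhancing
tumors, built around a digital phantom with known ground truth.

Orthotopic breast-tumor xenografts imaged weekly at 3 T show a
characteristic vascular signature: gadolinium uptake confined to a thin
enhancing rim around a necrotic, poorly perfused core that grows as the
tumor progresses. This package re-implements the full quantitative chain
used to measure that signature — pixel-wise baseline T1 mapping,
signal-to-concentration conversion, AUC₉₀ vascularity maps, rim/core
enhancement curves — and the exact statistical test on tumor take rates
across inoculation methods. Because no in-vivo data is distributed, a
synthetic tumor phantom emulates the acquisition protocol (3D SPGR at flip
angles 2°/10°/20°, TR = 6.2 ms; dynamic frames every 9.1 s for 8 min 52 s
with the bolus at 2 min) so every estimate can be validated against ground
truth. The audience is imaging scientists who need a tested, reproducible
reference for these classical DCE-MRI computations.

## Models

**SPGR signal.** S = M₀ sin α (1 − E₁)/(1 − E₁ cos α), E₁ = exp(−TR/T1).

**Variable-flip-angle T1 mapping (DESPOT1).** With y = S/sin α and
x = S/tan α, the SPGR equation is linear with slope E₁, so an unweighted
least-squares line over the flip angles yields T1 = −TR/ln E₁ and
M₀ = intercept/(1 − E₁). Slopes outside (0, 1) are flagged invalid.

**Concentration conversion.** Per frame the SPGR equation is inverted
exactly for T1(t); then C(t) = (1/T1(t) − 1/T1₀)/r₁ with relaxivity
r₁ = 3.7 s⁻¹·mM⁻¹ by default.

**AUC₉₀.** Trapezoidal integral of C(t) over the first 90 s after contrast
arrival in tissue (arrival detected from the tumor-median curve), reported
in mM·min. A semi-quantitative index of vascularity and vessel leakiness.

**Phantom kinetics.** Ground-truth curves follow the extended Tofts model
C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^(−K^trans(t−τ)/v_e) dτ with a
biexponential (Weinmann-type) population arterial input function, and Rician
noise (magnitude of complex Gaussian).

**Take-rate inference.** The Freeman–Halton generalization of Fisher's
exact test for r×2 tables: two-tailed p = Σ P(T) over all margin-consistent
tables with multivariate hypergeometric mass P(T) ≤ P(observed).

## Worked example

Run the analysis chain (each script is a thin driver over the library):

```sh
python analysis/01_simulate_phantom.py
python analysis/02_fit_t1_maps.py
python analysis/03_dce_quantification.py
python analysis/04_take_rate_inference.py
```

which prints, e.g.:

```
DCE quantification on the simulated tumor:
  bolus arrival detected at frame 14 (t = 127.4 s)
  mean AUC90: rim 1.32 mM*min, core 0.22 mM*min (ratio 5.9)
  peak SI_rel: rim 477%, core 216%
```

The bolus is injected at 120 s; the first enhanced frame is 14 (127.4 s).
The rim's mean AUC₉₀ exceeds the core's roughly six-fold — the rim-enhancing
/ necrotic-core pattern the phantom is built to emulate — and the relative
signal enhancement SI_rel(t) = (SI(t) − SI_base)/SI_base × 100% plateaus far
higher in the rim than the core. And the take-rate comparison:

```
Freeman-Halton exact test (two-tailed): p = 0.0028 (exact enumeration, 13 animals)
```

Only ultrasound-guided orthotopic injection established tumors (4/4 vs 0/4
and 0/5); p = 0.0028 (= 2/715 exactly) says the methods genuinely differ.

The same stages are scriptable through the CLI (`dcequant simulate`,
`fit-t1`, `dce`, `exact-test`, `pipeline`); `dcequant pipeline --seed 7
--outdir out/` runs everything from a config file and writes a provenance
manifest with content hashes.

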