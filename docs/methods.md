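# Methods

## The phantom and what it emulates

The digital phantom stands in for an orthotopic xenograft imaged with a
clinical 3 T DCE-MRI protocol. Its geometry is a spherical necrotic core
(default radius 5 voxels) wrapped in a vascular rim shell (default width
2 voxels), centred in a muscle slab occupying the lower three quarters of
the volume, with air elsewhere; the default grid is 32×32×8 voxels of
0.6×0.6×1 mm. Distances are Euclidean in voxel indices; the sphere may be
truncated by the slice extent, as a thick-slab acquisition through a larger
tumor would be, but must fit in-plane (violations raise a dimension error).

Per tissue class the ground truth is:

| class  | T1 (ms) | M₀ (a.u.) | K^trans (min⁻¹) | v_e  | v_p   |
|--------|---------|-----------|-----------------|------|-------|
| rim    | 1400    | 1000      | 0.25            | 0.35 | 0.03  |
| core   | 2000    | 1000      | 0.01            | 0.60 | 0.002 |
| muscle | 1200    | 800       | 0.10            | 0.12 | 0.02  |
| air    | —       | 0         | 0               | 0    | 0     |

These values are synthetic, chosen once to produce the qualitative in-vivo
pattern of interest — a strongly enhancing rim and a near-non-enhancing
core — with T1 values typical of tumor and muscle tissue at 3 T.

Tissue curves follow the extended Tofts model driven by a biexponential
Weinmann-type population arterial input function (amplitudes 3.99 and 4.78,
rates 0.144 and 0.0111 min⁻¹). No input function was measured for this
protocol, so the population curve is scaled by a dose amplitude of 0.57 mM
to peak at ≈5 mM plasma concentration for a 0.05 mmol/kg bolus; all AIF
parameters live in the run config and carry no analysis result on their
own. The contrast relaxivity defaults to r₁ = 3.7 s⁻¹·mM⁻¹ (a standard
gadopentetate value at 3 T) and is likewise configurable.

Signal generation uses the steady-state SPGR equation at the protocol
constants (TR 6.2 ms; VFA flip angles 2°/10°/20°; dynamic flip angle 20°,
a config parameter since the dynamic flip angle of the original keyhole
sequence is not recorded). T2*/TE decay is ignored: TE = 3.2 ms is short
against tissue T2* and the concentration pathway is purely T1. The keyhole
acquisition is modeled as fully sampled frames at the 9.1 s interval:
532 s of run give floor(532/9.1)+1 = 59 frames, timestamps t_k = 9.1·k s
with t = 0 at the first frame, bolus at 120 s. Noise is Rician — the
magnitude of complex Gaussian noise — with σ in signal units; the default
noise level is expressed as rim-baseline SNR 50.

What the phantom does **not** emulate: k-space/keyhole reconstruction
effects, B1 and slice-profile nonuniformity, motion, a measured (dispersed,
delayed, recirculating) arterial input, partial-volume mixing at tissue
boundaries, and spatial heterogeneity within a tissue class. Passing the
recovery tests therefore shows the analysis chain is self-consistent and
correctly inverts its forward models at realistic noise; it does not certify
accuracy against in-vivo confounds.

## Estimators

**T1 mapping.** The linearized DESPOT1 estimator is the primary fit:
unweighted least squares in (S/tan α, S/sin α) coordinates, slope E₁,
T1 = −TR/ln E₁, M₀ = intercept/(1 − E₁). Voxels with slope outside (0, 1)
(non-physical T1) are flagged and excluded, never clamped, and the validity
mask propagates to every downstream map. Voxels whose highest-flip-angle
signal falls below a threshold (default 5% of that volume's 99th
percentile) are masked before fitting. The linearized objective reweights
the noise, so at low SNR its minimizer drifts from the signal-space
least-squares minimizer (≈1% at SNR 50 with three angles); an optional
nonlinear refinement is provided. Unweighted linearized fitting is the
documented default because it is deterministic and era-typical.

**Concentration.** The SPGR equation is inverted algebraically per frame —
E₁(t) = (M₀ sin α − S)/(M₀ sin α − S cos α) — rather than via the linear
low-concentration approximation, which removes a model-mismatch term from
recovery tests; C(t) = (1/T1(t) − 1/T1₀)/r₁. Frames whose signal reaches
the SPGR asymptote M₀ sin α are uninvertible; such voxels are dropped from
the validity mask. Pre-arrival concentration is ≈0 by construction and is
reported as-is, not re-baselined.

**Arrival detection.** No detection rule is prescribed by the protocol, so
one is made explicit: arrival is the first frame at which the tumor-median
concentration exceeds k·SD of its pre-injection baseline for m consecutive
frames (defaults k = 3, m = 2; baseline = all frames more than one frame
interval before injection). On a noiseless series the SD collapses and the
rule reduces to the first frame with any enhancement. If never triggered
the injection frame is used and flagged.

**AUC₉₀.** Trapezoidal quadrature of C(t) from arrival to arrival + 90 s,
divided by 60 for mM·min. 90 s is not a multiple of 9.1 s, so the final
partial interval is integrated against the linear interpolant between the
bracketing frames — this endpoint convention is pinned by closed-form tests
(constant c → 1.5·c mM·min; a 0.01·t mM ramp → 0.675 mM·min).

**Rim/core ROIs.** Drawn morphologically instead of by hand: the core is
the tumor mask eroded by a Euclidean ball of radius rim_width (default 2),
the rim is the remainder. A single ball erosion is used rather than
iterating a cross-shaped structuring element because iteration measures L1
rather than Euclidean thickness and misplaces the shell on spherical
tumors; the volume border is treated as foreground so a tumor truncated by
the slab does not erode at that face.

**Enhancement curves.** ROI-mean signal first, then
SI_rel(t) = (SI(t) − SI_base)/SI_base × 100% with SI_base the mean
pre-injection ROI signal, making the baseline mean exactly zero.

**Exact test.** The Freeman–Halton r×2 test enumerates all success vectors
consistent with the margins (depth-first with bound pruning), accumulates
multivariate hypergeometric masses via log-gamma to avoid overflow, checks
they sum to 1 within 10⁻¹², and sums those ≤ the observed mass with a 10⁻⁷
relative tie tolerance. Tables over 200 observations are directed to the
seeded Monte-Carlo estimator (draws from the multivariate hypergeometric
null; binomial standard error). On the induction table (4/0, 0/4, 0/5) only
the observed vector and its guided/unguided mirror have minimal mass 1/715,
giving p = 2/715 ≈ 0.0028.

## Numerical choices

- Tofts convolution: exponentially weighted trapezoid recursion on a
  10×-refined uniform time grid, subsampled back to frame times; against
  the analytic constant-input solution the error is <0.5% at the 9.1 s
  frame interval (measured ≈10⁻⁵).
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds; identical seeds give bit-identical volumes, and the pipeline
  manifest records config, seed, version and output hashes.
- Degenerate inputs raise typed errors (empty ROI/air ROI, erosion emptying
  the core, AUC window past the end of the run, fewer than two flip angles,
  injection before the second frame) rather than returning silent values.

## Problem sizes

The default phantom (32×32×8, 59 frames) is the unit of all simulation
tests and drivers; recovery statistics that need replication (noisy T1
recovery) use 10⁴ replicate voxels, and Monte-Carlo p-value checks use 10⁵
draws. These sizes make every pipeline stage exact or statistically stable
while keeping a full run in seconds.

## Known limitations

- Unweighted linearized VFA fitting is noise-suboptimal; no B1 correction.
- Arrival detection assumes a sharp bolus; slow or dispersed arrivals bias
  AUC₉₀ windows.
- The measured in-vivo quantities of the original experiment (tumor
  volumes, growth timelines, histology) are observational inputs; the
  package only restates such values as mean ± sample SD and makes no
  attempt to re-derive them.
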