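# Methods

`quenchcal` implements the analysis by which tetramethylrhodamine (TMR)
self-quenching is calibrated as a short-range (15–25 Å) distance probe.
Two identical TMR dyes on the same molecule form a ground-state H-dimer when
close; exciton splitting makes the dimer's allowed absorption band
blue-shifted (550 → 520 nm) and the dimer itself dark, so emission reports
the monomer population and, through it, the inter-dye distance.  The
calibration rests on rigid polyproline-II rulers Cys-(Pro)n-Cys
(n = 0, 3, 5, 6; "0P…6P") that hold the two dyes at defined separations.

## Ruler geometry and accessible volumes

Rulers are built from ideal internal coordinates (NeRF placement) with the
canonical PPII dihedrals (φ, ψ, ω) = (−75°, +145°, 180°), which give a rise
of 3.09 Å/residue (SVD-projected Cα trace) — the textbook ~3.1 Å.  Backbone
N/CA/C/O plus CB are placed for every residue, and SG for the terminal
cysteines; side chains are not modelled further and no energy minimisation
is done (rigid-ruler assumption).

The dye explores an accessible volume (AV): all grid positions reachable
from the attachment sulfur by a linker of length L without steric clash.
We use the single-sphere (AV1) dye model with defaults L = 15 Å, linker
width 4.5 Å, dye radius 3.5 Å, grid 0.9 Å — plausible values for a
rhodamine on a thiol-reactive linker; they are configurable because no
single published set exists for this exact chemistry.  A grid cell is
*passable* if the linker half-width clears every atom's van der Waals
surface and *allowed* if the dye sphere clears it; the AV is every allowed
cell whose geodesic distance from the attachment atom is ≤ L.

The geodesic is computed by a chamfer flood fill over an extended stencil
(all primitive integer offsets up to 3 cells, Euclidean edge weights),
iterated to convergence (vectorised Bellman–Ford).  A 6-connected stencil
would give the Manhattan metric, whose free-space "ball" is an octahedron —
volume (4/3)L³ instead of (4/3)πL³ — so a wider stencil is not a
refinement but a correctness requirement; with the radius-3 stencil the
free-space AV volume is within ~3% of the analytic sphere at all tested
grid spacings.  The grid always places a node exactly at the attachment
atom (odd node count per axis), otherwise every geodesic inherits an
offset of up to √3·h/2.

The distance between AV centroids (R_mp) regressed on n gives
2.76 Å/residue across n = 0, 3, 5, 6 — slightly below the bare Cα rise
because the terminal dye clouds are asymmetrically occluded by the peptide.
The all-trans helix probability helper is plain (1 − p_cis)^n_bonds; the
bond-counting convention (whether terminal prolines count) is a caller
choice, since published ranges depend on it.

## Spectra

Synthetic monomer/dimer absorption bases are two-Gaussian sums: monomer
550 nm (major) + 520 nm shoulder at 0.55 relative amplitude, dimer with the
intensities reversed.  Band widths (18/20 nm) are FWHM: interpreted as
Gaussian σ the two bands merge and the monomer maximum drifts off 550 nm,
contradicting the band structure being modelled.  Unmixing is non-negative
least squares (fractions are physical populations), normalised to sum to 1.
Excitation and emission of a mixture are the *monomer* spectra scaled by the
monomer fraction — the dimer is taken as fully dark, the limiting case of
the exciton picture.

Exciton coupling uses the point-dipole form V = 5.04×10³ · κμ²/(n²R³)
cm⁻¹ (μ in Debye, R in Å); κ > 0 (cofacial) classifies H, κ < 0 J.  No
vibronic structure or extended-dipole correction is attempted.

The distance calibration is F(d) = F_min + (F_max − F_min)·d^h/(d50^h + d^h)
with h fixed at 1 (two-state monomer/dimer equilibrium); h can be varied
for sensitivity checks.  **Conditioning caveat:** over the ruler range
(7.6–24.6 Å) the h = 1 curve is nearly linear, so d50 is strongly
anti-correlated with F_max.  At 5% noise on four points the Cramér–Rao
bound on d50 is ~12 Å s.d. with F_max free, versus ~1.9 Å with both plateau
parameters known; the fit therefore exposes `fix_f_min`/`fix_f_max`, and
midpoint-recovery statements are made with the plateau fixed.  The floor is
physically near zero (full quenching below ~12 Å).

## TCSPC

Decays are modelled as Σᵢ aᵢ·e^(−t/τᵢ) convolved with the measured IRF
(FFT, zero-padded; sub-channel shift by Fourier phase) plus a flat
background.  Fitting uses variable projection: amplitudes and background
are linear and solved by weighted NNLS at each step of a nonlinear search
over log-lifetimes (and shift), with 3 deterministic log-spaced multi-starts.
The default statistic is the Poisson deviance with the linear solve
iteratively reweighted by model counts; Neyman χ² (weight floor 1 count) is
available but biases weak long-lived components low — on the preset decays
it pulls the 16.3 ns component down 17–23%, versus ~2% for the deviance.
The global fit shares one lifetime vector across histograms with free
per-curve amplitudes, shift and background.

Model-order selection picks the smallest n such that adding a component
gives no significant F-test improvement (α = 0.01) and the Pearson
residuals pass a lag-1 autocorrelation check (|r₁| < 4/√N).  Pearson
rather than deviance residuals are used for the adequacy check because
deviance residuals have non-zero channel-wise means at low counts, which
masquerades as correlation.

Amplitudes convert to fractional populations pᵢ = aᵢ/Σaⱼ (equal radiative
rates assumed — this convention reproduces both a 10 000:1000:1 population
ratio and a <0.5% slow-phase intensity share simultaneously) and to
fractional intensities fᵢ = aᵢτᵢ/Σaⱼτⱼ.

## FCS

Curves follow the single-species 3D Gaussian focal volume with triplet:
G(τ) = G0·(1+τ/τD)⁻¹·(1+τ/(s²τD))^(−1/2)·(1 + T/(1−T)·e^(−τ/τT)).
The structure parameter s is fixed at 5 by default (typical confocal
calibration; rarely identifiable from a single curve).  Positive parameters
are searched in log space; weights come from per-point errors when present,
else are uniform (uniform in log-lag on the quasi-logarithmic grid).  The
global fit ties τD, τT (and s) across curves with G0 and T free per curve.
Particle numbers are N = (1−T)/G0 (triplet-corrected; raw 1/G0 also
reported).

The timescale-bound logic refits the curve with one extra multiplicative
relaxation (1 + A·e^(−τ/τR); τR initialised on a µs–ms grid) and applies an
F-test at α = 0.01.  Because the triplet factor has the same functional
form, the reported "extra" term is whichever of the two lies farther in log
time from the base fit's triplet lifetime.  A non-detection bounds any
dimerisation dynamics to τ ≤ 100 ns (below the correlator's informative
lags) or to the window from the fitted diffusion time up to 300 ms (the
slowest self-quenching kinetics reported in the literature).

The triplet–power check is a one-sided Kendall rank test of T against laser
power.  With ≤ 4 power levels the exact null cannot reach p < 0.05 (minimum
1/n!), so a perfectly monotone series counts as consistent there.

The multiple-tau correlator uses m = 8 lags per octave with bin-doubling
and symmetric normalisation (each lag normalised by the means of its two
overlapping segments).  Its level-ℓ output equals, exactly, the direct
correlator of the 2^ℓ-binned trace — which is the oracle the tests use.

## Synthetic data

Generators emulate each measurement's statistical structure with ground
truth embedded in the returned object: TCSPC decays are Poisson draws of
the reconvolved expectation (Gaussian IRF, FWHM 120 ps, centred at 2 ns);
FCS curves get multiplicative Gaussian noise with s.d. ∝ √(1+τ/τD)
(long-lag scatter grows as fewer independent fluctuations are averaged — a
pragmatic stand-in for full correlator noise statistics); spectra get
additive Gaussian noise; blinking traces are sums of independent two-state
telegraph emitters with Poisson shot noise.  A master seed spawns
independent per-artifact streams, so adding a generator never shifts
another's output.

The preset scenario uses three-exponential decays with lifetimes
115 ps / 2.2 ns / 16.3 ns and amplitude ratio 10 000:1000:1 at 5×10⁶
counts over a 102 ns window (25 ps channels — the window spans ~6 slow
lifetimes, which the slow component's recovery needs); FCS with
τD = 0.24 ms, τT = 7 µs, s = 5; and a Hill midpoint of 18 Å read out at
575 nm.  Per-construct dimer fractions are derived self-consistently from
the Hill curve at the geometry module's ruler distances, and each
construct's FCS amplitude reflects the corresponding loss of visible
particles from a constant total concentration (dark fraction ≡ dimer
fraction).  Acquisition settings not published anywhere (channel count,
window, count rates) are plausible defaults and labelled as such.

What the generators deliberately omit: detector afterpulsing and dead time,
IRF tails/colour shift, photobleaching, cis-proline conformers, scattering
backgrounds, and photon-by-photon diffusion through the focus.  Passing
recovery tests therefore demonstrate estimator correctness under the
assumed noise models, not robustness to instrument artefacts.

## Problem sizes

Statistical guarantees are checked at: 50 Poisson decay replicates at
5×10⁶ counts (lifetime recovery and model-order selection), 100 FCS curves
at 2% noise (τD recovery and detection/false-alarm rates for an injected
50 µs relaxation), 200 Hill replicates at 5% noise, 10⁴-bin correlator
traces, and AV grids at L/10–L/12 spacing.
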