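# quenchcal

Calibration toolkit for **tetramethylrhodamine (TMR) self-quenching** as a
short-range (15–25 Å) distance probe.

When two TMR dyes on the same biomolecule come close, they form a
ground-state H-dimer: exciton coupling splits the excited state, the
allowed absorption band blue-shifts from 550 nm to 520 nm, and the dimer
goes dark.  Emission then reports the monomer population — a distance probe
complementary to FRET, sensitive exactly where conventional FRET pairs are
not.  `quenchcal` implements the full calibration pipeline built on
dye-labelled polyproline-II rulers Cys-(Pro)n-Cys (n = 0, 3, 5, 6):

- **geometry** — PPII ruler builder (φ = −75°, ψ = +145°, ω = 180°;
  ~3.1 Å rise/residue), AV1 accessible-volume engine (grid flood fill),
  mean dye positions and the distance-per-residue regression;
- **spectra** — monomer/dimer basis spectra, NNLS unmixing into species
  fractions, band-shift (cm⁻¹) and point-dipole exciton coupling
  V = 5.04×10³·κμ²/(n²R³) with H/J classification, the Hill distance
  calibration F(d) = F_min + (F_max−F_min)·d^h/(d50^h+d^h) with h = 1, and
  the Förster E ↔ R conversion R = R₀(1/E − 1)^(1/6);
- **tcspc** — IRF-reconvolution multi-exponential fitting (variable
  projection, Poisson deviance), global lifetime sharing across constructs,
  F-test model-order selection, fractional populations (∝ aᵢ) and
  intensities (∝ aᵢτᵢ);
- **fcs** — 3D diffusion × triplet model
  G(τ) = G0(1+τ/τD)⁻¹(1+τ/(s²τD))^(−1/2)(1 + T/(1−T)·e^(−τ/τT)),
  single and global fits, multiple-tau software correlator, particle
  numbers N = (1−T)/G0, triplet-vs-power Kendall test, and timescale
  bounds for undetected dimer dynamics (τ ≤ 100 ns or τD ≤ τ ≤ 300 ms);
- **synthetic** — generators for every input (Poisson TCSPC decays, noisy
  FCS curves, spectra, blinking traces, distance tables) with ground truth
  embedded, so every estimator is testable without any measured data.

## Worked example

Generate a full synthetic study and run the analysis from the shell:

```bash
quenchcal simulate --seed 1 --out study/
quenchcal fit-tcspc --decays study/0P_decay.csv --decays study/3P_decay.csv \
                    --decays study/5P_decay.csv --irf study/irf.csv \
                    --ncomp 3 --global
```

```
shared lifetimes (ns): 0.1149, 2.2, 16.16
global reduced chi2: 0.926
0P_decay: populations 0.9379, 0.0620, 0.0001
3P_decay: populations 0.9138, 0.0861, 0.0001
5P_decay: populations 0.9033, 0.0966, 0.0001
```

The three shared lifetimes (115 ps, 2.2 ns, 16.2 ns here) are recovered
from Poisson-noised decays of 5×10⁶ counts each; the per-construct
amplitude fractions show the fast (quenched-environment) population
dominating every construct.  The FCS side:

```bash
quenchcal fit-fcs --curves study/0P_fcs.csv --curves study/3P_fcs.csv \
                  --curves study/5P_fcs.csv
```

```
0P_fcs: G0=0.3358 tauD=0.2444 ms T=0.150 tauT=8.53 us N=2.53
3P_fcs: G0=0.2107 tauD=0.2444 ms T=0.157 tauT=8.53 us N=4.00
5P_fcs: G0=0.1864 tauD=0.2444 ms T=0.158 tauT=8.53 us N=4.52
```

One diffusion time (0.244 ms) and triplet lifetime are shared globally;
apparent particle numbers N fall from 5P to 0P because shorter rulers put a
larger fraction of molecules into the dark dimer state.  Distance
calibration and spectral decomposition:

```bash
quenchcal calibrate --table study/distance_emission.csv --fix-fmin 0 --fix-fmax 1
quenchcal unmix --spectrum study/3P_absorption.csv
quenchcal av --npro 6
```

```
d50   = 18.81 A (stderr 1.7)
monomer fraction: 0.4723
dimer fraction:   0.5277
1:CYS:SG: 15276 points, volume 11136 A^3
8:CYS:SG: 15796 points, volume 11515 A^3
mean dye separation: 24.64 A
```

The Hill midpoint lands near 18 Å (the floor and plateau are fixed here:
with four nearly collinear points the h = 1 midpoint is unidentifiable
otherwise — see `docs/methods.md`), the 3P absorption spectrum unmixes into
roughly half monomer / half dimer, and the 6P ruler holds its dye clouds
24.6 Å apart.  Every command takes `-o report.txt` to write a
machine-parseable key-value report including seeds and input checksums.

The same operations are available as a library:

```python
from quenchcal import synthetic as syn, tcspc

gen = syn.generate_decay(syn.paper_decay_model(), total_counts=5e6, seed=1)
fit = tcspc.fit_decay(gen.histogram, gen.irf, n_components=3)
print(fit.model.lifetimes)        # ~[0.115, 2.2, 16.3] ns
```

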