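"""Synthetic data generators with embedded ground truth.

Every pipeline stage has a generator that emulates the statistical structure
of the corresponding measurement — Poisson-noised reconvolved TCSPC decays,
diffusion x triplet FCS curves with lag-dependent multiplicative noise,
monomer/dimer absorption mixtures with the 550/520 nm exciton band
structure, Hill-form distance-response tables, and two-state blinking
intensity traces for end-to-end correlator validation.  Each generated
artifact carries its ground-truth parameters and seed, so recovery tests
compare fits against the embedded truth rather than hard-coded numbers.

All generators are deterministic under a fixed seed; a scenario-level master
seed spawns independent per-generator streams, so adding one generator does
not perturb the others' output.

The "paper preset" scenario mirrors the published polyproline study
conditions: constructs 0P/3P/5P/6P, three-exponential decays with lifetimes
115 ps / 2.2 ns / 16.3 ns and amplitude ratio 10 000 : 1000 : 1, FCS with a
0.24 ms diffusion time and 7 us triplet lifetime, and a Hill midpoint of
18 A read out at 575 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import geometry as geo
from . import spectra as sp
from .fcs import CorrelationCurve, FCSModel, fcs_eval
from .tcspc import DecayHistogram, InstrumentResponse, MultiExpModel, reconvolve

__all__ = [
    "ConstructConfig",
    "ScenarioConfig",
    "GeneratedDecay",
    "GeneratedCurve",
    "GeneratedTrace",
    "GeneratedSpectra",
    "GeneratedDistanceSeries",
    "paper_decay_model",
    "paper_fcs_model",
    "paper_hill_truth",
    "default_scenario",
    "gaussian_irf",
    "generate_decay",
    "generate_fcs_curve",
    "generate_blinking_trace",
    "generate_spectra_series",
    "generate_distance_series",
    "generate_scenario",
]

# Published-study presets: decay lifetimes (ns) and amplitude ratio, FCS
# diffusion/triplet times, and the Hill midpoint of the distance calibration.
PAPER_LIFETIMES_NS = (0.115, 2.2, 16.3)
PAPER_AMPLITUDE_RATIO = (10000.0, 1000.0, 1.0)
PAPER_TAU_D_MS = 0.24
PAPER_TAU_T_US = 7.0
PAPER_HILL_D50_A = 18.0
EMISSION_READOUT_NM = 575.0


def paper_decay_model() -> MultiExpModel:
    """Three-exponential preset with the published lifetimes and amplitude ratio."""
    return MultiExpModel(amplitudes=np.array(PAPER_AMPLITUDE_RATIO),
                         lifetimes=np.array(PAPER_LIFETIMES_NS))


def paper_fcs_model(g0: float = 0.1, triplet_fraction: float = 0.15) -> FCSModel:
    """Diffusion + triplet preset with the published tauD and tauT."""
    return FCSModel(g0=g0, tau_d_ms=PAPER_TAU_D_MS, s=5.0,
                    triplet_fraction=triplet_fraction, tau_t_us=PAPER_TAU_T_US)


def paper_hill_truth(f_min: float = 0.0, f_max: float = 1.0) -> sp.HillFit:
    """Hill ground truth with the published 18 A midpoint and h = 1."""
    return sp.HillFit(f_min=f_min, f_max=f_max, d50=PAPER_HILL_D50_A, h=1.0,
                      stderr={}, redchi=0.0, converged=True)


@dataclass
class ConstructConfig:
    """One polyproline construct of the length series.

    ``dark_fraction`` (the FCS-invisible molecule fraction) defaults to the
    dimer fraction: in the exciton picture the dimer is the dark species, so
    the two must agree within a construct.
    """

    label: str
    n_pro: int
    dimer_fraction: float
    dark_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dimer_fraction <= 1.0:
            raise ValueError("dimer_fraction must lie in [0, 1]")
        if self.dark_fraction is None:
            self.dark_fraction = self.dimer_fraction
        if not 0.0 <= self.dark_fraction <= 1.0:
            raise ValueError("dark_fraction must lie in [0, 1]")


@dataclass
class ScenarioConfig:
    """All ground truth needed to generate a full synthetic study."""

    constructs: list[ConstructConfig]
    # TCSPC settings
    irf_fwhm_ps: float = 120.0
    irf_centre_ns: float = 2.0
    channel_width_ps: float = 25.0
    n_channels: int = 4096
    total_counts: float = 5e6
    decay_models: dict = field(default_factory=dict)  # label -> MultiExpModel
    # FCS settings
    fcs_models: dict = field(default_factory=dict)    # label -> FCSModel
    fcs_noise: float = 0.02
    lag_grid_s: np.ndarray | None = None
    # Spectral settings
    spectral_noise: float = 0.01
    emission_readout_nm: float = EMISSION_READOUT_NM
    # Distance calibration
    hill_truth: sp.HillFit = field(default_factory=paper_hill_truth)
    distance_noise: float = 0.05
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        if self.lag_grid_s is None:
            self.lag_grid_s = default_lag_grid()


def default_lag_grid(lag_min_s: float = 1e-8, lag_max_s: float = 1.0,
                     m: int = 8) -> np.ndarray:
    """Quasi-logarithmic lag grid, m points per octave (multiple-tau style)."""
    n_oct = np.log2(lag_max_s / lag_min_s)
    n = int(np.ceil(n_oct * m)) + 1
    return np.geomspace(lag_min_s, lag_max_s, n)


def default_scenario(master_seed: int = 1,
                     n_focus_particles: float = 10.0) -> ScenarioConfig:
    """Paper-preset scenario for the 0P/3P/5P/6P length series.

    Dimer fractions per construct are derived self-consistently from the
    Hill ground truth evaluated at the geometry module's mean dye
    separations (monomer fraction = relative emission), and the FCS G0 of
    each construct reflects the corresponding loss of visible particles from
    a constant total concentration.
    """
    hill = paper_hill_truth()
    constructs, decay_models, fcs_models = [], {}, {}
    for label, n_pro in (("0P", 0), ("3P", 3), ("5P", 5), ("6P", 6)):
        distance = ruler_distance(n_pro)
        monomer_frac = float(hill(distance) / hill.f_max) if hill.f_max else 0.0
        dimer_frac = float(np.clip(1.0 - monomer_frac, 0.0, 1.0))
        constructs.append(ConstructConfig(label, n_pro, dimer_frac))
        # Fast-phase amplitude grows with dimer content, the 2 ns monomer
        # phase shrinks; the slow trace-level phase stays trace-level.
        a_fast = 10000.0 * (0.5 + dimer_frac)
        a_mid = 1000.0 * (1.5 - dimer_frac)
        decay_models[label] = MultiExpModel(
            amplitudes=np.array([a_fast, a_mid, 1.0]),
            lifetimes=np.array(PAPER_LIFETIMES_NS))
        n_visible = max(n_focus_particles * (1.0 - dimer_frac), 0.05)
        fcs_models[label] = paper_fcs_model(g0=1.0 / n_visible)
    return ScenarioConfig(constructs=constructs, decay_models=decay_models,
                          fcs_models=fcs_models, master_seed=master_seed)


_RULER_CACHE: dict[int, float] = {}


def ruler_distance(n_pro: int, dye: geo.DyeParameters | None = None) -> float:
    """Mean dye separation of the Cys-(Pro)n-Cys ruler from the AV engine
    with default dye parameters (cached: the result is deterministic)."""
    if dye is None and n_pro in _RULER_CACHE:
        return _RULER_CACHE[n_pro]
    structure = geo.build_polyproline(n_pro)
    av_a = geo.accessible_volume(structure, structure.attachment_atoms[0], dye)
    av_b = geo.accessible_volume(structure, structure.attachment_atoms[1], dye)
    d = geo.mean_position_distance(av_a, av_b)
    if dye is None:
        _RULER_CACHE[n_pro] = d
    return d


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

@dataclass
class GeneratedDecay:
    histogram: DecayHistogram
    irf: InstrumentResponse
    truth: MultiExpModel
    seed: int


@dataclass
class GeneratedCurve:
    curve: CorrelationCurve
    truth: FCSModel
    noise: float
    seed: int


@dataclass
class GeneratedTrace:
    intensity: np.ndarray
    bin_width_s: float
    truth: dict
    seed: int


@dataclass
class GeneratedSpectra:
    absorption: sp.Spectrum
    excitation: sp.Spectrum
    emission: sp.Spectrum
    truth: dict
    seed: int


@dataclass
class GeneratedDistanceSeries:
    points: list[tuple[float, float]]
    truth: sp.HillFit
    noise: float
    seed: int


def _seed_int(seed) -> int:
    """Collapse a seed or spawned SeedSequence to a plain int below 2^31."""
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return int(seed.generate_state(1, np.uint64)[0] % (2**31))


def gaussian_irf(channel_width_ps: float, n_channels: int,
                 fwhm_ps: float = 120.0, centre_ns: float = 2.0) -> InstrumentResponse:
    """Gaussian instrument response on the decay channel axis."""
    dt = channel_width_ps / 1000.0
    t = (np.arange(n_channels) + 0.5) * dt
    sigma = (fwhm_ps / 1000.0) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((t - centre_ns) / sigma) ** 2)
    return InstrumentResponse(channel_width_ps=channel_width_ps, values=vals)


def generate_decay(model: MultiExpModel, total_counts: float, seed: int,
                   irf_fwhm_ps: float = 120.0, irf_centre_ns: float = 2.0,
                   channel_width_ps: float = 25.0, n_channels: int = 4096,
                   background_fraction: float = 0.0,
                   label: str = "") -> GeneratedDecay:
    """Poisson-noised reconvolved decay plus its IRF.

    The noiseless expectation is the model reconvolved with a Gaussian IRF,
    scaled so the expected total equals ``total_counts`` (an optional flat
    background fraction is added before scaling).  Channel counts are drawn
    independently Poisson.
    """
    if total_counts < 1e3:
        raise ValueError("total_counts must be at least 1e3")
    irf = gaussian_irf(channel_width_ps, n_channels, irf_fwhm_ps, irf_centre_ns)
    expected = reconvolve(model, irf)
    if background_fraction > 0:
        bg_total = background_fraction * expected.sum() / (1 - background_fraction)
        expected = expected + bg_total / n_channels
    # FFT convolution can leave O(eps) negatives ahead of the IRF rise
    expected = np.clip(expected, 0.0, None)
    scale = total_counts / expected.sum()
    expected = expected * scale
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    truth = MultiExpModel(amplitudes=model.amplitudes * scale,
                          lifetimes=model.lifetimes.copy(),
                          shift_ps=model.shift_ps,
                          background=model.background * scale
                          + (background_fraction * total_counts / n_channels
                             if background_fraction > 0 else 0.0))
    hist = DecayHistogram(channel_width_ps=channel_width_ps,
                          counts=counts.astype(float), label=label)
    return GeneratedDecay(histogram=hist, irf=irf, truth=truth, seed=seed)


def generate_fcs_curve(model: FCSModel, lags_s: np.ndarray | None = None,
                       noise: float = 0.02, seed: int = 0,
                       power_label: str = "") -> GeneratedCurve:
    """FCS curve with multiplicative Gaussian noise.

    G = G_model * (1 + eps), eps ~ N(0, noise * w(tau)) with
    w = sqrt(1 + tau/tauD): long lags average fewer independent fluctuation
    events per trace, so their scatter grows (a pragmatic stand-in for the
    full correlator noise statistics)."""
    if noise < 0:
        raise ValueError("noise scale must be non-negative")
    if lags_s is None:
        lags_s = default_lag_grid()
    g = fcs_eval(model, lags_s)
    if noise > 0:
        rng = np.random.default_rng(seed)
        w = np.sqrt(1.0 + lags_s / (model.tau_d_ms * 1e-3))
        g = g * (1.0 + rng.normal(0.0, noise, size=g.size) * w)
    curve = CorrelationCurve(lags_s=np.asarray(lags_s, float), g=g,
                             power_label=power_label)
    return GeneratedCurve(curve=curve, truth=model, noise=noise, seed=seed)


def generate_blinking_trace(n_particles: int, k_on_hz: float, k_off_hz: float,
                            brightness_hz: float, duration_s: float,
                            bin_width_s: float, seed: int = 0) -> GeneratedTrace:
    """Sum of independent two-state (on/off) telegraph emitters with Poisson
    shot noise per bin.  The stationary on-probability is k_on/(k_on+k_off)
    and the intensity autocorrelation decays at rate k_on + k_off."""
    if k_on_hz <= 0 or k_off_hz <= 0:
        raise ValueError("rates must be positive")
    n_bins = int(round(duration_s / bin_width_s))
    if n_bins < 2:
        raise ValueError("duration too short for the bin width")
    rng = np.random.default_rng(seed)
    p_on = k_on_hz / (k_on_hz + k_off_hz)
    on_time = np.zeros(n_bins)  # expected on-time per bin, summed over particles
    edges = np.arange(n_bins + 1) * bin_width_s
    for _ in range(n_particles):
        t = 0.0
        state = rng.random() < p_on
        while t < duration_s:
            rate = k_off_hz if state else k_on_hz
            dwell = rng.exponential(1.0 / rate)
            t_end = min(t + dwell, duration_s)
            if state:
                # distribute the on-interval across bins
                i0 = int(t / bin_width_s)
                i1 = min(int(t_end / bin_width_s), n_bins - 1)
                if i0 == i1:
                    on_time[i0] += t_end - t
                else:
                    on_time[i0] += edges[i0 + 1] - t
                    on_time[i0 + 1:i1] += bin_width_s
                    on_time[i1] += t_end - edges[i1]
            t = t_end
            state = not state
    expected = brightness_hz * on_time
    counts = rng.poisson(expected).astype(float)
    truth = {"n_particles": n_particles, "k_on_hz": k_on_hz, "k_off_hz": k_off_hz,
             "brightness_hz": brightness_hz, "p_on": p_on,
             "relaxation_rate_hz": k_on_hz + k_off_hz}
    return GeneratedTrace(intensity=counts, bin_width_s=bin_width_s,
                          truth=truth, seed=seed)


def generate_spectra_series(dimer_fraction: float, noise: float = 0.01,
                            seed: int = 0,
                            basis: sp.SpectralBasis | None = None) -> GeneratedSpectra:
    """Absorption / excitation / emission spectra of one construct.

    Absorption mixes the monomer and dimer bases by the dimer fraction.
    Because the dimer is non-emissive in the exciton picture, the excitation
    spectrum is the *monomer* basis scaled by the monomer fraction, and the
    emission spectrum is the monomer emission band scaled likewise.
    Additive Gaussian noise is scaled to the monomer-basis peak.
    """
    if not 0.0 <= dimer_fraction <= 1.0:
        raise ValueError("dimer_fraction must lie in [0, 1]")
    if basis is None:
        basis = sp.default_basis()
    rng = np.random.default_rng(seed)
    mono_frac = 1.0 - dimer_fraction
    scale = float(basis.monomer.values.max())

    def noisy(values):
        if noise <= 0:
            return values
        return values + rng.normal(0.0, noise * scale, size=values.size)

    wl = basis.monomer.wavelengths
    absorption = sp.Spectrum(wl, noisy(mono_frac * basis.monomer.values
                                       + dimer_fraction * basis.dimer.values),
                             "absorption")
    excitation = sp.Spectrum(wl, noisy(mono_frac * basis.monomer.values),
                             "excitation")
    em_band = sp.monomer_emission_band()
    emission = sp.Spectrum(em_band.wavelengths,
                           noisy(mono_frac * em_band.values), "emission")
    truth = {"dimer_fraction": dimer_fraction, "monomer_fraction": mono_frac}
    return GeneratedSpectra(absorption=absorption, excitation=excitation,
                            emission=emission, truth=truth, seed=seed)


def generate_distance_series(hill: sp.HillFit, distances: Sequence[float],
                             noise: float = 0.05, seed: int = 0
                             ) -> GeneratedDistanceSeries:
    """(distance, emission) calibration table from a Hill ground truth with
    additive Gaussian noise of standard deviation ``noise * F_max``."""
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    f = np.asarray(hill(d), dtype=float)
    if noise > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise * max(abs(hill.f_max), 1e-12), size=f.size)
    return GeneratedDistanceSeries(points=list(zip(d.tolist(), f.tolist())),
                                   truth=hill, noise=noise, seed=seed)


def generate_scenario(config: ScenarioConfig | None = None) -> dict:
    """Generate the full synthetic study for a scenario.

    Returns a dict with per-construct decays, FCS curves and spectra, the
    distance-calibration table at the geometry-derived ruler distances, and
    the scenario config itself (which holds all ground truth).  Independent
    child seeds are spawned from the master seed per artifact.
    """
    if config is None:
        config = default_scenario()
    ss = np.random.SeedSequence(config.master_seed)
    n_c = len(config.constructs)
    children = ss.spawn(3 * n_c + 1)
    out = {"config": config, "decays": {}, "fcs": {}, "spectra": {}}
    for i, construct in enumerate(config.constructs):
        label = construct.label
        decay_model = config.decay_models[label]
        out["decays"][label] = generate_decay(
            decay_model, config.total_counts, _seed_int(children[3 * i]),
            irf_fwhm_ps=config.irf_fwhm_ps, irf_centre_ns=config.irf_centre_ns,
            channel_width_ps=config.channel_width_ps,
            n_channels=config.n_channels, label=label)
        out["fcs"][label] = generate_fcs_curve(
            config.fcs_models[label], config.lag_grid_s, config.fcs_noise,
            _seed_int(children[3 * i + 1]))
        out["spectra"][label] = generate_spectra_series(
            construct.dimer_fraction, config.spectral_noise,
            _seed_int(children[3 * i + 2]))
    distances = [ruler_distance(c.n_pro) for c in config.constructs]
    out["distance_series"] = generate_distance_series(
        config.hill_truth, distances, config.distance_noise,
        _seed_int(children[-1]))
    return out
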