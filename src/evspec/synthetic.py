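"""Synthetic generator for size-fractionated EV Raman spectra and particles.

The forward model emulates the measured structure of plasma-derived
extracellular-vesicle (EV) fractions: a fixed table of fingerprint-region
bands (assignments below), fraction-dependent amplitude scaling (raw plasma
vs large / mid / small EVs), multiplicative disease shifts for the
cardiovascular-disease (CVD) state, and acquisition artifacts — additive
shot-like noise, a slowly varying polynomial baseline, per-spectrum
multiplicative scatter, and rare cosmic-ray spikes.

Particle populations mirror nanoparticle-tracking size summaries for the
three EV subgroups (truncated normals with means/SDs 61+-23, 189+-84 and
432+-143 nm) and the seven-size fluorescent polystyrene bead panel used to
probe the filtration cascade.

All randomness flows from one root seed; each spectrum or population draws
from a counter-derived child stream so that the first k items of a run are
invariant to the total number requested.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import EvspecError, LabeledDataset, RamanSpectrum, WavenumberAxis

FRACTIONS = ("raw", "large", "mid", "small")
STATES = ("healthy", "cvd")

# Dominant fingerprint-region bands with literature assignments.
BAND_ASSIGNMENTS: dict[float, str] = {
    752: "Nucleic acids",
    759: "Tryptophan - ring breathing vibration",
    785: "Nucleic acids",
    851: "Tyrosine doublet (protein)",
    882: "Phosphatidylcholine",
    920: "Phosphate deformation and bending",
    960: "Polysaccharide structure",
    1003: "Phenylalanine, carotenoids",
    1045: "Proline",
    1124: "Lipids",
    1131: "C-N stretching of proteins",
    1144: "Lipids",
    1307: "Phospholipids, lipids, adenine",
    1341: "Glycine backbone and proline side chain",
    1368: "Tryptophan, guanine, thymine",
    1440: "Lipid and protein",
    1450: "CH2-deformation",
    1553: "Tryptophan",
    1656: "Lipid/Amide I",
}

# Base amplitudes for healthy raw plasma (arbitrary units); generator knobs.
BASE_AMPLITUDES: dict[float, float] = {
    1440: 1.0,
    1656: 1.0,
    1003: 0.9,
    1341: 0.7,
    960: 0.6,
    1124: 0.6,
    1307: 0.6,
    752: 0.5,
    851: 0.5,
    882: 0.5,
    1131: 0.5,
    1553: 0.5,
}
BASE_AMPLITUDES.update({c: 0.4 for c in BAND_ASSIGNMENTS if c not in BASE_AMPLITUDES})

# Fraction-dependent scaling.  Lipid/protein bands decline from raw plasma
# to small EVs (small EVs carry the least lipid/protein cargo); the
# phosphatidylcholine (882) and tryptophan (1553) bands are enriched in all
# EV fractions relative to raw plasma; the glycine-backbone band (1341) is
# elevated in small EVs.
_LIPID_PROTEIN_BANDS = (1124, 1440, 1656)
_LIPID_PROTEIN_SCALE = {"raw": 1.0, "large": 0.8, "mid": 0.65, "small": 0.5}
_EV_ENRICHED_BANDS = (882, 1553)

# Disease shifts for the CVD state: intensity increases of 17-68 % at the
# bands that discriminate CVD from healthy plasma, a decrease at the
# tryptophan band (1553), and an additional phenylalanine (1003) increase
# seen only in the small-EV fraction.
CVD_MULTIPLIERS: dict[float, float] = {
    752: 1.30,
    851: 1.40,
    960: 1.50,
    1144: 1.25,
    1440: 1.20,
    1656: 1.35,
    1553: 0.80,
}
CVD_SMALL_EXTRA: dict[float, float] = {1003: 1.40}

DEFAULT_FWHM = 12.0  # cm^-1, typical biological Raman bandwidth


@dataclass(frozen=True)
class PeakSpec:
    center: float
    fwhm: float
    amplitude: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise EvspecError(f"peak fwhm must be positive, got {self.fwhm}")
        if self.amplitude < 0:
            raise EvspecError(f"peak amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class ClassModifiers:
    """Per-class amplitude multipliers keyed by band center."""

    fraction: str
    state: str
    multipliers: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise EvspecError(f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}")
        if self.state not in STATES:
            raise EvspecError(f"unknown state {self.state!r}; expected one of {STATES}")
        for center, m in self.multipliers.items():
            if m <= 0:
                raise EvspecError(f"multiplier at {center} must be positive, got {m}")
            if center not in BASE_AMPLITUDES:
                raise EvspecError(f"multiplier at {center} has no base peak")


@dataclass(frozen=True)
class NoiseConfig:
    """Acquisition-artifact model parameters.

    additive_sd is expressed as a fraction of the largest base amplitude;
    scatter_sigma is the log-scale SD of the per-spectrum multiplicative
    factor; baseline_coeffs_sd are SDs of the (constant, linear, quadratic)
    polynomial baseline coefficients in axis (cm^-1) units; cosmic_rate is
    the expected number of cosmic-ray spikes per spectrum and
    cosmic_amp_range their amplitude range in multiples of the largest
    peak amplitude.
    """

    additive_sd: float = 0.02
    scatter_sigma: float = 0.10
    baseline_coeffs_sd: tuple[float, ...] = (0.1, 1e-4, 1e-7)
    cosmic_rate: float = 0.2
    cosmic_amp_range: tuple[float, float] = (5.0, 20.0)

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.scatter_sigma < 0 or self.cosmic_rate < 0:
            raise EvspecError("noise parameters must be nonnegative")
        if any(sd < 0 for sd in self.baseline_coeffs_sd):
            raise EvspecError("baseline coefficient SDs must be nonnegative")
        lo, hi = self.cosmic_amp_range
        if lo < 0 or lo > hi:
            raise EvspecError("cosmic_amp_range must satisfy 0 <= low <= high")


NOISELESS = NoiseConfig(0.0, 0.0, (0.0, 0.0, 0.0), 0.0, (0.0, 0.0))


@dataclass(frozen=True)
class SizePopulationSpec:
    """Truncated-normal diameter population for one EV fraction."""

    label: str
    mean_d: float
    sd_d: float
    n: int
    floor_d: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_d <= 0:
            raise EvspecError("mean diameter must be positive")
        if self.sd_d < 0:
            raise EvspecError("diameter SD must be nonnegative")
        if self.n < 1:
            raise EvspecError("population size must be >= 1")


#: Nanoparticle-tracking size summaries of the three isolated EV subgroups.
EV_SIZE_SPECS = {
    "small": SizePopulationSpec("small", 61.0, 23.0, 1, floor_d=30.0),
    "mid": SizePopulationSpec("mid", 189.0, 84.0, 1),
    "large": SizePopulationSpec("large", 432.0, 143.0, 1),
}

#: Nominal diameters (nm) of the seven-size fluorescent polystyrene bead panel.
BEAD_PANEL_NM = (40.0, 100.0, 200.0, 450.0, 500.0, 1000.0, 5000.0)


def _child_rng(seed: int, *counters: int) -> np.random.Generator:
    """Counter-derived child stream so prefixes are n-invariant."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, counters)]))


def build_peak_table(
    fraction: str,
    state: str,
    base_amplitudes: dict[float, float] | None = None,
    extra_multipliers: dict[float, float] | None = None,
    fwhm: float = DEFAULT_FWHM,
) -> list[PeakSpec]:
    """Band table for one (fraction, state) class.

    Amplitude = base amplitude x fraction multiplier x state multiplier.
    Deterministic for fixed inputs.
    """
    if fraction not in FRACTIONS:
        raise EvspecError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")
    if state not in STATES:
        raise EvspecError(f"unknown state {state!r}; expected one of {STATES}")
    base = dict(BASE_AMPLITUDES if base_amplitudes is None else base_amplitudes)

    peaks = []
    for center in sorted(base):
        amp = base[center]
        if center in _LIPID_PROTEIN_BANDS:
            amp *= _LIPID_PROTEIN_SCALE[fraction]
        if center in _EV_ENRICHED_BANDS and fraction != "raw":
            amp *= 1.4
        if center == 1341 and fraction == "small":
            amp *= 1.5
        if state == "cvd":
            amp *= CVD_MULTIPLIERS.get(center, 1.0)
            if fraction == "small":
                amp *= CVD_SMALL_EXTRA.get(center, 1.0)
        if extra_multipliers and center in extra_multipliers:
            amp *= extra_multipliers[center]
        peaks.append(PeakSpec(float(center), fwhm, amp, BAND_ASSIGNMENTS.get(center, "")))
    return peaks


def class_modifiers(fraction: str, state: str) -> ClassModifiers:
    """Effective multiplier table (relative to healthy raw plasma) for a class."""
    base = build_peak_table("raw", "healthy")
    cls = build_peak_table(fraction, state)
    mult = {
        b.center: c.amplitude / b.amplitude
        for b, c in zip(base, cls)
        if not np.isclose(c.amplitude, b.amplitude)
    }
    return ClassModifiers(fraction, state, mult)


def peak_signal(peaks: list[PeakSpec], axis: WavenumberAxis) -> np.ndarray:
    """Noiseless sum-of-Gaussians signal on the axis grid."""
    x = axis.values
    y = np.zeros_like(x)
    for p in peaks:
        if not axis.contains(p.center):
            raise EvspecError(f"peak center {p.center} outside axis [{axis.start}, {axis.stop}]")
        sigma = p.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y += p.amplitude * np.exp(-0.5 * ((x - p.center) / sigma) ** 2)
    return y


def generate_spectrum(
    peaks: list[PeakSpec],
    noise: NoiseConfig,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    fraction: str = "",
    state: str = "",
    sample_id: str = "",
) -> RamanSpectrum:
    """Forward model for one acquired spectrum.

    intensities = scatter x (sum of Gaussians + baseline polynomial)
                  + additive noise + cosmic spikes
    """
    axis = axis or WavenumberAxis()
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    x = axis.values
    y = peak_signal(peaks, axis)
    amp_scale = max((p.amplitude for p in peaks), default=1.0) or 1.0

    coeffs = [rng.normal(0.0, sd) if sd > 0 else 0.0 for sd in noise.baseline_coeffs_sd]
    baseline = np.polynomial.polynomial.polyval(x, coeffs)
    scatter = float(np.exp(rng.normal(0.0, noise.scatter_sigma))) if noise.scatter_sigma > 0 else 1.0
    out = scatter * (y + baseline)
    if noise.additive_sd > 0:
        out = out + rng.normal(0.0, noise.additive_sd * amp_scale, size=x.size)
    if noise.cosmic_rate > 0:
        n_spikes = rng.poisson(noise.cosmic_rate)
        if n_spikes:
            pos = rng.integers(0, x.size, size=n_spikes)
            lo, hi = noise.cosmic_amp_range
            out = out.copy()
            out[pos] += rng.uniform(lo, hi, size=n_spikes) * amp_scale
    return RamanSpectrum(axis, out, fraction=fraction, state=state, sample_id=sample_id)


def generate_dataset(
    design: dict[tuple[str, str], int],
    noise: NoiseConfig | None = None,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    label_by: str = "label",
) -> LabeledDataset:
    """Generate a labeled dataset with exact per-class counts.

    ``design`` maps (fraction, state) to the number of spectra.  Spectra are
    emitted class by class in the design's insertion order; spectrum i of the
    run draws from child stream (seed, i).
    """
    if not design:
        raise EvspecError("empty design: need at least one (fraction, state) class")
    noise = NoiseConfig() if noise is None else noise
    axis = axis or WavenumberAxis()

    spectra: list[RamanSpectrum] = []
    counter = 0
    for (fraction, state), n in design.items():
        if n < 1:
            raise EvspecError(f"class ({fraction}, {state}) count must be >= 1, got {n}")
        peaks = build_peak_table(fraction, state)
        for j in range(n):
            rng = _child_rng(seed, counter)
            spectra.append(
                generate_spectrum(
                    peaks, noise, axis, seed=rng,
                    fraction=fraction, state=state,
                    sample_id=f"{fraction}-{state}-{j:04d}",
                )
            )
            counter += 1
    return LabeledDataset(spectra, label_by=label_by)


def truncated_normal_moments(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Exact mean and SD of a normal(mean, sd) left-truncated at ``floor``."""
    if sd == 0:
        return mean, 0.0
    a = (floor - mean) / sd
    d = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return float(d.mean()), float(d.std())


def generate_particles(spec: SizePopulationSpec, seed: int = 0) -> np.ndarray:
    """Draw diameters (nm) from a left-truncated normal population."""
    rng = _child_rng(seed, zlib.crc32(spec.label.encode()))
    if spec.sd_d == 0:
        return np.full(spec.n, spec.mean_d)
    a = (spec.floor_d - spec.mean_d) / spec.sd_d
    d = stats.truncnorm(a, np.inf, loc=spec.mean_d, scale=spec.sd_d)
    return np.asarray(d.rvs(size=spec.n, random_state=rng), dtype=float)


def expected_bead_well(diameter_nm: float, pore_sizes: tuple[float, ...] = (5000, 500, 200, 100, 40)) -> float:
    """Membrane (pore size, nm) expected to trap a bead of nominal diameter.

    Applies the same diameter >= pore trapping rule as the cascade model, so
    the generator and the routing model cannot disagree; returns 0 for a
    particle expected in the eluate.
    """
    for pore in pore_sizes:
        if diameter_nm >= pore:
            return float(pore)
    return 0.0


def generate_bead_panel(
    n_per_size: int,
    seed: int = 0,
    dispersion_cv: float = 0.0,
    sizes_nm: tuple[float, ...] = BEAD_PANEL_NM,
) -> "pd.DataFrame":
    """Seven-size fluorescent bead panel with expected-well labels.

    Returns a DataFrame with columns ``label`` (nominal size, nm),
    ``diameter_nm`` and ``expected_well`` (pore size of the membrane that
    should trap the bead).  ``dispersion_cv`` adds relative Gaussian size
    dispersion (0 = exactly nominal).
    """
    import pandas as pd

    if n_per_size < 1:
        raise EvspecError("n_per_size must be >= 1")
    rows = []
    for k, nominal in enumerate(sizes_nm):
        rng = _child_rng(seed, 7000 + k)
        if dispersion_cv > 0:
            d = rng.normal(nominal, dispersion_cv * nominal, size=n_per_size)
            d = np.clip(d, 1.0, None)
        else:
            d = np.full(n_per_size, nominal)
        well = expected_bead_well(nominal)
        for v in d:
            rows.append((f"{nominal:g}nm", float(v), well))
    return pd.DataFrame(rows, columns=["label", "diameter_nm", "expected_well"])
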