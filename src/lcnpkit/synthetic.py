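"""Forward models with known ground truth for every analysis stage.

No public dataset accompanies the measurements this package analyzes, so
each stage is exercised against synthetic inputs whose generating
parameters are known exactly: SAXS profiles with planted mesophase and
lattice parameter, single-particle Raman populations with a planted
hybrid fraction, and binary masks with analytically known shape
statistics. All randomness flows from one integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .raman import RamanSpectrum, SpectrumBatch
from .saxs import CUBIC_GEOMETRIES, SAXSProfile

__all__ = [
    "SyntheticSAXSSpec",
    "SyntheticRamanSpec",
    "ShapeSpec",
    "LIPID_BANDS",
    "EV_BANDS",
    "SUBPOP_BANDS",
    "generate_saxs_profile",
    "generate_raman_population",
    "generate_blank",
    "generate_domain_mask",
    "generate_activity_series",
]


# ---------------------------------------------------------------- SAXS

@dataclass(frozen=True)
class SyntheticSAXSSpec:
    """Forward parametrization of a 1D scattering profile.

    ``phase_label`` selects the Bragg-peak series ("Pn3m", "Im3m",
    "Ia3d", "L3", or "none"); ``lattice_param`` is the cubic lattice
    parameter (or sponge spacing d_s) in nm. Peaks are Lorentzian with a
    common FWHM, their relative heights decaying with reflection order
    unless overridden; the diffuse background is a power law
    ``bg_scale * q**(-bg_exponent)`` and noise is multiplicative
    Gaussian with relative SD ``noise_sd``.
    """

    phase_label: str = "Pn3m"
    lattice_param: float = 10.1
    q_min: float = 0.054
    q_max: float = 3.232
    n_points: int = 1200
    peak_width: float = 0.03  # FWHM, nm^-1
    peak_amplitudes: Optional[tuple[float, ...]] = None
    bg_exponent: float = 2.0
    bg_scale: float = 0.01
    noise_sd: float = 0.0
    seed: int = 0
    label: str = ""
    ethanol_vv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lattice_param <= 0:
            raise ValueError("lattice_param must be positive")
        if self.q_min >= self.q_max:
            raise ValueError("q_min must be below q_max")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.phase_label not in (*CUBIC_GEOMETRIES, "L3", "none"):
            raise ValueError(f"unknown phase label {self.phase_label!r}")


def _lorentzian(q: np.ndarray, q0: float, fwhm: float) -> np.ndarray:
    g = fwhm / 2.0
    return g * g / ((q - q0) ** 2 + g * g)


def generate_saxs_profile(spec: SyntheticSAXSSpec) -> SAXSProfile:
    """Render the profile described by ``spec``; deterministic given seed.

    Cubic phases place Lorentzians at ``q = 2*pi*sqrt(N)/d`` over the
    space group's allowed reflections (those inside the grid); the L3
    sponge places one broad Lorentzian at ``q = 2*pi*sqrt(2)/d_s``. The
    grid must cover the first reflection, otherwise the profile would be
    unindexable and an error is raised.
    """
    q = np.linspace(spec.q_min, spec.q_max, spec.n_points)
    intensity = spec.bg_scale * q ** (-spec.bg_exponent)

    if spec.phase_label in CUBIC_GEOMETRIES:
        sqrtN = CUBIC_GEOMETRIES[spec.phase_label].allowed_sqrtN
        q_hkl = 2.0 * math.pi * sqrtN / spec.lattice_param
        if q_hkl[0] < spec.q_min or q_hkl[0] > spec.q_max:
            raise ValueError(
                f"first reflection at q={q_hkl[0]:.3f} nm^-1 lies outside the "
                f"grid [{spec.q_min}, {spec.q_max}]; profile would be unindexable"
            )
        if spec.peak_amplitudes is not None:
            amps = np.asarray(spec.peak_amplitudes, dtype=float)
            if len(amps) != len(sqrtN):
                raise ValueError(
                    f"{spec.phase_label} has {len(sqrtN)} allowed reflections; "
                    f"got {len(amps)} amplitudes"
                )
        else:
            amps = 1.0 / (1.0 + np.arange(len(sqrtN)))  # decay with order
        for q0, a in zip(q_hkl, amps):
            if spec.q_min <= q0 <= spec.q_max:
                intensity = intensity + a * _lorentzian(q, q0, spec.peak_width)
    elif spec.phase_label == "L3":
        q0 = 2.0 * math.pi * math.sqrt(2.0) / spec.lattice_param
        if q0 < spec.q_min or q0 > spec.q_max:
            raise ValueError(
                f"sponge correlation peak at q={q0:.3f} nm^-1 outside the grid"
            )
        amps = spec.peak_amplitudes or (1.0,)
        # broad correlation peak; L3 FWHM is several times a Bragg width
        intensity = intensity + amps[0] * _lorentzian(q, q0, max(spec.peak_width, 0.15))
        if len(amps) > 1 and amps[1] > 0:
            # weak high-q bump sometimes visible in swollen sponges
            intensity = intensity + amps[1] * _lorentzian(q, 1.63 * q0, 0.3)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity * (1.0 + spec.noise_sd * rng.standard_normal(len(q)))
        intensity = np.maximum(intensity, 0.0)
    return SAXSProfile(q, intensity, label=spec.label or spec.phase_label,
                       ethanol_vv=spec.ethanol_vv)


# ---------------------------------------------------------------- Raman

# (center cm^-1, Gaussian sigma cm^-1, amplitude in counts)
LIPID_BANDS: tuple[tuple[float, float, float], ...] = (
    (1300.0, 10.0, 60.0),   # CH2 twisting
    (1445.0, 12.0, 100.0),  # CH2 scissoring
    (1650.0, 10.0, 70.0),   # C=C stretch
)
EV_BANDS: tuple[tuple[float, float, float], ...] = (
    (700.0, 6.0, 30.0),    # cholesterol
    (715.0, 6.0, 30.0),    # choline C-N
    (1000.0, 3.0, 45.0),   # phenylalanine ring breathing
    (1660.0, 12.0, 50.0),  # amide I
)
SUBPOP_BANDS: tuple[tuple[float, float, float], ...] = (
    (965.0, 6.0, 80.0),
)


@dataclass(frozen=True)
class SyntheticRamanSpec:
    """Forward parametrization of a single-particle Raman population.

    Each particle is hybrid with probability ``hybrid_fraction``; hybrid
    spectra carry both the lipid and the vesicle band sets, pure
    spectra only the lipid set. A further fraction of particles
    (``subpop_fraction``, emulating the interfering minority population)
    carries an extra band near 965 cm^-1. Spectra sit on a degree-3
    polynomial fluorescence baseline with additive Gaussian noise, and
    cosmic spikes are injected as isolated single-channel excursions at
    a Poisson rate per spectrum.
    """

    n_particles: int = 200
    hybrid_fraction: float = 0.63
    lipid_bands: tuple[tuple[float, float, float], ...] = LIPID_BANDS
    ev_bands: tuple[tuple[float, float, float], ...] = EV_BANDS
    subpop_fraction: float = 0.0
    subpop_bands: tuple[tuple[float, float, float], ...] = SUBPOP_BANDS
    baseline_coeffs: tuple[float, ...] = (120.0, -60.0, 40.0, -15.0)
    spike_rate: float = 0.3
    spike_amplitude: float = 400.0
    noise_sd: float = 3.0
    wn_min: float = 300.0
    wn_max: float = 1900.0
    n_channels: int = 1600
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hybrid_fraction <= 1.0:
            raise ValueError("hybrid_fraction must be within [0, 1]")
        if not 0.0 <= self.subpop_fraction <= 1.0:
            raise ValueError("subpop_fraction must be within [0, 1]")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        for c, s, a in (*self.lipid_bands, *self.ev_bands):
            if not self.wn_min <= c <= self.wn_max:
                raise ValueError(f"band center {c} cm^-1 outside the grid")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.wn_min, self.wn_max, self.n_channels)


def _render_bands(wn: np.ndarray, bands: Sequence[tuple[float, float, float]],
                  scale: float = 1.0) -> np.ndarray:
    y = np.zeros_like(wn)
    for c, s, a in bands:
        y += scale * a * np.exp(-0.5 * ((wn - c) / s) ** 2)
    return y


def generate_blank(spec: SyntheticRamanSpec) -> RamanSpectrum:
    """Averaged buffer blank: the shared fluorescence baseline, noise-free
    (averaging over many acquisitions suppresses the noise)."""
    wn = spec.grid
    x = np.linspace(-1.0, 1.0, len(wn))
    return RamanSpectrum(wn, np.polyval(spec.baseline_coeffs[::-1], x), "blank")


def generate_raman_population(spec: SyntheticRamanSpec) -> tuple[SpectrumBatch, RamanSpectrum]:
    """Draw a particle population; returns (batch with ground-truth labels,
    averaged blank). Labels: "hybrid", "pure", or "subpop"."""
    rng = np.random.default_rng(spec.seed)
    wn = spec.grid
    x = np.linspace(-1.0, 1.0, len(wn))
    baseline = np.polyval(spec.baseline_coeffs[::-1], x)

    spectra: list[RamanSpectrum] = []
    labels: list[str] = []
    for i in range(spec.n_particles):
        is_sub = rng.random() < spec.subpop_fraction
        is_hybrid = rng.random() < spec.hybrid_fraction
        # particle-to-particle intensity variation (trap position, size)
        scale = rng.lognormal(mean=0.0, sigma=0.15)
        y = baseline + _render_bands(wn, spec.lipid_bands, scale)
        if is_sub:
            y = y + _render_bands(wn, spec.subpop_bands, scale)
            labels.append("subpop")
        elif is_hybrid:
            labels.append("hybrid")
        else:
            labels.append("pure")
        if is_hybrid and not is_sub:
            y = y + _render_bands(wn, spec.ev_bands, scale)
        if spec.noise_sd > 0:
            y = y + spec.noise_sd * rng.standard_normal(len(wn))
        n_spikes = rng.poisson(spec.spike_rate)
        for _ in range(n_spikes):
            ch = rng.integers(2, len(wn) - 2)
            y[ch] += spec.spike_amplitude * (1.0 + 0.5 * rng.random())
        spectra.append(RamanSpectrum(wn, y, particle_id=f"p{i:04d}"))
    return SpectrumBatch(spectra, np.array(labels)), generate_blank(spec)


# ---------------------------------------------------------------- masks

@dataclass(frozen=True)
class ShapeSpec:
    """One planted shape: an ellipse (a disk when axes are equal).

    ``a``/``b`` are semi-axes in pixels; ``theta`` the rotation in
    radians.
    """

    cy: float
    cx: float
    a: float
    b: float
    theta: float = 0.0

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    @property
    def perimeter(self) -> float:
        # Ramanujan's second approximation
        a, b = self.a, self.b
        h = ((a - b) / (a + b)) ** 2
        return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))

    @property
    def circularity(self) -> float:
        return min(1.0, 4.0 * math.pi * self.area / self.perimeter**2)

    @property
    def equivalent_diameter(self) -> float:
        return 2.0 * math.sqrt(self.area / math.pi)


def generate_domain_mask(
    shapes: Sequence[ShapeSpec], canvas: tuple[int, int] = (512, 512)
) -> tuple[np.ndarray, list[ShapeSpec]]:
    """Rasterize non-overlapping ellipses; returns (mask, analytic specs).

    Raises if any two shapes overlap or a shape leaves the canvas, so
    the analytic statistics stay exact for the planted population.
    """
    ny, nx = canvas
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros(canvas, dtype=bool)
    for k, s in enumerate(shapes):
        ct, st = math.cos(s.theta), math.sin(s.theta)
        u = (xx - s.cx) * ct + (yy - s.cy) * st
        v = -(xx - s.cx) * st + (yy - s.cy) * ct
        inside = (u / s.a) ** 2 + (v / s.b) ** 2 <= 1.0
        r = max(s.a, s.b)
        if s.cx - r < 0 or s.cx + r >= nx or s.cy - r < 0 or s.cy + r >= ny:
            raise ValueError(f"shape {k} extends beyond the canvas")
        if (mask & inside).any():
            raise ValueError(f"shape {k} overlaps a previously planted shape")
        mask |= inside
    return mask, list(shapes)


# ---------------------------------------------------------------- assays

def generate_activity_series(
    timepoints: Sequence[float],
    native_rate: float,
    activity_ratio: float,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic 415 nm absorbance time courses with a planted activity
    ratio; returns (timepoints, native, hybrid) with replicate columns."""
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    native = native_rate * t[:, None] * np.ones((1, n_replicates))
    hybrid = activity_ratio * native
    if noise_sd > 0:
        native = native + noise_sd * rng.standard_normal(native.shape)
        hybrid = hybrid + noise_sd * rng.standard_normal(hybrid.shape)
    return t, native, hybrid
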