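"""Mesophase assignment and geometry from 1D small-angle X-ray scattering.

Lyotropic lipid phases are identified from the spacing ratios of their
Bragg reflections: bicontinuous cubic phases give sharp peak series at
``q = (2*pi/d) * sqrt(h^2 + k^2 + l^2)`` over the allowed Miller indices of
the space group (Pn3m: sqrt(2, 3, 4, 6, 8, 9); Im3m: sqrt(2, 4, 6, 8)),
while the disordered sponge (L3) phase shows a single broad correlation
peak. From the lattice parameter ``d`` the aqueous channel radius follows
from the curvature properties of the underlying minimal surface,

    r_w = sqrt(-A0 / (2*pi*chi)) * d - l

with ``A0`` the dimensionless surface area per unit volume, ``chi`` the
Euler-Poincare characteristic of the surface, and ``l`` the hydrophobic
chain length of the lipid (1.8 nm for glyceryl monooleate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "SAXSProfile",
    "PeakSet",
    "MesophaseGeometry",
    "PhaseAssignment",
    "WaterChannelResult",
    "SpongeResult",
    "PN3M",
    "IM3M",
    "IA3D",
    "CUBIC_GEOMETRIES",
    "detect_peaks",
    "index_phase",
    "lattice_parameter",
    "water_channel_radius_cubic",
    "sponge_d_spacing",
    "sponge_water_radius",
    "analyze_series",
]

GMO_CHAIN_LENGTH_NM = 1.8  # hydrophobic chain length of glyceryl monooleate


@dataclass(frozen=True)
class MesophaseGeometry:
    """Minimal-surface constants and allowed reflections of a cubic phase.

    ``A0`` and ``chi`` are the standard literature constants for the
    triply periodic minimal surface underlying each space group; the
    allowed reflections are listed as sqrt(h^2+k^2+l^2) in increasing
    order, paired with a representative (h, k, l).
    """

    space_group: str
    A0: float
    chi: int
    reflections: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.chi >= 0:
            raise ValueError("Euler characteristic of a bicontinuous surface is negative")
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")

    @property
    def allowed_sqrtN(self) -> np.ndarray:
        return np.sqrt([h * h + k * k + l * l for h, k, l in self.reflections])

    @property
    def channel_slope(self) -> float:
        """The ratio r_w / d before chain-length subtraction."""
        return math.sqrt(-self.A0 / (2.0 * math.pi * self.chi))


PN3M = MesophaseGeometry(
    "Pn3m", 1.919, -2,
    ((1, 1, 0), (1, 1, 1), (2, 0, 0), (2, 1, 1), (2, 2, 0), (2, 2, 1)),
)
IM3M = MesophaseGeometry(
    "Im3m", 2.345, -4,
    ((1, 1, 0), (2, 0, 0), (2, 1, 1), (2, 2, 0)),
)
# Included for generality; gyroid phases do not occur in GMO/ethanol/water
# at these compositions but index the same way.
IA3D = MesophaseGeometry(
    "Ia3d", 3.091, -8,
    ((2, 1, 1), (2, 2, 0), (3, 2, 1), (4, 0, 0)),
)

CUBIC_GEOMETRIES: dict[str, MesophaseGeometry] = {
    g.space_group: g for g in (PN3M, IM3M, IA3D)
}


@dataclass
class SAXSProfile:
    """A 1D scattering curve: q in nm^-1, intensity in arbitrary units."""

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""
    ethanol_vv: Optional[float] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class PeakSet:
    """Detected Bragg-peak apexes, optionally carrying Miller assignments."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray
    miller: Optional[list[tuple[int, int, int]]] = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        self.prominences = np.atleast_1d(np.asarray(self.prominences, dtype=float))
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("peak positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PhaseAssignment:
    """Result of indexing a peak set against candidate mesophases."""

    phase: str  # space group, "L3", or "none"
    d: Optional[float] = None  # lattice parameter or sponge spacing, nm
    n_matched: int = 0
    residual: float = 0.0  # RMS relative residual of matched reflections
    d_per_reflection: Optional[np.ndarray] = None
    matched_sqrtN: Optional[np.ndarray] = None
    matched_q: Optional[np.ndarray] = None
    miller: Optional[list[tuple[int, int, int]]] = None

    @property
    def is_cubic(self) -> bool:
        return self.phase in CUBIC_GEOMETRIES


@dataclass
class WaterChannelResult:
    r_w: float  # nm
    l: float  # hydrophobic chain length used, nm
    source_phase: str
    physical: bool = True


@dataclass
class SpongeResult:
    q1: float  # nm^-1
    d_s: float  # nm
    r_w_s: Optional[float] = None
    reference: Optional[tuple[float, float]] = None  # (d_c_ref, r_w_ref)


def detect_peaks(
    profile: SAXSProfile,
    min_prominence: float = 0.02,
    smooth_window: int = 5,
) -> PeakSet:
    """Locate local maxima in a profile with sub-grid apex refinement.

    Parameters
    ----------
    min_prominence
        Prominence threshold relative to the profile's intensity range.
    smooth_window
        Width (points) of the light polynomial smoothing applied before
        peak picking; the apex is refined on the smoothed curve by
        parabolic interpolation of the three points around the maximum.
    """
    if len(profile) < 16:
        raise ValueError("profile too short for peak detection (need >= 16 points)")
    y = profile.intensity
    if smooth_window >= 3:
        w = min(smooth_window | 1, len(y) - 1 if (len(y) - 1) % 2 else len(y) - 2)
        y = savgol_filter(y, w, 2)
    span = float(np.ptp(y))
    if span <= 1e-10 * max(float(np.max(np.abs(y))), 1.0):  # flat profile
        return PeakSet(np.empty(0), np.empty(0), np.empty(0))
    idx, props = find_peaks(y, prominence=min_prominence * span)
    if len(idx) == 0:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0))

    q = profile.q
    positions = []
    for i in idx:
        if 0 < i < len(y) - 1:
            # parabola through (i-1, i, i+1); vertex offset in grid units
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            positions.append(q[i] + shift * (q[min(i + 1, len(q) - 1)] - q[i - 1]) / 2.0)
        else:
            positions.append(q[i])
    order = np.argsort(positions)
    return PeakSet(
        np.asarray(positions)[order],
        y[idx][order],
        props["prominences"][order],
    )


def _fit_origin_slope(sqrtN: np.ndarray, qvals: np.ndarray) -> float:
    """Least-squares slope of q = m * sqrtN through the origin (closed form)."""
    return float(np.dot(sqrtN, qvals) / np.dot(sqrtN, sqrtN))


def index_phase(
    peaks: PeakSet,
    candidates: Optional[Sequence[MesophaseGeometry]] = None,
    allow_l3: bool = True,
    rel_tol: float = 0.02,
    residual_cap: float = 0.02,
) -> PhaseAssignment:
    """Assign a mesophase to a detected peak set.

    Each cubic candidate anchors its first allowed reflection on the
    lowest-q peak, predicts the remaining reflections, and matches
    detected peaks within a relative tolerance; the slope of
    ``q = (2*pi/d) * sqrt(N)`` is then refit through the origin on the
    matched pairs. The winning candidate leaves the fewest detected
    peaks unmatched, breaking ties by RMS relative residual; a cubic
    call requires at least two matched reflections. A single broad peak
    is read as the sponge (L3) phase when allowed. If the best residual
    exceeds ``residual_cap`` the profile is declared unindexed.
    """
    if candidates is None:
        candidates = (PN3M, IM3M)
    if len(peaks) == 0:
        return PhaseAssignment("none")

    qpk = peaks.positions
    best: Optional[PhaseAssignment] = None
    best_key: Optional[tuple] = None
    for geom in candidates:
        sqrtN = geom.allowed_sqrtN
        # anchor: first peak is the first allowed reflection
        slope0 = qpk[0] / sqrtN[0]
        predicted = slope0 * sqrtN
        used: set[int] = set()
        m_sqrtN, m_q, m_hkl = [], [], []
        for s, qp, hkl in zip(sqrtN, predicted, geom.reflections):
            rel = np.abs(qpk - qp) / qp
            if used:
                rel[list(used)] = np.inf
            j = int(np.argmin(rel))
            if rel[j] <= rel_tol:
                used.add(j)
                m_sqrtN.append(s)
                m_q.append(qpk[j])
                m_hkl.append(hkl)
        if len(m_sqrtN) < 2:
            continue
        m_sqrtN_a = np.asarray(m_sqrtN)
        m_q_a = np.asarray(m_q)
        slope = _fit_origin_slope(m_sqrtN_a, m_q_a)
        resid = float(np.sqrt(np.mean(((m_q_a - slope * m_sqrtN_a) / m_q_a) ** 2)))
        n_unmatched = len(qpk) - len(used)
        # reflections the candidate predicts inside the observed peak range
        # but which match nothing weigh against it (e.g. the absent (111)
        # distinguishes an Im3m series from a Pn3m one)
        n_missing = int(
            np.sum(slope * sqrtN <= m_q_a.max() * (1 + rel_tol)) - len(m_sqrtN)
        )
        key = (n_unmatched, n_missing, resid)
        if best_key is None or key < best_key:
            best_key = key
            d = 2.0 * math.pi / slope
            best = PhaseAssignment(
                phase=geom.space_group,
                d=d,
                n_matched=len(m_sqrtN),
                residual=resid,
                d_per_reflection=2.0 * math.pi * m_sqrtN_a / m_q_a,
                matched_sqrtN=m_sqrtN_a,
                matched_q=m_q_a,
                miller=m_hkl,
            )

    if best is not None and best.residual <= residual_cap:
        return best
    if allow_l3 and len(peaks) == 1:
        q1 = float(qpk[0])
        return PhaseAssignment(
            "L3", d=sponge_d_spacing(q1), n_matched=1, residual=0.0,
            matched_q=np.array([q1]),
        )
    return PhaseAssignment("none")


def lattice_parameter(peaks: PeakSet, geometry: MesophaseGeometry) -> tuple[float, np.ndarray]:
    """Cubic lattice parameter from Miller-assigned peaks.

    Returns the mean over reflections of ``d = 2*pi*sqrt(N)/q_hkl``
    together with the per-reflection values. The peaks must carry Miller
    assignments (from :func:`index_phase` or set by the caller).
    """
    if peaks.miller is None:
        raise ValueError("peaks carry no Miller assignments; run index_phase first")
    if len(peaks.miller) != len(peaks):
        raise ValueError("one Miller triplet required per peak")
    sqrtN = np.sqrt([h * h + k * k + l * l for h, k, l in peaks.miller])
    d_per = 2.0 * math.pi * sqrtN / peaks.positions
    return float(np.mean(d_per)), d_per


def water_channel_radius_cubic(
    d: float,
    geometry: MesophaseGeometry,
    l: float = GMO_CHAIN_LENGTH_NM,
) -> WaterChannelResult:
    """Aqueous channel radius of a bicontinuous cubic phase.

    ``r_w = sqrt(-A0/(2*pi*chi)) * d - l``; a non-positive result is
    returned with ``physical=False`` rather than raised, since it simply
    means the lattice is too small to host a water channel at the
    assumed chain length.
    """
    if d <= 0:
        raise ValueError("lattice parameter must be positive")
    if l <= 0:
        raise ValueError("chain length must be positive")
    r_w = geometry.channel_slope * d - l
    return WaterChannelResult(r_w=r_w, l=l, source_phase=geometry.space_group,
                              physical=r_w > 0)


def sponge_d_spacing(q1: float) -> float:
    """Characteristic spacing of the sponge phase from its correlation peak.

    ``d_s = (2*pi/q1) * sqrt(2)``, treating the broad peak as the melted
    remnant of the lowest cubic reflection (110).
    """
    if q1 <= 0:
        raise ValueError("peak position must be positive")
    return 2.0 * math.pi * math.sqrt(2.0) / q1


def sponge_water_radius(d_s: float, d_c_ref: float, r_w_ref: float) -> float:
    """Sponge-phase channel radius scaled from a reference cubic phase.

    ``r_w(s) = (d_s / d_c_ref) * r_w(c)``, using the cubic phase formed
    at slightly lower solvent content as the geometric reference.
    """
    if d_s <= 0 or d_c_ref <= 0 or r_w_ref <= 0:
        raise ValueError(
            "sponge radius needs a positive d_s and a positive reference cubic "
            "(d_c_ref, r_w_ref); supply the cubic phase formed at lower ethanol"
        )
    return (d_s / d_c_ref) * r_w_ref


@dataclass
class SeriesEntry:
    ethanol_vv: float
    assignment: PhaseAssignment
    r_w: Optional[float] = None


@dataclass
class SeriesResult:
    """Phase evolution along an ethanol dilution series."""

    entries: list[SeriesEntry] = field(default_factory=list)
    transitions: list[tuple[float, str, str]] = field(default_factory=list)
    d_trend: Optional[str] = None  # vs increasing ethanol

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ethanol_vv": [e.ethanol_vv for e in self.entries],
                "phase": [e.assignment.phase for e in self.entries],
                "d_nm": [e.assignment.d for e in self.entries],
                "r_w_nm": [e.r_w for e in self.entries],
            }
        )


def analyze_series(
    profiles: Sequence[SAXSProfile],
    candidates: Optional[Sequence[MesophaseGeometry]] = None,
    l: float = GMO_CHAIN_LENGTH_NM,
    **detect_kwargs,
) -> SeriesResult:
    """Index each profile of an ethanol dilution series and report transitions.

    Profiles must carry ``ethanol_vv``; they are processed in order of
    decreasing ethanol content (the direction of dialysis). Each
    L3-to-cubic transition is reported at the ethanol fraction where the
    cubic phase first appears, along with the trend of the cubic lattice
    parameter versus ethanol content.
    """
    for p in profiles:
        if p.ethanol_vv is None:
            raise ValueError(f"profile {p.label!r} lacks ethanol_vv metadata")
    ordered = sorted(profiles, key=lambda p: -p.ethanol_vv)
    result = SeriesResult()
    prev_phase: Optional[str] = None
    for p in ordered:
        assignment = index_phase(detect_peaks(p, **detect_kwargs), candidates)
        r_w = None
        if assignment.is_cubic:
            r_w = water_channel_radius_cubic(
                assignment.d, CUBIC_GEOMETRIES[assignment.phase], l
            ).r_w
        result.entries.append(SeriesEntry(p.ethanol_vv, assignment, r_w))
        if prev_phase == "L3" and assignment.is_cubic:
            result.transitions.append((p.ethanol_vv, "L3", assignment.phase))
        prev_phase = assignment.phase

    cubic = [(e.ethanol_vv, e.assignment.d) for e in result.entries if e.assignment.is_cubic]
    if len(cubic) >= 2:
        etoh = np.array([c[0] for c in cubic])
        dvals = np.array([c[1] for c in cubic])
        order = np.argsort(etoh)
        diffs = np.diff(dvals[order])
        if np.all(diffs > 0):
            result.d_trend = "increasing"
        elif np.all(diffs < 0):
            result.d_trend = "decreasing"
        else:
            result.d_trend = "non-monotone"
    return result
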