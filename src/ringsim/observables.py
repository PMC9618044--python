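"""Measurements on simulated (or experimental) rings.

Intensity profiles live on a periodic arc-length domain of circumference
2πR, binned and convolved with a Gaussian point-spread function so that
simulated myosin densities are directly comparable with confocal
fluorescence kymographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.signal import find_peaks

from .params import ModelParams
from .ring_model import arc_coordinate, tangent_at
from .state import RingState

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IntensityProfile:
    """Arc-length-binned intensity on the periodic ring domain."""

    bin_centers: np.ndarray     # μm, uniform, periodic domain [0, L)
    intensity: np.ndarray       # arbitrary units, >= 0
    bin_width: float            # μm

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.bin_centers.shape != self.intensity.shape:
            raise ValueError("bin_centers and intensity must have equal shape")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensity must be non-negative")

    @property
    def circumference(self) -> float:
        return self.bin_width * len(self.bin_centers)


@dataclass
class Kymograph:
    """Row-stacked intensity profiles at uniform time spacing."""

    times: np.ndarray           # s
    data: np.ndarray            # (n_times, n_bins)
    bin_centers: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.data = np.asarray(self.data, float)
        if self.data.shape != (len(self.times), len(self.bin_centers)):
            raise ValueError("inconsistent kymograph shape")
        if len(self.times) > 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("kymograph requires uniform time spacing")

    def row(self, k: int) -> IntensityProfile:
        return IntensityProfile(self.bin_centers, self.data[k], self.bin_width)


@dataclass
class TensionTrace:
    """Mean ring tension versus time, with the per-cross-section values."""

    times: np.ndarray                   # s
    tension: np.ndarray                 # pN (mean over cross-sections)
    per_section: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# ring tension
# ---------------------------------------------------------------------------

def ring_tension(
    state: RingState, params: ModelParams, plane_spacing: float = 0.1
) -> float:
    """Mean over ring cross-sections of the axial filament tension forces.

    Requires a solved step (``state.last_report`` holds the per-bond tension
    multipliers).  Sampling planes are normal to the ring tangent, every
    ``plane_spacing`` of arc; each bond crossing a plane contributes its
    tension multiplier projected on the local ring tangent.
    """
    per = ring_tension_sections(state, params, plane_spacing)
    return float(np.mean(per)) if len(per) else 0.0


def ring_tension_sections(
    state: RingState, params: ModelParams, plane_spacing: float = 0.1
) -> np.ndarray:
    """Axial tension across each sampling cross-section (pN)."""
    L = params.circumference
    n_planes = max(1, int(round(L / plane_spacing)))
    sections = np.zeros(n_planes)
    report = state.last_report
    if report is None or len(report.seg_tension) == 0:
        return sections
    offsets = state.subunit_offsets()
    planes = (np.arange(n_planes) + 0.5) * (L / n_planes)
    for lam, fi, si in zip(report.seg_tension, report.seg_fil, report.seg_sub):
        fil = state.filaments[fi]
        ra, rb = fil.subunits[si], fil.subunits[si + 1]
        sa = float(arc_coordinate(ra, params.R))
        sb = float(arc_coordinate(rb, params.R))
        d = rb - ra
        nrm = np.linalg.norm(d)
        if nrm == 0:
            continue
        u = d / nrm
        axial = abs(float(u @ tangent_at(0.5 * (ra + rb))))
        lo, hi = min(sa, sb), max(sa, sb)
        if hi - lo <= L / 2:
            hit = (planes > lo) & (planes < hi)
        else:  # segment wraps through s = 0
            hit = (planes > hi) | (planes < lo)
        sections[hit] += lam * axial
    return sections


# ---------------------------------------------------------------------------
# simulated fluorescence
# ---------------------------------------------------------------------------

def render_fluorescence(
    positions_or_state, params: ModelParams, bin_width: float | None = None
) -> IntensityProfile:
    """PSF-convolved arc-length intensity profile of the myosin clusters.

    Each cluster contributes a unit-mass periodic Gaussian of FWHM
    ``psf_fwhm``, so the summed intensity equals the cluster count.
    """
    if isinstance(positions_or_state, RingState):
        pos = positions_or_state.myosin_positions()
    else:
        pos = np.atleast_2d(np.asarray(positions_or_state, float))
    bw = params.bin_width if bin_width is None else bin_width
    if bw > params.psf_fwhm / 4 + 1e-12:
        raise ValueError("bin width must be <= psf_fwhm/4")
    L = params.circumference
    n_bins = int(round(L / bw))
    bw = L / n_bins  # snap so the domain closes periodically
    edges = np.arange(n_bins + 1) * bw
    centers = edges[:-1] + 0.5 * bw
    if pos.shape[0] == 0:
        return IntensityProfile(centers, np.zeros(n_bins), bw)
    s = np.asarray(arc_coordinate(pos, params.R), float)
    hist, _ = np.histogram(s % L, bins=edges)
    sigma = params.psf_fwhm * _FWHM_TO_SIGMA
    # periodic Gaussian kernel, unit mass on the grid
    x = centers - centers[0]
    x = np.minimum(x, L - x)
    kern = np.exp(-0.5 * (x / sigma) ** 2)
    kern /= kern.sum()
    smooth = np.fft.irfft(np.fft.rfft(hist) * np.fft.rfft(kern), n=n_bins)
    return IntensityProfile(centers, np.clip(smooth, 0.0, None), bw)


def total_intensity(profile: IntensityProfile) -> float:
    """Total intensity (sum over bins), the analogue of total fluorescence."""
    return float(profile.intensity.sum())


# ---------------------------------------------------------------------------
# profile statistics
# ---------------------------------------------------------------------------

def relative_fluctuation(profile: IntensityProfile) -> float:
    """Ratio of the SD to the mean of the intensity over bins."""
    mean = float(profile.intensity.mean())
    if mean <= 0:
        raise ValueError("relative fluctuation undefined for a zero profile")
    return float(profile.intensity.std()) / mean


def autocorrelation(profile: IntensityProfile) -> tuple[np.ndarray, np.ndarray]:
    """Periodic spatial autocorrelation of the mean-subtracted intensity,
    normalized to 1 at zero separation.  Returns (lags, correlation)."""
    x = profile.intensity - profile.intensity.mean()
    var = float(np.mean(x * x))
    if var == 0:
        raise ValueError("autocorrelation undefined for a constant profile")
    n = len(x)
    f = np.fft.rfft(x)
    corr = np.fft.irfft(f * np.conj(f), n=n) / n / var
    k = n // 2 + 1
    return np.arange(k) * profile.bin_width, corr[:k]


def correlation_length(profile: IntensityProfile) -> float:
    """Separation at which the normalized autocorrelation has decayed 50%,
    by linear interpolation between bins."""
    lags, corr = autocorrelation(profile)
    below = np.where(corr < 0.5)[0]
    if len(below) == 0:
        return float(lags[-1])
    k = int(below[0])
    if k == 0:
        return 0.0
    c0, c1 = corr[k - 1], corr[k]
    frac = (c0 - 0.5) / (c0 - c1)
    return float(lags[k - 1] + frac * (lags[k] - lags[k - 1]))


# ---------------------------------------------------------------------------
# aggregates and gaps
# ---------------------------------------------------------------------------

def detect_aggregates(
    profile: IntensityProfile,
    prominence_frac: float = 0.25,
    min_separation: float = 0.3,
) -> np.ndarray:
    """Arc positions of myosin aggregates, called as profile peaks.

    Peaks must rise by at least ``prominence_frac``·mean above their
    surroundings and be at least ``min_separation`` apart; detection is
    periodic-aware (the profile is analyzed on a tripled domain).
    """
    y = profile.intensity
    n = len(y)
    mean = float(y.mean())
    if mean == 0:
        return np.zeros(0)
    tiled = np.concatenate([y, y, y])
    dist = max(1, int(round(min_separation / profile.bin_width)))
    peaks, _ = find_peaks(tiled, prominence=prominence_frac * mean, distance=dist)
    inner = peaks[(peaks >= n) & (peaks < 2 * n)] - n
    return profile.bin_centers[inner]


def mean_separation(peaks: np.ndarray, circumference: float) -> float | None:
    """Mean periodic arc distance between adjacent peaks, or None if < 2."""
    peaks = np.sort(np.asarray(peaks, float))
    if len(peaks) < 2:
        return None
    gaps = np.diff(np.concatenate([peaks, [peaks[0] + circumference]]))
    return float(gaps.mean())


def detect_gaps(
    profile: IntensityProfile, params: ModelParams, threshold_frac: float | None = None
) -> list[tuple[float, float]]:
    """Maximal contiguous arc runs lacking myosin, of width ≥ gap_min_width.

    'Lacking' means intensity below ``threshold_frac`` (default from params)
    of the ring-mean intensity; runs are periodic-aware.  Returns a list of
    (start_arc, width) in μm.
    """
    frac = params.gap_threshold_frac if threshold_frac is None else threshold_frac
    y = profile.intensity
    n = len(y)
    L = profile.circumference
    empty = y < frac * y.mean() if y.mean() > 0 else np.ones(n, bool)
    if empty.all():
        return [(0.0, L)]
    if not empty.any():
        return []
    # rotate so bin 0 is non-empty, then find runs
    start0 = int(np.argmin(empty))  # first False
    rolled = np.roll(empty, -start0)
    gaps = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            width = (j - i) * profile.bin_width
            if width >= params.gap_min_width:
                start = ((start0 + i) % n) * profile.bin_width
                gaps.append((float(start), float(width)))
            i = j
        else:
            i += 1
    return gaps


# ---------------------------------------------------------------------------
# mechanical connectivity
# ---------------------------------------------------------------------------

def mechanical_connectivity(
    state: RingState, params: ModelParams, section_spacing: float = 0.1
) -> tuple[bool, list]:
    """Circumferential percolation test plus the component graph.

    The ring counts as mechanically connected iff every arc cross-section
    is crossed by an actin filament or bridged by a myosin cluster engaged
    across it.  The returned component list partitions filaments and
    clusters into connected groups of the engagement/cross-link graph
    (an isolated but internally connected aggregate still means fracture).
    """
    from .mechanics import refresh_engagements

    refresh_engagements(state, params)
    L = params.circumference
    n_sec = max(1, int(round(L / section_spacing)))
    covered = np.zeros(n_sec, bool)
    sections = (np.arange(n_sec) + 0.5) * (L / n_sec)

    def mark(sa: float, sb: float) -> None:
        lo, hi = min(sa, sb), max(sa, sb)
        if hi - lo <= L / 2:
            covered[(sections > lo) & (sections < hi)] = True
        else:
            covered[(sections > hi) | (sections < lo)] = True

    G = nx.Graph()
    for fi, fil in enumerate(state.filaments):
        G.add_node(("filament", fi))
        s = np.asarray(arc_coordinate(fil.subunits, params.R), float)
        for k in range(fil.n_subunits - 1):
            mark(float(s[k]), float(s[k + 1]))
    for a, m in enumerate(state.myosins):
        G.add_node(("myosin", a))
        sm = float(arc_coordinate(m.position, params.R))
        for fi, si in m.engaged_subunits:
            G.add_edge(("myosin", a), ("filament", fi))
            ssub = float(arc_coordinate(state.filaments[fi].subunits[si], params.R))
            mark(sm, ssub)
    for x in state.crosslinks:
        G.add_edge(("filament", x.fil_a), ("filament", x.fil_b))

    components = [sorted(c) for c in nx.connected_components(G)] if G else []
    connected = bool(covered.all()) and G.number_of_nodes() > 0
    return connected, components


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

def kymograph(samples: list[tuple[float, IntensityProfile]]) -> Kymograph:
    """Stack (time, profile) samples into a kymograph.

    Requires at least two time points with identical binning.
    """
    if len(samples) < 2:
        raise ValueError("kymograph needs at least two time points")
    times = np.array([t for t, _ in samples], float)
    first = samples[0][1]
    for _, p in samples:
        if len(p.bin_centers) != len(first.bin_centers) or not np.isclose(
            p.bin_width, first.bin_width
        ):
            raise ValueError("inconsistent binning across kymograph rows")
    data = np.stack([p.intensity for _, p in samples])
    return Kymograph(times, data, first.bin_centers, first.bin_width)


def filament_lengths(state: RingState, params: ModelParams) -> np.ndarray:
    """Current filament lengths, μm."""
    return np.array([f.length(params.l0) for f in state.filaments])
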