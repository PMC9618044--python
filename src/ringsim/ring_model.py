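"""Ring geometry and construction of the initial, pre-equilibrated ring.

The ring lies on the inner face of a spherical membrane of radius ``R``,
inside an equatorial binding band of width ``w_band``.  Arc position ``s``
runs counter-clockwise from the +x axis, ``s ∈ [0, 2πR)``.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import ANTICLOCKWISE, CLOCKWISE, Filament, MyosinCluster, RingState


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def arc_coordinate(position, R: float) -> float | np.ndarray:
    """Arc-length coordinate along the ring equator, in [0, 2πR).

    Continuous and 2πR-periodic; works on a single (3,) position or an
    (n, 3) array.
    """
    pos = np.asarray(position, dtype=float)
    phi = np.arctan2(pos[..., 1], pos[..., 0]) % (2.0 * np.pi)
    return phi * R


def tangent_at(position) -> np.ndarray:
    """Unit vector(s) along +φ̂ (anticlockwise ring tangent) at a position."""
    pos = np.asarray(position, dtype=float)
    phi = np.arctan2(pos[..., 1], pos[..., 0])
    t = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=-1)
    return t


# ---------------------------------------------------------------------------
# sampling in the binding band
# ---------------------------------------------------------------------------

#: the two preferred (non-neighbouring) quarter-sectors for myosin binding
PREFERRED_SECTORS = ((0.0, 0.5 * np.pi), (np.pi, 1.5 * np.pi))


def sample_phi(rng: np.random.Generator, sector_bias: float = 1.0) -> float:
    """Azimuth drawn uniformly, or biased toward two opposite quarter-sectors.

    ``sector_bias`` is the probability weight (per unit arc) of the two
    preferred sectors relative to the two others; 1 means uniform.
    """
    if sector_bias == 1.0:
        return rng.uniform(0.0, 2.0 * np.pi)
    w = np.array([sector_bias, 1.0, sector_bias, 1.0])
    sector = rng.choice(4, p=w / w.sum())
    return (sector + rng.uniform()) * 0.5 * np.pi


def sample_band_position(
    params: ModelParams,
    rng: np.random.Generator,
    depth: float,
    sector_bias: float = 1.0,
) -> np.ndarray:
    """Random position at radius R − depth, uniform per membrane area in the
    equatorial band of width ``w_band``."""
    phi = sample_phi(rng, sector_bias)
    z_mem = rng.uniform(-0.5 * params.w_band, 0.5 * params.w_band)
    u = np.array(
        [
            np.sqrt(max(0.0, 1.0 - (z_mem / params.R) ** 2)) * np.cos(phi),
            np.sqrt(max(0.0, 1.0 - (z_mem / params.R) ** 2)) * np.sin(phi),
            z_mem / params.R,
        ]
    )
    return (params.R - depth) * u


# ---------------------------------------------------------------------------
# component construction
# ---------------------------------------------------------------------------

def seed_filament(
    anchor: np.ndarray,
    length: float,
    orientation: str,
    params: ModelParams,
) -> Filament:
    """Lay a filament of the given length along the ring tangent.

    Subunits follow the circle of constant z through the anchor (constant
    cylindrical radius), with exact chord spacing ``l0``; clockwise means
    the chain runs along −φ̂ when viewed from +z.
    """
    n_sub = int(length // params.l0) + 1
    frac_tip = length - (n_sub - 1) * params.l0
    rho_c = float(np.hypot(anchor[0], anchor[1]))
    if rho_c <= params.l0:
        raise ValueError("anchor too close to the axis to seed a tangential filament")
    sign = 1.0 if orientation == ANTICLOCKWISE else -1.0
    # the chain extends from the barbed (formin) end toward the pointed end;
    # the barbed segment carries the fractional tip growth, so its chord is
    # l0 + frac_tip while every other bond has chord l0
    seg = np.full(max(n_sub - 1, 0), params.l0)
    if n_sub > 1:
        seg[0] += frac_tip
    dtheta = 2.0 * np.arcsin(np.minimum(1.0, 0.5 * seg / rho_c))
    theta = sign * np.concatenate([[0.0], np.cumsum(dtheta)])
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    x = anchor[0] * cos_t - anchor[1] * sin_t
    y = anchor[0] * sin_t + anchor[1] * cos_t
    z = np.full(n_sub, anchor[2])
    return Filament(np.stack([x, y, z], axis=1), frac_tip=frac_tip, orientation=orientation)


def make_initial_ring(params: ModelParams, rng: np.random.Generator) -> RingState:
    """Construct a fresh ring in the equatorial binding band.

    Formin/myosin counts are Poisson with means ``rho_for·2πR`` and
    ``rho_myo·2πR``; filament orientations are clockwise or anticlockwise
    with equal probability and initial lengths are drawn from the
    steady-state length distribution at the normal turnover rates.  Myosin
    azimuths carry the two-sector binding bias that shapes the observed
    ~1 μm density correlation length.
    """
    from .length_theory import sample_lengths

    params.validate()
    L_ring = params.circumference
    state = RingState(rng=rng, mode="normal")

    n_for = rng.poisson(params.rho_for * L_ring)
    a = params.koff_for / params.v_pol if params.v_pol > 0 else None
    b = (params.r_sev / 60.0) / params.v_pol if params.v_pol > 0 else None
    if a is not None and (a > 0 or b > 0):
        lengths = sample_lengths(a, b, n_for, rng)
    else:
        lengths = np.full(n_for, 1.4)  # degenerate rates: fixed typical length
    for i in range(n_for):
        anchor = sample_band_position(params, rng, params.d_for_anchor)
        orient = ANTICLOCKWISE if rng.uniform() < 0.5 else CLOCKWISE
        state.filaments.append(seed_filament(anchor, lengths[i], orient, params))

    n_myo = rng.poisson(params.rho_myo * L_ring)
    for _ in range(n_myo):
        pos = sample_band_position(
            params, rng, params.d_myo_anchor, sector_bias=params.sector_bias
        )
        state.myosins.append(MyosinCluster(pos))

    _seed_crosslinks(state, params, rng)
    return state


def _seed_crosslinks(state: RingState, params: ModelParams, rng: np.random.Generator) -> None:
    """Link eligible subunit pairs at random up to the target line density."""
    from .turnover_kinetics import eligible_crosslink_pairs

    target = int(round(params.rho_x * params.circumference))
    pairs = eligible_crosslink_pairs(state, params)
    if not pairs:
        return
    n_new = min(target, len(pairs))
    chosen = rng.choice(len(pairs), size=n_new, replace=False)
    from .state import Crosslink

    for idx in chosen:
        fa, sa, fb, sb = pairs[idx]
        state.crosslinks.append(Crosslink(fa, sa, fb, sb))


def pre_equilibrate(state: RingState, params: ModelParams, duration_s: float) -> RingState:
    """Evolve the ring under normal turnover for ``duration_s`` seconds.

    Eleven simulated minutes suffice to reach the steady state used as the
    t = 0 condition of the turnover-free (ghost) protocols.
    """
    from .constrained_dynamics import step

    n_steps = int(round(duration_s / params.dt))
    for _ in range(n_steps):
        state = step(state, params, mode="normal")
    return state
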