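"""Force terms of the ring model.

Each interaction is either an explicit (position-dependent) force, or a
linear-in-velocity coupling that the constrained-dynamics solver folds into
its left-hand side.  Pairwise terms are momentum-conserving: the reaction is
always the exact negative, for explicit parts and coupling blocks alike.

Sign conventions: subunit tangent t̂_i points from subunit i−1 to subunit i
(barbed end = subunit 0), so t̂ points *away* from the barbed end; the motor
pull on a subunit is +f_s·t̂, which slides the filament so that the cluster
approaches the barbed end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .params import ModelParams
from .state import Filament, RingState


# ---------------------------------------------------------------------------
# elementary force terms
# ---------------------------------------------------------------------------

def capture_force(subunit_pos, tangent_unit, cluster_pos, params: ModelParams) -> np.ndarray:
    """Perpendicular capture spring of a myosin cluster on a bound subunit.

    f = −k_cap·[(r_i − r_α) − ((r_i − r_α)·T̂)T̂]; only the component
    perpendicular to the filament is applied, so the spring does not fight
    the motor pull.  Returns the force on the subunit; the reaction on the
    cluster is its negative.
    """
    d = np.asarray(subunit_pos, float) - np.asarray(cluster_pos, float)
    T = np.asarray(tangent_unit, float)
    perp = d - (d @ T) * T
    return -params.k_cap * perp


def shared_stall_force(n_fil_engaged: int, params: ModelParams) -> float:
    """Stall force per filament, shared when a cluster pulls many filaments."""
    if n_fil_engaged < 1:
        raise ValueError("n_fil_engaged must be >= 1")
    return params.f_stall * min(1.0, params.n_fil_share / n_fil_engaged)


def pull_force_coefficients(
    tangent_unit, n_fil_engaged: int, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Linearized motor force–velocity law for one engaged subunit.

    f = f_s·[1 − (v_i − v_α)·t̂ / v_myo0]·t̂ splits into an explicit part
    f_s·t̂ on the subunit (reaction −f_s·t̂ on the cluster) and a pairwise
    velocity coupling −B·(v_i − v_α) with B = (f_s/v_myo0)·t̂t̂ᵀ.

    Returns ``(explicit_force_on_subunit, B)``.
    """
    if params.v_myo0 <= 0:
        raise ValueError("v_myo0 must be > 0")
    t = np.asarray(tangent_unit, float)
    fs = shared_stall_force(n_fil_engaged, params)
    return fs * t, (fs / params.v_myo0) * np.outer(t, t)


def bending_energy(positions, kappa: float, l0: float) -> float:
    """Discrete worm-like-chain bending energy H = (κ/l0)·Σ(1 − t̂_i·t̂_{i−1})."""
    r = np.asarray(positions, float)
    if r.shape[0] < 3:
        return 0.0
    u = np.diff(r, axis=0)
    t = u / np.linalg.norm(u, axis=1, keepdims=True)
    return (kappa / l0) * float(np.sum(1.0 - np.einsum("ij,ij->i", t[1:], t[:-1])))


def bending_forces(filament, params: ModelParams) -> np.ndarray:
    """Exact negative gradient of the bending energy; zero net force/torque.

    Accepts a :class:`Filament` or a raw (n, 3) position array.
    """
    r = filament.subunits if isinstance(filament, Filament) else np.asarray(filament, float)
    n = r.shape[0]
    F = np.zeros_like(r, dtype=float)
    if n < 3:
        return F
    u = np.diff(r, axis=0)                      # (n-1, 3), u[k] = r[k+1]-r[k]
    norm = np.linalg.norm(u, axis=1, keepdims=True)
    t = u / norm
    c = np.einsum("ij,ij->i", t[:-1], t[1:])    # cos of bend angle at interior subunits
    pref = params.kappa / params.l0
    # dH/du_k summed over the (k-1,k) and (k,k+1) tangent pairs
    G = np.zeros_like(u)
    # contribution of pair (k, k+1) to u_k:  -(t_{k+1} - c_k t_k)/|u_k|
    G[:-1] += -pref * (t[1:] - c[:, None] * t[:-1]) / norm[:-1]
    # contribution of pair (k-1, k) to u_k:  -(t_{k-1} - c_{k-1} t_k)/|u_k|
    G[1:] += -pref * (t[:-1] - c[:, None] * t[1:]) / norm[1:]
    # F_i = G_{i+1} - G_i   (u_k depends on r_k with + and r_{k-1}... r index shift)
    F[:-1] += G
    F[1:] -= G
    return F


def crosslink_force(pos_a, pos_b, params: ModelParams) -> tuple[np.ndarray, bool]:
    """Hookean α-actinin spring between two cross-linked subunits.

    Returns ``(force_on_a, ruptured)``; rupture is flagged when the
    separation exceeds ``r_x_bind`` (the link then unbinds at turnover).
    """
    d = np.asarray(pos_b, float) - np.asarray(pos_a, float)
    dist = float(np.linalg.norm(d))
    ruptured = dist > params.r_x_bind
    if dist == 0.0:
        return np.zeros(3), ruptured
    f = params.k_x * (dist - params.r_x0) * (d / dist)
    return f, ruptured


def excluded_volume_forces(
    positions, params: ModelParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Pairwise linear repulsion between myosin clusters closer than d_excl.

    ``k_excl_myo`` is given in pN/nm (the conventional printed unit) and is
    converted to pN/μm here.  Coincident clusters repel along a fixed
    deterministic fallback axis so the probability-zero event cannot crash
    the solver.
    """
    r = np.atleast_2d(np.asarray(positions, float))
    F = np.zeros_like(r)
    if r.shape[0] < 2:
        return F
    k = params.k_excl_myo * 1e3  # pN/nm -> pN/μm
    tree = cKDTree(r)
    pairs = tree.query_pairs(params.d_excl_myo, output_type="ndarray")
    for i, j in pairs:
        d = r[j] - r[i]
        dist = float(np.linalg.norm(d))
        if dist == 0.0:
            u = _fallback_axis(rng)
        else:
            u = d / dist
        f = k * (params.d_excl_myo - dist) * u
        F[i] -= f
        F[j] += f
    return F


def _fallback_axis(rng: np.random.Generator | None) -> np.ndarray:
    if rng is None:
        return np.array([1.0, 0.0, 0.0])
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def confinement_force(position, params: ModelParams) -> np.ndarray:
    """Elastic restoring force toward the origin, active only outside radius R."""
    r = np.asarray(position, float)
    dist = float(np.linalg.norm(r))
    if dist <= params.R or dist == 0.0:
        return np.zeros(3)
    return -params.k_mb * (dist - params.R) * (r / dist)


def drag_coefficients(kind: str, params: ModelParams) -> float:
    """Diagonal drag coefficient (pN·s/μm) for a component kind.

    Formins and myosin clusters feel membrane-anchor drag; actin subunits
    feel cytosolic drag (cytosolic drag on the anchored species is
    negligible by comparison and omitted).
    """
    table = {
        "formin": params.gamma_for,
        "actin": params.gamma_act,
        "myosin": params.gamma_myo,
    }
    try:
        return table[kind]
    except KeyError:
        raise ValueError(f"unknown component kind {kind!r}") from None


def tangent_plane_basis(position) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the local membrane tangent plane at a position."""
    r = np.asarray(position, float)
    n = r / np.linalg.norm(r)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def diffusion_force(
    cluster_pos, params: ModelParams, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian force driving lateral diffusion of a myosin cluster.

    Acts in the local membrane tangent plane only.  With the default
    fluctuation–dissipation convention the per-axis discrete-time variance is
    2·D·γ²/dt, so the measured diffusivity of a free anchored cluster equals
    ``D_myo``; the 'halved' convention uses the correlator D·γ²·δ(t−t′)
    as sometimes written, which halves the realized diffusivity.
    """
    if params.D_myo == 0.0:
        return np.zeros(3)
    c = 2.0 if params.diffusion_convention == "fdt" else 1.0
    sigma = np.sqrt(c * params.D_myo * params.gamma_myo**2 / dt)
    e1, e2 = tangent_plane_basis(cluster_pos)
    xi = rng.normal(size=2)
    return sigma * (xi[0] * e1 + xi[1] * e2)


# ---------------------------------------------------------------------------
# whole-state force evaluation
# ---------------------------------------------------------------------------

@dataclass
class ForceEvaluation:
    """Explicit forces plus velocity-coupling data for one time step.

    Component ordering: all actin subunits filament by filament (subunit 0
    of each filament is its formin), then all myosin clusters.
    """

    F: np.ndarray                       # (n_comp, 3) explicit forces, pN
    gamma: np.ndarray                   # (n_comp,) diagonal drag, pN·s/μm
    coup_i: np.ndarray                  # (m,) int, first member of each coupling
    coup_j: np.ndarray                  # (m,) int, second member
    coup_B: np.ndarray                  # (m, 3, 3) coupling blocks, pN·s/μm
    ruptured_links: list = field(default_factory=list)
    n_sub: int = 0
    n_myo: int = 0


def refresh_engagements(state: RingState, params: ModelParams) -> None:
    """Recompute each cluster's engaged-subunit set from current positions.

    Inactive (blebbistatin-deactivated) clusters bind nothing; filaments of
    a single subunit have no tangent and cannot be pulled, so they are not
    engaged either.
    """
    subs = state.all_subunits()
    offsets = state.subunit_offsets() if state.filaments else np.array([0])
    # map flat index -> (filament, subunit)
    fil_of = np.concatenate(
        [np.full(f.n_subunits, fi) for fi, f in enumerate(state.filaments)]
    ) if state.filaments else np.zeros(0, int)
    sub_of = np.concatenate(
        [np.arange(f.n_subunits) for f in state.filaments]
    ) if state.filaments else np.zeros(0, int)

    tree = cKDTree(subs) if len(subs) else None
    for m in state.myosins:
        m.engaged_subunits = []
        if not m.active or tree is None:
            continue
        idx = tree.query_ball_point(m.position, params.r_myo_capture)
        for flat in idx:
            fi = int(fil_of[flat])
            if state.filaments[fi].n_subunits < 2:
                continue
            m.engaged_subunits.append((fi, int(sub_of[flat])))


def subunit_tangents(filament: Filament) -> np.ndarray:
    """Unit tangent T̂ at every subunit: mean of adjacent segment tangents,
    single adjacent segment at the ends."""
    r = filament.subunits
    u = np.diff(r, axis=0)
    t = u / np.linalg.norm(u, axis=1, keepdims=True)
    T = np.zeros_like(r)
    T[0] = t[0]
    T[-1] = t[-1]
    if r.shape[0] > 2:
        mid = t[:-1] + t[1:]
        T[1:-1] = mid / np.linalg.norm(mid, axis=1, keepdims=True)
    return T


def evaluate_forces(
    state: RingState,
    params: ModelParams,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
) -> ForceEvaluation:
    """Evaluate every force term for the current configuration.

    Engagement sets are refreshed first (explicit coupling: forces for the
    whole step derive from start-of-step engagements).
    """
    dt = params.dt if dt is None else dt
    rng = state.rng if rng is None else rng
    refresh_engagements(state, params)

    n_sub = state.n_subunits
    n_myo = len(state.myosins)
    n_comp = n_sub + n_myo
    F = np.zeros((n_comp, 3))
    gamma = np.zeros(n_comp)
    coup_i: list[int] = []
    coup_j: list[int] = []
    coup_B: list[np.ndarray] = []

    offsets = state.subunit_offsets() if state.filaments else np.array([0])

    # per-filament: bending, diagonal drags, neighbour artificial drag
    tangents: list[np.ndarray] = []
    for fi, fil in enumerate(state.filaments):
        o = int(offsets[fi])
        n = fil.n_subunits
        F[o : o + n] += bending_forces(fil, params)
        gamma[o] += drag_coefficients("formin", params)
        if n > 1:
            gamma[o + 1 : o + n] += drag_coefficients("actin", params)
        B = params.gamma_a * np.eye(3)
        for k in range(n - 1):
            coup_i.append(o + k)
            coup_j.append(o + k + 1)
            coup_B.append(B)
        tangents.append(subunit_tangents(fil) if n > 1 else np.zeros((n, 3)))

    # myosin: drag, capture, pull, excluded volume, diffusion
    myo0 = n_sub
    if n_myo:
        gamma[myo0:] = drag_coefficients("myosin", params)
        mpos = state.myosin_positions()
        F[myo0:] += excluded_volume_forces(mpos, params, rng)
        if params.D_myo > 0:
            for a, m in enumerate(state.myosins):
                F[myo0 + a] += diffusion_force(m.position, params, dt, rng)

    # engagements, batched: capture spring (perpendicular component only)
    # plus the linearized motor pull and its velocity-coupling block
    eng_sub, eng_myo, eng_T, eng_fs = [], [], [], []
    for a, m in enumerate(state.myosins):
        if not m.engaged_subunits:
            continue
        fs = shared_stall_force(m.n_filaments_engaged(), params)
        for fi, si in m.engaged_subunits:
            eng_sub.append(int(offsets[fi]) + si)
            eng_myo.append(myo0 + a)
            eng_T.append(tangents[fi][si])
            eng_fs.append(fs)
    if eng_sub:
        isub = np.asarray(eng_sub, int)
        imyo = np.asarray(eng_myo, int)
        T = np.asarray(eng_T, float)
        fs = np.asarray(eng_fs, float)
        subs_all = state.all_subunits()
        mpos_all = state.myosin_positions()
        d = subs_all[isub] - mpos_all[imyo - myo0]
        fc = -params.k_cap * (d - np.einsum("ij,ij->i", d, T)[:, None] * T)
        fp = fs[:, None] * T
        ftot = fc + fp
        np.add.at(F, isub, ftot)
        np.add.at(F, imyo, -ftot)
        B = (fs / params.v_myo0)[:, None, None] * T[:, :, None] * T[:, None, :]
        B += params.gamma_a * np.eye(3)[None, :, :]
        coup_i.extend(isub.tolist())
        coup_j.extend(imyo.tolist())
        coup_B.extend(B)

    # confinement (all components)
    all_pos = (
        np.concatenate([state.all_subunits(), state.myosin_positions()], axis=0)
        if n_comp
        else np.zeros((0, 3))
    )
    if n_comp:
        dist = np.linalg.norm(all_pos, axis=1)
        out = dist > params.R
        if np.any(out):
            F[out] += (
                -params.k_mb
                * (dist[out] - params.R)
                / dist[out]
            )[:, None] * all_pos[out]

    # cross-links
    ruptured = []
    for xi, link in enumerate(state.crosslinks):
        pa, pb = link.endpoints(state)
        f, rupt = crosslink_force(pa, pb, params)
        ia = int(offsets[link.fil_a]) + link.sub_a
        ib = int(offsets[link.fil_b]) + link.sub_b
        F[ia] += f
        F[ib] -= f
        if rupt:
            ruptured.append(xi)

    return ForceEvaluation(
        F=F,
        gamma=gamma,
        coup_i=np.asarray(coup_i, int),
        coup_j=np.asarray(coup_j, int),
        coup_B=np.asarray(coup_B, float).reshape(-1, 3, 3),
        ruptured_links=ruptured,
        n_sub=n_sub,
        n_myo=n_myo,
    )
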