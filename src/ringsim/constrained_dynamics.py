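"""Per-step force-balance linear system and the explicit-Euler integrator.

The ring is overdamped: at every step the unknown component velocities and
the Lagrange multipliers (filament tension per inter-subunit bond, one
anchoring normal force per formin and per myosin cluster) solve a sparse
linear system built from

* zero net force on every component (drags and motor force–velocity
  couplings are linear in the velocities), and
* constraint-stabilized kinematics dg/dt = −g/τ_c for the bond-length
  constraints |r_{i+1}−r_i| = l0 (plus the growing barbed segment's
  l0 + frac_tip) and the radial anchoring constraints |r| = R − d.

Positions then advance by explicit Euler with Δt, after which turnover
events are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mechanics import ForceEvaluation, evaluate_forces
from .params import ModelParams
from .state import RingState


@dataclass
class StepReport:
    """Diagnostics of one solved force-balance step."""

    time: float
    max_constraint_residual: float          # μm, before stabilization
    solver_residual: float                  # relative |Ax−b|/|b|
    seg_tension: np.ndarray                 # pN, one per inter-subunit bond
    seg_fil: np.ndarray                     # filament index of each bond
    seg_sub: np.ndarray                     # lower subunit index of each bond
    formin_anchor: np.ndarray               # pN, normal anchor force per formin
    myosin_anchor: np.ndarray               # pN, per cluster


@dataclass
class ForceBalanceSystem:
    """Assembled sparse saddle-point system A·x = b.

    Unknown layout: x = [v (3 per component, subunits then myosins),
    λ_tension (one per bond), λ_formin (one per filament), λ_myosin
    (one per cluster)].
    """

    A: sp.spmatrix
    b: np.ndarray
    n_sub: int
    n_myo: int
    seg_i: np.ndarray       # flat component index of each bond's lower subunit
    seg_j: np.ndarray
    seg_fil: np.ndarray
    seg_sub: np.ndarray
    seg_g: np.ndarray       # constraint violations at assembly, μm
    anchor_g: np.ndarray

    @property
    def n_comp(self) -> int:
        return self.n_sub + self.n_myo

    @property
    def n_constraints(self) -> int:
        return len(self.seg_g) + len(self.anchor_g)


def assemble(
    state: RingState,
    params: ModelParams,
    forces: ForceEvaluation | None = None,
) -> ForceBalanceSystem:
    """Build the force-balance system for the current configuration."""
    if forces is None:
        forces = evaluate_forces(state, params)
    n_sub, n_myo = forces.n_sub, forces.n_myo
    n_comp = n_sub + n_myo
    offsets = state.subunit_offsets() if state.filaments else np.array([0])

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.asarray(r, int).ravel())
        cols.append(np.asarray(c, int).ravel())
        vals.append(np.asarray(v, float).ravel())

    # --- velocity block: diagonal drag ---
    idx = np.arange(3 * n_comp)
    add(idx, idx, np.repeat(forces.gamma, 3))

    # --- velocity block: pairwise couplings (artificial drag, motor f–v) ---
    d3 = np.arange(3)
    RR, CC = np.meshgrid(d3, d3, indexing="ij")
    if len(forces.coup_i):
        ci = forces.coup_i[:, None, None]
        cj = forces.coup_j[:, None, None]
        B = forces.coup_B
        for rr, cc, sgn in (
            (ci, ci, 1.0), (cj, cj, 1.0), (ci, cj, -1.0), (cj, ci, -1.0)
        ):
            add(3 * rr + RR, 3 * cc + CC, sgn * B)

    # --- bond (tension) constraints, vectorized over filaments ---
    seg_i_l, seg_fil_l, seg_sub_l, seg_u_l, seg_g_l, seg_rate_l = [], [], [], [], [], []
    for fi, fil in enumerate(state.filaments):
        n = fil.n_subunits
        if n < 2:
            continue
        o = int(offsets[fi])
        d = np.diff(fil.subunits, axis=0)
        dist = np.linalg.norm(d, axis=1)
        safe = np.where(dist > 0, dist, 1.0)
        u = d / safe[:, None]
        target = np.full(n - 1, params.l0)
        target[0] += fil.frac_tip
        rate = np.zeros(n - 1)
        if params.v_pol > 0:
            rate[0] = params.v_pol  # growing barbed segment target lengthens
        seg_i_l.append(o + np.arange(n - 1))
        seg_fil_l.append(np.full(n - 1, fi))
        seg_sub_l.append(np.arange(n - 1))
        seg_u_l.append(u)
        seg_g_l.append(dist - target)
        seg_rate_l.append(rate)
    if seg_i_l:
        seg_i = np.concatenate(seg_i_l)
        seg_fil = np.concatenate(seg_fil_l)
        seg_sub = np.concatenate(seg_sub_l)
        seg_u = np.concatenate(seg_u_l, axis=0)
        seg_g = np.concatenate(seg_g_l)
        seg_rate = np.concatenate(seg_rate_l)
    else:
        seg_i = np.zeros(0, int)
        seg_fil = np.zeros(0, int)
        seg_sub = np.zeros(0, int)
        seg_u = np.zeros((0, 3))
        seg_g = np.zeros(0)
        seg_rate = np.zeros(0)
    seg_j = seg_i + 1
    n_seg = len(seg_i)

    # --- anchoring constraints (formins then myosins) ---
    anc_pos_l = [fil.subunits[0] for fil in state.filaments] + [
        m.position for m in state.myosins
    ]
    anc_comp = np.array(
        [int(offsets[fi]) for fi in range(len(state.filaments))]
        + [n_sub + a for a in range(n_myo)],
        dtype=int,
    )
    if len(anc_comp):
        anc_pos = np.asarray(anc_pos_l, float)
        anc_dist = np.linalg.norm(anc_pos, axis=1)
        safe = np.where(anc_dist > 0, anc_dist, 1.0)
        anc_u = anc_pos / safe[:, None]
        radii = np.concatenate(
            [
                np.full(len(state.filaments), params.R - params.d_for_anchor),
                np.full(n_myo, params.R - params.d_myo_anchor),
            ]
        )
        anc_g = anc_dist - radii
    else:
        anc_u = np.zeros((0, 3))
        anc_g = np.zeros(0)
    n_anc = len(anc_comp)

    nv = 3 * n_comp
    size = nv + n_seg + n_anc
    b = np.zeros(size)
    b[:nv] = forces.F.ravel()

    # multiplier columns in the balance rows (force −λ moved to LHS) and the
    # matching constraint rows ∂g/∂x · v = −g/τ (+ target rate); the bond
    # multiplier force on the lower subunit i is +λ·û (pulled toward i+1)
    if n_seg:
        colseg = nv + np.arange(n_seg)
        cols3 = np.repeat(colseg, 3)
        add(3 * seg_i[:, None] + d3, cols3, -seg_u)
        add(3 * seg_j[:, None] + d3, cols3, seg_u)
        add(np.repeat(colseg, 3), 3 * seg_j[:, None] + d3, seg_u)
        add(np.repeat(colseg, 3), 3 * seg_i[:, None] + d3, -seg_u)
        b[colseg] = -seg_g / params.tau_c + seg_rate
    if n_anc:
        colanc = nv + n_seg + np.arange(n_anc)
        add(3 * anc_comp[:, None] + d3, np.repeat(colanc, 3), -anc_u)
        add(np.repeat(colanc, 3), 3 * anc_comp[:, None] + d3, anc_u)
        b[colanc] = -anc_g / params.tau_c

    A = sp.coo_matrix(
        (np.concatenate(vals) if vals else np.zeros(0),
         (np.concatenate(rows) if rows else np.zeros(0, int),
          np.concatenate(cols) if cols else np.zeros(0, int))),
        shape=(size, size),
    ).tocsc()

    return ForceBalanceSystem(
        A=A,
        b=b,
        n_sub=n_sub,
        n_myo=n_myo,
        seg_i=seg_i,
        seg_j=seg_j,
        seg_fil=seg_fil,
        seg_sub=seg_sub,
        seg_g=seg_g,
        anchor_g=anc_g,
    )


def solve(system: ForceBalanceSystem) -> tuple[np.ndarray, dict, StepReport]:
    """Solve the assembled sparse system exactly.

    Returns ``(velocities, multipliers, report)`` with velocities of shape
    (n_comp, 3) and multipliers keyed 'tension', 'formin_anchor',
    'myosin_anchor' (all in pN).
    """
    n_comp = system.n_comp
    nv = 3 * n_comp
    if system.A.shape[0] == 0:
        empty = np.zeros(0)
        report = StepReport(0.0, 0.0, 0.0, empty, empty.astype(int),
                            empty.astype(int), empty, empty)
        return np.zeros((0, 3)), {"tension": empty, "formin_anchor": empty,
                                  "myosin_anchor": empty}, report

    try:
        x = spla.splu(system.A, permc_spec="COLAMD").solve(system.b)
    except RuntimeError:  # exactly singular factorization
        x = np.full(system.A.shape[0], np.nan)
    if not np.all(np.isfinite(x)):
        bad = _diagnose_singularity(system)
        raise np.linalg.LinAlgError(
            f"singular force-balance system; ill-conditioned component cluster: {bad}"
        )
    v = x[:nv].reshape(n_comp, 3)
    n_seg = len(system.seg_g)
    lam_seg = x[nv : nv + n_seg]
    lam_anc = x[nv + n_seg :]
    n_fil = len(system.anchor_g) - system.n_myo
    mult = {
        "tension": lam_seg,
        "formin_anchor": lam_anc[:n_fil],
        "myosin_anchor": lam_anc[n_fil:],
    }
    bnorm = float(np.linalg.norm(system.b))
    res = float(np.linalg.norm(system.A @ x - system.b)) / (bnorm if bnorm > 0 else 1.0)
    g_all = np.concatenate([system.seg_g, system.anchor_g]) if system.n_constraints else np.zeros(1)
    report = StepReport(
        time=0.0,
        max_constraint_residual=float(np.max(np.abs(g_all))),
        solver_residual=res,
        seg_tension=lam_seg,
        seg_fil=system.seg_fil,
        seg_sub=system.seg_sub,
        formin_anchor=mult["formin_anchor"],
        myosin_anchor=mult["myosin_anchor"],
    )
    return v, mult, report


def _diagnose_singularity(system: ForceBalanceSystem) -> str:
    gam = system.A.diagonal()[: 3 * system.n_comp]
    bad = np.unique(np.where(gam == 0)[0] // 3)
    if len(bad):
        return f"components with zero drag {bad.tolist()[:5]}"
    return "degenerate constraint geometry (coincident subunits?)"


def step(
    state: RingState,
    params: ModelParams,
    mode: str = "normal",
    rng: np.random.Generator | None = None,
) -> RingState:
    """Advance the ring by one time step Δt, then apply turnover.

    Raises RuntimeError if any constraint residual exceeds 0.1·l0, which
    indicates the time step is too large for the parameter set.
    """
    from .turnover_kinetics import apply_turnover, effective_params

    rng = state.rng if rng is None else rng
    eff = effective_params(params, mode)
    if state.filaments or state.myosins:
        forces = evaluate_forces(state, eff, eff.dt, rng)
        system = assemble(state, eff, forces)
        if system.n_constraints and np.max(
            np.abs(np.concatenate([system.seg_g, system.anchor_g]))
        ) > 0.1 * eff.l0:
            raise RuntimeError(
                "constraint residual exceeds 0.1·l0: time step too large for "
                "this parameter set"
            )
        v, mult, report = solve(system)
        report.time = state.time
        # Euler advance
        offsets = state.subunit_offsets()
        for fi, fil in enumerate(state.filaments):
            o = int(offsets[fi])
            fil.subunits += v[o : o + fil.n_subunits] * eff.dt
        for a, m in enumerate(state.myosins):
            m.position += v[system.n_sub + a] * eff.dt
        state.last_report = report
    state.time += eff.dt
    state = apply_turnover(state, params, mode, eff.dt, rng)
    return state
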