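"""Stochastic component turnover and the experimental-perturbation modes.

Species exchange with the (virtual) cytoplasm: formins (each carrying its
filament), myosin-II clusters and α-actinin cross-links dissociate at
first-order rates and, in modes with association, rebind at rates chosen to
hold the configured line densities.  Filaments grow at the formin-mediated
polymerization speed and are severed by cofilin at a rate proportional to
their length, keeping the barbed (formin) portion.

Modes:

========================== ==================================================
normal                      full turnover (intact cell)
ghost                       permeabilized cell: no association, v_pol = 0,
                            koff_for = 0, slowed severing and myosin loss
ghost_plus_myosin_turnover  ghost with normal myosin binding/unbinding
ghost_plus_actin_turnover   ghost with normal formin/actin dynamics
blebbistatin                ghost with a refreshed random subset of clusters
                            exerting no motor forces
diffusion                   ghost with lateral myosin diffusivity D_myo
========================== ==================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .params import ModelParams
from .state import ANTICLOCKWISE, Crosslink, Filament, MyosinCluster, RingState

MODES = (
    "normal",
    "ghost",
    "ghost_plus_myosin_turnover",
    "ghost_plus_actin_turnover",
    "blebbistatin",
    "diffusion",
)

#: species that associate (bind) in each mode
_BINDING = {
    "normal": frozenset({"formin", "myosin", "crosslink"}),
    "ghost": frozenset(),
    "ghost_plus_myosin_turnover": frozenset({"myosin"}),
    "ghost_plus_actin_turnover": frozenset({"formin"}),
    "blebbistatin": frozenset(),
    "diffusion": frozenset(),
}


@dataclass
class TurnoverMode:
    """A run mode plus its mode-specific parameter overrides."""

    mode: str = "normal"
    bleb_fraction: float | None = None
    D_myo: float | None = None
    myosin_scale: float | None = None
    actin_scale: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")


def binding_species(mode: str) -> frozenset[str]:
    return _BINDING[mode]


def effective_params(params: ModelParams, mode: str | TurnoverMode) -> ModelParams:
    """Resolve mode-dependent rates into a plain parameter set.

    Ghost-derived modes inherit the ghost kinetics (no association,
    koff_for = 0, v_pol = 0, tuned severing and myosin off-rate); the
    partial-rescue modes restore the normal kinetics of one species.
    Blebbistatin and diffusion act on top of the ghost kinetics.
    """
    tm = mode if isinstance(mode, TurnoverMode) else TurnoverMode(mode)
    if tm.mode == "normal":
        eff = params.replace()
    else:
        eff = params.replace(
            v_pol=params.v_pol_ghost,
            r_sev=params.r_sev_ghost,
            koff_for=params.koff_for_ghost,
            koff_myo=params.koff_myo_ghost,
        )
        if tm.mode == "ghost_plus_myosin_turnover":
            eff = eff.replace(koff_myo=params.koff_myo)
        elif tm.mode == "ghost_plus_actin_turnover":
            eff = eff.replace(
                koff_for=params.koff_for, v_pol=params.v_pol, r_sev=params.r_sev
            )
    if tm.mode != "blebbistatin":
        eff = eff.replace(bleb_fraction=0.0)
    elif tm.bleb_fraction is not None:
        eff = eff.replace(bleb_fraction=tm.bleb_fraction)
    if tm.mode != "diffusion":
        eff = eff.replace(D_myo=0.0)
    elif tm.D_myo is not None:
        eff = eff.replace(D_myo=tm.D_myo)
    return eff


# ---------------------------------------------------------------------------
# elementary kinetics
# ---------------------------------------------------------------------------

def polymerize(filament: Filament, params: ModelParams, dt: float) -> Filament:
    """Barbed-end growth by v_pol·dt via the fractional tip segment.

    A new subunit is inserted just behind the formin once the fractional
    growth reaches one subunit spacing l0.
    """
    if params.v_pol <= 0:
        return filament
    filament.frac_tip += params.v_pol * dt
    while filament.frac_tip >= params.l0:
        filament.frac_tip -= params.l0
        r = filament.subunits
        if r.shape[0] == 1:
            from .ring_model import tangent_at

            sign = 1.0 if filament.orientation == ANTICLOCKWISE else -1.0
            u = sign * tangent_at(r[0])
        else:
            d = r[1] - r[0]
            u = d / np.linalg.norm(d)
        # distance formin -> new subunit = l0 + remaining frac_tip
        new = r[0] + u * (params.l0 + filament.frac_tip)
        filament.subunits = np.insert(r, 1, new, axis=0)
    return filament


def sever(
    filament: Filament,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
) -> tuple[Filament, bool]:
    """Cofilin severing: one event with probability ≈ r_sev·L·dt.

    The cut point is uniform along the filament length; the portion from
    the cut to the pointed end is discarded (truncated to the subunit
    grid), the barbed/formin portion retained.  Returns (filament,
    severed_flag).
    """
    L = filament.length(params.l0)
    rate = (params.r_sev / 60.0) * L  # 1/(μm·min) -> 1/(μm·s)
    if rate <= 0 or rng.uniform() > -np.expm1(-rate * dt):
        return filament, False
    x = rng.uniform(0.0, L)
    # distance from the barbed end to subunit m (m>=1) is m·l0 + frac_tip
    m_keep = int((x - filament.frac_tip) // params.l0) if x >= filament.frac_tip else 0
    n_new = max(1, m_keep + 1)
    if n_new < filament.n_subunits:
        filament.subunits = filament.subunits[:n_new]
        if n_new == 1:
            filament.frac_tip = min(filament.frac_tip, x)
    return filament, True


def blebbistatin_mask(
    state: RingState, bleb_fraction: float, rng: np.random.Generator
) -> None:
    """Flag a uniformly random round(fraction·N) subset of clusters inactive.

    Inactive clusters exert no capture or pull forces but keep their
    anchoring, drag and excluded-volume interactions.
    """
    if not 0.0 <= bleb_fraction <= 1.0:
        raise ValueError("bleb_fraction must lie in [0, 1]")
    n = len(state.myosins)
    for m in state.myosins:
        m.active = True
    n_off = int(round(bleb_fraction * n))
    if n_off:
        for idx in rng.choice(n, size=n_off, replace=False):
            state.myosins[idx].active = False


def scan_turnover_times(
    base_params: ModelParams, myosin_scale: float = 1.0, actin_scale: float = 1.0
) -> ModelParams:
    """Derived parameters for the turnover-time scans.

    The myosin off-rate is scaled (its on-rate follows automatically since
    binding balances dissociation at the configured density, keeping the
    on/off ratio fixed).  The formin off-rate is co-scaled with v_pol and
    r_sev so koff_for/v_pol and r_sev/v_pol — and hence the steady-state
    filament length distribution — are unchanged.  The load-free myosin
    velocity is set to five times its normal value in these scans.
    """
    if myosin_scale <= 0 or actin_scale <= 0:
        raise ValueError("scales must be > 0")
    return base_params.replace(
        koff_myo=base_params.koff_myo * myosin_scale,
        koff_for=base_params.koff_for * actin_scale,
        v_pol=base_params.v_pol * actin_scale,
        r_sev=base_params.r_sev * actin_scale,
        v_myo0=5.0 * base_params.v_myo0,
    )


# ---------------------------------------------------------------------------
# whole-state turnover
# ---------------------------------------------------------------------------

def eligible_crosslink_pairs(state: RingState, params: ModelParams) -> list:
    """Subunit pairs on distinct filaments within r_x_bind, not yet linked."""
    subs = state.all_subunits()
    if subs.shape[0] < 2:
        return []
    fil_of = np.concatenate(
        [np.full(f.n_subunits, fi) for fi, f in enumerate(state.filaments)]
    )
    sub_of = np.concatenate([np.arange(f.n_subunits) for f in state.filaments])
    existing = {
        frozenset(((x.fil_a, x.sub_a), (x.fil_b, x.sub_b))) for x in state.crosslinks
    }
    tree = cKDTree(subs)
    out = []
    for i, j in tree.query_pairs(params.r_x_bind):
        fa, sa = int(fil_of[i]), int(sub_of[i])
        fb, sb = int(fil_of[j]), int(sub_of[j])
        if fa == fb:
            continue
        if frozenset(((fa, sa), (fb, sb))) in existing:
            continue
        out.append((fa, sa, fb, sb))
    return out


def _bernoulli_removal(n: int, koff: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean keep-mask under exact exponential per-step removal probability."""
    if koff <= 0 or n == 0:
        return np.ones(n, bool)
    p = -np.expm1(-koff * dt)
    return rng.uniform(size=n) >= p


def apply_turnover(
    state: RingState,
    params: ModelParams,
    mode: str | TurnoverMode = "normal",
    dt: float | None = None,
    rng: np.random.Generator | None = None,
) -> RingState:
    """Apply one time step of stochastic turnover to the state in place."""
    tm = mode if isinstance(mode, TurnoverMode) else TurnoverMode(mode)
    eff = effective_params(params, tm)
    dt = eff.dt if dt is None else dt
    rng = state.rng if rng is None else rng
    binds = binding_species(tm.mode)
    L_ring = eff.circumference

    # --- dissociation ---
    keep_fil = _bernoulli_removal(len(state.filaments), eff.koff_for, dt, rng)
    if not keep_fil.all():
        remap = {}
        new_fils = []
        for fi, (f, k) in enumerate(zip(state.filaments, keep_fil)):
            if k:
                remap[fi] = len(new_fils)
                new_fils.append(f)
        state.filaments = new_fils
        state.crosslinks = [
            Crosslink(remap[x.fil_a], x.sub_a, remap[x.fil_b], x.sub_b)
            for x in state.crosslinks
            if x.fil_a in remap and x.fil_b in remap
        ]
    keep_myo = _bernoulli_removal(len(state.myosins), eff.koff_myo, dt, rng)
    if not keep_myo.all():
        state.myosins = [m for m, k in zip(state.myosins, keep_myo) if k]

    # cross-links: first-order unbinding plus forced rupture beyond r_x_bind
    kept_links = []
    keep_x = _bernoulli_removal(len(state.crosslinks), eff.koff_x, dt, rng)
    for x, k in zip(state.crosslinks, keep_x):
        if not k:
            continue
        pa, pb = x.endpoints(state)
        if float(np.linalg.norm(pb - pa)) > eff.r_x_bind:
            continue
        kept_links.append(x)
    state.crosslinks = kept_links

    # --- severing and polymerization ---
    severed_any = False
    for fil in state.filaments:
        _, cut = sever(fil, eff, dt, rng)
        severed_any = severed_any or cut
        polymerize(fil, eff, dt)
    if severed_any:
        state.crosslinks = [
            x
            for x in state.crosslinks
            if x.sub_a < state.filaments[x.fil_a].n_subunits
            and x.sub_b < state.filaments[x.fil_b].n_subunits
        ]

    # --- association ---
    from .ring_model import sample_band_position
    from .state import CLOCKWISE

    if "formin" in binds and eff.koff_for > 0:
        n_new = rng.poisson(eff.koff_for * eff.rho_for * L_ring * dt)
        for _ in range(n_new):
            anchor = sample_band_position(eff, rng, eff.d_for_anchor)
            orient = ANTICLOCKWISE if rng.uniform() < 0.5 else CLOCKWISE
            state.filaments.append(
                Filament(anchor[None, :].copy(), frac_tip=0.0, orientation=orient)
            )
    if "myosin" in binds and eff.koff_myo > 0:
        n_new = rng.poisson(eff.koff_myo * eff.rho_myo * L_ring * dt)
        for _ in range(n_new):
            pos = sample_band_position(
                eff, rng, eff.d_myo_anchor, sector_bias=eff.sector_bias
            )
            state.myosins.append(MyosinCluster(pos))
    if "crosslink" in binds:
        target = eff.rho_x * L_ring
        current = len(state.crosslinks)
        rate = eff.koff_x * target + max(0.0, target - current) / eff.tau_x_control
        n_att = rng.poisson(rate * dt)
        if n_att:
            pairs = eligible_crosslink_pairs(state, eff)
            if pairs:
                n_new = min(n_att, len(pairs))
                for idx in rng.choice(len(pairs), size=n_new, replace=False):
                    fa, sa, fb, sb = pairs[idx]
                    state.crosslinks.append(Crosslink(fa, sa, fb, sb))

    # --- blebbistatin subset refresh (every bleb_refresh seconds) ---
    if tm.mode == "blebbistatin":
        period = eff.bleb_refresh
        if int(state.time / period) != int((state.time - dt) / period) or not any(
            not m.active for m in state.myosins
        ):
            blebbistatin_mask(state, eff.bleb_fraction, rng)

    # drop stale engagement references
    for m in state.myosins:
        m.engaged_subunits = [
            (fi, si)
            for fi, si in m.engaged_subunits
            if fi < len(state.filaments) and si < state.filaments[fi].n_subunits
        ]
    state.mode = tm.mode
    return state
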