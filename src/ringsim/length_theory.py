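"""Steady-state actin filament length distribution.

Filaments grow from formins at speed ``v_pol``; cofilin severs them at rate
``r_sev`` per unit length at a uniformly random point (the pointed-end
portion is lost); whole filaments disappear when their formin dissociates
at ``koff_for`` and renucleate at zero length.  With the reduced rates
a = koff_for/v_pol and b = r_sev/v_pol the stationary length density obeys

    p'' + (a + b·l)·p' + 2·b·p = 0,

whose normalizable solution, fixed by the master-equation boundary values
p(0) = a and p'(0) = b − a² (renucleation flux and severing influx at zero
length), is available in closed form:

    p(l) = (a + b·l)·exp(−a·l − b·l²/2),    mean = √(π/2b)·erfcx(a/√(2b)).

The distribution depends only on the ratios a and b; rescaling all three
rates jointly leaves it unchanged.

All rates here are in 1/s, μm/s and 1/(μm·s) — note the simulation-facing
parameter ``r_sev`` is configured in 1/(μm·min) and is converted by
:func:`calibrated_mean_length`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import erfcx


@dataclass
class LengthDistribution:
    """Stationary filament-length pdf on a uniform grid."""

    lengths: np.ndarray     # μm
    pdf: np.ndarray         # 1/μm, integrates to 1
    mean: float             # μm

    def cdf(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid

        c = cumulative_trapezoid(self.pdf, self.lengths, initial=0.0)
        return c / c[-1]


def _reduced_rates(koff_for: float, v_pol: float, r_sev: float) -> tuple[float, float]:
    if v_pol <= 0:
        raise ValueError("v_pol must be > 0 (no stationary growth process otherwise)")
    if koff_for < 0 or r_sev < 0:
        raise ValueError("rates must be >= 0")
    a = koff_for / v_pol
    b = r_sev / v_pol
    if a == 0 and b == 0:
        raise ValueError("koff_for and r_sev cannot both be zero: no normalizable "
                         "stationary distribution")
    return a, b


# ---------------------------------------------------------------------------
# closed form
# ---------------------------------------------------------------------------

def stationary_pdf(l, koff_for: float, v_pol: float, r_sev: float) -> np.ndarray:
    """Closed-form stationary pdf p(l) = (a+b·l)·exp(−a·l − b·l²/2)."""
    a, b = _reduced_rates(koff_for, v_pol, r_sev)
    l = np.asarray(l, float)
    return (a + b * l) * np.exp(-a * l - 0.5 * b * l * l)


def stationary_mean(koff_for: float, v_pol: float, r_sev: float) -> float:
    """Closed-form mean length √(π/2b)·erfcx(a/√(2b)) (→ 1/a as r_sev → 0)."""
    a, b = _reduced_rates(koff_for, v_pol, r_sev)
    if b == 0:
        return 1.0 / a
    z = a / np.sqrt(2.0 * b)
    return float(np.sqrt(np.pi / (2.0 * b)) * erfcx(z))


def sample_lengths(a: float, b: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n lengths from the stationary distribution by inverse transform.

    The cumulative distribution is F(l) = 1 − exp(−a·l − b·l²/2), so with
    w ~ Exp(1) the quadratic b·l²/2 + a·l = w inverts exactly.
    """
    if a < 0 or b < 0 or (a == 0 and b == 0):
        raise ValueError("need a >= 0, b >= 0, not both zero")
    w = rng.exponential(size=n)
    if b == 0:
        return w / a
    return (-a + np.sqrt(a * a + 2.0 * b * w)) / b


# ---------------------------------------------------------------------------
# ODE solution
# ---------------------------------------------------------------------------

def solve_length_ode(
    koff_for: float,
    v_pol: float,
    r_sev: float,
    l_max: float | None = None,
    n_grid: int = 2001,
) -> LengthDistribution:
    """Numerically integrate the stationary length ODE and normalize.

    The one-parameter family of decaying solutions is pinned by the
    master-equation boundary values p(0) = a (renucleation flux) and
    p'(0) = b − a², which match the stochastic process near l = 0.
    """
    a, b = _reduced_rates(koff_for, v_pol, r_sev)
    if l_max is None:
        l_max = 12.0 * stationary_mean(koff_for, v_pol, r_sev)
    grid = np.linspace(0.0, l_max, n_grid)

    def rhs(l, y):
        p, dp = y
        return [dp, -(a + b * l) * dp - 2.0 * b * p]

    sol = solve_ivp(
        rhs, (0.0, l_max), [a, b - a * a], t_eval=grid, rtol=1e-10, atol=1e-14
    )
    if not sol.success:
        raise RuntimeError(f"length ODE integration failed: {sol.message}")
    p = np.clip(sol.y[0], 0.0, None)
    norm = np.trapezoid(p, grid)
    if norm <= 0:
        raise RuntimeError("length ODE produced a non-normalizable solution")
    p /= norm
    mean = float(np.trapezoid(grid * p, grid))
    return LengthDistribution(grid, p, mean)


# ---------------------------------------------------------------------------
# stochastic process oracle
# ---------------------------------------------------------------------------

def simulate_length_process(
    koff_for: float,
    v_pol: float,
    r_sev: float,
    n_filaments: int,
    t_end: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact event-driven simulation of n independent filament lengths.

    Each filament grows at ``v_pol``; severing occurs at total rate
    r_sev·l(t) (time-inhomogeneous, sampled by exact inversion of the
    cumulative hazard) with a uniform cut keeping the barbed portion;
    formin dissociation resets the length to zero.  Returns the lengths at
    ``t_end``, which should be several relaxation times.
    """
    a, b = _reduced_rates(koff_for, v_pol, r_sev)  # validates inputs
    del a, b
    lengths = np.empty(n_filaments)
    for i in range(n_filaments):
        t = 0.0
        l = 0.0
        while True:
            t_off = rng.exponential(1.0 / koff_for) if koff_for > 0 else np.inf
            if r_sev > 0:
                w = rng.exponential()
                # solve r_sev·(l·τ + v·τ²/2) = w for the severing time τ
                disc = l * l + 2.0 * v_pol * w / r_sev
                t_sev = (-l + np.sqrt(disc)) / v_pol
            else:
                t_sev = np.inf
            t_next = min(t_off, t_sev, t_end - t)
            l += v_pol * t_next
            t += t_next
            if t >= t_end:
                break
            if t_off <= t_sev:
                l = 0.0
            else:
                l *= rng.uniform()
        lengths[i] = l
    return lengths


def calibrated_mean_length(params, method: str = "ode") -> float:
    """Mean steady-state filament length at the configured normal rates, μm.

    ``method`` is 'ode' (numerical ODE solution), 'closed_form', or
    'process' (stochastic simulation with 10,000 filaments).
    """
    r_sev_si = params.r_sev / 60.0  # 1/(μm·min) -> 1/(μm·s)
    if method == "ode":
        return solve_length_ode(params.koff_for, params.v_pol, r_sev_si).mean
    if method == "closed_form":
        return stationary_mean(params.koff_for, params.v_pol, r_sev_si)
    if method == "process":
        rng = np.random.default_rng(0)
        relax = 5.0 * stationary_mean(params.koff_for, params.v_pol, r_sev_si) / params.v_pol
        samples = simulate_length_process(
            params.koff_for, params.v_pol, r_sev_si, 10_000, 4.0 * relax, rng
        )
        return float(samples.mean())
    raise ValueError(f"unknown method {method!r}")
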