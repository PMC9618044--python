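"""Model parameters for the contractile-ring simulation.

All quantities are in pN–μm–s units unless a field's docline says otherwise
(two exceptions, kept in their conventional printed units: ``k_excl_myo`` in
pN/nm and ``r_sev`` in 1/(μm·min)).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

#: Thermal energy at room temperature, pN·μm.
KBT = 4.1e-3


@dataclass
class ModelParams:
    """Physical constants, rates and mode switches of the ring model.

    Defaults describe a normal fission-yeast cytokinetic ring of radius
    3.7 μm with full component turnover.  Ghost (permeabilized-cell) values
    are held in the ``*_ghost`` fields and applied by
    :func:`ringsim.turnover_kinetics.effective_params`.
    """

    # --- geometry ---
    R: float = 3.7                #: cell / ring radius, μm
    w_band: float = 0.2           #: membrane binding-zone width, μm
    l0: float = 0.1               #: actin subunit spacing, μm
    d_for_anchor: float = 0.030   #: formin offset below the membrane, μm
    d_myo_anchor: float = 0.080   #: myosin offset below the membrane, μm

    # --- actin filament elasticity ---
    lp: float = 10.0              #: actin persistence length, μm

    # --- myosin capture and force-velocity ---
    r_myo_capture: float = 0.08   #: capture radius of a myosin cluster, μm
    k_cap: float = 400.0          #: capture spring constant, pN/μm
    f_stall: float = 4.0          #: stall force per engaged filament, pN
    n_fil_share: int = 10         #: filament count above which stall force is shared
    v_myo0: float = 0.24          #: load-free gliding velocity, μm/s

    # --- myosin excluded volume ---
    d_excl_myo: float = 0.045     #: myosin-myosin excluded-volume range, μm
    k_excl_myo: float = 4.0       #: excluded-volume stiffness, pN/nm

    # --- cross-linkers (alpha-actinin) ---
    r_x0: float = 0.030           #: cross-link rest length, μm
    k_x: float = 25.0             #: cross-link spring constant, pN/μm
    r_x_bind: float = 0.050       #: capture / rupture distance, μm
    koff_x: float = 3.3           #: cross-link off-rate, 1/s

    # --- confinement ---
    k_mb: float = 20.0            #: confinement stiffness at the membrane, pN/μm

    # --- drags ---
    gamma_for: float = 500.0      #: formin membrane-anchor drag, pN·s/μm
    gamma_myo: float = 1000.0     #: myosin membrane-anchor drag, pN·s/μm
    gamma_act: float = 0.2        #: cytosolic drag of an actin subunit, pN·s/μm
    gamma_a: float = 4.0          #: artificial pairwise drag, pN·s/μm

    # --- numerics ---
    dt: float = 0.01              #: time step, s
    tau_c: float | None = None    #: constraint-stabilization time, s (default 10·dt)

    # --- turnover rates (normal ring) ---
    v_pol: float = 0.07           #: formin-mediated polymerization speed, μm/s
    r_sev: float = 1.8            #: cofilin severing rate, 1/(μm·min)
    koff_for: float = 0.020       #: formin off-rate, 1/s
    koff_myo: float = 0.026       #: myosin cluster off-rate, 1/s

    # --- turnover rates (ghost ring) ---
    v_pol_ghost: float = 0.0      #: polymerization speed in ghosts, μm/s
    r_sev_ghost: float = 0.05     #: severing rate in ghosts, 1/(μm·min)
    koff_for_ghost: float = 0.0   #: formin off-rate in ghosts, 1/s
    koff_myo_ghost: float = 2e-4  #: myosin off-rate in ghosts, 1/s

    # --- densities ---
    rho_for: float = 15.0         #: formin line density, 1/μm
    rho_x: float = 25.0           #: cross-linker line density target, 1/μm
    rho_myo: float = 8.0          #: myosin cluster line density, 1/μm

    # --- myosin binding sector bias ---
    sector_bias: float = 4.0      #: binding weight of the two preferred quarter-sectors

    # --- imaging / analysis ---
    psf_fwhm: float = 0.6         #: imaging point-spread FWHM, μm
    gap_min_width: float = 0.6    #: minimum width of a myosin gap, μm
    bin_width: float = 0.08       #: arc-length bin width of intensity profiles, μm
    peak_prominence_frac: float = 0.25  #: aggregate-call prominence, fraction of mean
    peak_min_separation: float = 0.3    #: minimum aggregate separation, μm
    gap_threshold_frac: float = 0.05    #: emptiness threshold, fraction of mean

    # --- perturbation modes ---
    D_myo: float = 0.0            #: lateral myosin diffusivity, μm²/s
    bleb_fraction: float = 0.0    #: fraction of motors deactivated (blebbistatin)
    bleb_refresh: float = 1.0     #: deactivated-subset refresh interval, s
    diffusion_convention: str = "fdt"  #: 'fdt' or 'halved' noise correlator

    # --- cross-linker binding controller ---
    tau_x_control: float = 1.0    #: relaxation time of the cross-link density controller, s

    def __post_init__(self) -> None:
        if self.tau_c is None:
            self.tau_c = 10.0 * self.dt
        self.validate()

    # derived -----------------------------------------------------------
    @property
    def kappa(self) -> float:
        """Bending modulus κ = kBT·lp, pN·μm²."""
        return KBT * self.lp

    @property
    def circumference(self) -> float:
        """Ring circumference 2πR, μm."""
        import math

        return 2.0 * math.pi * self.R

    # validation --------------------------------------------------------
    _NONNEGATIVE = (
        "v_pol", "v_pol_ghost", "D_myo", "bleb_fraction",
        "koff_x", "koff_for", "koff_myo", "koff_for_ghost", "koff_myo_ghost",
        "r_sev", "r_sev_ghost", "rho_for", "rho_x", "rho_myo",
    )

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                continue
            if f.name in self._NONNEGATIVE:
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            elif f.name in ("n_fil_share",):
                if v < 1:
                    raise ValueError(f"{f.name} must be >= 1, got {v}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v}")
        if not 0.0 <= self.bleb_fraction <= 1.0:
            raise ValueError(f"bleb_fraction must lie in [0,1], got {self.bleb_fraction}")
        if self.diffusion_convention not in ("fdt", "halved"):
            raise ValueError(
                f"diffusion_convention must be 'fdt' or 'halved', got {self.diffusion_convention!r}"
            )

    # config I/O --------------------------------------------------------
    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load from a flat YAML/JSON key-value file; unknown keys rejected."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
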