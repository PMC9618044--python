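"""In-memory representation of the mechanical state of the ring.

Positions are 3D, in μm, with the cell centre at the origin and the ring
lying in the equatorial band of the membrane sphere (|z| ≤ w_band/2).

A filament is an ordered chain of coarse-grained actin subunits spaced
``l0`` apart; subunit 0 *is* the formin dimer processively bound to the
barbed end and anchored to the membrane.  Myosin-II clusters are
membrane-anchored point particles that engage any subunit within their
capture radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

CLOCKWISE = "clockwise"
ANTICLOCKWISE = "anticlockwise"


@dataclass
class Filament:
    """An inextensible, flexible actin filament anchored at its barbed end.

    ``subunits[0]`` is the barbed end / formin; ``subunits[-1]`` the pointed
    end.  ``frac_tip`` is the partially polymerized length of the barbed
    segment, so total length = (n-1)·l0 + frac_tip.
    """

    subunits: np.ndarray            # (n, 3) float array
    frac_tip: float = 0.0
    orientation: str = CLOCKWISE    # bookkeeping only

    def __post_init__(self) -> None:
        self.subunits = np.atleast_2d(np.asarray(self.subunits, dtype=float))
        if self.subunits.shape[1] != 3:
            raise ValueError("subunits must be an (n, 3) array")
        if self.frac_tip < 0:
            raise ValueError("frac_tip must be >= 0")

    @property
    def n_subunits(self) -> int:
        return self.subunits.shape[0]

    def length(self, l0: float) -> float:
        return (self.n_subunits - 1) * l0 + self.frac_tip

    @property
    def barbed(self) -> np.ndarray:
        return self.subunits[0]

    @property
    def pointed(self) -> np.ndarray:
        return self.subunits[-1]


@dataclass
class ForminAnchor:
    """Membrane anchor of a filament's barbed end (a view on subunit 0)."""

    filament_index: int

    def position(self, state: "RingState") -> np.ndarray:
        return state.filaments[self.filament_index].barbed


@dataclass
class MyosinCluster:
    """Coarse-grained membrane-anchored cluster of myosin-II dimers."""

    position: np.ndarray
    active: bool = True
    #: list of (filament_index, subunit_index) currently within capture radius
    engaged_subunits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)

    def n_filaments_engaged(self) -> int:
        return len({f for f, _ in self.engaged_subunits})


@dataclass
class Crosslink:
    """α-actinin spring joining two subunits on distinct filaments."""

    fil_a: int
    sub_a: int
    fil_b: int
    sub_b: int

    def __post_init__(self) -> None:
        if self.fil_a == self.fil_b:
            raise ValueError("cross-link endpoints must lie on distinct filaments")

    def endpoints(self, state: "RingState") -> tuple[np.ndarray, np.ndarray]:
        return (
            state.filaments[self.fil_a].subunits[self.sub_a],
            state.filaments[self.fil_b].subunits[self.sub_b],
        )


@dataclass
class RingState:
    """Complete mechanical state of the ring at one instant."""

    filaments: list = field(default_factory=list)
    myosins: list = field(default_factory=list)
    crosslinks: list = field(default_factory=list)
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    mode: str = "normal"
    #: diagnostics of the most recent dynamics step (StepReport or None)
    last_report: object = None
    #: slow controller state for the cross-link binding rate
    xlink_rate: float = 0.0

    @property
    def formins(self) -> list[ForminAnchor]:
        return [ForminAnchor(i) for i in range(len(self.filaments))]

    @property
    def n_subunits(self) -> int:
        return sum(f.n_subunits for f in self.filaments)

    def myosin_positions(self) -> np.ndarray:
        if not self.myosins:
            return np.zeros((0, 3))
        return np.array([m.position for m in self.myosins])

    def all_subunits(self) -> np.ndarray:
        """Concatenated (n_subunits, 3) array of every subunit position."""
        if not self.filaments:
            return np.zeros((0, 3))
        return np.concatenate([f.subunits for f in self.filaments], axis=0)

    def subunit_offsets(self) -> np.ndarray:
        """Start index of each filament in the flat subunit array."""
        counts = [f.n_subunits for f in self.filaments]
        return np.concatenate([[0], np.cumsum(counts)])

    def iter_segments(self) -> Iterator[tuple[int, int]]:
        """Yield (filament_index, segment_index) for every bonded pair."""
        for fi, f in enumerate(self.filaments):
            for si in range(f.n_subunits - 1):
                yield fi, si

    def total_actin_length(self, l0: float) -> float:
        return sum(f.length(l0) for f in self.filaments)

    def copy(self) -> "RingState":
        """Deep copy sharing the RNG (the RNG advances across copies)."""
        import copy as _copy

        new = RingState(
            filaments=[
                Filament(f.subunits.copy(), f.frac_tip, f.orientation)
                for f in self.filaments
            ],
            myosins=[
                MyosinCluster(m.position.copy(), m.active, list(m.engaged_subunits))
                for m in self.myosins
            ],
            crosslinks=[_copy.copy(x) for x in self.crosslinks],
            time=self.time,
            rng=self.rng,
            mode=self.mode,
            xlink_rate=self.xlink_rate,
        )
        return new
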