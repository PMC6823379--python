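"""In-memory data model: species, box, frames and trajectories.

The z axis is the membrane normal / applied-field axis throughout.  Frames
store *wrapped* coordinates (each periodic coordinate folded into [0, L));
consumers that need continuous paths (the crossing detector, finite-difference
velocities) unwrap on demand via minimum-image displacements and never store
the unwrapped result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CapabilityError, ContractError, OrderingError

__all__ = [
    "IonSpecies",
    "BoxGeometry",
    "FieldSpec",
    "Frame",
    "Trajectory",
    "minimum_image",
    "finite_difference_velocities",
]


@dataclass(frozen=True)
class IonSpecies:
    """One particle species.

    charge is in elementary-charge units (…, -1, 0, +1, …);
    diffusion_const in nm^2/ns (may be None for file-derived species);
    count is the number of particles of this species, when known.
    """

    name: str
    charge: int = 0
    diffusion_const: float | None = None
    count: int = 0

    def __post_init__(self):
        if self.count < 0:
            raise ContractError(f"species {self.name}: count must be >= 0")
        if self.charge != int(self.charge):
            raise ContractError(f"species {self.name}: charge must be an integer")
        if self.diffusion_const is not None and self.diffusion_const < 0:
            # zero is allowed for bookkeeping; the simulator requires > 0
            raise ContractError(
                f"species {self.name}: diffusion_const must be >= 0"
            )


@dataclass(frozen=True)
class BoxGeometry:
    """Orthorhombic simulation box, lengths in nm."""

    L_x: float
    L_y: float
    L_z: float
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        if min(self.L_x, self.L_y, self.L_z) <= 0:
            raise ContractError("box lengths must all be > 0")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.L_x, self.L_y, self.L_z])

    @property
    def area(self) -> float:
        """Cross-sectional area A = L_x * L_y in nm^2."""
        return self.L_x * self.L_y

    @property
    def volume(self) -> float:
        return self.L_x * self.L_y * self.L_z


@dataclass(frozen=True)
class FieldSpec:
    """Uniform external electric field along z, in V/nm (signed; 0 allowed)."""

    E_z: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.E_z):
            raise ContractError("E_z must be finite")


@dataclass
class Frame:
    """One snapshot: positions (N, 3) in nm, optional velocities (N, 3) in nm/ns.

    species_index maps each particle to an entry of the owning trajectory's
    species table.  Positions are wrapped into [0, L) on periodic axes at
    construction.
    """

    time: float
    box: BoxGeometry
    species_index: np.ndarray
    position: np.ndarray
    velocity: np.ndarray | None = None

    def __post_init__(self):
        self.species_index = np.asarray(self.species_index, dtype=np.intp)
        self.position = np.array(self.position, dtype=float)
        if self.position.ndim != 2 or self.position.shape[1] != 3:
            raise ContractError("position must have shape (N, 3)")
        n = self.position.shape[0]
        if self.species_index.shape != (n,):
            raise ContractError("species_index length must match position rows")
        if self.velocity is not None:
            self.velocity = np.array(self.velocity, dtype=float)
            if self.velocity.shape != (n, 3):
                raise ContractError("velocity must have shape (N, 3)")
        L = self.box.lengths
        for ax in range(3):
            if self.box.periodic[ax]:
                self.position[:, ax] %= L[ax]

    @property
    def n(self) -> int:
        return self.position.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.position[:, 2]


def minimum_image(delta: np.ndarray, length: float) -> np.ndarray:
    """Fold displacements into the minimum-image interval (-L/2, L/2]."""
    return delta - length * np.round(np.asarray(delta, dtype=float) / length)


class Trajectory:
    """Time-ordered sequence of frames sharing one species table.

    Enforced at construction: strictly increasing times, species indices in
    range, and constant per-species particle counts across frames.
    """

    def __init__(self, species: Sequence[IonSpecies], frames: Sequence[Frame]):
        self.species: tuple[IonSpecies, ...] = tuple(species)
        self.frames: list[Frame] = list(frames)
        if not self.frames:
            raise ContractError("trajectory needs at least one frame")
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise OrderingError("frame times must be strictly increasing")
        n_sp = len(self.species)
        ref = np.bincount(self.frames[0].species_index, minlength=n_sp)
        for k, f in enumerate(self.frames):
            if f.species_index.size and f.species_index.max() >= n_sp:
                raise ContractError(f"frame {k}: species index out of range")
            if not np.array_equal(
                np.bincount(f.species_index, minlength=n_sp), ref
            ):
                raise ContractError(
                    f"frame {k}: per-species particle counts changed"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def has_velocities(self) -> bool:
        return all(f.velocity is not None for f in self.frames)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_by_name(self, name: str) -> IonSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"no species named {name!r}")

    def species_charges(self) -> Mapping[str, int]:
        return {s.name: s.charge for s in self.species}

    def charges(self, frame: Frame | None = None) -> np.ndarray:
        """Per-particle charge array (e) for a frame (default: first frame)."""
        f = frame if frame is not None else self.frames[0]
        q = np.array([s.charge for s in self.species], dtype=float)
        return q[f.species_index]

    def mask(self, name: str, frame: Frame | None = None) -> np.ndarray:
        f = frame if frame is not None else self.frames[0]
        idx = self.species_names.index(name)
        return f.species_index == idx

    def with_frames(self, frames: Iterable[Frame]) -> "Trajectory":
        return Trajectory(self.species, list(frames))


def finite_difference_velocities(traj: Trajectory) -> Trajectory:
    """Attach velocities as minimum-image displacement / frame interval.

    Forward finite differences over each (k-1, k) frame pair, assigned to
    frame k; the first frame has no preceding interval and is dropped.  Used
    when a trajectory carries no stored velocities but a consumer (the
    center-of-mass current) needs them.
    """
    if len(traj) < 2:
        raise CapabilityError(
            "need at least two frames to finite-difference velocities"
        )
    out: list[Frame] = []
    for prev, cur in zip(traj.frames[:-1], traj.frames[1:]):
        dt = cur.time - prev.time
        delta = cur.position - prev.position
        L = cur.box.lengths
        for ax in range(3):
            if cur.box.periodic[ax]:
                delta[:, ax] = minimum_image(delta[:, ax], L[ax])
        out.append(
            Frame(
                time=cur.time,
                box=cur.box,
                species_index=cur.species_index,
                position=cur.position.copy(),
                velocity=delta / dt,
            )
        )
    return traj.with_frames(out)
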