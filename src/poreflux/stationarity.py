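"""Stationarity diagnostics: stem occupancy, plateau time, diffusion time.

Whether a driven pore run has reached a stationary transport regime is
judged from (a) the number of ions occupying the stem region of the pore
(from the trans-side detection plane to 4 nm above it, by default) settling
to a plateau, and (b) the co-diffusion time scale

    tau = L^2 / D_eff,      D_eff = 2 D+ D- / (D+ + D-)

(the harmonic mean of the two diffusion constants), the time for the ionic
atmosphere to relax over a distance L of solvent.  With D+ = 2.54 and
D- = 2.45 nm^2/ns and L = 18.5 nm this evaluates to ~137 ns.

The plateau estimator is this package's own definition (the settling time
itself has no standard estimator): the earliest time t* whose rolling mean
over [t*, t* + window] stays within a tolerance of the final rolling mean
for the remainder of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ContractError
from .model import Trajectory

__all__ = [
    "OccupancySeries",
    "DiffusionTimeSpec",
    "stem_occupancy",
    "plateau_time",
    "diffusion_time",
]


@dataclass
class OccupancySeries:
    """Per-frame ion counts inside a z region [z_lo, z_hi)."""

    times: np.ndarray
    count_by_species: dict[str, np.ndarray]
    region: tuple[float, float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name, c in self.count_by_species.items():
            c = np.asarray(c, dtype=np.int64)
            if c.shape != self.times.shape:
                raise ContractError(f"species {name}: count length mismatch")
            self.count_by_species[name] = c


@dataclass(frozen=True)
class DiffusionTimeSpec:
    """tau = L^2 / D_eff with the harmonic-mean diffusion constant."""

    L: float
    D_plus: float
    D_minus: float

    @property
    def D_eff(self) -> float:
        return 2.0 * self.D_plus * self.D_minus / (self.D_plus + self.D_minus)

    @property
    def tau(self) -> float:
        return self.L ** 2 / self.D_eff


def stem_occupancy(traj: Trajectory, region: tuple[float, float],
                   species: Iterable[str] | None = None) -> OccupancySeries:
    """Count ions of each species with wrapped z in [z_lo, z_hi) per frame."""
    z_lo, z_hi = region
    if not z_lo < z_hi:
        raise ContractError("region must satisfy z_lo < z_hi")
    lz = traj.frames[0].box.L_z
    if z_lo < 0 or z_hi > lz:
        raise ContractError(f"region {region} outside the box [0, {lz}]")
    names = list(species) if species is not None else list(traj.species_names)
    counts = {nm: np.zeros(len(traj), dtype=np.int64) for nm in names}
    for k, f in enumerate(traj.frames):
        inside = (f.z >= z_lo) & (f.z < z_hi)
        for nm in names:
            counts[nm][k] = int((inside & traj.mask(nm, f)).sum())
    return OccupancySeries(times=traj.times, count_by_species=counts,
                           region=(z_lo, z_hi))


def plateau_time(times: np.ndarray, values: np.ndarray, window: float = 50.0,
                 tolerance: float = 0.10) -> tuple[float, bool]:
    """Earliest settling time of a series, by rolling-mean stability.

    Computes the mean over [t, t + window] for every admissible start t and
    returns the earliest t* from which all subsequent window means stay
    within tolerance * max(|final mean|, 1) of the final window mean (the
    floor of one count keeps the stability check meaningful when the plateau
    sits at or near zero).  Returns (series end, False) when never satisfied.

    window and times share units (ns); window must be shorter than the span.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size < 2:
        raise ContractError("times and values must match and have >= 2 points")
    span = times[-1] - times[0]
    if window >= span:
        raise ContractError(f"window {window} >= series span {span}")
    # window means via cumulative sums on the (possibly irregular) grid
    starts_idx = np.flatnonzero(times <= times[-1] - window)
    means = np.empty(starts_idx.size)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for j, i in enumerate(starts_idx):
        stop = int(np.searchsorted(times, times[i] + window, side="right"))
        means[j] = (csum[stop] - csum[i]) / (stop - i)
    final = means[-1]
    tol = tolerance * max(abs(final), 1.0)
    ok = np.abs(means - final) <= tol
    # earliest start from which every later window mean stays in tolerance
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        return float(times[starts_idx[0]]), True
    t_star = float(times[starts_idx[bad[-1] + 1]]) if bad[-1] + 1 < means.size \
        else float(times[-1])
    # windows adjacent to the end always track the final mean, so a plateau
    # is only credited when held for at least two windows of confirmation
    if t_star > times[-1] - 2.0 * window:
        return float(times[-1]), False
    return t_star, True


def diffusion_time(L: float, D_plus: float, D_minus: float) -> DiffusionTimeSpec:
    """Diffusion-time scale tau = L^2 / D_eff (ns) for a solvent span L (nm)."""
    if min(L, D_plus, D_minus) <= 0:
        raise ContractError("L, D_plus and D_minus must all be positive")
    return DiffusionTimeSpec(L=L, D_plus=D_plus, D_minus=D_minus)
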