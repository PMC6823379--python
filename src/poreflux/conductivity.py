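"""Bulk ionic conductivity from center-of-mass currents.

The instantaneous current of a symmetric binary electrolyte along z is

    I(t) = (1/L_z) * N_ions * e * (v_z+ - v_z-)

with v_z+- the z velocity of each species' center of mass and N_ions the
(common) number of ions per species.  The average current <I> is the slope
of an ordinary least-squares fit to the cumulative sum of I(t), and the
conductivity is kappa = <I> / (E A) with A = L_x * L_y the cross-sectional
area.  When several field strengths were run, their kappas are averaged.

nernst_einstein_kappa provides the ideal-electrolyte closed form

    kappa_NE = sum_i N_i q_i^2 e^2 D_i / (k_B T V)

which is exact for the package's non-interacting Brownian generator and
therefore serves as an independent oracle for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CapabilityError, ContractError, DegenerateFitError
from .model import (BoxGeometry, FieldSpec, Frame, IonSpecies, Trajectory,
                    finite_difference_velocities, minimum_image)
from .units import (E_CHARGE, K_B_J, KAPPA_PA_VNM_NM2_TO_S_M, unit_current)

__all__ = [
    "CurrentSeries",
    "ConductivityResult",
    "com_velocity_current",
    "current_series",
    "mean_current",
    "conductivity",
    "average_conductivity",
    "nernst_einstein_kappa",
    "msd_diffusion",
]


@dataclass
class CurrentSeries:
    """Instantaneous current I(t) in pA and its running time integral.

    cumulative[k] = sum_{j<=k} I[j] * dt_j (pA ns) with left-Riemann weights
    over the actual inter-frame intervals; the first interval is taken equal
    to the second (for the regular sampling the generator and MD engines
    produce, this is a plain cumulative sum times the sampling interval).
    """

    times: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.times.shape != self.I.shape:
            raise ContractError("times and I must have the same length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ContractError("times must be strictly increasing")

    @property
    def cumulative(self) -> np.ndarray:
        if self.times.size < 2:
            return self.I * 0.0
        dts = np.diff(self.times)
        dts = np.concatenate([[dts[0]], dts])
        return np.cumsum(self.I * dts)


@dataclass(frozen=True)
class ConductivityResult:
    mean_current: float      # pA
    field: FieldSpec
    area: float              # nm^2
    kappa: float             # S/m
    fit_r2: float | None = None


def com_velocity_current(frame: Frame, traj: Trajectory,
                         species_pos: str, species_neg: str) -> float:
    """Instantaneous z current of one frame, in pA.

    Uses the (mass-uniform) mean z velocity of each species as its
    center-of-mass velocity.  Requires stored velocities and equal counts of
    the two species (the formula carries a single N_ions).
    """
    if frame.velocity is None:
        raise CapabilityError(
            "frame has no velocities; attach them with "
            "finite_difference_velocities or use current_series"
        )
    mp = traj.mask(species_pos, frame)
    mn = traj.mask(species_neg, frame)
    n_pos, n_neg = int(mp.sum()), int(mn.sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both species must be non-empty")
    if n_pos != n_neg:
        raise ContractError(
            f"species counts differ ({n_pos} vs {n_neg}); the center-of-mass "
            "current formula assumes a symmetric salt"
        )
    v_pos = frame.velocity[mp, 2].mean()
    v_neg = frame.velocity[mn, 2].mean()
    return unit_current(n_pos * (v_pos - v_neg) / frame.box.L_z)


def current_series(traj: Trajectory, species_pos: str, species_neg: str,
                   velocities: str = "auto") -> CurrentSeries:
    """I(t) over a trajectory.

    velocities: 'stored' uses frame velocities (error if absent),
    'finite-difference' always recomputes them from positions, 'auto' uses
    stored ones when present.
    """
    if velocities not in ("auto", "stored", "finite-difference"):
        raise ContractError(f"unknown velocities mode {velocities!r}")
    if velocities == "finite-difference" or (
        velocities == "auto" and not traj.has_velocities
    ):
        if len(traj) < 2:
            raise CapabilityError(
                "a single frame without stored velocities cannot yield a current"
            )
        traj = finite_difference_velocities(traj)
    ivals = [com_velocity_current(f, traj, species_pos, species_neg)
             for f in traj.frames]
    return CurrentSeries(times=traj.times, I=np.array(ivals))


def mean_current(series: CurrentSeries) -> tuple[float, float]:
    """(<I> in pA, r^2): OLS slope of the cumulative current versus time."""
    if series.times.size < 3:
        raise DegenerateFitError("need at least 3 points to fit <I>")
    if np.ptp(series.times) == 0:
        raise DegenerateFitError("constant time vector")
    fit = stats.linregress(series.times, series.cumulative)
    return float(fit.slope), float(fit.rvalue ** 2)


def conductivity(mean_i: float, field: FieldSpec, box: BoxGeometry,
                 fit_r2: float | None = None) -> ConductivityResult:
    """kappa = <I>/(E A) in S/m; E must be nonzero."""
    if field.E_z == 0:
        raise ContractError(
            "conductivity is undefined at E = 0; use nernst_einstein_kappa"
        )
    kappa = mean_i / (field.E_z * box.area) * KAPPA_PA_VNM_NM2_TO_S_M
    return ConductivityResult(mean_current=mean_i, field=field, area=box.area,
                              kappa=kappa, fit_r2=fit_r2)


def average_conductivity(results: Sequence[ConductivityResult]) -> float:
    """Arithmetic mean of per-field conductivities (all from the same system)."""
    if not results:
        raise ContractError("average_conductivity needs at least one result")
    areas = {round(r.area, 9) for r in results}
    if len(areas) > 1:
        raise ContractError("results come from boxes with different areas")
    return float(np.mean([r.kappa for r in results]))


def msd_diffusion(traj: Trajectory, species: str, max_lag: int = 20,
                  axis: int = 2) -> float:
    """Diffusion constant (nm^2/ns) from the mean-squared displacement.

    Unwraps each particle's path via minimum-image inter-frame displacements,
    computes the variance of the displacement over lags 1..max_lag (the
    variance, not the raw second moment, so a uniform drift cancels exactly)
    and returns half the through-origin slope of MSD versus lag time.
    Validation utility: recovers the generator's input D on bulk runs.
    """
    if len(traj) < max_lag + 2:
        raise ContractError("trajectory shorter than the requested lag range")
    m = traj.mask(species)
    if not m.any():
        raise ContractError(f"no particles of species {species!r}")
    L = np.array([f.box.lengths[axis] for f in traj.frames])
    coords = np.stack([f.position[m, axis] for f in traj.frames])
    steps = np.diff(coords, axis=0)
    for k in range(steps.shape[0]):
        steps[k] = minimum_image(steps[k], L[k])
    unwrapped = np.concatenate([coords[:1], coords[:1] + np.cumsum(steps, axis=0)])
    times = traj.times
    lags = np.arange(1, max_lag + 1)
    msd = np.array([
        np.var(unwrapped[lag:] - unwrapped[:-lag]) for lag in lags
    ])
    tau = lags * float(np.mean(np.diff(times)))
    # through-origin fit: D = <msd, t> / (2 <t, t>)
    return float(np.dot(msd, tau) / np.dot(tau, tau) / 2.0)


def nernst_einstein_kappa(species: Iterable[IonSpecies], box: BoxGeometry,
                          temperature: float) -> float:
    """Ideal-electrolyte conductivity sum_i N_i q_i^2 e^2 D_i / (k_B T V), S/m."""
    if temperature <= 0:
        raise ContractError("temperature must be > 0")
    v_m3 = box.volume * 1e-27
    total = 0.0
    for sp in species:
        d = sp.diffusion_const
        if d is None or sp.count == 0 or sp.charge == 0:
            continue
        total += sp.count * sp.charge ** 2 * E_CHARGE ** 2 * (d * 1e-9)
    return total / (K_B_J * temperature * v_m3)
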