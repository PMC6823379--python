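"""Pore current from plane-crossing events.

An ion contributes a crossing event whenever its minimum-image path between
two consecutive frames straddles the detection plane (an xy plane at the
trans mouth of the pore); the event is signed by the direction of travel
along z.  Signed cumulative counts N_c(t), N_a(t) for cations and anions
give the transported charge Q(t) = e (N_c(t) - N_a(t)), held in exact
integer arithmetic.

The mean current over a fixed-event window is I_bar = dQ/dt where t_ini is
the first time |Q| reaches q_ini (default 5 e) and t_end the first time it
reaches q_ini + delta_Q (default 40 more charges); its error bar uses the
mean absolute deviation of the single-charge increments,
sigma = (1/N) sum |dQ_i - I dt_i| and deltaI = 2 sigma / dt.  Runs at
several biases assemble into an I-V curve; an experimental reference line
I_ref = dV / R_ref (1 GOhm), times 0.7 for negative bias to emulate the
~30% rectification of these channels, provides the comparison scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, WindowUnreachableError
from .model import Trajectory, minimum_image
from .units import PA_PER_E_NS

__all__ = [
    "CrossingRecord",
    "CurrentTrace",
    "WindowEstimate",
    "IVPoint",
    "IVReferenceSpec",
    "ReferenceCurrent",
    "detect_crossings",
    "cumulative_charge",
    "window_average_current",
    "successive_windows",
    "whole_run_current",
    "assemble_iv",
    "reference_current",
    "neutralize_ion_counts",
]


@dataclass(frozen=True)
class CrossingRecord:
    """One signed plane crossing: +1 crossed in +z, -1 in -z."""

    time: float
    particle_id: int
    species: str
    direction: int

    def __post_init__(self):
        if self.direction not in (-1, +1):
            raise ContractError("direction must be +1 or -1")


@dataclass
class CurrentTrace:
    """Signed cumulative crossings per charge class and Q(t) = N_c - N_a (e).

    Integer arithmetic throughout: Q is exact for any event list.
    """

    times: np.ndarray
    N_c: np.ndarray
    N_a: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.N_c = np.asarray(self.N_c, dtype=np.int64)
        self.N_a = np.asarray(self.N_a, dtype=np.int64)
        if not (self.times.shape == self.N_c.shape == self.N_a.shape):
            raise ContractError("times, N_c, N_a must have equal length")

    @property
    def Q(self) -> np.ndarray:
        return self.N_c - self.N_a


@dataclass(frozen=True)
class WindowEstimate:
    """Mean current over one fixed-charge window, with the error statistic."""

    q_ini: int
    delta_Q: int
    t_ini: float
    t_end: float
    I_bar: float       # pA, transport-signed
    sigma: float       # e
    delta_I: float     # pA
    n_events: int


@dataclass(frozen=True)
class IVPoint:
    bias: float                    # mV
    I_bar: float                   # pA
    delta_I: float                 # pA
    window: WindowEstimate | None  # None for whole-run (e.g. zero-bias) points
    run_id: str


@dataclass(frozen=True)
class IVReferenceSpec:
    """Experimental comparison line: R_ref in GOhm, rectification in (0, 1]."""

    R_ref: float = 1.0
    rectification_neg: float = 0.7

    def __post_init__(self):
        if self.R_ref <= 0:
            raise ContractError("R_ref must be > 0")
        if not 0 < self.rectification_neg <= 1:
            raise ContractError("rectification_neg must be in (0, 1]")


@dataclass(frozen=True)
class ReferenceCurrent:
    i_ref: float        # pA
    comparison: float   # pA, the plotted I_ref / 10 line


def detect_crossings(traj: Trajectory, plane_z: float,
                     species_filter: Iterable[str] | None = None
                     ) -> list[CrossingRecord]:
    """Signed crossing events of an xy plane at plane_z.

    Per particle and frame pair, the z displacement is interpreted under the
    minimum-image convention; the traveled segment [z0, z0 + dz] (which may
    extend past the periodic boundary) generates one event when it straddles
    the plane or one of its periodic images.  A wrap far from the plane
    therefore yields no event, and a genuine crossing carried across the
    boundary is still counted.  Events are stamped at the later frame.
    """
    if len(traj) < 2:
        raise ContractError("need at least 2 frames")
    lz0 = traj.frames[0].box.L_z
    if not 0 <= plane_z <= lz0:
        raise ContractError(f"plane_z={plane_z} outside the box [0, {lz0}]")
    names = np.array(traj.species_names)
    keep = None
    if species_filter is not None:
        wanted = set(species_filter)
        keep = np.array([nm in wanted for nm in names])
    records: list[CrossingRecord] = []
    for prev, cur in zip(traj.frames[:-1], traj.frames[1:]):
        lz = prev.box.L_z
        z0 = prev.z
        dz = minimum_image(cur.z - z0, lz)
        z1 = z0 + dz
        hit = np.zeros(z0.shape, dtype=bool)
        direction = np.sign(dz)
        for img in (plane_z - lz, plane_z, plane_z + lz):
            up = (z0 < img) & (img <= z1)
            down = (z1 <= img) & (img < z0)
            hit |= up | down
        if keep is not None:
            hit &= keep[cur.species_index]
        for pid in np.flatnonzero(hit):
            records.append(CrossingRecord(
                time=cur.time, particle_id=int(pid),
                species=str(names[cur.species_index[pid]]),
                direction=int(direction[pid]),
            ))
    return records


def cumulative_charge(records: Sequence[CrossingRecord],
                      time_grid: np.ndarray,
                      species_charge: Mapping[str, int]) -> CurrentTrace:
    """Accumulate signed crossings into N_c(t), N_a(t) on a time grid.

    species_charge maps species names to their charge sign; species with
    charge > 0 count toward N_c, charge < 0 toward N_a, neutral species are
    ignored.  Records must be time-sorted.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    t_rec = np.array([r.time for r in records])
    if t_rec.size and np.any(np.diff(t_rec) < 0):
        raise ContractError("records must be time-sorted")
    n_c = np.zeros(time_grid.size, dtype=np.int64)
    n_a = np.zeros(time_grid.size, dtype=np.int64)
    if t_rec.size:
        cat_steps = np.zeros(t_rec.size, dtype=np.int64)
        an_steps = np.zeros(t_rec.size, dtype=np.int64)
        for i, r in enumerate(records):
            q = species_charge.get(r.species, 0)
            if q > 0:
                cat_steps[i] = r.direction
            elif q < 0:
                an_steps[i] = r.direction
        # events at t contribute to grid points with time >= t
        idx = np.searchsorted(t_rec, time_grid, side="right")
        n_c = np.concatenate([[0], np.cumsum(cat_steps)])[idx]
        n_a = np.concatenate([[0], np.cumsum(an_steps)])[idx]
    return CurrentTrace(times=time_grid, N_c=n_c, N_a=n_a)


def _first_reach_times(times: np.ndarray, q_signed: np.ndarray,
                       levels: np.ndarray) -> np.ndarray:
    """For each level, the first trace time with q_signed >= level."""
    running_max = np.maximum.accumulate(q_signed)
    idx = np.searchsorted(running_max, levels, side="left")
    return times[idx]


def window_average_current(trace: CurrentTrace, q_ini: int = 5,
                           delta_Q: int = 40) -> WindowEstimate:
    """Mean current over the window |Q| in [q_ini, q_ini + delta_Q].

    Works on -Q for net-negative transport and restores the sign on output.
    t_ini is the first time |Q| >= q_ini; t_end the first time
    |Q| >= q_ini + delta_Q.  sigma is the mean absolute deviation of the
    delta_Q single-charge increment times from I * dt_i, in e;
    delta_I = 2 sigma / dt converted to pA.
    """
    if delta_Q < 1 or q_ini < 0:
        raise ContractError("need q_ini >= 0 and delta_Q >= 1")
    q = trace.Q
    sign = 1 if q[np.argmax(np.abs(q))] >= 0 else -1
    qs = sign * q
    target = q_ini + delta_Q
    achieved = int(np.max(qs))
    if achieved < target:
        raise WindowUnreachableError(required=target,
                                     achieved=int(np.max(np.abs(q))))
    levels = np.arange(q_ini, target + 1)
    reach = _first_reach_times(trace.times, qs, levels)
    t_ini, t_end = float(reach[0]), float(reach[-1])
    dt = t_end - t_ini
    if dt <= 0:
        raise ContractError("degenerate window: all charge arrived at once")
    rate = delta_Q / dt                       # e/ns
    gaps = np.diff(reach)                     # per-unit-charge waiting times
    sigma = float(np.mean(np.abs(1.0 - rate * gaps)))   # e
    return WindowEstimate(
        q_ini=q_ini, delta_Q=delta_Q, t_ini=t_ini, t_end=t_end,
        I_bar=sign * rate * PA_PER_E_NS, sigma=sigma,
        delta_I=2.0 * sigma * PA_PER_E_NS / dt, n_events=delta_Q,
    )


def successive_windows(trace: CurrentTrace, q_ini: int = 5, delta_Q: int = 40,
                       stride: int = 190) -> list[WindowEstimate]:
    """Windows at |Q| in [q_ini + k stride, q_ini + k stride + delta_Q], k = 0, 1, ...

    Returns the reachable prefix; stride = 190 reproduces the [5, 45] and
    [195, 235] windows used to compare early and late transport.
    """
    if stride < 1:
        raise ContractError("stride must be >= 1")
    out: list[WindowEstimate] = []
    k = 0
    while True:
        try:
            out.append(window_average_current(trace, q_ini + k * stride, delta_Q))
        except WindowUnreachableError:
            break
        k += 1
    return out


def whole_run_current(trace: CurrentTrace) -> float:
    """OLS slope of Q(t) over the whole run, in pA.

    The estimator reported when the event-window is unreachable (notably the
    zero-bias run).
    """
    if trace.times.size < 3 or np.ptp(trace.times) == 0:
        raise ContractError("need >= 3 distinct times for a whole-run slope")
    fit = stats.linregress(trace.times, trace.Q.astype(float))
    return float(fit.slope) * PA_PER_E_NS


def assemble_iv(windows_by_run: Mapping[str, Sequence[WindowEstimate | None]],
                biases: Mapping[str, float]) -> list[IVPoint]:
    """Pair window estimates with their run's bias into a sorted I-V curve.

    windows_by_run may include None entries produced by whole-run estimators
    only through :func:`IVPoint` construction by the caller; duplicate
    (run, window-start) pairs are rejected.  Output is sorted by bias then
    window start, independent of input order.
    """
    points: list[IVPoint] = []
    for run_id, wins in windows_by_run.items():
        if run_id not in biases:
            raise ContractError(f"run {run_id!r} has no bias")
        seen: set[int | None] = set()
        for w in wins:
            key = w.q_ini if w is not None else None
            if key in seen:
                raise ContractError(
                    f"duplicate window starting at {key} e in run {run_id!r}"
                )
            seen.add(key)
            if w is None:
                continue
            points.append(IVPoint(bias=float(biases[run_id]), I_bar=w.I_bar,
                                  delta_I=w.delta_I, window=w, run_id=run_id))
    points.sort(key=lambda p: (p.bias, p.window.q_ini if p.window else -1))
    return points


def reference_current(bias_mv: float,
                      spec: IVReferenceSpec = IVReferenceSpec()
                      ) -> ReferenceCurrent:
    """Ohmic reference I_ref = dV / R_ref in pA (mV / GOhm = pA), with the
    negative-branch rectification factor, and the I_ref/10 comparison line."""
    i = bias_mv / spec.R_ref
    if bias_mv < 0:
        i *= spec.rectification_neg
    return ReferenceCurrent(i_ref=i, comparison=i / 10.0)


def neutralize_ion_counts(nominal_pairs: int, protein_charge: int
                          ) -> tuple[int, int]:
    """Asymmetric cation/anion split neutralizing an embedded protein charge.

    Starting from nominal_pairs of each species, returns (n_cations,
    n_anions) with n_anions - n_cations = protein_charge, removing
    ceil(|q|/2) from one side and adding floor(|q|/2) to the other so the
    total ion count changes by at most one.
    """
    q = int(protein_charge)
    if nominal_pairs < abs(q):
        raise ContractError(
            f"cannot neutralize charge {q} with only {nominal_pairs} pairs"
        )
    if q >= 0:
        n_cat = nominal_pairs - math.ceil(q / 2)
        n_an = nominal_pairs + math.floor(q / 2)
    else:
        n_cat = nominal_pairs + math.ceil(-q / 2)
        n_an = nominal_pairs - math.floor(-q / 2)
    if min(n_cat, n_an) < 0:
        raise ContractError("neutralization yields a negative ion count")
    return n_cat, n_an
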