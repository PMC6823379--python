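"""Charge-density profiles along z and the electrostatic potential.

The system is decomposed into n_slices bins along z (the membrane normal);
each particle's charge accrues to the bin containing its wrapped z, the
histogram is normalized by the per-frame bin volume L_x*L_y*dz and averaged
over frames, per species.  For a system that is theoretically symmetric
about the bilayer center, the profile can be symmetrized,
rho_sym(z) = (rho(z) + rho(2 z_c - z)) / 2, before integration.

The potential follows by double numerical integration of the 1-D Poisson
equation with composite trapezoid rule:

    psi(z) = -(1/eps0) * int_{z0}^{z} dz' int_{z0}^{z'} rho(z'') dz''

with psi(z0) = 0 and dpsi/dz(z0) = 0 at a configurable reference z0
(default: the lower grid edge, which leaves the potential flat in bulk
solution).  Only the vacuum permittivity enters: any relative dielectric
constant used as a force-field screening parameter at simulation time is a
property of the dynamics, not of this post-processing.  An applied uniform
field adds the component psi_ext(z) = -E_z (z - z0), and the corresponding
transmembrane bias is dV = E_z * L_z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ContractError
from .model import BoxGeometry, FieldSpec, Trajectory
from .units import EPS0_E_PER_V_NM

__all__ = [
    "ChargeDensityProfile",
    "PotentialProfile",
    "charge_density_profile",
    "symmetrize_profile",
    "potential_from_density",
    "add_external_field",
    "potential_bias",
]


@dataclass
class ChargeDensityProfile:
    """Per-species charge density on a uniform z grid, in e/nm^3.

    bin_edges has n_slices + 1 entries; area (nm^2) is the cross section the
    densities were normalized with, kept so net charge can be recovered.
    """

    bin_edges: np.ndarray
    rho_by_species: dict[str, np.ndarray]
    area: float = 1.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        n = self.bin_edges.size - 1
        if n < 2:
            raise ContractError("need at least 2 slices")
        for name, r in self.rho_by_species.items():
            r = np.asarray(r, dtype=float)
            if r.shape != (n,):
                raise ContractError(
                    f"species {name}: profile length {r.shape} != n_slices {n}"
                )
            self.rho_by_species[name] = r

    @property
    def n_slices(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ContractError("grid is not uniform")
        return float(widths[0])

    @property
    def rho_total(self) -> np.ndarray:
        return np.sum(list(self.rho_by_species.values()), axis=0)

    def net_charge(self) -> float:
        """Total system charge in e: sum over bins of rho * bin volume."""
        return float(np.sum(self.rho_total * np.diff(self.bin_edges)) * self.area)


@dataclass
class PotentialProfile:
    """Electrostatic potential psi(z) in V and its per-source decomposition.

    psi equals the bin-wise sum of components; psi(reference_z) = 0.
    """

    z_grid: np.ndarray
    components: dict[str, np.ndarray]
    reference_z: float

    @property
    def psi(self) -> np.ndarray:
        return np.sum(list(self.components.values()), axis=0)


def charge_density_profile(traj: Trajectory, frame_range: slice | None = None,
                           n_slices: int = 100) -> ChargeDensityProfile:
    """Frame-averaged per-species charge density along z.

    Binning is by fractional z (z / L_z of that frame), so frames with
    different boxes contribute to matching slices; each frame is normalized
    by its own bin volume.  The returned edges use the mean box.
    """
    if n_slices < 2:
        raise ContractError("n_slices must be >= 2")
    frames = traj.frames[frame_range] if frame_range is not None else traj.frames
    if not frames:
        raise ContractError("empty frame selection")
    charges = {s.name: float(s.charge) for s in traj.species}
    acc = {name: np.zeros(n_slices) for name in charges}
    mean_lz = 0.0
    mean_area = 0.0
    for f in frames:
        lz = f.box.L_z
        dz = lz / n_slices
        vol = f.box.area * dz
        frac = np.clip(f.z / lz, 0.0, np.nextafter(1.0, 0.0))
        bins = (frac * n_slices).astype(np.intp)
        for k, sp in enumerate(traj.species):
            m = f.species_index == k
            if sp.charge == 0 or not m.any():
                continue
            counts = np.bincount(bins[m], minlength=n_slices)
            acc[sp.name] += sp.charge * counts / vol
        mean_lz += lz
        mean_area += f.box.area
    n_f = len(frames)
    mean_lz /= n_f
    mean_area /= n_f
    edges = np.linspace(0.0, mean_lz, n_slices + 1)
    rho = {name: a / n_f for name, a in acc.items()}
    return ChargeDensityProfile(bin_edges=edges, rho_by_species=rho,
                                area=mean_area)


def symmetrize_profile(profile: ChargeDensityProfile,
                       z_center: float | None = None) -> ChargeDensityProfile:
    """Average each species profile with its mirror image about z_center.

    Defaults to the grid midpoint.  If the grid is symmetric about z_center
    the mirror is an exact bin reversal; otherwise mirrored values are
    obtained by linear interpolation (re-gridding onto the same bins).
    Idempotent; even profiles are fixed points and odd ones cancel to zero.
    """
    z = profile.bin_centers
    if z_center is None:
        z_center = 0.5 * (profile.bin_edges[0] + profile.bin_edges[-1])
    mirrored_grid = 2.0 * z_center - z
    exact = np.allclose(mirrored_grid, z[::-1], rtol=0, atol=1e-9)
    out = {}
    for name, r in profile.rho_by_species.items():
        if exact:
            mirror = r[::-1]
        else:
            mirror = np.interp(mirrored_grid, z, r)
        out[name] = 0.5 * (r + mirror)
    return ChargeDensityProfile(bin_edges=profile.bin_edges.copy(),
                                rho_by_species=out, area=profile.area)


def potential_from_density(profile: ChargeDensityProfile,
                           reference_z: float | None = None
                           ) -> PotentialProfile:
    """Double trapezoid integration of each species density, then sum.

    psi and dpsi/dz vanish at the grid point nearest reference_z (default:
    the lower edge of the grid).  Requires a uniform grid.  Linear in the
    density, so the per-species components sum exactly to the total.
    """
    profile.bin_width  # raises on non-uniform grids
    z = profile.bin_centers
    if reference_z is None:
        reference_z = float(profile.bin_edges[0])
    i0 = int(np.argmin(np.abs(z - reference_z)))
    comps: dict[str, np.ndarray] = {}
    for name, rho in profile.rho_by_species.items():
        e1 = cumulative_trapezoid(rho, z, initial=0.0)
        e1 = e1 - e1[i0]
        s = cumulative_trapezoid(e1, z, initial=0.0)
        psi = -(s - s[i0]) / EPS0_E_PER_V_NM
        comps[name] = psi
    return PotentialProfile(z_grid=z, components=comps,
                            reference_z=float(z[i0]))


def add_external_field(potential: PotentialProfile, field: FieldSpec,
                       z_ref: float | None = None) -> PotentialProfile:
    """Superpose the applied-field component psi_ext(z) = -E_z (z - z_ref).

    Accumulates into the 'external' component, so adding a field and then
    its negative restores the original values exactly.
    """
    if z_ref is None:
        z_ref = potential.reference_z
    ext = -field.E_z * (potential.z_grid - z_ref)
    comps = {k: v.copy() for k, v in potential.components.items()}
    comps["external"] = comps.get("external", 0.0) + ext
    return PotentialProfile(z_grid=potential.z_grid.copy(), components=comps,
                            reference_z=potential.reference_z)


def potential_bias(field: FieldSpec, box: BoxGeometry) -> float:
    """Transmembrane bias dV = E_z * L_z, in mV."""
    return field.E_z * box.L_z * 1e3
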