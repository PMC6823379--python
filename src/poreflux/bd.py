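"""Brownian-dynamics trajectory generator and analytic electrostatics fixtures.

The generator produces trajectories with the statistical structure the
analysis layer assumes: an ideal (non-interacting) electrolyte of charged
point particles drifting and diffusing in a periodic box under a uniform
field along z, optionally blocked by a reflecting membrane slab pierced by a
cylindrical pore.

Dynamics are overdamped (position Langevin): per step

    dz = mu * q * E * dt + sqrt(2 D dt) * xi,     mu = D / (k_B T)

with x and y purely diffusive.  The Einstein relation mu = D/(k_B T) is
hard-wired, which makes the Nernst-Einstein conductivity an *exact* oracle
for this generator rather than an approximation.  Ion-ion interactions,
explicit solvent and box fluctuations are deliberately absent: the analysis
layer, not electrolyte physics, is what the generator exercises.

For bulk (membrane-free) runs the update is integrated exactly over each
sampling interval: the sum of Euler-Maruyama steps with constant drift is
Gaussian with mean mu*q*E*dt_sample and variance 2*D*dt_sample, so drawing
the aggregated increment reproduces the per-step chain's law exactly.  Pore
runs step explicitly because reflections depend on position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, ContractError
from .model import BoxGeometry, FieldSpec, Frame, IonSpecies, Trajectory
from .units import EPS0_E_PER_V_NM, thermal_energy_ev

__all__ = [
    "MembraneModel",
    "BDConfig",
    "DensityFixture",
    "simulate_bulk",
    "simulate_pore",
    "make_density_fixture",
]


@dataclass(frozen=True)
class MembraneModel:
    """Reflecting slab normal to z, pierced by a cylindrical pore.

    Emulates a lipid bilayer carrying a single channel: the slab occupies
    |z - z_center| < half_thickness; the pore is the cylinder of radius
    pore_radius around pore_axis_xy (default: box center, resolved by the
    simulator).  pore_radius = 0 seals the membrane.
    """

    z_center: float
    half_thickness: float
    pore_radius: float = 0.0
    pore_axis_xy: tuple[float, float] | None = None

    def __post_init__(self):
        if self.half_thickness <= 0:
            raise ContractError("half_thickness must be > 0")
        if self.pore_radius < 0:
            raise ContractError("pore_radius must be >= 0")


@dataclass(frozen=True)
class BDConfig:
    """Full parameterization of one generator run; the seed fixes the output.

    Defaults mirror the emulated protocol: T = 320 K and diffusion constants
    D+ = 2.54, D- = 2.45 nm^2/ns carried by the species list; sampling every
    500 ps for bulk conductivity runs and every 100 ps for pore runs is
    obtained through timestep * sample_every.
    """

    species: tuple[IonSpecies, ...]
    box: BoxGeometry
    field: FieldSpec = field(default_factory=FieldSpec)
    temperature: float = 320.0
    timestep: float = 0.01          # ns
    n_steps: int = 1000
    sample_every: int = 10          # steps between stored frames
    seed: int = 0
    membrane: MembraneModel | None = None

    def __post_init__(self):
        if not self.species:
            raise ConfigurationError("at least one species is required")
        for sp in self.species:
            if not sp.diffusion_const:
                raise ConfigurationError(
                    f"species {sp.name} needs a positive diffusion constant"
                )
            if sp.count <= 0:
                raise ConfigurationError(
                    f"species {sp.name} needs a positive particle count"
                )
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be > 0")
        if self.n_steps < self.sample_every or self.sample_every < 1:
            raise ConfigurationError("need n_steps >= sample_every >= 1")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        m = self.membrane
        if m is not None:
            lo, hi = m.z_center - m.half_thickness, m.z_center + m.half_thickness
            if lo <= 0 or hi >= self.box.L_z:
                raise ConfigurationError("membrane slab must lie inside the box")
            if m.pore_radius > min(self.box.L_x, self.box.L_y) / 2:
                raise ConfigurationError(
                    "pore_radius exceeds half the smallest lateral box length"
                )
        # stability: per-step drift must stay well below the geometric scales
        # the analysis resolves (100-slice bin width along z; pore radius and
        # slab half-thickness when a membrane is present)
        scales = [self.box.L_z / 100.0]
        if m is not None:
            scales.append(m.half_thickness)
            if m.pore_radius > 0:
                scales.append(m.pore_radius)
        kt = thermal_energy_ev(self.temperature)
        drift = max(
            abs(sp.charge) * sp.diffusion_const * abs(self.field.E_z)
            * self.timestep / kt
            for sp in self.species
        )
        limit = 0.25 * min(scales)
        if drift >= limit:
            raise ConfigurationError(
                f"per-step drift {drift:.4g} nm exceeds 0.25x the smallest "
                f"resolved length ({limit:.4g} nm); reduce the timestep"
            )

    @property
    def n_particles(self) -> int:
        return sum(sp.count for sp in self.species)

    def particle_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(species_index, charge, D) per particle, species-blocked."""
        sidx = np.concatenate([
            np.full(sp.count, k, dtype=np.intp)
            for k, sp in enumerate(self.species)
        ])
        q = np.concatenate([
            np.full(sp.count, float(sp.charge)) for sp in self.species
        ])
        d = np.concatenate([
            np.full(sp.count, float(sp.diffusion_const)) for sp in self.species
        ])
        return sidx, q, d


def _init_positions(config: BDConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions in the fluid region (outside the membrane wall)."""
    L = config.box.lengths
    n = config.n_particles
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * L
    m = config.membrane
    if m is None:
        return pos
    ax = m.pore_axis_xy or (config.box.L_x / 2, config.box.L_y / 2)
    for _ in range(200):
        bad = _in_wall(pos, m, ax)
        if not bad.any():
            break
        pos[bad] = rng.uniform(0.0, 1.0, size=(int(bad.sum()), 3)) * L
    return pos


def _in_wall(pos: np.ndarray, m: MembraneModel,
             axis: tuple[float, float]) -> np.ndarray:
    in_slab = np.abs(pos[:, 2] - m.z_center) < m.half_thickness
    r2 = (pos[:, 0] - axis[0]) ** 2 + (pos[:, 1] - axis[1]) ** 2
    return in_slab & (r2 >= m.pore_radius ** 2)


def simulate_bulk(config: BDConfig) -> Trajectory:
    """Drift-diffusion run in a fully periodic box (no membrane).

    Frames are stored every sample_every steps starting at t = dt_sample;
    each frame's velocity is the particle's unwrapped displacement over the
    preceding sampling interval divided by that interval, emulating how an
    MD engine reports sampled velocities.
    """
    if config.membrane is not None:
        raise ConfigurationError("simulate_bulk: config must not have a membrane")
    rng = np.random.default_rng(config.seed)
    sidx, q, d = config.particle_arrays()
    kt = thermal_energy_ev(config.temperature)
    L = config.box.lengths
    dt_s = config.timestep * config.sample_every
    n_frames = config.n_steps // config.sample_every
    drift_z = q * d * config.field.E_z / kt  # nm/ns

    pos = _init_positions(config, rng)
    frames = []
    sigma = np.sqrt(2.0 * d * dt_s)
    for k in range(1, n_frames + 1):
        disp = rng.standard_normal((config.n_particles, 3)) * sigma[:, None]
        disp[:, 2] += drift_z * dt_s
        pos = pos + disp
        frames.append(Frame(
            time=k * dt_s, box=config.box, species_index=sidx,
            position=pos % L, velocity=disp / dt_s,
        ))
        pos %= L
    return Trajectory(config.species, frames)


def simulate_pore(config: BDConfig) -> Trajectory:
    """Drift-diffusion run with a reflecting membrane slab and cylindrical pore.

    Explicit Euler-Maruyama steps; any proposed move ending inside the slab
    but outside the pore cylinder is reflected specularly in z about the slab
    face on the side the particle came from.  A particle already inside the
    pore that would exit the cylinder laterally into the wall has its x, y
    move rejected instead (z proceeds).  Unresolvable proposals (never seen
    at stable timesteps) fall back to rejecting the whole move, so the
    particle count is conserved unconditionally.
    """
    m = config.membrane
    if m is None:
        raise ConfigurationError("simulate_pore: config needs a membrane")
    rng = np.random.default_rng(config.seed)
    sidx, q, d = config.particle_arrays()
    kt = thermal_energy_ev(config.temperature)
    L = config.box.lengths
    n = config.n_particles
    dt = config.timestep
    dt_s = dt * config.sample_every
    n_frames = config.n_steps // config.sample_every
    drift_z = q * d * config.field.E_z / kt * dt
    sigma = np.sqrt(2.0 * d * dt)
    axis = m.pore_axis_xy or (config.box.L_x / 2, config.box.L_y / 2)
    z_lo, z_hi = m.z_center - m.half_thickness, m.z_center + m.half_thickness

    pos = _init_positions(config, rng)
    frames = []
    for k in range(1, n_frames + 1):
        start = pos.copy()
        for _ in range(config.sample_every):
            old = pos
            prop = old + rng.standard_normal((n, 3)) * sigma[:, None]
            prop[:, 2] += drift_z
            prop_w = prop % L
            new = prop_w.copy()
            # came-from side decides the reflecting face; particles whose old
            # z lies inside the slab band were in the pore interior
            from_above = old[:, 2] >= z_hi
            from_below = old[:, 2] <= z_lo
            for _it in range(8):
                bad = _in_wall(new, m, axis)
                if not bad.any():
                    break
                refl = bad & (from_above | from_below)
                face = np.where(from_above, z_hi, z_lo)
                new[refl, 2] = 2.0 * face[refl] - new[refl, 2]
                lateral = bad & ~(from_above | from_below)
                new[lateral, 0] = old[lateral, 0]
                new[lateral, 1] = old[lateral, 1]
                new %= L
            bad = _in_wall(new, m, axis)
            if bad.any():
                new[bad] = old[bad]
            pos = new
        # net displacement over the sampling interval, unwrapped step-free:
        # reflections keep |true displacement| << L/2, so minimum image holds
        delta = pos - start
        delta -= L * np.round(delta / L)
        frames.append(Frame(
            time=k * dt_s, box=config.box, species_index=sidx,
            position=pos, velocity=delta / dt_s,
        ))
    return Trajectory(config.species, frames)


# ---------------------------------------------------------------------------
# analytic density fixtures


@dataclass(frozen=True)
class DensityFixture:
    """A 1-D charge density with its exact electrostatic potential.

    grid holds bin centers (nm), rho the charge density (e/nm^3) sampled
    there, and closed_form_potential the analytic solution of the 1-D
    Poisson equation for rho with psi and dpsi/dz zero at grid[0] -- the same
    reference convention the numerical double integration uses.  The callable
    is verified against rho by a finite-difference Poisson check at
    construction (via :func:`make_density_fixture`).
    """

    grid: np.ndarray
    rho: np.ndarray
    closed_form_potential: Callable[[np.ndarray], np.ndarray]

    @property
    def bin_edges(self) -> np.ndarray:
        dz = self.grid[1] - self.grid[0]
        return np.concatenate([self.grid - dz / 2, [self.grid[-1] + dz / 2]])


def _slab_double_integral(z: np.ndarray, z_left: float, z_right: float,
                          rho0: float) -> np.ndarray:
    """Second antiderivative of a uniform slab density, zero (with zero slope)
    left of the slab."""
    z = np.asarray(z, dtype=float)
    w = z_right - z_left
    inside = np.clip(z, z_left, z_right) - z_left
    out = 0.5 * rho0 * inside ** 2
    out = out + rho0 * w * np.clip(z - z_right, 0.0, None)
    return out


def _gauss_double_integral(z: np.ndarray, mu: float, s: float,
                           q_area: float) -> np.ndarray:
    """Second antiderivative of a Gaussian sheet of areal charge q_area."""
    u = (np.asarray(z, dtype=float) - mu) / s
    return q_area * s * (u * norm.cdf(u) + norm.pdf(u))


def make_density_fixture(kind: str, **params) -> DensityFixture:
    """Build an analytic test density.

    kind 'null'            -> rho = 0, potential = 0
    kind 'capacitor'       -> two opposite uniform slabs (params: sigma e/nm^2,
                              separation nm, width nm) giving a potential ramp
                              of total drop sigma*separation/eps0 between them
    kind 'gaussian_dipole' -> two opposite Gaussian sheets (params: sigma,
                              separation, s) with an erf-based closed form

    Common params: z_lo, z_hi, n control the grid (defaults -8..8 nm, 401).
    """
    z_lo = params.pop("z_lo", -8.0)
    z_hi = params.pop("z_hi", 8.0)
    n = params.pop("n", 401)
    grid = np.linspace(z_lo, z_hi, n)

    if kind == "null":
        rho = np.zeros_like(grid)

        def psi(z):
            return np.zeros_like(np.asarray(z, dtype=float))

    elif kind == "capacitor":
        sigma = params.pop("sigma", 0.05)       # e/nm^2 per sheet
        sep = params.pop("separation", 4.0)     # center-to-center, nm
        width = params.pop("width", 0.5)        # slab thickness, nm
        rho0 = sigma / width
        c1, c2 = -sep / 2, +sep / 2             # +slab left, -slab right

        def sample_slab(center, height):
            # midpoint-of-jump sampling: grid points landing exactly on a
            # slab edge take half height, keeping the trapezoid integral of
            # the sampled density exact on aligned grids
            d = np.abs(grid - center) - width / 2
            return height * np.where(
                np.isclose(d, 0.0, atol=1e-12), 0.5, (d < 0).astype(float))

        rho = sample_slab(c1, rho0) + sample_slab(c2, -rho0)

        def psi(z):
            s = (_slab_double_integral(z, c1 - width / 2, c1 + width / 2, rho0)
                 + _slab_double_integral(z, c2 - width / 2, c2 + width / 2,
                                         -rho0))
            return -s / EPS0_E_PER_V_NM

    elif kind == "gaussian_dipole":
        sigma = params.pop("sigma", 0.05)       # e/nm^2 per sheet
        sep = params.pop("separation", 4.0)
        s_w = params.pop("s", 0.6)              # Gaussian width, nm
        c1, c2 = -sep / 2, +sep / 2
        rho = sigma * (norm.pdf(grid, c1, s_w) - norm.pdf(grid, c2, s_w))

        def psi(z):
            s = (_gauss_double_integral(z, c1, s_w, sigma)
                 + _gauss_double_integral(z, c2, s_w, -sigma))
            s0 = (_gauss_double_integral(grid[0], c1, s_w, sigma)
                  + _gauss_double_integral(grid[0], c2, s_w, -sigma))
            # subtract value and slope at the reference (both ~0 for far tails)
            slope0 = (sigma * (norm.cdf((grid[0] - c1) / s_w)
                               - norm.cdf((grid[0] - c2) / s_w)))
            z = np.asarray(z, dtype=float)
            return -(s - s0 - slope0 * (z - grid[0])) / EPS0_E_PER_V_NM

    else:
        raise ContractError(f"unknown fixture kind {kind!r}")
    if params:
        raise ContractError(f"unknown fixture parameters {sorted(params)}")

    fixture = DensityFixture(grid=grid, rho=rho, closed_form_potential=psi)
    _check_poisson(fixture)
    return fixture


def _check_poisson(fx: DensityFixture) -> None:
    """Numerically verify d(psi)/dz = -(1/eps0) * cumulative integral of rho.

    The first-derivative form is used because it is continuous even for
    piecewise-constant densities (where the second derivative jumps).
    """
    from scipy.integrate import cumulative_trapezoid

    z = fx.grid
    h = (z[1] - z[0]) * 0.5
    dpsi = (fx.closed_form_potential(z + h)
            - fx.closed_form_potential(z - h)) / (2 * h)
    e1 = cumulative_trapezoid(fx.rho, z, initial=0.0)
    resid = dpsi + e1 / EPS0_E_PER_V_NM
    scale = max(np.max(np.abs(e1)) / EPS0_E_PER_V_NM, 1e-12)
    if np.max(np.abs(resid - resid[0])) > 0.05 * scale:
        raise ConfigurationError(
            "fixture closed-form potential fails the Poisson consistency check"
        )
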