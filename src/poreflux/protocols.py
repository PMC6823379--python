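"""Frozen study conditions for the package's validation experiments.

These are the standard generator configurations the test-suite, the
acceptance script and the examples all share, so every consumer measures
the same system:

* bulk validation -- symmetric KCl-like electrolyte at T = 320 K with the
  measured coarse-grained diffusion constants D+ = 2.54, D- = 2.45 nm^2/ns,
  500 ions per species plus a neutral tracer species, sampled every 500 ps;
* pore runs -- a 8 x 8 x 16 nm box holding a 4 nm reflecting slab across
  the box middle pierced by a 1.3 nm-radius cylindrical pore (an
  alpha-hemolysin-like lumen), 300 ions per species (~0.5 M), sampled every
  100 ps, with the crossing plane at the trans face of the slab.

Run lengths and timesteps are scaled for desk-scale turnaround; the
timestep per field strength respects the generator's drift-stability bound.
"""

from __future__ import annotations

import numpy as np

from .bd import BDConfig, MembraneModel, simulate_pore
from .crossings import CurrentTrace, cumulative_charge, detect_crossings
from .electrostatics import potential_bias
from .model import BoxGeometry, FieldSpec, IonSpecies, Trajectory

__all__ = [
    "D_PLUS", "D_MINUS", "TEMPERATURE",
    "bulk_validation_config", "pore_config", "run_iv_point",
    "LINEAR_IV_PROTOCOL", "SATURATION_IV_PROTOCOL",
    "PORE_BOX", "PORE_MEMBRANE", "PLANE_Z", "derive_seeds",
]

#: coarse-grained cation/anion diffusion constants, nm^2/ns
D_PLUS, D_MINUS = 2.54, 2.45
#: simulation temperature, K
TEMPERATURE = 320.0

#: pore-system geometry (nm)
PORE_BOX = BoxGeometry(8.0, 8.0, 16.0)
PORE_MEMBRANE = MembraneModel(z_center=8.0, half_thickness=2.0,
                              pore_radius=1.3)
#: crossing-detection plane: the trans face of the slab
PLANE_Z = PORE_MEMBRANE.z_center - PORE_MEMBRANE.half_thickness

#: linear-response I-V protocol: field (V/nm) -> (run time ns, timestep ns).
#: Biases span 32-80 mV: without electrolyte screening the generator's
#: upstream ion accumulation grows with the drift speed, so its linear
#: regime is narrower than a real electrolyte's.  Run lengths scale roughly
#: inversely with the field so every bias yields a comparable number of
#: 40-crossing windows.
LINEAR_IV_PROTOCOL: dict[float, tuple[float, float]] = {
    0.002: (600.0, 0.02),
    0.003: (450.0, 0.02),
    0.004: (400.0, 0.02),
    0.005: (330.0, 0.02),
}

#: drift-dominated protocol probing the limiting current
SATURATION_IV_PROTOCOL: dict[float, tuple[float, float]] = {
    0.04: (40.0, 0.005),
    0.08: (25.0, 0.0025),
    0.12: (20.0, 0.0018),
}


def derive_seeds(base: int, n: int) -> list[int]:
    """n independent child seeds (< 2^31) from one base seed."""
    return [int(s) for s in
            np.random.SeedSequence(base).generate_state(n) % (2 ** 31)]


def bulk_validation_config(seed: int, n_ions: int = 500,
                           n_tracers: int = 100, field_e: float = 0.02,
                           n_frames: int = 2500) -> BDConfig:
    """Bulk electrolyte run for the conductivity/diffusion recovery checks.

    Box sized for ~0.6 M (ions per volume); 500 ps sampling; the neutral
    'W' tracer species supports the mean-squared-displacement check under
    the applied field.
    """
    molarity_nm3 = 0.6 * 0.602214076           # ions per nm^3
    L = (n_ions / molarity_nm3) ** (1.0 / 3.0)
    species = (
        IonSpecies("K+", +1, D_PLUS, n_ions),
        IonSpecies("CL-", -1, D_MINUS, n_ions),
        IonSpecies("W", 0, 2.50, n_tracers),
    )
    sample_every = 40
    return BDConfig(
        species=species, box=BoxGeometry(L, L, L), field=FieldSpec(field_e),
        temperature=TEMPERATURE, timestep=0.5 / sample_every,
        n_steps=n_frames * sample_every, sample_every=sample_every, seed=seed,
    )


def pore_config(field_e: float, run_time: float, timestep: float, seed: int,
                n_ions: int = 300,
                membrane: MembraneModel = PORE_MEMBRANE) -> BDConfig:
    """Membrane + pore run under a field, sampled every 100 ps."""
    species = (
        IonSpecies("K+", +1, D_PLUS, n_ions),
        IonSpecies("CL-", -1, D_MINUS, n_ions),
    )
    sample_every = max(1, round(0.1 / timestep))
    return BDConfig(
        species=species, box=PORE_BOX, field=FieldSpec(field_e),
        temperature=TEMPERATURE, timestep=timestep,
        n_steps=round(run_time / timestep), sample_every=sample_every,
        seed=seed, membrane=membrane,
    )


def run_iv_point(field_e: float, run_time: float, timestep: float, seed: int
                 ) -> tuple[float, CurrentTrace, Trajectory]:
    """One I-V point: simulate, detect crossings, accumulate Q(t).

    Returns (bias in mV, crossing trace, trajectory).
    """
    cfg = pore_config(field_e, run_time, timestep, seed)
    traj = simulate_pore(cfg)
    records = detect_crossings(traj, PLANE_Z)
    trace = cumulative_charge(records, traj.times, traj.species_charges())
    return potential_bias(cfg.field, cfg.box), trace, traj
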