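"""File formats: GRO coordinates, plain-text frame tables, optional XTC/TRR.

The frame-table format is the package's interchange format for trajectories:
tab-separated text, one row per particle per frame, mandatory header::

    frame_time_ns  particle_id  species  charge_e  x  y  z  vx  vy  vz  box_x  box_y  box_z

Lengths in nm, times in ns, velocities in nm/ns, charge in e.  Velocity
columns may be empty when the source carries no velocities.  The per-row box
columns let the box vary frame-to-frame (NPT-style trajectories).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapabilityError, OrderingError, ParseError, StructureError
from .model import BoxGeometry, Frame, IonSpecies, Trajectory

__all__ = [
    "read_gro",
    "write_gro",
    "read_frames",
    "write_frames",
    "read_mdanalysis",
    "infer_charge",
]

FRAME_TABLE_COLUMNS = [
    "frame_time_ns", "particle_id", "species", "charge_e",
    "x", "y", "z", "vx", "vy", "vz", "box_x", "box_y", "box_z",
]


def infer_charge(name: str) -> int:
    """Guess an ion charge from a trailing +/- in its (residue) name.

    'NA+'/'K+' -> +1, 'CL-' -> -1, anything else -> 0.  Used only when no
    explicit species mapping is supplied.
    """
    s = name.strip()
    n_plus = len(s) - len(s.rstrip("+"))
    n_minus = len(s) - len(s.rstrip("-"))
    return n_plus - n_minus


# ---------------------------------------------------------------------------
# GRO


def read_gro(
    path, species_map: Mapping[str, IonSpecies] | None = None
) -> tuple[tuple[IonSpecies, ...], Frame]:
    """Read a fixed-column GRO file into a species table and a single frame.

    species_map maps residue names to IonSpecies templates (charge, diffusion
    constant); unmapped residues get charge inferred from a trailing +/- and
    no diffusion constant.  Velocities are read when present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("GRO file needs title, atom count and box lines", path)
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise ParseError("atom-count line is not an integer", path, line=2)
    if len(lines) < n_atoms + 3:
        raise StructureError(
            f"{path}: header declares {n_atoms} atoms but only "
            f"{len(lines) - 3} atom records are present"
        )
    resnames: list[str] = []
    pos = np.empty((n_atoms, 3))
    vel = np.empty((n_atoms, 3))
    have_vel = True
    for i in range(n_atoms):
        ln = lines[2 + i]
        lineno = 3 + i
        if len(ln) < 44:
            raise ParseError("atom record shorter than 44 columns", path, lineno)
        resnames.append(ln[5:10].strip())
        try:
            pos[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except ValueError:
            raise ParseError("malformed coordinate columns", path, lineno)
        if len(ln) >= 68:
            try:
                vel[i] = [float(ln[44:52]), float(ln[52:60]), float(ln[60:68])]
            except ValueError:
                raise ParseError("malformed velocity columns", path, lineno)
        else:
            have_vel = False
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise ParseError("box line needs at least three lengths", path,
                         line=3 + n_atoms)
    box = BoxGeometry(*(float(v) for v in box_fields[:3]))

    names = list(dict.fromkeys(resnames))
    species = []
    for nm in names:
        count = resnames.count(nm)
        if species_map and nm in species_map:
            t = species_map[nm]
            species.append(IonSpecies(t.name, t.charge, t.diffusion_const, count))
        else:
            species.append(IonSpecies(nm, infer_charge(nm), None, count))
    name_of = {nm: (species_map[nm].name if species_map and nm in species_map
                    else nm) for nm in names}
    index_of = {sp.name: k for k, sp in enumerate(species)}
    sidx = np.array([index_of[name_of[nm]] for nm in resnames], dtype=np.intp)
    frame = Frame(
        time=0.0, box=box, species_index=sidx, position=pos,
        velocity=vel if have_vel else None,
    )
    return tuple(species), frame


def write_gro(path, frame: Frame, species: Sequence[IonSpecies],
              title: str = "poreflux frame") -> None:
    """Write one frame in GRO format (positions to 3, velocities to 4 decimals)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{title}\n{frame.n:5d}\n")
        for i in range(frame.n):
            sp = species[frame.species_index[i]]
            resname = sp.name[:5]
            x, y, z = frame.position[i]
            rec = (f"{(i % 99999) + 1:5d}{resname:<5s}{resname:>5s}"
                   f"{(i % 99999) + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
            if frame.velocity is not None:
                vx, vy, vz = frame.velocity[i]
                rec += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(rec + "\n")
        fh.write(f"{frame.box.L_x:10.5f}{frame.box.L_y:10.5f}{frame.box.L_z:10.5f}\n")


# ---------------------------------------------------------------------------
# frame table


def write_frames(path, traj: Trajectory) -> None:
    """Write a trajectory as a frame table (tab-separated text)."""
    rows = []
    for f in traj.frames:
        names = np.array(traj.species_names)[f.species_index]
        charges = traj.charges(f).astype(int)
        block = pd.DataFrame({
            "frame_time_ns": f.time,
            "particle_id": np.arange(f.n),
            "species": names,
            "charge_e": charges,
            "x": f.position[:, 0], "y": f.position[:, 1], "z": f.position[:, 2],
            "vx": f.velocity[:, 0] if f.velocity is not None else np.nan,
            "vy": f.velocity[:, 1] if f.velocity is not None else np.nan,
            "vz": f.velocity[:, 2] if f.velocity is not None else np.nan,
            "box_x": f.box.L_x, "box_y": f.box.L_y, "box_z": f.box.L_z,
        })
        rows.append(block)
    table = pd.concat(rows, ignore_index=True)[FRAME_TABLE_COLUMNS]
    # shortest-repr floats + round_trip parsing in read_frames make the
    # write/read cycle bitwise exact
    table.to_csv(path, sep="\t", index=False)


def _traj_from_table(table: pd.DataFrame,
                     species_map: Mapping[str, IonSpecies] | None) -> Trajectory:
    missing = [c for c in FRAME_TABLE_COLUMNS[:7] if c not in table.columns]
    if missing:
        raise ParseError(f"frame table lacks required columns {missing}")
    have_vel = all(c in table.columns for c in ("vx", "vy", "vz")) and \
        not table[["vx", "vy", "vz"]].isna().any().any()

    # species table from (name, charge) pairs, optionally enriched with D
    pairs = table[["species", "charge_e"]].drop_duplicates()
    species: list[IonSpecies] = []
    for nm, q in pairs.itertuples(index=False):
        d = None
        if species_map and nm in species_map:
            d = species_map[nm].diffusion_const
        count = int(((table["species"] == nm) &
                     (table["frame_time_ns"] == table["frame_time_ns"].iloc[0])
                     ).sum())
        species.append(IonSpecies(str(nm), int(q), d, count))
    index_of = {sp.name: k for k, sp in enumerate(species)}

    frames: list[Frame] = []
    times = table["frame_time_ns"].to_numpy()
    # group in file order; times must come back strictly increasing
    boundaries = np.flatnonzero(np.diff(times) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [len(table)]])
    last_t = -np.inf
    for s, e in zip(starts, ends):
        block = table.iloc[s:e]
        t = float(block["frame_time_ns"].iloc[0])
        if t <= last_t:
            raise OrderingError(
                f"frame times not strictly increasing at t={t} ns"
            )
        last_t = t
        box = BoxGeometry(float(block["box_x"].iloc[0]),
                          float(block["box_y"].iloc[0]),
                          float(block["box_z"].iloc[0]))
        sidx = np.array([index_of[nm] for nm in block["species"]], dtype=np.intp)
        frames.append(Frame(
            time=t, box=box, species_index=sidx,
            position=block[["x", "y", "z"]].to_numpy(),
            velocity=block[["vx", "vy", "vz"]].to_numpy() if have_vel else None,
        ))
    return Trajectory(tuple(species), frames)


def read_frames(path, format: str = "auto",
                species_map: Mapping[str, IonSpecies] | None = None,
                topology=None) -> Trajectory:
    """Read a trajectory.

    format 'frame-table' (default for .tsv/.txt/.dat) reads the documented
    tabular text format; 'mdanalysis' dispatches to :func:`read_mdanalysis`
    (topology required).
    """
    if format == "auto":
        format = ("mdanalysis"
                  if str(path).endswith((".xtc", ".trr")) else "frame-table")
    if format == "frame-table":
        try:
            table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        except Exception as exc:  # pandas raises many parser types
            raise ParseError(f"cannot parse frame table: {exc}", path)
        return _traj_from_table(table, species_map)
    if format == "mdanalysis":
        if topology is None:
            raise CapabilityError("XTC/TRR reading needs a GRO topology path")
        return read_mdanalysis(topology, path, species_map)
    raise ParseError(f"unknown trajectory format {format!r}")


def read_mdanalysis(topology, trajectory,
                    species_map: Mapping[str, IonSpecies] | None = None
                    ) -> Trajectory:
    """Optional XTC/TRR adapter via MDAnalysis.

    Converts MDAnalysis native units (A, ps, A/ps) to nm, ns, nm/ns.  Species
    are assigned from residue names through species_map (or charge inference).
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - env without the extra
        raise CapabilityError(
            "MDAnalysis is required for XTC/TRR reading; "
            "install the 'traj' extra"
        ) from exc
    u = mda.Universe(str(topology), str(trajectory))
    resnames = [str(r) for r in u.atoms.resnames]
    names = list(dict.fromkeys(resnames))
    species = []
    for nm in names:
        count = resnames.count(nm)
        if species_map and nm in species_map:
            t = species_map[nm]
            species.append(IonSpecies(t.name, t.charge, t.diffusion_const, count))
        else:
            species.append(IonSpecies(nm, infer_charge(nm), None, count))
    index_of = {sp.name: k for k, sp in enumerate(species)}
    name_of = {nm: (species_map[nm].name if species_map and nm in species_map
                    else nm) for nm in names}
    sidx = np.array([index_of[name_of[nm]] for nm in resnames], dtype=np.intp)
    frames = []
    for ts in u.trajectory:
        box = BoxGeometry(*(ts.dimensions[:3] / 10.0))
        vel = None
        if ts.has_velocities:
            vel = u.atoms.velocities * 100.0  # A/ps -> nm/ns
        frames.append(Frame(
            time=ts.time / 1000.0, box=box, species_index=sidx,
            position=u.atoms.positions / 10.0, velocity=vel,
        ))
    return Trajectory(tuple(species), frames)
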