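"""Atomic structures, trajectories and scalar grids: the coordinate layer.

Coordinates are always in Angstrom.  Structures are read with gemmi (PDB,
mmCIF, or auto-detected); trajectories are multi-model PDB files sharing a
fixed topology.  Scalar fields (water-occupancy densities) are written as
OpenDX grids.

Alternate conformations are resolved at read time: for each atom name within
a residue the highest-occupancy altloc is kept, ties broken by altloc
identifier order, so downstream distance metrics always see a single
conformer.  Hydrogens are retained when present and flagged, but every
deposited-model metric in this package works heavy-atom-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueKey",
    "Structure",
    "Trajectory",
    "DensityGrid",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_density_grid",
    "read_density_grid",
    "is_water",
]

#: residue names recognised as water
WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


def is_water(residue_name: str) -> bool:
    return residue_name.upper() in WATER_NAMES


@dataclass(frozen=True)
class ResidueKey:
    """Identity of a residue: author chain id / sequence number / icode.

    Author numbering is preserved verbatim from the coordinate file; no
    renumbering is ever applied, so residue references like L386 mean the
    same thing here as in the deposition.
    """

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def same_site(self, other: "ResidueKey") -> bool:
        """True if chain/number/icode match (residue name ignored)."""
        return (
            self.chain_id == other.chain_id
            and self.seq_number == other.seq_number
            and self.insertion_code == other.insertion_code
        )

    def __str__(self) -> str:  # e.g. "R:LEU386"
        return f"{self.chain_id}:{self.residue_name}{self.seq_number}{self.insertion_code}"


@dataclass
class Atom:
    """One atom: name, element, coordinate (Angstrom) and hydrogen flag."""

    name: str
    element: str
    coord: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")


class Structure:
    """A hierarchical atomic model: ordered residues, each with >=1 atom.

    Atom order is the file order; `coords()` returns an (n_atoms, 3) array in
    that order, which is also the frame layout used by Trajectory.
    """

    def __init__(self, model_id: int = 1, metadata: dict | None = None):
        self.model_id = model_id
        self.metadata: dict = metadata or {}
        self._residues: dict[ResidueKey, list[Atom]] = {}

    # -- construction -----------------------------------------------------
    def add_atom(self, key: ResidueKey, atom: Atom) -> None:
        self._residues.setdefault(key, []).append(atom)

    # -- access ------------------------------------------------------------
    @property
    def residues(self) -> dict[ResidueKey, list[Atom]]:
        return self._residues

    def residue_keys(self) -> list[ResidueKey]:
        return list(self._residues.keys())

    def atoms(self) -> Iterator[tuple[ResidueKey, Atom]]:
        for key, atoms in self._residues.items():
            for atom in atoms:
                yield key, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(a) for a in self._residues.values())

    @property
    def n_residues(self) -> int:
        return len(self._residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, a in self.atoms()], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(f"expected shape {(self.n_atoms, 3)}, got {xyz.shape}")
        for i, (_, atom) in enumerate(self.atoms()):
            atom.coord = xyz[i].copy()

    def find_residue(
        self, chain_id: str, seq_number: int, insertion_code: str = ""
    ) -> tuple[ResidueKey, list[Atom]]:
        for key, atoms in self._residues.items():
            if (
                key.chain_id == chain_id
                and key.seq_number == seq_number
                and key.insertion_code == insertion_code
            ):
                return key, atoms
        raise KeyError(f"residue {chain_id}:{seq_number}{insertion_code} not found")

    def chain(self, chain_id: str) -> "Structure":
        """Sub-structure containing one chain (atoms shared, not copied)."""
        sub = Structure(self.model_id, dict(self.metadata))
        for key, atoms in self._residues.items():
            if key.chain_id == chain_id:
                sub._residues[key] = atoms
        return sub

    def copy(self) -> "Structure":
        new = Structure(self.model_id, dict(self.metadata))
        for key, atoms in self._residues.items():
            new._residues[key] = [
                Atom(a.name, a.element, a.coord.copy(), a.is_hydrogen) for a in atoms
            ]
        return new

    def water_oxygen_indices(self) -> np.ndarray:
        """Flat atom indices of water oxygens (the waters' density positions)."""
        idx = [
            i
            for i, (key, atom) in enumerate(self.atoms())
            if is_water(key.residue_name) and atom.element.upper() == "O"
        ]
        return np.array(idx, dtype=int)


@dataclass
class Trajectory:
    """Fixed-topology sequence of coordinate frames (Angstrom)."""

    topology: Structure
    frames: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for t, frame in enumerate(self.frames):
            frame = np.asarray(frame, dtype=float)
            if frame.shape != (n, 3):
                raise ValueError(
                    f"frame {t}: expected {n} atoms, got {frame.shape[0]}"
                )
            self.frames[t] = frame
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class DensityGrid:
    """Cubic lattice of local water-occupancy densities (waters per A^3).

    Each grid point holds the trajectory-averaged count of water oxygens
    within ``r`` of the point, divided by the sphere volume V_r = 4/3 pi r^3.
    A single water therefore contributes to every grid point within r of it
    (overlapping spheres): the field is a local density, not a partition, and
    does not sum to the water count.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # shape (nx, ny, nz)
    r: float = 1.0
    n_frames: int = 0
    n_waters: int = 0
    bulk_density: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 3-D array")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def point_coords(self) -> np.ndarray:
        """(n_points, 3) array of grid-point coordinates, x fastest-varying last."""
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ijk = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        return self.origin + ijk * self.spacing


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep, per atom name, the highest-occupancy altloc (ties: altloc order)."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if (
            prev is None
            or atom.occ > prev.occ
            or (atom.occ == prev.occ and (atom.altloc or "") < (prev.altloc or ""))
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def _convert_model(model: gemmi.Model, model_id: int) -> Structure:
    st = Structure(model_id=model_id)
    for chain in model:
        for residue in chain:
            key = ResidueKey(
                chain_id=chain.name,
                seq_number=residue.seqid.num,
                insertion_code=(residue.seqid.icode or "").strip(),
                residue_name=residue.name,
            )
            for atom in _resolve_altlocs(residue):
                el = atom.element.name if atom.element else "X"
                st.add_atom(
                    key,
                    Atom(
                        name=atom.name,
                        element=el,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_hydrogen=el.upper() in ("H", "D"),
                    ),
                )
    if st.n_atoms == 0:
        raise ValueError("model contains no atoms")
    return st


def _read_gemmi(path: str | Path, fmt: str) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            doc = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            doc = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if len(doc) == 0:
        raise ValueError(f"{path}: file contains no model")
    return doc


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read the first model of a PDB or mmCIF file into a Structure.

    Author residue numbering is preserved; altlocs are reduced to the
    highest-occupancy conformer per atom.
    """
    doc = _read_gemmi(path, format)
    return _convert_model(doc[0], model_id=1)


def read_trajectory(
    path: str | Path, topology: Structure | None = None, format: str = "multi-model-pdb"
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Every MODEL becomes one frame; the atom count of each frame must match
    the topology (the first model if no topology is given).
    """
    if format != "multi-model-pdb":
        raise ValueError(
            "only the multi-model PDB dialect is supported natively; convert "
            "binary formats through an adapter (see trajectory_from_arrays)"
        )
    doc = _read_gemmi(path, "pdb")
    models = [_convert_model(m, i + 1) for i, m in enumerate(doc)]
    if topology is None:
        topology = models[0]
    frames = []
    for t, model in enumerate(models):
        if model.n_atoms != topology.n_atoms:
            raise ValueError(
                f"frame {t}: atom count {model.n_atoms} does not match "
                f"topology ({topology.n_atoms})"
            )
        frames.append(model.coords())
    return Trajectory(topology=topology, frames=frames)


def trajectory_from_arrays(topology: Structure, frames: Sequence[np.ndarray]) -> Trajectory:
    """Adapter entry point: wrap externally produced coordinate frames.

    Binary trajectory readers (MDAnalysis, mdtraj, ...) can feed their
    per-frame coordinate arrays here; the core package stays format-free.
    """
    return Trajectory(topology=topology, frames=[np.asarray(f, float) for f in frames])


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    doc = gemmi.Structure()
    doc.name = "gpcrprofile"
    for i, st in enumerate(structures):
        model = gemmi.Model(i + 1)
        chains: dict[str, gemmi.Chain] = {}
        for key, atoms in st.residues.items():
            chain = chains.get(key.chain_id)
            if chain is None:
                chain = gemmi.Chain(key.chain_id)
                chains[key.chain_id] = chain
            res = gemmi.Residue()
            res.name = key.residue_name or "UNK"
            res.seqid = gemmi.SeqId(key.seq_number, key.insertion_code or " ")
            for atom in atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = 1.0
                res.add_atom(ga)
            chain.add_residue(res)
        for chain in chains.values():
            model.add_chain(chain)
        doc.add_model(model)
    doc.setup_entities()
    return doc


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a Structure as PDB or mmCIF (by extension when format='auto')."""
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    doc = _to_gemmi([structure])
    if fmt == "pdb":
        doc.write_pdb(str(path))
    elif fmt == "mmcif":
        doc.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB file."""
    snapshots = []
    for frame in traj.frames:
        st = traj.topology.copy()
        st.set_coords(frame)
        snapshots.append(st)
    _to_gemmi(snapshots).write_pdb(str(path))


# ---------------------------------------------------------------------------
# OpenDX scalar grids


def write_density_grid(grid: DensityGrid, path: str | Path, format: str = "dx") -> None:
    """Write a DensityGrid as an OpenDX scalar field.

    Values are emitted in the DX convention: z fastest-varying (x slowest),
    three per line.
    """
    if format != "dx":
        raise ValueError(f"unknown grid format {format!r}")
    if grid.values.size == 0:
        raise ValueError("cannot write an empty grid")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    d = grid.spacing
    lines = [
        "# OpenDX scalar field written by gpcrprofile",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.reshape(-1)  # C order: z fastest, matching DX
    for i in range(0, flat.size, 3):
        chunk = flat[i : i + 3]
        lines.append(" ".join(f"{v:.10g}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def read_density_grid(path: str | Path) -> DensityGrid:
    """Read an OpenDX scalar field written by :func:`write_density_grid`."""
    counts: list[int] | None = None
    origin: list[float] | None = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = 0
    reading = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if reading:
            if line.startswith(("attribute", "object")):
                reading = False
                continue
            values.extend(float(v) for v in line.split())
            if len(values) >= n_items:
                reading = False
            continue
        if line.startswith("object 1"):
            counts = [int(v) for v in line.split()[-3:]]
        elif line.startswith("origin"):
            origin = [float(v) for v in line.split()[1:4]]
        elif line.startswith("delta"):
            deltas.append([float(v) for v in line.split()[1:4]])
        elif "data follows" in line:
            n_items = int(line.split()[-3])
            reading = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a recognised OpenDX scalar field")
    spacing = deltas[0][0]
    arr = np.array(values[: math.prod(counts)], dtype=float).reshape(counts)
    return DensityGrid(origin=np.array(origin), spacing=spacing, values=arr)
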