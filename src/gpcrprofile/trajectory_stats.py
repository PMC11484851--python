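"""Per-frame trajectory statistics: RMSD and distance series, hydrogen-bond
occupancies, and the water-occupancy density grid.

The water density at grid point *i* is

    rho_i = 1/(T * V_r) * sum_t sum_j H(r - |x_{j,t} - c_i|)

where T is the number of frames, the inner sum runs over the water oxygens,
V_r = 4/3 pi r^3 is the probe-sphere volume (r = 1 A by default), c_i is the
grid-point coordinate and H the Heaviside step.  Frames are first superposed
on the initial frame over a fit selection (receptor C-alphas) so the grid is
attached to the receptor frame of reference.  A single water contributes to
every grid point within r of it — the field is a local density, not a
partition, and does not sum to the number of waters.

Hydrogen-bond occupancy follows the classic geometric criterion: donor to
acceptor heavy-atom distance <= 0.35 nm and hydrogen-donor-acceptor angle
<= 30 degrees; the occupancy is the fraction of frames in which any
qualifying donor-H...acceptor triple of the residue pair satisfies it.  When
the topology carries no hydrogens the distance term alone is applied and the
result is flagged accordingly.

Trajectories are assumed pre-imaged (molecules whole, no periodic wrapping);
no periodic imaging is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import superpose
from .structio import DensityGrid, Structure, Trajectory

__all__ = [
    "TimeSeries",
    "HBondCriterion",
    "GridRegion",
    "select_atoms",
    "residue_atom_indices",
    "rmsd_series",
    "min_distance_series",
    "hbond_probability",
    "water_density_grid",
    "high_density_regions",
    "BULK_WATER_DENSITY",
]

#: literature number density of bulk water at ambient conditions, waters/A^3
BULK_WATER_DENSITY = 0.0334


@dataclass
class TimeSeries:
    """One value per trajectory frame, with a metric name and unit."""

    metric: str
    values: np.ndarray
    unit: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self) -> str:
        lines = [f"# {self.metric} ({self.unit})", "frame\tvalue"]
        lines += [f"{i}\t{v:.6f}" for i, v in enumerate(self.values)]
        return "\n".join(lines) + "\n"


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    donor_acceptor_cutoff: heavy-atom D...A distance, A.
    angle_cutoff: hydrogen-donor-acceptor angle, degrees (applied only when
    hydrogens are available or required).
    """

    donor_acceptor_cutoff: float = 3.5
    angle_cutoff: float = 30.0
    require_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")


# ---------------------------------------------------------------------------
# selections


def select_atoms(
    topology: Structure,
    chain: str | None = None,
    name: str | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Flat atom indices matching chain / atom-name / heavy filters."""
    idx = [
        i
        for i, (key, atom) in enumerate(topology.atoms())
        if (chain is None or key.chain_id == chain)
        and (name is None or atom.name == name)
        and (not heavy_only or not atom.is_hydrogen)
    ]
    if not idx:
        raise ValueError("selection matched no atoms")
    return np.array(idx, dtype=int)


def residue_atom_indices(
    topology: Structure, chain: str, seq_number: int, heavy_only: bool = True
) -> np.ndarray:
    """Flat atom indices of one residue (heavy atoms by default)."""
    target_key, _ = topology.find_residue(chain, seq_number)
    idx = [
        i
        for i, (key, atom) in enumerate(topology.atoms())
        if key is target_key and (not heavy_only or not atom.is_hydrogen)
    ]
    if not idx:
        raise ValueError(f"residue {chain}:{seq_number} has no qualifying atoms")
    return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# series


def rmsd_series(
    traj: Trajectory, fit_indices: np.ndarray, report_indices: np.ndarray | None = None
) -> TimeSeries:
    """Per-frame RMSD of the report selection from frame 0, after
    superposing each frame on frame 0 over the fit selection."""
    fit_indices = np.asarray(fit_indices, int)
    report_indices = (
        fit_indices if report_indices is None else np.asarray(report_indices, int)
    )
    ref = traj.frames[0]
    ref_fit = ref[fit_indices]
    ref_rep = ref[report_indices]
    out = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        sup = superpose(ref_fit, frame[fit_indices])
        moved = sup.transform(frame[report_indices])
        out[t] = np.sqrt(np.mean(np.sum((moved - ref_rep) ** 2, axis=1)))
    return TimeSeries(metric="rmsd", values=out)


def min_distance_series(
    traj: Trajectory, chain_a: str, res_a: int, chain_b: str, res_b: int
) -> TimeSeries:
    """Per-frame minimum distance over all heavy-atom pairs of two residues."""
    ia = residue_atom_indices(traj.topology, chain_a, res_a, heavy_only=True)
    ib = residue_atom_indices(traj.topology, chain_b, res_b, heavy_only=True)
    out = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        xa, xb = frame[ia], frame[ib]
        d2 = np.sum((xa[:, None] - xb[None, :]) ** 2, axis=-1)
        out[t] = math.sqrt(float(d2.min()))
    return TimeSeries(metric=f"min_dist_{chain_a}{res_a}_{chain_b}{res_b}", values=out)


# ---------------------------------------------------------------------------
# hydrogen-bond occupancy

from . import chem  # noqa: E402  (tables only)


def _donor_triples(topology: Structure, chain: str, seq: int):
    """(donor_heavy_idx, [attached hydrogen idx]) pairs for a residue."""
    key, atoms = topology.find_residue(chain, seq)
    flat = list(topology.atoms())
    own = [(i, a) for i, (k, a) in enumerate(flat) if k is key]
    names = {a.name for _, a in own}
    donors = chem.donor_atoms(key.residue_name, names)
    hydrogens = [(i, a) for i, a in own if a.is_hydrogen]
    out = []
    for name in donors:
        di = next(i for i, a in own if a.name == name)
        dcoord = next(a for _, a in own if a.name == name).coord
        attached = [
            hi for hi, ha in hydrogens if np.linalg.norm(ha.coord - dcoord) < 1.25
        ]
        out.append((di, attached))
    return out


def _acceptor_indices(topology: Structure, chain: str, seq: int) -> list[int]:
    key, atoms = topology.find_residue(chain, seq)
    names = {a.name for a in atoms}
    acceptors = chem.acceptor_atoms(key.residue_name, names)
    return [
        i
        for i, (k, a) in enumerate(topology.atoms())
        if k is key and a.name in acceptors
    ]


def hbond_probability(
    traj: Trajectory,
    donor_res: tuple[str, int],
    acceptor_res: tuple[str, int],
    criterion: HBondCriterion | None = None,
) -> float:
    """Fraction of frames in which the residue pair forms a hydrogen bond.

    Any qualifying donor(-H)...acceptor combination of the two residues
    counts; the pair is bonded in a frame if at least one combination
    satisfies the criterion.
    """
    criterion = criterion or HBondCriterion()
    donors = _donor_triples(traj.topology, *donor_res)
    acceptors = _acceptor_indices(traj.topology, *acceptor_res)
    if not donors:
        raise ValueError(f"residue {donor_res} has no donor atoms")
    if not acceptors:
        raise ValueError(f"residue {acceptor_res} has no acceptor atoms")
    have_h = any(hs for _, hs in donors)
    if criterion.require_hydrogens and not have_h:
        raise ValueError("criterion requires hydrogens but the donor residue has none")
    cos_min = math.cos(math.radians(criterion.angle_cutoff))
    bonded = 0
    for frame in traj.frames:
        hit = False
        for di, h_idx in donors:
            d = frame[di]
            for ai in acceptors:
                a = frame[ai]
                if np.linalg.norm(d - a) > criterion.donor_acceptor_cutoff:
                    continue
                if not have_h:
                    hit = True
                    break
                # angle term: some attached H with H-D-A angle <= cutoff
                for hi in h_idx:
                    v_h = frame[hi] - d
                    v_a = a - d
                    c = float(
                        np.dot(v_h, v_a)
                        / (np.linalg.norm(v_h) * np.linalg.norm(v_a))
                    )
                    if c >= cos_min:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        bonded += hit
    return bonded / traj.n_frames


# ---------------------------------------------------------------------------
# water density


@dataclass
class GridRegion:
    """Axis-aligned box over which the density grid is evaluated."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, float)
        self.max_corner = np.asarray(self.max_corner, float)
        if np.any(self.max_corner <= self.min_corner):
            raise ValueError("region box must have positive extent")

    @classmethod
    def around_selection(
        cls, topology: Structure, indices: np.ndarray, margin: float = 4.0
    ) -> "GridRegion":
        xyz = topology.coords()[np.asarray(indices, int)]
        return cls(xyz.min(axis=0) - margin, xyz.max(axis=0) + margin)


def water_density_grid(
    traj: Trajectory,
    region: GridRegion,
    spacing: float = 0.4,
    r: float = 1.0,
    fit_indices: np.ndarray | None = None,
    bulk_density: float | None = BULK_WATER_DENSITY,
) -> DensityGrid:
    """Evaluate the water-occupancy density rho_i on a cubic grid.

    Each frame is first superposed on frame 0 over ``fit_indices`` (skip by
    passing None); then, for every grid point, water oxygens within ``r``
    are counted.  rho_i = counts / (T * V_r).
    """
    if spacing <= 0 or r <= 0:
        raise ValueError("spacing and probe radius must be positive")
    water_idx = traj.topology.water_oxygen_indices()
    dims = (
        np.floor((region.max_corner - region.min_corner) / spacing + 1e-9).astype(int) + 1
    )
    nx, ny, nz = (int(v) for v in dims)
    counts = np.zeros(nx * ny * nz)
    grid = DensityGrid(
        origin=region.min_corner,
        spacing=spacing,
        values=counts.reshape(nx, ny, nz),
        r=r,
        n_frames=traj.n_frames,
        n_waters=len(water_idx),
        bulk_density=bulk_density,
    )
    if len(water_idx) == 0:
        import warnings

        warnings.warn("trajectory contains no water oxygens; density grid is all zero")
        return grid
    points = grid.point_coords()
    tree = cKDTree(points)
    ref_fit = traj.frames[0][fit_indices] if fit_indices is not None else None
    for frame in traj.frames:
        if ref_fit is not None:
            sup = superpose(ref_fit, frame[fit_indices])
            waters = sup.transform(frame[water_idx])
        else:
            waters = frame[water_idx]
        for neighbours in tree.query_ball_point(waters, r):
            counts[neighbours] += 1.0
    v_r = 4.0 / 3.0 * math.pi * r**3
    grid.values = (counts / (traj.n_frames * v_r)).reshape(nx, ny, nz)
    return grid


@dataclass
class DensityCluster:
    """A 26-connected cluster of grid points above the density threshold."""

    indices: np.ndarray  # (n, 3) integer grid indices
    peak_ratio: float  # peak rho / bulk
    peak_index: tuple[int, int, int]
    size: int


def high_density_regions(
    grid: DensityGrid, k: float = 2.0, bulk_density: float | None = None
) -> list[DensityCluster]:
    """Clusters of grid points whose density reaches k-fold bulk density.

    Points with rho >= k * bulk are grouped into 26-connected components,
    returned sorted by descending peak ratio.
    """
    bulk = bulk_density if bulk_density is not None else grid.bulk_density
    if bulk is None or bulk <= 0:
        raise ValueError("bulk density is unset and cannot be estimated")
    mask = grid.values >= k * bulk
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        vals = grid.values[labels == lab]
        peak_pos = idx[int(np.argmax(vals))]
        clusters.append(
            DensityCluster(
                indices=idx,
                peak_ratio=float(vals.max() / bulk),
                peak_index=tuple(int(v) for v in peak_pos),
                size=int(idx.shape[0]),
            )
        )
    clusters.sort(key=lambda c: c.peak_ratio, reverse=True)
    return clusters
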