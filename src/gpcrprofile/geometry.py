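"""Rigid-body superposition, RMSD, residue distances and helix axes.

The primitive layer under the hallmark, interface and trajectory statistics:
least-squares rigid fits (Kabsch, proper rotations only), RMSD of one
selection after fitting on another, minimum heavy-atom inter-residue
distances, principal-axis helix fits and signed displacement projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Atom, ResidueKey, Structure

__all__ = [
    "Superposition",
    "HelixAxis",
    "superpose",
    "apply_superposition",
    "rmsd_after_superposition",
    "min_residue_distance",
    "helix_axis",
    "displacement_along_axis",
    "pair_atoms",
]


@dataclass
class Superposition:
    """Result of a least-squares rigid fit: x_fit = rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class HelixAxis:
    """Principal axis of a helix: origin (centroid), unit direction, length."""

    origin: np.ndarray
    direction: np.ndarray
    length: float


def superpose(ref: np.ndarray, mobile: np.ndarray) -> Superposition:
    """Least-squares rigid fit of ``mobile`` onto ``ref`` (Kabsch).

    Minimises the RMSD over all proper rotations and translations;
    reflections are excluded by flipping the smallest singular direction when
    the optimal orthogonal matrix has negative determinant.
    """
    ref = np.asarray(ref, float)
    mobile = np.asarray(mobile, float)
    if ref.shape != mobile.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"point sets must have matching (n,3) shapes, got {ref.shape} vs {mobile.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([ref_c, mob_c]), tol=1e-9) < 2:
        raise ValueError("degenerate (coincident or collinear) point set")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref.mean(axis=0) - rot @ mobile.mean(axis=0)
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def apply_superposition(sup: Superposition, coords: np.ndarray) -> np.ndarray:
    return sup.transform(coords)


def pair_atoms(
    ref: Structure, mobile: Structure, atom_name: str | None = "CA"
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms between two structures by (chain, seq_number, atom name).

    Unpaired atoms are dropped; fewer than 3 surviving pairs is an error.
    """

    def index(st: Structure) -> dict[tuple[str, int, str, str], np.ndarray]:
        out = {}
        for key, atom in st.atoms():
            if atom_name is not None and atom.name != atom_name:
                continue
            out[(key.chain_id, key.seq_number, key.insertion_code, atom.name)] = atom.coord
        return out

    a = index(ref)
    b = index(mobile)
    shared = [k for k in a if k in b]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} paired atoms; need at least 3")
    return (
        np.array([a[k] for k in shared]),
        np.array([b[k] for k in shared]),
    )


def rmsd_after_superposition(
    fit_ref: np.ndarray,
    fit_mobile: np.ndarray,
    report_ref: np.ndarray,
    report_mobile: np.ndarray,
) -> float:
    """RMSD of the report selection after fitting mobile onto ref on the fit
    selection.  With fit == report this is the ordinary best-fit RMSD."""
    sup = superpose(fit_ref, fit_mobile)
    moved = sup.transform(np.asarray(report_mobile, float))
    diff = moved - np.asarray(report_ref, float)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _residue_coords(atoms: list[Atom], which: str) -> np.ndarray:
    if which == "heavy":
        sel = [a.coord for a in atoms if not a.is_hydrogen]
    elif which == "all":
        sel = [a.coord for a in atoms]
    else:
        raise ValueError(f"atom filter must be 'heavy' or 'all', got {which!r}")
    if not sel:
        raise ValueError("residue has no qualifying atoms")
    return np.array(sel)


def min_residue_distance(
    atoms_a: list[Atom], atoms_b: list[Atom], atoms: str = "heavy"
) -> float:
    """Minimum pairwise distance between two residues' atoms (default heavy).

    This is the convention used for inter-residue distance time series:
    the minimum over all possible heavy-atom pairs of the two residues.
    """
    xa = _residue_coords(atoms_a, atoms)
    xb = _residue_coords(atoms_b, atoms)
    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def min_atom_pair(
    atoms_a: list[Atom], atoms_b: list[Atom], atoms: str = "heavy"
) -> tuple[float, str, str]:
    """Minimum inter-residue distance plus the closest atom-name pair."""
    fa = [a for a in atoms_a if atoms == "all" or not a.is_hydrogen]
    fb = [b for b in atoms_b if atoms == "all" or not b.is_hydrogen]
    if not fa or not fb:
        raise ValueError("residue has no qualifying atoms")
    xa = np.array([a.coord for a in fa])
    xb = np.array([b.coord for b in fb])
    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
    return float(np.sqrt(d2[i, j])), fa[i].name, fb[j].name


def helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Axis of a helix from its C-alpha trace.

    The second differences of consecutive C-alpha positions of an ideal
    helix are purely radial (the axial rise cancels), so they span the plane
    orthogonal to the helix axis; the axis is recovered as the normal of
    that plane (smallest principal component of the second-difference
    cloud).  This is exact for an ideal helix of any length, unlike a plain
    PCA of the C-alpha positions, which is biased by the spiral for short
    helices.  Near-straight traces fall back to the point-cloud PCA.
    Direction is oriented from the first toward the last residue (N->C).
    """
    x = np.asarray(ca_coords, float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 5:
        raise ValueError("helix axis needs at least 5 C-alpha coordinates")
    centroid = x.mean(axis=0)
    # second differences at several lags are purely radial for an ideal
    # helix; pooling lags improves the plane fit under coordinate noise
    us = []
    for lag in range(1, max(2, min(7, (x.shape[0] - 1) // 2 + 1))):
        d = x[2 * lag :] - 2 * x[lag:-lag] + x[: -2 * lag]
        us.append(d)
    u = np.vstack(us)
    cov = u.T @ u
    w, v = np.linalg.eigh(cov)
    if w[-1] > 1e-10:
        direction = v[:, 0]  # normal of the radial plane
    else:  # degenerate (straight) trace: principal axis of the points
        _, _, vt = np.linalg.svd(x - centroid)
        direction = vt[0]
    span = x[-1] - x[0]
    if np.dot(direction, span) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    proj = (x - centroid) @ direction
    return HelixAxis(origin=centroid, direction=direction, length=float(proj.max() - proj.min()))


def displacement_along_axis(
    point_ref: np.ndarray, point_new: np.ndarray, axis: np.ndarray
) -> float:
    """Signed displacement of a point along a unit axis (dot product)."""
    axis = np.asarray(axis, float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    return float(np.dot(np.asarray(point_new, float) - np.asarray(point_ref, float), axis))


def in_plane_displacement(
    point_ref: np.ndarray, point_new: np.ndarray, axis: np.ndarray
) -> float:
    """Magnitude of the displacement component orthogonal to a unit axis."""
    axis = np.asarray(axis, float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    d = np.asarray(point_new, float) - np.asarray(point_ref, float)
    d_perp = d - np.dot(d, axis) * axis
    return float(np.linalg.norm(d_perp))
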