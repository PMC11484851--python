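"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the library code paths they are used to
check: the quaternion superposition oracle (Horn's method) is independent of
the SVD-based Kabsch fit, and the density/contact/distance oracles are plain
double loops over the raw coordinates.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from gpcrprofile import chem, synthetic
from gpcrprofile.structio import Structure


# ---------------------------------------------------------------------------
# independent oracles


def quaternion_superpose(ref: np.ndarray, mobile: np.ndarray) -> float:
    """Best-fit RMSD via Horn's quaternion eigenvalue method."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mobile, float)
    rc = ref - ref.mean(axis=0)
    mc = mob - mob.mean(axis=0)
    m = mc.T @ rc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = float(np.sum(rc**2) + np.sum(mc**2))
    rmsd_sq = max(0.0, (e0 - 2.0 * lam) / ref.shape[0])
    return math.sqrt(rmsd_sq)


def brute_force_min_distance(xa: np.ndarray, xb: np.ndarray) -> float:
    best = math.inf
    for a in xa:
        for b in xb:
            best = min(best, float(np.linalg.norm(a - b)))
    return best


def brute_force_density(
    frames_waters: list[np.ndarray], grid_points: np.ndarray, r: float
) -> np.ndarray:
    """Direct Heaviside double sum: rho_i = 1/(T V_r) sum_t sum_j H(r - |x - c|)."""
    T = len(frames_waters)
    v_r = 4.0 / 3.0 * math.pi * r**3
    counts = np.zeros(len(grid_points))
    for waters in frames_waters:
        for x in waters:
            d = np.linalg.norm(grid_points - x, axis=1)
            counts += (d <= r).astype(float)
    return counts / (T * v_r)


def brute_force_contacts(
    structure: Structure, chain_a: str, chain_b: str, hbond_cutoff=3.5, vdw_cutoff=4.5
) -> dict[tuple[int, int], str]:
    """All-pairs residue contact classification from raw coordinates."""
    out: dict[tuple[int, int], str] = {}
    res_a = [(k, v) for k, v in structure.residues.items() if k.chain_id == chain_a]
    res_b = [(k, v) for k, v in structure.residues.items() if k.chain_id == chain_b]
    for ka, aa in res_a:
        ah = [x for x in aa if not x.is_hydrogen]
        a_names = {x.name for x in ah}
        for kb, bb in res_b:
            bh = [x for x in bb if not x.is_hydrogen]
            b_names = {x.name for x in bh}
            dmin = brute_force_min_distance(
                np.array([x.coord for x in ah]), np.array([x.coord for x in bh])
            )
            if dmin > vdw_cutoff:
                continue
            da = set(chem.donor_atoms(ka.residue_name, a_names))
            aa_ = set(chem.acceptor_atoms(ka.residue_name, a_names))
            db = set(chem.donor_atoms(kb.residue_name, b_names))
            ab = set(chem.acceptor_atoms(kb.residue_name, b_names))
            polar = math.inf
            for x in ah:
                for y in bh:
                    if (x.name in da and y.name in ab) or (x.name in aa_ and y.name in db):
                        polar = min(polar, float(np.linalg.norm(x.coord - y.coord)))
            out[(ka.seq_number, kb.seq_number)] = (
                "hbond" if polar <= hbond_cutoff else "vdw"
            )
    return out


def random_rigid_transform(rng: np.random.Generator):
    """A random proper rotation + translation."""
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] = -rot[:, 0]
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


def transform_structure(structure: Structure, rot: np.ndarray, trans: np.ndarray) -> Structure:
    moved = structure.copy()
    moved.set_coords(moved.coords() @ rot.T + trans)
    return moved


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def bundle_result():
    return synthetic.make_bundle(
        synthetic.BundleSpec(seed=0, gap_346_753=7.3, dry_salt_bridge=2.9, r350_y558_hbond=2.9)
    )


@pytest.fixture(scope="session")
def bundle_pair():
    return synthetic.make_bundle_pair(
        synthetic.BundleSpec(seed=0, gap_346_753=7.3, dry_salt_bridge=3.8, r350_y558_hbond=2.9)
    )


@pytest.fixture(scope="session")
def complex_result():
    return synthetic.make_complex(synthetic.ComplexSpec(seed=0))
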