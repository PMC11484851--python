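"""Receptor–G-alpha interface contacts and alpha5-helix insertion geometry.

Enumerates residue-residue contacts across a two-chain interface and
classifies them: a hydrogen bond is a donor/acceptor heavy-atom pair within
the hydrogen-bond cutoff (3.5 A default, no angle term because deposited
models lack hydrogens); any other residue pair with heavy atoms within the
van der Waals cutoff (4.5 A default) is a hydrophobic/vdW contact.  One
record is kept per residue pair per type, carrying the minimal distance and
its atom pair as evidence.  Ionic pairs (Asp/Glu vs Arg/Lys/His) within
4.0 A are additionally flagged as salt bridges in the notes column.

The alpha5 tilt quantifies how vertically the G-alpha C-terminal helix
inserts into the receptor: the angle between the alpha5 principal axis and
the receptor bundle axis, folded into [0, 90] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .geometry import helix_axis
from .numbering import NumberingMap
from .structio import ResidueKey, Structure

__all__ = [
    "ContactRecord",
    "InterfaceReport",
    "detect_contacts",
    "pocket_composition",
    "alpha5_tilt",
    "HBOND_CUTOFF",
    "VDW_CUTOFF",
    "SALT_BRIDGE_CUTOFF",
]

HBOND_CUTOFF = 3.5
VDW_CUTOFF = 4.5
SALT_BRIDGE_CUTOFF = 4.0


@dataclass
class ContactRecord:
    """One interface contact at residue-pair granularity."""

    receptor_res: ResidueKey
    receptor_label: str | None
    ga_res: ResidueKey
    ga_label: str | None
    contact_type: str  # "hbond" | "vdw"
    min_distance: float
    atom_pair: tuple[str, str]
    notes: str = ""

    def as_row(self) -> dict:
        return {
            "receptor_res": str(self.receptor_res),
            "receptor_label": self.receptor_label or "",
            "ga_res": str(self.ga_res),
            "ga_label": self.ga_label or "",
            "type": self.contact_type,
            "min_dist_A": round(self.min_distance, 3),
            "atom_pair": f"{self.atom_pair[0]}-{self.atom_pair[1]}",
            "notes": self.notes,
        }


@dataclass
class InterfaceReport:
    contacts: list[ContactRecord] = field(default_factory=list)
    alpha5_tilt_deg: float | None = None
    pocket_residues: list[str] = field(default_factory=list)

    @property
    def hbond_count(self) -> int:
        return sum(1 for c in self.contacts if c.contact_type == "hbond")

    @property
    def vdw_count(self) -> int:
        return sum(1 for c in self.contacts if c.contact_type == "vdw")

    def hbond_partner_labels(self) -> list[tuple[str | None, str | None]]:
        return [(c.receptor_label, c.ga_label) for c in self.contacts if c.contact_type == "hbond"]


def _chain_atom_table(structure: Structure, chain_id: str):
    """Flatten a chain's heavy atoms: coords, residue index, atom names."""
    keys: list[ResidueKey] = []
    res_atom_names: list[set[str]] = []
    coords: list[np.ndarray] = []
    names: list[str] = []
    res_idx: list[int] = []
    for key, atoms in structure.chain(chain_id).residues.items():
        heavy = [a for a in atoms if not a.is_hydrogen]
        if not heavy:
            continue
        keys.append(key)
        res_atom_names.append({a.name for a in heavy})
        for a in heavy:
            coords.append(a.coord)
            names.append(a.name)
            res_idx.append(len(keys) - 1)
    if not coords:
        raise ValueError(f"chain {chain_id!r}: empty selection")
    return keys, res_atom_names, np.array(coords), names, np.array(res_idx)


def _label_or_none(nmap: NumberingMap | None, key: ResidueKey) -> str | None:
    if nmap is None:
        return None
    try:
        return nmap.label_of(key).text
    except KeyError:
        return None


def detect_contacts(
    complex_structure: Structure,
    receptor_chain: str,
    ga_chain: str,
    bw_map: NumberingMap | None = None,
    cgn_map: NumberingMap | None = None,
    hbond_cutoff: float = HBOND_CUTOFF,
    vdw_cutoff: float = VDW_CUTOFF,
) -> InterfaceReport:
    """Enumerate receptor/G-alpha residue contacts across the interface.

    Residue pairs qualifying as hydrogen bonds are recorded as 'hbond'; the
    remaining pairs within the vdW cutoff as 'vdw'.  No pair is recorded
    twice.  Contacts without a generic label are still reported, unlabeled.
    """
    if receptor_chain == ga_chain:
        raise ValueError("receptor and G-alpha chains must differ")
    r_keys, r_names, r_xyz, r_atom_names, r_res = _chain_atom_table(
        complex_structure, receptor_chain
    )
    g_keys, g_names, g_xyz, g_atom_names, g_res = _chain_atom_table(
        complex_structure, ga_chain
    )
    cutoff = max(hbond_cutoff, vdw_cutoff)
    pairs = cKDTree(r_xyz).query_ball_tree(cKDTree(g_xyz), r=cutoff)

    # per residue pair: overall min distance and min donor/acceptor distance
    best: dict[tuple[int, int], tuple[float, str, str]] = {}
    best_polar: dict[tuple[int, int], tuple[float, str, str]] = {}
    donors_r = [set(chem.donor_atoms(k.residue_name, names)) for k, names in zip(r_keys, r_names)]
    accept_r = [set(chem.acceptor_atoms(k.residue_name, names)) for k, names in zip(r_keys, r_names)]
    donors_g = [set(chem.donor_atoms(k.residue_name, names)) for k, names in zip(g_keys, g_names)]
    accept_g = [set(chem.acceptor_atoms(k.residue_name, names)) for k, names in zip(g_keys, g_names)]

    for i, neighbours in enumerate(pairs):
        ri = int(r_res[i])
        for j in neighbours:
            gj = int(g_res[j])
            d = float(np.linalg.norm(r_xyz[i] - g_xyz[j]))
            keypair = (ri, gj)
            if keypair not in best or d < best[keypair][0]:
                best[keypair] = (d, r_atom_names[i], g_atom_names[j])
            an_r, an_g = r_atom_names[i], g_atom_names[j]
            is_da = (an_r in donors_r[ri] and an_g in accept_g[gj]) or (
                an_r in accept_r[ri] and an_g in donors_g[gj]
            )
            if is_da and (keypair not in best_polar or d < best_polar[keypair][0]):
                best_polar[keypair] = (d, an_r, an_g)

    records: list[ContactRecord] = []
    for (ri, gj), (dmin, a_r, a_g) in sorted(best.items()):
        r_key, g_key = r_keys[ri], g_keys[gj]
        polar = best_polar.get((ri, gj))
        notes = ""
        if chem.is_ionic_pair(r_key.residue_name, [], g_key.residue_name, []):
            ionic_d = _ionic_min_distance(r_key, g_key, complex_structure)
            if ionic_d is not None and ionic_d <= SALT_BRIDGE_CUTOFF:
                notes = "salt bridge"
        if polar is not None and polar[0] <= hbond_cutoff:
            records.append(
                ContactRecord(
                    receptor_res=r_key,
                    receptor_label=_label_or_none(bw_map, r_key),
                    ga_res=g_key,
                    ga_label=_label_or_none(cgn_map, g_key),
                    contact_type="hbond",
                    min_distance=polar[0],
                    atom_pair=(polar[1], polar[2]),
                    notes=notes,
                )
            )
        elif dmin <= vdw_cutoff:
            records.append(
                ContactRecord(
                    receptor_res=r_key,
                    receptor_label=_label_or_none(bw_map, r_key),
                    ga_res=g_key,
                    ga_label=_label_or_none(cgn_map, g_key),
                    contact_type="vdw",
                    min_distance=dmin,
                    atom_pair=(a_r, a_g),
                    notes=notes,
                )
            )
    return InterfaceReport(contacts=records)


def _ionic_min_distance(
    r_key: ResidueKey, g_key: ResidueKey, structure: Structure
) -> float | None:
    def group(key: ResidueKey) -> np.ndarray | None:
        rn = key.residue_name.upper()
        names = chem.CHARGED_POSITIVE.get(rn) or chem.CHARGED_NEGATIVE.get(rn)
        if not names:
            return None
        _, atoms = structure.find_residue(key.chain_id, key.seq_number, key.insertion_code)
        sel = [a.coord for a in atoms if a.name in names]
        return np.array(sel) if sel else None

    xa, xb = group(r_key), group(g_key)
    if xa is None or xb is None:
        return None
    return float(np.sqrt(np.min(np.sum((xa[:, None] - xb[None, :]) ** 2, axis=-1))))


def pocket_composition(
    complex_structure: Structure,
    receptor_chain: str,
    ga_chain: str,
    bw_map: NumberingMap | None,
    cgn_map: NumberingMap,
    ga_labels: tuple[str, ...] = ("H5.20", "H5.25"),
    cutoff: float = VDW_CUTOFF,
) -> set[str]:
    """Receptor residues (as BW labels) within ``cutoff`` of the named
    G-alpha positions — the hydrophobic pocket receiving the alpha5 tip."""
    probe_coords = []
    for label in ga_labels:
        key = cgn_map.residue_of(label)  # raises KeyError if unmapped
        _, atoms = complex_structure.find_residue(
            key.chain_id, key.seq_number, key.insertion_code
        )
        probe_coords.extend(a.coord for a in atoms if not a.is_hydrogen)
    probe = np.array(probe_coords)
    labels: set[str] = set()
    for key, atoms in complex_structure.chain(receptor_chain).residues.items():
        xyz = np.array([a.coord for a in atoms if not a.is_hydrogen])
        if xyz.size == 0:
            continue
        dmin = np.sqrt(np.min(np.sum((xyz[:, None] - probe[None, :]) ** 2, axis=-1)))
        if dmin <= cutoff:
            label = _label_or_none(bw_map, key)
            labels.add(label if label is not None else str(key))
    return labels


def alpha5_tilt(a5_ca: np.ndarray, bundle_ca_or_axis: np.ndarray) -> float:
    """Angle (degrees, in [0, 90]) between the alpha5 helix axis and the
    receptor bundle axis.

    ``bundle_ca_or_axis`` may be a (n,3) C-alpha cloud (its principal axis is
    used) or a single unit 3-vector.
    """
    a5_axis = helix_axis(np.asarray(a5_ca, float)).direction
    ref = np.asarray(bundle_ca_or_axis, float)
    if ref.ndim == 2:
        centroid = ref.mean(axis=0)
        _, _, vt = np.linalg.svd(ref - centroid)
        ref_axis = vt[0]
    elif ref.shape == (3,):
        n = np.linalg.norm(ref)
        if n == 0:
            raise ValueError("degenerate bundle axis")
        ref_axis = ref / n
    else:
        raise ValueError("bundle reference must be (n,3) coordinates or a 3-vector")
    cosang = abs(float(np.dot(a5_axis, ref_axis)))
    return math.degrees(math.acos(min(1.0, cosang)))
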