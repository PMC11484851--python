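"""Class-A GPCR activation hallmarks on a generically numbered receptor.

Activation of a class-A receptor leaves geometric fingerprints: the TM3
DRY-motif salt bridge (D3.49-R3.50) breaks, R3.50 swings toward TM7 and can
hydrogen-bond Y5.58, the cytoplasmic end of TM6 moves outward by several
Angstrom to open the G-protein crevice, and the TM7 NPxxY/NPxxL motif shifts
toward the intracellular side.  In receptors carrying L7.53 instead of the
conserved tyrosine, the usual 3.46-7.53 contact (<= 4.5 A) is replaced by a
wide, water-filled gap.  This module measures all of these on a structure
with a Ballesteros-Weinstein map, optionally against an inactive reference.

Sign convention: the receptor bundle axis is oriented extracellular ->
intracellular positive, so a "downward" (intracellular) displacement is
positive.  Orientation is fixed by an explicit intracellular reference point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import chem
from .geometry import (
    displacement_along_axis,
    helix_axis,
    in_plane_displacement,
    min_residue_distance,
    superpose,
)
from .numbering import NumberingMap
from .structio import Atom, ResidueKey, Structure

__all__ = [
    "HallmarkReport",
    "motif_gap",
    "salt_bridge_or_hbond",
    "tm6_outward",
    "tm7_downward",
    "bundle_axis",
    "hallmark_report",
    "CONTACT_CUTOFF",
    "HBOND_CUTOFF",
    "SALT_BRIDGE_CUTOFF",
]

#: heavy-atom distance at or under which two residues are in direct
#: (hydrophobic / van der Waals) contact
CONTACT_CUTOFF = 4.5
#: donor-acceptor heavy-atom hydrogen-bond cutoff for static models
HBOND_CUTOFF = 3.5
#: charged-group N/O distance for a salt bridge
SALT_BRIDGE_CUTOFF = 4.0

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def _residue_atoms(structure: Structure, nmap: NumberingMap, label: str) -> tuple[ResidueKey, list[Atom]]:
    key = nmap.residue_of(label)
    return structure.find_residue(key.chain_id, key.seq_number, key.insertion_code)


def _ca(structure: Structure, nmap: NumberingMap, label: str) -> np.ndarray:
    _, atoms = _residue_atoms(structure, nmap, label)
    for atom in atoms:
        if atom.name == "CA":
            return atom.coord
    raise ValueError(f"residue at label {label} has no CA atom")


def motif_gap(
    structure: Structure,
    nmap: NumberingMap,
    label_a: str = "3.46",
    label_b: str = "7.53",
    contact_cutoff: float = CONTACT_CUTOFF,
) -> tuple[float, bool]:
    """Minimum heavy-atom gap between two generic positions and a contact flag.

    The canonical activation rearrangement puts positions 3.46 and 7.53 in
    direct contact (<= 4.5 A); a larger gap indicates the contact is absent
    (e.g. replaced by a hydrated cavity in NPxxL receptors).
    """
    _, atoms_a = _residue_atoms(structure, nmap, label_a)
    _, atoms_b = _residue_atoms(structure, nmap, label_b)
    d = min_residue_distance(atoms_a, atoms_b, atoms="heavy")
    return d, d <= contact_cutoff


def _polar_sidechain(atoms: list[Atom]) -> list[Atom]:
    return [
        a
        for a in atoms
        if not a.is_hydrogen
        and a.element.upper() in ("N", "O")
        and a.name not in BACKBONE_NAMES
    ]


def _charged_group(key: ResidueKey, atoms: list[Atom]) -> list[Atom]:
    rn = key.residue_name.upper()
    names = chem.CHARGED_POSITIVE.get(rn) or chem.CHARGED_NEGATIVE.get(rn)
    if not names:
        return []
    return [a for a in atoms if a.name in names]


def salt_bridge_or_hbond(
    structure: Structure,
    nmap: NumberingMap,
    pair: tuple[str, str],
    kind: str = "hbond",
    cutoff: float | None = None,
) -> tuple[float, bool]:
    """Polar-pair distance between two labelled residues and a presence flag.

    kind='hbond': minimum over side-chain N/O atom pairs, default cutoff
    3.5 A.  kind='salt_bridge': minimum over charged-group N/O atoms
    (Asp/Glu carboxylate vs Arg/Lys/His nitrogens), default cutoff 4.0 A.
    Heavy-atom criterion only; deposited models lack hydrogens.
    """
    if kind not in ("hbond", "salt_bridge"):
        raise ValueError(f"kind must be 'hbond' or 'salt_bridge', got {kind!r}")
    if cutoff is None:
        cutoff = HBOND_CUTOFF if kind == "hbond" else SALT_BRIDGE_CUTOFF
    key_a, atoms_a = _residue_atoms(structure, nmap, pair[0])
    key_b, atoms_b = _residue_atoms(structure, nmap, pair[1])
    if kind == "salt_bridge":
        sel_a = _charged_group(key_a, atoms_a)
        sel_b = _charged_group(key_b, atoms_b)
    else:
        sel_a = _polar_sidechain(atoms_a)
        sel_b = _polar_sidechain(atoms_b)
    if not sel_a:
        raise ValueError(f"residue {key_a} has no qualifying polar atoms for {kind}")
    if not sel_b:
        raise ValueError(f"residue {key_b} has no qualifying polar atoms for {kind}")
    d = min_residue_distance(sel_a, sel_b, atoms="heavy")
    return d, d <= cutoff


def bundle_axis(
    structure: Structure,
    nmap: NumberingMap,
    intracellular_point: np.ndarray | None = None,
) -> np.ndarray:
    """Principal axis of all TM C-alpha atoms, intracellular-positive.

    The axis is the leading principal component of every C-alpha whose BW
    label belongs to TM1-TM7; orientation is fixed so the axis points from
    the extracellular toward the intracellular side, using the supplied
    intracellular reference point (e.g. the centroid of ICL residues).
    """
    coords = []
    for key, label in nmap.items():
        major = label.text.split(".")[0]
        if not major.isdigit() or not 1 <= int(major) <= 7:
            continue
        try:
            _, atoms = structure.find_residue(key.chain_id, key.seq_number, key.insertion_code)
        except KeyError:
            continue
        for atom in atoms:
            if atom.name == "CA":
                coords.append(atom.coord)
    coords = np.asarray(coords)
    if coords.shape[0] < 5:
        raise ValueError("too few TM C-alpha atoms to define a bundle axis")
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    axis = vt[0]
    if intracellular_point is not None:
        if np.dot(np.asarray(intracellular_point, float) - centroid, axis) < 0:
            axis = -axis
    return axis / np.linalg.norm(axis)


DEFAULT_CORE_MAJORS = (1, 2, 3, 4)


def _core_ca_pairs(
    active: Structure,
    inactive: Structure,
    map_active: NumberingMap,
    map_inactive: NumberingMap,
    core_labels: list[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired core C-alpha coordinates (active, inactive) by shared BW label."""
    if core_labels is None:
        labels_a = {l.text for _, l in map_active.items()}
        labels_i = {l.text for _, l in map_inactive.items()}
        core_labels = sorted(
            l
            for l in labels_a & labels_i
            if l.split(".")[0].isdigit() and int(l.split(".")[0]) in DEFAULT_CORE_MAJORS
        )
    xa, xi = [], []
    for label in core_labels:
        try:
            xa.append(_ca(active, map_active, label))
            xi.append(_ca(inactive, map_inactive, label))
        except (KeyError, ValueError):
            continue
    if len(xa) < 3:
        raise ValueError("fewer than 3 shared core C-alpha positions")
    return np.array(xa), np.array(xi)


def tm6_outward(
    active: Structure,
    inactive: Structure,
    map_active: NumberingMap,
    map_inactive: NumberingMap,
    probe_label: str = "6.30",
    core_labels: list[str] | None = None,
    intracellular_point: np.ndarray | None = None,
    axis: np.ndarray | None = None,
) -> float:
    """In-membrane-plane displacement (A) of the TM6 probe C-alpha.

    The active structure is superposed on the inactive one over the core
    C-alpha set (default TM1-TM4), then the probe C-alpha displacement is
    projected into the plane orthogonal to the bundle axis — the component
    that measures the outward opening of the G-protein crevice.  ``axis``
    overrides the fitted bundle axis when the membrane normal is known.
    """
    core_a, core_i = _core_ca_pairs(active, inactive, map_active, map_inactive, core_labels)
    sup = superpose(core_i, core_a)  # put active into the inactive frame
    probe_a = sup.transform(_ca(active, map_active, probe_label))
    probe_i = _ca(inactive, map_inactive, probe_label)
    if axis is None:
        axis = bundle_axis(inactive, map_inactive, intracellular_point)
    return in_plane_displacement(probe_i, probe_a, np.asarray(axis, float))


def tm7_downward(
    active: Structure,
    inactive: Structure,
    map_active: NumberingMap,
    map_inactive: NumberingMap,
    probe_labels: tuple[str, ...] = ("7.49", "7.50", "7.51", "7.52", "7.53"),
    core_labels: list[str] | None = None,
    intracellular_point: np.ndarray | None = None,
    axis: np.ndarray | None = None,
) -> float:
    """Mean signed displacement (A) of the TM7 motif C-alphas along the
    bundle axis, intracellular-positive ("downward" shifts are > 0)."""
    core_a, core_i = _core_ca_pairs(active, inactive, map_active, map_inactive, core_labels)
    sup = superpose(core_i, core_a)
    if axis is None:
        axis = bundle_axis(inactive, map_inactive, intracellular_point)
    axis = np.asarray(axis, float)
    disps = []
    for label in probe_labels:
        try:
            pa = sup.transform(_ca(active, map_active, label))
            pi = _ca(inactive, map_inactive, label)
        except (KeyError, ValueError):
            continue
        disps.append(displacement_along_axis(pi, pa, axis))
    if len(disps) < 2:
        raise ValueError("fewer than 2 resolvable TM7 probe residues")
    return float(np.mean(disps))


@dataclass
class HallmarkReport:
    """Activation-hallmark metrics for one receptor structure.

    Distances in Angstrom; ``tm6_outward``/``tm7_downward`` are None when no
    inactive reference was supplied.  ``notes`` records the conventions used
    per metric.
    """

    dry_salt_bridge_distance: float | None = None
    dry_salt_bridge_intact: bool | None = None
    r350_y558_hbond_distance: float | None = None
    r350_y558_hbond_present: bool | None = None
    gap_346_753: float | None = None
    contact_346_753: bool | None = None
    tm6_outward: float | None = None
    tm7_downward: float | None = None
    cavity_residues: list[str] = field(default_factory=list)
    notes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"schema": "hallmark-report/1", **asdict(self)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HallmarkReport":
        data = json.loads(text)
        data.pop("schema", None)
        return cls(**data)


CAVITY_PROBE_LABELS = ("3.46", "3.50", "7.49", "7.53")
CAVITY_RADIUS = 6.0


def _cavity_residues(structure: Structure, nmap: NumberingMap) -> list[str]:
    """BW labels of residues lining the 3.46-7.53 gap.

    The cavity centre is the midpoint of the closest heavy atoms of 3.46 and
    7.53; residues whose heavy atoms come within CAVITY_RADIUS of it line
    the cavity."""
    try:
        _, atoms_a = _residue_atoms(structure, nmap, "3.46")
        _, atoms_b = _residue_atoms(structure, nmap, "7.53")
    except KeyError:
        return []
    xa = np.array([a.coord for a in atoms_a if not a.is_hydrogen])
    xb = np.array([b.coord for b in atoms_b if not b.is_hydrogen])
    d2 = np.sum((xa[:, None] - xb[None, :]) ** 2, axis=-1)
    i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
    centre = 0.5 * (xa[i] + xb[j])
    labels = []
    for key, label in nmap.items():
        try:
            _, atoms = structure.find_residue(key.chain_id, key.seq_number, key.insertion_code)
        except KeyError:
            continue
        x = np.array([a.coord for a in atoms if not a.is_hydrogen])
        if x.size and np.min(np.linalg.norm(x - centre, axis=1)) <= CAVITY_RADIUS:
            labels.append(label.text)
    return sorted(labels)


def hallmark_report(
    active: Structure,
    map_active: NumberingMap,
    inactive: Structure | None = None,
    map_inactive: NumberingMap | None = None,
    intracellular_point: np.ndarray | None = None,
    axis: np.ndarray | None = None,
) -> HallmarkReport:
    """Compute every hallmark metric; reference-requiring metrics are left
    None when no inactive structure is given."""
    report = HallmarkReport()
    report.notes["distance_convention"] = "minimum heavy-atom distance between residues"
    report.notes["sign_convention"] = "bundle axis extracellular->intracellular positive"
    try:
        d, present = salt_bridge_or_hbond(active, map_active, ("3.49", "3.50"), kind="salt_bridge")
        report.dry_salt_bridge_distance = d
        report.dry_salt_bridge_intact = present
    except (KeyError, ValueError) as exc:
        report.notes["dry_salt_bridge"] = str(exc)
    try:
        d, present = salt_bridge_or_hbond(active, map_active, ("3.50", "5.58"), kind="hbond")
        report.r350_y558_hbond_distance = d
        report.r350_y558_hbond_present = present
    except (KeyError, ValueError) as exc:
        report.notes["r350_y558_hbond"] = str(exc)
    try:
        d, contact = motif_gap(active, map_active)
        report.gap_346_753 = d
        report.contact_346_753 = contact
    except (KeyError, ValueError) as exc:
        report.notes["gap_346_753"] = str(exc)
    report.cavity_residues = _cavity_residues(active, map_active)
    if inactive is not None and map_inactive is not None:
        report.tm6_outward = tm6_outward(
            active, inactive, map_active, map_inactive,
            intracellular_point=intracellular_point, axis=axis,
        )
        report.tm7_downward = tm7_downward(
            active, inactive, map_active, map_inactive,
            intracellular_point=intracellular_point, axis=axis,
        )
    else:
        report.notes["tm6_tm7"] = "no inactive reference supplied; displacement metrics unavailable"
    return report
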