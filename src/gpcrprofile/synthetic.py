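"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators build idealised 7TM helix bundles (with the receptor's generic
numbering laid out like an endothelin-receptor-type class-A GPCR), two-chain
receptor/G-alpha complexes with planted hydrogen bonds and hydrophobic
contacts, hydration trajectories with known local water density and planted
hydrogen-bond occupancy, and concentration-response / saturation-binding
datasets with known parameters.  Every generator returns a machine-readable
ground-truth ledger alongside its data; downstream tests consume the ledger
and never re-derive the truth by hand.

Bundles are built with the membrane normal along z and the intracellular
side at +z; the ledger records the intracellular reference point.  Helices
use a 96 degrees/residue turn (exactly 4 turns per 15 residues) so that the
principal axis of a helix's C-alpha cloud coincides exactly with its
geometric axis; the rise is 1.5 A/residue and the C-alpha radius 2.3 A.
Side chains use idealised atom templates pointing radially outward from the
bundle so that planted inter-residue distances are exact minima.

Construction is verified: after planting, every planted metric is recomputed
with plain numpy and generation fails loudly if a plant is infeasible or two
plants interfere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem
from .numbering import AnchorTable, GenericLabel, NumberingMap, build_bw_map
from .structio import Atom, ResidueKey, Structure, Trajectory

__all__ = [
    "BundleSpec",
    "BundleResult",
    "ComplexSpec",
    "ComplexResult",
    "HydrationSpec",
    "AssaySpec",
    "make_bundle",
    "make_bundle_pair",
    "make_complex",
    "make_hydration_traj",
    "make_hbond_traj",
    "make_dose_response_data",
    "make_saturation_binding_data",
    "make_random_interface",
]

RISE = 1.5  # A per residue
TURN = math.radians(96.0)  # 15 residues = exactly 4 turns
CA_RADIUS = 2.3
BUNDLE_RADIUS = 10.0
Z_INTRACELLULAR = 10.0  # z level of the intracellular helix ends

# receptor segment layout: author-numbered like the endothelin ET_B receptor,
# (first_author, first_minor, last_minor, direction); direction +1 means the
# generic minor index grows toward the intracellular (+z) side
SEGMENTS: dict[str, tuple[int, int, int, int]] = {
    "TM1": (96, 36, 57, +1),
    "TM2": (135, 38, 57, -1),
    "TM3": (185, 36, 56, +1),
    "TM4": (225, 38, 57, -1),
    "TM5": (275, 40, 66, +1),
    "TM6": (314, 26, 48, -1),
    "TM7": (366, 33, 56, +1),
}
ANCHOR_MINOR = {"TM1": 50, "TM2": 50, "TM3": 50, "TM4": 50, "TM5": 58, "TM6": 30, "TM7": 50}

# residue identities at the positions the hallmark/interface metrics probe
RESIDUE_NAMES: dict[int, str] = {
    140: "ILE",  # 2.43
    147: "ASP",  # 2.50
    195: "LEU",  # 3.46
    198: "ASP",  # 3.49
    199: "ARG",  # 3.50
    202: "ALA",  # 3.53
    203: "VAL",  # 3.54
    293: "TYR",  # 5.58
    296: "MET",  # 5.61
    300: "MET",  # 5.65
    314: "HIS",  # 6.26
    318: "ARG",  # 6.30
    321: "VAL",  # 6.33
    324: "THR",  # 6.36
    325: "VAL",  # 6.37
    379: "SER",  # 7.46
    382: "ASN",  # 7.49
    383: "PRO",  # 7.50
    386: "LEU",  # 7.53
    389: "VAL",  # 7.56
    390: "SER",  # 8.47
}

# intracellular loop residues (author number, name, loop tag)
LOOP_RESIDUES = [
    (134, "ASN", "ICL1"),
    (206, "TRP", "ICL2"),
    (207, "ALA", "ICL2"),
    (208, "ARG", "ICL2"),
    (209, "ILE", "ICL2"),
    (210, "LYS", "ICL2"),
]

H8_RESIDUES = [(390, 47), (391, 48), (392, 49), (393, 50), (394, 51), (395, 52)]

# G-alpha-i1 alpha5 helix + wavy hook, residues 340-354
ALPHA5_SEQ = "TDTIIKNNLKDCGLF"
ALPHA5_START = 340


# ---------------------------------------------------------------------------
# low-level builders


def _residue_atoms_at(
    name: str, ca: np.ndarray, u_r: np.ndarray, u_t: np.ndarray, u_z: np.ndarray
) -> list[Atom]:
    """Backbone + template side chain in a local frame (u_r radially out)."""
    atoms = [
        Atom("N", "N", ca - 1.2 * u_t + 0.3 * u_z),
        Atom("CA", "C", ca.copy()),
        Atom("C", "C", ca + 1.2 * u_t + 0.4 * u_z),
        Atom("O", "O", ca + 1.6 * u_t + 1.5 * u_z),
    ]
    for atom_name, element, (x, y, z) in chem.SIDECHAIN_TEMPLATES.get(name.upper(), []):
        atoms.append(Atom(atom_name, element, ca + x * u_r + y * u_t + z * u_z))
    return atoms


def _helix_frame(axis_xy: np.ndarray, i: int, z: float, phase: float):
    """CA position and local frame for residue i of a vertical helix."""
    ang = phase + i * TURN
    ca = np.array(
        [
            axis_xy[0] + CA_RADIUS * math.cos(ang),
            axis_xy[1] + CA_RADIUS * math.sin(ang),
            z,
        ]
    )
    # side chains point radially outward from the bundle centre (origin),
    # keeping inter-helix side-chain collisions out of the picture
    r_xy = np.array([ca[0], ca[1], 0.0])
    nrm = np.linalg.norm(r_xy)
    u_r = r_xy / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    u_z = np.array([0.0, 0.0, 1.0])
    u_t = np.cross(u_z, u_r)
    return ca, u_r, u_t, u_z


@dataclass
class BundleSpec:
    """Recipe for a synthetic 7TM bundle with planted hallmark geometry.

    Distances are minimum heavy-atom distances (None = leave unplanted);
    tm6_outward / tm7_downward are displacements applied to the *active*
    copy of a bundle pair.  All randomness (jitter of helix placement,
    direction of the TM6 shift) derives from the seed.
    """

    seed: int = 0
    gap_346_753: float | None = 7.3
    dry_salt_bridge: float | None = None
    r350_y558_hbond: float | None = None
    tm6_outward: float = 7.0
    tm7_downward: float = 1.5
    bundle_radius: float = BUNDLE_RADIUS
    placement_jitter: float = 0.0  # A, rigid in-plane jitter per helix
    chain_id: str = "R"
    include_loops: bool = True


@dataclass
class BundleResult:
    structure: Structure
    anchors: AnchorTable
    bw_map: NumberingMap
    ledger: dict
    intracellular_point: np.ndarray


def _build_base_bundle(spec: BundleSpec, rng: np.random.Generator) -> Structure:
    st = Structure(metadata={"generator": "make_bundle", "seed": spec.seed})
    chain = spec.chain_id
    n_helices = len(SEGMENTS)
    for k, (seg, (first_author, lo, hi, direction)) in enumerate(SEGMENTS.items()):
        ang = 2 * math.pi * k / n_helices
        axis_xy = spec.bundle_radius * np.array([math.cos(ang), math.sin(ang)])
        if spec.placement_jitter > 0:
            axis_xy = axis_xy + rng.uniform(-spec.placement_jitter, spec.placement_jitter, 2)
        n_res = hi - lo + 1
        phase = float(rng.uniform(0, 2 * math.pi)) if spec.placement_jitter > 0 else 0.0
        for i in range(n_res):
            author = first_author + i
            # +1: minor grows intracellular, last residue ends at z_ic
            z = Z_INTRACELLULAR - RISE * ((n_res - 1 - i) if direction > 0 else i)
            ca, u_r, u_t, u_z = _helix_frame(axis_xy, i, z, phase)
            name = RESIDUE_NAMES.get(author, "ALA")
            key = ResidueKey(chain, author, "", name)
            for atom in _residue_atoms_at(name, ca, u_r, u_t, u_z):
                st.add_atom(key, atom)
    # helix 8: short stretch running radially outward at the intracellular side
    tm7_ang = 2 * math.pi * 6 / n_helices
    h8_dir = np.array([math.cos(tm7_ang), math.sin(tm7_ang), 0.0])
    h8_start = spec.bundle_radius * h8_dir + np.array([0.0, 0.0, Z_INTRACELLULAR + 2.0])
    for j, (author, _minor) in enumerate(H8_RESIDUES):
        ca = h8_start + (j + 1) * 5.0 * h8_dir
        name = RESIDUE_NAMES.get(author, "ALA")
        key = ResidueKey(chain, author, "", name)
        # side chains point toward the intracellular space (+z), clear of
        # both the helix bundle above and the neighbouring H8 residues
        u_r = np.array([0.0, 0.0, 1.0])
        u_t = np.cross(h8_dir, u_r)
        for atom in _residue_atoms_at(name, ca, u_r, u_t, h8_dir):
            st.add_atom(key, atom)
    if spec.include_loops:
        # intracellular loops placed below the helix ends, between their TMs
        icl1_xy = spec.bundle_radius * 1.25 * np.array(
            [math.cos(2 * math.pi * 0.5 / n_helices), math.sin(2 * math.pi * 0.5 / n_helices)]
        )
        icl2_xy = spec.bundle_radius * 1.25 * np.array(
            [math.cos(2 * math.pi * 2.5 / n_helices), math.sin(2 * math.pi * 2.5 / n_helices)]
        )
        for idx, (author, name, tag) in enumerate(LOOP_RESIDUES):
            base = icl1_xy if tag == "ICL1" else icl2_xy
            ca = np.array([base[0], base[1], Z_INTRACELLULAR + 3.0]) + np.array(
                [0.0, 0.0, 0.0]
            )
            # spread ICL2 residues along the loop direction
            if tag == "ICL2":
                perp = np.array([-base[1], base[0], 0.0])
                perp /= np.linalg.norm(perp)
                ca = ca + (idx - 3) * 5.0 * perp
            u_r = base / np.linalg.norm(base)
            u_r = np.array([u_r[0], u_r[1], 0.0])
            u_z = np.array([0.0, 0.0, 1.0])
            u_t = np.cross(u_z, u_r)
            key = ResidueKey(chain, author, "", name)
            for atom in _residue_atoms_at(name, ca, u_r, u_t, u_z):
                st.add_atom(key, atom)
    return st


def _bundle_anchor_table(chain_id: str) -> AnchorTable:
    table = AnchorTable(chain_id=chain_id)
    for seg, (first_author, lo, hi, _direction) in SEGMENTS.items():
        tm = seg[2]
        anchor_minor = ANCHOR_MINOR[seg]
        anchor_author = first_author + (anchor_minor - lo)
        table.anchors[seg] = (anchor_author, f"{tm}.{anchor_minor}")
        table.segment_ranges[seg] = (first_author, first_author + (hi - lo))
    # helix 8 as an eighth offset segment
    table.anchors["H8"] = (390, "8.47")
    table.segment_ranges["H8"] = (390, 395)
    return table


def _bundle_bw_map(structure: Structure, anchors: AnchorTable, include_loops: bool) -> NumberingMap:
    nmap = build_bw_map(structure, anchors)
    if include_loops:
        for author, name, tag in LOOP_RESIDUES:
            try:
                key, _ = structure.find_residue(anchors.chain_id, author)
            except KeyError:
                continue
            nmap.add(key, GenericLabel("BW", f"{tag}.{author}"))
    return nmap


# ---------------------------------------------------------------------------
# planting


def _heavy(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if not a.is_hydrogen]


def _min_dist(atoms_a: list[Atom], atoms_b: list[Atom]) -> float:
    xa = np.array([a.coord for a in atoms_a])
    xb = np.array([b.coord for b in atoms_b])
    return float(np.sqrt(np.min(np.sum((xa[:, None] - xb[None, :]) ** 2, axis=-1))))


BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


def _plant_pair(
    atoms_a: list[Atom],
    atoms_b: list[Atom],
    a_name: str,
    b_name: str,
    distance: float,
    direction: np.ndarray,
    check_sets: tuple[list[Atom], list[Atom]] | None = None,
    max_iter: int = 60,
) -> None:
    """Place atom ``b_name`` of B exactly ``distance`` from atom ``a_name`` of
    A along ``direction``, then push interfering side-chain atoms apart so
    the planted pair is the strict minimum over the check sets (default: all
    heavy atoms of the two residues).  Backbone atoms are never moved;
    raises if the plant cannot be realised without moving one.
    """
    a = next(x for x in atoms_a if x.name == a_name)
    b = next(x for x in atoms_b if x.name == b_name)
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    b.coord = a.coord + distance * u
    set_a, set_b = check_sets if check_sets is not None else (_heavy(atoms_a), _heavy(atoms_b))
    for _ in range(max_iter):
        clean = True
        for x in set_a:
            for y in set_b:
                if x is a and y is b:
                    continue
                d = float(np.linalg.norm(x.coord - y.coord))
                if d <= distance + 0.3:
                    movers = [m for m in (y, x) if m is not a and m is not b]
                    movers = [m for m in movers if m.name not in BACKBONE_NAMES]
                    if not movers:
                        raise ValueError(
                            f"plant {a_name}..{b_name} at {distance} A would "
                            f"require moving a backbone atom ({x.name}/{y.name})"
                        )
                    mover = movers[0]
                    other = x if mover is y else y
                    away = mover.coord - other.coord
                    n = np.linalg.norm(away)
                    away = away / n if n > 1e-9 else u
                    mover.coord = mover.coord + (distance + 0.5 - d) * away
                    clean = False
        if clean:
            break
    else:
        raise ValueError(f"infeasible plant: {a_name}..{b_name} at {distance} A")
    got = _min_dist(set_a, set_b)
    if abs(got - distance) > 1e-9:
        raise ValueError(
            f"plant verification failed: wanted {distance}, got {got} for {a_name}..{b_name}"
        )


def _plant_spread(
    origin: np.ndarray,
    atoms_a: list[Atom],
    atoms_b: list[Atom],
    a_name: str,
    b_name: str,
    distance: float,
    relocate_a: tuple[str, ...] = (),
    relocate_b: tuple[str, ...] = (),
    spread: float = 2.2,
) -> None:
    """Deterministic exact plant in free space.

    Atom ``a_name`` goes to ``origin``, ``b_name`` to ``origin + d*z``; any
    named companion atoms are parked on perpendicular rakes (+x for A, +y
    for B) so every non-planted pair is strictly farther than ``distance``.
    """
    a = next(x for x in atoms_a if x.name == a_name)
    b = next(x for x in atoms_b if x.name == b_name)
    origin = np.asarray(origin, float)
    a.coord = origin.copy()
    b.coord = origin + np.array([0.0, 0.0, distance])
    for k, name in enumerate(relocate_a):
        atom = next(x for x in atoms_a if x.name == name)
        atom.coord = origin + np.array([(k + 1) * spread, 0.0, 0.0])
    for k, name in enumerate(relocate_b):
        atom = next(x for x in atoms_b if x.name == name)
        atom.coord = b.coord + np.array([0.0, (k + 1) * spread, 0.0])


def _polar_sidechain_atoms(key: ResidueKey, atoms: list[Atom]) -> list[Atom]:
    return [
        a
        for a in atoms
        if a.element.upper() in ("N", "O") and a.name not in ("N", "CA", "C", "O", "OXT")
    ]


def _charged_atoms(key: ResidueKey, atoms: list[Atom]) -> list[Atom]:
    names = chem.CHARGED_POSITIVE.get(key.residue_name.upper()) or chem.CHARGED_NEGATIVE.get(
        key.residue_name.upper(), ()
    )
    return [a for a in atoms if a.name in names]


def make_bundle(spec: BundleSpec) -> BundleResult:
    """Build one bundle with the spec's planted static distances."""
    rng = np.random.default_rng(spec.seed)
    st = _build_base_bundle(spec, rng)
    anchors = _bundle_anchor_table(spec.chain_id)
    ledger: dict = {
        "seed": spec.seed,
        "intracellular_point": [0.0, 0.0, Z_INTRACELLULAR + 40.0],
        "bundle_axis": [0.0, 0.0, 1.0],
    }
    chain = spec.chain_id

    _plant_statics(st, spec, ledger)
    bw_map = _bundle_bw_map(st, anchors, spec.include_loops)
    return BundleResult(
        structure=st,
        anchors=anchors,
        bw_map=bw_map,
        ledger=ledger,
        intracellular_point=np.array([0.0, 0.0, Z_INTRACELLULAR + 40.0]),
    )


def make_bundle_pair(spec: BundleSpec) -> tuple[BundleResult, BundleResult, dict]:
    """An (active, inactive) bundle pair with planted TM6/TM7 displacements.

    The inactive bundle is the unshifted base; the active copy has every
    TM6 residue translated laterally by ``tm6_outward`` A (direction seeded)
    and the TM7 + helix-8 residues translated by ``tm7_downward`` A toward
    the intracellular side (+z).  Static distance plants are applied to the
    active copy after the shifts.
    """
    rng = np.random.default_rng(spec.seed)
    base_spec = replace(
        spec, gap_346_753=None, dry_salt_bridge=None, r350_y558_hbond=None
    )
    inactive = make_bundle(base_spec)
    active_st = inactive.structure.copy()
    chain = spec.chain_id

    theta = float(np.random.default_rng(spec.seed + 1).uniform(0, 2 * math.pi))
    lateral = spec.tm6_outward * np.array([math.cos(theta), math.sin(theta), 0.0])
    tm6_first, lo, hi, _ = SEGMENTS["TM6"]
    for seq in range(tm6_first, tm6_first + (hi - lo) + 1):
        _, atoms = active_st.find_residue(chain, seq)
        for atom in atoms:
            atom.coord = atom.coord + lateral
    axial = np.array([0.0, 0.0, spec.tm7_downward])
    tm7_first, lo7, hi7, _ = SEGMENTS["TM7"]
    tm7_seqs = list(range(tm7_first, tm7_first + (hi7 - lo7) + 1)) + [a for a, _ in H8_RESIDUES]
    for seq in tm7_seqs:
        _, atoms = active_st.find_residue(chain, seq)
        for atom in atoms:
            atom.coord = atom.coord + axial

    # re-apply static plants on the shifted copy
    active = BundleResult(
        structure=active_st,
        anchors=inactive.anchors,
        bw_map=_bundle_bw_map(active_st, inactive.anchors, spec.include_loops),
        ledger=dict(inactive.ledger),
        intracellular_point=inactive.intracellular_point,
    )
    _plant_statics(active_st, spec, active.ledger)

    ledger = dict(active.ledger)
    ledger.update(
        {
            "tm6_outward": spec.tm6_outward,
            "tm7_downward": spec.tm7_downward,
            "tm6_direction": lateral.tolist(),
        }
    )
    active.ledger = ledger
    return active, inactive, ledger


def _plant_statics(st: Structure, spec: BundleSpec, ledger: dict) -> None:
    """Apply the spec's static distance plants in the free space just below
    the intracellular mouth of the bundle, then verify each planted minimum.

    Each plant gets its own well-separated site so plants on overlapping
    residues (e.g. R3.50 in both the DRY salt bridge and the R-Y hydrogen
    bond) cannot interfere.
    """
    chain = spec.chain_id
    if spec.gap_346_753 is not None:
        _, atoms_a = st.find_residue(chain, 195)  # L3.46
        _, atoms_b = st.find_residue(chain, 386)  # L7.53
        _plant_spread(
            np.array([0.0, 0.0, Z_INTRACELLULAR + 3.0]),
            atoms_a, atoms_b, "CD1", "CD1", spec.gap_346_753,
        )
        got = _min_dist(_heavy(atoms_a), _heavy(atoms_b))
        if abs(got - spec.gap_346_753) > 1e-9:
            raise ValueError(f"gap plant failed: wanted {spec.gap_346_753}, got {got}")
        ledger["gap_346_753"] = spec.gap_346_753
        ledger["contact_346_753"] = spec.gap_346_753 <= 4.5
    if spec.dry_salt_bridge is not None:
        key_a, atoms_a = st.find_residue(chain, 198)  # D3.49
        key_b, atoms_b = st.find_residue(chain, 199)  # R3.50
        _plant_spread(
            np.array([7.0, 0.0, Z_INTRACELLULAR + 4.0]),
            atoms_a, atoms_b, "OD1", "NH1", spec.dry_salt_bridge,
            relocate_a=("OD2",), relocate_b=("NE", "NH2"),
        )
        ledger["dry_salt_bridge"] = spec.dry_salt_bridge
    if spec.r350_y558_hbond is not None:
        key_a, atoms_a = st.find_residue(chain, 199)  # R3.50
        key_b, atoms_b = st.find_residue(chain, 293)  # Y5.58
        _plant_spread(
            np.array([-7.0, 0.0, Z_INTRACELLULAR + 4.0]),
            atoms_a, atoms_b, "NH2", "OH", spec.r350_y558_hbond,
        )
        ledger["r350_y558_hbond"] = spec.r350_y558_hbond
    # verify the polar-set minima after all plants (shared residues)
    if spec.dry_salt_bridge is not None:
        key_a, atoms_a = st.find_residue(chain, 198)
        key_b, atoms_b = st.find_residue(chain, 199)
        got = _min_dist(_charged_atoms(key_a, atoms_a), _charged_atoms(key_b, atoms_b))
        if abs(got - spec.dry_salt_bridge) > 1e-9:
            raise ValueError(f"salt-bridge plant failed: wanted {spec.dry_salt_bridge}, got {got}")
    if spec.r350_y558_hbond is not None:
        key_a, atoms_a = st.find_residue(chain, 199)
        key_b, atoms_b = st.find_residue(chain, 293)
        got = _min_dist(
            _polar_sidechain_atoms(key_a, atoms_a), _polar_sidechain_atoms(key_b, atoms_b)
        )
        if abs(got - spec.r350_y558_hbond) > 1e-9:
            raise ValueError(f"R-Y hbond plant failed: wanted {spec.r350_y558_hbond}, got {got}")


# ---------------------------------------------------------------------------
# complexes


@dataclass
class ComplexSpec:
    """Receptor bundle + G-alpha alpha5 helix with planted interface contacts.

    ``planted_hbonds`` / ``planted_vdw`` are lists of
    (receptor_author_seq, receptor_atom, ga_author_seq, ga_atom, distance);
    hydrogen-bond distances must be <= the hbond cutoff and vdW distances in
    (hbond_cutoff, vdw_cutoff].  ``alpha5_tilt_deg`` tilts the alpha5 axis
    away from the bundle axis in the x-z plane.
    """

    seed: int = 0
    bundle: BundleSpec = field(default_factory=lambda: BundleSpec(gap_346_753=None))
    alpha5_tilt_deg: float = 10.0
    ga_chain: str = "A"
    standoff: float = 18.0  # gap between receptor IC side and alpha5 centre
    hbond_cutoff: float = 3.5
    vdw_cutoff: float = 4.5
    planted_hbonds: list[tuple] = field(
        default_factory=lambda: [
            (318, "NH1", 341, "OD1", 2.9),  # 6.30 .. H5.13
            (208, "NH1", 347, "OD1", 2.9),  # ICL2 .. H5.19
            (134, "ND2", 350, "OD1", 2.9),  # ICL1 .. H5.22
            (390, "OG", 354, "OXT", 2.9),  # 8.47 .. H5.26 C-terminal carboxylate
        ]
    )
    planted_vdw: list[tuple] = field(
        default_factory=lambda: [
            (203, "CG1", 348, "CD1", 4.0),  # 3.54 .. H5.20
            (296, "CE", 348, "CD2", 4.0),  # 5.61 .. H5.20
            (300, "CE", 348, "CG", 4.0),  # 5.65 .. H5.20
            (321, "CG1", 353, "CD1", 4.0),  # 6.33 .. H5.25
            (325, "CG1", 353, "CD2", 4.0),  # 6.37 .. H5.25
            (389, "CG1", 353, "CG", 4.0),  # 7.56 .. H5.25
        ]
    )


@dataclass
class ComplexResult:
    structure: Structure
    bw_map: NumberingMap
    cgn_map: NumberingMap
    ledger: dict
    intracellular_point: np.ndarray


THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _build_alpha5(spec: ComplexSpec, keep_full: set[int]) -> Structure:
    """alpha5 helix of G-alpha-i1 (340-354) below the receptor, tilted in x-z.

    Side chains are truncated at CB except for residues taking part in
    planted contacts (``keep_full``), keeping the unplanted helix body clear
    of the interface.
    """
    st = Structure(metadata={"generator": "alpha5"})
    tilt = math.radians(spec.alpha5_tilt_deg)
    axis = np.array([math.sin(tilt), 0.0, math.cos(tilt)])  # unit
    e1 = np.array([math.cos(tilt), 0.0, -math.sin(tilt)])
    e2 = np.array([0.0, 1.0, 0.0])
    n = len(ALPHA5_SEQ)
    centre = np.array([0.0, 0.0, Z_INTRACELLULAR + spec.standoff])
    start = centre - axis * RISE * (n - 1) / 2.0
    for i, letter in enumerate(ALPHA5_SEQ):
        author = ALPHA5_START + i
        name = THREE_LETTER[letter]
        ang = i * TURN
        # C-terminus-first insertion: the wavy hook (F354) sits nearest the
        # receptor's intracellular mouth, the helix runs away from it
        ca = start + axis * RISE * (n - 1 - i) + CA_RADIUS * (
            math.cos(ang) * e1 + math.sin(ang) * e2
        )
        u_r = math.cos(ang) * e1 + math.sin(ang) * e2
        u_t = np.cross(axis, u_r)
        key = ResidueKey(spec.ga_chain, author, "", name)
        atoms = _residue_atoms_at(name, ca, u_r, u_t, axis)
        if author not in keep_full:
            atoms = [a for a in atoms if a.name in ("N", "CA", "C", "O", "CB")]
        for atom in atoms:
            st.add_atom(key, atom)
    # C-terminal carboxylate oxygen on the final residue
    key, atoms = st.find_residue(spec.ga_chain, ALPHA5_START + n - 1)
    c = next(a for a in atoms if a.name == "C")
    st.add_atom(key, Atom("OXT", "O", c.coord + np.array([0.0, 0.6, -1.2])))
    return st


def make_complex(spec: ComplexSpec) -> ComplexResult:
    """Two-chain receptor/G-alpha model with an exact planted contact ledger.

    After planting, every cross-chain residue pair is classified with a
    plain-numpy scan; generation fails if the realised contact set differs
    from the planted one (interfering plants, accidental contacts).
    """
    bundle = make_bundle(replace(spec.bundle, seed=spec.seed))
    st = bundle.structure

    r_chain = spec.bundle.chain_id
    g_chain = spec.ga_chain
    planted: list[tuple] = []
    for r_seq, r_atom, g_seq, g_atom, d in spec.planted_hbonds:
        if d > spec.hbond_cutoff:
            raise ValueError(f"planted hbond distance {d} exceeds cutoff {spec.hbond_cutoff}")
        planted.append((r_seq, g_seq, "hbond", d, r_atom, g_atom))
    for r_seq, r_atom, g_seq, g_atom, d in spec.planted_vdw:
        if not spec.hbond_cutoff < d <= spec.vdw_cutoff:
            raise ValueError(
                f"planted vdW distance {d} must lie in ({spec.hbond_cutoff}, {spec.vdw_cutoff}]"
            )
        planted.append((r_seq, g_seq, "vdw", d, r_atom, g_atom))

    keep_full = {g_seq for _r, g_seq, _k, _d, _ra, _ga in planted} | {ALPHA5_START + len(ALPHA5_SEQ) - 1}
    a5 = _build_alpha5(spec, keep_full)
    for key, atom in a5.atoms():
        st.add_atom(key, atom)

    # each plant gets its own site on a ring in the free space between the
    # receptor's intracellular mouth and the alpha5 helix
    for idx, (r_seq, g_seq, _kind, d, r_atom_name, g_atom_name) in enumerate(planted):
        ang = 2 * math.pi * idx / max(len(planted), 1)
        site = np.array(
            [16.0 * math.cos(ang), 16.0 * math.sin(ang), Z_INTRACELLULAR + 10.0]
        )
        _, r_atoms = st.find_residue(r_chain, r_seq)
        _, g_atoms = st.find_residue(g_chain, g_seq)
        _plant_spread(site, r_atoms, g_atoms, r_atom_name, g_atom_name, d)

    _verify_complex(st, r_chain, g_chain, planted, spec.hbond_cutoff, spec.vdw_cutoff)

    ledger = {
        "seed": spec.seed,
        "alpha5_tilt_deg": spec.alpha5_tilt_deg,
        "contacts": [
            {
                "receptor_seq": r_seq,
                "ga_seq": g_seq,
                "type": kind,
                "distance": d,
                "atoms": [ra, ga],
            }
            for r_seq, g_seq, kind, d, ra, ga in planted
        ],
        "hbond_count": sum(1 for p in planted if p[2] == "hbond"),
        "vdw_count": sum(1 for p in planted if p[2] == "vdw"),
        "intracellular_point": bundle.ledger["intracellular_point"],
    }
    cgn_map = NumberingMap("CGN")
    for i in range(len(ALPHA5_SEQ)):
        author = ALPHA5_START + i
        key, _ = st.find_residue(g_chain, author)
        cgn_map.add(key, GenericLabel("CGN", f"H5.{author - 328}"))
    return ComplexResult(
        structure=st,
        bw_map=bundle.bw_map,
        cgn_map=cgn_map,
        ledger=ledger,
        intracellular_point=bundle.intracellular_point,
    )


def _verify_complex(
    st: Structure,
    r_chain: str,
    g_chain: str,
    planted: list[tuple],
    hbond_cutoff: float,
    vdw_cutoff: float,
) -> None:
    """Plain-numpy cross-chain classification; must equal the planted set."""
    expected = {(r, g): (kind, d) for r, g, kind, d, _, _ in planted}
    found: dict[tuple[int, int], tuple[str, float]] = {}
    r_res = [(k, v) for k, v in st.residues.items() if k.chain_id == r_chain]
    g_res = [(k, v) for k, v in st.residues.items() if k.chain_id == g_chain]
    for rk, ratoms in r_res:
        rh = _heavy(ratoms)
        r_names = {a.name for a in rh}
        for gk, gatoms in g_res:
            gh = _heavy(gatoms)
            dmin = _min_dist(rh, gh)
            if dmin > vdw_cutoff:
                continue
            g_names = {a.name for a in gh}
            r_d = set(chem.donor_atoms(rk.residue_name, r_names))
            r_a = set(chem.acceptor_atoms(rk.residue_name, r_names))
            g_d = set(chem.donor_atoms(gk.residue_name, g_names))
            g_a = set(chem.acceptor_atoms(gk.residue_name, g_names))
            polar_min = math.inf
            for x in rh:
                for y in gh:
                    ok = (x.name in r_d and y.name in g_a) or (
                        x.name in r_a and y.name in g_d
                    )
                    if ok:
                        polar_min = min(polar_min, float(np.linalg.norm(x.coord - y.coord)))
            if polar_min <= hbond_cutoff:
                found[(rk.seq_number, gk.seq_number)] = ("hbond", polar_min)
            else:
                found[(rk.seq_number, gk.seq_number)] = ("vdw", dmin)
    if set(found) != set(expected):
        extra = set(found) - set(expected)
        missing = set(expected) - set(found)
        raise ValueError(
            f"contact plants interfered: unplanned={sorted(extra)}, missing={sorted(missing)}"
        )
    for pair, (kind, d) in expected.items():
        got_kind, got_d = found[pair]
        if got_kind != kind or abs(got_d - d) > 1e-9:
            raise ValueError(
                f"plant verification failed for {pair}: wanted {kind}@{d}, got {got_kind}@{got_d}"
            )


def make_random_interface(seed: int, n_per_chain: int = 10, box: float = 18.0) -> Structure:
    """A randomised two-chain residue soup for oracle comparisons.

    Residues are random amino acids with template side chains at random
    positions/orientations in a box; no ledger — truth comes from a
    brute-force scan in the consuming test.
    """
    rng = np.random.default_rng(seed)
    st = Structure(metadata={"generator": "make_random_interface", "seed": seed})
    names = list(chem.SIDECHAIN_TEMPLATES)
    for chain, z_off in (("R", 0.0), ("A", 6.0)):
        for i in range(n_per_chain):
            name = names[int(rng.integers(len(names)))]
            ca = rng.uniform(0, box, 3) + np.array([0.0, 0.0, z_off])
            # random orthonormal frame
            q = rng.normal(size=(3, 3))
            u, _, vt = np.linalg.svd(q)
            rot = u @ vt
            if np.linalg.det(rot) < 0:
                rot[:, 0] = -rot[:, 0]
            key = ResidueKey(chain, i + 1, "", name)
            for atom in _residue_atoms_at(name, ca, rot[:, 0], rot[:, 1], rot[:, 2]):
                st.add_atom(key, atom)
    return st


# ---------------------------------------------------------------------------
# hydration + hydrogen-bond trajectories


@dataclass
class HydrationSpec:
    """Uniform water bath with an optional planted high-density hotspot.

    ``density`` is the bulk number density in waters/A^3 (0.0334 matches
    ambient liquid water); the hotspot multiplies the local density inside a
    sphere.  Waters are i.i.d. uniform each frame, so the density grid
    estimator can be checked against its analytic expectation.
    """

    box: float = 12.0
    density: float = 0.0334
    frames: int = 50
    seed: int = 0
    hotspot_center: np.ndarray | None = None
    hotspot_radius: float = 2.0
    hotspot_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.box <= 0:
            raise ValueError("density and box must be positive")
        if self.hotspot_multiplier < 1.0 and self.hotspot_center is not None:
            raise ValueError("hotspot depletion (multiplier < 1) is not supported")


def make_hydration_traj(spec: HydrationSpec) -> tuple[Trajectory, dict]:
    """Waters i.i.d. uniform at the stated density, plus a static 3-atom
    anchor chain for superposition selections."""
    rng = np.random.default_rng(spec.seed)
    n_base = round(spec.density * spec.box**3)
    n_extra = 0
    if spec.hotspot_center is not None and spec.hotspot_multiplier > 1.0:
        v_hot = 4.0 / 3.0 * math.pi * spec.hotspot_radius**3
        n_extra = round(spec.density * (spec.hotspot_multiplier - 1.0) * v_hot)
    topo = Structure(metadata={"generator": "make_hydration_traj", "seed": spec.seed})
    anchor = ResidueKey("R", 1, "", "GLY")
    topo.add_atom(anchor, Atom("N", "N", np.array([-3.0, -3.0, -3.0])))
    topo.add_atom(anchor, Atom("CA", "C", np.array([-5.0, -3.0, -3.0])))
    topo.add_atom(anchor, Atom("C", "C", np.array([-4.0, -5.0, -3.0])))
    for j in range(n_base + n_extra):
        topo.add_atom(ResidueKey("W", j + 1, "", "HOH"), Atom("O", "O", np.zeros(3)))
    anchor_xyz = topo.coords()[:3]
    frames = []
    for _t in range(spec.frames):
        waters = rng.uniform(0, spec.box, size=(n_base, 3))
        if n_extra:
            # uniform points in the hotspot sphere
            pts = []
            while len(pts) < n_extra:
                cand = rng.uniform(-1, 1, size=(n_extra * 2, 3))
                cand = cand[np.sum(cand**2, axis=1) <= 1.0]
                pts.extend(cand)
            extra = np.array(pts[:n_extra]) * spec.hotspot_radius + spec.hotspot_center
            waters = np.vstack([waters, extra])
        frames.append(np.vstack([anchor_xyz, waters]))
    ledger = {
        "density": spec.density,
        "n_waters": n_base + n_extra,
        "frames": spec.frames,
        "hotspot": None
        if spec.hotspot_center is None
        else {
            "center": np.asarray(spec.hotspot_center, float).tolist(),
            "radius": spec.hotspot_radius,
            "multiplier": spec.hotspot_multiplier,
        },
    }
    return Trajectory(topology=topo, frames=frames), ledger


def make_hbond_traj(occupancy: float, frames: int, seed: int = 0) -> tuple[Trajectory, dict]:
    """Arg/Asp pair hydrogen-bonded in exactly round(occupancy * frames) frames.

    The donor (Arg NH1) sits 2.8 A from the acceptor (Asp OD1) in bonded
    frames and 8 A away otherwise; which frames are bonded is a seeded
    permutation, so the realised occupancy is exact by construction.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    topo = Structure(metadata={"generator": "make_hbond_traj", "seed": seed})
    arg = ResidueKey("R", 1, "", "ARG")
    asp = ResidueKey("R", 2, "", "ASP")
    # backbone atoms parked far away so only side chains can interact
    topo.add_atom(arg, Atom("N", "N", np.array([0.0, 20.0, 0.0])))
    topo.add_atom(arg, Atom("CA", "C", np.array([1.5, 20.0, 0.0])))
    topo.add_atom(arg, Atom("NE", "N", np.array([6.0, 2.0, 0.0])))
    topo.add_atom(arg, Atom("NH1", "N", np.array([8.0, 0.0, 0.0])))
    topo.add_atom(arg, Atom("NH2", "N", np.array([8.0, 3.0, 0.0])))
    topo.add_atom(asp, Atom("CA", "C", np.array([-1.5, 0.0, 0.0])))
    topo.add_atom(asp, Atom("CG", "C", np.array([-1.0, 1.0, 0.0])))
    topo.add_atom(asp, Atom("OD1", "O", np.array([0.0, 0.0, 0.0])))
    topo.add_atom(asp, Atom("OD2", "O", np.array([-1.0, -1.2, 0.0])))
    base = topo.coords()
    n_bonded = round(occupancy * frames)
    order = np.random.default_rng(seed).permutation(frames)
    bonded_frames = set(int(i) for i in order[:n_bonded])
    nh1_index = 3  # flat order above
    frames_list = []
    for t in range(frames):
        xyz = base.copy()
        if t in bonded_frames:
            xyz[nh1_index] = np.array([2.8, 0.0, 0.0])  # 2.8 A from OD1
        frames_list.append(xyz)
    ledger = {
        "occupancy": n_bonded / frames,
        "n_bonded": n_bonded,
        "frames": frames,
        "donor": ["R", 1],
        "acceptor": ["R", 2],
    }
    return Trajectory(topology=topo, frames=frames_list), ledger


# ---------------------------------------------------------------------------
# assays


@dataclass
class AssaySpec:
    """Ground-truth parameters and design for synthetic assay datasets."""

    # concentration-response
    pec50: float = 8.0
    top: float = 3.0
    bottom: float = 1.0
    concentrations: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0] + [6e-6 / 10**k for k in range(9, -1, -1)]
        )
    )
    # saturation binding (paper-style 2-200 pM design)
    kd: float = 60e-12
    bmax: float = 1000.0
    ns_slope: float = 5e11
    ligand: np.ndarray = field(
        default_factory=lambda: np.geomspace(2e-12, 200e-12, 8)
    )
    noise_sd: float = 0.05  # luminescence fold-change units
    # gamma-counting noise, fraction of Bmax (Poisson level for ~2500 cpm)
    binding_noise_sd: float = 0.02
    replicates: int = 3
    binding_replicates: int = 6  # duplicate wells x 3 experiments
    seed: int = 0


def make_dose_response_data(spec: AssaySpec) -> tuple[pd.DataFrame, dict]:
    """Noisy 3-parameter logistic data (fold-change units)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.replicates):
        for c in np.sort(spec.concentrations):
            if c > 0:
                y = spec.bottom + (spec.top - spec.bottom) / (
                    1.0 + 10.0 ** (-spec.pec50 - np.log10(c))
                )
            else:
                y = spec.bottom
            rows.append(
                {
                    "conc_M": c,
                    "response": y + rng.normal(0, spec.noise_sd),
                    "replicate": rep,
                    "treatment": "agonist",
                }
            )
    ledger = {"pec50": spec.pec50, "top": spec.top, "bottom": spec.bottom, "seed": spec.seed}
    return pd.DataFrame(rows), ledger


def make_saturation_binding_data(spec: AssaySpec) -> tuple[pd.DataFrame, dict]:
    """Noisy one-site total-binding data on the 2-200 pM design."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.binding_replicates):
        for L in spec.ligand:
            total = spec.bmax * L / (spec.kd + L) + spec.ns_slope * L
            noise = rng.normal(0, spec.binding_noise_sd * spec.bmax)
            rows.append(
                {
                    "conc_M": L,
                    "counts": total + noise,
                    "replicate": rep,
                    "treatment": "total",
                }
            )
    ledger = {
        "kd": spec.kd,
        "bmax": spec.bmax,
        "ns_slope": spec.ns_slope,
        "seed": spec.seed,
    }
    return pd.DataFrame(rows), ledger
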