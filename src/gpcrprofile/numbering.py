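"""Generic residue numbering: Ballesteros-Weinstein (receptor) and CGN (G-alpha).

Ballesteros-Weinstein (BW) labels are computed from per-helix anchors: the
most conserved residue of transmembrane helix *t* is defined as ``t.50`` and
every other residue in the helix is offset from it (``t.49`` one residue
N-terminal, and so on).  Helix 8 uses the same scheme as ``8.nn``.  Loop
residues (ICL/ECL) carry free-text tags supplied through explicit table rows,
matching the mixed style used in the structural literature (e.g. R208^ICL2
alongside S390^8.47).

CGN (common G-alpha numbering) is not offset-computable and is always driven
by an explicit table; a default table for the alpha5 helix of G-alpha-i1
ships with the package.

Bulges and deletions (x.451-style labels) are not handled: maps built here
assume a plain one-residue-per-position offset within each segment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .structio import ResidueKey, Structure

__all__ = [
    "GenericLabel",
    "AnchorTable",
    "NumberingMap",
    "build_bw_map",
    "build_cgn_map",
    "read_anchor_table",
    "read_cgn_table",
    "default_cgn_table",
]


@dataclass(frozen=True)
class GenericLabel:
    """A generic residue label, e.g. BW '7.50' or CGN 'H5.25'."""

    scheme: str  # "BW" or "CGN"
    text: str

    def __post_init__(self) -> None:
        if self.scheme not in ("BW", "CGN"):
            raise ValueError(f"unknown numbering scheme {self.scheme!r}")
        if not self.text:
            raise ValueError("label text must be non-empty")
        if self.scheme == "BW" and "." in self.text:
            major, minor = self.text.split(".", 1)
            # numeric BW labels must parse; loop tags like "ICL2" are free text
            if major.isdigit() != minor.isdigit() and major.isdigit():
                raise ValueError(f"malformed BW label {self.text!r}")

    def __str__(self) -> str:
        return self.text


@dataclass
class AnchorTable:
    """Per-segment anchors: (segment id, anchor seq number, anchor label).

    segment_ranges maps segment id -> (first_seq, last_seq), inclusive, in
    author numbering.  Ranges must not overlap.
    """

    anchors: dict[str, tuple[int, str]] = field(default_factory=dict)
    segment_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    chain_id: str = "R"

    def validate(self) -> None:
        spans = sorted(self.segment_ranges.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("segment residue ranges overlap")
        for seg, (seq, _label) in self.anchors.items():
            if seg not in self.segment_ranges:
                raise ValueError(f"anchor for unknown segment {seg!r}")
            lo, hi = self.segment_ranges[seg]
            if not lo <= seq <= hi:
                raise ValueError(f"anchor {seq} outside segment {seg} range {lo}-{hi}")


class NumberingMap:
    """Bijective residue-key <-> generic-label map for one scheme."""

    def __init__(self, scheme: str):
        self.scheme = scheme
        self._by_key: dict[tuple[str, int, str], GenericLabel] = {}
        self._by_label: dict[str, ResidueKey] = {}

    def add(self, key: ResidueKey, label: GenericLabel) -> None:
        site = (key.chain_id, key.seq_number, key.insertion_code)
        if site in self._by_key:
            raise ValueError(f"residue {key} already mapped")
        if label.text in self._by_label:
            raise ValueError(f"label {label.text} already mapped")
        self._by_key[site] = label
        self._by_label[label.text] = key

    def __len__(self) -> int:
        return len(self._by_key)

    def label_of(self, key: ResidueKey) -> GenericLabel:
        site = (key.chain_id, key.seq_number, key.insertion_code)
        try:
            return self._by_key[site]
        except KeyError:
            raise KeyError(f"residue {key} has no {self.scheme} label") from None

    def residue_of(self, label: GenericLabel | str) -> ResidueKey:
        text = label.text if isinstance(label, GenericLabel) else str(label)
        try:
            return self._by_label[text]
        except KeyError:
            raise KeyError(f"label {text!r} not present in {self.scheme} map") from None

    def lookup(self, query: GenericLabel | ResidueKey | str):
        """Resolve a label to a residue key or a residue key to its label."""
        if isinstance(query, ResidueKey):
            return self.label_of(query)
        return self.residue_of(query)

    def items(self):
        for (chain, seq, icode), label in self._by_key.items():
            yield self._by_label[label.text], label


def build_bw_map(
    structure: Structure, anchors: AnchorTable, chain_id: str | None = None
) -> NumberingMap:
    """Assign BW labels to every residue inside each anchored segment.

    The anchor residue gets its anchor label (e.g. P383 -> 7.50) and labels
    change by exactly one minor unit per residue along the sequence.
    """
    anchors.validate()
    chain = chain_id or anchors.chain_id
    nmap = NumberingMap("BW")
    present = {
        key.seq_number: key
        for key in structure.residue_keys()
        if key.chain_id == chain and not key.insertion_code
    }
    for seg, (anchor_seq, anchor_label) in anchors.anchors.items():
        lo, hi = anchors.segment_ranges[seg]
        major, minor = anchor_label.split(".")
        minor0 = int(minor)
        for seq in range(lo, hi + 1):
            if seq not in present:
                continue
            idx = minor0 + (seq - anchor_seq)
            if idx <= 0 or idx >= 100:
                raise ValueError(
                    f"segment {seg}: computed index {major}.{idx} out of range "
                    "(segment range too wide for the anchor)"
                )
            nmap.add(present[seq], GenericLabel("BW", f"{major}.{idx}"))
    return nmap


def build_cgn_map(
    chain: Structure, rows: list[tuple[str, int, str]], chain_id: str | None = None
) -> NumberingMap:
    """Build a CGN map from explicit (chain, seq_number, label) rows.

    Rows whose residue is absent from the chain are skipped (the deposited
    model may be truncated); duplicate labels raise.
    """
    nmap = NumberingMap("CGN")
    present = {
        (key.chain_id, key.seq_number): key
        for key in chain.residue_keys()
        if not key.insertion_code
    }
    chains_present = {c for c, _ in present}
    for row_chain, seq, label in rows:
        if row_chain == "*":
            matches = [present[(c, seq)] for c in sorted(chains_present) if (c, seq) in present]
            if chain_id is not None:
                matches = [k for k in matches if k.chain_id == chain_id]
            if not matches:
                continue
            key = matches[0]
        else:
            key = present.get((row_chain, seq))
            if key is None:
                continue
        nmap.add(key, GenericLabel("CGN", label))
    return nmap


# ---------------------------------------------------------------------------
# TSV interfaces: columns chain, seq_number, label, scheme


def read_anchor_table(path: str | Path, chain_id: str = "R") -> AnchorTable:
    """Read BW anchors from TSV with columns segment, chain, seq_number, label,
    range_start, range_end."""
    table = AnchorTable(chain_id=chain_id)
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            seg = row["segment"]
            table.anchors[seg] = (int(row["seq_number"]), row["label"])
            table.segment_ranges[seg] = (int(row["range_start"]), int(row["range_end"]))
            if row.get("chain"):
                table.chain_id = row["chain"]
    table.validate()
    return table


def write_anchor_table(table: AnchorTable, path: str | Path) -> None:
    """Write a BW anchor table in the TSV layout read_anchor_table expects."""
    lines = ["segment\tchain\tseq_number\tlabel\trange_start\trange_end"]
    for seg, (seq, label) in table.anchors.items():
        lo, hi = table.segment_ranges[seg]
        lines.append(f"{seg}\t{table.chain_id}\t{seq}\t{label}\t{lo}\t{hi}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cgn_table(path: str | Path) -> list[tuple[str, int, str]]:
    """Read CGN rows (chain, seq_number, label) from TSV; '#' lines ignored."""
    rows: list[tuple[str, int, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "chain":  # header
            continue
        rows.append((parts[0], int(parts[1]), parts[2]))
    return rows


def default_cgn_table() -> list[tuple[str, int, str]]:
    """The packaged G-alpha-i1 alpha5/wavy-hook CGN table (residues 340-354)."""
    ref = resources.files("gpcrprofile.data").joinpath("cgn_gai1.tsv")
    with resources.as_file(ref) as path:
        return read_cgn_table(path)
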