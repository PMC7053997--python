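"""Generic residue numbering for GPCR sequences.

Assigns Ballesteros-Weinstein-style generic labels to receptor residues from
an annotated multiple alignment. Each segment (TM helix or extracellular loop)
carries one anchor: the x.50 position, placed at the segment's most conserved
residue (for TMs the classical Ballesteros-Weinstein anchors; for EL1 the
conserved Trp, EL1.50; for EL2 the disulfide-bonded Cys, EL2.50). Labels then
run per alignment column relative to the anchor column, so a receptor whose
sequence has a deletion inside the segment simply skips the corresponding
index — generic indices of shorter sequences need not be consecutive.

Columns that are gaps in every sequence carry no label index of their own:
inserting an all-gap column into an alignment does not shift any label.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "AlignmentBlock",
    "GenericResidueMap",
    "assign_generic_numbers",
    "read_alignment_block",
]

_LABEL_RE = re.compile(r"^(?P<segment>[A-Za-z0-9]+)\.(?P<index>\d+)$")


def _split_label(label: str) -> tuple[str, int]:
    m = _LABEL_RE.match(label)
    if not m:
        raise ConfigurationError(f"malformed generic label {label!r} (expected e.g. '3.50' or 'EL2.50')")
    return m.group("segment"), int(m.group("index"))


@dataclass
class AlignmentBlock:
    """A gapped alignment with anchor-column and segment-window annotation.

    Parameters
    ----------
    sequences : dict receptor_id -> gapped sequence ('-' gaps)
    anchor_columns : dict generic_label -> 1-based alignment column
        One "x.50" anchor per segment in scope, e.g. {"EL2.50": 12}.
    segment_windows : dict segment name -> (first_col, last_col), 1-based inclusive
        Which alignment columns belong to each segment; labels are only
        assigned inside these windows.
    starts : dict receptor_id -> 1-based sequence position of the first
        residue of the gapped text (defaults to 1). Lets a block cover just
        a loop region of a full-length receptor.
    """

    sequences: dict[str, str]
    anchor_columns: dict[str, int]
    segment_windows: dict[str, tuple[int, int]]
    starts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise DataError("gapped sequences must all have equal length")
        self.n_columns = lengths.pop() if lengths else 0
        for label, col in self.anchor_columns.items():
            _split_label(label)
            if not (1 <= col <= self.n_columns):
                raise ConfigurationError(f"anchor column {col} for {label} out of bounds")
        for seg, (a, b) in self.segment_windows.items():
            if not (1 <= a <= b <= self.n_columns):
                raise ConfigurationError(f"segment window {seg}: ({a}, {b}) out of bounds")


@dataclass
class GenericResidueMap:
    """Per-residue generic labels for one receptor.

    ``entries`` is ordered by sequence position; each entry is
    (sequence_position, one-letter residue code, generic label or None).
    """

    receptor_id: str
    entries: list[tuple[int, str, str | None]]

    def __post_init__(self) -> None:
        pos = [p for p, _, _ in self.entries]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise DataError("sequence positions must be strictly increasing")
        labels = [l for _, _, l in self.entries if l is not None]
        if len(labels) != len(set(labels)):
            raise DataError("a generic label may map to at most one position")

    def position_of(self, label: str) -> int:
        for p, _, l in self.entries:
            if l == label:
                return p
        raise KeyError(label)

    def label_of(self, position: int) -> str | None:
        for p, _, l in self.entries:
            if p == position:
                return l
        raise KeyError(position)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["position", "residue", "label"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def assign_generic_numbers(block: AlignmentBlock, receptor_id: str) -> GenericResidueMap:
    """Assign generic labels to one receptor's residues from the alignment.

    Every non-gap position of the receptor inside an anchored segment window
    receives a label; the label index at a column is the anchor index (50)
    plus the signed count of non-all-gap columns between the anchor column
    and that column.

    Raises
    ------
    ConfigurationError
        If a segment window has no anchor defined.
    DataError
        If the receptor's sequence has a gap at an anchor column inside a
        window that applies to it.
    """
    if receptor_id not in block.sequences:
        raise DataError(f"receptor {receptor_id!r} not present in alignment block")
    seq = block.sequences[receptor_id]
    start = block.starts.get(receptor_id, 1)

    anchors_by_segment: dict[str, tuple[int, int]] = {}
    for label, col in block.anchor_columns.items():
        seg, idx = _split_label(label)
        anchors_by_segment[seg] = (idx, col)

    # column -> label-index offset, counting only columns occupied by at
    # least one sequence (all-gap columns are invisible to the numbering)
    occupied = [any(s[c] != "-" for s in block.sequences.values())
                for c in range(block.n_columns)]
    cum = [0] * (block.n_columns + 1)
    for c in range(block.n_columns):
        cum[c + 1] = cum[c] + (1 if occupied[c] else 0)

    labels_by_column: dict[int, str] = {}
    for seg, (a, b) in block.segment_windows.items():
        if seg not in anchors_by_segment:
            raise ConfigurationError(f"segment {seg!r} has no x.50 anchor defined")
        anchor_idx, anchor_col = anchors_by_segment[seg]
        if not (a <= anchor_col <= b):
            raise ConfigurationError(
                f"anchor column {anchor_col} for {seg} lies outside its window ({a}, {b})")
        if seq[anchor_col - 1] == "-":
            raise DataError(
                f"{receptor_id}: anchor {seg}.{anchor_idx} column {anchor_col} is a gap")
        for col in range(a, b + 1):
            offset = cum[col] - cum[anchor_col]
            labels_by_column[col] = f"{seg}.{anchor_idx + offset}"

    entries: list[tuple[int, str, str | None]] = []
    pos = start
    for col in range(1, block.n_columns + 1):
        aa = seq[col - 1]
        if aa == "-":
            continue
        entries.append((pos, aa, labels_by_column.get(col)))
        pos += 1
    return GenericResidueMap(receptor_id, entries)


def read_alignment_block(fasta_path, sidecar_path) -> AlignmentBlock:
    """Load an AlignmentBlock from a gapped FASTA plus a JSON side-car.

    The side-car holds ``anchor_columns`` (label -> 1-based column),
    ``segment_windows`` (segment -> [first, last]) and optionally
    ``starts`` (receptor_id -> 1-based first sequence position).
    """
    from Bio import SeqIO

    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not sequences:
        raise DataError(f"no sequences in {fasta_path}")
    meta = json.loads(Path(sidecar_path).read_text())
    return AlignmentBlock(
        sequences=sequences,
        anchor_columns={k: int(v) for k, v in meta["anchor_columns"].items()},
        segment_windows={k: (int(v[0]), int(v[1])) for k, v in meta["segment_windows"].items()},
        starts={k: int(v) for k, v in meta.get("starts", {}).items()},
    )
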