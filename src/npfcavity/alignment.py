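"""Gapped multiple sequence alignments, reference numbering and cavity fingerprints.

A binding-site *fingerprint* is the ordered set of residues a sequence presents
at the alignment columns that line the transporter substrate cavity.  Columns
are addressed indirectly: a :class:`PositionMap` ties alignment columns to the
residue numbering of a reference sequence (NPF6.3 in the Arabidopsis NPF
analysis), and cavity positions are named labels ("Pos16") anchored to
reference residue numbers.  All coordinates — alignment columns and residue
numbers — are 1-based, matching PDB and structural-biology convention.

The gap symbol is ``-``.  ``X`` (unknown residue) is accepted and treated as a
gap by downstream descriptor encoding, since no physicochemical descriptor is
defined for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentShapeError, AlphabetError, AnchorError, ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_VALID = set(AMINO_ACIDS) | {GAP, UNKNOWN}


@dataclass
class Alignment:
    """An in-memory gapped alignment: ordered (id, gapped sequence) records."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentShapeError("ids and sequences differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentShapeError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            for sid, seq in zip(self.ids, self.sequences):
                if len(seq) != len(self.sequences[0]):
                    raise AlignmentShapeError(
                        f"sequence {sid!r} has length {len(seq)}, "
                        f"expected {len(self.sequences[0])}"
                    )
        for sid, seq in zip(self.ids, self.sequences):
            for col, ch in enumerate(seq, start=1):
                if ch not in _VALID:
                    raise AlphabetError(
                        f"illegal symbol {ch!r} in sequence {sid!r} at column {col}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None


@dataclass
class PositionMap:
    """Bijection between alignment columns and reference residue numbers.

    ``column_to_residue`` contains only columns where the reference has a
    residue (reference-gap columns are absent); it is strictly increasing in
    both key and value.  ``anchors`` names cavity positions by reference
    residue number; ``anchor_columns`` resolves each to its alignment column.
    """

    reference_id: str
    column_to_residue: dict[int, int]
    anchors: dict[str, int] = field(default_factory=dict)
    anchor_columns: dict[str, int] = field(default_factory=dict)

    @property
    def residue_to_column(self) -> dict[int, int]:
        return {r: c for c, r in self.column_to_residue.items()}

    def column_of_residue(self, residue_number: int) -> int:
        inv = self.residue_to_column
        if residue_number not in inv:
            raise AnchorError(
                f"residue number {residue_number} not present on reference "
                f"{self.reference_id!r}"
            )
        return inv[residue_number]


@dataclass
class BindingSiteFingerprint:
    """One sequence's residues at the ordered cavity positions."""

    sequence_id: str
    residues: list[str]
    positions: list[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.positions):
            raise ConfigurationError(
                f"fingerprint for {self.sequence_id!r}: {len(self.residues)} "
                f"residues for {len(self.positions)} positions"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Residue case is normalized to upper.  Raises
    :class:`~npfcavity.errors.AlignmentShapeError` on ragged records and
    :class:`~npfcavity.errors.AlphabetError` on symbols outside the 20-letter
    alphabet plus ``-``/``X``.
    """
    if format != "fasta":
        raise ValueError(f"unsupported alignment format {format!r}")
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentShapeError(f"no FASTA records found in {path}")
    return Alignment(ids=ids, sequences=seqs)


def build_position_map(
    aln: Alignment, reference_id: str, anchors: Mapping[str, int] | None = None
) -> PositionMap:
    """Map alignment columns to reference residue numbers and resolve anchors.

    Non-gap reference columns are numbered consecutively from 1.  Anchors map
    position labels to reference residue numbers; each is resolved to the
    alignment column carrying that residue.  An anchor beyond the reference
    length raises :class:`~npfcavity.errors.AnchorError`.
    """
    ref_seq = aln.sequence(reference_id)  # raises KeyError if absent
    column_to_residue: dict[int, int] = {}
    resnum = 0
    for col, ch in enumerate(ref_seq, start=1):
        if ch != GAP:
            resnum += 1
            column_to_residue[col] = resnum
    pmap = PositionMap(
        reference_id=reference_id,
        column_to_residue=column_to_residue,
        anchors=dict(anchors or {}),
    )
    inv = pmap.residue_to_column
    for label, anchor_res in pmap.anchors.items():
        if anchor_res not in inv:
            raise AnchorError(
                f"anchor {label!r} → residue {anchor_res} exceeds reference "
                f"{reference_id!r} length ({resnum} residues)"
            )
        pmap.anchor_columns[label] = inv[anchor_res]
    return pmap


def extract_fingerprints(
    aln: Alignment,
    pmap: PositionMap,
    positions: Sequence[str],
    labels: pd.DataFrame | None = None,
) -> list[BindingSiteFingerprint]:
    """Extract one fingerprint per sequence at the configured positions.

    ``positions`` is an ordered list of position labels that must resolve
    through ``pmap.anchor_columns``.  Gap symbols are preserved.  ``labels``,
    when given, is a DataFrame indexed by sequence id whose columns become
    fingerprint annotations.
    """
    unresolved = [p for p in positions if p not in pmap.anchor_columns]
    if unresolved:
        raise ConfigurationError(f"unresolvable position labels: {unresolved}")
    cols = [pmap.anchor_columns[p] for p in positions]
    out = []
    for sid, seq in zip(aln.ids, aln.sequences):
        residues = [seq[c - 1] for c in cols]
        ann: dict[str, str] = {}
        if labels is not None and sid in labels.index:
            ann = {k: str(v) for k, v in labels.loc[sid].items()}
        out.append(
            BindingSiteFingerprint(
                sequence_id=sid, residues=residues, positions=list(positions), labels=ann
            )
        )
    return out


def fingerprints_to_frame(fps: Iterable[BindingSiteFingerprint]) -> pd.DataFrame:
    """Tabulate fingerprints: one row per sequence, one column per position.

    Label annotations are appended as extra columns.
    """
    fps = list(fps)
    if not fps:
        return pd.DataFrame()
    positions = fps[0].positions
    rows = {}
    for fp in fps:
        if fp.positions != positions:
            raise ConfigurationError(
                f"fingerprint {fp.sequence_id!r} has a different position configuration"
            )
        rows[fp.sequence_id] = list(fp.residues)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=positions)
    frame.index.name = "sequence_id"
    label_keys = sorted({k for fp in fps for k in fp.labels})
    for key in label_keys:
        frame[key] = [fp.labels.get(key, "") for fp in fps]
    return frame


def frame_to_fingerprints(
    frame: pd.DataFrame, positions: Sequence[str] | None = None
) -> list[BindingSiteFingerprint]:
    """Inverse of :func:`fingerprints_to_frame`."""
    if positions is None:
        positions = [c for c in frame.columns if str(c).startswith("Pos")]
    label_cols = [c for c in frame.columns if c not in positions]
    out = []
    for sid, row in frame.iterrows():
        out.append(
            BindingSiteFingerprint(
                sequence_id=str(sid),
                residues=[str(row[p]) for p in positions],
                positions=list(positions),
                labels={c: str(row[c]) for c in label_cols if str(row[c])},
            )
        )
    return out


def drop_positions(
    fps: Iterable[BindingSiteFingerprint], drop: Sequence[str]
) -> list[BindingSiteFingerprint]:
    """Remove named positions from every fingerprint (e.g. the ExxE[K/R] motif
    positions Pos1–Pos3) so the downstream encoding/PCA can be repeated on the
    reduced position set as a bias control."""
    drop_set = set(drop)
    out = []
    for fp in fps:
        keep = [i for i, p in enumerate(fp.positions) if p not in drop_set]
        out.append(
            BindingSiteFingerprint(
                sequence_id=fp.sequence_id,
                residues=[fp.residues[i] for i in keep],
                positions=[fp.positions[i] for i in keep],
                labels=dict(fp.labels),
            )
        )
    return out
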