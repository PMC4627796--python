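"""Sequences, per-residue score tracks and MoRF interval annotations.

File conventions: FASTA for sequences; tab-separated tracks with columns
``seq_id  pos  aa  score`` (header line, positions 1-based and contiguous);
tab-separated annotations with columns ``seq_id  start  end  label``
(1-based inclusive intervals, label ``morf`` or ``masked``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZU"
VALID_AA = frozenset(STANDARD_AA + AMBIGUOUS_AA)

ANNOTATION_LABELS = ("morf", "masked")


class Space(str, enum.Enum):
    """Score space of a track: raw (arbitrary scale) or normalized (0, 1)."""

    RAW = "raw"
    NORMALIZED = "normalized"


@dataclass
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_AA
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ResidueTrack:
    """One real-valued score per residue of one sequence.

    ``space`` declares whether values are on the feature's raw scale or on
    the normalized (0, 1) scale produced by a fitted rank-to-Gaussian map.
    Normalized values must lie strictly inside (0, 1).
    """

    sequence_id: str
    values: np.ndarray
    space: Space = Space.RAW
    feature: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError(f"track for {self.sequence_id!r} must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"track for {self.sequence_id!r} contains non-finite values")
        self.space = Space(self.space)
        if self.space is Space.NORMALIZED and (vals.min() <= 0.0 or vals.max() >= 1.0):
            raise ValueError(
                f"normalized track for {self.sequence_id!r} has values outside (0, 1)"
            )
        self.values = vals

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, space: Space | None = None) -> "ResidueTrack":
        return ResidueTrack(
            self.sequence_id, values, self.space if space is None else space, self.feature
        )


@dataclass
class MoRFAnnotation:
    """Labeled intervals on one sequence, 1-based inclusive coordinates.

    Residues outside every interval are implicitly non-MoRF. ``masked``
    intervals are excluded from evaluation entirely.
    """

    sequence_id: str
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        checked = []
        for start, end, label in self.intervals:
            start, end = int(start), int(end)
            if label not in ANNOTATION_LABELS:
                raise ValueError(
                    f"{self.sequence_id}: unknown annotation label {label!r}"
                )
            if not 1 <= start <= end:
                raise ValueError(
                    f"{self.sequence_id}: invalid interval ({start}, {end})"
                )
            checked.append((start, end, label))
        checked.sort()
        for (s1, e1, _), (s2, _e2, _) in zip(checked, checked[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.sequence_id}: overlapping intervals "
                    f"({s1}, {e1}) and ({s2}, {_e2})"
                )
        self.intervals = checked

    def validate_length(self, length: int) -> None:
        for start, end, _ in self.intervals:
            if end > length:
                raise ValueError(
                    f"{self.sequence_id}: interval ({start}, {end}) exceeds "
                    f"sequence length {length}"
                )

    def label_vector(self, length: int) -> np.ndarray:
        """Per-residue labels: 1 = MoRF, 0 = non-MoRF, -1 = masked."""
        self.validate_length(length)
        labels = np.zeros(length, dtype=np.int8)
        for start, end, label in self.intervals:
            labels[start - 1 : end] = 1 if label == "morf" else -1
        return labels

    def morf_residue_count(self) -> int:
        return sum(e - s + 1 for s, e, lab in self.intervals if lab == "morf")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if any(c in seq for c in "-."):
            raise ValueError(f"sequence {rec.id!r} contains gap characters")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Per-residue track TSV

TRACK_HEADER = "seq_id\tpos\taa\tscore"


def read_track(path, sequences=None) -> list[ResidueTrack]:
    """Read per-residue tracks; one ResidueTrack per sequence, in file order.

    If ``sequences`` (mapping id -> SequenceRecord) is given, residue letters
    and track lengths are checked against it; a mismatch is an error.
    """
    seq_map = _as_mapping(sequences)
    order: list[str] = []
    per_seq: dict[str, list[tuple[int, str, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and not _is_int(parts[1] if len(parts) > 1 else ""):
                continue  # header
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            sid, pos_s, aa, score_s = parts
            if not _is_int(pos_s):
                raise ValueError(f"{path}:{lineno}: position {pos_s!r} not an integer")
            try:
                score = float(score_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: score {score_s!r} not parseable"
                ) from None
            if sid not in per_seq:
                per_seq[sid] = []
                order.append(sid)
            per_seq[sid].append((int(pos_s), aa, score))

    tracks = []
    for sid in order:
        rows = per_seq[sid]
        positions = [p for p, _, _ in rows]
        for i, p in enumerate(positions, start=1):
            if p != i:
                raise ValueError(
                    f"{path}: sequence {sid!r} position gap: expected {i}, got {p}"
                )
        if seq_map is not None:
            if sid not in seq_map:
                raise ValueError(f"{path}: track for unknown sequence {sid!r}")
            seq = seq_map[sid].residues
            if len(rows) != len(seq):
                raise ValueError(
                    f"{path}: track length {len(rows)} != sequence length "
                    f"{len(seq)} for {sid!r}"
                )
            for p, aa, _ in rows:
                if aa.upper() != seq[p - 1]:
                    raise ValueError(
                        f"{path}: residue mismatch for {sid!r} at position {p}: "
                        f"track has {aa!r}, sequence has {seq[p - 1]!r}"
                    )
        tracks.append(ResidueTrack(sid, np.array([s for _, _, s in rows])))
    if not tracks:
        raise ValueError(f"no track rows found in {path}")
    return tracks


def write_track(tracks, sequences, path, fmt: str = ".17g") -> None:
    seq_map = _as_mapping(sequences)
    with open(path, "w") as fh:
        fh.write(TRACK_HEADER + "\n")
        for track in tracks:
            seq = seq_map[track.sequence_id].residues
            if len(seq) != len(track):
                raise ValueError(
                    f"track length {len(track)} != sequence length {len(seq)} "
                    f"for {track.sequence_id!r}"
                )
            for i, v in enumerate(track.values):
                fh.write(
                    f"{track.sequence_id}\t{i + 1}\t{seq[i]}\t{format(v, fmt)}\n"
                )


# ---------------------------------------------------------------------------
# Annotation TSV

def read_annotations(path, sequences=None) -> list[MoRFAnnotation]:
    seq_map = _as_mapping(sequences)
    order: list[str] = []
    per_seq: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and not _is_int(parts[1] if len(parts) > 1 else ""):
                continue  # header
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            sid, start_s, end_s, label = parts
            if not (_is_int(start_s) and _is_int(end_s)):
                raise ValueError(f"{path}:{lineno}: non-integer interval bounds")
            if sid not in per_seq:
                per_seq[sid] = []
                order.append(sid)
            per_seq[sid].append((int(start_s), int(end_s), label))

    annotations = []
    for sid in order:
        ann = MoRFAnnotation(sid, per_seq[sid])
        if seq_map is not None:
            if sid not in seq_map:
                raise ValueError(f"{path}: annotation for unknown sequence {sid!r}")
            ann.validate_length(len(seq_map[sid]))
        annotations.append(ann)
    return annotations


def write_annotations(annotations, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tlabel\n")
        for ann in annotations:
            for start, end, label in ann.intervals:
                fh.write(f"{ann.sequence_id}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------

def _as_mapping(sequences):
    if sequences is None:
        return None
    if isinstance(sequences, dict):
        return sequences
    return {rec.id: rec for rec in sequences}


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True
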