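"""PSI-BLAST ASCII PSSM parsing and conservation feature extraction.

Only the 44-column ASCII dialect is supported: each position row carries the
position index, the query residue, 20 log-odds integers, 20 weighted observed
percentage (WOP) integers, the information-per-position (IPP) column and the
relative-weight-of-gapless-real-matches-to-pseudocounts (RWGRMP) column.
Binary or XML PSSM outputs are rejected.

Three per-residue conservation features are extracted:

* IPP — the information content of the alignment column;
* WOP — the weighted observed percentage of the residue actually present in
  the query at that position (the file stores integers, already rounded
  down);
* RWGRMP — the per-position relative weight column.  RWGRMP is
  anti-correlated with MoRFs, so downstream fusion consumes its complement
  (1 - v) on the normalized (0, 1) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tracks_io import ResidueTrack, Space

logger = logging.getLogger(__name__)

#: PSI-BLAST column order for the 20 standard amino acids.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass
class PSSMProfile:
    """Per-position content of one PSI-BLAST ASCII PSSM."""

    sequence_id: str
    query_residues: str
    log_odds: np.ndarray  # (L, 20) int
    wop: np.ndarray       # (L, 20) int, 0..100
    ipp: np.ndarray       # (L,) float, >= 0
    rwgrmp: np.ndarray    # (L,) float, >= 0

    def __post_init__(self) -> None:
        L = len(self.query_residues)
        self.log_odds = np.asarray(self.log_odds, dtype=int)
        self.wop = np.asarray(self.wop, dtype=int)
        self.ipp = np.asarray(self.ipp, dtype=float)
        self.rwgrmp = np.asarray(self.rwgrmp, dtype=float)
        if L == 0:
            raise ValueError(f"profile {self.sequence_id!r} has zero length")
        if self.log_odds.shape != (L, 20) or self.wop.shape != (L, 20):
            raise ValueError(f"profile {self.sequence_id!r}: matrix shape mismatch")
        if self.ipp.shape != (L,) or self.rwgrmp.shape != (L,):
            raise ValueError(f"profile {self.sequence_id!r}: vector length mismatch")
        if self.wop.min() < 0 or self.wop.max() > 100:
            raise ValueError(f"profile {self.sequence_id!r}: WOP outside [0, 100]")
        if self.ipp.min() < 0 or self.rwgrmp.min() < 0:
            raise ValueError(f"profile {self.sequence_id!r}: negative IPP or RWGRMP")

    def __len__(self) -> int:
        return len(self.query_residues)


def parse_ascii_pssm(path, sequence_id: str | None = None) -> PSSMProfile:
    """Parse one PSI-BLAST ASCII PSSM file.

    ``sequence_id`` defaults to the file stem.  Header lines before the data
    block and the K/lambda footer after it are ignored.  A data row must have
    exactly 44 whitespace-separated tokens; anything else is a parse error
    naming the line.
    """
    path = Path(path)
    sid = sequence_id if sequence_id is not None else path.stem

    residues: list[str] = []
    log_odds: list[list[int]] = []
    wop: list[list[int]] = []
    ipp: list[float] = []
    rwgrmp: list[float] = []
    in_data = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                if in_data:
                    in_data = False  # blank line ends the data block
                continue
            if not tokens[0].lstrip("-").isdigit():
                if in_data:
                    in_data = False  # footer reached
                continue
            if not in_data and residues:
                raise ValueError(
                    f"{path}:{lineno}: unexpected numeric row after data block end"
                )
            in_data = True
            if len(tokens) != 44:
                raise ValueError(
                    f"{path}:{lineno}: expected 44 columns in PSSM row, "
                    f"got {len(tokens)}"
                )
            pos = int(tokens[0])
            if pos != len(residues) + 1:
                raise ValueError(
                    f"{path}:{lineno}: non-monotone position index {pos} "
                    f"(expected {len(residues) + 1})"
                )
            aa = tokens[1].upper()
            if len(aa) != 1 or not aa.isalpha():
                raise ValueError(f"{path}:{lineno}: invalid query residue {tokens[1]!r}")
            try:
                lo = [int(t) for t in tokens[2:22]]
                wp = [int(t) for t in tokens[22:42]]
                ip = float(tokens[42])
                rw = float(tokens[43])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unreadable numeric value in PSSM row"
                ) from None
            residues.append(aa)
            log_odds.append(lo)
            wop.append(wp)
            ipp.append(ip)
            rwgrmp.append(rw)

    if not residues:
        raise ValueError(f"{path}: no PSSM data rows found")
    return PSSMProfile(
        sequence_id=sid,
        query_residues="".join(residues),
        log_odds=np.array(log_odds),
        wop=np.array(wop),
        ipp=np.array(ipp),
        rwgrmp=np.array(rwgrmp),
    )


def load_pssm_dir(directory, sequence_ids) -> dict[str, PSSMProfile]:
    """Load ``<id>.pssm`` files for the given sequence ids from a directory."""
    directory = Path(directory)
    missing = [sid for sid in sequence_ids if not (directory / f"{sid}.pssm").exists()]
    if missing:
        raise FileNotFoundError(
            f"missing PSSM files in {directory} for sequences: {', '.join(missing)}"
        )
    return {
        sid: parse_ascii_pssm(directory / f"{sid}.pssm", sequence_id=sid)
        for sid in sequence_ids
    }


def extract_ipp(profile: PSSMProfile) -> ResidueTrack:
    return ResidueTrack(profile.sequence_id, profile.ipp.copy(), Space.RAW, feature="ipp")


def extract_rwgrmp(profile: PSSMProfile) -> ResidueTrack:
    return ResidueTrack(
        profile.sequence_id, profile.rwgrmp.copy(), Space.RAW, feature="rwgrmp"
    )


def extract_wop(profile: PSSMProfile) -> ResidueTrack:
    """WOP of the query residue at each position.

    Residues without a dedicated PSSM column (X/B/Z/U) get WOP = 0: an
    unknown residue carries no conservation evidence.
    """
    values = np.zeros(len(profile), dtype=float)
    for i, aa in enumerate(profile.query_residues):
        col = AA_INDEX.get(aa)
        if col is None:
            logger.warning(
                "profile %s position %d: query residue %r has no PSSM column; WOP=0",
                profile.sequence_id, i + 1, aa,
            )
            continue
        values[i] = profile.wop[i, col]
    return ResidueTrack(profile.sequence_id, values, Space.RAW, feature="wop")


def complement_track(track: ResidueTrack) -> ResidueTrack:
    """Replace a normalized score v by 1 - v.

    Defined only on the normalized (0, 1) scale, where the target Gaussian is
    symmetric about 0.5 so the complement is exact; raw-scale inputs (which
    may be unbounded) are rejected.
    """
    if track.space is not Space.NORMALIZED:
        raise ValueError("complement_track requires a normalized-space track")
    return ResidueTrack(
        track.sequence_id, 1.0 - track.values, Space.NORMALIZED, track.feature
    )
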