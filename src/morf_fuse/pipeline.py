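"""The full prediction hierarchy and its training mode.

Per sequence the pipeline runs:

    PSSM -> IPP, RWGRMP, WOP            (raw conservation features)
         -> normalize; complement RWGRMP
         -> ics  = normalize(bayes(IPP_n, 1 - RWGRMP_n, WOP_n))
         -> mcs  = normalize(window rules(ics, disorder_n))
    morf_dc  = normalize(bayes(mcs_n, disorder_n))
    final    = bayes(morf_dc_n, chibi_n)

where disorder and chibi (local-sequence MoRF propensity) tracks are
consumed pre-computed, and every "normalize" applies a rank map fitted once
on the training population (a MapBundle of eight maps).  The final score is
in (0, 1); intervals are called as maximal runs of residues at or above the
cutoff (default 0.66).

Training mode (``fit_bundle``) pools each feature's raw values over all
training residues, fits its map, and feeds the normalized tracks forward so
the maps of the derived features (ics, mcs, morf_dc) are fitted on exactly
the score populations prediction will produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import McsParams, compute_ics, compute_mcs
from .fusion import bayes_combine
from .normalization import NormalizationMap, apply_map, fit_map, load_map, save_map
from .pssm import (
    PSSMProfile,
    complement_track,
    extract_ipp,
    extract_rwgrmp,
    extract_wop,
    load_pssm_dir,
)
from .tracks_io import ResidueTrack, SequenceRecord, Space

#: Features with a fitted normalization map, in fitting order.
BUNDLE_FEATURES = ("ipp", "rwgrmp", "wop", "disorder", "chibi", "ics", "mcs", "morf_dc")

DEFAULT_CUTOFF = 0.66


@dataclass
class PipelineConfig:
    """Thresholds, window sizes and the calling cutoff."""

    mcs_params: McsParams = field(default_factory=McsParams)
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff {self.cutoff} outside (0, 1)")


@dataclass
class MapBundle:
    """The eight fitted normalization maps the pipeline needs."""

    maps: dict[str, NormalizationMap]

    def __post_init__(self) -> None:
        missing = [f for f in BUNDLE_FEATURES if f not in self.maps]
        if missing:
            raise ValueError(f"bundle missing maps for: {', '.join(missing)}")

    def __getitem__(self, feature: str) -> NormalizationMap:
        return self.maps[feature]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for feature in BUNDLE_FEATURES:
            save_map(self.maps[feature], directory / f"{feature}.map")

    @classmethod
    def load(cls, directory) -> "MapBundle":
        directory = Path(directory)
        maps = {}
        for feature in BUNDLE_FEATURES:
            path = directory / f"{feature}.map"
            if not path.exists():
                raise FileNotFoundError(f"bundle map file missing: {path}")
            maps[feature] = load_map(path)
        return cls(maps)


@dataclass
class PredictionResult:
    """All intermediate tracks plus the final score and called intervals."""

    sequence_id: str
    ipp_n: ResidueTrack
    rwgrmp_n: ResidueTrack  # complemented
    wop_n: ResidueTrack
    ics: ResidueTrack
    disorder_n: ResidueTrack
    mcs: ResidueTrack
    morf_dc: ResidueTrack
    chibi_n: ResidueTrack
    final: ResidueTrack
    calls: list[tuple[int, int]]

    TRACK_NAMES = (
        "ipp_n", "rwgrmp_n", "wop_n", "ics", "disorder_n",
        "mcs", "morf_dc", "chibi_n", "final",
    )

    def tracks(self) -> dict[str, ResidueTrack]:
        return {name: getattr(self, name) for name in self.TRACK_NAMES}


# ---------------------------------------------------------------------------
# Shared per-sequence plumbing

def _conservation_raw(profile: PSSMProfile):
    return extract_ipp(profile), extract_rwgrmp(profile), extract_wop(profile)


def _normalized_conservation(profile, bundle):
    ipp_raw, rw_raw, wop_raw = _conservation_raw(profile)
    ipp_n = apply_map(bundle["ipp"], ipp_raw)
    rw_n = complement_track(apply_map(bundle["rwgrmp"], rw_raw))
    wop_n = apply_map(bundle["wop"], wop_raw)
    return ipp_n, rw_n, wop_n


def _as_feature(track: ResidueTrack, feature: str) -> ResidueTrack:
    """Re-flag a combined (0, 1) track as the raw input of a named feature."""
    return ResidueTrack(track.sequence_id, track.values, Space.RAW, feature=feature)


def compute_morf_dc(
    mcs_n: ResidueTrack,
    disorder_n: ResidueTrack,
    morf_dc_map: NormalizationMap | None = None,
) -> ResidueTrack:
    """Fuse conservation (mcs) and disorder into the intermediate predictor."""
    combined = bayes_combine([mcs_n, disorder_n])
    combined.feature = "morf_dc"
    if morf_dc_map is None:
        return combined
    return apply_map(morf_dc_map, combined)


def compute_final(morf_dc_n: ResidueTrack, chibi_n: ResidueTrack) -> ResidueTrack:
    """Fuse the disorder+conservation predictor with the local-sequence track."""
    combined = bayes_combine([morf_dc_n, chibi_n])
    combined.feature = "final"
    return combined


def call_morfs(result, cutoff: float = DEFAULT_CUTOFF) -> list[tuple[int, int]]:
    """Maximal runs of final score >= cutoff, as 1-based inclusive intervals."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    track = result.final if isinstance(result, PredictionResult) else result
    above = track.values >= cutoff
    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start + 1, i))
            start = None
    if start is not None:
        intervals.append((start + 1, above.size))
    return intervals


# ---------------------------------------------------------------------------
# Training mode

def fit_bundle(
    sequences,
    profiles: dict[str, PSSMProfile],
    disorder_tracks: dict[str, ResidueTrack],
    chibi_tracks: dict[str, ResidueTrack],
    config: PipelineConfig | None = None,
) -> MapBundle:
    """Fit all eight normalization maps on a training dataset.

    The rank maps are population maps over all training residues; MoRF
    annotations are not needed for fitting.
    """
    if config is None:
        config = PipelineConfig()
    sequences = list(sequences)
    _check_components(sequences, profiles, disorder_tracks, chibi_tracks)

    raw_cons = {rec.id: _conservation_raw(profiles[rec.id]) for rec in sequences}
    maps: dict[str, NormalizationMap] = {}
    ids = [rec.id for rec in sequences]

    for slot, feature in ((0, "ipp"), (1, "rwgrmp"), (2, "wop")):
        pooled = np.concatenate([raw_cons[sid][slot].values for sid in ids])
        maps[feature] = fit_map(pooled, feature)
    maps["disorder"] = fit_map(
        np.concatenate([disorder_tracks[sid].values for sid in ids]), "disorder"
    )
    maps["chibi"] = fit_map(
        np.concatenate([chibi_tracks[sid].values for sid in ids]), "chibi"
    )

    ics_raw: dict[str, ResidueTrack] = {}
    disorder_n: dict[str, ResidueTrack] = {}
    for sid in ids:
        ipp_raw, rw_raw, wop_raw = raw_cons[sid]
        ipp_n = apply_map(maps["ipp"], ipp_raw)
        rw_n = complement_track(apply_map(maps["rwgrmp"], rw_raw))
        wop_n = apply_map(maps["wop"], wop_raw)
        ics_raw[sid] = compute_ics(ipp_n, rw_n, wop_n)
        disorder_n[sid] = apply_map(maps["disorder"], disorder_tracks[sid])
    maps["ics"] = fit_map(
        np.concatenate([ics_raw[sid].values for sid in ids]), "ics"
    )

    mcs_raw: dict[str, ResidueTrack] = {}
    for sid in ids:
        ics_n = apply_map(maps["ics"], ics_raw[sid])
        mcs_raw[sid] = _as_feature(
            compute_mcs(ics_n, disorder_n[sid], config.mcs_params), "mcs"
        )
    maps["mcs"] = fit_map(
        np.concatenate([mcs_raw[sid].values for sid in ids]), "mcs"
    )

    morf_dc_raw = []
    for sid in ids:
        mcs_n = apply_map(maps["mcs"], mcs_raw[sid])
        morf_dc_raw.append(compute_morf_dc(mcs_n, disorder_n[sid]).values)
    maps["morf_dc"] = fit_map(np.concatenate(morf_dc_raw), "morf_dc")

    return MapBundle(maps)


# ---------------------------------------------------------------------------
# Prediction mode

def predict(
    sequences,
    profiles,
    disorder_tracks,
    chibi_tracks,
    bundle: MapBundle,
    config: PipelineConfig | None = None,
) -> list[PredictionResult]:
    """Run the full hierarchy for every sequence.

    ``profiles`` may be a mapping id -> PSSMProfile or a directory of
    ``<id>.pssm`` files.  Deterministic: identical inputs give bit-identical
    outputs.
    """
    if config is None:
        config = PipelineConfig()
    sequences = list(sequences)
    if not isinstance(profiles, dict):
        profiles = load_pssm_dir(profiles, [rec.id for rec in sequences])
    disorder_tracks = _track_mapping(disorder_tracks)
    chibi_tracks = _track_mapping(chibi_tracks)
    _check_components(sequences, profiles, disorder_tracks, chibi_tracks)

    results = []
    for rec in sequences:
        sid = rec.id
        ipp_n, rw_n, wop_n = _normalized_conservation(profiles[sid], bundle)
        ics_n = compute_ics(ipp_n, rw_n, wop_n, ics_map=bundle["ics"])
        disorder_n = apply_map(bundle["disorder"], disorder_tracks[sid])
        mcs_raw = _as_feature(
            compute_mcs(ics_n, disorder_n, config.mcs_params), "mcs"
        )
        mcs_n = apply_map(bundle["mcs"], mcs_raw)
        morf_dc_n = compute_morf_dc(mcs_n, disorder_n, morf_dc_map=bundle["morf_dc"])
        chibi_n = apply_map(bundle["chibi"], chibi_tracks[sid])
        final = compute_final(morf_dc_n, chibi_n)
        results.append(
            PredictionResult(
                sequence_id=sid,
                ipp_n=ipp_n,
                rwgrmp_n=rw_n,
                wop_n=wop_n,
                ics=ics_n,
                disorder_n=disorder_n,
                mcs=mcs_n,
                morf_dc=morf_dc_n,
                chibi_n=chibi_n,
                final=final,
                calls=call_morfs(final, config.cutoff),
            )
        )
    return results


def write_predictions(results, sequences, prefix) -> tuple[Path, Path]:
    """Write per-residue scores and called intervals as TSV files.

    Produces ``<prefix>.scores.tsv`` (all intermediate tracks, one row per
    residue) and ``<prefix>.calls.tsv``.  Float formatting is fixed so that
    repeated runs on identical inputs are byte-identical.
    """
    prefix = Path(prefix)
    seq_map = {rec.id: rec for rec in sequences} if not isinstance(sequences, dict) else sequences
    scores_path = prefix.with_name(prefix.name + ".scores.tsv")
    calls_path = prefix.with_name(prefix.name + ".calls.tsv")

    with open(scores_path, "w") as fh:
        fh.write("seq_id\tpos\taa\t" + "\t".join(PredictionResult.TRACK_NAMES) + "\n")
        for res in results:
            seq = seq_map[res.sequence_id].residues
            cols = [getattr(res, name).values for name in PredictionResult.TRACK_NAMES]
            for i in range(len(seq)):
                row = "\t".join(format(c[i], ".12g") for c in cols)
                fh.write(f"{res.sequence_id}\t{i + 1}\t{seq[i]}\t{row}\n")

    with open(calls_path, "w") as fh:
        fh.write("seq_id\tstart\tend\n")
        for res in results:
            for start, end in res.calls:
                fh.write(f"{res.sequence_id}\t{start}\t{end}\n")
    return scores_path, calls_path


# ---------------------------------------------------------------------------

def _track_mapping(tracks) -> dict[str, ResidueTrack]:
    if isinstance(tracks, dict):
        return tracks
    return {t.sequence_id: t for t in tracks}


def _check_components(sequences, profiles, disorder_tracks, chibi_tracks) -> None:
    missing: dict[str, list[str]] = {"PSSM": [], "disorder": [], "chibi": []}
    for rec in sequences:
        if rec.id not in profiles:
            missing["PSSM"].append(rec.id)
        if rec.id not in disorder_tracks:
            missing["disorder"].append(rec.id)
        if rec.id not in chibi_tracks:
            missing["chibi"].append(rec.id)
    problems = [
        f"{kind} missing for: {', '.join(ids)}" for kind, ids in missing.items() if ids
    ]
    if problems:
        raise ValueError("; ".join(problems))
    for rec in sequences:
        L = len(rec)
        for kind, obj in (
            ("PSSM", profiles[rec.id]),
            ("disorder", disorder_tracks[rec.id]),
            ("chibi", chibi_tracks[rec.id]),
        ):
            if len(obj) != L:
                raise ValueError(
                    f"{kind} length {len(obj)} != sequence length {L} for {rec.id!r}"
                )
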