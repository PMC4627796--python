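"""Bayes-rule combination of normalized propensity tracks.

Each normalized score is treated as an independent two-class posterior with
equal priors, so the combined posterior at a residue is

    combined = prod(p_i) / ( prod(p_i) + prod(1 - p_i) )

which reduces to the identity for a single track and leaves 0.5 fixed.  The
product is evaluated as a sum of log-odds followed by the logistic inverse,
which is exact for this form and immune to underflow on long products.

The output is flagged raw: each fusion level of the hierarchy re-normalizes
its combined score with a freshly fitted rank map before the next level, and
that inter-level normalization is what distinguishes the hierarchy from a
flat product over all components.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

from .tracks_io import ResidueTrack, Space


def log_odds(track: ResidueTrack) -> ResidueTrack:
    """Elementwise ln(p / (1 - p)) of a normalized track."""
    if track.space is not Space.NORMALIZED:
        raise ValueError("log_odds requires a normalized-space track")
    v = track.values
    if np.any(v <= 0.0) or np.any(v >= 1.0):
        raise ValueError("log_odds undefined at 0 or 1")
    return ResidueTrack(track.sequence_id, logit(v), Space.RAW, feature=None)


def logistic(values) -> np.ndarray:
    """Inverse of the log-odds transform, 1 / (1 + exp(-x))."""
    return expit(np.asarray(values, dtype=float))


def bayes_combine(tracks) -> ResidueTrack:
    """Combine one or more normalized tracks for the same sequence.

    Symmetric in its inputs and strictly monotone in each of them; output
    values are strictly inside (0, 1) whenever the inputs are.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("bayes_combine needs at least one track")
    sid = tracks[0].sequence_id
    length = len(tracks[0])
    for t in tracks:
        if t.sequence_id != sid:
            raise ValueError(
                f"mixed sequence ids in bayes_combine: {sid!r} vs {t.sequence_id!r}"
            )
        if len(t) != length:
            raise ValueError(f"track length mismatch for {sid!r}")
        if t.space is not Space.NORMALIZED:
            raise ValueError("bayes_combine requires normalized-space tracks")
    total = np.zeros(length)
    for t in tracks:
        total += logit(t.values)
    return ResidueTrack(sid, expit(total), Space.RAW, feature=None)
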