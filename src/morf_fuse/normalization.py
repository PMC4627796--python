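"""Rank-to-Gaussian score normalization.

Propensity tracks coming from heterogeneous predictors live on unknown,
often skewed scales.  Before Bayes-rule fusion each feature D is passed
through a monotone map, fitted once on a training population, that carries
scores from the empirical distribution to a Gaussian N(mu = 0.5,
sigma^2 = 0.01):

    normalized(x) = mu + sigma * Phi^-1( clip( ecdf(x), eps, 1 - eps ) )

where ``ecdf(x)`` is the fraction of training scores <= x (ties share one
cumulative value) and ``Phi^-1`` is the standard normal quantile function.
Clipping at ``eps`` keeps every normalized value strictly inside (0, 1), so
no single component can saturate the fused posterior: with sigma = 0.1
essentially all mass lies in (0.2, 0.8) and extreme raw outliers are tamed
to the map's floor/ceiling.

Between training knots the cumulative probability is interpolated linearly
in the raw value; below the smallest knot it is 0 (clipped to eps), above
the largest it is 1 (clipped to 1 - eps).  The map is therefore monotone
non-decreasing everywhere and strictly increasing across the observed range.

``eps`` defaults to max(1/(2n), 1e-6) for a training population of size n:
resolution grows with data while Phi^-1(0) and Phi^-1(1) stay unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .tracks_io import ResidueTrack, Space

MAP_FORMAT_VERSION = "morf-fuse-normalization-map v1"

MIN_TRAINING_SCORES = 100


@dataclass
class NormalizationMap:
    """Monotone raw -> N(0.5, 0.01) map for one named feature."""

    feature_name: str
    knots_raw: np.ndarray   # strictly increasing raw values
    knots_cum: np.ndarray   # matching cumulative probabilities, in (0, 1]
    epsilon: float
    mu: float = 0.5
    sigma: float = 0.1
    n_training: int = field(default=0)

    def __post_init__(self) -> None:
        self.knots_raw = np.asarray(self.knots_raw, dtype=float)
        self.knots_cum = np.asarray(self.knots_cum, dtype=float)
        if self.knots_raw.size == 0:
            raise ValueError("normalization map has no knots")
        if self.knots_raw.shape != self.knots_cum.shape:
            raise ValueError("knot arrays have mismatched shapes")
        if np.any(np.diff(self.knots_raw) <= 0):
            raise ValueError("knot raw values must be strictly increasing")
        if np.any(np.diff(self.knots_cum) < 0):
            raise ValueError("knot cumulative probabilities must be non-decreasing")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError(f"epsilon {self.epsilon} outside (0, 0.5)")

    def transform(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        p = np.interp(x, self.knots_raw, self.knots_cum)
        # below the smallest training score the cumulative fraction is 0;
        # np.interp clamps to the first knot's value instead, so override.
        p = np.where(x < self.knots_raw[0], 0.0, p)
        p = np.clip(p, self.epsilon, 1.0 - self.epsilon)
        return self.mu + self.sigma * ndtri(p)

    @property
    def floor(self) -> float:
        """Smallest reachable normalized value, mu + sigma * Phi^-1(eps)."""
        return self.mu + self.sigma * float(ndtri(self.epsilon))

    @property
    def ceiling(self) -> float:
        return self.mu + self.sigma * float(ndtri(1.0 - self.epsilon))


def fit_map(training_scores, feature_name: str, epsilon: float | None = None) -> NormalizationMap:
    """Fit a normalization map on a training score population.

    Requires at least 100 finite scores.  Knots are the sorted distinct
    training values; each knot's cumulative probability is the fraction of
    training scores less than or equal to it.
    """
    scores = np.asarray(training_scores, dtype=float).ravel()
    if scores.size < MIN_TRAINING_SCORES:
        raise ValueError(
            f"need >= {MIN_TRAINING_SCORES} training scores for {feature_name!r}, "
            f"got {scores.size}"
        )
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"non-finite training scores for {feature_name!r}")
    n = scores.size
    uniq, counts = np.unique(scores, return_counts=True)
    cum = np.cumsum(counts) / n
    if epsilon is None:
        epsilon = max(1.0 / (2 * n), 1e-6)
    return NormalizationMap(
        feature_name=feature_name,
        knots_raw=uniq,
        knots_cum=cum,
        epsilon=float(epsilon),
        n_training=n,
    )


def apply_map(nmap: NormalizationMap, track: ResidueTrack) -> ResidueTrack:
    """Apply a fitted map elementwise to a raw-space track."""
    if track.space is not Space.RAW:
        raise ValueError(
            f"apply_map expects a raw-space track, got {track.space.value!r}"
        )
    if track.feature is not None and track.feature != nmap.feature_name:
        raise ValueError(
            f"map fitted for feature {nmap.feature_name!r} applied to track of "
            f"feature {track.feature!r}"
        )
    return ResidueTrack(
        track.sequence_id,
        nmap.transform(track.values),
        Space.NORMALIZED,
        feature=nmap.feature_name,
    )


# ---------------------------------------------------------------------------
# Persistence: versioned, self-describing text format.

_FLOAT_FMT = ".17g"  # round-trips IEEE doubles exactly


def save_map(nmap: NormalizationMap, path) -> None:
    if nmap.knots_raw.size == 0:
        raise ValueError("refusing to save a map with no knots")
    with open(path, "w") as fh:
        fh.write(MAP_FORMAT_VERSION + "\n")
        fh.write(f"feature\t{nmap.feature_name}\n")
        fh.write(f"epsilon\t{format(nmap.epsilon, _FLOAT_FMT)}\n")
        fh.write(f"mu\t{format(nmap.mu, _FLOAT_FMT)}\n")
        fh.write(f"sigma\t{format(nmap.sigma, _FLOAT_FMT)}\n")
        fh.write(f"n_training\t{nmap.n_training}\n")
        fh.write(f"knots\t{nmap.knots_raw.size}\n")
        for raw, cum in zip(nmap.knots_raw, nmap.knots_cum):
            fh.write(f"{format(raw, _FLOAT_FMT)}\t{format(cum, _FLOAT_FMT)}\n")


def load_map(path) -> NormalizationMap:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != MAP_FORMAT_VERSION:
        raise ValueError(f"{path}: not a {MAP_FORMAT_VERSION!r} file")
    header: dict[str, str] = {}
    idx = 1
    while idx < len(lines):
        parts = lines[idx].split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed header line {idx + 1}")
        key, value = parts
        header[key] = value
        idx += 1
        if key == "knots":
            break
    for required in ("feature", "epsilon", "mu", "sigma", "knots"):
        if required not in header:
            raise ValueError(f"{path}: missing {required!r} field")
    n_knots = int(header["knots"])
    rows = lines[idx : idx + n_knots]
    if len(rows) != n_knots:
        raise ValueError(f"{path}: expected {n_knots} knot rows, found {len(rows)}")
    knots_raw = np.empty(n_knots)
    knots_cum = np.empty(n_knots)
    for i, row in enumerate(rows):
        parts = row.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed knot row {idx + i + 1}")
        knots_raw[i], knots_cum[i] = float(parts[0]), float(parts[1])
    return NormalizationMap(
        feature_name=header["feature"],
        knots_raw=knots_raw,
        knots_cum=knots_cum,
        epsilon=float(header["epsilon"]),
        mu=float(header["mu"]),
        sigma=float(header["sigma"]),
        n_training=int(header.get("n_training", 0)),
    )
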