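"""Seeded synthetic datasets with the statistical structure the method assumes.

Each simulated protein carries one intrinsically disordered region (IDR)
and, inside it, one MoRF interval (5-25 residues in ``short`` mode, 31-45 in
``long`` mode).  Per-residue component scores are drawn from class-
conditional Beta distributions:

* disorder is elevated over the whole IDR — including the MoRF, which does
  not dip, as a long-disorder predictor behaves;
* the local-sequence (chibi-style) propensity and the conservation features
  IPP and WOP are enriched in MoRFs; RWGRMP is depleted in MoRFs
  (anti-correlated), matching the complement rule downstream;
* all families are class-conditionally independent by default; a Gaussian
  copula ``correlation`` knob couples them to probe robustness when the
  fusion model's independence premise is violated.

Default Beta parameters give single-source MoRF-vs-rest AUCs of roughly
0.65-0.75, the realistic operating range for individual predictors.  The
``well_separated`` preset strengthens every family to an (8,2)/(2,8)
contrast for label-recovery checks.

Conservation features are emitted both in memory and as syntactically valid
PSI-BLAST ASCII PSSM files; IPP and RWGRMP are quantized to two decimals at
generation time so the written files round-trip the planted values exactly.
Every generator is pure given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .pssm import AA_INDEX, PSSMProfile
from .tracks_io import (
    MoRFAnnotation,
    ResidueTrack,
    SequenceRecord,
    Space,
    write_annotations,
    write_fasta,
    write_track,
)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

MORF_LENGTHS = {"short": (5, 25), "long": (31, 45)}


@dataclass
class SimSpec:
    """Generative settings for one synthetic dataset."""

    n_sequences: int = 100
    length_range: tuple[int, int] = (120, 240)
    morf_mode: str = "short"  # short | long | mixed
    idr_fraction: tuple[float, float] = (0.35, 0.55)
    # class-conditional Beta(a, b) parameters
    disorder_idr: tuple[float, float] = (5.0, 3.0)
    disorder_ordered: tuple[float, float] = (3.0, 5.0)
    chibi_morf: tuple[float, float] = (4.0, 3.0)
    chibi_other: tuple[float, float] = (3.0, 4.0)
    ipp_morf: tuple[float, float] = (4.0, 3.0)
    ipp_other: tuple[float, float] = (3.0, 4.0)
    wop_morf: tuple[float, float] = (4.0, 3.0)
    wop_other: tuple[float, float] = (3.0, 4.0)
    rwgrmp_morf: tuple[float, float] = (3.0, 4.0)  # anti-correlated with MoRFs
    rwgrmp_other: tuple[float, float] = (4.0, 3.0)
    ipp_scale: float = 2.0
    rwgrmp_scale: float = 1.5
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.morf_mode not in ("short", "long", "mixed"):
            raise ValueError(f"unknown morf_mode {self.morf_mode!r}")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        max_morf = max(
            MORF_LENGTHS[m][1]
            for m in (("short", "long") if self.morf_mode == "mixed" else (self.morf_mode,))
        )
        if max_morf + 4 > lo:
            raise ValueError(
                f"MoRFs up to {max_morf} residues cannot fit in sequences of "
                f"length >= {lo}"
            )

    @classmethod
    def well_separated(cls, **overrides) -> "SimSpec":
        """Strong class contrast on every MoRF-linked feature family."""
        strong, weak = (8.0, 2.0), (2.0, 8.0)
        params = dict(
            disorder_idr=strong, disorder_ordered=weak,
            chibi_morf=strong, chibi_other=weak,
            ipp_morf=strong, ipp_other=weak,
            wop_morf=strong, wop_other=weak,
            rwgrmp_morf=weak, rwgrmp_other=strong,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class SimDataset:
    """In-memory view of one simulated dataset."""

    spec: SimSpec
    sequences: list[SequenceRecord]
    annotations: list[MoRFAnnotation]
    disorder_tracks: dict[str, ResidueTrack]
    chibi_tracks: dict[str, ResidueTrack]
    profiles: dict[str, PSSMProfile]
    morf_masks: dict[str, np.ndarray] = field(default_factory=dict)
    idr_masks: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_dataset(spec: SimSpec) -> SimDataset:
    """Generate sequences, annotations, score tracks and PSSM profiles."""
    rng = np.random.default_rng(spec.seed)
    sequences = []
    annotations = []
    disorder_tracks = {}
    chibi_tracks = {}
    profiles = {}
    morf_masks = {}
    idr_masks = {}

    for i in range(spec.n_sequences):
        sid = f"syn{i:04d}"
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        mode = spec.morf_mode
        if mode == "mixed":
            mode = "short" if rng.random() < 0.5 else "long"
        mlo, mhi = MORF_LENGTHS[mode]
        morf_len = int(rng.integers(mlo, mhi + 1))

        frac = rng.uniform(*spec.idr_fraction)
        idr_len = min(max(int(round(L * frac)), morf_len + 4), L)
        idr_start = int(rng.integers(0, L - idr_len + 1))
        morf_start = idr_start + int(rng.integers(0, idr_len - morf_len + 1))

        idr = np.zeros(L, dtype=bool)
        idr[idr_start : idr_start + idr_len] = True
        morf = np.zeros(L, dtype=bool)
        morf[morf_start : morf_start + morf_len] = True

        residues = "".join(rng.choice(list(STANDARD_AA), size=L))
        sequences.append(SequenceRecord(sid, residues))
        annotations.append(
            MoRFAnnotation(sid, [(morf_start + 1, morf_start + morf_len, "morf")])
        )

        draw = _make_sampler(rng, L, spec.correlation)
        disorder = draw(idr, spec.disorder_idr, spec.disorder_ordered)
        chibi = draw(morf, spec.chibi_morf, spec.chibi_other)
        ipp = _quantize(spec.ipp_scale * draw(morf, spec.ipp_morf, spec.ipp_other))
        wop_frac = draw(morf, spec.wop_morf, spec.wop_other)
        wop = np.clip(np.floor(100.0 * wop_frac), 0, 100).astype(int)
        rwgrmp = _quantize(
            spec.rwgrmp_scale * draw(morf, spec.rwgrmp_morf, spec.rwgrmp_other)
        )

        disorder_tracks[sid] = ResidueTrack(sid, disorder, Space.RAW, feature="disorder")
        chibi_tracks[sid] = ResidueTrack(sid, chibi, Space.RAW, feature="chibi")
        profiles[sid] = _build_profile(sid, residues, ipp, wop, rwgrmp)
        morf_masks[sid] = morf
        idr_masks[sid] = idr

    return SimDataset(
        spec=spec,
        sequences=sequences,
        annotations=annotations,
        disorder_tracks=disorder_tracks,
        chibi_tracks=chibi_tracks,
        profiles=profiles,
        morf_masks=morf_masks,
        idr_masks=idr_masks,
    )


def _make_sampler(rng: np.random.Generator, L: int, rho: float):
    """Class-conditional Beta sampler, optionally coupled by a Gaussian copula.

    With rho = 0 each feature family draws independently; with rho > 0 all
    families generated for the same sequence share a per-residue latent
    normal, inducing cross-family correlation while preserving the marginal
    Beta distributions.
    """
    if rho == 0.0:
        def draw(mask, ab_in, ab_out):
            values = np.empty(L)
            values[mask] = rng.beta(*ab_in, size=int(mask.sum()))
            values[~mask] = rng.beta(*ab_out, size=int((~mask).sum()))
            return values
        return draw

    shared = rng.standard_normal(L)

    def draw(mask, ab_in, ab_out):
        z = rho * shared + np.sqrt(1.0 - rho * rho) * rng.standard_normal(L)
        u = norm.cdf(z)
        values = np.empty(L)
        values[mask] = beta_dist.ppf(u[mask], *ab_in)
        values[~mask] = beta_dist.ppf(u[~mask], *ab_out)
        return values

    return draw


def _quantize(values: np.ndarray) -> np.ndarray:
    """Round to two decimals so '%.2f' file output round-trips exactly."""
    return np.round(values * 100.0) / 100.0


def _build_profile(sid, residues, ipp, wop_query, rwgrmp) -> PSSMProfile:
    L = len(residues)
    wop = np.zeros((L, 20), dtype=int)
    for i, aa in enumerate(residues):
        col = AA_INDEX.get(aa)
        if col is not None:
            wop[i, col] = wop_query[i]
    return PSSMProfile(
        sequence_id=sid,
        query_residues=residues,
        log_odds=np.zeros((L, 20), dtype=int),
        wop=wop,
        ipp=ipp,
        rwgrmp=rwgrmp,
    )


# ---------------------------------------------------------------------------
# ASCII PSSM writing

_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)
_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def write_synthetic_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect the parser accepts.

    Planted IPP/WOP/RWGRMP values are recovered exactly on re-parsing,
    provided IPP and RWGRMP carry at most two decimals (the column format).
    """
    if len(profile) == 0:
        raise ValueError("refusing to write a zero-length profile")
    if profile.wop.min() < 0 or profile.wop.max() > 100:
        raise ValueError("WOP values outside [0, 100]")
    letters = "  ".join(_AA_ORDER)
    with open(path, "w") as fh:
        fh.write("\n" + _PSSM_HEADER + "\n")
        fh.write("            " + letters + "   " + letters + "\n")
        for i in range(len(profile)):
            lo = "".join(f"{v:4d}" for v in profile.log_odds[i])
            wp = "".join(f"{v:4d}" for v in profile.wop[i])
            fh.write(
                f"{i + 1:5d} {profile.query_residues[i]} {lo}  {wp}"
                f"  {profile.ipp[i]:5.2f} {profile.rwgrmp[i]:9.2f}\n"
            )
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1374     0.3176\n")
        fh.write("Standard Gapped      0.0410     0.2670\n")


def write_dataset(dataset: SimDataset, outdir) -> dict[str, Path]:
    """Write a simulated dataset to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)

    paths = {
        "fasta": outdir / "sequences.fasta",
        "annotations": outdir / "annotations.tsv",
        "disorder": outdir / "disorder.tsv",
        "chibi": outdir / "chibi.tsv",
        "pssm_dir": pssm_dir,
    }
    write_fasta(dataset.sequences, paths["fasta"])
    write_annotations(dataset.annotations, paths["annotations"])
    seq_map = {rec.id: rec for rec in dataset.sequences}
    write_track(
        [dataset.disorder_tracks[r.id] for r in dataset.sequences],
        seq_map, paths["disorder"],
    )
    write_track(
        [dataset.chibi_tracks[r.id] for r in dataset.sequences],
        seq_map, paths["chibi"],
    )
    for rec in dataset.sequences:
        write_synthetic_pssm(dataset.profiles[rec.id], pssm_dir / f"{rec.id}.pssm")
    return paths
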