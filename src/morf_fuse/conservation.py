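"""Conservation propensity scores: ics and its MoRF-aware smoothing mcs.

The initial conservation score ics is the Bayes combination of the three
normalized PSSM features — IPP, the complement of RWGRMP, and WOP — refit to
the normalized scale so that the window thresholds below are quantile
meaningful.

mcs then rewrites ics residue by residue under two window rules that encode
what a MoRF looks like to a conservation track: a short disordered window
containing a handful of well-conserved residues is MoRF-like (its signal is
amplified and spread over the window), while a longer structured window with
uniformly unremarkable conservation is MoRF-unlike (its signal is damped).

Scenario 1 (checked first): residue r sits at the center of a 7-residue
window whose average normalized disorder exceeds ``disorder_hi`` (0.45) and
which contains k >= ``min_conserved`` (3) residues with ics >
``ics_conserved`` (0.45).  Then mcs(r) is the mean ics of those k conserved
residues, and for every conserved residue beyond the third a square root is
applied twice — i.e. the mean is raised to the power 1/4^(k-3) — pushing
mcs toward 1 as conservation evidence accumulates.

Scenario 2: residue r sits at the center of a 15-residue window whose
average normalized disorder is below ``disorder_lo`` (0.45) and in which no
residue has ics > ``ics_cap`` (0.60).  Then mcs(r) = ics(r) times the window
average disorder, damping structured unconserved stretches.

Every other residue keeps mcs(r) = ics(r).  All inequalities are strict, so
a disorder track pinned at exactly 0.45 fires neither scenario.  Windows are
truncated at the sequence ends and averages taken over the residues present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fusion import bayes_combine
from .normalization import NormalizationMap, apply_map
from .tracks_io import ResidueTrack, Space


@dataclass
class McsParams:
    """Window sizes and thresholds of the two mcs scenarios.

    ``root_per_extra`` selects the square-root boost arity: True applies the
    root twice per extra conserved residue (exponent 1/4^(k-3)); False
    applies it twice in total whenever k > 3 (exponent 1/4).
    """

    disorder_window: int = 7
    structured_window: int = 15
    disorder_hi: float = 0.45
    disorder_lo: float = 0.45
    ics_conserved: float = 0.45
    ics_cap: float = 0.60
    min_conserved: int = 3
    root_per_extra: bool = True

    def __post_init__(self) -> None:
        for name in ("disorder_window", "structured_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
        for name in ("disorder_hi", "disorder_lo", "ics_conserved", "ics_cap"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_conserved < 1:
            raise ValueError("min_conserved must be >= 1")


def compute_ics(
    ipp_n: ResidueTrack,
    rwgrmp_c: ResidueTrack,
    wop_n: ResidueTrack,
    ics_map: NormalizationMap | None = None,
) -> ResidueTrack:
    """Bayes-combine the three normalized conservation features.

    ``rwgrmp_c`` must already be the complement of normalized RWGRMP.  When
    ``ics_map`` (fitted on the training population of combined values) is
    given, the combination is re-normalized so downstream thresholds act on
    the (0, 1) quantile scale; otherwise the raw combination is returned.
    """
    combined = bayes_combine([ipp_n, rwgrmp_c, wop_n])
    combined.feature = "ics"
    if ics_map is None:
        return combined
    return apply_map(ics_map, combined)


def compute_mcs(
    ics: ResidueTrack, disorder_n: ResidueTrack, params: McsParams | None = None
) -> ResidueTrack:
    """Apply the two mcs window rules to an ics track.

    Window averages use exactly rounded floating-point sums (``math.fsum``)
    and the scenario-1 boost applies ``math.sqrt`` literally, twice per
    extra conserved residue, so results are independent of summation order
    and reproducible bit for bit across implementations of the rules.
    """
    if params is None:
        params = McsParams()
    if len(ics) != len(disorder_n):
        raise ValueError("ics and disorder tracks have different lengths")
    if ics.sequence_id != disorder_n.sequence_id:
        raise ValueError("ics and disorder tracks refer to different sequences")
    if disorder_n.space is not Space.NORMALIZED:
        raise ValueError("disorder track must be in normalized space")

    v_ics = ics.values
    v_dis = disorder_n.values
    L = v_ics.size
    h1 = params.disorder_window // 2
    h2 = params.structured_window // 2

    mcs = np.empty(L)
    for r in range(L):
        lo, hi = max(0, r - h1), min(L, r + h1 + 1)
        dis_avg = math.fsum(v_dis[lo:hi]) / (hi - lo)
        if dis_avg > params.disorder_hi:
            cons = v_ics[lo:hi]
            cons = cons[cons > params.ics_conserved]
            k = cons.size
            if k >= params.min_conserved:
                value = math.fsum(cons) / k
                extras = k - params.min_conserved
                if params.root_per_extra:
                    for _ in range(2 * extras):
                        value = math.sqrt(value)
                elif extras > 0:
                    value = math.sqrt(math.sqrt(value))
                mcs[r] = value
                continue
        lo2, hi2 = max(0, r - h2), min(L, r + h2 + 1)
        window_ics = v_ics[lo2:hi2]
        dis_avg2 = math.fsum(v_dis[lo2:hi2]) / (hi2 - lo2)
        if dis_avg2 < params.disorder_lo and window_ics.max() <= params.ics_cap:
            mcs[r] = v_ics[r] * dis_avg2
        else:
            mcs[r] = v_ics[r]

    return ResidueTrack(ics.sequence_id, mcs, ics.space, feature="mcs")
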