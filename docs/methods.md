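# Methods

## Problem and model

MoRFs (molecular recognition features) are short binding elements inside
intrinsically disordered regions. No single signal identifies them well:
local sequence composition, long-range disorder and evolutionary
conservation each give per-residue AUCs in the 0.6–0.75 range on realistic
data. `morf-fuse` treats each of these as an independently computed
propensity track and fuses them with Bayes rule in a fixed hierarchy,
conservation first being reshaped into a MoRF-specific score.

The fusion primitive treats k normalized scores p_i in (0, 1) as
independent two-class posteriors under equal priors:

    combined = prod(p_i) / ( prod(p_i) + prod(1 - p_i) ).

It is symmetric, strictly monotone in each input, reduces to the identity
for k = 1, and leaves 0.5 (the non-informative point) fixed. It is computed
as a sum of log-odds followed by the logistic inverse, which is
algebraically identical and immune to underflow. Equal priors are a
deliberate choice: the class imbalance of MoRFs is left to the score scale
rather than folded into the combination, and no per-component weights are
learned. A consequence worth knowing: fusing a strong track with a weaker
independent one can yield an AUC between the two — unweighted fusion
guarantees no dominance over its best input, only over each *source of
information* when the sources are complementary.

## Rank-to-Gaussian normalization

Propensities from heterogeneous predictors are not probabilities; extreme
values near 0 or 1 would dominate the product. Each feature D therefore
gets a map fitted once on a training population:

    Map_D(x) = mu + sigma * Phi^-1( clip( ecdf(x), eps, 1 - eps ) )

with mu = 0.5 and sigma = 0.1 (target N(0.5, 0.01)). Conventions:

* `ecdf(x)` is the fraction of training scores **≤ x**; ties share one
  cumulative value.
* `eps = max(1/(2n), 1e-6)` for n training scores: resolution grows with
  data, Phi^-1(0)/Phi^-1(1) stay unreachable, and every output is strictly
  inside (0, 1).
* Between the sorted distinct training values the cumulative probability is
  interpolated **linearly in the raw value** (monotone and deterministic;
  the step-function alternative would make query scores between close knots
  ambiguous under float noise). Below the smallest training score the
  cumulative probability is 0, clipped to eps — the map's floor is
  `0.5 + 0.1 * Phi^-1(eps)`; above the largest it is 1, clipped to 1 − eps.
* Maps are fitted on the designated training set only and never refitted on
  query data.

Because ecdf of a constant population is 1 everywhere, a constant raw
track does not normalize to 0.5; "non-informative component" means a
constant 0.5 track *on the normalized scale*, which contributes zero
log-odds and leaves the fusion unchanged exactly.

The fitted map of a feature is a full knot table (one knot per distinct
training value, ~2 × 10^4 knots for a 100-sequence training set). Bundles
are therefore built on demand (`morf-fuse train`, seconds of work) rather
than shipped with the package.

## Conservation scores

Three features are read from PSI-BLAST ASCII PSSMs (44-column dialect:
position, query residue, 20 log-odds, 20 weighted observed percentages,
information per position, relative weight): IPP, the query residue's WOP
(integers as printed — the file already stores them rounded down), and
RWGRMP. Query residues without a PSSM column (X/B/Z/U) get WOP = 0 and a
log warning: an unknown residue carries no conservation evidence. RWGRMP
is anti-correlated with MoRFs, so fusion consumes its complement `1 − v`,
taken on the normalized scale where the N(0.5, 0.01) target is symmetric
about 0.5 and the complement is exact (raw RWGRMP is unbounded above, so a
raw-scale complement would be ill-defined).

`ics` is the Bayes combination of the three, re-normalized with its own
training map so that the window thresholds below are quantile-meaningful.

`mcs` rewrites ics under two rules (all inequalities strict; windows
truncated at sequence ends, averages over the residues present, center
always included):

* **Scenario 1** (checked first): center of a 7-residue window with average
  normalized disorder > 0.45 containing k ≥ 3 residues with ics > 0.45 →
  the mean ics of those k conserved residues (the center counted only if it
  qualifies), with a square root applied twice per conserved residue beyond
  the third, i.e. exponent 1/4^(k−3). Roots of values in (0, 1) only
  increase them, so accumulating conservation evidence pushes mcs toward 1.
  The alternative reading — the root pair applied once total whenever
  k > 3 — is selectable via `McsParams(root_per_extra=False)`.
* **Scenario 2**: center of a 15-residue window with average disorder
  < 0.45 and no window ics > 0.60 → ics × window-average disorder, damping
  structured unconserved stretches (always ≤ ics, since the factor is
  < 0.45).
* Otherwise mcs = ics. Both scenario conditions use 0.45 on the disorder
  average with opposite strict inequalities but different window sizes, so
  overlap is possible; scenario 1 — the MoRF-positive signal — wins.

Numerical choice: window averages use exactly rounded summation
(`math.fsum`) and the boost applies `sqrt` literally rather than `pow`,
so mcs values are independent of summation order and bit-reproducible
across any faithful re-implementation of the rules — the test suite holds
a naive per-residue oracle to exact (bit-level) agreement.

## Hierarchy and calling

    ics -> mcs -> normalize -> +disorder -> MoRF_DC -> normalize -> +chibi -> final

Each intermediate fusion output is re-normalized before the next level;
this inter-level rank refit is what distinguishes the hierarchy from a
flat product of all five normalized features (a property the tests assert
as inequality of tracks). The final score stays on (0, 1) un-refitted.
Interval calling takes maximal runs of final ≥ cutoff, default 0.66, with
the comparison closed so the suggested cutoff is inclusive. The disorder
track is used in normalized form both inside the mcs window conditions and
in the MoRF_DC fusion.

## Evaluation

Per-residue ROC_MoRF with micro-averaging: residues pooled across the
dataset, TPR = TP/N_MoRF, FPR = FP/N_non-MoRF, positive call at
score ≥ threshold. The curve is tie-grouped (all residues at a threshold
change status together), so its trapezoidal area equals the Mann–Whitney
concordance probability with half credit for ties. `fpr_at_tpr` returns
the smallest FPR among thresholds whose TPR reaches the target, since
discrete score sets rarely hit a target exactly. Length-based masking
removes MoRF intervals > 30 residues (`short_only`) or ≤ 30 (`long_only`)
from both classes; explicitly `masked` annotation intervals are always
removed. No deduplication of near-identical sequences is applied. AUC is
invariant under any strictly monotone transform of the scores, which the
tests use as a regression guard: normalization never changes a feature's
AUC_MoRF on the population its map was fitted on.

## Synthetic data

The generator emulates the structure the method assumes: each sequence has
one IDR (35–55% of its length) containing one MoRF (5–25 residues in
`short` mode, 31–45 in `long`); disorder is drawn Beta(5,3) over the IDR —
including the MoRF, which does not dip — and Beta(3,5) elsewhere; chibi,
IPP and WOP are Beta(4,3) in MoRFs vs Beta(3,4) outside; RWGRMP is
reversed (Beta(3,4) in MoRFs). These defaults put every single-source
MoRF-vs-rest AUC near 0.7, the realistic operating range for individual
predictors; the `well_separated` preset raises every contrast to
Beta(8,2)/Beta(2,8) for label-recovery checks. Feature families are
class-conditionally independent by default (the fusion model's premise); a
Gaussian-copula `correlation` knob couples them to probe robustness. IPP
and RWGRMP are quantized to two decimals at generation so the written
ASCII PSSMs round-trip the planted values exactly.

What passing tests on this data do **not** show: real disorder and
conservation predictors are correlated through the underlying alignment,
real MoRF boundaries are uncertain, sequences are homologous, and
annotation is sparse (a sequence may contain unannotated true MoRFs). The
synthetic results bound the method's behavior under its own assumptions,
not its accuracy on curated benchmarks. One visible artifact: because the
generative process matches the mcs window rules exactly, mcs alone can
separate classes better than the final fused score (the weaker
local-sequence component dilutes the unweighted product) — on real data,
where mcs's assumptions hold only approximately, the fused score is the
robust choice.

## Problem sizes and degenerate inputs

Tests and the acceptance script use 100-sequence datasets (~18,000
residues) for label recovery, 10^5-point samples for the normalization
moment checks, 10^3–10^4 random instances for oracle equivalences; all
generators are pure given (spec, seed). Degenerate inputs are rejected
early with named errors: empty sequences, duplicate FASTA ids, track
position gaps, residue mismatches between track and FASTA, overlapping or
out-of-range annotation intervals, PSSM rows with wrong column counts,
normalization with < 100 training scores, fusion of tracks from different
sequences or outside (0, 1).

## Known limitations

* The Bayes combination uses equal priors and no component weights; a
  prior reflecting MoRF sparseness could be added but none is defined here.
* The complement rule and all thresholds are fixed configuration; no
  threshold learning is included.
* Disorder and local-sequence propensity tracks are consumed pre-computed;
  the package does not run the upstream predictors or PSI-BLAST.
* Only the 44-column ASCII PSSM dialect is parsed.
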