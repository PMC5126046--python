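# Methods

This note documents the models, estimators and design choices behind
`phagehgt`, and what the synthetic-data tests do and do not demonstrate.

## The screening logic

A temperate phage integrated in genome A is a *recent-transfer* candidate in
genome B when (i) its genes are much more similar to one phage of B than to
B's other resident phages, (ii) that similarity is at least as high as the
similarity of the two hosts' own orthologs (a phage that arrived recently
has had less time to diverge than the host backgrounds), and (iii) vertical
descent would require an implausible number of independent phage losses on
the host phylogeny. Supporting evidence comes from presence/absence of the
phage's cargo genes across genome sets, compositional (GC) anomaly of cargo
regions, att-site structure, and phage:host copy ratios from qPCR.

## Sequence comparison

Pairwise global alignment uses affine-gap scoring (match +2, mismatch −3,
gap open −5, gap extend −2; a gap of length k costs open + (k−1)·extend),
computed by Biopython's `PairwiseAligner` with deterministic first-traceback
tie-breaking. An exhaustive alignment enumerator in the test suite verifies
score optimality on small inputs.

Poorly aligned columns are removed by a simplified conserved-block filter: a
column passes iff its gap fraction is strictly below `max_gap_fraction`
(default 0.5 — for pairwise alignments this removes every gapped column);
maximal runs of passing columns are kept only if they are at least
`min_block_len` (10) columns long with mean match fraction at least
`min_conservation` (0.5). This is deliberately not a bit-exact reproduction
of any published trimmer; group-level identity statistics are insensitive to
the residual differences at the precision reported.

Percent identity defaults to matches over gap-free columns.

The homology screen is a seeded search: 11-mer exact seeds, one ungapped
X-drop extension per (query, subject) diagonal family, and an E-value
E = K·m·N·exp(−λS) with λ solved exactly from the scoring scheme
(Σ pᵢpⱼ e^{λ sᵢⱼ} = 1 at uniform base frequencies) and K fixed at 0.1, a
standard-order approximation. Only the cutoff (default 10⁻⁵) is
scientifically load-bearing; presence calls are monotone in it.

Ortholog pairing is reciprocal-best-hit by post-trim identity (ties: longer
aligned length, then lexicographic id). Synteny blocks are maximal runs of
pairs consecutive in both gene orders with consistent orientation; genes
private to one side form discrepant regions. Every gene lands in exactly one
block or one region.

## Nei–Gojobori synonymous divergence

The original (equal-pathway-weight) NG86 estimator:

* per-codon synonymous site fractions s = Σ_positions (synonymous changes ÷
  admissible changes), where single-base changes producing stop codons are
  excluded from numerator and denominator;
* pathway-averaged difference counts per codon pair over all orderings of
  the differing positions, excluding pathways through stop codons; when no
  stop-free pathway exists the average over all orderings is used and
  flagged (the stop intermediate counts as a nonsynonymous step);
* S is the mean of the two sequences' site sums, pS = Sd/S, and
  dS = −(3/4)·ln(1 − (4/3)·pS); pS ≥ 3/4 is outside the Jukes–Cantor domain
  and yields an explicit flag, never a silent NaN. dN analogously.

Only the standard genetic code is wired in (the organisms in scope are
bacterial); the code table is injectable for testing. Codon columns
containing gaps, ambiguity codes or stop codons are dropped pairwise at
alignment construction and counted. Columns are grouped as consecutive
alignment-column triplets, which is frame-correct when gap runs have lengths
divisible by 3 — true for the pure-substitution generator here; real indel
alignments should be codon-aware before import.

Bootstrap SEs resample codon columns with replacement (default 1000
replicates, vectorized); replicates where the statistic is undefined are
dropped and counted, with a flag when they exceed half.

## GC-profile segmentation

The cumulative profile accumulates +1 for A/T, −1 for G/C, 0 for ambiguous
bases, and is detrended by the straight line through its endpoints.
Segmentation is recursive binary splitting: the interior cut maximizing the
two-proportion statistic

t(n) = |p_L − p_R| ÷ √( p̂(1−p̂)(1/n_L + 1/n_R) )

is accepted iff t ≥ halting threshold (default 7) and both sides are at
least the minimum segment length (default 100 bp); leftmost argmax on ties.
After the recursion, each interior boundary is re-localized by re-maximizing
t between its final neighbouring boundaries and pruned if it no longer
clears the threshold there, iterated to a fixed point. This refinement is
standard for binary segmentation: the first global cut against a mixed
background inherits a positional error (tens of bp at moderate GC contrast)
that the final, locally homogeneous neighbourhood corrects. The merit
function is *not* a bit-exact reproduction of any published GC-profile tool;
the two user-facing knobs (threshold, minimum length) have the conventional
meanings, and behavior is validated on planted inserts: a 2 kb GC-0.60
insert in a 10 kb GC-0.35 background is recovered with boundaries within
±50 bp in ≈95% of runs (the intrinsic change-point error at this contrast
puts a boundary beyond 50 bp ~3% of the time), with a false-split rate ≤2%
on homogeneous sequences.

Segments whose GC differs from the genome background by at least
`alien_delta` (default 0.05) are flagged alien.

## Attachment sites

attP is built by circularizing the prophage (last `window` + first `window`
bases, default 300; full halves with a warning when shorter). From a genome
and prophage span, attL/attR/attB are the corresponding junction windows;
attB is host-left + host-right flank. The core is the longest string common
to all four sequences with an occurrence *touching* each junction offset
(s ≤ offset ≤ s+L): the offset is a between-characters position, so a
single-nucleotide core — which occurs in nature — cannot strictly span it,
and "touching" is the weakest overlap that still encodes the recombination
crossover. Ties are broken by total occurrence distance to the offsets,
then lexicographically. Inverted-repeat arms are sought within a window
(default 200 bp) either side of the core under a Hamming mismatch bound
(default 1; indels out of scope for determinism), scored by longest arm,
then fewest mismatches, then proximity to the core, with an arm-length cap
(default 50 bp) to bound the exhaustive scan. Both searches are verified
against brute-force enumeration oracles in the tests.

## Statistics

Mann–Whitney U uses midranks; the exact null distribution when n₁+n₂ ≤ 20
with no ties, otherwise the normal approximation with tie-corrected variance
and continuity correction (scipy backend, validated against full labeling
enumeration). Observations are gene-level and may be phylogenetically
non-independent; the verdict record notes this rather than correcting it.

Dollo loss counting assumes a single gain above the carriers' MRCA and
returns the number of maximal carrier-free subtrees inside the MRCA clade,
which equals the brute-force minimum over loss placements.

qPCR standard curves are least squares Ct on log₁₀ copies; efficiency
10^(−1/slope) − 1; non-negative slopes are rejected. Plate effects are
removed by rescaling each plate so its calibrator-gene mean matches the
cross-plate mean (the simplest calibrator-anchored normalization; the
method behind published plate corrections varies and is not reproduced
bit-exact). Copy ratios are per-replicate, tested by a one-sample two-tailed
t-test against the expected value (1 for a single lysogen); replicates with
zero denominator copies are dropped and logged, and a zero-variance ratio
vector short-circuits to t = 0, p = 1 (or p = 0 if offset from the
expectation).

## The verdict classifier

`recent_transfer` iff (i) candidate-pair identity exceeds
candidate-vs-resident identity (two-tailed MWU p < 0.01 and higher median),
and (ii) candidate identity is not significantly below host-ortholog
identity (one-sided MWU p ≥ 0.05) *or* mean candidate dS ≤ mean host dS,
and (iii) the Dollo loss count is ≥ 2 when a tree is supplied.
`vertical_or_ancient` iff (i) fails; otherwise `indeterminate`, always with
a reason and the full statistics record. All thresholds are configuration
(`VerdictConfig`), not constants; the defaults encode the P < 0.01
significance convention and the ≥2-losses parsimony bar. The label is a
pure function of the recorded statistics, and lowering candidate dS with
other evidence fixed can never flip a recent-transfer call away.

## Synthetic data: what it emulates, and what it does not

`simulate_study` builds two annotated genomes realizing three divergence
groups — host orthologs (default target dS 0.10), a candidate phage pair
(0.07), and three resident phages (0.27), eight genes per group, mean gene
length 600 nt — plus a GC-0.60 insert of 2 kb at the candidate phage 3′ end
against an AT-rich backbone (GC 0.40, as in endosymbiont chromosomes), att
cores (default ATGA) with 12-bp inverted-repeat arms planted at the prophage
boundaries, a five-taxon host tree on which the two carriers require three
losses, and qPCR tables generated from true copy ratios (phage:host 2.90,
flank:host 3.21 and 2.45, host:host 1.01; standards 10³–10⁷ in triplicate,
efficiency 1.00, Ct noise 0.08, nine sample replicates). The Ct noise and
triplicate standards are chosen so the simulated copy-ratio dispersion
(cv ≈ 6–9%) matches the dispersion this experimental design exhibits.

Gene pairs evolve by a Poisson number of purely synonymous single-base
substitutions with expectation S·pS_target, pS_target =
(3/4)(1 − e^{−(4/3)dS}); multiple hits at a site make the downstream NG86
estimate very slightly conservative (≈5% at dS 0.10), well inside the
tested recovery band. A mixed mode adds nonsynonymous (never stop-creating)
changes. There is no recombination, no indel evolution, no codon-usage
selection, no rate variation among sites, and resident phages are derived
from the candidate's gene set rather than from an explicit phylogeny.
Passing tests therefore demonstrate correctness of the estimators and the
decision logic under the assumed substitution model — not robustness to
alignment error, indels, or recombination in real prophage data.

`make_att_fixture` plants a core (and optionally arms) between random
flanks and resamples until the planted core is the *unique* longest common
junction string; without that guarantee ~1% of random fixtures carry an
equally long chance junction string and the planted truth is ambiguous.

All generators are deterministic under a seed, and every truth record
suffices to score the corresponding pipeline stage without re-derivation.

## Problem sizes

The test suite and the reproduction script use: 100 gene pairs × 999 nt
with 1000 bootstrap replicates for divergence recovery; 1000 null
replicates (n = 30 per group) for MWU calibration; 20 planted-insert and 50
homogeneous 12/10 kb sequences for segmentation; 100 att fixtures; all
rooted trees sampled to 8 leaves for Dollo; 100 simulated qPCR experiments;
and one study-regime plus 100 null-regime full-pipeline runs (eight genes
per group). These sizes put every stochastic check comfortably inside its
statistical tolerance while keeping a full run in minutes.
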