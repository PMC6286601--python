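# Methods

This note documents the statistical model behind `motifrank`, the
conventions the implementation commits to where several readings are
possible, and what the synthetic benchmarks do and do not demonstrate.

## Null model and motif automata

Every sequence is modelled under its own zeroth-order null: bases i.i.d.
with the maximum-likelihood composition estimated from that sequence's
valid (A/C/G/T) bases. Symbols outside the alphabet follow a *skip* policy:
they reset the search automaton, are excluded from the composition and do
not count towards the sequence length `l`. The rationale is that a masked or
unknown base should never help complete a match. Higher-order (dinucleotide)
backgrounds are not modelled.

A motif pattern is parsed into a syntax tree (literals, `N` class, union,
concatenation, star, optional) and compiled into a *search* DFA via
Thompson construction of `.*pattern`, subset construction, and
partition-refinement minimization that preserves the end-state marking.
Search automata are total and have no dead state, because a fresh match can
start at any position. A separate full-match automaton (which may have a
dead state) backs the exhaustive enumeration of fixed-length matches.
Subset construction aborts beyond a configurable state cap (default 10⁵)
since pathological expressions can blow up exponentially.

**Occurrence convention.** An occurrence is registered on every transition
*into* an end state during a left-to-right scan, including end→end
self-loops. Overlapping occurrences therefore all count (`AA` occurs 3
times in `AAAA`), and for expressions ending in `*` each extension that
still ends a match (e.g. `GA*` on `GAA`) counts as a new occurrence ending
at that position. This is the only convention under which the scan count,
the embedded chain below, and a sliding-window count for plain k-mers agree
exactly; the alternative (treating star-extension self-loops as staying
inside one occurrence) would make the embedded model assign probability
zero to a second occurrence of motifs like `A`. A non-overlapping mode
(reset to the initial state after each occurrence) is available.

## Embedded chain and exact sequence p-values

Under the composition `f`, the DFA is a Markov chain with transition matrix
`T(i,j) = Σ_{s: δ(i,s)=j} f_s`. The embedded chain for `n_obs` occurrences
consists of `n_obs` template copies plus one absorbing final state
(dimension `n_obs·k + 1` for a `k`-state template). All transition mass
entering an end state is redirected one copy forward — the copy index
counts completed occurrences — and the `n_obs`-th entry falls into the
final state; in non-overlapping mode the next copy is entered at the
initial state instead. The SSP is the exact tail probability

    SSP = P(count ≥ n_obs) = [eTPM^l](initial, final),

evaluated by binary exponentiation (≤ 2⌈log₂ l⌉ matrix products, hence the
`O((k·n_obs)³ log l)` cost per sequence). `P(count ≥ 1)` is computed
without the embedding by making end states absorbing in the template and
raising it to the `l`-th power; for `n_obs = 1` both routes coincide (unit
tests enforce agreement to 1e-10, and an exhaustive enumeration over all
`4^l` words checks the embedding exactly for small cases).

Numerical conventions: SSPs are clamped to `[1e-300, 1]` so `−ln` stays
finite; `n_obs = 0` gives SSP = 1 exactly; matrices are dense up to
dimension 512 and sparse (CSR) above, with identical results to 1e-10; the
embedding dimension is capped (default 2·10⁴) with an error that recommends
the MSR statistic, which never builds the embedding. SSPs are discrete tail
probabilities and therefore conservative as p-values; calibration
diagnostics use the standard randomized (mid-p) smoothing
`P(>n) + U·P(=n)`, but reported SSPs are always `P(≥ n_obs)`.

## Rank statistics

**Brownian bridge (BB).** Log scores `ls_i = −ln(SSP_i + α)` with dampening
`α = 10⁻⁵` (bounds the influence of a single extreme SSP) are mean-adjusted
and summed; the running sum starts and ends at zero. The default statistic
is the one-sided maximum `D = max_i r_i` — sensitive to enrichment at the
top of the list; reverse the ranking for the other end — tested against the
exact bridge law `P(M ≥ D) = exp(−2D²/(Nσ²))`. The two-sided option uses
`max|r_i|` against the Kolmogorov distribution (alternating series,
truncated when a term falls below 1e-12; being alternating, the truncation
error is smaller than the last term). Each statistic is paired with its own
law; mixing the one-sided maximum with the two-sided series would be
mis-calibrated by construction. Two finite-sample refinements are on by
default and can be disabled: standardization by the empirical score
variance (exact uniform SSPs give `−ln U ~ Exp(1)` with variance ≈ 1, the
`assume_unit_variance` flag restores that), and Siegmund's corrected
diffusion approximation `D → D + ρσ` with `ρ = −ζ(½)/√(2π) ≈ 0.5826`,
which compensates the systematic undershoot of a discrete-time maximum
relative to the continuous supremum. Without the correction, null p-values
at N = 500 are measurably conservative (mean ≈ 0.54).

**Resetting random walk (RW).** SSPs are thresholded into integer steps:
`+u` if SSP ≤ p₀, else `−d`, requiring negative null drift
`p₀u − (1−p₀)d < 0` (defaults p₀ = 0.05, u = 3, d = 1). The walk restarts
at 0 whenever an update would take it to −1 or below, making the maximum
sensitive to local runs of enriched sequences anywhere in the list — the
same construction as maximal-segment scores in local alignment statistics.
`P(max ≥ M)` under the null (i.i.d. steps with `P(+u) = p₀`) is computed
three ways: an exact dynamic program over heights `{0..M−1}` with
absorption at `M` (absorbed mass accumulated additively, so p-values keep
full relative precision down to ~1e-300); a Gumbel-type tail
`1 − exp(−K·N·e^{−λ*M})` with `λ*` the positive root of
`p₀e^{λu} + (1−p₀)e^{−λd} = 1` and the prefactor `K` fixed once per scheme
by matching the exact recursion at a reference point (it has no simple
closed form for general integer schemes); and Monte Carlo for validation.
Note the statistic only reacts to SSPs below `p₀`: a motif whose
single-occurrence SSP exceeds the threshold (e.g. a 7-mer in sequences of
1000 bases, where `P(≥1) ≈ 0.06`) is invisible to the walk, so `p₀` should
be chosen with the expected background occurrence probability in mind.

**Modified sum of ranks (MSR).** With `p_i = P(≥1 occurrence)` and
`λ_i = −ln(1 − p_i)` (the Poisson rate reproducing `p_i`), the sequences
tile a pseudo-time axis `[0, λ.]` with consecutive intervals of length
`λ_i` in rank order; under the null, motif occurrences fall uniformly on
that axis. Each of the `n.` occurrences scores its interval midpoint `r_m`,
and

    W = (√n. / λ.) (Σ n_i r_i / n. − λ./2)

is asymptotically `N(0, 1/12)`. The p-value is `2(1 − Φ(√12·|W|))` —
standardizing first is what makes the null p-value uniform; a flag keeps
the unstandardized form for comparison. Degenerate inputs: `n. = 0` returns
p = 1 with a warning; `p_i = 1` (motif unavoidable) is clamped to
`1 − 1e-12`; sequences with `λ_i = 0` contribute zero-length intervals and
stay in the list. MSR only needs `P(≥1)` and is the default for screens.

The three nulls differ: BB and RW assume uniform SSPs, whereas MSR
conditions on the observed total count and only randomizes placement.
Because real SSPs are discrete (mostly exactly 1 for motifs absent from a
sequence), BB and RW are conservative on real cohorts — the longer the
motif, the more so — while MSR stays calibrated under rank shuffling
(measured KS p ≈ 0.8 on 500-sequence null cohorts). Calibration tests
therefore check BB/RW on simulated uniform SSPs (with mid-p smoothing for
the RW's lattice-valued maximum) and MSR on shuffled real cohorts.

## Synthetic cohorts

`SimDesign` generates ranked cohorts of i.i.d. sequences (uniform base
composition by default — the composition is a free parameter — with rank
defined by generation order) and overwrites motif copies at uniform
non-overlapping offsets within uniformly chosen sequences of a target rank
region. Defaults are the reference benchmark conditions: 1000 sequences of
1000 bases, the 7-mer `ACGTGAT`, 100 insertions in the top half.
Overwriting (rather than splicing) keeps lengths fixed. The co-insertion
mode places all motifs of an event into the same sequence, emulating
co-acting factors. The spike-in protocol inserts the 10-mer `AATGCCCGGT`
100 times among the top 500 ranks plus twice-50 times among the top 100
(200 copies in total) into an otherwise null cohort.

What these benchmarks do **not** emulate about real data: heterogeneous
sequence lengths and compositions across a transcriptome, dinucleotide and
repeat structure, correlated ranks, and biologically clustered motif
positions within a sequence. Passing the power and calibration suites shows
the statistics behave as designed under their own null and under controlled
enrichment — not that any particular biological signal will be detected.

## Problem sizes used by the test suite

Stochastic checks run at sizes chosen to keep the full suite fast while
leaving each conclusion unambiguous: calibration uses 500 lists of 500
null SSPs (BB, RW) and 500 rank shuffles of a 500×300-base cohort (MSR);
the insertion-power comparison uses 100 replicates of 500 sequences × 500
bases with 100 insertions — at this length a single 7-mer occurrence has
`P(≥1) ≈ 0.03 < p₀`, so all three statistics respond, and the observed
ordering (RW most sensitive, then BB, then MSR, with median log₁₀ RCPs
around −35/−16/−15) is stable across seed batches; combined-motif
comparisons use 12 replicates of 300×300 cohorts; the spike-in screen uses
a 600×300 cohort. The exhaustive SSP oracle enumerates all 4^10 words; the
Monte-Carlo oracles use 10⁵ simulated sequences.

## Known limitations

- Zeroth-order background only; no PWM motifs; no bounded-repeat syntax
  (write unions instead).
- Reported SSPs and RW/BB p-values are conservative for discrete counts by
  construction (exact tail probabilities).
- The RW scheme is parametric; its detection power depends on `p₀` relative
  to the background single-occurrence probability (see above).
- Automaton state counts follow the minimized-total-search-DFA convention
  stated here; other tools may count states of a plain match automaton or
  include dead states, giving different numbers for the same expression.
- Complex expressions can produce large automata; construction is guarded
  by the state cap, and the embedding by a dimension cap whose error
  message points to MSR.
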