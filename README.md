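# motifrank

Regular-expression motif enrichment in ranked sequence lists.

Functional-genomics experiments typically produce a *ranked* list of
sequences — 3′UTRs ordered by fold change after a miRNA transfection, or
promoters ordered by binding affinity — rather than a clean
foreground/background split. `motifrank` tests whether a sequence motif,
written as a regular expression over `{A,C,G,T,N}`, is biased towards one
end of such a ranking (or clusters anywhere inside it). It is aimed at
hypothesis-driven analyses: a stem-loop like `TTTCNNNGAAA`, a set of
binding k-mers `(ACGTGAT)|(GCATTGT)`, or a co-occurrence constraint such as
a miRNA seed target with an upstream U-rich element,
`(TTTTAAAN*SEED)|(SEEDN*TTTTAAA)` — motifs no k-mer screen can express.

## Method

The analysis has two stages.

**1. Exact per-sequence p-values (SSPs).** Each motif is compiled to a
total deterministic *search* automaton over the four bases (Thompson
construction of the NFA for `.*pattern`, subset construction, Hopcroft-style
minimization): entering an end state means an occurrence ends at the current
position, so overlapping occurrences are counted naturally. Under the null
model — each sequence i.i.d. from its own base composition — the automaton
becomes a Markov chain with transition matrix `T` (entry `(i,j)` sums the
frequencies of bases moving state `i` to `j`). To score a sequence of valid
length `l` containing the motif `n_obs` times, the chain is *embedded*:
`n_obs` copies of the template are chained so that every transition entering
an end state advances one copy, the last advance falling into an absorbing
final state. The sequence-specific p-value is the exact tail probability

    SSP = P(count ≥ n_obs) = [ eTPM^l ](initial, final),

computed by binary matrix exponentiation in `O((k·n_obs)³ log l)` for a
k-mer. `P(count ≥ 1)` has a cheaper route (end states made absorbing in the
plain template), which the MSR statistic below uses exclusively.

**2. Rank-correlation p-value (RCP).** Three statistics turn the ordered
SSPs into a single p-value:

- **BB (Brownian bridge).** Running sum of mean-adjusted log scores
  `ls_i = −ln(SSP_i + α)` (dampening `α = 10⁻⁵`). Under the null the
  trajectory is a bridge; the default tests the one-sided maximum `D`
  against `P(M ≥ D) = exp(−2D²/(Nσ²))` (two-sided option: Kolmogorov
  distribution of `max|r_i|`), with Siegmund's continuity correction and
  empirical-variance standardization.
- **RW (resetting random walk).** SSP ≤ p₀ gives an integer up-step `+u`,
  otherwise `−d` (defaults p₀=0.05, u=3, d=1; null drift must be negative).
  The walk restarts at 0 whenever it would reach −1, so its maximum detects
  runs of enriched sequences anywhere in the list. `P(max ≥ M)` comes from
  an exact lattice recursion (default), a Gumbel-type tail approximation, or
  Monte Carlo.
- **MSR (modified sum of ranks).** Sequence `i` occupies an interval of
  length `λ_i = −ln(1 − p_i)` (`p_i = P(≥1 occurrence)`) on a Poisson
  pseudo-time axis; under the null the `n.` observed occurrences fall
  uniformly on `[0, λ.]`. The standardized mean midpoint score
  `W = (√n./λ.)(Σ n_i r_i / n. − λ./2)` is `N(0, 1/12)`; the p-value is
  two-sided normal. MSR never builds the embedding, so it stays cheap for
  long sequences or high counts.

Exhaustive k-mer screens (all `4^k` motifs, Bonferroni column, parallel over
motifs) and a synthetic-cohort generator for power studies are included.

## Worked example

Generate a synthetic ranked cohort — 500 sequences of 500 bases with the
7-mer `ACGTGAT` inserted 100 times into the top half — and test that motif:

```python
import motifrank as mr

design = mr.SimDesign(n_sequences=500, length=500, insertions=100, seed=7)
ids, seqs = mr.gen_ranked_sequences(design)
model = mr.MotifEnrichment(dict(zip(ids, seqs)))
print(model.fit("ACGTGAT", method="msr").summary())
```

```
        Motif Rank Enrichment Results
====================================================
Motif pattern:       ACGTGAT
Automaton states:    8
Counting mode:       overlapping
Method:              msr (modified sum of ranks)
No. sequences:       500
Total occurrences:   112
Statistic:           -2.47166
P-value:             1.10857e-17
log10 p-value:       -16.96
====================================================
```

The 112 occurrences (100 inserted plus background) sit in the top half, so
the mean interval midpoint falls far below `λ./2`: `W = −2.47` is ~8.6 null
standard deviations out and the rank correlation is overwhelming. The other
two methods agree on the same cohort (`method="bb"` → p = 4.7e-16;
`method="rw"` → max = 91, p = 5.9e-31; the walk is the most sensitive here
because the enriched half produces a long run of up-steps).

The same analysis from the shell:

```bash
motifrank --fasta cohort.fa --rank cohort.rank.tsv \
          --motif ACGTGAT --method msr --out results --ssp-table
```

writes `results.rcp.tsv` (motif, method, statistic, raw and
Bonferroni-corrected p-values, occurrence count) and `results.ssp.tsv`
(per-sequence rank, length, `n_obs`, SSP, `P(≥1)`). `--kmer-screen 6`
screens all 4096 6-mers instead; `--reverse` tests the other end of the
ranking.

### Pattern dialect

Literals `ACGT` (and `U`, transliterated to `T`), `N` for any base, union
`|`, grouping `(...)`, Kleene star `*` (lazy `*?` is accepted and treated as
`*`), optional `?`. Bounded repeats are written as unions, e.g. the
G-quadruplex loop `(N|NN|NNN|NNNN)`. Helpers: `combine_any([m1, m2, ...])`
builds `(m1)|(m2)|...`; `combine_cooccur(m1, m2)` builds
`(m1N*m2)|(m2N*m1)` — both motifs in either order, any gap.

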