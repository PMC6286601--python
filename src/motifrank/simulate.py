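"""Synthetic ranked cohorts, motif-insertion experiments and k-mer screens.

The generator emulates the standard benchmark for rank-correlation motif
methods: a cohort of i.i.d. random sequences, ranked by generation order,
with a known motif overwritten into sequences of a target rank region
(e.g. 100 copies of a 7-mer in the top half).  A spike-in protocol inserts a
10-mer into an otherwise null cohort: 100 single insertions among the top
500 sequences plus 50 double insertions among the top 100.  Exhaustive k-mer
screens evaluate one rank-correlation p-value per k-mer with a Bonferroni
column for the tested family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .embedding import BaseComposition, SSP_FLOOR, _ssp_value, p_ge1_batch
from .motifs import ALPHABET, Motif, encode_sequence, enumerate_kmers
from .rank_stats import RankedList, rcp

__all__ = [
    "SimDesign",
    "gen_ranked_sequences",
    "spike_in_10mer",
    "kmer_screen",
    "bonferroni",
    "power_experiment",
    "SPIKE_10MER",
]

#: 10-mer used by the spike-in protocol.
SPIKE_10MER = "AATGCCCGGT"


@dataclass(frozen=True)
class SimDesign:
    """Design of a synthetic ranked cohort with motif insertions.

    Defaults mirror the reference benchmark: 1000 sequences of 1000 bases,
    uniform base composition, and a 7-mer (ACGTGAT) inserted 100 times at
    random non-overlapping offsets within uniformly chosen sequences of the
    top half of the ranking.  ``co_insertion`` places all motifs of an
    insertion event into the same sequence (testing co-occurring factors).
    ``region`` is a 1-based inclusive rank interval; None means top half.
    """

    n_sequences: int = 1000
    length: int = 1000
    composition: tuple = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple = ("ACGTGAT",)
    insertions: int = 100
    region: Optional[tuple] = None
    co_insertion: bool = False
    seed: Optional[int] = None

    def rank_region(self) -> tuple[int, int]:
        region = self.region or (1, self.n_sequences // 2)
        lo, hi = region
        if not (1 <= lo <= hi <= self.n_sequences):
            raise ValueError(f"region {region} outside [1, {self.n_sequences}]")
        return lo, hi

    def validate(self) -> None:
        BaseComposition(tuple(self.composition))
        lo, hi = self.rank_region()
        size = hi - lo + 1
        for m in self.motifs:
            if len(m) > self.length:
                raise ValueError(f"motif {m!r} longer than the sequences")
            capacity = size * (self.length // len(m))
            if self.insertions > capacity:
                raise ValueError(
                    f"{self.insertions} insertions exceed the region capacity "
                    f"({capacity}) for motif {m!r}"
                )


def _insert_at_free_offset(seq: np.ndarray, motif_codes: np.ndarray,
                           occupied: list, rng: np.random.Generator) -> None:
    """Overwrite the motif at a uniform non-overlapping offset (lengths fixed)."""
    length = seq.size
    mlen = motif_codes.size
    for _ in range(200):
        off = int(rng.integers(0, length - mlen + 1))
        if all(off + mlen <= s or off >= e for s, e in occupied):
            seq[off:off + mlen] = motif_codes
            occupied.append((off, off + mlen))
            return
    # rejection failed: enumerate the free offsets exactly
    free = [off for off in range(length - mlen + 1)
            if all(off + mlen <= s or off >= e for s, e in occupied)]
    if not free:
        raise ValueError("no free offset left for insertion (sequence saturated)")
    off = int(rng.choice(free))
    seq[off:off + mlen] = motif_codes
    occupied.append((off, off + mlen))


def gen_ranked_sequences(design: SimDesign, rng=None) -> tuple[list, list]:
    """Generate the cohort; returns (ids, sequences) in rank order.

    Sequences are i.i.d. from the design composition; each insertion event
    picks a sequence uniformly from the rank region (with replacement) and
    overwrites the motif at a uniform offset that does not overlap earlier
    insertions in that sequence.  Fully reproducible under the design seed.
    """
    design.validate()
    rng = np.random.default_rng(design.seed if rng is None else rng)
    n, length = design.n_sequences, design.length
    comp = np.asarray(design.composition, dtype=float)
    mat = rng.choice(4, size=(n, length), p=comp).astype(np.int8)
    lo, hi = design.rank_region()
    occupied: dict[int, list] = {}
    motif_codes = [encode_sequence(m) for m in design.motifs]
    if design.co_insertion:
        for _ in range(design.insertions):
            i = int(rng.integers(lo - 1, hi))
            occ = occupied.setdefault(i, [])
            for mc in motif_codes:
                _insert_at_free_offset(mat[i], mc, occ, rng)
    else:
        for mc in motif_codes:
            for _ in range(design.insertions):
                i = int(rng.integers(lo - 1, hi))
                occ = occupied.setdefault(i, [])
                _insert_at_free_offset(mat[i], mc, occ, rng)
    ids = [f"seq_{i + 1:05d}" for i in range(n)]
    lut = np.array(list(ALPHABET))
    seqs = ["".join(lut[row]) for row in mat]
    return ids, seqs


def spike_in_10mer(sequences: Sequence[str], seed: Optional[int] = None) -> list:
    """Spike the 10-mer AATGCCCGGT into a ranked cohort.

    Protocol: one copy inserted 100 times into uniformly chosen sequences of
    the top 500 ranks, plus two copies inserted 50 times into uniformly
    chosen sequences of the top 100 ranks (200 copies in total).  Offsets
    are uniform and non-overlapping within each sequence; sequence lengths
    are unchanged (overwrite).  Requires at least 500 sequences.
    """
    n = len(sequences)
    if n < 500:
        raise ValueError(f"spike-in protocol needs >= 500 sequences, got {n}")
    rng = np.random.default_rng(seed)
    arrs = [encode_sequence(s) for s in sequences]
    occupied: dict[int, list] = {}
    mc = encode_sequence(SPIKE_10MER)
    for _ in range(100):
        i = int(rng.integers(0, 500))
        _insert_at_free_offset(arrs[i], mc, occupied.setdefault(i, []), rng)
    for _ in range(50):
        i = int(rng.integers(0, 100))
        occ = occupied.setdefault(i, [])
        _insert_at_free_offset(arrs[i], mc, occ, rng)
        _insert_at_free_offset(arrs[i], mc, occ, rng)
    lut = np.array(list(ALPHABET) + ["N"])
    return ["".join(lut[a]) for a in arrs]


def bonferroni(pvalues, family_size: int) -> np.ndarray:
    """Bonferroni correction: min(1, p * family_size), elementwise."""
    p = np.asarray(pvalues, dtype=float)
    if family_size < p.size:
        raise ValueError("family_size must be at least the number of p-values")
    return np.minimum(1.0, p * family_size)


def _encode_cohort(sequences: Sequence[str]):
    codes = [encode_sequence(s) for s in sequences]
    n = len(codes)
    max_len = max(c.size for c in codes)
    mat = np.full((n, max_len), -1, dtype=np.int8)
    comps = np.zeros((n, 4))
    lengths = np.zeros(n, dtype=np.int64)
    for i, c in enumerate(codes):
        mat[i, : c.size] = c
        v = c[c >= 0]
        comps[i] = np.bincount(v, minlength=4)[:4] / v.size
        lengths[i] = v.size
    return mat, comps, lengths


def _kmer_counts(mat: np.ndarray, k: int) -> np.ndarray:
    """Overlapping window counts of every k-mer, per sequence."""
    from numpy.lib.stride_tricks import sliding_window_view
    n, length = mat.shape
    counts = np.zeros((n, 4 ** k), dtype=np.int32)
    if length < k:
        return counts
    pow4 = 4 ** np.arange(k - 1, -1, -1)
    win = sliding_window_view(mat, k, axis=1).astype(np.int64)
    valid = (win >= 0).all(axis=2)
    codes = (win * pow4).sum(axis=2)
    for i in range(n):
        if valid[i].any():
            counts[i] = np.bincount(codes[i][valid[i]], minlength=4 ** k)
    return counts


def _screen_chunk(kmers, counts_chunk, comps, lengths, method, counting,
                  options) -> list:
    out = []
    for kmer, n_obs in zip(kmers, counts_chunk):
        motif = Motif.compile(kmer, counting=counting)
        p1 = p_ge1_batch(motif.dfa, comps, lengths)
        ssps = np.ones(len(lengths))
        one = n_obs == 1
        ssps[one] = np.clip(p1[one], SSP_FLOOR, 1.0)
        for i in np.flatnonzero(n_obs >= 2):
            comp = BaseComposition(tuple(comps[i]))
            ssps[i] = _ssp_value(motif, comp, int(lengths[i]), int(n_obs[i]))
        ranked = RankedList.from_arrays(ssps, counts=n_obs, p_ge1=p1)
        res = rcp(ranked, method=method, motif=kmer, **options)
        out.append((kmer, res.statistic, res.pvalue, res.log10_pvalue,
                    int(n_obs.sum())))
    return out


def kmer_screen(
    sequences: Sequence[str],
    k: int = 6,
    method: str = "msr",
    workers: int = 1,
    counting: str = "overlapping",
    family_size: Optional[int] = None,
    **options,
) -> pd.DataFrame:
    """Exhaustive screen of all 4^k k-mers against a ranked sequence list.

    Returns one row per k-mer with the raw rank-correlation p-value, its
    Bonferroni correction at the tested family size (default 4^k) and the
    rank of the motif by raw p-value.  The screen is embarrassingly parallel
    over motifs; results are identical for any worker count.
    """
    if not 1 <= k <= 8:
        raise ValueError("full screens support k between 1 and 8")
    mat, comps, lengths = _encode_cohort(sequences)
    counts = _kmer_counts(mat, k)
    kmers = enumerate_kmers(k)
    chunk = 256
    tasks = [(kmers[i:i + chunk], counts.T[i:i + chunk]) for i in
             range(0, len(kmers), chunk)]
    results = Parallel(n_jobs=workers)(
        delayed(_screen_chunk)(km, ct, comps, lengths, method, counting, options)
        for km, ct in tasks
    )
    rows = [r for chunk_rows in results for r in chunk_rows]
    df = pd.DataFrame(rows, columns=["motif", "statistic", "p_raw",
                                     "log10_p_raw", "n_total"])
    df.insert(1, "method", method)
    family = family_size if family_size is not None else len(kmers)
    df["p_bonferroni"] = bonferroni(df["p_raw"].to_numpy(), family)
    df = df.sort_values(["p_raw", "log10_p_raw", "motif"],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def power_experiment(
    design: SimDesign,
    insertions_grid: Sequence[int],
    patterns: Optional[Sequence[str]] = None,
    methods: Sequence[str] = ("bb", "rw", "msr"),
    replicates: int = 10,
    seed: Optional[int] = None,
    counting: str = "overlapping",
    **options,
) -> pd.DataFrame:
    """Detection-power experiment over an insertion-count grid.

    For each insertion count, *replicates* cohorts are generated from the
    design and every (pattern, method) pair is evaluated.  The table reports
    the median RCP, the median -log10 RCP and its standard error per cell.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    from .embedding import ssp_records
    patterns = list(patterns) if patterns is not None else [design.motifs[0]]
    motifs = {p: Motif.compile(p, counting=counting) for p in patterns}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(insertions_grid) * replicates)
    raw = []
    idx = 0
    for ins in insertions_grid:
        for rep in range(replicates):
            rng = np.random.default_rng(children[idx]); idx += 1
            d = replace(design, insertions=int(ins), seed=None)
            ids, seqs = gen_ranked_sequences(d, rng=rng)
            for pat in patterns:
                ranked = RankedList(ssp_records(motifs[pat], seqs, ids))
                for method in methods:
                    res = rcp(ranked, method=method, motif=pat, **options)
                    raw.append((pat, method, int(ins), rep, res.pvalue,
                                res.log10_pvalue))
    rawdf = pd.DataFrame(raw, columns=["motif", "method", "insertions",
                                       "replicate", "pvalue", "log10_pvalue"])
    grouped = rawdf.groupby(["motif", "method", "insertions"])
    table = grouped.agg(
        median_pvalue=("pvalue", "median"),
        median_neg_log10=("log10_pvalue", lambda v: float(np.median(-v))),
        se_neg_log10=("log10_pvalue", lambda v: float(np.std(-v, ddof=1)
                                                      / np.sqrt(len(v)))),
    ).reset_index()
    table.attrs["raw"] = rawdf
    return table
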