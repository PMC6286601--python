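"""Model / results interface for motif rank-enrichment analyses.

`MotifEnrichment` holds the data (sequences in experimental rank order);
`fit` evaluates one motif hypothesis with one of the three rank statistics
and returns a `MotifEnrichmentResults` carrying the statistic, the p-value,
the per-sequence diagnostics and a text `summary()`.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import io as _io
from .embedding import ssp_records
from .motifs import Motif
from .rank_stats import RankedList, rcp
from .simulate import kmer_screen


class MotifEnrichment:
    """Rank-enrichment model for regular-expression motifs.

    Parameters
    ----------
    sequences
        Either an ordered mapping ID -> sequence (the mapping order is the
        experimental rank, best first) or a plain list of sequences.
    ids
        Explicit IDs when *sequences* is a list.
    counting
        Occurrence counting mode: "overlapping" (default) or
        "non-overlapping".
    """

    def __init__(self, sequences, ids: Optional[Sequence[str]] = None,
                 counting: str = "overlapping"):
        if isinstance(sequences, dict):
            self.ids = list(sequences.keys())
            self.sequences = [sequences[i] for i in self.ids]
        else:
            self.sequences = list(sequences)
            self.ids = (list(ids) if ids is not None
                        else [f"seq_{i + 1}" for i in range(len(self.sequences))])
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences lengths differ")
        self.counting = counting
        self._cache: dict = {}

    @classmethod
    def from_files(cls, fasta_path, rank_path, reverse: bool = False,
                   counting: str = "overlapping") -> "MotifEnrichment":
        """Build the model from a FASTA file and a rank file (best rank first)."""
        seqs = _io.read_fasta(fasta_path)
        ids, _ = _io.read_rank(rank_path, fasta_ids=seqs.keys(), reverse=reverse)
        return cls({i: seqs[i] for i in ids}, counting=counting)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def compile(self, pattern: str) -> Motif:
        return Motif.compile(pattern, counting=self.counting)

    def ranked_list(self, motif) -> RankedList:
        """Per-sequence SSP records for a motif, in rank order (cached)."""
        if isinstance(motif, str):
            motif = self.compile(motif)
        key = (motif.pattern, motif.counting)
        if key not in self._cache:
            self._cache[key] = RankedList(
                ssp_records(motif, self.sequences, self.ids))
        return self._cache[key]

    def fit(self, motif, method: str = "msr", **options) -> "MotifEnrichmentResults":
        """Evaluate one motif with one rank statistic (bb | rw | msr)."""
        if isinstance(motif, str):
            motif = self.compile(motif)
        ranked = self.ranked_list(motif)
        result = rcp(ranked, method=method, motif=motif.pattern, **options)
        return MotifEnrichmentResults(self, motif, ranked, result)

    def fit_kmers(self, k: int = 6, method: str = "msr", workers: int = 1,
                  **options) -> pd.DataFrame:
        """Exhaustive k-mer screen over this model's ranked sequences."""
        return kmer_screen(self.sequences, k=k, method=method,
                           workers=workers, counting=self.counting, **options)


class MotifEnrichmentResults:
    """Fitted motif-enrichment result: statistic, p-value and diagnostics."""

    def __init__(self, model: MotifEnrichment, motif: Motif,
                 ranked: RankedList, result):
        self.model = model
        self.motif = motif
        self.ranked = ranked
        self.result = result

    @property
    def method(self) -> str:
        return self.result.method

    @property
    def statistic(self) -> float:
        return self.result.statistic

    @property
    def pvalue(self) -> float:
        return self.result.pvalue

    @property
    def log10_pvalue(self) -> float:
        return self.result.log10_pvalue

    @property
    def n_total(self) -> int:
        return self.result.n_total

    @property
    def detail(self):
        """Method-specific result object (BBResult, RWResult or MSRResult)."""
        return self.result.detail

    def ssp_table(self) -> pd.DataFrame:
        """Per-sequence table: rank, ID, length, n_obs, ssp, p_ge1."""
        return _io.ssp_frame(self.ranked, motif=self.motif.pattern)

    _METHOD_NAMES = {
        "bb": "Brownian bridge",
        "rw": "resetting random walk",
        "msr": "modified sum of ranks",
    }

    def summary(self) -> str:
        lines = [
            "        Motif Rank Enrichment Results",
            "=" * 52,
            f"Motif pattern:       {self.motif.pattern}",
            f"Automaton states:    {self.motif.dfa.n_states}",
            f"Counting mode:       {self.motif.counting}",
            f"Method:              {self.method} "
            f"({self._METHOD_NAMES[self.method]})",
            f"No. sequences:       {self.ranked.n}",
            f"Total occurrences:   {self.n_total}",
            f"Statistic:           {self.statistic:.6g}",
            f"P-value:             {self.pvalue:.5e}",
            f"log10 p-value:       {self.log10_pvalue:.4g}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<MotifEnrichmentResults {self.motif.pattern!r} "
                f"method={self.method} p={self.pvalue:.3e}>")
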