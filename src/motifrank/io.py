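"""File formats: FASTA sequences, rank lists and TSV result tables."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered ID -> sequence map.

    Sequences are uppercased and U transliterated to T; other non-ACGT
    symbols are retained (downstream counting applies the skip policy).
    Duplicate IDs and empty files are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def read_rank(path, fasta_ids: Optional[Sequence[str]] = None,
              reverse: bool = False) -> tuple[list, Optional[list]]:
    """Read a rank file: one sequence ID per line, best rank first.

    An optional tab-separated second column carries the experimental score
    (echoed to output only; the file order defines the rank).  ``reverse``
    flips the order, to test enrichment at the other end of the list.
    Unknown or duplicate IDs are errors.
    """
    ids: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            ids.append(parts[0].strip())
            if len(parts) > 1 and parts[1].strip():
                scores.append(float(parts[1]))
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate IDs in rank file {path}: {dupes}")
    if fasta_ids is not None:
        known = set(fasta_ids)
        missing = [i for i in ids if i not in known]
        if missing:
            raise ValueError(
                f"rank file {path} lists IDs absent from the FASTA: {missing}"
            )
    if scores and len(scores) != len(ids):
        raise ValueError(f"rank file {path} has a score for only some IDs")
    out_scores: Optional[list] = scores if scores else None
    if reverse:
        ids = ids[::-1]
        out_scores = out_scores[::-1] if out_scores else None
    return ids, out_scores


def write_fasta(path, ids: Sequence[str], sequences: Sequence[str],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(ids, sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_rank(path, ids: Sequence[str],
               scores: Optional[Sequence[float]] = None) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(ids):
            if scores is not None:
                fh.write(f"{sid}\t{scores[i]}\n")
            else:
                fh.write(f"{sid}\n")


def _fmt_p(p: float) -> str:
    """p-values in scientific notation with 6 significant digits."""
    return f"{p:.5e}"


def write_rcp_table(df: pd.DataFrame, path) -> None:
    """Write a result table (one row per motif/method) as TSV."""
    out = df.copy()
    for col in ("p_raw", "p_bonferroni"):
        if col in out:
            out[col] = out[col].map(_fmt_p)
    for col in ("statistic", "log10_p_raw"):
        if col in out:
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def ssp_frame(ranked, motif: Optional[str] = None) -> pd.DataFrame:
    """Per-sequence SSP table for a ranked list."""
    rows = [(r.id, r.length, r.n_obs, r.ssp, r.p_ge1) for r in ranked.records]
    df = pd.DataFrame(rows, columns=["id", "length", "n_obs", "ssp", "p_ge1"])
    if motif is not None:
        df.insert(0, "motif", motif)
    df.insert(1 if motif is not None else 0, "rank",
              np.arange(1, len(df) + 1))
    return df


def write_ssp_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("ssp", "p_ge1"):
        out[col] = out[col].map(_fmt_p)
    out.to_csv(path, sep="\t", index=False)
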