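"""Markov-chain embedding: exact per-sequence motif p-values.

Under the null model each sequence is i.i.d. from its own base composition.
The motif's search DFA then becomes a Markov chain whose transition
probability matrix (TPM) assigns each edge the frequency of the base it
consumes.  To get the probability of seeing the motif at least ``n_obs``
times, the template chain is replicated ``n_obs`` times (the embedded chain,
eDFA): the copy index records how many occurrences have been completed, so
every transition that enters an end state advances one copy, and completing
the ``n_obs``-th occurrence falls into a single absorbing final state.  The
sequence-specific p-value (SSP)

    SSP = P(count >= n_obs)  =  [eTPM ** l][initial, final]

is read from the matrix power at the sequence length ``l`` (valid bases
only).  P(count >= 1) has a cheaper route that never builds the embedding:
make the end states of the template absorbing and raise the plain TPM to the
power ``l`` (used by the MSR rank statistic, which only needs the rate
``lambda_i = -ln(1 - p_i)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .motifs import (
    DFA,
    Motif,
    count_occurrences_batch,
    encode_sequence,
)

__all__ = [
    "BaseComposition",
    "composition_of",
    "dfa_to_tpm",
    "build_etpm",
    "matrix_power",
    "ssp",
    "ssp_records",
    "p_ge1",
    "p_ge1_batch",
    "SSPRecord",
    "EmbeddingTooLargeError",
]

#: Numerical floor applied to SSPs so downstream -ln() stays finite.
SSP_FLOOR = 1e-300

#: Dimension above which the embedded matrix is held sparse.
DENSE_CAP = 512

#: Default guard on the embedded chain dimension (memory protection).
DEFAULT_DIM_CAP = 20_000


class EmbeddingTooLargeError(ValueError):
    """Embedded chain dimension exceeds the cap.

    Raised before any allocation.  The MSR rank statistic only needs the
    single-occurrence probability and avoids the embedding entirely; prefer
    it for long sequences or high occurrence counts.
    """


@dataclass(frozen=True)
class BaseComposition:
    """Base frequencies (A, C, G, T) of a sequence; non-negative, sum to 1."""

    freqs: tuple

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("composition must be 4 non-negative frequencies summing to 1")

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "BaseComposition":
        total = counts.sum()
        if total == 0:
            raise ValueError("sequence has no valid (A/C/G/T) bases")
        return cls(tuple(np.asarray(counts, dtype=float) / total))


def composition_of(sequence: str) -> BaseComposition:
    """Maximum-likelihood base frequencies of a sequence.

    Only A/C/G/T count; other symbols are excluded (the skip policy).  A
    sequence with no valid base is an error.  Zero frequencies are allowed —
    a motif needing an absent base simply gets zero-probability paths.
    """
    codes = encode_sequence(sequence)
    valid = codes[codes >= 0]
    counts = np.bincount(valid, minlength=4)[:4] if valid.size else np.zeros(4)
    return BaseComposition.from_counts(counts)


def _transition_onehot(dfa: DFA) -> np.ndarray:
    """(4, n, n) indicator tensor: onehot[s, i, delta(i, s)] = 1."""
    n = dfa.n_states
    onehot = np.zeros((4, n, n))
    rows = np.arange(n)
    for sym in range(4):
        onehot[sym, rows, dfa.delta[:, sym]] = 1.0
    return onehot


def dfa_to_tpm(dfa: DFA, comp: BaseComposition) -> np.ndarray:
    """Transition probability matrix of the DFA under a base composition.

    Entry (i, j) sums the frequencies of the bases moving state i to state j;
    rows sum to one because the automaton is total.
    """
    n = dfa.n_states
    tpm = np.zeros((n, n))
    rows = np.arange(n)
    freqs = comp.as_array
    for sym in range(4):
        np.add.at(tpm, (rows, dfa.delta[:, sym]), freqs[sym])
    return tpm


def matrix_power(M, l: int, return_ops: bool = False):
    """M**l by binary exponentiation (works for dense and scipy.sparse).

    Uses at most 2*ceil(log2 l) matrix multiplications; l = 0 gives the
    identity.
    """
    if l < 0:
        raise ValueError("negative matrix power")
    dense = not sp.issparse(M)
    ident = np.eye(M.shape[0]) if dense else sp.identity(M.shape[0], format="csr")
    result = None
    ops = 0
    p = M
    while l:
        if l & 1:
            result = p if result is None else result @ p
            ops += 0 if result is p else 1
        l >>= 1
        if l:
            p = p @ p
            ops += 1
    out = ident if result is None else result
    return (out, ops) if return_ops else out


def build_etpm(
    dfa: DFA,
    comp: BaseComposition,
    n_obs: int,
    counting: str = "overlapping",
    dim_cap: int = DEFAULT_DIM_CAP,
    representation: str = "auto",
):
    """Embedded transition probability matrix for ``n_obs`` occurrences.

    The state space is ``n_obs`` copies of the template chain plus one
    absorbing final state (dimension ``n_obs * n_states + 1``).  The copy
    index counts completed occurrences: transition mass that *enters* an end
    state is redirected to the entered state in the next copy (to the
    absorbing final state from the last copy).  In non-overlapping mode the
    occurrence instead restarts the next copy at the initial state.  All
    other mass stays inside its copy, so each diagonal block is the template
    TPM with the end-state columns blanked.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    n = dfa.n_states
    dim = n_obs * n + 1
    if dim > dim_cap:
        raise EmbeddingTooLargeError(
            f"embedded chain dimension {dim} exceeds the cap ({dim_cap}); "
            "use the MSR method, which avoids the embedding"
        )
    tpm = dfa_to_tpm(dfa, comp)
    into_end = tpm * dfa.is_end[np.newaxis, :]   # mass entering an end state
    within = tpm - into_end
    final = n_obs * n
    if representation == "auto":
        representation = "dense" if dim <= DENSE_CAP else "sparse"

    if representation == "dense":
        M = np.zeros((dim, dim))
        for c in range(n_obs):
            lo = c * n
            M[lo:lo + n, lo:lo + n] = within
            if c + 1 < n_obs:
                if counting == "overlapping":
                    M[lo:lo + n, lo + n:lo + 2 * n] += into_end
                else:
                    M[lo:lo + n, lo + n + dfa.start] += into_end.sum(axis=1)
            else:
                M[lo:lo + n, final] += into_end.sum(axis=1)
        M[final, final] = 1.0
        return M

    if representation != "sparse":
        raise ValueError(f"unknown representation {representation!r}")
    blocks = []
    w = sp.csr_matrix(within)
    e = sp.csr_matrix(into_end)
    e_sum = into_end.sum(axis=1)
    rows, cols, vals = [], [], []
    for c in range(n_obs):
        lo = c * n
        wc = w.tocoo()
        rows.extend(wc.row + lo); cols.extend(wc.col + lo); vals.extend(wc.data)
        if c + 1 < n_obs:
            if counting == "overlapping":
                ec = e.tocoo()
                rows.extend(ec.row + lo); cols.extend(ec.col + lo + n); vals.extend(ec.data)
            else:
                nz = np.flatnonzero(e_sum)
                rows.extend(nz + lo); cols.extend([lo + n + dfa.start] * len(nz))
                vals.extend(e_sum[nz])
        else:
            nz = np.flatnonzero(e_sum)
            rows.extend(nz + lo); cols.extend([final] * len(nz)); vals.extend(e_sum[nz])
    rows.append(final); cols.append(final); vals.append(1.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(dim, dim))


@dataclass
class SSPRecord:
    """Per-sequence motif result.

    ``ssp`` is P(count >= n_obs) under the i.i.d. null for this sequence's
    length and composition (1 exactly when n_obs = 0); ``p_ge1`` is
    P(count >= 1) and ``lam`` the Poisson rate -ln(1 - p_ge1) used by MSR.
    """

    id: Optional[str]
    length: int
    composition: BaseComposition
    n_obs: int
    ssp: float
    p_ge1: float

    @property
    def lam(self) -> float:
        p = min(self.p_ge1, 1.0 - 1e-12)
        return -np.log1p(-p)


def p_ge1(dfa: DFA, comp: BaseComposition, l: int) -> float:
    """P(at least one occurrence in l bases) without building the embedding.

    End states are made absorbing in the template TPM; the probability is
    the end-state mass of the initial-state row of TPM**l.
    """
    tpm = dfa_to_tpm(dfa, comp)
    ends = dfa.is_end
    tpm[ends, :] = 0.0
    tpm[np.ix_(ends, ends)] = np.eye(int(ends.sum()))
    powered = matrix_power(tpm, int(l))
    return float(np.clip(powered[dfa.start, ends].sum(), 0.0, 1.0))


def p_ge1_batch(dfa: DFA, comps: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Vectorized :func:`p_ge1` over many (composition, length) pairs.

    ``comps`` is (B, 4), ``lengths`` (B,) integers.  The per-sequence matrix
    powers share one binary-exponentiation sweep over the length bits.
    """
    comps = np.asarray(comps, dtype=float)
    lengths = np.asarray(lengths, dtype=np.int64)
    b = comps.shape[0]
    n = dfa.n_states
    onehot = _transition_onehot(dfa)
    tpms = np.einsum("bs,sij->bij", comps, onehot)
    ends = dfa.is_end
    tpms[:, ends, :] = 0.0
    idx = np.flatnonzero(ends)
    tpms[:, idx, idx] = 1.0

    result = np.broadcast_to(np.eye(n), (b, n, n)).copy()
    max_bits = int(lengths.max()).bit_length() if lengths.size else 0
    p = tpms
    for bit in range(max_bits):
        mask = ((lengths >> bit) & 1).astype(bool)
        if mask.any():
            result[mask] = result[mask] @ p[mask]
        if bit + 1 < max_bits:
            p = p @ p
    return np.clip(result[:, dfa.start, :][:, ends].sum(axis=1), 0.0, 1.0)


def _ssp_value(motif: Motif, comp: BaseComposition, length: int, n_obs: int,
               dim_cap: int = DEFAULT_DIM_CAP, representation: str = "auto") -> float:
    if n_obs == 0:
        return 1.0
    etpm = build_etpm(motif.dfa, comp, n_obs, counting=motif.counting,
                      dim_cap=dim_cap, representation=representation)
    powered = matrix_power(etpm, int(length))
    start = motif.dfa.start          # initial state lives in copy 0
    final = motif.dfa.n_states * n_obs
    val = powered[start, final]   # works for dense and sparse alike
    return float(np.clip(val, SSP_FLOOR, 1.0))


def ssp(
    motif: Motif,
    sequence: str,
    seq_id: Optional[str] = None,
    dim_cap: int = DEFAULT_DIM_CAP,
    representation: str = "auto",
) -> SSPRecord:
    """Sequence-specific p-value record for one motif and one sequence.

    Counts occurrences, estimates the composition on valid bases, and reads
    P(count >= n_obs) from the embedded chain raised to the sequence length.
    ``ssp`` is clamped to (1e-300, 1] so logarithms stay finite.
    """
    codes = encode_sequence(sequence)
    valid = codes[codes >= 0]
    comp = BaseComposition.from_counts(np.bincount(valid, minlength=4)[:4]
                                       if valid.size else np.zeros(4))
    length = int(valid.size)
    from .motifs import count_occurrences
    n_obs = count_occurrences(motif, sequence)
    value = _ssp_value(motif, comp, length, n_obs, dim_cap, representation)
    p1 = p_ge1(motif.dfa, comp, length)
    return SSPRecord(id=seq_id, length=length, composition=comp,
                     n_obs=n_obs, ssp=value, p_ge1=p1)


def ssp_randomized(motif: Motif, record: SSPRecord, u: float,
                   dim_cap: int = DEFAULT_DIM_CAP) -> float:
    """Mid-p style smoothing of the discrete SSP: P(>n) + u * P(=n).

    With u ~ U(0,1) the smoothed value is exactly uniform under the null.
    Intended for calibration diagnostics; reported SSPs stay P(>= n_obs).
    """
    p_gt = _ssp_value(motif, record.composition, record.length,
                      record.n_obs + 1, dim_cap)
    return p_gt + u * (record.ssp - p_gt)


def ssp_records(
    motif: Motif,
    sequences: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    dim_cap: int = DEFAULT_DIM_CAP,
) -> list[SSPRecord]:
    """SSP records for a list of sequences, in the given (rank) order.

    Occurrence counting and the single-occurrence probabilities are computed
    in one vectorized pass; the embedding is only built for sequences that
    contain the motif more than once (for a single occurrence the two
    computational routes coincide, so the absorbing-template value is used).
    """
    n_seq = len(sequences)
    if ids is None:
        ids = [f"seq_{i + 1}" for i in range(n_seq)]
    codes = [encode_sequence(s) for s in sequences]
    max_len = max((c.size for c in codes), default=0)
    mat = np.full((n_seq, max_len), -1, dtype=np.int8)
    for i, c in enumerate(codes):
        mat[i, : c.size] = c
    counts = count_occurrences_batch(motif, mat)
    comps = np.zeros((n_seq, 4))
    lengths = np.zeros(n_seq, dtype=np.int64)
    for i, c in enumerate(codes):
        v = c[c >= 0]
        if v.size == 0:
            raise ValueError(f"sequence {ids[i]!r} has no valid bases")
        comps[i] = np.bincount(v, minlength=4)[:4] / v.size
        lengths[i] = v.size
    p1 = p_ge1_batch(motif.dfa, comps, lengths)
    records = []
    for i in range(n_seq):
        comp = BaseComposition(tuple(comps[i]))
        n_obs = int(counts[i])
        if n_obs == 0:
            value = 1.0
        elif n_obs == 1:
            value = float(np.clip(p1[i], SSP_FLOOR, 1.0))
        else:
            value = _ssp_value(motif, comp, int(lengths[i]), n_obs, dim_cap)
        records.append(SSPRecord(id=str(ids[i]), length=int(lengths[i]),
                                 composition=comp, n_obs=n_obs, ssp=value,
                                 p_ge1=float(p1[i])))
    return records
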