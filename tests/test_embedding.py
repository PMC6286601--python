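"""Transition matrices, embedded chains and exact sequence p-values."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

import motifrank as mr
from motifrank.embedding import BaseComposition, _ssp_value, p_ge1_batch


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seq,expected", [
    ("ACGT", (0.25, 0.25, 0.25, 0.25)),
    ("AAAA", (1.0, 0.0, 0.0, 0.0)),
    ("AACGTT", (1 / 3, 1 / 6, 1 / 6, 1 / 3)),
])
def test_composition_examples(seq, expected):
    comp = mr.composition_of(seq)
    assert np.allclose(comp.as_array, expected)


def test_composition_skips_unknown_and_rejects_empty():
    assert np.allclose(mr.composition_of("ANNA").as_array, (1, 0, 0, 0))
    with pytest.raises(ValueError):
        mr.composition_of("NNN")


def test_composition_validation():
    with pytest.raises(ValueError):
        BaseComposition((0.5, 0.5, 0.5, -0.5))


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def test_tpm_single_base_motif_uniform():
    dfa = mr.Motif.compile("A").dfa
    tpm = mr.dfa_to_tpm(dfa, BaseComposition.uniform())
    assert np.allclose(tpm, [[0.75, 0.25], [0.75, 0.25]])


def test_tpm_degenerate_composition_is_deterministic():
    dfa = mr.Motif.compile("ACG").dfa
    tpm = mr.dfa_to_tpm(dfa, BaseComposition((1, 0, 0, 0)))
    assert set(np.unique(tpm)) <= {0.0, 1.0}
    assert np.allclose(tpm.sum(axis=1), 1.0)


def test_tpm_rows_sum_to_one(rng):
    for pattern in ["ACGTGAT", "TTTCNNNGAAA", "(A|T)N*G"]:
        dfa = mr.Motif.compile(pattern).dfa
        f = rng.dirichlet(np.ones(4))
        tpm = mr.dfa_to_tpm(dfa, BaseComposition(tuple(f)))
        assert np.allclose(tpm.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# eTPM
# ---------------------------------------------------------------------------

def test_etpm_single_base_motif():
    # motif A, uniform, n_obs=1: 2 template states + absorbing final
    m = mr.Motif.compile("A")
    e = mr.build_etpm(m.dfa, BaseComposition.uniform(), 1)
    assert e.shape == (3, 3)
    start = m.dfa.start
    assert e[start, start] == 0.75 and e[start, 2] == 0.25
    assert e[2, 2] == 1.0


def test_etpm_two_occurrences_two_steps():
    m = mr.Motif.compile("A")
    e = mr.build_etpm(m.dfa, BaseComposition.uniform(), 2)
    assert np.allclose(mr.matrix_power(e, 1)[m.dfa.start, -1], 0.0)
    assert np.allclose(mr.matrix_power(e, 2)[m.dfa.start, -1], 0.0625)


def test_etpm_block_structure_and_row_sums():
    m = mr.Motif.compile("AC?G")
    comp = BaseComposition((0.3, 0.3, 0.2, 0.2))
    n = m.dfa.n_states
    e = mr.build_etpm(m.dfa, comp, 3)
    assert e.shape == (3 * n + 1, 3 * n + 1)
    assert np.allclose(e.sum(axis=1), 1.0, atol=1e-12)
    tpm = mr.dfa_to_tpm(m.dfa, comp)
    within = tpm * ~m.dfa.is_end[np.newaxis, :]
    for c in range(3):
        assert np.allclose(e[c * n:(c + 1) * n, c * n:(c + 1) * n], within)
    # absorbing final state
    final = 3 * n
    assert e[final, final] == 1.0 and e[final, :final].sum() == 0.0


def test_etpm_dim_cap_mentions_msr():
    m = mr.Motif.compile("ACGTGAT")
    with pytest.raises(mr.EmbeddingTooLargeError, match="MSR"):
        mr.build_etpm(m.dfa, BaseComposition.uniform(), 10, dim_cap=50)


def test_dense_and_sparse_agree():
    m = mr.Motif.compile("ACGT")
    comp = BaseComposition((0.2, 0.3, 0.3, 0.2))
    for n_obs in (1, 3):
        dense = mr.build_etpm(m.dfa, comp, n_obs, representation="dense")
        sparse = mr.build_etpm(m.dfa, comp, n_obs, representation="sparse")
        assert sp.issparse(sparse)
        assert np.allclose(dense, sparse.toarray(), atol=1e-12)
        pd_ = mr.matrix_power(dense, 100)[0, -1]
        ps_ = mr.matrix_power(sparse, 100)[0, -1]
        assert abs(pd_ - ps_) < 1e-10


# ---------------------------------------------------------------------------
# matrix power
# ---------------------------------------------------------------------------

def test_matrix_power_identity_and_base(rng):
    M = rng.dirichlet(np.ones(6), size=6)
    assert np.allclose(mr.matrix_power(M, 0), np.eye(6))
    assert np.allclose(mr.matrix_power(M, 1), M)


def test_matrix_power_matches_naive_product(rng):
    M = rng.dirichlet(np.ones(6), size=6)
    naive = np.eye(6)
    for _ in range(13):
        naive = naive @ M
    fast, ops = mr.matrix_power(M, 13, return_ops=True)
    assert np.allclose(fast, naive, atol=1e-12)
    assert ops <= 2 * int(np.ceil(np.log2(13)))
    assert np.allclose(fast.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# SSP
# ---------------------------------------------------------------------------

def test_ssp_no_occurrence_is_one():
    rec = mr.ssp(mr.Motif.compile("A"), "C")
    assert rec.n_obs == 0 and rec.ssp == 1.0 and rec.p_ge1 == 0.0


def test_ssp_single_base_half_composition():
    rec = mr.ssp(mr.Motif.compile("A"), "AC")
    assert rec.n_obs == 1
    assert abs(rec.ssp - 0.75) < 1e-12      # 1 - 0.5^2


def test_p_ge1_single_base():
    dfa = mr.Motif.compile("A").dfa
    u = BaseComposition.uniform()
    assert abs(mr.p_ge1(dfa, u, 1) - 0.25) < 1e-12
    assert abs(mr.p_ge1(dfa, u, 3) - 0.578125) < 1e-12


def _exhaustive_ssp(pattern, l, comp, n_obs):
    """Oracle: sum of composition-weighted probabilities over all 4^l words."""
    m = mr.Motif.compile(pattern)
    total = 0.0
    for word in itertools.product("ACGT", repeat=l):
        s = "".join(word)
        if mr.count_occurrences(m, s) >= n_obs:
            p = 1.0
            for ch in s:
                p *= comp["ACGT".index(ch)]
            total += p
    return total


@pytest.mark.parametrize("pattern", ["AT", "AA", "(A|T)G", "AN*T"])
def test_ssp_equals_exhaustive_enumeration(pattern):
    comp = (0.3, 0.2, 0.2, 0.3)
    bc = BaseComposition(comp)
    m = mr.Motif.compile(pattern)
    for n_obs in (1, 2, 3):
        ours = _ssp_value(m, bc, 6, n_obs)
        oracle = _exhaustive_ssp(pattern, 6, comp, n_obs)
        assert abs(ours - oracle) < 1e-10


def test_ssp_nonoverlap_mode_equals_exhaustive():
    comp = (0.4, 0.1, 0.1, 0.4)
    bc = BaseComposition(comp)
    m = mr.Motif.compile("AA", counting="non-overlapping")
    for n_obs in (1, 2):
        total = 0.0
        for word in itertools.product("ACGT", repeat=6):
            s = "".join(word)
            if mr.count_occurrences(m, s) >= n_obs:
                p = 1.0
                for ch in s:
                    p *= comp["ACGT".index(ch)]
                total += p
        assert abs(_ssp_value(m, bc, 6, n_obs) - total) < 1e-10


def test_ssp_n1_equals_p_ge1(rng):
    for pattern in ["ACG", "TTTCNNNGAAA", "(AC)|(GT)", "AN?G"]:
        m = mr.Motif.compile(pattern)
        f = rng.dirichlet(np.ones(4))
        bc = BaseComposition(tuple(f))
        l = int(rng.integers(5, 60))
        assert abs(_ssp_value(m, bc, l, 1) - mr.p_ge1(m.dfa, bc, l)) < 1e-10


def test_ssp_non_increasing_in_n_obs():
    m = mr.Motif.compile("AC")
    bc = BaseComposition.uniform()
    values = [_ssp_value(m, bc, 30, n) for n in range(1, 6)]
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def test_initial_row_mass_conserved():
    m = mr.Motif.compile("ACG")
    e = mr.build_etpm(m.dfa, BaseComposition.uniform(), 3)
    powered = mr.matrix_power(e, 200)
    assert abs(powered[m.dfa.start].sum() - 1.0) < 1e-9


def test_ssp_records_match_individual_ssp(null_cohort):
    ids, seqs = null_cohort
    motif = mr.Motif.compile("ACG")
    records = mr.ssp_records(motif, seqs[:25], ids[:25])
    for rec, s in zip(records, seqs[:25]):
        single = mr.ssp(motif, s)
        assert rec.n_obs == single.n_obs
        assert abs(rec.ssp - single.ssp) < 1e-10
        assert abs(rec.p_ge1 - single.p_ge1) < 1e-10


def test_p_ge1_batch_matches_scalar(rng):
    m = mr.Motif.compile("TTTCNNNGAAA")
    comps = rng.dirichlet(np.ones(4), size=12)
    lengths = rng.integers(11, 120, size=12)
    batch = p_ge1_batch(m.dfa, comps, lengths)
    for i in range(12):
        scalar = mr.p_ge1(m.dfa, BaseComposition(tuple(comps[i])), int(lengths[i]))
        assert abs(batch[i] - scalar) < 1e-12


def test_smoothed_ssp_uniform_under_null(rng):
    """Mid-p smoothed SSPs are exactly uniform under the matched null.

    Sequences are simulated from a fixed composition and their discrete
    P(count >= n) values are smoothed with P(> n) + U P(= n); the result
    must pass a KS test against U(0,1) at the 0.01 level.
    """
    m = mr.Motif.compile("AC")
    comp = (0.3, 0.2, 0.2, 0.3)
    bc = BaseComposition(comp)
    length = 40
    sf = {n: _ssp_value(m, bc, length, n) for n in range(0, 14)}
    sf[0] = 1.0
    seqs = rng.choice(list("ACGT"), size=(600, length), p=comp)
    vals = []
    for row in seqs:
        n_obs = mr.count_occurrences(m, "".join(row))
        p_ge = sf[n_obs]
        p_gt = sf[n_obs + 1]
        vals.append(p_gt + rng.random() * (p_ge - p_gt))
    assert stats.kstest(vals, "uniform").pvalue > 0.01


def test_scan_count_equals_edfa_simulation(rng):
    """Automaton-consistency oracle: scanning counts occurrences exactly as
    the embedded chain does.

    With a one-hot composition the eTPM for symbol s is a 0/1 matrix — the
    transition function of the embedded automaton.  Simulating a sequence
    through those matrices and reading off the copy index of the final state
    must reproduce count_occurrences for every (motif, sequence) pair.
    """
    patterns = ["A", "AA", "AT", "(A|T)G", "AN*T", "GA*", "ACGT",
                "(AC)|(GT)", "TTTCNNNGAAA"]
    pairs = 0
    while pairs < 60:
        pattern = patterns[pairs % len(patterns)]
        m = mr.Motif.compile(pattern)
        n = m.dfa.n_states
        seq = "".join(rng.choice(list("ACGT"))
                      for _ in range(int(rng.integers(1, 50))))
        scan = mr.count_occurrences(m, seq)
        k = scan + 2                      # enough copies to avoid absorption
        step = {}
        for sym, base in enumerate("ACGT"):
            onehot = np.zeros(4)
            onehot[sym] = 1.0
            e = mr.build_etpm(m.dfa, BaseComposition(tuple(onehot)), k)
            step[base] = np.argmax(e, axis=1)   # deterministic 0/1 rows
        state = m.dfa.start                      # copy 0, initial state
        for base in seq:
            state = int(step[base][state])
        assert state // n == scan, (pattern, seq)
        pairs += 1


def test_ssp_floor_protects_logs():
    # impossible-base motif on a long sequence: ssp must stay positive
    m = mr.Motif.compile("AAAA")
    rec = mr.ssp(m, "A" * 2000)
    assert rec.ssp >= 1e-300
    assert np.isfinite(-np.log(rec.ssp))


def test_embedding_cost_grows_with_n_obs():
    """eDFA dimension is linear in n_obs (cubic matrix cost, log-l powering)."""
    m = mr.Motif.compile("ACGTGAT")
    dims = [mr.build_etpm(m.dfa, BaseComposition.uniform(), n).shape[0]
            for n in (1, 2, 4)]
    n = m.dfa.n_states
    assert dims == [n + 1, 2 * n + 1, 4 * n + 1]
    _, ops_small = mr.matrix_power(np.eye(3), 8, return_ops=True)
    _, ops_big = mr.matrix_power(np.eye(3), 4096, return_ops=True)
    assert ops_big <= 2 * 12 and ops_small <= 2 * 3
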