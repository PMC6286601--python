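"""Rank-correlation / clustering p-values for a motif over a ranked list.

Given the per-sequence p-values (SSPs) of a motif along an experimentally
ranked sequence list, three statistics test whether the motif signal is
biased in the ranking:

Brownian bridge (BB)
    Running sum of mean-adjusted log scores -ln(SSP + alpha).  Under the
    null (exchangeable scores) the standardized trajectory converges to a
    Brownian bridge; the maximum absolute excursion is tested against the
    Kolmogorov distribution (default), or the one-sided maximum against its
    exact survival exp(-2 D^2 / (N sigma^2)) with ``alternative="greater"``.

Resetting random walk (RW)
    SSPs become integer steps (+u for SSP <= p0, -d otherwise; negative null
    drift required).  The walk restarts at 0 whenever it would reach -1, so
    its maximum is sensitive to runs of enriched sequences *anywhere* in the
    list, in the spirit of maximal-segment-score statistics from local
    alignment theory.  P(max >= M) comes from an exact lattice recursion, a
    Gumbel-type tail approximation, or Monte Carlo.

Modified sum of ranks (MSR)
    Each sequence i occupies an interval of length lambda_i = -ln(1 - p_i)
    on a pseudo-time axis (p_i = P(>=1 occurrence)), so under the null the
    n. observed occurrences fall uniformly on [0, lambda.].  The mean
    midpoint score of the occurrences, centred and scaled, is asymptotically
    N(0, 1/12); the p-value is two-sided normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .embedding import SSPRecord

__all__ = [
    "RankedList",
    "BBResult",
    "RWScheme",
    "RWResult",
    "MSRResult",
    "RCPResult",
    "bb_rcp",
    "rw_rcp",
    "msr_rcp",
    "rcp",
    "bridge_max_sf",
    "rw_max_sf_exact",
    "rw_max_sf_gumbel",
    "rw_lambda_star",
]

LOG10E = math.log10(math.e)


@dataclass
class RankedList:
    """SSP records in experimental rank order (rank 1 = first element)."""

    records: list

    def __post_init__(self):
        if len(self.records) < 2:
            raise ValueError("a ranked list needs at least 2 sequences")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence IDs in a ranked list must be unique")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ssps(self) -> np.ndarray:
        return np.array([r.ssp for r in self.records])

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.n_obs for r in self.records])

    @property
    def p_ge1(self) -> np.ndarray:
        return np.array([r.p_ge1 for r in self.records])

    @property
    def lams(self) -> np.ndarray:
        return np.array([r.lam for r in self.records])

    @classmethod
    def from_arrays(cls, ssps, counts=None, p_ge1=None, ids=None) -> "RankedList":
        """Build a ranked list directly from statistic arrays (no sequences).

        Convenient for simulation studies where SSPs are drawn from a null
        rather than computed from sequences.
        """
        ssps = np.asarray(ssps, dtype=float)
        n = ssps.size
        counts = np.zeros(n, dtype=int) if counts is None else np.asarray(counts)
        p_ge1 = np.zeros(n) if p_ge1 is None else np.asarray(p_ge1, dtype=float)
        ids = [f"seq_{i + 1}" for i in range(n)] if ids is None else list(ids)
        from .embedding import BaseComposition
        comp = BaseComposition.uniform()
        recs = [SSPRecord(id=ids[i], length=0, composition=comp,
                          n_obs=int(counts[i]), ssp=float(ssps[i]),
                          p_ge1=float(p_ge1[i])) for i in range(n)]
        return cls(recs)


# ---------------------------------------------------------------------------
# Brownian bridge
# ---------------------------------------------------------------------------

def bridge_max_sf(x: float, alternative: str = "two-sided",
                  tol: float = 1e-12) -> tuple[float, float]:
    """Survival function of the standardized bridge maximum.

    ``alternative="two-sided"``: Kolmogorov law for sup|B(t)|,
    2 * sum_{k>=1} (-1)^{k-1} exp(-2 k^2 x^2), truncated once a term drops
    below *tol* (alternating series: truncation error < last term).
    ``alternative="greater"``: exact one-sided law exp(-2 x^2).
    Returns ``(p, log_p)``; p clipped to (0, 1].
    """
    if x <= 0:
        return 1.0, 0.0
    if alternative == "greater":
        logp = -2.0 * x * x
        p = math.exp(logp) if logp > -700 else 1e-300
        return min(p, 1.0), logp
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    if x < 1e-4:
        return 1.0, 0.0
    s = 0.0
    k = 1
    while k <= 200_000:
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * x * x)
        s += term
        if abs(term) < tol:
            break
        k += 1
    p = float(min(max(s, 1e-300), 1.0))
    if x >= 1.0:
        # stable log: p = 2 e^{-2x^2} (1 - e^{-6x^2} + e^{-16x^2} - ...)
        corr = 0.0
        for k, sign in ((2, -1.0), (3, 1.0), (4, -1.0)):
            corr += sign * math.exp(-2.0 * (k * k - 1) * x * x)
        logp = math.log(2.0) - 2.0 * x * x + math.log1p(corr)
    else:
        logp = math.log(p)
    return p, logp


@dataclass
class BBResult:
    """Brownian-bridge test output: trajectory, max excursion and p-value."""

    trajectory: np.ndarray        # r_0 .. r_N, starts and ends at 0
    d: float                      # max excursion (|.| or one-sided)
    sigma2: float                 # standardization variance of the log scores
    statistic: float              # D / sqrt(N sigma^2)
    pvalue: float
    log_pvalue: float
    alpha: float
    alternative: str


#: Siegmund's corrected-diffusion overshoot constant, -zeta(1/2)/sqrt(2 pi).
#: The discrete-time running sum undershoots the continuous bridge supremum;
#: adding RHO * sigma to the crossing level removes the O(1/sqrt(N)) bias of
#: the analytic survival law.
SIEGMUND_RHO = 0.5826


def bb_rcp(ranked, alpha: float = 1e-5, assume_unit_variance: bool = False,
           alternative: str = "greater",
           continuity_correction: bool = True) -> BBResult:
    """Brownian-bridge rank-correlation p-value.

    Log scores ls_i = -ln(ssp_i + alpha) (alpha is a score dampening factor)
    are mean-adjusted and summed; the running sum starts and ends at zero.
    The default statistic is the one-sided maximum of the running sum
    (sensitive to enrichment at the top of the list; reverse the rank to
    test the bottom), tested against its exact bridge law exp(-2 D^2 /
    (N sigma^2)); ``alternative="two-sided"`` uses max|r_i| against the
    Kolmogorov distribution.  Standardization uses the empirical score
    variance unless ``assume_unit_variance`` (appropriate for exactly
    uniform SSPs, where -ln U is Exp(1)).  ``continuity_correction`` applies
    Siegmund's overshoot correction D -> D + 0.5826 sigma, which removes the
    conservative finite-N bias of the continuous-time approximation.
    """
    ssps = ranked.ssps if isinstance(ranked, RankedList) else np.asarray(ranked, float)
    n = ssps.size
    if n < 2:
        raise ValueError("need at least 2 sequences")
    ls = -np.log(ssps + alpha)
    r = np.concatenate([[0.0], np.cumsum(ls - ls.mean())])
    sigma2 = 1.0 if assume_unit_variance else float(ls.var(ddof=1))
    d = float(np.abs(r).max() if alternative == "two-sided" else r.max())
    if sigma2 <= 0.0 or d <= 0.0:
        return BBResult(trajectory=r, d=max(d, 0.0), sigma2=sigma2,
                        statistic=0.0, pvalue=1.0, log_pvalue=0.0,
                        alpha=alpha, alternative=alternative)
    d_eff = d + SIEGMUND_RHO * math.sqrt(sigma2) if continuity_correction else d
    x = d_eff / math.sqrt(n * sigma2)
    p, logp = bridge_max_sf(x, alternative=alternative)
    return BBResult(trajectory=r, d=d, sigma2=sigma2, statistic=x,
                    pvalue=p, log_pvalue=logp, alpha=alpha,
                    alternative=alternative)


# ---------------------------------------------------------------------------
# Resetting random walk
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RWScheme:
    """Integer scoring scheme: +up for SSP <= p0, -down otherwise.

    The null drift p0*up - (1-p0)*down must be negative (the standard
    condition for maximal-segment statistics to have an extreme-value tail).
    """

    p0: float = 0.05
    up: int = 3
    down: int = 1

    def __post_init__(self):
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must be in (0, 1)")
        if self.up <= 0 or self.down <= 0:
            raise ValueError("up and down must be positive integers")
        if self.p0 * self.up - (1.0 - self.p0) * self.down >= 0:
            raise ValueError(
                "scheme has non-negative null drift; the max statistic "
                "theory requires p0*up < (1-p0)*down"
            )


def rw_lambda_star(scheme: RWScheme) -> float:
    """Positive root of p0*e^(lam*u) + (1-p0)*e^(-lam*d) = 1 (tail exponent)."""
    q = 1.0 - scheme.p0

    def f(lam):
        return scheme.p0 * math.exp(lam * scheme.up) + q * math.exp(-lam * scheme.down) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-14))


def _walk(steps: np.ndarray) -> tuple[np.ndarray, int]:
    """Trajectory with reset-at--1 semantics; returns (heights, max)."""
    h = 0
    traj = np.zeros(steps.size + 1, dtype=np.int64)
    m = 0
    for i, s in enumerate(steps):
        h += int(s)
        if h <= -1:
            h = 0
        traj[i + 1] = h
        if h > m:
            m = h
    return traj, m


def rw_max_sf_exact(m: int, n: int, scheme: RWScheme) -> tuple[float, float]:
    """Exact P(max >= m) for the resetting walk over n null steps.

    Lattice recursion over heights {0..m-1} with absorption at >= m and the
    reset-to-0 rule below 0.  The absorbed mass is accumulated additively,
    so tiny p-values keep full relative precision.  Returns (p, log p).
    """
    if m <= 0:
        return 1.0, 0.0
    p0, u, d = scheme.p0, scheme.up, scheme.down
    q = 1.0 - p0
    v = np.zeros(m)
    v[0] = 1.0
    absorbed = 0.0
    for _ in range(n):
        nv = np.zeros(m)
        # up-steps
        if m > u:
            nv[u:] += p0 * v[:m - u]
        absorbed += p0 * v[max(m - u, 0):].sum()
        # down-steps (height < d resets to 0)
        nv[: m - d] += q * v[d:]
        nv[0] += q * v[:d].sum()
        v = nv
    if absorbed > 0.0:
        return float(min(absorbed, 1.0)), math.log(min(absorbed, 1.0))
    # below float underflow: fall back to the Gumbel tail for the log value
    _, logp = rw_max_sf_gumbel(m, n, scheme)
    return 1e-300, logp


_GUMBEL_K_CACHE: dict = {}


def _gumbel_k(scheme: RWScheme) -> float:
    """Prefactor K of the Gumbel tail, calibrated once per scheme.

    K has no simple closed form for general integer schemes; it is fixed
    deterministically by matching the exact lattice recursion at a reference
    point in the moderate tail.
    """
    key = (scheme.p0, scheme.up, scheme.down)
    if key not in _GUMBEL_K_CACHE:
        lam = rw_lambda_star(scheme)
        n0 = 1000
        m0 = max(int(math.ceil(math.log(n0) / lam)) + 6, scheme.up + 1)
        p_exact, _ = rw_max_sf_exact(m0, n0, scheme)
        _GUMBEL_K_CACHE[key] = -math.log1p(-p_exact) / (n0 * math.exp(-lam * m0))
    return _GUMBEL_K_CACHE[key]


def rw_max_sf_gumbel(m: int, n: int, scheme: RWScheme) -> tuple[float, float]:
    """Gumbel-type tail approximation P(max >= m) ~ 1 - exp(-K n e^(-lam m))."""
    if m <= 0:
        return 1.0, 0.0
    lam = rw_lambda_star(scheme)
    k = _gumbel_k(scheme)
    log_rate = math.log(k * n) - lam * m
    if log_rate > 700:
        return 1.0, 0.0
    rate = math.exp(log_rate)
    p = -math.expm1(-rate)
    if p <= 0.0:
        return 1e-300, log_rate
    logp = math.log(p) if p > 1e-12 else log_rate + math.log1p(-rate / 2.0)
    return min(p, 1.0), min(logp, 0.0)


def _rw_max_sf_mc(m: int, n: int, scheme: RWScheme, n_sims: int,
                  rng: np.random.Generator) -> tuple[float, float]:
    if m <= 0:
        return 1.0, 0.0
    hits = 0
    block = min(n_sims, 20_000)
    done = 0
    while done < n_sims:
        b = min(block, n_sims - done)
        h = np.zeros(b, dtype=np.int64)
        mx = np.zeros(b, dtype=np.int64)
        for _ in range(n):
            step = np.where(rng.random(b) <= scheme.p0, scheme.up, -scheme.down)
            h = h + step
            h[h <= -1] = 0
            np.maximum(mx, h, out=mx)
        hits += int((mx >= m).sum())
        done += b
    p = (hits + 1) / (n_sims + 1)
    return p, math.log(p)


@dataclass
class RWResult:
    """Resetting random-walk test output."""

    steps: np.ndarray
    trajectory: np.ndarray
    m: int                        # max walk value
    scheme: RWScheme
    pvalue: float
    log_pvalue: float
    mode: str


def rw_rcp(ranked, scheme: Optional[RWScheme] = None, mode: str = "exact",
           n_sims: int = 10_000, rng=None) -> RWResult:
    """Random-walk rank-clustering p-value.

    SSPs at or below ``scheme.p0`` give an up-step (+up), larger SSPs a
    down-step (-down); the walk restarts at zero whenever it would hit -1.
    The p-value is P(max >= observed max) under the null of uniform SSPs,
    by exact dynamic programming (``mode="exact"``), the Gumbel tail
    approximation (``"gumbel"``), or Monte Carlo (``"monte-carlo"``).
    """
    scheme = scheme or RWScheme()
    ssps = ranked.ssps if isinstance(ranked, RankedList) else np.asarray(ranked, float)
    n = ssps.size
    steps = np.where(ssps <= scheme.p0, scheme.up, -scheme.down).astype(np.int64)
    traj, m = _walk(steps)
    if mode == "exact":
        p, logp = rw_max_sf_exact(m, n, scheme)
    elif mode == "gumbel":
        p, logp = rw_max_sf_gumbel(m, n, scheme)
    elif mode == "monte-carlo":
        rng = np.random.default_rng(rng)
        p, logp = _rw_max_sf_mc(m, n, scheme, n_sims, rng)
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")
    return RWResult(steps=steps, trajectory=traj, m=m, scheme=scheme,
                    pvalue=p, log_pvalue=logp, mode=mode)


# ---------------------------------------------------------------------------
# Modified sum of ranks
# ---------------------------------------------------------------------------

@dataclass
class MSRResult:
    """Modified-sum-of-ranks test output."""

    lam_total: float              # lambda. = sum of per-sequence rates
    n_total: int                  # n. = total motif occurrences
    midpoints: np.ndarray         # interval midpoint score per sequence
    w: float                      # test statistic, null N(0, 1/12)
    pvalue: float
    log_pvalue: float
    standardized: bool


def msr_rcp(ranked, standardized: bool = True) -> MSRResult:
    """Modified-sum-of-ranks rank-correlation p-value.

    Sequences occupy consecutive intervals of length lambda_i on a Poisson
    pseudo-time axis; each of the n. motif occurrences scores the midpoint
    of its sequence's interval.  W = (sqrt(n.)/lambda.) (mean score -
    lambda./2) is N(0, 1/12) under the null; the default standardizes by
    sqrt(12) before the two-sided normal p-value (``standardized=False``
    applies the normal CDF to W directly, for comparison).
    """
    if not isinstance(ranked, RankedList):
        raise TypeError("msr_rcp needs a RankedList (requires counts and p_ge1)")
    lams = ranked.lams
    counts = ranked.counts
    lam_total = float(lams.sum())
    n_total = int(counts.sum())
    cum = np.concatenate([[0.0], np.cumsum(lams)])
    midpoints = (cum[:-1] + cum[1:]) / 2.0
    if n_total == 0 or lam_total <= 0.0:
        import warnings
        warnings.warn("no motif occurrence in the list; MSR p-value is 1")
        return MSRResult(lam_total=lam_total, n_total=n_total,
                         midpoints=midpoints, w=0.0, pvalue=1.0,
                         log_pvalue=0.0, standardized=standardized)
    mean_score = float(counts @ midpoints) / n_total
    w = math.sqrt(n_total) / lam_total * (mean_score - lam_total / 2.0)
    z = abs(w) * (math.sqrt(12.0) if standardized else 1.0)
    pvalue = float(min(2.0 * stats.norm.sf(z), 1.0))
    log_pvalue = float(min(math.log(2.0) + stats.norm.logsf(z), 0.0))
    return MSRResult(lam_total=lam_total, n_total=n_total, midpoints=midpoints,
                     w=w, pvalue=max(pvalue, 1e-300), log_pvalue=log_pvalue,
                     standardized=standardized)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

@dataclass
class RCPResult:
    """Uniform record of a motif rank-correlation test."""

    motif: Optional[str]
    method: str
    statistic: float
    pvalue: float
    log10_pvalue: float
    n_sequences: int
    n_total: int
    detail: object = field(repr=False, default=None)


def rcp(ranked: RankedList, method: str = "msr", motif: Optional[str] = None,
        **options) -> RCPResult:
    """Dispatch to one of the three rank statistics (bb | rw | msr)."""
    if method == "bb":
        res = bb_rcp(ranked, **options)
        stat = res.statistic
    elif method == "rw":
        res = rw_rcp(ranked, **options)
        stat = float(res.m)
    elif method == "msr":
        res = msr_rcp(ranked, **options)
        stat = res.w
    else:
        raise ValueError(f"unknown method {method!r}; expected bb, rw or msr")
    n_total = int(ranked.counts.sum())
    return RCPResult(motif=motif, method=method, statistic=float(stat),
                     pvalue=res.pvalue, log10_pvalue=res.log_pvalue * LOG10E,
                     n_sequences=ranked.n, n_total=n_total, detail=res)
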