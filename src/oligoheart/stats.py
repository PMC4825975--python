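"""Exact and Monte-Carlo gene-set statistics.

One-tailed hypergeometric enrichment, Fisher's exact test on 2x2 carrier
tables, and the gene-set permutation p-value ``(r+1)/(n+1)`` used to confirm
case/control contrasts of rare-inheritance events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom


class ValidationError(ValueError):
    """Raised for impossible or inconsistent statistical inputs."""


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the population size, ``K`` the number of marked items and ``n``
    the draw size.  Summation is done in log space for numerical stability
    with extreme tables.
    """
    if not (0 <= k and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"impossible configuration k={k} K={K} n={n} N={N}")
    if k > min(K, n):
        raise ValidationError(f"k={k} exceeds min(K={K}, n={n})")
    lo = max(0, n - (N - K))
    support = np.arange(max(k, lo), min(K, n) + 1)
    if support.size == 0:
        return 0.0
    return float(np.exp(logsumexp(hypergeom.logpmf(support, N, K, n))))


def fisher_exact(table, sided: str = "one_tailed") -> float:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Rows are cohorts, columns carrier/non-carrier.  One-tailed is the upper
    hypergeometric tail of cell ``a`` given the margins (enrichment of
    carriers in the first cohort); two-tailed uses the probability-ordering
    convention (sum of all tables with fixed margins whose probability does
    not exceed the observed table's).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError(f"cell counts must be non-negative integers: {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + c  # carrier margin
    n = a + b  # first-cohort margin
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        warnings.warn("degenerate 2x2 margins; p = 1", stacklevel=2)
        return 1.0
    if sided == "one_tailed":
        return hypergeom_upper(a, K, n, N)
    if sided == "two_tailed":
        lo = max(0, n - (N - K))
        support = np.arange(lo, min(K, n) + 1)
        logp = hypergeom.logpmf(support, N, K, n)
        obs = hypergeom.logpmf(a, N, K, n)
        # relative tolerance guards against ties lost to rounding
        keep = logp <= obs + 1e-7
        return float(min(1.0, np.exp(logsumexp(logp[keep]))))
    raise ValidationError(f"sided must be one_tailed or two_tailed, got {sided!r}")


@dataclass
class PermutationResult:
    """Outcome of a Monte-Carlo gene-set permutation."""

    observed: float
    null: np.ndarray
    r: int
    n: int
    empirical_p: float
    observed_table: tuple = None

    def __post_init__(self):
        assert abs(self.empirical_p - (self.r + 1) / (self.n + 1)) < 1e-12


def carrier_table(case_inc: np.ndarray, ctrl_inc: np.ndarray, gene_idx) -> tuple:
    """2x2 carrier table for a gene set.

    ``case_inc``/``ctrl_inc`` are boolean individual x gene incidence
    matrices (True where the individual has a qualifying inheritance event
    in the gene).  An individual carrying events in several genes of the set
    is counted once.
    """
    gene_idx = np.asarray(gene_idx)
    k_case = int(case_inc[:, gene_idx].any(axis=1).sum())
    k_ctrl = int(ctrl_inc[:, gene_idx].any(axis=1).sum())
    return ((k_case, case_inc.shape[0] - k_case), (k_ctrl, ctrl_inc.shape[0] - k_ctrl))


def montecarlo_geneset_p(
    case_inc: np.ndarray,
    ctrl_inc: np.ndarray,
    target_idx,
    n_perm: int = 999,
    seed: int = 0,
    sided: str = "one_tailed",
    tie_break: str = "conservative",
) -> PermutationResult:
    """Permutation p-value for a target gene set against random draws.

    The observed statistic is the Fisher p for the carrier table of the
    target set.  Each replicate draws ``m = |target|`` genes uniformly
    without replacement from the incidence universe (the matrix columns) and
    recomputes the statistic; ``empirical_p = (r+1)/(n+1)`` where ``r``
    counts replicates at least as extreme (replicate p <= observed p).

    ``tie_break='randomized'`` instead ranks the observed statistic among the
    replicates with a uniform jitter on ties, which makes the p-value exactly
    uniform on {1/(n+1), ..., 1} under exchangeability; the conservative
    default is super-uniform when the discrete statistic has ties.
    """
    case_inc = np.asarray(case_inc, dtype=bool)
    ctrl_inc = np.asarray(ctrl_inc, dtype=bool)
    if case_inc.shape[1] != ctrl_inc.shape[1]:
        raise ValidationError("case and control incidence must share the gene universe")
    n_genes = case_inc.shape[1]
    target_idx = np.asarray(target_idx)
    m = target_idx.size
    if m > n_genes:
        raise ValidationError(f"target set of {m} exceeds universe of {n_genes}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")

    rng = np.random.default_rng(seed)
    obs_table = carrier_table(case_inc, ctrl_inc, target_idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = fisher_exact(obs_table, sided)
        # Fisher p depends only on the two carrier counts; memoize per pair.
        cache: dict = {}
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n_genes, size=m, replace=False)
            key = (
                int(case_inc[:, idx].any(axis=1).sum()),
                int(ctrl_inc[:, idx].any(axis=1).sum()),
            )
            if key not in cache:
                tab = (
                    (key[0], case_inc.shape[0] - key[0]),
                    (key[1], ctrl_inc.shape[0] - key[1]),
                )
                cache[key] = fisher_exact(tab, sided)
            null[i] = cache[key]

    if tie_break == "conservative":
        r = int((null <= observed).sum())
    elif tie_break == "randomized":
        jitter = rng.random(n_perm + 1)
        r = int(sum((p < observed) or (p == observed and u < jitter[0])
                    for p, u in zip(null, jitter[1:])))
    else:
        raise ValidationError(f"unknown tie_break {tie_break!r}")
    return PermutationResult(
        observed=observed,
        null=null,
        r=r,
        n=n_perm,
        empirical_p=(r + 1) / (n_perm + 1),
        observed_table=obs_table,
    )


def negative_control_contrast(
    case_inc: np.ndarray,
    ctrl_inc: np.ndarray,
    control_idx,
    signal_idx=None,
    sided: str = "two_tailed",
):
    """Carrier table and Fisher p for a negative-control gene list.

    Used for gene lists expected to carry no disease signal (the study's
    ocular-malformation list).  Warns if the control list overlaps the
    signal list instead of failing.
    """
    control_idx = np.asarray(control_idx)
    if signal_idx is not None:
        overlap = np.intersect1d(control_idx, np.asarray(signal_idx))
        if overlap.size:
            warnings.warn(
                f"negative-control list shares {overlap.size} genes with the signal list",
                stacklevel=2,
            )
    if control_idx.size == 0:
        warnings.warn("empty negative-control list; p = 1", stacklevel=2)
        return ((0, case_inc.shape[0]), (0, ctrl_inc.shape[0])), 1.0
    table = carrier_table(np.asarray(case_inc, bool), np.asarray(ctrl_inc, bool), control_idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = fisher_exact(table, sided)
    return table, p
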