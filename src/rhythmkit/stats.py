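"""Group-level inference: rank tests, Storey positive-FDR q-values and
frequency-wise permutation testing of coherence spectra.

Within-group phase differences are tested against zero with the one-sample
Wilcoxon signed-rank test; between-group comparisons of averaged phase /
MESOR / amplitude use the two-sided Mann–Whitney rank-sum test, with the
resulting p-value family corrected by Storey's positive false discovery
rate.  Group differences in coherence are assessed frequency by frequency:
the observed rank-sum statistic is compared against its distribution under
random reassignment of group labels to participants (group sizes
preserved), with the add-one rule so permutation p-values are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PermutationResult",
    "test_vs_zero",
    "pairwise_group_test",
    "storey_fdr",
    "permutation_coherence_test",
]


@dataclass
class PermutationResult:
    """Per-frequency permutation test outcome for one group pair."""

    freq: np.ndarray
    statistic: np.ndarray          # observed rank-sum of the first group
    p_perm: np.ndarray
    n_permutations: int
    seed: int | None
    alpha: float
    exact: bool = False            # True when all assignments were enumerated

    @property
    def significant_mask(self) -> np.ndarray:
        return self.p_perm < self.alpha


def test_vs_zero(
    values: Sequence[float],
    method: Literal["signed_rank", "mannwhitney_zero"] = "signed_rank",
) -> tuple[float, float]:
    """Two-sided one-sample location test of median 0.

    Default is the Wilcoxon signed-rank test.  ``mannwhitney_zero``
    compares the sample against an equal-length zero vector with the
    rank-sum test (a literal reading of "Mann–Whitney against zero mean"),
    kept for fidelity comparisons.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 5:
        raise ValueError("test_vs_zero requires at least 5 finite values")
    if method == "signed_rank":
        if np.all(v == 0):
            return 0.0, 1.0
        res = sstats.wilcoxon(v, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "mannwhitney_zero":
        if np.all(v == 0):
            return float(len(v) ** 2 / 2), 1.0
        res = sstats.mannwhitneyu(v, np.zeros_like(v), alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def pairwise_group_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney rank-sum test between independent groups.

    Exact null distribution for small tie-free samples, normal
    approximation with continuity correction otherwise; ties take midranks
    (scipy's 'auto' policy).  Identical samples return the maximal
    attainable p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("pairwise_group_test requires n >= 3 per group")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def storey_fdr(p_values: Sequence[float], lambda_: float = 0.5) -> np.ndarray:
    """Storey positive-FDR q-values for a family of p-values.

    pi0 is estimated as #{p > lambda} / (m * (1 - lambda)), capped at 1;
    q-values are the step-up-monotonized pi0 * m * p_(i) / i, capped at 1.
    q is monotone non-decreasing in p within the family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d family")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 <= lambda_ < 1.0:
        raise ValueError("lambda_ must lie in [0, 1)")
    m = len(p)
    pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
    pi0 = float(min(pi0, 1.0))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    # step-up: running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def permutation_coherence_test(
    spectra_a: np.ndarray,
    spectra_b: np.ndarray,
    freq: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    mode: Literal["pointwise", "maxstat"] = "pointwise",
) -> PermutationResult:
    """Frequency-wise permutation test of group difference in coherence.

    ``spectra_a``/``spectra_b`` are (participants x frequencies) matrices
    of per-participant coherence values.  At each frequency the observed
    statistic is the two-sided rank-sum deviation between groups; its null
    is built by reassigning group labels to participants ``n_perm`` times
    with the true group sizes preserved — one label assignment is shared
    across all frequencies, as labels belong to participants.  p-values
    use the add-one rule, (1 + #{perm >= obs}) / (n_perm + 1), and are
    never 0.  When fewer than ``n_perm`` distinct assignments exist they
    are enumerated exactly (flagged via ``exact``), with
    p = #{perm >= obs} / n_total, the identity assignment included.

    ``mode='maxstat'`` additionally compares each observed deviation
    against the permutation distribution of the cross-frequency maximum
    (family-wise control across frequencies).
    """
    a = np.atleast_2d(np.asarray(spectra_a, dtype=float))
    b = np.atleast_2d(np.asarray(spectra_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share one frequency grid")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 3 or n_b < 3:
        raise ValueError("permutation test requires group sizes >= 3")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = n_a + n_b
    nf = a.shape[1]
    pooled = np.vstack([a, b])
    ranks = sstats.rankdata(pooled, axis=0)  # midranks per frequency
    mu = n_a * (n + 1) / 2.0

    obs_t = ranks[:n_a].sum(axis=0)
    obs_dev = np.abs(obs_t - mu)

    total = comb(n, n_a)
    exact = total <= n_perm
    if exact:
        sel = np.zeros((total, n), dtype=float)
        for i, combo in enumerate(combinations(range(n), n_a)):
            sel[i, list(combo)] = 1.0
        perm_t = sel @ ranks
        n_eff = total
    else:
        rng = np.random.default_rng(seed)
        sel = np.zeros((n_perm, n), dtype=float)
        for i in range(n_perm):
            sel[i, rng.permutation(n)[:n_a]] = 1.0
        perm_t = sel @ ranks
        n_eff = n_perm
    perm_dev = np.abs(perm_t - mu)

    tol = 1e-9
    if mode == "pointwise":
        ge = perm_dev >= obs_dev[None, :] - tol
        exceed = ge.sum(axis=0)
    elif mode == "maxstat":
        perm_max = perm_dev.max(axis=1)
        exceed = (perm_max[:, None] >= obs_dev[None, :] - tol).sum(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if exact:
        p = exceed / n_eff  # identity assignment counted, so p > 0
    else:
        p = (1.0 + exceed) / (n_eff + 1.0)

    return PermutationResult(
        freq=np.arange(nf, dtype=float) if freq is None else np.asarray(freq, float),
        statistic=obs_t,
        p_perm=p,
        n_permutations=n_eff,
        seed=seed,
        alpha=alpha,
        exact=exact,
    )
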