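"""Two-tailed permutation test for stratum enrichment of cases.

Disease labels are shuffled uniformly across the whole cohort; after each
shuffle the case proportion of every mitonuclear stratum is recomputed and
its absolute deviation from the overall case proportion recorded.  A
stratum's p-value is the fraction of shuffles whose deviation is at least
the observed one (ties count as exceedances).  Because label shuffling
holds both the stratum sizes and the total case count fixed, each
stratum's null is exactly hypergeometric, which provides a closed-form
oracle (:func:`exact_stratum_p`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import IndividualRecord, StratumCountTable, stratify

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "permutation_test",
    "exact_stratum_p",
]

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12  # guards >= comparisons of deviations against float noise


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the label-shuffling test.

    ``estimator``: ``"raw"`` reports b/B (the fraction of exceedances);
    ``"add-one"`` reports (b+1)/(B+1), which avoids zero p-values.
    ``shared_stream=False`` gives every stratum its own independent
    shuffle stream instead of scoring all strata on each shared shuffle.
    """

    n_permutations: int = 10_000
    seed: int | None = None
    estimator: str = "raw"
    shared_stream: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.estimator not in ("raw", "add-one"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass(frozen=True)
class PermutationResult:
    """Per-stratum permutation outcomes plus the configuration used."""

    table: pd.DataFrame  # stratum, n_cases, n_total, proportion, deviation,
    #                      exceedances, p_perm, p_exact
    overall_proportion: float
    config: PermutationConfig

    def p_value(self, stratum: str) -> float:
        return float(self.table.set_index("stratum").loc[stratum, "p_perm"])


def exact_stratum_p(
    n_total_cohort: int, n_cases_cohort: int, n_stratum: int, k_observed: int
) -> float:
    """Exact two-tailed p-value of the shuffle null for one stratum.

    Under uniform label shuffling the stratum case count K follows
    Hypergeometric(N, K_cases, n); the p-value sums the PMF over every k
    whose absolute deviation |k/n - pbar| is at least the observed one.
    """
    N, K, n, k = n_total_cohort, n_cases_cohort, n_stratum, k_observed
    if not (0 <= K <= N and 0 < n <= N and 0 <= k <= n):
        raise ValueError(f"impossible counts (N={N}, K={K}, n={n}, k={k})")
    pbar = K / N
    ks = np.arange(max(0, n - (N - K)), min(n, K) + 1)
    dev = np.abs(ks / n - pbar)
    d_obs = abs(k / n - pbar)
    pmf = stats.hypergeom.pmf(ks, N, K, n)
    return float(pmf[dev >= d_obs - _TIE_EPS].sum())


def _estimate(b: np.ndarray, B: int, estimator: str) -> np.ndarray:
    if estimator == "add-one":
        return (b + 1.0) / (B + 1.0)
    return b / float(B)


def permutation_test(
    records: list[IndividualRecord], config: PermutationConfig | None = None
) -> PermutationResult:
    """Run the label-shuffling enrichment test on a stratified cohort.

    Every stratifiable record contributes its status to the shuffled label
    pool; all strata are scored on each shared shuffle (one permutation
    stream) unless ``config.shared_stream`` is False.  Results are
    reproducible given ``config.seed``.
    """
    config = config or PermutationConfig()
    table = stratify(records)
    labels = table.labels
    if len(labels) < 2:
        # degenerate but well-defined: the single stratum is the whole
        # cohort, its deviation is 0 and every shuffle ties (p = 1)
        logger.warning("permutation test on a single stratum: p is trivially 1")

    index = {s: i for i, s in enumerate(labels)}
    usable = [r for r in records if r.stratum is not None]
    strat_idx = np.array([index[r.stratum] for r in usable], dtype=np.intp)
    status = np.array([r.status for r in usable], dtype=np.int8)
    # canonical order makes the Monte-Carlo stream, and hence the p-values,
    # invariant to the order records arrive in
    canon = np.lexsort((status, strat_idx))
    strat_idx, status = strat_idx[canon], status[canon]

    sizes = np.array([table.strata[s][1] for s in labels], dtype=float)
    obs_cases = np.array([table.strata[s][0] for s in labels], dtype=float)
    pbar = table.case_proportion
    obs_dev = np.abs(obs_cases / sizes - pbar)

    B = config.n_permutations
    rng = np.random.default_rng(config.seed)
    S = len(labels)
    exceed = np.zeros(S, dtype=np.int64)

    if config.shared_stream:
        for _ in range(B):
            perm = rng.permutation(status)
            counts = np.bincount(strat_idx[perm == 1], minlength=S)
            dev = np.abs(counts / sizes - pbar)
            exceed += dev >= obs_dev - _TIE_EPS
    else:
        for j in range(S):
            sub = rng.spawn(1)[0]
            for _ in range(B):
                perm = sub.permutation(status)
                k = int((perm[strat_idx == j] == 1).sum())
                if abs(k / sizes[j] - pbar) >= obs_dev[j] - _TIE_EPS:
                    exceed[j] += 1

    p_perm = _estimate(exceed.astype(float), B, config.estimator)
    p_exact = [
        exact_stratum_p(table.n_total, table.n_cases, int(sizes[j]), int(obs_cases[j]))
        for j in range(S)
    ]

    out = pd.DataFrame(
        {
            "stratum": labels,
            "n_cases": obs_cases.astype(int),
            "n_total": sizes.astype(int),
            "proportion": obs_cases / sizes,
            "deviation": obs_dev,
            "exceedances": exceed,
            "p_perm": p_perm,
            "p_exact": p_exact,
        }
    )
    return PermutationResult(table=out, overall_proportion=pbar, config=config)
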