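"""Synthetic case-control cohorts with known mitonuclear structure.

Generates individual-level cohorts from a declared generative model:
stratum population frequencies, a baseline disease odds, per-stratum
odds ratios relative to a reference stratum, and optional sex/age
effects.  Two sampling modes are supported:

* **population** — draw N individuals from the population; each one's
  status is Bernoulli with logit = log(baseline odds) + log OR(stratum)
  + covariate terms (covariates centred at their generating means, so the
  baseline odds is the disease odds of a reference-stratum individual
  with average covariates).
* **case-control** (default; the study design) — fix the numbers of
  cases and controls and draw each subject's stratum from the
  status-conditional distribution implied by Bayes' rule,
  P(g | status) ∝ freq_g · P(status | g), with covariates then drawn
  per status group.

``expand_counts`` is the deterministic fixture builder: it turns a
stratum count table into an individual-level cohort with exactly those
counts, ordered by stratum then status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import IndividualRecord, StratumCountTable

__all__ = ["SimulationSpec", "simulate_cohort", "expand_counts"]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class SimulationSpec:
    """Generative model of a mitonuclear case-control cohort.

    ``stratum_freqs`` must sum to 1; ``odds_ratios`` gives each stratum's
    disease odds ratio (missing strata default to 1, the reference).
    Exactly one of ``n`` (population mode) or ``n_cases``/``n_controls``
    (case-control mode) must be set.  Ages are normal per status group
    (defaults: cases mean 65.8 y, controls mean 69.7 y, sd 8 — the
    profile of the study cohort); sex is Bernoulli(0.5).
    """

    stratum_freqs: dict[str, float]
    baseline_odds: float = 1.0
    odds_ratios: dict[str, float] = field(default_factory=dict)
    sex_log_or: float = 0.0
    age_log_or: float = 0.0
    age_mean_cases: float = 65.8
    age_mean_controls: float = 69.7
    age_sd: float = 8.0
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.stratum_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"stratum frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.stratum_freqs.values()):
            raise ValueError("stratum frequencies must be non-negative")
        if self.baseline_odds <= 0:
            raise ValueError("baseline odds must be positive")
        if any(v <= 0 for v in self.odds_ratios.values()):
            raise ValueError("odds ratios must be positive")
        unknown = set(self.odds_ratios) - set(self.stratum_freqs)
        if unknown:
            raise ValueError(f"odds ratios for unknown strata: {sorted(unknown)}")
        pop = self.n is not None
        cc = self.n_cases is not None and self.n_controls is not None
        if pop == cc:
            raise ValueError("set exactly one of n (population) or n_cases/n_controls")
        if pop and self.n <= 0:
            raise ValueError("n must be positive")
        if cc and (self.n_cases <= 0 or self.n_controls <= 0):
            raise ValueError("n_cases and n_controls must be positive")

    @property
    def labels(self) -> list[str]:
        return list(self.stratum_freqs)

    def stratum_logit(self, label: str) -> float:
        return float(np.log(self.baseline_odds) + np.log(self.odds_ratios.get(label, 1.0)))


def _split_stratum(label: str) -> tuple[str | None, str | None]:
    if "_" in label:
        cluster, genotype = label.rsplit("_", 1)
        return cluster, genotype
    return label, None


def simulate_cohort(spec: SimulationSpec) -> list[IndividualRecord]:
    """Draw a cohort from the generative model; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels
    freqs = np.array([spec.stratum_freqs[s] for s in labels])
    logits = np.array([spec.stratum_logit(s) for s in labels])
    p_case = 1.0 / (1.0 + np.exp(-logits))

    if spec.n is not None:
        n = spec.n
        strat_idx = rng.choice(len(labels), size=n, p=freqs)
        sex = rng.integers(0, 2, size=n)  # 1 = M
        age = rng.normal(spec.age_mean_controls, spec.age_sd, size=n)
        eta = (
            logits[strat_idx]
            + spec.sex_log_or * (sex - 0.5)
            + spec.age_log_or * (age - spec.age_mean_controls)
        )
        status = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        statuses = status.astype(int)
    else:
        w_case = freqs * p_case
        w_ctrl = freqs * (1.0 - p_case)
        if w_case.sum() <= 0 or w_ctrl.sum() <= 0:
            raise ValueError("infeasible case-control targets: a status group has zero probability")
        statuses = np.concatenate(
            [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
        )
        n = statuses.size
        strat_idx = np.empty(n, dtype=np.intp)
        strat_idx[: spec.n_cases] = rng.choice(
            len(labels), size=spec.n_cases, p=w_case / w_case.sum()
        )
        strat_idx[spec.n_cases:] = rng.choice(
            len(labels), size=spec.n_controls, p=w_ctrl / w_ctrl.sum()
        )
        sex = rng.integers(0, 2, size=n)
        age = np.where(
            statuses == 1,
            rng.normal(spec.age_mean_cases, spec.age_sd, size=n),
            rng.normal(spec.age_mean_controls, spec.age_sd, size=n),
        )

    records = []
    for i in range(n):
        cluster, genotype = _split_stratum(labels[strat_idx[i]])
        records.append(
            IndividualRecord(
                sample_id=f"S{i:06d}",
                status=int(statuses[i]),
                sex="M" if sex[i] == 1 else "F",
                age=float(np.clip(age[i], 0.0, None)),
                cluster=cluster,
                genotype=genotype,
            )
        )
    return records


def expand_counts(count_table: StratumCountTable) -> list[IndividualRecord]:
    """Deterministically expand a stratum count table into individuals.

    Produces exactly the given per-stratum case/control counts (controls
    first within each stratum), no covariates; the inverse of
    :func:`mitonuclear.cohort.stratify` up to ordering.
    """
    records: list[IndividualRecord] = []
    for label in count_table.labels:
        k, n_tot = count_table.strata[label]
        cluster, genotype = _split_stratum(label)
        for j in range(n_tot):
            status = 0 if j < n_tot - k else 1
            records.append(
                IndividualRecord(
                    sample_id=f"{label}_{j + 1:04d}",
                    status=status,
                    cluster=cluster,
                    genotype=genotype,
                )
            )
    return records
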