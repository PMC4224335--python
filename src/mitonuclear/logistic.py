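"""Dummy-coded logistic regression with Wald odds-ratio contrasts.

The 12-level mitonuclear genotype enters the model as k-1 indicator
variables against a reference stratum (HV_CC in the headline analysis),
optionally alongside sex and age covariates.  Fitting is maximum
likelihood by iteratively reweighted least squares (IRLS); standard
errors come from the inverse Fisher information at the MLE, and each
odds ratio exp(beta) is reported with a 95% Wald interval
exp(beta +/- 1.959964 * SE).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import IndividualRecord

__all__ = ["DesignSpec", "LogisticFit", "encode_design", "fit_logistic", "fit_stratum_model"]

logger = logging.getLogger(__name__)

_Z_95 = 1.959964  # two-sided 95% normal quantile
_SEPARATION_BETA = 15.0  # |beta| beyond this while deviance falls flags separation


@dataclass(frozen=True)
class DesignSpec:
    """Design of the stratum-contrast model.

    ``covariates`` may include ``"sex"`` (indicator, M=1) and ``"age"``
    (years, uncentred).  ``stratum_order`` fixes the report order of the
    indicator columns; by default strata are sorted, reference first.
    """

    reference_stratum: str = "HV_CC"
    covariates: tuple[str, ...] = ()
    stratum_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        bad = set(self.covariates) - {"sex", "age"}
        if bad:
            raise ValueError(f"unsupported covariates: {sorted(bad)}")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood fit with Wald inference per term."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    loglike: float
    n_iter: int
    converged: bool
    n_obs: int

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int_or(self) -> pd.DataFrame:
        lo = np.exp(self.params - _Z_95 * self.bse)
        hi = np.exp(self.params + _Z_95 * self.bse)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def summary_frame(self) -> pd.DataFrame:
        """Odds-ratio table (term, coefficient, SE, OR, CI bounds, p)."""
        ci = self.conf_int_or()
        return pd.DataFrame(
            {
                "term": self.params.index,
                "coefficient": self.params.values,
                "se": self.bse.values,
                "odds_ratio": self.odds_ratios.values,
                "ci_low": ci["ci_low"].values,
                "ci_high": ci["ci_high"].values,
                "p": self.pvalues.values,
            }
        ).reset_index(drop=True)


def encode_design(
    records: list[IndividualRecord], spec: DesignSpec | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the dummy-coded design matrix and binary response.

    Columns: intercept, one indicator per non-reference stratum (named by
    the stratum label), then requested covariates.  Records with a
    missing stratum — or a missing requested covariate — are dropped
    listwise with a logged count.
    """
    spec = spec or DesignSpec()
    usable: list[IndividualRecord] = []
    n_dropped = 0
    for r in records:
        if r.stratum is None:
            n_dropped += 1
            continue
        if "sex" in spec.covariates and r.sex is None:
            n_dropped += 1
            continue
        if "age" in spec.covariates and r.age is None:
            n_dropped += 1
            continue
        usable.append(r)
    if n_dropped:
        logger.info("encode_design: dropped %d records with missing fields", n_dropped)
    if not usable:
        raise ValueError("no usable records")

    strata = sorted({r.stratum for r in usable})
    if spec.reference_stratum not in strata:
        raise ValueError(f"reference stratum {spec.reference_stratum!r} absent from data")
    if spec.stratum_order is not None:
        order = [s for s in spec.stratum_order if s != spec.reference_stratum]
        if set(order) != set(strata) - {spec.reference_stratum}:
            raise ValueError("stratum_order does not match observed strata")
        others = order
    else:
        others = [s for s in strata if s != spec.reference_stratum]

    n = len(usable)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    labels = np.array([r.stratum for r in usable])
    for s in others:
        cols[s] = (labels == s).astype(float)
    if "sex" in spec.covariates:
        cols["sex_M"] = np.array([1.0 if r.sex == "M" else 0.0 for r in usable])
    if "age" in spec.covariates:
        cols["age"] = np.array([float(r.age) for r in usable])

    X = pd.DataFrame(cols)
    y = np.array([r.status for r in usable], dtype=float)
    return X, y


def fit_logistic(
    design: pd.DataFrame,
    response: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a binary logistic regression by IRLS.

    Iterates weighted least squares on the working response until the
    deviance changes by less than ``tol`` or ``max_iter`` is reached.
    Raises on rank-deficient designs (naming the collinear columns);
    quasi-separation (any |beta| > 15 while the deviance is still
    falling) produces a warning and a fit flagged non-converged.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    names = list(design.columns) if hasattr(design, "columns") else [
        f"x{i}" for i in range(X.shape[1])
    ]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # smallest R diagonals of the QR factorisation name the collinear columns
        _, Rm = np.linalg.qr(X)
        diag = np.abs(np.diag(Rm))
        bad = [names[i] for i in np.argsort(diag)[: X.shape[1] - rank]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta = np.zeros(X.shape[1])
    deviance = np.inf
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)

        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        new_dev = -2.0 * float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        delta = deviance - new_dev
        deviance = new_dev
        if np.max(np.abs(beta)) > _SEPARATION_BETA and delta > tol:
            separated = True
            break
        if abs(delta) < tol:
            converged = True
            break

    if separated:
        warnings.warn(
            "possible (quasi-)separation: coefficient magnitude exceeds "
            f"{_SEPARATION_BETA}; estimates unreliable",
            RuntimeWarning,
            stacklevel=2,
        )

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    bse = np.sqrt(np.diag(cov))
    loglike = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))

    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglike=loglike,
        n_iter=it,
        converged=converged,
        n_obs=len(y),
    )


def fit_stratum_model(
    records: list[IndividualRecord], spec: DesignSpec | None = None, **fit_kwargs
) -> LogisticFit:
    """Convenience: encode the stratum-contrast design and fit it."""
    X, y = encode_design(records, spec)
    return fit_logistic(X, y, **fit_kwargs)
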