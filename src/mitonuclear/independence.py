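"""Likelihood-ratio (G) test of independence for R x C contingency tables.

G = 2 * sum over non-zero cells of O * ln(O / E), with expected counts
E = (row total * column total) / grand total, referred to a chi-square
distribution on (r - 1)(c - 1) degrees of freedom.  The uncorrected
statistic is the default; the Williams small-sample correction is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GTestResult", "g_test"]


@dataclass(frozen=True)
class GTestResult:
    """G statistic, degrees of freedom and upper-tail chi-square p-value."""

    G: float
    df: int
    p: float
    williams_corrected: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.G, self.df, self.p]], columns=["G", "df", "p"]
        )


def g_test(observed, williams: bool = False) -> GTestResult:
    """G-test of independence on an R x C table of counts.

    Parameters
    ----------
    observed
        2-D array-like (or DataFrame) of non-negative counts with at
        least two rows and two columns; no row or column may be all zero.
    williams
        Apply the Williams q correction (divides G by
        ``1 + (a-1)(b-1)/(6 n df)`` with a, b the reciprocal-margin
        sums).  Off by default.

    Zero observed cells contribute 0 to the sum (the x*ln x limit).
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("observed must be a table with >=2 rows and >=2 columns")
    if (O < 0).any():
        raise ValueError("observed counts must be non-negative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("all-zero row or column: degrees of freedom undefined")

    n = O.sum()
    E = np.outer(row, col) / n
    mask = O > 0
    G = 2.0 * float((O[mask] * np.log(O[mask] / E[mask])).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)

    if williams:
        q = 1.0 + ((n / row).sum() - 1.0) * ((n / col).sum() - 1.0) / (6.0 * n * df)
        G /= q

    p = float(stats.chi2.sf(G, df))
    return GTestResult(G=G, df=df, p=p, williams_corrected=williams)
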