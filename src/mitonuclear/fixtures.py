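"""Machine-readable copies of the published summary tables.

The study's only published inputs are its printed count and result
tables; this module ships them as TSV resources and validates their
internal arithmetic at load time (stratum counts sum to the cohort
margins; per-cluster stratum sums reproduce the haplogroup table).
``fixture_cohort`` expands the stratum counts into the 1,477-record
individual-level cohort used by the permutation and logistic stages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import IndividualRecord, StratumCountTable
from .simulate import expand_counts

__all__ = ["load_fixture", "fixture_count_table", "fixture_cohort"]

_NAMES = ("table1", "table2", "table3", "pi0")

_EXPECTED_CASES = 1118
_EXPECTED_TOTAL = 1477


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("mitonuclear.data").joinpath(f"{name}.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _validate(table1: pd.DataFrame, table2: pd.DataFrame) -> None:
    cases = int(table2["n_cases"].sum())
    total = int(table2["n_total"].sum())
    if cases != _EXPECTED_CASES or total != _EXPECTED_TOTAL:
        raise ValueError(
            f"stratum table margins {cases}/{total} != expected "
            f"{_EXPECTED_CASES}/{_EXPECTED_TOTAL}"
        )
    clusters = table2["stratum"].str.rsplit("_", n=1).str[0]
    by_cluster_cases = table2.groupby(clusters)["n_cases"].sum()
    by_cluster_ctrl = (
        table2.groupby(clusters)
        .apply(lambda d: (d["n_total"] - d["n_cases"]).sum(), include_groups=False)
    )
    t1 = table1.set_index("cluster")
    for c in t1.index:
        if int(by_cluster_cases[c]) != int(t1.loc[c, "n_cases"]):
            raise ValueError(f"cluster {c}: stratum case sum != haplogroup table")
        if int(by_cluster_ctrl[c]) != int(t1.loc[c, "n_controls"]):
            raise ValueError(f"cluster {c}: stratum control sum != haplogroup table")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one fixture (``table1``, ``table2``, ``table3`` or ``pi0``).

    Cross-table consistency of the counts is checked on every load;
    an inconsistent resource raises ``ValueError``.
    """
    if name not in _NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {_NAMES}")
    df = _read(name)
    if name in ("table1", "table2"):
        _validate(_read("table1"), _read("table2"))
    return df


def fixture_count_table() -> StratumCountTable:
    """The stratum count table as a :class:`StratumCountTable`."""
    df = load_fixture("table2")
    return StratumCountTable(
        {str(r.stratum): (int(r.n_cases), int(r.n_total)) for r in df.itertuples()}
    )


def fixture_cohort() -> list[IndividualRecord]:
    """The deterministic 1,477-record individual-level fixture cohort."""
    return expand_counts(fixture_count_table())
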