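"""Cohort data model, TSV I/O and mitonuclear stratification.

An individual carries a binary disease status (0 healthy, 1 affected),
optional sex/age covariates, an mtDNA haplogroup cluster and a diploid
nuclear genotype.  The joint (cluster, genotype) category — the
"mitonuclear genotype", e.g. ``HV_CC`` — is the unit of the association
analysis; with 4 clusters and 3 genotypes the cohort splits into 12
strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genotyping import cluster_haplogroup

__all__ = [
    "IndividualRecord",
    "StratumCountTable",
    "GenotypeMargins",
    "read_cohort",
    "write_cohort",
    "stratify",
    "genotype_margins",
    "read_count_table",
    "write_count_table",
]

logger = logging.getLogger(__name__)

_COHORT_COLUMNS = ["sample_id", "status", "sex", "age", "cluster", "genotype"]


@dataclass(frozen=True)
class IndividualRecord:
    """One subject of the case-control cohort.

    ``status`` is 0 (healthy) or 1 (diseased).  ``cluster`` and
    ``genotype`` may be ``None`` (missing); such records are retained by
    I/O but excluded from stratification.  Genotypes are normalised to
    lexicographically sorted allele pairs (``CG``, never ``GC``).
    """

    sample_id: str
    status: int
    sex: str | None = None
    age: float | None = None
    cluster: str | None = None
    genotype: str | None = None

    def __post_init__(self) -> None:
        if self.status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {self.status!r}")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M', 'F' or missing, got {self.sex!r}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.genotype is not None:
            g = "".join(sorted(self.genotype.upper()))
            if len(g) != 2:
                raise ValueError(f"genotype must be two alleles, got {self.genotype!r}")
            object.__setattr__(self, "genotype", g)

    @property
    def stratum(self) -> str | None:
        """Mitonuclear stratum label ``<CLUSTER>_<GENOTYPE>``, or None."""
        if self.cluster is None or self.genotype is None:
            return None
        return f"{self.cluster}_{self.genotype}"


@dataclass(frozen=True)
class StratumCountTable:
    """Per-stratum case/total counts with overall margins."""

    strata: dict[str, tuple[int, int]]  # label -> (n_cases, n_total)

    def __post_init__(self) -> None:
        for label, (k, n) in self.strata.items():
            if not 0 <= k <= n:
                raise ValueError(f"stratum {label}: invalid counts ({k}, {n})")
        if self.n_total == 0:
            raise ValueError("count table is empty")

    @property
    def labels(self) -> list[str]:
        return list(self.strata)

    @property
    def n_cases(self) -> int:
        return sum(k for k, _ in self.strata.values())

    @property
    def n_total(self) -> int:
        return sum(n for _, n in self.strata.values())

    @property
    def case_proportion(self) -> float:
        return self.n_cases / self.n_total

    def proportion(self, label: str) -> float:
        k, n = self.strata[label]
        return k / n

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (label, k, n, k / n) for label, (k, n) in self.strata.items()
        ]
        return pd.DataFrame(
            rows, columns=["stratum", "n_cases", "n_total", "proportion"]
        )


def _parse_missing(value: str) -> str | None:
    v = value.strip()
    return None if v in ("", "NA", "NaN", "nan") else v


def read_cohort(path: str | Path) -> list[IndividualRecord]:
    """Read a cohort TSV into validated records.

    Required columns: sample_id, status, sex, age, genotype and either
    ``cluster`` or ``haplogroup`` (fine haplogroup labels are collapsed to
    clusters on the fly).  ``NA`` marks missing values.  Rows with missing
    cluster or genotype are retained but will be skipped by
    :func:`stratify`.  Malformed rows raise ``ValueError`` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("NA")
    cols = set(df.columns)
    required = {"sample_id", "status", "sex", "age", "genotype"}
    missing = required - cols
    if missing or not ({"cluster", "haplogroup"} & cols):
        raise ValueError(
            f"{path}: malformed header; missing columns "
            f"{sorted(missing) or ['cluster or haplogroup']}"
        )

    records: list[IndividualRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        status_raw = _parse_missing(d["status"])
        if status_raw not in ("0", "1"):
            raise ValueError(f"{path} row {i}: status must be 0 or 1, got {status_raw!r}")
        if "cluster" in cols:
            cluster = _parse_missing(d["cluster"])
        else:
            hap = _parse_missing(d["haplogroup"])
            cluster = cluster_haplogroup(hap) if hap is not None else None
        age_raw = _parse_missing(d["age"])
        try:
            record = IndividualRecord(
                sample_id=str(d["sample_id"]),
                status=int(status_raw),
                sex=_parse_missing(d["sex"]),
                age=float(age_raw) if age_raw is not None else None,
                cluster=cluster,
                genotype=_parse_missing(d["genotype"]),
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
        records.append(record)
    return records


def write_cohort(records: list[IndividualRecord], path: str | Path) -> None:
    """Write records to a cohort TSV (``NA`` for missing values)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "status": r.status,
                "sex": r.sex if r.sex is not None else "NA",
                "age": r.age if r.age is not None else "NA",
                "cluster": r.cluster if r.cluster is not None else "NA",
                "genotype": r.genotype if r.genotype is not None else "NA",
            }
        )
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def stratify(records: list[IndividualRecord]) -> StratumCountTable:
    """Tabulate case/total counts per mitonuclear stratum.

    Records lacking a cluster or genotype are excluded (a count is
    logged).  Strata are keyed ``<CLUSTER>_<GENOTYPE>`` and sorted by
    label; only observed strata appear.
    """
    counts: dict[str, list[int]] = {}
    n_skipped = 0
    for r in records:
        s = r.stratum
        if s is None:
            n_skipped += 1
            continue
        k = counts.setdefault(s, [0, 0])
        k[0] += r.status
        k[1] += 1
    if n_skipped:
        logger.info("stratify: excluded %d records with missing cluster/genotype", n_skipped)
    if not counts:
        raise ValueError("no stratifiable records (all missing cluster or genotype)")
    return StratumCountTable({s: tuple(counts[s]) for s in sorted(counts)})


@dataclass(frozen=True)
class GenotypeMargins:
    """Genotype-by-status counts and per-group allele frequencies."""

    counts: pd.DataFrame  # index genotype, columns ["cases", "controls"]
    allele_frequencies: pd.DataFrame  # index allele, columns ["cases", "controls"]


def genotype_margins(table: StratumCountTable) -> GenotypeMargins:
    """Collapse strata over clusters to genotype margins and allele frequencies.

    Allele frequency in a status group = (2·hom + het) / (2·group size),
    computed from the biallelic genotype labels.
    """
    geno: dict[str, list[int]] = {}
    for label, (k, n) in table.strata.items():
        g = label.rsplit("_", 1)[1]
        row = geno.setdefault(g, [0, 0])
        row[0] += k
        row[1] += n - k
    counts = pd.DataFrame.from_dict(
        geno, orient="index", columns=["cases", "controls"]
    ).sort_index()

    alleles: dict[str, dict[str, float]] = {}
    group_sizes = counts.sum(axis=0)
    for g, row in counts.iterrows():
        for allele in g:
            a = alleles.setdefault(allele, {"cases": 0.0, "controls": 0.0})
            a["cases"] += row["cases"]
            a["controls"] += row["controls"]
    freq = pd.DataFrame.from_dict(alleles, orient="index").sort_index()
    freq = freq / (2.0 * group_sizes)
    return GenotypeMargins(counts=counts, allele_frequencies=freq)


def read_count_table(path: str | Path) -> StratumCountTable:
    """Read a stratum count TSV (columns: stratum, n_cases, n_total, ...)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"stratum", "n_cases", "n_total"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: count table needs columns {sorted(required)}")
    return StratumCountTable(
        {str(r.stratum): (int(r.n_cases), int(r.n_total)) for r in df.itertuples()}
    )


def write_count_table(table: StratumCountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
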