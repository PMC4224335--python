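"""Full-analysis orchestration: G-tests, permutation, q-values, logistic ORs.

``run_pipeline`` executes the three-step association analysis on a cohort
file and writes the report tables: (1) haplogroup-by-status and
genotype-by-status G-tests; (2) the per-stratum permutation table with
exact hypergeometric oracles and Storey q-values; (3) the dummy-coded
logistic odds-ratio table against the reference stratum.  All randomness
flows from the configured seed, so re-running a configuration
byte-reproduces every output; the renderer only formats stage outputs and
recomputes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import IndividualRecord, genotype_margins, read_cohort, stratify
from .independence import GTestResult, g_test
from .logistic import DesignSpec, LogisticFit, fit_stratum_model
from .permutation import PermutationConfig, PermutationResult, permutation_test
from .qvalue import pi0_bootstrap, pi0_smoother, qvalues

__all__ = ["AnalysisConfig", "ReportBundle", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run.

    ``pi0_mode`` is ``"smoother"``, ``"bootstrap"`` or ``"fixed:<value>"``
    (e.g. ``"fixed:0.227"`` to use a published estimate).
    """

    input_path: str | Path
    output_dir: str | Path = "mitonuclear_out"
    reference_stratum: str = "HV_CC"
    n_permutations: int = 10_000
    seed: int = 0
    pi0_mode: str = "smoother"
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.pi0_mode not in ("smoother", "bootstrap") and not self.pi0_mode.startswith(
            "fixed:"
        ):
            raise ValueError(f"invalid pi0 mode {self.pi0_mode!r}")

    def resolve_pi0(self, pvals: np.ndarray) -> float:
        if self.pi0_mode == "smoother":
            return pi0_smoother(pvals)
        if self.pi0_mode == "bootstrap":
            return pi0_bootstrap(pvals, seed=self.seed)
        return float(self.pi0_mode.split(":", 1)[1])


@dataclass(frozen=True)
class ReportBundle:
    """All stage outputs of one run."""

    haplogroup_gtest: GTestResult | None
    genotype_gtest: GTestResult | None
    permutation: PermutationResult
    stratum_table: pd.DataFrame  # permutation table + q column
    pi0: float
    logistic: LogisticFit
    logistic_table: pd.DataFrame


def _cluster_by_status(records: list[IndividualRecord]) -> pd.DataFrame:
    table = stratify(records)
    rows: dict[str, list[int]] = {}
    for label, (k, n) in table.strata.items():
        cluster = label.rsplit("_", 1)[0]
        row = rows.setdefault(cluster, [0, 0])
        row[0] += k
        row[1] += n - k
    return pd.DataFrame.from_dict(rows, orient="index", columns=["cases", "controls"])


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Run the full association analysis and write report TSVs."""
    records = read_cohort(config.input_path)
    n_strat = sum(r.stratum is not None for r in records)
    logger.info(
        "pipeline: %d records (%d stratifiable), seed=%d, B=%d",
        len(records), n_strat, config.seed, config.n_permutations,
    )

    counts = stratify(records)

    # step 1: marginal G-tests; degenerate (single-level) margins are skipped
    cluster_tab = _cluster_by_status(records)
    hap_g = g_test(cluster_tab) if len(cluster_tab) >= 2 else None
    if hap_g is None:
        logger.warning("haplogroup G-test skipped: fewer than 2 clusters")
    geno_tab = genotype_margins(counts).counts
    gen_g = g_test(geno_tab) if len(geno_tab) >= 2 else None
    if gen_g is None:
        logger.warning("genotype G-test skipped: fewer than 2 genotypes")

    # step 2: permutation enrichment with q-values across the stratum p-values
    perm = permutation_test(
        records,
        PermutationConfig(n_permutations=config.n_permutations, seed=config.seed),
    )
    pvals = perm.table["p_perm"].to_numpy()
    pi0 = config.resolve_pi0(pvals)
    stratum_table = perm.table.assign(q=qvalues(pvals, pi0))

    # step 3: logistic odds ratios against the reference stratum
    fit = fit_stratum_model(
        records,
        DesignSpec(reference_stratum=config.reference_stratum, covariates=config.covariates),
    )
    logistic_table = fit.summary_frame()

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if hap_g is not None:
        hap_g.to_frame().to_csv(outdir / "gtest_haplogroup.tsv", sep="\t", index=False)
    if gen_g is not None:
        gen_g.to_frame().to_csv(outdir / "gtest_genotype.tsv", sep="\t", index=False)
    stratum_table.to_csv(outdir / "permutation.tsv", sep="\t", index=False)
    logistic_table.to_csv(outdir / "logistic.tsv", sep="\t", index=False)
    with open(outdir / "run_info.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"n_permutations\t{config.n_permutations}\n")
        fh.write(f"n_records\t{len(records)}\n")
        fh.write(f"n_stratified\t{n_strat}\n")
        fh.write(f"pi0\t{pi0}\n")
        fh.write(f"reference_stratum\t{config.reference_stratum}\n")

    return ReportBundle(
        haplogroup_gtest=hap_g,
        genotype_gtest=gen_g,
        permutation=perm,
        stratum_table=stratum_table,
        pi0=pi0,
        logistic=fit,
        logistic_table=logistic_table,
    )


def load_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Read a flat ``key = value`` config file; keyword overrides win."""
    values: dict[str, object] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path} line {i}: expected key = value")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key in ("n_permutations", "seed"):
            values[key] = int(raw)
        elif key == "covariates":
            values[key] = tuple(c.strip() for c in raw.split(",") if c.strip())
        else:
            values[key] = raw
    values.update(overrides)
    return AnalysisConfig(**values)
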