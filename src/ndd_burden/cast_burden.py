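"""Per-gene CAST burden scan.

For each eligible gene the qualifying variants are collapsed to a binary
per-sample carrier indicator (the CAST statistic), which is tested two
ways: a right-tailed Fisher exact test on the case/control carrier table,
and a Firth logistic regression of case status on the indicator adjusted
for sex, standardized age, and family history.  The regression's per-gene
p-value is the penalized likelihood-ratio test of the carrier term (the
null fit is shared across genes); the Wald machinery supplies the reported
odds ratio and confidence interval.  Under the complete separation the
penetrant-model filter produces (all carriers are cases), the Wald
statistic is deflated because the standard error inflates with the
estimate, so the likelihood-ratio version is the one with usable power.
Both p-value columns are Benjamini-Hochberg adjusted across eligible
genes; genes with an adjusted value at or below 0.5% are flagged
significant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exact_stats import ContingencyTable2x2, bh_adjust, fisher_exact
from .firth_glm import build_design, fit_firth, penalized_lrt, wald_inference
from .synthetic_cohort import GenotypeMatrix, SampleRecord, VariantSite
from .variant_qc import QCThresholds, apply_qc, eligible_genes, penetrant_model_filter

__all__ = [
    "GeneBurdenResult",
    "carrier_indicator",
    "gene_table",
    "run_burden",
    "run_pipeline",
    "write_results",
    "read_results",
    "results_to_frame",
]

FDR_LEVEL = 0.005  # the scan's FDR-adjusted significance threshold (0.5%)

RESULT_COLUMNS = [
    "gene",
    "n_case_carriers",
    "n_case_total",
    "n_control_carriers",
    "n_control_total",
    "fisher_p",
    "firth_beta",
    "firth_or",
    "ci_low",
    "ci_high",
    "firth_p",
    "q_fisher",
    "q_firth",
    "converged",
]


@dataclass
class GeneBurdenResult:
    """One gene's burden-test summary."""

    gene: str
    n_case_carriers: int
    n_case_total: int
    n_control_carriers: int
    n_control_total: int
    fisher_p: float
    firth_beta: float
    firth_or: float
    ci_low: float
    ci_high: float
    firth_p: float
    q_fisher: float = np.nan
    q_firth: float = np.nan
    converged: bool = True

    def significant(self, fdr: float = FDR_LEVEL, column: str = "q_firth") -> bool:
        return getattr(self, column) <= fdr


def carrier_indicator(
    gene: str, sites: Sequence[VariantSite], genotypes: GenotypeMatrix
) -> np.ndarray:
    """Binary CAST indicator: 1 iff a sample carries >= 1 qualifying allele
    at any of the gene's sites (presence/absence, not a dosage sum;
    missing calls count as non-carrier).
    """
    idx = [i for i, s in enumerate(sites) if s.gene == gene]
    if not idx:
        warnings.warn(f"gene {gene} has no surviving sites; all-zero indicator")
        return np.zeros(genotypes.n_samples, dtype=np.int8)
    return (genotypes.dosage[:, idx] >= 1).any(axis=1).astype(np.int8)


def gene_table(indicator: np.ndarray, samples: Sequence[SampleRecord]) -> ContingencyTable2x2:
    """Case/control carrier table for one gene's CAST indicator."""
    indicator = np.asarray(indicator)
    if indicator.shape[0] != len(samples):
        raise ValueError("indicator is not aligned with the sample list")
    is_case = np.array([s.status == "case" for s in samples])
    carrier = indicator >= 1
    return ContingencyTable2x2(
        a=int((carrier & is_case).sum()),
        b=int((~carrier & is_case).sum()),
        c=int((carrier & ~is_case).sum()),
        d=int((~carrier & ~is_case).sum()),
    )


def run_burden(
    sites: Sequence[VariantSite],
    genotypes: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    thresholds: QCThresholds = QCThresholds(),
    *,
    eligible: set[str] | None = None,
    fdr: float = FDR_LEVEL,
) -> list[GeneBurdenResult]:
    """Burden-test every eligible gene on already-filtered inputs.

    ``eligible`` normally comes from :func:`variant_qc.eligible_genes` on
    the post-QC (pre-penetrant-filter) site list; if omitted it is computed
    from the sites given.  Results carry per-column BH q-values and are
    sorted by (q_firth, gene).
    """
    if eligible is None:
        eligible = eligible_genes(sites, thresholds, genotypes)
    genes = sorted(eligible)
    if not genes:
        warnings.warn("no eligible genes; empty burden result")
        return []

    y = np.array([1.0 if s.status == "case" else 0.0 for s in samples])
    sex = np.array([1.0 if s.sex == "male" else 0.0 for s in samples])
    age = np.array([s.age_months for s in samples], dtype=float)
    fam = np.array([1.0 if s.family_history else 0.0 for s in samples])

    # covariate-only null fit, shared by every gene's likelihood-ratio test
    X_all, all_names = build_design(np.zeros(len(y)), sex, age, fam)
    null_cols = [j for j, n in enumerate(all_names) if n != "carrier"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_null = fit_firth(X_all[:, null_cols], y, [all_names[j] for j in null_cols])

    results: list[GeneBurdenResult] = []
    for gene in genes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ind = carrier_indicator(gene, sites, genotypes)
        table = gene_table(ind, samples)
        fisher_p = fisher_exact(table, tail="right")
        if ind.min() == ind.max():
            # degenerate indicator (no carriers, or everyone a carrier):
            # no effect estimable; both tests are null
            beta, or_, lo, hi, firth_p, conv = 0.0, 1.0, np.nan, np.nan, 1.0, True
        else:
            X, names = build_design(ind, sex, age, fam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_firth(X, y, names)
            conv = fit.converged
            if "carrier" not in fit.names:
                # carrier column collinear with a covariate; no separate effect
                beta, or_, lo, hi, firth_p = 0.0, 1.0, np.nan, np.nan, 1.0
            elif conv:
                row = wald_inference(fit).loc["carrier"]
                beta, or_, lo, hi = (
                    float(row["estimate"]),
                    float(row["OR"]),
                    float(row["ci_low"]),
                    float(row["ci_high"]),
                )
                firth_p = (
                    penalized_lrt(fit, fit_null)
                    if fit_null.converged and not fit.dropped
                    else float(row["p"])
                )
            else:
                j = fit.names.index("carrier")
                beta = float(fit.beta[j])
                or_, lo, hi, firth_p = float(np.exp(beta)), np.nan, np.nan, np.nan
        results.append(
            GeneBurdenResult(
                gene=gene,
                n_case_carriers=table.a,
                n_case_total=table.n_cases,
                n_control_carriers=table.c,
                n_control_total=table.n_controls,
                fisher_p=fisher_p,
                firth_beta=beta,
                firth_or=or_,
                ci_low=lo,
                ci_high=hi,
                firth_p=firth_p,
                converged=conv,
            )
        )
    q_fisher = bh_adjust([r.fisher_p for r in results])
    q_firth = bh_adjust([r.firth_p if np.isfinite(r.firth_p) else 1.0 for r in results])
    for r, qa, qb in zip(results, q_fisher, q_firth):
        r.q_fisher = float(qa)
        r.q_firth = float(qb)
    results.sort(key=lambda r: (r.q_firth, r.gene))
    return results


def run_pipeline(
    sites: Sequence[VariantSite],
    genotypes: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    thresholds: QCThresholds = QCThresholds(),
    *,
    fdr: float = FDR_LEVEL,
    apply_penetrant_filter: bool = True,
) -> tuple[list[GeneBurdenResult], pd.DataFrame]:
    """Full scan on raw inputs: QC -> eligibility -> penetrant filter ->
    per-gene tests.  Gene eligibility (>=5 LoF sites) is assessed on the
    post-QC site list, before the penetrant filter.  Returns (results,
    penetrant-filter removal log).
    """
    qsites, qgeno = apply_qc(sites, genotypes, thresholds)
    eligible = eligible_genes(qsites, thresholds, qgeno)
    if apply_penetrant_filter:
        fsites, fgeno, log = penetrant_model_filter(qsites, qgeno, samples)
    else:
        fsites, fgeno = qsites, qgeno
        log = pd.DataFrame(columns=["variant_key", "reason", "n_control_carriers"])
    results = run_burden(fsites, fgeno, samples, thresholds, eligible=eligible, fdr=fdr)
    return results, log


def results_to_frame(results: Sequence[GeneBurdenResult]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results], columns=RESULT_COLUMNS)
    return df


def write_results(
    results: Sequence[GeneBurdenResult],
    path: str | Path,
    *,
    thresholds: QCThresholds | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    seed: int | None = None,
) -> Path:
    """Write one TSV row per gene plus a companion JSON log recording the
    thresholds, sample counts, seed and software version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.17g")
    log = {
        "software": "ndd-burden",
        "version": __version__,
        "n_results": len(results),
        "n_cases": n_cases,
        "n_controls": n_controls,
        "seed": seed,
        "thresholds": None
        if thresholds is None
        else {
            "min_depth": thresholds.min_depth,
            "max_maf": thresholds.max_maf,
            "lof_consequences": sorted(thresholds.lof_consequences),
            "min_lof_variants_per_gene": thresholds.min_lof_variants_per_gene,
        },
    }
    path.with_suffix(path.suffix + ".log.json").write_text(json.dumps(log, indent=2))
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
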