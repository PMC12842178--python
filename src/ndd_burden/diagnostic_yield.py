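"""Cohort description and diagnostic-yield statistics.

Diagnostic yield is the fraction of tested patients with a reportable
finding (pathogenic, likely pathogenic, or VUS).  Subgroup yields are
reported two ways: against the whole cohort (n=94 denominator — the
convention the study's printed subgroup percentages follow) and within
each subgroup.  Pairwise subgroup comparisons use the two-tailed Fisher
exact test on within-group diagnosed/undiagnosed tables, with an optional
pooled ID/GDD group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .exact_stats import ContingencyTable2x2, fisher_exact
from .synthetic_cohort import SUBGROUPS, FindingsRecord, SampleRecord

__all__ = [
    "YieldReport",
    "compute_yields",
    "pairwise_yield_tests",
    "summarize_demographics",
]


@dataclass
class YieldReport:
    """Yield summary for one cohort."""

    n_total: int
    n_diagnosed: int
    overall_yield: float  # percent
    per_subgroup: pd.DataFrame  # subgroup, n_patients, n_diagnosed, yields
    demographics: dict[str, float] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None

    def round1(self, x: float) -> float:
        return round(x, 1)


def _subgroup_sizes_from_input(
    cohort: pd.DataFrame | Sequence[SampleRecord],
) -> tuple[Mapping[str, int], int, set[str] | None]:
    """Subgroup sizes, total n and (if resolvable) the set of case ids.

    Accepts either the demographics fixture (label/value table) or a list
    of sample records; only case samples count toward the denominators.
    """
    if isinstance(cohort, pd.DataFrame):
        counts = dict(zip(cohort["label"], cohort["value"]))
        sizes = {g: int(counts[g]) for g in SUBGROUPS if g in counts}
        n_total = int(counts["male"]) + int(counts["female"])
        return sizes, n_total, None
    cases = [s for s in cohort if s.status == "case"]
    sizes = {g: sum(s.subgroup == g for s in cases) for g in SUBGROUPS}
    return sizes, len(cases), {s.sample_id for s in cases}


def compute_yields(
    cohort: pd.DataFrame | Sequence[SampleRecord],
    findings: Sequence[FindingsRecord],
) -> YieldReport:
    """Per-subgroup and overall diagnostic yields.

    A case is diagnosed if it has >= 1 finding (a case with several variant
    records — e.g. a compound heterozygote — counts once).
    ``yield_vs_cohort`` divides by the whole cohort size;
    ``yield_within_group`` divides by the subgroup size.  Percentages are
    kept at full precision; round for display.
    """
    sizes, n_total, case_ids = _subgroup_sizes_from_input(cohort)
    if case_ids is not None:
        unknown = {f.case_id for f in findings} - case_ids
        if unknown:
            raise ValueError(f"findings reference unknown case ids: {sorted(unknown)}")
    diagnosed_by_group: dict[str, set[str]] = {g: set() for g in sizes}
    for f in findings:
        if f.phenotype not in diagnosed_by_group:
            raise ValueError(f"finding for {f.case_id} has unknown subgroup {f.phenotype!r}")
        diagnosed_by_group[f.phenotype].add(f.case_id)
    all_diagnosed = set().union(*diagnosed_by_group.values()) if diagnosed_by_group else set()
    rows = []
    for g, n_g in sizes.items():
        d = len(diagnosed_by_group[g])
        rows.append(
            {
                "subgroup": g,
                "n_patients": n_g,
                "n_diagnosed": d,
                "yield_vs_cohort": 100.0 * d / n_total if n_total else 0.0,
                "yield_within_group": 100.0 * d / n_g if n_g else 0.0,
            }
        )
    per_subgroup = pd.DataFrame(rows)
    return YieldReport(
        n_total=n_total,
        n_diagnosed=len(all_diagnosed),
        overall_yield=100.0 * len(all_diagnosed) / n_total if n_total else 0.0,
        per_subgroup=per_subgroup,
        demographics=summarize_demographics(cohort),
    )


def pairwise_yield_tests(report: YieldReport, *, pool_id_gdd: bool = True) -> pd.DataFrame:
    """Two-tailed Fisher tests on diagnosed/undiagnosed tables for every
    unordered subgroup pair (plus the pooled ID/GDD group vs the others
    when ``pool_id_gdd``).  Groups with zero patients are skipped with a
    warning.  The result is also attached to ``report.pairwise``.
    """
    df = report.per_subgroup.set_index("subgroup")
    groups: dict[str, tuple[int, int]] = {
        g: (int(df.loc[g, "n_diagnosed"]), int(df.loc[g, "n_patients"])) for g in df.index
    }
    if pool_id_gdd and "ID" in groups and "GDD" in groups:
        d = groups["ID"][0] + groups["GDD"][0]
        n = groups["ID"][1] + groups["GDD"][1]
        groups["ID/GDD"] = (d, n)
    rows = []
    for ga, gb in combinations(groups, 2):
        if {ga, gb} & {"ID", "GDD"} and "ID/GDD" in (ga, gb):
            continue  # a pooled group is not compared against its parts
        (da, na), (db, nb) = groups[ga], groups[gb]
        if na == 0 or nb == 0:
            warnings.warn(f"skipping pair ({ga}, {gb}): empty group")
            continue
        table = ContingencyTable2x2(a=da, b=na - da, c=db, d=nb - db)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "a_diagnosed": da,
                "a_undiagnosed": na - da,
                "b_diagnosed": db,
                "b_undiagnosed": nb - db,
                "two_sided_p": fisher_exact(table, tail="two_sided"),
            }
        )
    out = pd.DataFrame(rows)
    report.pairwise = out
    return out


def summarize_demographics(
    cohort: pd.DataFrame | Sequence[SampleRecord],
) -> dict[str, float]:
    """Cohort percentages (male, family history, prematurity where known,
    subgroup shares), full precision; display style rounds to integers."""
    if isinstance(cohort, pd.DataFrame):
        counts = dict(zip(cohort["label"], cohort["value"]))
        n_total = int(counts["male"]) + int(counts["female"])
        out = {
            "n_total": float(n_total),
            "pct_male": 100.0 * counts["male"] / n_total,
            "pct_family_history": 100.0 * counts["family_history"] / n_total,
        }
        if "premature_birth" in counts:
            out["pct_premature"] = 100.0 * counts["premature_birth"] / n_total
        for g in SUBGROUPS:
            if g in counts:
                out[f"pct_{g}"] = 100.0 * counts[g] / n_total
        return out
    cases = [s for s in cohort if s.status == "case"]
    n_total = len(cases)
    if n_total == 0:
        return {"n_total": 0.0}
    out = {
        "n_total": float(n_total),
        "pct_male": 100.0 * sum(s.sex == "male" for s in cases) / n_total,
        "pct_family_history": 100.0 * sum(s.family_history for s in cases) / n_total,
    }
    for g in SUBGROUPS:
        out[f"pct_{g}"] = 100.0 * sum(s.subgroup == g for s in cases) / n_total
    return out
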