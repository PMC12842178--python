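"""Variant-level quality control for the burden scan.

Three filters, applied in this order in the standard pipeline:

1. call-level depth masking (calls under 20x become missing) and
   site-level frequency/consequence filtering (gnomAD MAF < 5%,
   predicted loss-of-function consequences only);
2. the penetrant-model filter: any case-observed variant also present in
   at least one control — in any zygosity — is removed, approximating a
   fully penetrant Mendelian model;
3. gene eligibility: only genes with at least 5 distinct surviving LoF
   sites enter the CAST scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import MISSING, GenotypeMatrix, SampleRecord, VariantSite

__all__ = [
    "QCThresholds",
    "DEFAULT_LOF_CONSEQUENCES",
    "KNOWN_CONSEQUENCES",
    "classify_lof",
    "apply_qc",
    "penetrant_model_filter",
    "eligible_genes",
]

#: predicted protein-truncating classes counted as LoF (configurable; the
#: study does not enumerate its own set)
DEFAULT_LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
        "stop_lost",
    }
)

KNOWN_CONSEQUENCES = DEFAULT_LOF_CONSEQUENCES | {
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "splice_region_variant",
    "inframe_deletion",
    "inframe_insertion",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
}


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds.

    min_depth: calls below this read depth become missing (boundary kept:
        depth 20 passes at the default 20x).
    max_maf: sites at or above this gnomAD frequency are removed (strict
        "below 5%" reading: 0.05 itself fails).
    min_lof_variants_per_gene: gene eligibility bound (>= 5 distinct sites
        by default; ``eligibility_unit='carriers'`` switches to counting
        carrier individuals instead — the study wording admits both).
    strict_consequences: raise on unrecognized consequence terms instead of
        warning and treating them as non-LoF.
    """

    min_depth: int = 20
    max_maf: float = 0.05
    lof_consequences: frozenset[str] = DEFAULT_LOF_CONSEQUENCES
    min_lof_variants_per_gene: int = 5
    eligibility_unit: Literal["sites", "carriers"] = "sites"
    strict_consequences: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.max_maf <= 1:
            raise ValueError("max_maf must be in (0, 1]")
        if not self.lof_consequences:
            raise ValueError("lof_consequences must be non-empty")


def classify_lof(consequence: str, thresholds: QCThresholds = QCThresholds()) -> bool:
    """True iff the consequence term is in the configured LoF set."""
    if consequence not in KNOWN_CONSEQUENCES and consequence not in thresholds.lof_consequences:
        if thresholds.strict_consequences:
            raise ValueError(f"unrecognized consequence term {consequence!r}")
        warnings.warn(f"unrecognized consequence term {consequence!r}; treated as non-LoF")
        return False
    return consequence in thresholds.lof_consequences


def apply_qc(
    sites: Sequence[VariantSite],
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    *,
    require_lof: bool = True,
) -> tuple[list[VariantSite], GenotypeMatrix]:
    """Depth-mask calls and drop high-frequency / non-LoF sites.

    Calls with depth < min_depth are set to missing.  Sites with
    gnomad_af >= max_maf are removed; sites absent from gnomAD (af None)
    are kept as rare.  With ``require_lof`` (the burden path), non-LoF
    sites are removed as well.  Surviving site order is preserved.
    """
    if genotypes.n_sites != len(sites):
        raise ValueError("genotype matrix does not match the site list")
    dosage = genotypes.dosage.copy()
    dosage[genotypes.depth < thresholds.min_depth] = MISSING
    keep = []
    for i, site in enumerate(sites):
        if site.gnomad_af is not None and site.gnomad_af >= thresholds.max_maf:
            continue
        if require_lof and not classify_lof(site.consequence, thresholds):
            continue
        keep.append(i)
    filtered = GenotypeMatrix(dosage[:, keep], genotypes.depth[:, keep].copy())
    return [sites[i] for i in keep], filtered


def _carrier_masks(
    genotypes: GenotypeMatrix, samples: Sequence[SampleRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site case/control carrier counts (missing counts as non-carrier)."""
    is_case = np.array([s.status == "case" for s in samples])
    carrier = genotypes.dosage >= 1
    return carrier[is_case].sum(axis=0), carrier[~is_case].sum(axis=0)


def penetrant_model_filter(
    sites: Sequence[VariantSite],
    genotypes: GenotypeMatrix,
    samples: Sequence[SampleRecord],
) -> tuple[list[VariantSite], GenotypeMatrix, pd.DataFrame]:
    """Keep only case-carried sites with zero control carriers.

    A case-observed variant present in any control, in any zygosity, is
    excluded (fully-penetrant-like model).  Control-only and carrier-free
    sites are removed from the analysis set too: they cannot contribute to
    any case's CAST indicator, so the per-gene tables are unchanged either
    way.  Returns (sites, genotypes, removal_log); the log lists each
    removed variant_key with its reason and triggering control count.
    """
    if genotypes.n_samples != len(samples):
        raise ValueError("genotype matrix does not match the sample list")
    case_n, control_n = _carrier_masks(genotypes, samples)
    keep, log_rows = [], []
    for i, site in enumerate(sites):
        if case_n[i] >= 1 and control_n[i] == 0:
            keep.append(i)
            continue
        if control_n[i] >= 1 and case_n[i] >= 1:
            reason = "case_variant_in_control"
        elif control_n[i] >= 1:
            reason = "control_only"
        else:
            reason = "no_carrier"
        log_rows.append(
            {"variant_key": site.variant_key, "reason": reason,
             "n_control_carriers": int(control_n[i])}
        )
    log = pd.DataFrame(log_rows, columns=["variant_key", "reason", "n_control_carriers"])
    return [sites[i] for i in keep], genotypes.subset_sites(keep), log


def eligible_genes(
    sites: Sequence[VariantSite],
    thresholds: QCThresholds = QCThresholds(),
    genotypes: GenotypeMatrix | None = None,
) -> set[str]:
    """Genes with >= min_lof_variants_per_gene distinct surviving LoF sites.

    Expects sites already LoF-classified and QC-filtered.  With
    ``eligibility_unit='carriers'`` the bound applies to the number of
    carrier individuals instead (requires ``genotypes``).
    """
    if thresholds.eligibility_unit == "carriers":
        if genotypes is None:
            raise ValueError("carrier-based eligibility requires genotypes")
        counts: dict[str, set[int]] = {}
        carrier = genotypes.dosage >= 1
        for i, site in enumerate(sites):
            counts.setdefault(site.gene, set()).update(np.nonzero(carrier[:, i])[0].tolist())
        return {g for g, c in counts.items() if len(c) >= thresholds.min_lof_variants_per_gene}
    per_gene: dict[str, set[str]] = {}
    for site in sites:
        per_gene.setdefault(site.gene, set()).add(site.variant_key)
    return {g for g, keys in per_gene.items() if len(keys) >= thresholds.min_lof_variants_per_gene}
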