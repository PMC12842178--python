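"""Synthetic case/control exome cohorts and in-study fixture tables.

The simulator emulates the study design the burden scan assumes: a small
pediatric NDD case series (default 94 cases) against a large population
control panel (default 1246), genotyped at rare predicted loss-of-function
sites, with a handful of genes planted to carry an exact case-only burden
(5-8 case carriers, zero controls) and the remaining genes carrying sparse
background LoF variation independent of case/control status.

Everything is driven by a single :class:`numpy.random.Generator`, so a
(config, seed) pair reproduces the cohort byte-identically.

The module also packages two fixture tables transcribed from the study:
the cohort demographics table and the 38-row diagnostic-findings table
(37 distinct cases; one compound-heterozygous case contributes two rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimulationConfig",
    "SampleRecord",
    "VariantSite",
    "GenotypeMatrix",
    "FindingsRecord",
    "ConfigurationError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "load_fixture_tables",
    "samples_to_frame",
    "frame_to_samples",
]

SUBGROUPS = ("ID", "ASD", "GDD", "SLD")
#: case subgroup mix of the study cohort (ID 39, ASD 36, GDD 13, SLD 6 of 94)
SUBGROUP_PROBS = {"ID": 39 / 94, "ASD": 36 / 94, "GDD": 13 / 94, "SLD": 6 / 94}
LOF_TERMS = (
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "stop_lost",
)
MISSING = -1  # dosage code for a missing genotype call


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally impossible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated case/control LoF cohort.

    Defaults mirror the study conditions: 94 cases vs 1246 population
    controls, planted genes with exactly six case carriers and zero control
    carriers, case covariates matching the cohort description (65% male,
    ages 1-168 months, 27% positive family history).  The control panel's
    covariates are unpublished; defaults (50% male, 5% family history,
    ages drawn from the case range so the age adjustment stays estimable
    rather than becoming a perfect case/control separator) are discussed
    in the methods note.
    """

    n_cases: int = 94
    n_controls: int = 1246
    n_genes: int = 50
    n_enriched_genes: int = 4
    variants_per_gene: int | tuple[int, int] = 8
    background_carrier_freq: float = 0.005
    enriched_case_carrier_count: int = 6
    enriched_control_carrier_count: int = 0
    sex_male_prob_cases: float = 61 / 94
    sex_male_prob_controls: float = 0.5
    age_range_cases: tuple[int, int] = (1, 168)
    age_range_controls: tuple[int, int] = (1, 168)
    famhist_prob_cases: float = 0.27
    famhist_prob_controls: float = 0.05
    hom_carrier_prob: float = 0.0
    share_with_control: bool = False
    variable_depth: bool = False
    mean_depth: int = 100
    low_depth_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_enriched_genes > self.n_genes:
            raise ConfigurationError("n_enriched_genes exceeds n_genes")
        if self.enriched_case_carrier_count > self.n_cases:
            raise ConfigurationError("more enriched case carriers than cases")
        if self.enriched_control_carrier_count > self.n_controls:
            raise ConfigurationError("more enriched control carriers than controls")
        for name in (
            "background_carrier_freq",
            "sex_male_prob_cases",
            "sex_male_prob_controls",
            "famhist_prob_cases",
            "famhist_prob_controls",
            "hom_carrier_prob",
            "low_depth_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for rng_name in ("age_range_cases", "age_range_controls"):
            lo, hi = getattr(self, rng_name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"invalid {rng_name}={lo, hi}")
        lo, hi = self._variant_range()
        if lo < 1:
            raise ConfigurationError("variants_per_gene must be >= 1")
        if self.enriched_case_carrier_count + self.enriched_control_carrier_count > hi:
            raise ConfigurationError(
                "variants_per_gene too small for private enriched carrier sites"
            )

    def _variant_range(self) -> tuple[int, int]:
        v = self.variants_per_gene
        if isinstance(v, int):
            return v, v
        lo, hi = v
        return int(lo), int(hi)


@dataclass(frozen=True)
class SampleRecord:
    """One study participant."""

    sample_id: str
    status: Literal["case", "control"]
    sex: Literal["male", "female"]
    age_months: int
    family_history: bool
    subgroup: str = "none"

    def __post_init__(self) -> None:
        if self.status == "control" and self.subgroup != "none":
            raise ValueError("controls must have subgroup='none'")
        if self.age_months < 0:
            raise ValueError("age_months must be non-negative")


@dataclass(frozen=True)
class VariantSite:
    """One rare-variant site, keyed chrom:pos:ref:alt."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    gnomad_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based and >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Per-(sample, site) dosage and read depth.

    dosage is int8 with values {0, 1, 2} or -1 for missing; depth is a
    non-negative int32.  Rows align with the sample list, columns with the
    site list.
    """

    dosage: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.dosage.shape != self.depth.shape:
            raise ValueError("dosage and depth shapes differ")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def subset_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(self.dosage[:, idx].copy(), self.depth[:, idx].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return np.array_equal(self.dosage, other.dosage) and np.array_equal(
            self.depth, other.depth
        )


@dataclass(frozen=True)
class FindingsRecord:
    """One diagnostic finding (one row of the findings fixture)."""

    case_id: str
    phenotype: str
    gene: str
    transcript: str
    variant: str
    zygosity: str
    inheritance: str
    segregation: str

    def __post_init__(self) -> None:
        if self.phenotype not in SUBGROUPS:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


def _simulate_samples(config: SimulationConfig, rng: np.random.Generator) -> list[SampleRecord]:
    samples: list[SampleRecord] = []
    subgroup_labels = list(SUBGROUP_PROBS)
    subgroup_p = np.array([SUBGROUP_PROBS[s] for s in subgroup_labels])
    for i in range(config.n_cases):
        lo, hi = config.age_range_cases
        samples.append(
            SampleRecord(
                sample_id=f"CASE{i + 1:04d}",
                status="case",
                sex="male" if rng.random() < config.sex_male_prob_cases else "female",
                age_months=int(rng.integers(lo, hi + 1)),
                family_history=bool(rng.random() < config.famhist_prob_cases),
                subgroup=str(rng.choice(subgroup_labels, p=subgroup_p)),
            )
        )
    for i in range(config.n_controls):
        lo, hi = config.age_range_controls
        samples.append(
            SampleRecord(
                sample_id=f"CTRL{i + 1:04d}",
                status="control",
                sex="male" if rng.random() < config.sex_male_prob_controls else "female",
                age_months=int(rng.integers(lo, hi + 1)),
                family_history=bool(rng.random() < config.famhist_prob_controls),
            )
        )
    return samples


def _dosage_for_carrier(config: SimulationConfig, rng: np.random.Generator) -> int:
    return 2 if rng.random() < config.hom_carrier_prob else 1


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleRecord], list[VariantSite], GenotypeMatrix, set[str]]:
    """Simulate a case/control LoF cohort with planted burden genes.

    Returns (samples, sites, genotypes, truth) where truth is the set of
    enriched gene symbols.  Enriched genes carry *exactly*
    ``enriched_case_carrier_count`` case carriers (each on a private het
    site by default) and ``enriched_control_carrier_count`` control
    carriers; all other genes carry background variation independent of
    status.  Only sites with at least one carrier are emitted, as in a
    jointly called VCF.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _simulate_samples(config, rng)
    n_samples = len(samples)
    case_idx = np.arange(config.n_cases)
    control_idx = np.arange(config.n_cases, n_samples)

    gene_names = [f"GENE{g + 1:04d}" for g in range(config.n_genes)]
    enriched = sorted(
        rng.choice(config.n_genes, size=config.n_enriched_genes, replace=False).tolist()
    )
    truth = {gene_names[g] for g in enriched}
    lo_v, hi_v = config._variant_range()

    sites: list[VariantSite] = []
    dosage_cols: list[np.ndarray] = []
    alleles = ("A", "C", "G", "T")
    for g, gene in enumerate(gene_names):
        n_slots = int(rng.integers(lo_v, hi_v + 1)) if lo_v != hi_v else lo_v
        # slot -> list of (sample index, dosage)
        slot_carriers: dict[int, list[tuple[int, int]]] = {}
        if gene in truth:
            carriers = rng.choice(case_idx, size=config.enriched_case_carrier_count, replace=False)
            for j, s in enumerate(np.sort(carriers)):
                slot_carriers.setdefault(j, []).append((int(s), _dosage_for_carrier(config, rng)))
            ctrl = rng.choice(
                control_idx, size=config.enriched_control_carrier_count, replace=False
            )
            offset = config.enriched_case_carrier_count
            for j, s in enumerate(np.sort(ctrl)):
                slot_carriers.setdefault(offset + j, []).append(
                    (int(s), _dosage_for_carrier(config, rng))
                )
            if config.share_with_control:
                # adversarial option: one planted site carried by both a case
                # and a control, to exercise the penetrant-model filter
                shared_case = int(rng.choice(case_idx))
                shared_ctrl = int(rng.choice(control_idx))
                j = max(slot_carriers) + 1 if slot_carriers else 0
                slot_carriers[j] = [(shared_case, 1), (shared_ctrl, 1)]
        else:
            carrier_mask = rng.random(n_samples) < config.background_carrier_freq
            for s in np.nonzero(carrier_mask)[0]:
                j = int(rng.integers(0, n_slots))
                slot_carriers.setdefault(j, []).append((int(s), _dosage_for_carrier(config, rng)))
        for j in sorted(slot_carriers):
            pos = 1_000_000 * (g + 1) + 100 * j + 1
            ref = alleles[int(rng.integers(0, 4))]
            alt = alleles[(alleles.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            af = round(float(rng.uniform(1e-5, 0.01)), 6)
            sites.append(
                VariantSite(
                    chrom=f"chr{g % 22 + 1}",
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    consequence=str(rng.choice(LOF_TERMS)),
                    gnomad_af=af,
                )
            )
            col = np.zeros(n_samples, dtype=np.int8)
            for s, dose in slot_carriers[j]:
                col[s] = dose
            dosage_cols.append(col)

    n_sites = len(sites)
    dosage = (
        np.stack(dosage_cols, axis=1) if n_sites else np.zeros((n_samples, 0), dtype=np.int8)
    )
    if config.variable_depth:
        depth = rng.poisson(config.mean_depth, size=(n_samples, n_sites)).astype(np.int32)
        low = rng.random((n_samples, n_sites)) < config.low_depth_prob
        depth[low] = rng.integers(1, 20, size=int(low.sum()))
    else:
        depth = np.full((n_samples, n_sites), config.mean_depth, dtype=np.int32)
    return samples, sites, GenotypeMatrix(dosage, depth), truth


# ---------------------------------------------------------------------------
# VCF + sample-sheet round trip

_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_cohort(
    samples: Sequence[SampleRecord],
    sites: Sequence[VariantSite],
    genotypes: GenotypeMatrix,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write a VCFv4.2 (GT/DP per sample; GENE, CSQCLASS, GNOMAD_AF INFO
    keys) and a tab-separated sample sheet under ``out_prefix``.

    Returns (vcf_path, sample_sheet_path).  ``read_cohort`` on the output
    reproduces the inputs exactly.
    """
    if genotypes.n_samples != len(samples) or genotypes.n_sites != len(sites):
        raise ValueError("genotype matrix dimensions do not match samples/sites")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = out_prefix.with_suffix(".vcf")
    sheet_path = out_prefix.parent / (out_prefix.name + ".samples.tsv")

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for chrom in sorted({s.chrom for s in sites}, key=lambda c: (len(c), c)):
        header.contigs.add(chrom, length=300_000_000)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQCLASS", 1, "String", "Predicted consequence class")
    header.info.add("GNOMAD_AF", 1, "Float", "gnomAD allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s.sample_id)

    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for i in order:
            site = sites[i]
            rec = vcf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
            )
            rec.info["GENE"] = site.gene
            rec.info["CSQCLASS"] = site.consequence
            if site.gnomad_af is not None:
                rec.info["GNOMAD_AF"] = site.gnomad_af
            for r, s in enumerate(samples):
                rec.samples[s.sample_id]["GT"] = _GT[int(genotypes.dosage[r, i])]
                rec.samples[s.sample_id]["DP"] = int(genotypes.depth[r, i])
            vcf.write(rec)

    samples_to_frame(samples).to_csv(sheet_path, sep="\t", index=False)
    return vcf_path, sheet_path


def read_cohort(
    vcf_path: str | Path, sheet_path: str | Path
) -> tuple[list[SampleRecord], list[VariantSite], GenotypeMatrix]:
    """Read a cohort written by :func:`write_cohort`."""
    samples = frame_to_samples(pd.read_csv(sheet_path, sep="\t"))
    sample_ids = [s.sample_id for s in samples]
    sites: list[VariantSite] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if vcf_samples != sample_ids:
            raise ValueError("VCF sample order does not match the sample sheet")
        for rec in vcf:
            af = rec.info.get("GNOMAD_AF")
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=rec.info["GENE"],
                    consequence=rec.info["CSQCLASS"],
                    # AFs are generated/stored to 6 decimals; normalise away
                    # the float32 representation htslib uses for Float INFO
                    gnomad_af=None if af is None else round(float(af), 6),
                )
            )
            dcol = np.empty(len(sample_ids), dtype=np.int8)
            pcol = np.empty(len(sample_ids), dtype=np.int32)
            for r, sid in enumerate(sample_ids):
                call = rec.samples[sid]
                gt = call["GT"]
                dcol[r] = MISSING if gt is None or gt[0] is None else sum(gt)
                pcol[r] = call["DP"] if call["DP"] is not None else 0
            dosage_cols.append(dcol)
            depth_cols.append(pcol)
    n = len(sample_ids)
    if dosage_cols:
        geno = GenotypeMatrix(np.stack(dosage_cols, 1), np.stack(depth_cols, 1))
    else:
        geno = GenotypeMatrix(np.zeros((n, 0), np.int8), np.zeros((n, 0), np.int32))
    return samples, sites, geno


def samples_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "status": [s.status for s in samples],
            "sex": [s.sex for s in samples],
            "age_months": [s.age_months for s in samples],
            "family_history": [s.family_history for s in samples],
            "subgroup": [s.subgroup for s in samples],
        }
    )


def frame_to_samples(df: pd.DataFrame) -> list[SampleRecord]:
    def _bool(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return str(v).strip().lower() in ("true", "1", "yes")

    return [
        SampleRecord(
            sample_id=str(r.sample_id),
            status=str(r.status),
            sex=str(r.sex),
            age_months=int(r.age_months),
            family_history=_bool(r.family_history),
            subgroup=str(r.subgroup),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Packaged fixture tables

def load_fixture_tables() -> tuple[pd.DataFrame, list[FindingsRecord]]:
    """Load the packaged cohort-demographics and diagnostic-findings tables.

    Returns (cohort_summary, findings).  cohort_summary is a label/value
    table (counts of 94 patients by sex, family history, prematurity and
    NDD subgroup); findings holds 38 variant records over 37 distinct cases.
    """
    pkg = resources.files("ndd_burden") / "fixtures"
    summary = pd.read_csv(pkg / "cohort_demographics.tsv", sep="\t")
    # keep_default_na: "N/A" is a real segregation category, not a missing value
    fdf = pd.read_csv(pkg / "diagnostic_findings.tsv", sep="\t", dtype=str, keep_default_na=False)
    required = {
        "case_id", "phenotype", "gene", "transcript",
        "variant", "zygosity", "inheritance", "segregation",
    }
    if set(fdf.columns) != required or fdf.isna().any().any():
        raise ValueError("corrupted findings fixture")
    findings = [FindingsRecord(**row) for row in fdf.to_dict("records")]
    return summary, findings
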