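"""Shared builders for small hand-constructed cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ndd_burden import GenotypeMatrix, SampleRecord, VariantSite


def make_samples(n_cases: int, n_controls: int) -> list[SampleRecord]:
    out = []
    for i in range(n_cases):
        out.append(
            SampleRecord(
                sample_id=f"CASE{i:03d}",
                status="case",
                sex="male" if i % 2 else "female",
                age_months=12 + i,
                family_history=bool(i % 3 == 0),
                subgroup=["ID", "ASD", "GDD", "SLD"][i % 4],
            )
        )
    for i in range(n_controls):
        out.append(
            SampleRecord(
                sample_id=f"CTRL{i:03d}",
                status="control",
                sex="male" if i % 2 else "female",
                age_months=24 + i,
                family_history=False,
            )
        )
    return out


def make_site(gene: str, i: int, consequence: str = "stop_gained",
              gnomad_af: float | None = 0.0001) -> VariantSite:
    return VariantSite(
        chrom="chr1", pos=1000 * (i + 1), ref="A", alt="T",
        gene=gene, consequence=consequence, gnomad_af=gnomad_af,
    )


def make_genotypes(dosage: np.ndarray, depth: int = 100) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(dosage, np.full(dosage.shape, depth, dtype=np.int32))


@pytest.fixture
def small_cohort():
    """4 cases / 6 controls, one gene with 2 sites: site 0 is case-private,
    site 1 is shared by a case and a control."""
    samples = make_samples(4, 6)
    sites = [make_site("GENEA", 0), make_site("GENEA", 1)]
    dosage = np.zeros((10, 2), dtype=np.int8)
    dosage[0, 0] = 1  # case 0 carries the private site
    dosage[1, 1] = 1  # case 1 and control 0 share site 1
    dosage[4, 1] = 1
    return samples, sites, make_genotypes(dosage)
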