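"""Shared builders for the test suite.

Everything is generated programmatically; no stored fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from extremophen.io_core import (
    AnnotatedVariant,
    ClinVarSig,
    CohortDesign,
    FunctionalClass,
)


def make_variant(
    sample_id: str = "S1",
    chrom: str = "1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
    functional_class: FunctionalClass = FunctionalClass.NONSYNONYMOUS_SNV,
    gene: str = "GENE1",
    sift: float | None = 0.01,
    af_1000g: float | None = 0.001,
    af_esp6500: float | None = 0.001,
    af_exac_eas: float | None = 0.001,
    clinvar: ClinVarSig = ClinVarSig.ABSENT,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        functional_class=functional_class, gene=gene, sift=sift,
        af_1000g=af_1000g, af_esp6500=af_esp6500, af_exac_eas=af_exac_eas,
        clinvar=clinvar,
    )


def random_variant(rng: np.random.Generator, sample_id: str) -> AnnotatedVariant:
    """A variant with annotations spread across all filter-relevant regimes."""
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
    if rng.random() < 0.2:  # indel
        ref, alt = (ref, ref + alt) if rng.random() < 0.5 else (ref + alt, ref)
    classes = list(FunctionalClass)
    sift = None if rng.random() < 0.25 else float(rng.uniform(0, 0.12))
    afs = [
        None if rng.random() < 0.25 else float(rng.uniform(0, 0.12))
        for _ in range(3)
    ]
    clinvar_options = [ClinVarSig.ABSENT, ClinVarSig.PATHOGENIC,
                       ClinVarSig.LIKELY_PATHOGENIC, ClinVarSig.BENIGN,
                       ClinVarSig.VUS]
    clinvar = clinvar_options[rng.choice(5, p=[0.6, 0.1, 0.1, 0.1, 0.1])]
    return AnnotatedVariant(
        sample_id=sample_id,
        chrom=str(1 + rng.integers(22)),
        pos=int(rng.integers(1, 10**8)),
        ref=ref,
        alt=alt,
        functional_class=classes[rng.integers(len(classes))],
        gene=f"G{rng.integers(50):03d}",
        sift=sift,
        af_1000g=afs[0],
        af_esp6500=afs[1],
        af_exac_eas=afs[2],
        clinvar=clinvar,
    )


@pytest.fixture
def study_design() -> CohortDesign:
    """The reference three-group cohort: DM(6), DR(5), DM-DR(4)."""
    return CohortDesign.from_items(
        [
            ("DM", [f"DM_{i}" for i in range(1, 7)]),
            ("DR", [f"DR_{i}" for i in range(1, 6)]),
            ("DM-DR", [f"DMDR_{i}" for i in range(1, 5)]),
        ]
    )
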