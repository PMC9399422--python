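"""Candidate-variant filter: boundary semantics, reason codes, oracle
equivalence and order properties."""

from __future__ import annotations

import numpy as np
import pytest

from extremophen.io_core import (
    AnnotatedVariant,
    ClinVarSig,
    FunctionalClass,
    VariantClass,
)
from extremophen.variant_filter import (
    FilterConfig,
    FilterReason,
    filter_cohort,
    is_candidate,
)

from conftest import make_variant, random_variant


def brute_force_is_candidate(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Independent re-statement of the filter: protein-altering AND
    ((SIFT <= 0.05 AND all three AFs < 0.05) OR ClinVar pathogenic-ish),
    with the default missing-data policies spelled out long-hand."""
    protein_altering = v.functional_class in {
        FunctionalClass.NONSYNONYMOUS_SNV,
        FunctionalClass.MISSENSE,
        FunctionalClass.STOPGAIN,
        FunctionalClass.STOPLOSS,
        FunctionalClass.FRAMESHIFT_INSERTION,
        FunctionalClass.FRAMESHIFT_DELETION,
        FunctionalClass.NONFRAMESHIFT_INDEL,
    }
    if not protein_altering:
        return False
    if v.clinvar in {ClinVarSig.PATHOGENIC, ClinVarSig.LIKELY_PATHOGENIC}:
        return True
    if v.sift is None:
        deleterious = v.variant_class is VariantClass.INDEL
    else:
        deleterious = v.sift <= cfg.sift_max
    rare = all(
        af is None or af < cfg.af_max
        for af in (v.af_1000g, v.af_esp6500, v.af_exac_eas)
    )
    return deleterious and rare


class TestIsCandidate:
    def test_sift_boundary_is_inclusive(self):
        v = make_variant(sift=0.05, af_1000g=0.001, af_esp6500=0.0, af_exac_eas=None)
        ok, reason = is_candidate(v)
        assert ok and reason is FilterReason.PASS_DELETERIOUS_RARE

    def test_clinvar_rescues_high_sift(self):
        v = make_variant(sift=0.30, clinvar=ClinVarSig.PATHOGENIC)
        ok, reason = is_candidate(v)
        assert ok and reason is FilterReason.PASS_CLINVAR

    def test_synonymous_fails_class_gate_despite_good_scores(self):
        v = make_variant(
            functional_class=FunctionalClass.SYNONYMOUS_SNV,
            sift=0.001, af_1000g=0.0, af_esp6500=0.0, af_exac_eas=0.0,
        )
        ok, reason = is_candidate(v)
        assert not ok and reason is FilterReason.FAIL_CLASS

    def test_af_boundary_is_strict(self):
        v = make_variant(sift=0.01, af_1000g=0.05)
        ok, reason = is_candidate(v)
        assert not ok and reason is FilterReason.FAIL_AF

    def test_rarity_requires_all_three_databases(self):
        v = make_variant(sift=0.01, af_1000g=0.001, af_esp6500=0.001, af_exac_eas=0.06)
        assert not is_candidate(v)[0]

    def test_indel_with_absent_sift_exempted_by_default(self):
        v = make_variant(ref="A", alt="AT", sift=None,
                         functional_class=FunctionalClass.FRAMESHIFT_INSERTION)
        ok, reason = is_candidate(v)
        assert ok and reason is FilterReason.PASS_DELETERIOUS_RARE

    def test_indel_absent_sift_fail_policy(self):
        cfg = FilterConfig(missing_sift_policy_indel="fail")
        v = make_variant(ref="A", alt="AT", sift=None,
                         functional_class=FunctionalClass.FRAMESHIFT_INSERTION)
        ok, reason = is_candidate(v, cfg)
        assert not ok and reason is FilterReason.FAIL_SIFT

    def test_snp_with_absent_sift_fails_deleterious_test(self):
        ok, reason = is_candidate(make_variant(sift=None))
        assert not ok and reason is FilterReason.FAIL_SIFT

    def test_missing_af_policies(self):
        v = make_variant(sift=0.01, af_1000g=None, af_esp6500=None, af_exac_eas=None)
        assert is_candidate(v)[0]
        assert not is_candidate(v, FilterConfig(missing_af_policy="treat_as_fail"))[0]

    def test_alternative_precedence_requires_deleterious(self):
        # deleterious AND (rare OR ClinVar): high SIFT cannot be rescued
        cfg = FilterConfig(clinvar_rescue_independent=False)
        v = make_variant(sift=0.30, clinvar=ClinVarSig.PATHOGENIC)
        assert not is_candidate(v, cfg)[0]
        common = make_variant(sift=0.01, af_1000g=0.2, clinvar=ClinVarSig.PATHOGENIC)
        ok, reason = is_candidate(common, cfg)
        assert ok and reason is FilterReason.PASS_CLINVAR

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(sift_max=1.5)
        with pytest.raises(ValueError):
            FilterConfig(missing_af_policy="whatever")


class TestFilterCohort:
    def test_hand_counted_subset(self):
        variants = [
            make_variant(sample_id="A", pos=1),                      # pass
            make_variant(sample_id="A", pos=2, sift=0.5),            # fail sift
            make_variant(sample_id="B", pos=3, ref="A", alt="AT", sift=None,
                         functional_class=FunctionalClass.FRAMESHIFT_INSERTION),  # pass
            make_variant(sample_id="B", pos=4,
                         functional_class=FunctionalClass.SYNONYMOUS_SNV),  # fail class
            make_variant(sample_id="B", pos=5, af_1000g=0.3),        # fail af
            make_variant(sample_id="B", pos=6, sift=0.9,
                         clinvar=ClinVarSig.LIKELY_PATHOGENIC),      # pass clinvar
        ]
        candidates, summary = filter_cohort(variants)
        assert [v.pos for v in candidates] == [1, 3, 6]
        assert summary.candidate_counts[VariantClass.SNP] == 2
        assert summary.candidate_counts[VariantClass.INDEL] == 1
        assert summary.per_sample.loc["A", "total"] == 1
        assert summary.per_sample.loc["B", "total"] == 2
        assert len(summary.reasons) == 6

    def test_empty_input(self):
        candidates, summary = filter_cohort([])
        assert candidates == [] and summary.n_candidates == 0
        assert summary.per_sample.empty

    def test_oracle_equivalence_on_random_fixture(self):
        rng = np.random.default_rng(42)
        cfg = FilterConfig()
        variants = [random_variant(rng, f"S{i % 5}") for i in range(1000)]
        candidates, summary = filter_cohort(variants, cfg)
        expected = [v for v in variants if brute_force_is_candidate(v, cfg)]
        assert candidates == expected
        for v, reason in zip(variants, summary.reasons):
            assert reason.passed == brute_force_is_candidate(v, cfg)

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        variants = [random_variant(rng, "S1") for _ in range(300)]
        once, _ = filter_cohort(variants)
        twice, _ = filter_cohort(once)
        assert twice == once

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(11)
        variants = [random_variant(rng, "S1") for _ in range(400)]
        loose = FilterConfig(sift_max=0.2, af_max=0.2)
        tight_set = {id(v) for v in filter_cohort(variants)[0]}
        loose_set = {id(v) for v in filter_cohort(variants, loose)[0]}
        assert tight_set <= loose_set

    def test_output_subset_of_input_with_one_reason_each(self):
        rng = np.random.default_rng(3)
        variants = [random_variant(rng, "S1") for _ in range(200)]
        candidates, summary = filter_cohort(variants)
        assert set(map(id, candidates)) <= set(map(id, variants))
        assert len(summary.reasons) == len(variants)
        assert all(isinstance(r, FilterReason) for r in summary.reasons)
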