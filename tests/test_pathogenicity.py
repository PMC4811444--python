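"""HGVS typing, pathogenicity rules, origin assignment, cohort summary."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from brcaudit.catalogue import GERMLINE_DB, Catalogue, CatalogueVariant
from brcaudit.datasets import EXAMPLE_COHORT_SIZE, example_cohort
from brcaudit.pathogenicity import (
    BENIGN,
    FRAMESHIFT,
    GERMLINE,
    HETEROZYGOUS,
    HOMOZYGOUS_OR_LOH,
    INFRAME_DELETION,
    LIKELY_PATHOGENIC_SAME_CODON,
    MISSENSE,
    NONSENSE,
    OTHER,
    PATHOGENIC,
    SOMATIC,
    SYNONYMOUS,
    UNDETERMINED,
    VUS,
    ObservedVariant,
    OriginConfig,
    assign_origin,
    classify_cohort,
    classify_mutation_type,
    classify_pathogenicity,
    cohort_summary,
)

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


class TestClassifyMutationType:
    @pytest.mark.parametrize(
        "hgvs_p,expected",
        [
            ("p.Gln1777ProfsTer74", FRAMESHIFT),
            ("p.Cys226ValfsTer8", FRAMESHIFT),
            ("p.Gln563Ter", NONSENSE),
            ("p.Glu2872Ter", NONSENSE),
            ("p.Val1709del", INFRAME_DELETION),
            ("p.Pro1770Leu", MISSENSE),
            ("p.Leu5=", SYNONYMOUS),
            ("p.Gly10_Leu12del", INFRAME_DELETION),
            ("p.Ala3dup", OTHER),
        ],
    )
    def test_protein_notation(self, hgvs_p, expected):
        assert classify_mutation_type(hgvs_p) == expected

    @pytest.mark.parametrize(
        "hgvs_c,expected",
        [
            ("c.676delT", FRAMESHIFT),
            ("c.2405_2406delTG", FRAMESHIFT),
            ("c.5125_5127delGTT", INFRAME_DELETION),
            ("c.5329dupC", FRAMESHIFT),
            ("c.100_102del", INFRAME_DELETION),
            ("c.10insAT", FRAMESHIFT),
            ("c.1687C>T", OTHER),  # substitution needs protein context
        ],
    )
    def test_coding_notation_fallback(self, hgvs_c, expected):
        assert classify_mutation_type("", hgvs_c) == expected

    @pytest.mark.parametrize("bad", ["p.banana", "p.12Leu", "c.?del", "g.100A>T"])
    def test_unparseable_tokens_raise(self, bad):
        with pytest.raises(ValueError, match="HGVS"):
            if bad.startswith("p."):
                classify_mutation_type(bad)
            else:
                classify_mutation_type("", bad)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation_type("", "")

    def test_agrees_with_codon_arithmetic_oracle(self):
        """Random coding mutations on a synthetic CDS: the expected type is
        derived independently by codon arithmetic plus translation."""
        rng = np.random.default_rng(31)
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(200):
            n_codons = int(rng.integers(10, 40))
            codons = []
            while len(codons) < n_codons:
                codon = "".join(rng.choice(list("ACGT"), size=3))
                if codon not in stops:
                    codons.append(codon)
            cds = "".join(codons)
            protein = str(Seq(cds).translate())
            kind = rng.choice(["sub", "del"])
            if kind == "sub":
                i = int(rng.integers(len(cds)))
                new_base = rng.choice([b for b in "ACGT" if b != cds[i]])
                mutated = cds[:i] + new_base + cds[i + 1 :]
                codon_idx = i // 3
                old_aa = protein[codon_idx]
                new_aa = str(
                    Seq(mutated[codon_idx * 3 : codon_idx * 3 + 3]).translate()
                )
                hgvs_p = f"p.{AA3[old_aa]}{codon_idx + 1}" + (
                    "=" if new_aa == old_aa else AA3[new_aa]
                )
                expected = (
                    SYNONYMOUS
                    if new_aa == old_aa
                    else NONSENSE if new_aa == "*" else MISSENSE
                )
                assert classify_mutation_type(hgvs_p) == expected
            else:
                length = int(rng.integers(1, 7))
                start = int(rng.integers(len(cds) - length))
                # oracle: frameshift iff the deleted length is not a codon multiple
                if length % 3 != 0:
                    codon_idx = start // 3
                    hgvs_p = (
                        f"p.{AA3[protein[codon_idx]]}{codon_idx + 1}"
                        f"GlyfsTer{int(rng.integers(2, 40))}"
                    )
                    assert classify_mutation_type(hgvs_p) == FRAMESHIFT
                    hgvs_c = (
                        f"c.{start + 1}del"
                        if length == 1
                        else f"c.{start + 1}_{start + length}del"
                    )
                    assert classify_mutation_type("", hgvs_c) == FRAMESHIFT
                else:
                    hgvs_c = f"c.{start + 1}_{start + length}del"
                    assert classify_mutation_type("", hgvs_c) == INFRAME_DELETION


def catalogue_record(gene, hgvs_c, hgvs_p, significance, af=None):
    return CatalogueVariant(
        chrom="x",
        start=abs(hash((gene, hgvs_c))) % 10000,
        ref="A",
        alt="C",
        gene=gene,
        sources=frozenset({GERMLINE_DB}),
        significance={GERMLINE_DB: significance},
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        population_af=af,
    )


class TestClassifyPathogenicity:
    def test_recorded_pathogenic_wins(self):
        record = catalogue_record("BRCA1", "c.5125_5127delGTT", "p.Val1709del", "Pathogenic")
        obs = ObservedVariant(
            "s1", "BRCA1", "c.5125_5127delGTT", "p.Val1709del",
            tumour_vaf=0.5, catalogue_match=record,
        )
        assert classify_pathogenicity(obs, INFRAME_DELETION, [record]) == PATHOGENIC

    def test_premature_stop_is_pathogenic_even_when_unrecorded(self):
        obs = ObservedVariant("s1", "BRCA2", "c.8614G>T", "p.Glu2872Ter", tumour_vaf=0.4)
        assert classify_pathogenicity(obs, NONSENSE, []) == PATHOGENIC

    def test_same_codon_pathogenic_missense(self):
        record = catalogue_record("BRCA1", "c.5309C>G", "p.Pro1770Arg", "Pathogenic")
        obs = ObservedVariant("s1", "BRCA1", "c.5309C>T", "p.Pro1770Leu", tumour_vaf=0.5)
        assert (
            classify_pathogenicity(obs, MISSENSE, [record])
            == LIKELY_PATHOGENIC_SAME_CODON
        )

    def test_common_majority_benign_polymorphism(self):
        record = catalogue_record(
            "BRCA2", "c.1114A>C", "p.Asn372His", "Benign:4|Pathogenic:1", af=0.25
        )
        obs = ObservedVariant(
            "s1", "BRCA2", "c.1114A>C", "p.Asn372His",
            tumour_vaf=0.5, catalogue_match=record,
        )
        # one pathogenic submitter among four benign must NOT trigger rule 1
        assert classify_pathogenicity(obs, MISSENSE, [record]) == BENIGN

    def test_borderline_frequency_majority_benign(self):
        record = catalogue_record(
            "BRCA1", "c.3119G>A", "p.Ser1040Asn",
            "Benign/Likely_benign:8|Uncertain_significance:1|Pathogenic:1", af=0.01,
        )
        obs = ObservedVariant(
            "s1", "BRCA1", "c.3119G>A", "p.Ser1040Asn",
            tumour_vaf=0.5, catalogue_match=record,
        )
        assert classify_pathogenicity(obs, MISSENSE, [record]) == BENIGN

    def test_everything_else_is_vus(self):
        obs = ObservedVariant("s1", "BRCA1", "c.5309C>T", "p.Pro1770Leu", tumour_vaf=0.5)
        assert classify_pathogenicity(obs, MISSENSE, []) == VUS

    def test_total_function_on_random_inputs(self):
        rng = np.random.default_rng(3)
        classes = {PATHOGENIC, LIKELY_PATHOGENIC_SAME_CODON, BENIGN, VUS}
        for _ in range(100):
            mt = str(rng.choice([FRAMESHIFT, NONSENSE, MISSENSE, SYNONYMOUS, OTHER]))
            obs = ObservedVariant("s", "G", "c.1A>C", "p.Lys2Arg", tumour_vaf=0.5)
            assert classify_pathogenicity(obs, mt, []) in classes


class TestAssignOrigin:
    @pytest.mark.parametrize(
        "tumour,normal,expected",
        [
            (0.46, 0.49, (GERMLINE, HETEROZYGOUS)),
            (0.38, 0.00, (SOMATIC, HETEROZYGOUS)),
            (0.92, 0.51, (GERMLINE, HOMOZYGOUS_OR_LOH)),
            (0.40, 0.10, (UNDETERMINED, HETEROZYGOUS)),
            (0.40, None, (UNDETERMINED, HETEROZYGOUS)),
        ],
    )
    def test_threshold_cases(self, tumour, normal, expected):
        obs = ObservedVariant("s", "G", "c.1A>C", tumour_vaf=tumour, normal_vaf=normal)
        assert assign_origin(obs) == expected

    def test_missing_tumour_vaf_rejected(self):
        with pytest.raises(ValueError):
            assign_origin(ObservedVariant("s", "G", "c.1A>C"))

    @given(
        nv1=st.floats(0, 1, allow_nan=False),
        nv2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_normal_vaf(self, nv1, nv2):
        """Raising the normal VAF can never move a call toward somatic."""
        lo, hi = sorted((nv1, nv2))
        order = {SOMATIC: 0, UNDETERMINED: 1, GERMLINE: 2}
        call_lo = assign_origin(
            ObservedVariant("s", "G", "c.1A>C", tumour_vaf=0.5, normal_vaf=lo)
        )[0]
        call_hi = assign_origin(
            ObservedVariant("s", "G", "c.1A>C", tumour_vaf=0.5, normal_vaf=hi)
        )[0]
        assert order[call_hi] >= order[call_lo]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            OriginConfig(germline_min_normal_vaf=0.1, somatic_max_normal_vaf=0.2)


class TestCohortSummary:
    def test_example_cohort_reproduces_clinical_counts(self):
        observed, catalogue, _ = example_cohort()
        calls = classify_cohort(observed, catalogue)
        summary = cohort_summary(calls, EXAMPLE_COHORT_SIZE)
        assert summary["n_mutated_samples"] == 13
        assert summary["pct_mutated"] == 28
        assert summary["per_gene_counts"] == {"BRCA1": 8, "BRCA2": 5}
        assert summary["mutually_exclusive"] is True

    def test_shared_variant_counts_once_per_sample(self):
        observed, catalogue, _ = example_cohort()
        calls = classify_cohort(observed, catalogue)
        shared = [c for c in calls if c.hgvs_c == "c.2405_2406delTG"]
        assert len(shared) == 2 and len({c.sample_id for c in shared}) == 2

    def test_no_pathogenic_calls_gives_zero_percent(self):
        summary = cohort_summary([], 47)
        assert summary["pct_mutated"] == 0
        assert summary["n_mutated_samples"] == 0

    def test_cohort_size_too_small_rejected(self):
        observed, catalogue, _ = example_cohort()
        calls = classify_cohort(observed, catalogue)
        with pytest.raises(ValueError):
            cohort_summary(calls, 3)


class TestExampleCohortCalls:
    def test_all_thirteen_actionable_and_origins_match(self):
        observed, catalogue, confirmations = example_cohort()
        calls = classify_cohort(observed, catalogue)
        by_case = {(c.sample_id, c.hgvs_c): c for c in calls}
        likely = by_case[("3520", "c.5309C>T")]
        assert likely.classification == LIKELY_PATHOGENIC_SAME_CODON
        somatic_cases = {"3512", "3501", "3516"}
        actionable = [
            c
            for c in calls
            if c.classification in (PATHOGENIC, LIKELY_PATHOGENIC_SAME_CODON)
        ]
        assert len(actionable) == 13
        for c in actionable:
            expected = SOMATIC if c.sample_id in somatic_cases else GERMLINE
            assert c.origin == expected
        benign = [c for c in calls if c.classification == BENIGN]
        assert len(benign) == 3  # the common polymorphisms never count
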