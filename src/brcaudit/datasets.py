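"""Bundled example data: a 47-sample high-grade serous ovarian cancer cohort.

The cohort carries 13 actionable BRCA1/BRCA2 mutations (8 in BRCA1, 5 in
BRCA2; all BRCA1 and two BRCA2 mutations germline, three BRCA2 somatic)
plus a handful of common benign polymorphisms, together with the
knowledge-base records needed to classify them and a Sanger confirmation
table marking every reported mutation as orthogonally confirmed.

The mutation identities (HGVS strings, database status, germline/somatic
labels, submitter tallies, population frequencies) are real clinical
observations for these genes. The tumour/normal allele fractions and the
genomic coordinates attached to the knowledge-base records are SYNTHETIC:
fractions were chosen to be consistent with the recorded germline/somatic
and zygosity labels, and coordinates are placeholders on a synthetic
contig (classification operates on HGVS and annotation only).
"""

from __future__ import annotations

from .catalogue import GERMLINE_DB, Catalogue, CatalogueVariant
from .pathogenicity import ObservedVariant, attach_catalogue_matches

_CHROM = "example"

# gene, hgvs_c, hgvs_p, recorded class (None = absent from the databases),
# population AF (None = rare/unknown)
_CATALOGUE_ROWS = [
    ("BRCA1", "c.5329dupC", "p.Gln1777ProfsTer74", "Pathogenic", None),
    ("BRCA1", "c.676delT", "p.Cys226ValfsTer8", "Pathogenic", None),
    ("BRCA1", "c.1687C>T", "p.Gln563Ter", "Pathogenic", None),
    ("BRCA1", "c.2405_2406delTG", "p.Val802GlufsTer7", "Pathogenic", None),
    ("BRCA1", "c.3767_3768delCA", "p.Thr1256ArgfsTer10", "Pathogenic", None),
    ("BRCA1", "c.5125_5127delGTT", "p.Val1709del", "Pathogenic", None),
    # recorded pathogenic missense sharing codon 1770 with an unrecorded one
    ("BRCA1", "c.5309C>G", "p.Pro1770Arg", "Pathogenic", None),
    ("BRCA2", "c.6202dupA", "p.Ile2068AsnfsTer10", "Pathogenic", None),
    ("BRCA2", "c.7069_7070delCT", "p.Leu2357ValfsTer2", "Pathogenic", None),
    # common polymorphisms with multi-submitter tallies
    (
        "BRCA1",
        "c.3119G>A",
        "p.Ser1040Asn",
        "Benign/Likely_benign:8|Uncertain_significance:1|Pathogenic:1",
        0.01,
    ),
    ("BRCA2", "c.1114A>C", "p.Asn372His", "Benign:4|Pathogenic:1", 0.25),
    ("BRCA2", "c.865A>C", "p.Asn289His", "Benign:7", 0.07),
]

# case, gene, hgvs_c, hgvs_p, tumour VAF, normal VAF (VAFs synthetic,
# consistent with the recorded germline/somatic and zygosity labels)
_OBSERVED_ROWS = [
    ("3506", "BRCA1", "c.5329dupC", "p.Gln1777ProfsTer74", 0.91, 0.49),
    ("3513", "BRCA1", "c.676delT", "p.Cys226ValfsTer8", 0.88, 0.51),
    ("3508", "BRCA1", "c.1687C>T", "p.Gln563Ter", 0.47, 0.50),
    ("3521", "BRCA1", "c.2405_2406delTG", "p.Val802GlufsTer7", 0.52, 0.48),
    ("3528", "BRCA1", "c.2405_2406delTG", "p.Val802GlufsTer7", 0.45, 0.52),
    ("3489", "BRCA1", "c.3767_3768delCA", "p.Thr1256ArgfsTer10", 0.49, 0.50),
    ("3505", "BRCA1", "c.5125_5127delGTT", "p.Val1709del", 0.46, 0.49),
    ("3520", "BRCA1", "c.5309C>T", "p.Pro1770Leu", 0.53, 0.51),
    ("3512", "BRCA2", "c.2813delC", "p.Ala938GlufsTer22", 0.38, 0.00),
    ("3523", "BRCA2", "c.6202dupA", "p.Ile2068AsnfsTer10", 0.50, 0.49),
    ("3514", "BRCA2", "c.6574delA", "p.Met2192TrpfsTer14", 0.89, 0.48),
    ("3501", "BRCA2", "c.7069_7070delCT", "p.Leu2357ValfsTer2", 0.36, 0.01),
    ("3516", "BRCA2", "c.8614G>T", "p.Glu2872Ter", 0.34, 0.02),
    # benign polymorphism carriers
    ("3502", "BRCA1", "c.3119G>A", "p.Ser1040Asn", 0.48, 0.51),
    ("3509", "BRCA2", "c.1114A>C", "p.Asn372His", 0.51, 0.49),
    ("3509", "BRCA2", "c.865A>C", "p.Asn289His", 0.47, 0.50),
]

EXAMPLE_COHORT_SIZE = 47


def example_catalogue() -> Catalogue:
    """Knowledge-base records for the example cohort (synthetic coordinates)."""
    variants = []
    for i, (gene, hgvs_c, hgvs_p, significance, af) in enumerate(_CATALOGUE_ROWS):
        variants.append(
            CatalogueVariant(
                chrom=_CHROM,
                start=1000 + 10 * i,  # synthetic placeholder coordinates
                ref="A",
                alt="C",
                gene=gene,
                sources=frozenset({GERMLINE_DB}),
                significance={GERMLINE_DB: significance},
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                population_af=af,
            )
        )
    return Catalogue(variants)


def example_cohort() -> tuple[list[ObservedVariant], Catalogue, dict[str, bool]]:
    """(observed variants, knowledge-base catalogue, Sanger confirmations).

    Confirmations are keyed by ``(case, hgvs_c)`` joined with ``:`` and
    mark every reported actionable mutation as confirmed.
    """
    catalogue = example_catalogue()
    observed = [
        ObservedVariant(
            sample_id=case,
            gene=gene,
            hgvs_c=hgvs_c,
            hgvs_p=hgvs_p,
            tumour_vaf=tumour_vaf,
            normal_vaf=normal_vaf,
        )
        for case, gene, hgvs_c, hgvs_p, tumour_vaf, normal_vaf in _OBSERVED_ROWS
    ]
    attach_catalogue_matches(observed, catalogue)
    confirmations = {
        f"{case}:{hgvs_c}": True
        for case, gene, hgvs_c, _, _, _ in _OBSERVED_ROWS[:13]
    }
    return observed, catalogue, confirmations
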