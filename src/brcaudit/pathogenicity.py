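"""Mutation-type, pathogenicity and germline/somatic classification.

Observed tumour variants are typed from their HGVS notation, classified
with a deliberately small rule set suited to BRCA1/BRCA2 truncating-
mutation biology — any change producing a premature stop codon
(frameshift or nonsense) is pathogenic regardless of database status —
and assigned a germline or somatic origin from the allele fraction in
matched normal tissue.

The HGVS parser intentionally covers only the constructs that occur in
this problem space (substitutions, del, dup, ins, delins, frameshifts,
Ter, synonymous '='); anything else raises naming the offending token
rather than guessing.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import pct
from .catalogue import Catalogue, CatalogueVariant

# mutation types
FRAMESHIFT = "frameshift"
NONSENSE = "nonsense"
MISSENSE = "missense"
INFRAME_DELETION = "inframe_deletion"
SYNONYMOUS = "synonymous"
OTHER = "other"

# classifications
PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC_SAME_CODON = "likely_pathogenic_same_codon"
BENIGN = "benign"
VUS = "VUS"

# origins
GERMLINE = "germline"
SOMATIC = "somatic"
UNDETERMINED = "undetermined"

# tumour zygosity
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS_OR_LOH = "homozygous_or_LOH"

_AA = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|"
    "Trp|Tyr|Val|Ter"
)
_RE_FS = re.compile(rf"^p\.\(?(?P<ref>{_AA})(?P<codon>\d+)(?:{_AA})?fs(?:Ter(?:\d+|\?))?\)?$")
_RE_SUB = re.compile(rf"^p\.\(?(?P<ref>{_AA})(?P<codon>\d+)(?:(?P<new>{_AA})|(?P<syn>=))\)?$")
_RE_DEL = re.compile(rf"^p\.\(?(?P<ref>{_AA})(?P<codon>\d+)(?:_(?:{_AA})(?:\d+))?del\)?$")
_RE_DUP = re.compile(rf"^p\.\(?({_AA})(\d+)(?:_(?:{_AA})(?:\d+))?dup\)?$")
_RE_DELINS = re.compile(rf"^p\.\(?({_AA})(\d+)(?:_(?:{_AA})(?:\d+))?delins(?:{_AA})+\)?$")
_RE_INS = re.compile(rf"^p\.\(?({_AA})(\d+)_(?:{_AA})(?:\d+)ins(?:{_AA})+\)?$")

_RE_C = re.compile(
    r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?"
    r"(?:(?P<kind>del|dup)(?P<seq1>[ACGT]*)"
    r"|(?P<ins>ins)(?P<seq2>[ACGT]+)"
    r"|(?P<delins>delins)(?P<seq3>[ACGT]+)"
    r"|(?P<from>[ACGT])>(?P<to>[ACGT]))$"
)


@dataclass
class ObservedVariant:
    """One variant observed in a tumour (with optional matched normal)."""

    sample_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str = ""
    tumour_vaf: float | None = None
    normal_vaf: float | None = None
    catalogue_match: CatalogueVariant | None = None

    def __post_init__(self) -> None:
        for vaf in (self.tumour_vaf, self.normal_vaf):
            if vaf is not None and not (0.0 <= vaf <= 1.0):
                raise ValueError(f"allele fraction {vaf} outside [0, 1]")


@dataclass(frozen=True)
class OriginConfig:
    """Allele-fraction thresholds for origin and tumour zygosity calls.

    A variant seen at >= 20% in normal tissue is constitutional
    (germline); one essentially absent from normal (<= 5%, allowing FFPE
    noise) is somatic; in between the evidence is inconclusive. A tumour
    allele fraction >= 85% indicates homozygosity or loss of the
    wild-type allele.
    """

    germline_min_normal_vaf: float = 0.20
    somatic_max_normal_vaf: float = 0.05
    homozygous_min_tumour_vaf: float = 0.85

    def __post_init__(self) -> None:
        if self.somatic_max_normal_vaf >= self.germline_min_normal_vaf:
            raise ValueError("somatic threshold must lie below the germline threshold")


@dataclass(frozen=True)
class PathogenicityCall:
    sample_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    mutation_type: str
    classification: str
    origin: str
    tumour_zygosity: str

    def __post_init__(self) -> None:
        if self.mutation_type in (FRAMESHIFT, NONSENSE) and self.classification not in (
            PATHOGENIC,
        ):
            raise ValueError("premature-stop mutations must classify pathogenic")


def classify_mutation_type(hgvs_p: str, hgvs_c: str = "") -> str:
    """Mutation type from protein (preferred) or coding HGVS notation."""
    p = (hgvs_p or "").strip()
    if p:
        if _RE_FS.match(p):
            return FRAMESHIFT
        m = _RE_SUB.match(p)
        if m:
            if m.group("syn"):
                return SYNONYMOUS
            if m.group("new") == "Ter":
                return NONSENSE
            if m.group("new") == m.group("ref"):
                return SYNONYMOUS
            return MISSENSE
        if _RE_DEL.match(p):
            return INFRAME_DELETION
        if _RE_DUP.match(p) or _RE_DELINS.match(p) or _RE_INS.match(p):
            return OTHER
        raise ValueError(f"unsupported protein HGVS token: {p!r}")
    c = (hgvs_c or "").strip()
    if not c:
        raise ValueError("at least one of hgvs_p / hgvs_c is required")
    m = _RE_C.match(c)
    if not m:
        raise ValueError(f"unsupported coding HGVS token: {c!r}")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    span = end - start + 1
    if m.group("kind") == "del":
        net = -(len(m.group("seq1")) or span)
    elif m.group("kind") == "dup":
        net = len(m.group("seq1")) or span
    elif m.group("ins"):
        net = len(m.group("seq2"))
    elif m.group("delins"):
        net = len(m.group("seq3")) - span
    else:  # substitution with no protein annotation
        return OTHER
    if net % 3 != 0:
        return FRAMESHIFT
    if m.group("kind") == "del":
        return INFRAME_DELETION
    return OTHER


def protein_codon(hgvs_p: str) -> int | None:
    """First affected codon number of a protein HGVS string, if parseable."""
    p = (hgvs_p or "").strip()
    for regex in (_RE_SUB, _RE_FS, _RE_DEL):
        m = regex.match(p)
        if m:
            return int(m.group("codon"))
    for regex in (_RE_DUP, _RE_DELINS, _RE_INS):
        m = regex.match(p)
        if m:
            return int(m.group(2))
    return None


def _is_missense_hgvs(hgvs_p: str) -> bool:
    m = _RE_SUB.match((hgvs_p or "").strip())
    return bool(
        m and not m.group("syn") and m.group("new") not in ("Ter", m.group("ref"))
    )


def _submitter_tallies(variant: CatalogueVariant) -> tuple[int, int]:
    """(pathogenic, benign) submitter tallies over all per-source strings.

    Accepts both plain class strings ("Pathogenic") and tallied
    multi-submitter strings ("Benign/Likely_benign:8|Uncertain:1|Pathogenic:1").
    """
    pathogenic = benign = 0
    for text in variant.significance.values():
        for token in re.split(r"[|;,]", text):
            token = token.strip()
            if not token:
                continue
            cls, _, count_text = token.rpartition(":")
            if cls and count_text.isdigit():
                count = int(count_text)
            else:
                cls, count = token, 1
            cls_lower = cls.lower()
            if "conflicting" in cls_lower:
                continue
            if "pathogenic" in cls_lower:
                pathogenic += count
            if "benign" in cls_lower:
                benign += count
    return pathogenic, benign


def is_pathogenic_record(variant: CatalogueVariant) -> bool:
    """Recorded pathogenic: strictly more pathogenic than benign submissions."""
    pathogenic, benign = _submitter_tallies(variant)
    return pathogenic > 0 and pathogenic > benign


def is_majority_benign(variant: CatalogueVariant) -> bool:
    pathogenic, benign = _submitter_tallies(variant)
    return benign > pathogenic


def classify_pathogenicity(
    variant: ObservedVariant,
    mutation_type: str,
    catalogue: Catalogue | Sequence[CatalogueVariant],
) -> str:
    """Ordered classification rules; every variant gets exactly one class.

    1. recorded pathogenic in a catalogue -> pathogenic;
    2. frameshift or nonsense (premature stop codon) -> pathogenic;
    3. unrecorded missense sharing a codon with a recorded pathogenic
       missense -> likely pathogenic (same-codon argument);
    4. common (population AF >= 1%) and majority-benign -> benign;
    5. otherwise a variant of uncertain significance.
    """
    match = variant.catalogue_match
    if match is not None and is_pathogenic_record(match):
        return PATHOGENIC
    if mutation_type in (FRAMESHIFT, NONSENSE):
        return PATHOGENIC
    if mutation_type == MISSENSE and match is None:
        codon = protein_codon(variant.hgvs_p)
        if codon is not None:
            for cv in catalogue:
                if (
                    cv.gene == variant.gene
                    and _is_missense_hgvs(cv.hgvs_p)
                    and protein_codon(cv.hgvs_p) == codon
                    and cv.hgvs_p != variant.hgvs_p
                    and is_pathogenic_record(cv)
                ):
                    return LIKELY_PATHOGENIC_SAME_CODON
    if (
        match is not None
        and match.population_af is not None
        and match.population_af >= 0.01
        and is_majority_benign(match)
    ):
        return BENIGN
    return VUS


def assign_origin(
    variant: ObservedVariant, config: OriginConfig | None = None
) -> tuple[str, str]:
    """(origin, tumour_zygosity) from tumour and matched-normal VAFs."""
    config = config or OriginConfig()
    if variant.tumour_vaf is None:
        raise ValueError("origin assignment requires a tumour allele fraction")
    zygosity = (
        HOMOZYGOUS_OR_LOH
        if variant.tumour_vaf >= config.homozygous_min_tumour_vaf
        else HETEROZYGOUS
    )
    nv = variant.normal_vaf
    if nv is None:
        origin = UNDETERMINED
    elif nv >= config.germline_min_normal_vaf:
        origin = GERMLINE
    elif nv <= config.somatic_max_normal_vaf:
        origin = SOMATIC
    else:
        origin = UNDETERMINED
    return origin, zygosity


def classify_cohort(
    observed: Iterable[ObservedVariant],
    catalogue: Catalogue | Sequence[CatalogueVariant],
    origin_config: OriginConfig | None = None,
) -> list[PathogenicityCall]:
    """Full per-variant classification of an observed cohort."""
    calls = []
    for variant in observed:
        mutation_type = classify_mutation_type(variant.hgvs_p, variant.hgvs_c)
        classification = classify_pathogenicity(variant, mutation_type, catalogue)
        origin, zygosity = assign_origin(variant, origin_config)
        calls.append(
            PathogenicityCall(
                sample_id=variant.sample_id,
                gene=variant.gene,
                hgvs_c=variant.hgvs_c,
                hgvs_p=variant.hgvs_p,
                mutation_type=mutation_type,
                classification=classification,
                origin=origin,
                tumour_zygosity=zygosity,
            )
        )
    return calls


def cohort_summary(
    calls: Sequence[PathogenicityCall], cohort_size: int
) -> dict[str, object]:
    """Cohort-level counts of samples carrying actionable mutations.

    A sample counts as mutated when it carries at least one pathogenic or
    same-codon likely-pathogenic call; the percentage is rounded half-up
    to an integer. ``mutually_exclusive`` reports whether no sample has
    mutations in more than one gene.
    """
    distinct_samples = {c.sample_id for c in calls}
    if cohort_size < len(distinct_samples):
        raise ValueError(
            f"cohort_size {cohort_size} below the {len(distinct_samples)} "
            "distinct samples observed"
        )
    actionable = [
        c
        for c in calls
        if c.classification in (PATHOGENIC, LIKELY_PATHOGENIC_SAME_CODON)
    ]
    mutated_samples = sorted({c.sample_id for c in actionable})
    per_gene = Counter(c.gene for c in actionable)
    genes_by_sample: dict[str, set[str]] = {}
    for c in actionable:
        genes_by_sample.setdefault(c.sample_id, set()).add(c.gene)
    mutually_exclusive = all(len(g) <= 1 for g in genes_by_sample.values())
    return {
        "n_mutated_samples": len(mutated_samples),
        "mutated_samples": mutated_samples,
        "per_gene_counts": dict(sorted(per_gene.items())),
        "pct_mutated": pct(len(mutated_samples), cohort_size, ndigits=0),
        "mutually_exclusive": mutually_exclusive,
        "n_actionable_calls": len(actionable),
    }


def attach_catalogue_matches(
    observed: Iterable[ObservedVariant],
    catalogue: Catalogue | Sequence[CatalogueVariant],
) -> list[ObservedVariant]:
    """Link observed variants to catalogue records by (gene, hgvs_c)."""
    by_hgvs = {(cv.gene, cv.hgvs_c): cv for cv in catalogue if cv.hgvs_c}
    out = []
    for variant in observed:
        if variant.catalogue_match is None:
            variant.catalogue_match = by_hgvs.get((variant.gene, variant.hgvs_c))
        out.append(variant)
    return out


def write_calls_tsv(calls: Iterable[PathogenicityCall], path: str | Path) -> None:
    """Emit a clinical-table-shaped TSV of per-case calls."""
    rows = [
        {
            "case": c.sample_id,
            "gene": c.gene,
            "hgvs_c": c.hgvs_c,
            "hgvs_p": c.hgvs_p,
            "mutation_type": c.mutation_type,
            "origin": c.origin,
            "tumour_zygosity": c.tumour_zygosity,
            "classification": c.classification,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observed_tsv(path: str | Path) -> list[ObservedVariant]:
    """Read observed variants from TSV with columns
    sample_id, gene, hgvs_c, hgvs_p, tumour_vaf, normal_vaf."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    observed = []
    for row in frame.itertuples():
        observed.append(
            ObservedVariant(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                hgvs_c=str(row.hgvs_c),
                hgvs_p=str(row.hgvs_p),
                tumour_vaf=float(row.tumour_vaf) if row.tumour_vaf != "" else None,
                normal_vaf=float(row.normal_vaf) if row.normal_vaf != "" else None,
            )
        )
    return observed
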