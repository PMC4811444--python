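"""Variant catalogues: reading, normalisation, and merging.

A catalogue is the deduplicated list of knowledge-base variants (one
germline-oriented source such as ClinVar, one somatic-oriented source such
as COSMIC) that drives the callability audit. Variants from both sources
are left-normalised against the same reference so that equivalent indel
representations collapse onto a single key ``(chrom, start, ref, alt)``;
the per-source significance annotations are retained side by side rather
than reconciled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping
from urllib.parse import quote, unquote

import pysam

from .reference_panel import GenomicInterval

logger = logging.getLogger(__name__)

GERMLINE_DB = "GERMLINE_DB"
SOMATIC_DB = "SOMATIC_DB"

MAX_INDEL_LEN = 100  # catalogues are restricted to SNVs and small (<100 bp) indels

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class CatalogueVariant:
    """One knowledge-base variant in VCF-style (anchored) representation."""

    chrom: str
    start: int  # 0-based position of the first ref base
    ref: str
    alt: str
    gene: str
    sources: frozenset[str] = frozenset()
    significance: Mapping[str, str] = field(default_factory=dict)
    hgvs_c: str = ""
    hgvs_p: str = ""
    population_af: float | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.start}")
        bad = set(self.ref + self.alt) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT allele characters {sorted(bad)}")
        if abs(len(self.ref) - len(self.alt)) > MAX_INDEL_LEN:
            raise ValueError("indel longer than the catalogue size limit")
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise ValueError("population_af must lie in [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.start, self.ref, self.alt)

    @property
    def end(self) -> int:
        return self.start + len(self.ref)

    @property
    def locus(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def var_type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt) and self.alt.startswith(self.ref):
            return "INS"
        if len(self.alt) < len(self.ref) and self.ref.startswith(self.alt):
            return "DEL"
        return "DELINS"


class Catalogue:
    """An ordered, key-unique collection of catalogue variants."""

    def __init__(self, variants: Iterable[CatalogueVariant] = ()):
        self._by_key: dict[VariantKey, CatalogueVariant] = {}
        for v in variants:
            if v.key in self._by_key:
                raise ValueError(f"duplicate catalogue key {v.key}")
            self._by_key[v.key] = v

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[CatalogueVariant]:
        return iter(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def get(self, key: VariantKey) -> CatalogueVariant | None:
        return self._by_key.get(key)

    @property
    def variants(self) -> list[CatalogueVariant]:
        return sorted(self._by_key.values(), key=lambda v: v.key)

    @property
    def per_source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self._by_key.values():
            for src in v.sources:
                counts[src] = counts.get(src, 0) + 1
        return counts

    @property
    def genes(self) -> set[str]:
        return {v.gene for v in self._by_key.values()}


def left_normalize(
    variant: CatalogueVariant, reference: Mapping[str, str]
) -> CatalogueVariant:
    """Shift a variant to its leftmost minimal representation.

    Classic left-alignment: repeatedly trim a shared terminal base and,
    whenever an allele would empty, re-anchor one reference base to the
    left; finally trim shared leading bases. SNVs pass through unchanged
    and the operation is idempotent.
    """
    seq = reference[variant.chrom]
    pos, ref, alt = variant.start, variant.ref, variant.alt
    if seq[pos : pos + len(ref)] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match reference at {variant.chrom}:{pos}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 0:
                break  # cannot re-anchor past the sequence start
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                base = seq[pos]
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (pos, ref, alt) == (variant.start, variant.ref, variant.alt):
        return variant
    return replace(variant, start=pos, ref=ref, alt=alt)


def merge_catalogues(a: Catalogue, b: Catalogue) -> Catalogue:
    """Key-wise union of two normalised catalogues.

    Variants sharing a key carry the union of source tags and the merged
    per-source significance annotations; ``|union| = |a| + |b| - |overlap|``.
    """
    merged: dict[VariantKey, CatalogueVariant] = {v.key: v for v in a}
    for v in b:
        existing = merged.get(v.key)
        if existing is None:
            merged[v.key] = v
            continue
        if existing.gene != v.gene:
            raise ValueError(
                f"conflicting gene labels {existing.gene!r} vs {v.gene!r} "
                f"for variant {v.key}"
            )
        significance = dict(existing.significance)
        significance.update(v.significance)
        merged[v.key] = replace(
            existing,
            sources=existing.sources | v.sources,
            significance=significance,
            hgvs_c=existing.hgvs_c or v.hgvs_c,
            hgvs_p=existing.hgvs_p or v.hgvs_p,
            population_af=(
                existing.population_af
                if existing.population_af is not None
                else v.population_af
            ),
        )
    return Catalogue(merged.values())


def flag_out_of_design(
    catalogue: Catalogue,
    exons: Iterable[GenomicInterval],
    junction_bp: int = 50,
) -> set[VariantKey]:
    """Keys of variants whose span leaves the exon intervals +- junction_bp.

    Such variants are outside the design footprint of an exon+junction
    panel; they are flagged, not removed.
    """
    padded = [
        GenomicInterval(e.chrom, max(0, e.start - junction_bp), e.end + junction_bp)
        for e in exons
    ]
    flagged = set()
    for v in catalogue:
        if not any(iv.contains(v.locus) for iv in padded):
            flagged.add(v.key)
    return flagged


# ---------------------------------------------------------------------------
# VCF and hotspot I/O
# ---------------------------------------------------------------------------


def _encode_significance(significance: Mapping[str, str]) -> str:
    return quote(json.dumps(dict(significance), sort_keys=True), safe="")


def _decode_significance(raw: str, default_source: str) -> dict[str, str]:
    text = unquote(raw)
    try:
        decoded = json.loads(text)
        if isinstance(decoded, dict):
            return {str(k): str(v) for k, v in decoded.items()}
    except json.JSONDecodeError:
        pass
    return {default_source: text}


def read_catalogue_vcf(
    path: str | Path,
    source: str,
    reference: Mapping[str, str],
    significance_key: str = "SIG",
    af_key: str = "AF",
    gene_key: str = "GENE",
) -> Catalogue:
    """Read one source catalogue from VCF, normalising as it goes.

    Multi-allelic records are split one variant per alt; coordinates are
    converted to the internal 0-based convention; records whose REF
    disagrees with the reference sequence are rejected with a logged
    warning, as are symbolic alleles.
    """
    variants: dict[VariantKey, CatalogueVariant] = {}
    n_rejected = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.chrom not in reference:
                n_rejected += 1
                logger.warning("record on unknown sequence %s rejected", rec.chrom)
                continue
            ref = (rec.ref or "").upper()
            start = rec.start  # pysam exposes the 0-based start
            if reference[rec.chrom][start : start + len(ref)] != ref:
                n_rejected += 1
                logger.warning(
                    "REF mismatch at %s:%d rejected", rec.chrom, rec.pos
                )
                continue
            info = dict(rec.info)
            gene = info.get(gene_key, "")
            if isinstance(gene, tuple):
                gene = gene[0] or ""
            raw_sig = info.get(significance_key)
            if isinstance(raw_sig, tuple):
                raw_sig = raw_sig[0]
            significance = (
                _decode_significance(str(raw_sig), source) if raw_sig else {}
            )
            af = info.get(af_key)
            if isinstance(af, tuple):
                af = af[0]
            raw_sources = info.get("SRC")
            if isinstance(raw_sources, tuple):
                raw_sources = ",".join(raw_sources)
            sources = (
                frozenset(str(raw_sources).split(","))
                if raw_sources
                else frozenset({source})
            )
            hgvs_c = str(info.get("HGVSC") or "")
            hgvs_p = str(info.get("HGVSP") or "")
            for alt in rec.alts or ():
                alt = alt.upper()
                if set(alt) - set("ACGT"):
                    n_rejected += 1
                    logger.warning(
                        "symbolic/non-ACGT alt at %s:%d rejected", rec.chrom, rec.pos
                    )
                    continue
                try:
                    variant = left_normalize(
                        CatalogueVariant(
                            chrom=rec.chrom,
                            start=start,
                            ref=ref,
                            alt=alt,
                            gene=str(gene),
                            sources=sources,
                            significance=significance,
                            hgvs_c=hgvs_c,
                            hgvs_p=hgvs_p,
                            # round away float32 noise introduced by VCF storage
                            population_af=round(float(af), 6) if af is not None else None,
                        ),
                        reference,
                    )
                except ValueError as exc:
                    n_rejected += 1
                    logger.warning("record at %s:%d rejected: %s", rec.chrom, rec.pos, exc)
                    continue
                if variant.key in variants:
                    logger.warning("duplicate key %s after normalisation", variant.key)
                    continue
                variants[variant.key] = variant
    if n_rejected:
        logger.warning("%d records rejected while reading %s", n_rejected, path)
    return Catalogue(variants.values())


def write_catalogue_vcf(
    catalogue: Catalogue,
    path: str | Path,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write a catalogue as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("SRC", 1, "String", "Comma-joined source database tags")
    header.info.add("SIG", 1, "String", "Percent-encoded per-source significance")
    header.info.add("AF", 1, "Float", "Population allele frequency")
    header.info.add("HGVSC", 1, "String", "Coding HGVS")
    header.info.add("HGVSP", 1, "String", "Protein HGVS")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in catalogue:
            rec = out.new_record(
                contig=v.chrom, start=v.start, alleles=(v.ref, v.alt)
            )
            rec.info["GENE"] = v.gene
            rec.info["SRC"] = ",".join(sorted(v.sources))
            if v.significance:
                rec.info["SIG"] = _encode_significance(v.significance)
            if v.population_af is not None:
                rec.info["AF"] = v.population_af
            if v.hgvs_c:
                rec.info["HGVSC"] = v.hgvs_c
            if v.hgvs_p:
                rec.info["HGVSP"] = v.hgvs_p
            out.write(rec)


def write_hotspot_tsv(catalogue: Catalogue, path: str | Path) -> None:
    """Export the hotspot list (gene, chrom, 1-based pos, ref, alt, sources)."""
    with open(path, "w") as handle:
        handle.write("gene\tchrom\tpos\tref\talt\tsources\n")
        for v in catalogue:
            handle.write(
                f"{v.gene}\t{v.chrom}\t{v.start + 1}\t{v.ref}\t{v.alt}\t"
                f"{','.join(sorted(v.sources))}\n"
            )
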