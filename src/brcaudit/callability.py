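"""Hotspot-forced callability classification.

For every catalogue variant the caller is *forced* to evaluate the locus:
the outcome is REFERENCE, VARIANT, or NOCALL, and every locus is assigned
a review tier:

AUTOMATIC
    the software alone resolves the locus;
REVIEW
    the locus is resolvable but only with human inspection of the
    alignments (modelled here as a tier plus an optional override table);
UNCALLABLE
    no amount of inspection helps — the locus is outside every amplicon
    insert, or the variant is a short pure-repeat indel inside a long
    homopolymer run, where flow-sequencer error is indistinguishable
    from signal.

The decision procedure is deterministic and ordered: context rules first
(coverage, homopolymer indel), then per-pileup quality rules (depth,
strand balance, base/mapping quality, noise-band allele fraction), then
context-proximity rules that demote an otherwise clean call to REVIEW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .catalogue import Catalogue, CatalogueVariant, VariantKey
from .reference_panel import (
    AmpliconPanel,
    ContextConfig,
    ContextFlags,
    GenomicInterval,
    annotate_context,
    covered_regions,
    find_homopolymers,
)

logger = logging.getLogger(__name__)

# statuses
REFERENCE = "REFERENCE"
VARIANT = "VARIANT"
NOCALL = "NOCALL"

# tiers, worst to best
UNCALLABLE = "UNCALLABLE"
REVIEW = "REVIEW"
AUTOMATIC = "AUTOMATIC"
_TIER_RANK = {AUTOMATIC: 0, REVIEW: 1, UNCALLABLE: 2}

# machine-readable no-call / demotion reasons
NOT_COVERED = "not_covered"
HOMOPOLYMER_INDEL = "homopolymer_indel"
NEAR_HOMOPOLYMER = "near_homopolymer"
STRAND_BIAS = "strand_bias"
LOW_BASE_QUALITY = "low_base_quality"
LOW_DEPTH = "low_depth"
NOISY = "noisy"
POOR_MAPPING = "poor_mapping"
AMPLICON_END = "amplicon_end"
BLACKLIST = "blacklist"


@dataclass(frozen=True)
class PileupColumn:
    """Per-locus pileup summary.

    ``allele_counts`` maps allele keys to (forward, reverse) read counts.
    Allele keys: the base itself for substitution alleles, ``+SEQ`` for
    insertions and ``-SEQ`` for deletions (relative to the anchored
    VCF-style representation).
    """

    chrom: str
    pos: int  # 0-based
    allele_counts: Mapping[str, tuple[int, int]]
    mean_base_quality: float = 30.0
    mean_mapping_quality: float = 50.0

    def __post_init__(self) -> None:
        for allele, (fwd, rev) in self.allele_counts.items():
            if fwd < 0 or rev < 0:
                raise ValueError(f"negative read count for allele {allele!r}")

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.allele_counts.values())

    def counts(self, allele: str) -> tuple[int, int]:
        return tuple(self.allele_counts.get(allele, (0, 0)))  # type: ignore[return-value]


@dataclass(frozen=True)
class CallerConfig:
    """Quality thresholds of the forced-call classifier.

    min_depth defaults to 100 reads: loci below the panel's routinely
    attained 100x coverage floor are not trusted to an automatic call.
    noise_vaf_band brackets allele fractions too high for clean reference
    but too low for a confident heterozygous variant.
    """

    min_depth: int = 100
    min_vaf: float = 0.05
    min_base_quality: float = 20.0
    min_mapping_quality: float = 20.0
    strand_bias_alpha: float = 0.001
    noise_vaf_band: tuple[float, float] = (0.02, 0.05)

    def __post_init__(self) -> None:
        if not (0 < self.min_vaf < 1):
            raise ValueError("min_vaf must lie in (0, 1)")
        low, high = self.noise_vaf_band
        if not (0 <= low < high <= 1):
            raise ValueError("noise_vaf_band must satisfy 0 <= low < high <= 1")


@dataclass(frozen=True)
class CallabilityResult:
    variant: CatalogueVariant
    status: str
    tier: str
    reasons: frozenset[str] = frozenset()
    #: fraction of samples in which the locus was NOCALL (multi-sample audits)
    no_call_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.tier == UNCALLABLE and not (
            self.reasons & {NOT_COVERED, HOMOPOLYMER_INDEL}
        ):
            raise ValueError("UNCALLABLE requires a coverage or homopolymer reason")
        if self.tier == AUTOMATIC and self.reasons:
            raise ValueError("AUTOMATIC results carry no reasons")


def strand_balance_test(
    forward_ref: int, reverse_ref: int, forward_alt: int, reverse_alt: int
) -> float:
    """Two-sided Fisher exact p-value for strand x allele independence."""
    counts = (forward_ref, reverse_ref, forward_alt, reverse_alt)
    if any(c < 0 for c in counts):
        raise ValueError("read counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("strand balance of an empty table is undefined")
    table = [[forward_ref, reverse_ref], [forward_alt, reverse_alt]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pileup_allele_key(variant: CatalogueVariant) -> str:
    """Pileup allele key under which reads supporting ``variant`` appear."""
    vt = variant.var_type
    if vt == "INS":
        return "+" + variant.alt[len(variant.ref):]
    if vt == "DEL":
        return "-" + variant.ref[len(variant.alt):]
    return variant.alt


def _is_homopolymer_indel(
    variant: CatalogueVariant, context: ContextFlags, config: ContextConfig
) -> bool:
    """Short pure-repeat indel extending/contracting a long adjacent run."""
    if context.hp_run is None or context.hp_run.length < config.min_homopolymer_len:
        return False
    vt = variant.var_type
    if vt == "INS":
        indel_seq = variant.alt[len(variant.ref):]
    elif vt == "DEL":
        indel_seq = variant.ref[len(variant.alt):]
    else:
        return False
    return (
        1 <= len(indel_seq) <= config.max_hp_indel_len
        and set(indel_seq) == {context.hp_run.base}
    )


def evaluate_hotspot(
    variant: CatalogueVariant,
    pileup: PileupColumn | None,
    context: ContextFlags,
    config: CallerConfig | None = None,
    context_config: ContextConfig | None = None,
) -> CallabilityResult:
    """Forced evaluation of one catalogue variant at its locus."""
    config = config or CallerConfig()
    context_config = context_config or ContextConfig()

    # rule 1: outside every amplicon insert — nothing to evaluate
    if context.uncovered:
        return CallabilityResult(variant, NOCALL, UNCALLABLE, frozenset({NOT_COVERED}))

    # rule 2: pure-repeat indel in a long homopolymer run
    if _is_homopolymer_indel(variant, context, context_config):
        return CallabilityResult(
            variant, NOCALL, UNCALLABLE, frozenset({HOMOPOLYMER_INDEL})
        )

    # rule 3: pileup quality failures
    if pileup is None or pileup.depth == 0:
        return CallabilityResult(variant, NOCALL, REVIEW, frozenset({LOW_DEPTH}))
    depth = pileup.depth
    alt_key = pileup_allele_key(variant)
    fwd_alt, rev_alt = pileup.counts(alt_key)
    alt_total = fwd_alt + rev_alt
    vaf = alt_total / depth

    reasons: set[str] = set()
    if depth < config.min_depth:
        reasons.add(LOW_DEPTH)
    if alt_total > 0:
        if fwd_alt == 0 or rev_alt == 0:
            reasons.add(STRAND_BIAS)
        else:
            fwd_ref, rev_ref = pileup.counts(variant.ref[0])
            if (
                strand_balance_test(fwd_ref, rev_ref, fwd_alt, rev_alt)
                < config.strand_bias_alpha
            ):
                reasons.add(STRAND_BIAS)
    if pileup.mean_base_quality < config.min_base_quality:
        reasons.add(LOW_BASE_QUALITY)
    if pileup.mean_mapping_quality < config.min_mapping_quality:
        reasons.add(POOR_MAPPING)
    low, high = config.noise_vaf_band
    if low <= vaf < high:
        reasons.add(NOISY)
    if reasons:
        return CallabilityResult(variant, NOCALL, REVIEW, frozenset(reasons))

    status = VARIANT if vaf >= config.min_vaf else REFERENCE

    # rule 4: clean pileup in a context that demands human review
    demote: set[str] = set()
    if context.near_homopolymer:
        demote.add(NEAR_HOMOPOLYMER)
    if context.near_amplicon_end:
        demote.add(AMPLICON_END)
    if context.in_blacklist:
        demote.add(BLACKLIST)
    if demote:
        return CallabilityResult(variant, status, REVIEW, frozenset(demote))

    # rule 5: fully automatic call
    return CallabilityResult(variant, status, AUTOMATIC)


PileupSource = Mapping[tuple[str, int], PileupColumn]


def audit_catalogue(
    catalogue: Catalogue,
    pileups: PileupSource | Sequence[PileupSource],
    panel: AmpliconPanel,
    reference: Mapping[str, str],
    config: CallerConfig | None = None,
    context_config: ContextConfig | None = None,
    runs=None,
    blacklist: Sequence[GenomicInterval] = (),
) -> list[CallabilityResult]:
    """Audit every catalogue variant against one or more sample pileups.

    ``pileups`` is either one mapping ``(chrom, 0-based pos) -> PileupColumn``
    or a sequence of such mappings (one per sample). With several samples a
    variant's panel-level tier is the worst tier observed in any sample and
    ``no_call_frequency`` records how often the locus was NOCALL.
    """
    config = config or CallerConfig()
    context_config = context_config or ContextConfig()
    if isinstance(pileups, Mapping):
        samples: list[PileupSource] = [pileups]
    else:
        samples = list(pileups)
    if not samples:
        raise ValueError("audit requires at least one sample pileup source")
    if runs is None:
        runs = []
        for chrom, seq in reference.items():
            runs.extend(
                find_homopolymers(seq, context_config.min_homopolymer_len, chrom)
            )
    covered = covered_regions(panel)

    results: list[CallabilityResult] = []
    for variant in catalogue:
        context = annotate_context(
            variant.locus, panel, runs, context_config, blacklist, covered=covered
        )
        per_sample: list[CallabilityResult] = []
        for sample in samples:
            pileup = sample.get((variant.chrom, variant.start))
            if pileup is None and not context.uncovered:
                logger.warning(
                    "missing pileup at covered locus %s:%d",
                    variant.chrom,
                    variant.start,
                )
                per_sample.append(
                    CallabilityResult(variant, NOCALL, REVIEW, frozenset({LOW_DEPTH}))
                )
                continue
            per_sample.append(
                evaluate_hotspot(variant, pileup, context, config, context_config)
            )
        worst = max(per_sample, key=lambda r: _TIER_RANK[r.tier])
        reasons = frozenset().union(
            *(r.reasons for r in per_sample if r.tier == worst.tier)
        )
        n_nocall = sum(1 for r in per_sample if r.status == NOCALL)
        results.append(
            CallabilityResult(
                variant,
                worst.status,
                worst.tier,
                reasons,
                no_call_frequency=n_nocall / len(per_sample),
            )
        )
    return results


def apply_overrides(
    results: Iterable[CallabilityResult],
    overrides: Mapping[VariantKey, str],
) -> list[CallabilityResult]:
    """Merge a human-review override table (variant key -> resolved status).

    Overrides model the outcome of visual alignment inspection: they
    resolve the *status* of REVIEW-tier loci but never change the tier —
    a locus that needed review still counts as review-tier in reports.
    """
    out = []
    for r in results:
        status = overrides.get(r.variant.key)
        if status is not None and r.tier != UNCALLABLE:
            if status not in (REFERENCE, VARIANT, NOCALL):
                raise ValueError(f"invalid override status {status!r}")
            r = CallabilityResult(
                r.variant, status, r.tier, r.reasons, r.no_call_frequency
            )
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def write_results_tsv(results: Iterable[CallabilityResult], path: str | Path) -> None:
    rows = [
        {
            "gene": r.variant.gene,
            "chrom": r.variant.chrom,
            "pos": r.variant.start + 1,
            "ref": r.variant.ref,
            "alt": r.variant.alt,
            "status": r.status,
            "tier": r.tier,
            "reasons": ";".join(sorted(r.reasons)),
            "no_call_frequency": (
                "" if r.no_call_frequency is None else f"{r.no_call_frequency:.4f}"
            ),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_overrides_tsv(path: str | Path) -> dict[VariantKey, str]:
    """Read a 2-column override TSV: ``chrom:pos:ref:alt`` (1-based), status."""
    overrides: dict[VariantKey, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key_text, status = line.split("\t")
            chrom, pos, ref, alt = key_text.split(":")
            overrides[(chrom, int(pos) - 1, ref, alt)] = status
    return overrides


def write_pileups_tsv(pileups: PileupSource, path: str | Path) -> None:
    """One row per allele: chrom, 1-based pos, allele, fwd, rev, mean_bq, mean_mq."""
    with open(path, "w") as handle:
        handle.write("chrom\tpos\tallele\tfwd\trev\tmean_bq\tmean_mq\n")
        for (chrom, pos), col in sorted(pileups.items()):
            if not col.allele_counts:
                handle.write(
                    f"{chrom}\t{pos + 1}\t.\t0\t0\t"
                    f"{col.mean_base_quality:.2f}\t{col.mean_mapping_quality:.2f}\n"
                )
            for allele, (fwd, rev) in sorted(col.allele_counts.items()):
                handle.write(
                    f"{chrom}\t{pos + 1}\t{allele}\t{fwd}\t{rev}\t"
                    f"{col.mean_base_quality:.2f}\t{col.mean_mapping_quality:.2f}\n"
                )


def read_pileups_tsv(path: str | Path) -> dict[tuple[str, int], PileupColumn]:
    frame = pd.read_csv(path, sep="\t", dtype={"allele": str})
    pileups: dict[tuple[str, int], PileupColumn] = {}
    for (chrom, pos), group in frame.groupby(["chrom", "pos"], sort=True):
        counts = {
            str(row.allele): (int(row.fwd), int(row.rev))
            for row in group.itertuples()
            if str(row.allele) != "." and not (row.fwd == 0 and row.rev == 0)
        }
        pileups[(str(chrom), int(pos) - 1)] = PileupColumn(
            chrom=str(chrom),
            pos=int(pos) - 1,
            allele_counts=counts,
            mean_base_quality=float(group.mean_bq.iloc[0]),
            mean_mapping_quality=float(group.mean_mq.iloc[0]),
        )
    return pileups
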