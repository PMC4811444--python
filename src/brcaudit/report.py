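"""Panel-level report: per-gene callability, sensitivity, Sanger workload.

Definitions follow assay-validation usage, not the epidemiological ones:

sensitivity
    fraction of catalogue variants the panel could detect,
    ``100 x (total - uncallable) / total``;
specificity
    fraction of reported variants confirmed by an orthogonal method
    (Sanger), undefined when nothing was reported.

All percentages are rounded half-up to one decimal. Note that half-up is
a single consistent rule; published tables produced with other software
occasionally mix rounding conventions, so isolated one-ulp differences
against external tables are expected and documented rather than chased.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import pct
from .callability import (
    AUTOMATIC,
    HOMOPOLYMER_INDEL,
    NOT_COVERED,
    REVIEW,
    UNCALLABLE,
    CallabilityResult,
)
from .catalogue import Catalogue, VariantKey
from .reference_panel import Transcript
from .sanger_plan import PlanConfig, full_gene_reactions, rescue_reactions

NOT_APPLICABLE = None


@dataclass(frozen=True)
class ReportRow:
    gene: str
    coding_bp: int
    n_source_a: int
    n_source_b: int
    n_total: int
    n_sanger_full_gene: int
    n_automatic: int
    n_review: int
    n_uncallable: int
    sensitivity_pct: float

    def __post_init__(self) -> None:
        if self.n_automatic + self.n_review + self.n_uncallable != self.n_total:
            raise ValueError(
                f"tier counts do not partition the total in row {self.gene!r}"
            )


@dataclass(frozen=True)
class PanelReport:
    rows: tuple[ReportRow, ...]
    total: ReportRow
    pct_automatic: float
    pct_review: float
    pct_uncallable: float
    pct_challenging: float  # review + uncallable
    pct_hp_indel_uncallable: float
    pct_unamplifiable: float
    specificity_pct: float | None
    n_rescue_reactions: int
    source_a: str = "GERMLINE_DB"
    source_b: str = "SOMATIC_DB"

    def to_frame(self) -> pd.DataFrame:
        rows = [*self.rows, self.total]
        return pd.DataFrame(
            {
                "gene": [r.gene for r in rows],
                "coding_bp": [r.coding_bp for r in rows],
                f"n_{self.source_a}": [r.n_source_a for r in rows],
                f"n_{self.source_b}": [r.n_source_b for r in rows],
                "n_total": [r.n_total for r in rows],
                "n_sanger_full_gene": [r.n_sanger_full_gene for r in rows],
                "n_automatic": [r.n_automatic for r in rows],
                "n_review": [r.n_review for r in rows],
                "n_uncallable": [r.n_uncallable for r in rows],
                "sensitivity_pct": [r.sensitivity_pct for r in rows],
            }
        )

    def overall(self) -> dict[str, object]:
        return {
            "pct_automatic": self.pct_automatic,
            "pct_review": self.pct_review,
            "pct_uncallable": self.pct_uncallable,
            "pct_challenging": self.pct_challenging,
            "pct_hp_indel_uncallable": self.pct_hp_indel_uncallable,
            "pct_unamplifiable": self.pct_unamplifiable,
            "specificity_pct": self.specificity_pct,
            "n_rescue_reactions": self.n_rescue_reactions,
        }

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.overall(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    def to_text(self) -> str:
        lines = [
            "Panel callability report",
            "(specificity = confirmed fraction of reported positives against an "
            "orthogonal method; percentages rounded half-up to one decimal)",
            "",
            self.to_frame().to_string(index=False),
            "",
        ]
        for key, value in self.overall().items():
            lines.append(f"{key}: {'NA' if value is None else value}")
        return "\n".join(lines) + "\n"


def sensitivity(n_total: int, n_uncallable: int) -> float:
    """Percentage of catalogue variants the panel could detect."""
    if n_total <= 0:
        raise ValueError("sensitivity of an empty catalogue is undefined")
    if not (0 <= n_uncallable <= n_total):
        raise ValueError("uncallable count must lie within [0, n_total]")
    return pct(n_total - n_uncallable, n_total)


def composition_from_counts(tier_counts: Mapping[str, int]) -> dict[str, float]:
    """Tier percentages (plus 'challenging' = review + uncallable)."""
    total = sum(tier_counts.values())
    if total == 0:
        raise ValueError("composition of an empty audit is undefined")
    n_review = tier_counts.get(REVIEW, 0)
    n_uncallable = tier_counts.get(UNCALLABLE, 0)
    return {
        "automatic": pct(tier_counts.get(AUTOMATIC, 0), total),
        "review": pct(n_review, total),
        "uncallable": pct(n_uncallable, total),
        "challenging": pct(n_review + n_uncallable, total),
    }


def composition(results: Sequence[CallabilityResult]) -> dict[str, object]:
    """Tier and reason percentages of an audit (reasons over the full total)."""
    if not results:
        raise ValueError("composition of an empty audit is undefined")
    tiers = Counter(r.tier for r in results)
    out: dict[str, object] = composition_from_counts(tiers)
    reason_counts: Counter[str] = Counter()
    for r in results:
        for reason in r.reasons:
            reason_counts[reason] += 1
    out["reasons"] = {
        reason: pct(count, len(results))
        for reason, count in sorted(reason_counts.items())
    }
    return out


def specificity(n_reported: int, n_confirmed: int) -> float | None:
    """Confirmed fraction of reported variants; None when nothing reported."""
    if n_reported == 0:
        return NOT_APPLICABLE
    if not (0 <= n_confirmed <= n_reported):
        raise ValueError("confirmed count must lie within [0, n_reported]")
    return pct(n_confirmed, n_reported)


def build_report(
    results: Sequence[CallabilityResult],
    catalogue: Catalogue,
    transcripts: Sequence[Transcript],
    plan_config: PlanConfig | None = None,
    confirmations: Mapping[VariantKey, bool] | None = None,
    source_a: str = "GERMLINE_DB",
    source_b: str = "SOMATIC_DB",
) -> PanelReport:
    """Aggregate an audit into the per-gene + Total panel report."""
    plan_config = plan_config or PlanConfig()
    tx_by_gene = {t.gene: t for t in transcripts}
    genes = sorted({r.variant.gene for r in results})
    missing = [g for g in genes if g not in tx_by_gene]
    if missing:
        raise ValueError(f"genes {missing} present in audit but not in transcripts")

    rows = []
    for gene in genes:
        gene_results = [r for r in results if r.variant.gene == gene]
        tiers = Counter(r.tier for r in gene_results)
        n_total = len(gene_results)
        rows.append(
            ReportRow(
                gene=gene,
                coding_bp=tx_by_gene[gene].coding_length,
                n_source_a=sum(
                    1 for r in gene_results if source_a in r.variant.sources
                ),
                n_source_b=sum(
                    1 for r in gene_results if source_b in r.variant.sources
                ),
                n_total=n_total,
                n_sanger_full_gene=full_gene_reactions(tx_by_gene[gene], plan_config),
                n_automatic=tiers.get(AUTOMATIC, 0),
                n_review=tiers.get(REVIEW, 0),
                n_uncallable=tiers.get(UNCALLABLE, 0),
                sensitivity_pct=sensitivity(n_total, tiers.get(UNCALLABLE, 0)),
            )
        )

    n_total = sum(r.n_total for r in rows)
    n_uncallable = sum(r.n_uncallable for r in rows)
    total_row = ReportRow(
        gene="Total",
        coding_bp=sum(r.coding_bp for r in rows),
        n_source_a=sum(r.n_source_a for r in rows),
        n_source_b=sum(r.n_source_b for r in rows),
        n_total=n_total,
        n_sanger_full_gene=sum(r.n_sanger_full_gene for r in rows),
        n_automatic=sum(r.n_automatic for r in rows),
        n_review=sum(r.n_review for r in rows),
        n_uncallable=n_uncallable,
        sensitivity_pct=sensitivity(n_total, n_uncallable),
    )

    tiers = Counter(r.tier for r in results)
    comp = composition_from_counts(tiers)
    n_hp_indel = sum(
        1
        for r in results
        if r.tier == UNCALLABLE and HOMOPOLYMER_INDEL in r.reasons
    )
    n_unamplifiable = sum(
        1 for r in results if r.tier == UNCALLABLE and NOT_COVERED in r.reasons
    )

    uncallable_by_chrom: dict[str, list[int]] = {}
    for r in results:
        if r.tier == UNCALLABLE:
            uncallable_by_chrom.setdefault(r.variant.chrom, []).append(
                r.variant.start
            )
    n_rescue = sum(
        rescue_reactions(loci, plan_config, chrom=chrom).n_reactions
        for chrom, loci in sorted(uncallable_by_chrom.items())
    )

    if confirmations is None:
        spec = NOT_APPLICABLE
    else:
        spec = specificity(len(confirmations), sum(bool(v) for v in confirmations.values()))

    return PanelReport(
        rows=tuple(rows),
        total=total_row,
        pct_automatic=comp["automatic"],
        pct_review=comp["review"],
        pct_uncallable=comp["uncallable"],
        pct_challenging=comp["challenging"],
        pct_hp_indel_uncallable=pct(n_hp_indel, n_total),
        pct_unamplifiable=pct(n_unamplifiable, n_total),
        specificity_pct=spec,
        n_rescue_reactions=n_rescue,
        source_a=source_a,
        source_b=source_b,
    )


def read_confirmations_tsv(path: str | Path) -> dict[VariantKey, bool]:
    """2-column TSV: ``chrom:pos:ref:alt`` (1-based pos), confirmed yes/no."""
    confirmations: dict[VariantKey, bool] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key_text, value = line.split("\t")
            chrom, pos, ref, alt = key_text.split(":")
            confirmations[(chrom, int(pos) - 1, ref, alt)] = value.strip().lower() in (
                "yes",
                "y",
                "true",
                "1",
            )
    return confirmations
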