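"""Sanger sequencing workload planning.

Two planning regimes:

* whole-gene confirmation: one reaction per ~150 bp of coding exon, with
  a single reaction sufficing for any exon shorter than one reaction;
* blind-spot rescue: the minimum number of fixed-length readable windows
  covering a set of uncallable loci, found greedily left-to-right (which
  is provably optimal for covering points with fixed-length intervals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .reference_panel import GenomicInterval, Transcript


@dataclass(frozen=True)
class PlanConfig:
    """reaction_len: readable target of one capillary reaction, in bp."""

    reaction_len: int = 150

    def __post_init__(self) -> None:
        if self.reaction_len < 1:
            raise ValueError("reaction_len must be positive")


@dataclass(frozen=True)
class SangerPlan:
    reactions: tuple[GenomicInterval, ...]
    n_reactions: int
    covered_loci: int

    def __post_init__(self) -> None:
        if self.n_reactions != len(self.reactions):
            raise ValueError("n_reactions must equal the number of reactions")


def full_gene_reactions(
    transcript: Transcript, config: PlanConfig | None = None
) -> int:
    """Reactions needed to confirm every coding exon of one gene."""
    config = config or PlanConfig()
    total = 0
    for exon in transcript.exons:
        if exon.length < config.reaction_len:
            total += 1
        else:
            total += math.ceil(exon.length / config.reaction_len)
    return total


def rescue_reactions(
    loci: Sequence[int] | Iterable[int],
    config: PlanConfig | None = None,
    chrom: str = "ref",
) -> SangerPlan:
    """Minimum set of fixed-length windows covering all given loci.

    Greedy left-to-right placement (window start at the leftmost
    uncovered locus) attains the true minimum for fixed-length point
    covering. Duplicate loci are deduplicated silently.
    """
    config = config or PlanConfig()
    points = sorted({int(p) for p in loci})
    if not points:
        raise ValueError("rescue planning requires at least one locus")
    reactions: list[GenomicInterval] = []
    i = 0
    while i < len(points):
        start = points[i]
        end = start + config.reaction_len
        reactions.append(GenomicInterval(chrom, start, end))
        while i < len(points) and points[i] < end:
            i += 1
    return SangerPlan(tuple(reactions), len(reactions), len(points))


def write_plan_bed(plan: SangerPlan, path: str | Path) -> None:
    """Reaction intervals as BED plus a one-line count summary comment."""
    with open(path, "w") as handle:
        handle.write(
            f"# {plan.n_reactions} reactions covering {plan.covered_loci} loci\n"
        )
        for i, iv in enumerate(plan.reactions, start=1):
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\treaction_{i}\n")
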