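"""Reference sequence, exon model, amplicon design and sequence context.

Everything positional in this package uses a single convention: 0-based,
half-open intervals on named sequences. VCF (1-based) and BED (0-based
half-open) are converted at the I/O boundary only.

The sequence-context annotations computed here — coverage by amplicon
inserts, homopolymer runs and their neighbourhoods, proximity to amplicon
insert boundaries — are what drive the callability tiers downstream:
loci outside every insert cannot be assayed at all, and small indels
inside long homopolymer runs are indistinguishable from the dominant
error mode of flow/semiconductor sequencing chemistry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

_IUPAC = frozenset("ACGTRYSWKMBDHVN")
_STANDARD_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on sequence ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap(self, other: "GenomicInterval") -> int:
        """bp separating the two intervals; 0 when they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap between intervals on different sequences")
        return max(0, other.start - self.end, self.start - other.end)


@dataclass(frozen=True)
class Transcript:
    """Coding exon structure of one gene (coding portions only)."""

    gene: str
    transcript_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end or cur.chrom != prev.chrom:
                raise ValueError(
                    f"exons of {self.transcript_id} must be sorted and "
                    "non-overlapping on one sequence"
                )

    @property
    def coding_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end
        )


@dataclass(frozen=True)
class AmpliconPanel:
    """Multiplex-PCR amplicon design: insert intervals tagged by primer pool."""

    amplicons: tuple[tuple[GenomicInterval, int], ...]
    n_pools: int = 1

    def __post_init__(self) -> None:
        if self.n_pools < 1:
            raise ValueError("panel needs at least one primer pool")
        for insert, pool in self.amplicons:
            if not (1 <= pool <= self.n_pools):
                raise ValueError(
                    f"pool id {pool} for insert {insert} outside [1, {self.n_pools}]"
                )

    @property
    def inserts(self) -> list[GenomicInterval]:
        return [insert for insert, _ in self.amplicons]

    @property
    def chroms(self) -> set[str]:
        return {insert.chrom for insert, _ in self.amplicons}


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one repeated base."""

    interval: GenomicInterval
    base: str
    length: int

    def __post_init__(self) -> None:
        if self.base not in _STANDARD_BASES:
            raise ValueError(f"homopolymer base must be A/C/G/T, got {self.base!r}")
        if self.length != self.interval.length:
            raise ValueError("run length must equal its interval length")


@dataclass(frozen=True)
class ContextConfig:
    """Thresholds for context annotation.

    min_homopolymer_len
        Shortest run (bp) treated as a homopolymer context.
    proximity_window
        A locus within this many bp of a run is "near" it.
    amplicon_end_margin
        A locus within this many bp of the boundary of every covering
        insert sits in the artefact-prone end of an amplicon.
    max_hp_indel_len
        Longest pure-repeat indel (bp) considered indistinguishable from
        homopolymer sequencing error.
    """

    min_homopolymer_len: int = 4
    proximity_window: int = 3
    amplicon_end_margin: int = 5
    max_hp_indel_len: int = 2

    def __post_init__(self) -> None:
        for name in (
            "min_homopolymer_len",
            "proximity_window",
            "amplicon_end_margin",
            "max_hp_indel_len",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class ContextFlags:
    """Context annotation of one locus against a panel and its reference."""

    uncovered: bool
    in_homopolymer: bool
    near_homopolymer: bool
    near_amplicon_end: bool
    in_blacklist: bool = False
    #: longest homopolymer run containing or abutting the locus, if any
    hp_run: HomopolymerRun | None = None


def load_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an upper-cased name -> sequence mapping.

    Rejects duplicate record names, empty records, and characters outside
    the IUPAC nucleotide alphabet.
    """
    sequences: dict[str, str] = {}
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate FASTA record name {record.id!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise ValueError(f"empty FASTA record {record.id!r}")
            bad = set(seq) - _IUPAC
            if bad:
                raise ValueError(
                    f"non-IUPAC characters {sorted(bad)} in record {record.id!r}"
                )
            sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def find_homopolymers(
    sequence: str, min_len: int, chrom: str = "ref"
) -> list[HomopolymerRun]:
    """All maximal runs of one base with length >= ``min_len``, sorted.

    Ambiguity codes (including N) never form or extend a run.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    runs: list[HomopolymerRun] = []
    i, n = 0, len(sequence)
    while i < n:
        base = sequence[i]
        j = i + 1
        while j < n and sequence[j] == base:
            j += 1
        if base in _STANDARD_BASES and j - i >= min_len:
            runs.append(HomopolymerRun(GenomicInterval(chrom, i, j), base, j - i))
        i = j
    return runs


def covered_regions(panel: AmpliconPanel) -> list[GenomicInterval]:
    """Union of amplicon inserts as disjoint sorted intervals."""
    if not panel.amplicons:
        raise ValueError("cannot compute coverage of an empty panel")
    merged: list[GenomicInterval] = []
    for iv in sorted(panel.inserts):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def annotate_context(
    locus: GenomicInterval,
    panel: AmpliconPanel,
    runs: Sequence[HomopolymerRun],
    config: ContextConfig | None = None,
    blacklist: Sequence[GenomicInterval] = (),
    covered: Sequence[GenomicInterval] | None = None,
) -> ContextFlags:
    """Annotate one locus with the context flags that drive callability.

    ``covered`` may be passed to reuse a precomputed :func:`covered_regions`
    result when annotating many loci against the same panel.
    """
    config = config or ContextConfig()
    if locus.chrom not in panel.chroms:
        raise ValueError(f"locus sequence {locus.chrom!r} absent from panel")
    if covered is None:
        covered = covered_regions(panel)
    uncovered = not any(iv.contains(locus) for iv in covered)

    covering = [ins for ins in panel.inserts if ins.contains(locus)]
    near_end = bool(covering) and all(
        min(locus.start - ins.start, ins.end - locus.end)
        < config.amplicon_end_margin
        for ins in covering
    )

    same_chrom = [r for r in runs if r.interval.chrom == locus.chrom]
    gaps = [(locus.gap(r.interval), r) for r in same_chrom]
    in_hp = any(locus.overlaps(r.interval) for r in same_chrom)
    near_hp = any(g <= config.proximity_window for g, _ in gaps)
    adjacent = [r for g, r in gaps if g == 0]
    hp_run = max(adjacent, key=lambda r: r.length) if adjacent else None

    in_black = any(iv.overlaps(locus) for iv in blacklist)
    return ContextFlags(
        uncovered=uncovered,
        in_homopolymer=in_hp,
        near_homopolymer=near_hp,
        near_amplicon_end=near_end,
        in_blacklist=in_black,
        hp_run=hp_run,
    )


# ---------------------------------------------------------------------------
# I/O: BED panel, BED blacklist, exon tables
# ---------------------------------------------------------------------------


def read_panel_bed(path: str | Path, n_pools: int | None = None) -> AmpliconPanel:
    """Read an amplicon panel from BED (0-based half-open, column 4 = pool id)."""
    amplicons: list[tuple[GenomicInterval, int]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            pool = int(fields[3]) if len(fields) > 3 and fields[3].isdigit() else 1
            amplicons.append((GenomicInterval(chrom, start, end), pool))
    if not amplicons:
        raise ValueError(f"no amplicons found in {path}")
    pools = max(pool for _, pool in amplicons)
    return AmpliconPanel(tuple(amplicons), n_pools=n_pools or pools)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals from BED (e.g. an artefact blacklist)."""
    intervals = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_panel_bed(panel: AmpliconPanel, path: str | Path) -> None:
    with open(path, "w") as handle:
        for insert, pool in panel.amplicons:
            handle.write(f"{insert.chrom}\t{insert.start}\t{insert.end}\t{pool}\n")


def read_exon_table(path: str | Path) -> list[Transcript]:
    """Read an exon model TSV (gene, transcript_id, chrom, start, end)."""
    by_tx: dict[tuple[str, str], list[GenomicInterval]] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            gene, tx, chrom, start, end = row[:5]
            by_tx.setdefault((gene, tx), []).append(
                GenomicInterval(chrom, int(start), int(end))
            )
    return [
        Transcript(gene, tx, tuple(sorted(exons)))
        for (gene, tx), exons in by_tx.items()
    ]


def write_exon_table(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as handle:
        for t in transcripts:
            for e in t.exons:
                handle.write(f"{t.gene}\t{t.transcript_id}\t{e.chrom}\t{e.start}\t{e.end}\n")


def write_reference_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    """Write a name -> sequence mapping as wrapped FASTA."""
    with open(path, "w") as handle:
        for name, seq in reference.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")
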