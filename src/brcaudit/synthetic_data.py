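"""Synthetic data generator with full truth labels.

Everything the audit pipeline consumes can be generated here: a reference
sequence with homopolymer runs planted at recorded positions, a two-gene
exon model, a tiled multiplex amplicon panel with deliberate coverage
gaps, a pair of variant catalogues with a controlled key overlap, amplicon
pileups with a homopolymer-length-dependent indel error model and optional
strand-bias artefacts, and a tumour/normal cohort with known germline and
somatic variants. Every planted feature is returned as a truth record so
that parameter-recovery tests can compare pipeline output against ground
truth.

The default configuration reproduces the geometry of a published BRCA1/2
amplicon-panel validation: catalogues of 6,106 and 1,071 variants sharing
exactly 224 keys (6,953 merged), coding footprints of 5,659 and 10,262 bp,
a planted callability composition of roughly 87% automatic / 12% review /
1% uncallable (13 homopolymer indels, 52 variants in amplification gaps,
all gaps in the larger gene), and a 47-sample cohort with 13 mutated
samples split 8/5 between the genes, of which 3 carry somatic mutations.

Randomness: each generator draws from its own fixed-order stream seeded
from ``(config.seed, stream_id)``, so adding a generator never perturbs
the output of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .callability import (
    AUTOMATIC,
    HOMOPOLYMER_INDEL,
    NEAR_HOMOPOLYMER,
    NOT_COVERED,
    REVIEW,
    STRAND_BIAS,
    UNCALLABLE,
    PileupColumn,
    pileup_allele_key,
)
from .catalogue import (
    GERMLINE_DB,
    SOMATIC_DB,
    Catalogue,
    CatalogueVariant,
)
from .pathogenicity import GERMLINE, SOMATIC, ObservedVariant
from .reference_panel import (
    AmpliconPanel,
    ContextConfig,
    GenomicInterval,
    HomopolymerRun,
    Transcript,
    write_exon_table,
    write_panel_bed,
    write_reference_fasta,
)

_BASES = "ACGT"
_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val"
).split()


def _default_exon_sizes() -> dict[str, tuple[int, ...]]:
    # synthetic exon models matching the coding footprints of the two genes
    # (5,659 bp over 22 coding exons and 10,262 bp over 26)
    return {
        "BRCA1": (260,) * 21 + (199,),
        "BRCA2": (400,) * 25 + (262,),
    }


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study-shaped conditions."""

    seed: int = 0
    chrom: str = "chrS"
    exon_sizes_by_gene: dict[str, tuple[int, ...]] = field(
        default_factory=_default_exon_sizes
    )
    intron_len: int = 300
    junction_bp: int = 50  # exon-intron junction footprint of the panel
    amplicon_len: int = 150
    amplicon_overlap: int = 30
    n_pools: int = 3
    hp_run_lengths: tuple[int, ...] = (4, 5, 6, 7, 8) * 12
    gap_fraction: float = 0.005  # fraction of coding bases left unamplifiable
    n_gap_segments: int = 4
    gap_gene: str | None = None  # default: the gene with the largest footprint
    # catalogue geometry
    n_catalogue_a: int = 6106
    n_catalogue_b: int = 1071
    n_overlap: int = 224
    # planted callability composition (fractions of the merged catalogue)
    frac_review: float = 829 / 6953
    frac_hp_indel: float = 13 / 6953
    frac_gap: float = 52 / 6953
    strand_bias_fraction: float = 0.0
    # pileup model
    depth_mean: float = 500.0
    variant_present_prob: float = 0.1
    present_vaf: float = 0.5
    biased_vaf: float = 0.30
    hp_indel_rate_base: float = 0.01  # per-read error rate per bp of run length
    hp_indel_rate_cap: float = 0.2
    deamination_rate: float = 0.0  # optional FFPE C>T noise channel, off by default
    n_audit_samples: int = 3
    # cohort model
    purity: float = 0.7
    n_samples: int = 47
    n_mutated: int = 13
    mutated_gene_split: tuple[int, ...] = (8, 5)
    n_somatic: int = 3  # somatic carriers, drawn from the second gene
    loh_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_catalogue_a, self.n_catalogue_b):
            raise ValueError("n_overlap cannot exceed either catalogue size")
        for name in (
            "gap_fraction",
            "frac_review",
            "frac_hp_indel",
            "frac_gap",
            "strand_bias_fraction",
            "variant_present_prob",
            "present_vaf",
            "biased_vaf",
            "hp_indel_rate_base",
            "hp_indel_rate_cap",
            "deamination_rate",
            "loh_prob",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if any(length < 2 for length in self.hp_run_lengths):
            raise ValueError("homopolymer run lengths must be >= 2")
        if sum(self.mutated_gene_split) != self.n_mutated:
            raise ValueError("mutated_gene_split must sum to n_mutated")
        if len(self.mutated_gene_split) != len(self.exon_sizes_by_gene):
            raise ValueError("mutated_gene_split needs one entry per gene")
        if self.n_somatic > self.mutated_gene_split[-1]:
            raise ValueError("n_somatic exceeds the carriers of the last gene")


def paper_shape(seed: int = 0) -> SimConfig:
    """The study-shaped preset (the class defaults) at a given seed."""
    return SimConfig(seed=seed)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted feature."""

    key: tuple
    planted_tier: str = ""
    planted_reason: str = ""
    planted_origin: str = ""
    planted_vafs: tuple[float, float] | None = None  # (tumour, normal)


@dataclass(frozen=True)
class SimulatedGenome:
    reference: dict[str, str]
    transcripts: tuple[Transcript, ...]
    runs: tuple[HomopolymerRun, ...]
    panel: AmpliconPanel
    gap_intervals: tuple[GenomicInterval, ...]

    def gene_at(self, pos: int) -> str:
        for t in self.transcripts:
            for e in t.exons:
                if e.start <= pos < e.end:
                    return t.gene
        raise ValueError(f"position {pos} is not exonic")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % 2**31, stream])


# ---------------------------------------------------------------------------
# genome: reference + exon model + homopolymer truth + panel
# ---------------------------------------------------------------------------


def _subtract(iv: GenomicInterval, cuts: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    pieces = [iv]
    for cut in sorted(cuts):
        next_pieces = []
        for piece in pieces:
            if not piece.overlaps(cut):
                next_pieces.append(piece)
                continue
            if piece.start < cut.start:
                next_pieces.append(GenomicInterval(piece.chrom, piece.start, cut.start))
            if cut.end < piece.end:
                next_pieces.append(GenomicInterval(piece.chrom, cut.end, piece.end))
        pieces = next_pieces
    return pieces


def _tile(iv: GenomicInterval, amplicon_len: int, overlap: int) -> list[GenomicInterval]:
    if iv.length <= amplicon_len:
        return [iv]
    step = amplicon_len - overlap
    starts = list(range(iv.start, iv.end - amplicon_len, step))
    last = iv.end - amplicon_len
    if not starts or starts[-1] != last:
        starts.append(last)
    return [GenomicInterval(iv.chrom, s, s + amplicon_len) for s in starts]


def generate_genome(config: SimConfig) -> SimulatedGenome:
    """Reference, exon model, planted homopolymer runs, panel and gaps."""
    rng = _rng(config, 0)
    chrom = config.chrom
    cc = ContextConfig()

    # exon layout: genes laid out sequentially, introns between exons
    cursor = config.intron_len
    transcripts: list[Transcript] = []
    for gene, sizes in config.exon_sizes_by_gene.items():
        exons = []
        for size in sizes:
            exons.append(GenomicInterval(chrom, cursor, cursor + size))
            cursor += size + config.intron_len
        transcripts.append(Transcript(gene, f"{gene}_tx", tuple(exons)))
    ref_length = cursor
    coding_bp = sum(t.coding_length for t in transcripts)

    # homopolymer slots: evenly spaced positions inside exons, margins at
    # the exon edges wide enough that run neighbourhoods stay exonic
    lengths = list(config.hp_run_lengths)
    run_specs: list[tuple[int, int]] = []  # (start, length)
    if lengths:
        max_run = max(lengths)
        spacing = max_run + 12
        slots: list[int] = []
        for t in transcripts:
            for e in t.exons:
                usable = e.length - 24 - max_run
                if usable < 0:
                    continue
                for k in range(usable // spacing + 1):
                    slots.append(e.start + 12 + k * spacing)
        if len(slots) < len(lengths):
            raise ValueError(
                f"cannot fit {len(lengths)} homopolymer runs into the exon space"
            )
        chosen = sorted(rng.choice(len(slots), size=len(lengths), replace=False))
        run_specs = [(slots[i], L) for i, L in zip(chosen, lengths)]

    # background sequence with accidental runs kept strictly shorter than
    # the shortest planted run (and never >= 4)
    max_bg_run = max(1, min([4, *lengths]) - 1) if lengths else 3
    seq = []
    for _ in range(ref_length):
        b = _BASES[rng.integers(4)]
        if len(seq) >= max_bg_run and all(
            seq[-j] == b for j in range(1, max_bg_run + 1)
        ):
            b = [x for x in _BASES if x != b][rng.integers(3)]
        seq.append(b)

    runs: list[HomopolymerRun] = []
    for start, length in run_specs:
        base = _BASES[rng.integers(4)]
        for p in range(start, start + length):
            seq[p] = base
        # make the run maximal: flanking bases must differ from the run base
        # without seeding a new accidental run
        for flank, neighbor in ((start - 1, start - 2), (start + length, start + length + 1)):
            if seq[flank] == base:
                banned = {base, seq[neighbor]}
                choices = [x for x in _BASES if x not in banned]
                seq[flank] = choices[rng.integers(len(choices))]
        runs.append(
            HomopolymerRun(GenomicInterval(chrom, start, start + length), base, length)
        )
    runs.sort(key=lambda r: r.interval.start)

    # unamplifiable gaps: short segments inside exons of one gene, kept
    # clear of homopolymer neighbourhoods so planted labels stay pure
    gap_intervals: list[GenomicInterval] = []
    gap_bp = round(config.gap_fraction * coding_bp)
    if gap_bp > 0 and config.n_gap_segments > 0:
        gap_gene = config.gap_gene or max(
            transcripts, key=lambda t: t.coding_length
        ).gene
        seg_lens = [
            gap_bp // config.n_gap_segments
            + (1 if i < gap_bp % config.n_gap_segments else 0)
            for i in range(config.n_gap_segments)
        ]
        seg_lens = [s for s in seg_lens if s > 0]
        margin = 20
        target = next(t for t in transcripts if t.gene == gap_gene)
        run_zones = [
            GenomicInterval(
                chrom, r.interval.start - margin, r.interval.end + margin
            )
            for r in runs
        ]
        candidates: list[GenomicInterval] = []
        for e in sorted(target.exons, key=lambda iv: -iv.length):
            inner = GenomicInterval(chrom, e.start + 30, e.end - 30)
            candidates.extend(_subtract(inner, run_zones))
        candidates.sort(key=lambda iv: -iv.length)
        for seg_len, stretch in zip(seg_lens, candidates):
            if stretch.length < seg_len:
                raise ValueError("insufficient run-free exon space for gaps")
            mid = (stretch.start + stretch.end) // 2
            gap_intervals.append(
                GenomicInterval(chrom, mid - seg_len // 2, mid - seg_len // 2 + seg_len)
            )
        if len(gap_intervals) < len(seg_lens):
            raise ValueError("insufficient exon space for the requested gaps")
        gap_intervals.sort()

    # panel: tile exon + junction regions, excluding the gaps
    amplicons: list[tuple[GenomicInterval, int]] = []
    pool = 0
    for t in transcripts:
        for e in t.exons:
            region = GenomicInterval(
                chrom, e.start - config.junction_bp, e.end + config.junction_bp
            )
            for piece in _subtract(region, gap_intervals):
                for insert in _tile(piece, config.amplicon_len, config.amplicon_overlap):
                    amplicons.append((insert, pool % config.n_pools + 1))
                    pool += 1
    panel = AmpliconPanel(tuple(amplicons), n_pools=config.n_pools)

    return SimulatedGenome(
        reference={chrom: "".join(seq)},
        transcripts=tuple(transcripts),
        runs=tuple(runs),
        panel=panel,
        gap_intervals=tuple(gap_intervals),
    )


def generate_reference(config: SimConfig) -> tuple[dict[str, str], tuple[HomopolymerRun, ...]]:
    """Reference mapping plus the planted homopolymer truth list."""
    genome = generate_genome(config)
    return genome.reference, genome.runs


# ---------------------------------------------------------------------------
# catalogues with planted callability composition
# ---------------------------------------------------------------------------


def generate_catalogues(
    config: SimConfig, genome: SimulatedGenome
) -> tuple[Catalogue, Catalogue, list[TruthRecord]]:
    """Two source catalogues with exactly ``n_overlap`` shared keys.

    The merged catalogue carries the planted composition of clean,
    near-homopolymer, homopolymer-indel, strand-bias and in-gap variants.
    """
    rng = _rng(config, 1)
    cc = ContextConfig()
    chrom = config.chrom
    seq = genome.reference[chrom]

    n_total = config.n_catalogue_a + config.n_catalogue_b - config.n_overlap
    n_hp_indel = round(config.frac_hp_indel * n_total)
    n_gap = round(config.frac_gap * n_total)
    n_review = round(config.frac_review * n_total)
    n_bias = round(config.strand_bias_fraction * n_total)
    n_clean = n_total - n_hp_indel - n_gap - n_review - n_bias
    if n_clean < 0:
        raise ValueError("planted composition fractions exceed 1")

    def _choose(pool: list, n: int, label: str) -> list:
        if len(pool) < n:
            raise ValueError(
                f"only {len(pool)} candidate {label} sites for {n} requested variants"
            )
        idx = sorted(rng.choice(len(pool), size=n, replace=False))
        return [pool[i] for i in idx]

    # homopolymer-indel candidates: 1-2 bp pure-repeat indels anchored one
    # base left of each run (already left-normalised by construction)
    hp_pool: list[tuple[int, str, str]] = []
    for run in genome.runs:
        if run.length < cc.min_homopolymer_len:
            continue
        anchor = run.interval.start - 1
        left = seq[anchor]
        for k in (1, 2):
            if k > cc.max_hp_indel_len or k > run.length:
                continue
            hp_pool.append((anchor, left + run.base * k, left))  # deletion
            hp_pool.append((anchor, left, left + run.base * k))  # insertion
    hp_keys = _choose(hp_pool, n_hp_indel, "homopolymer-indel")

    # near-homopolymer SNVs: positions within the proximity window of a run
    d = cc.proximity_window
    review_positions: list[int] = []
    for run in genome.runs:
        s, e = run.interval.start, run.interval.end
        review_positions.extend(range(s - d - 1, s))
        review_positions.extend(range(e, e + d + 1))
    review_pool = [
        (p, seq[p], alt)
        for p in review_positions
        for alt in _BASES
        if alt != seq[p]
    ]
    review_keys = _choose(review_pool, n_review, "near-homopolymer")

    # in-gap SNVs (uncallable: outside every amplicon insert)
    gap_pool = [
        (p, seq[p], alt)
        for g in genome.gap_intervals
        for p in range(g.start + 1, g.end - 1)
        for alt in _BASES
        if alt != seq[p]
    ]
    gap_keys = _choose(gap_pool, n_gap, "in-gap")

    # clean SNVs: exonic, covered, clear of runs, gaps and gap edges
    excluded: set[int] = set()
    for run in genome.runs:
        excluded.update(
            range(run.interval.start - d - 1, run.interval.end + d + 1)
        )
    for g in genome.gap_intervals:
        excluded.update(
            range(g.start - cc.amplicon_end_margin - 2, g.end + cc.amplicon_end_margin + 2)
        )
    clean_pool = [
        (p, seq[p], alt)
        for t in genome.transcripts
        for e in t.exons
        for p in range(e.start, e.end)
        if p not in excluded
        for alt in _BASES
        if alt != seq[p]
    ]
    clean_and_bias = _choose(clean_pool, n_clean + n_bias, "clean")
    bias_keys = clean_and_bias[:n_bias]
    clean_keys = clean_and_bias[n_bias:]

    planted: list[tuple[tuple[int, str, str], str, str]] = (
        [(k, UNCALLABLE, HOMOPOLYMER_INDEL) for k in hp_keys]
        + [(k, UNCALLABLE, NOT_COVERED) for k in gap_keys]
        + [(k, REVIEW, NEAR_HOMOPOLYMER) for k in review_keys]
        + [(k, REVIEW, STRAND_BIAS) for k in bias_keys]
        + [(k, AUTOMATIC, "") for k in clean_keys]
    )

    significance_classes = np.array(
        ["Pathogenic", "Likely_pathogenic", "Uncertain_significance", "Benign"]
    )

    def _make_variant(entry, source: str) -> CatalogueVariant:
        (pos, ref, alt), _, _ = entry
        cls = str(rng.choice(significance_classes))
        return CatalogueVariant(
            chrom=chrom,
            start=pos,
            ref=ref,
            alt=alt,
            gene=genome.gene_at(pos),
            sources=frozenset({source}),
            significance={source: cls},
        )

    order = rng.permutation(n_total)
    shared = [planted[i] for i in order[: config.n_overlap]]
    a_only = [
        planted[i]
        for i in order[config.n_overlap : config.n_catalogue_a]
    ]
    b_only = [planted[i] for i in order[config.n_catalogue_a :]]

    cat_a = Catalogue(_make_variant(e, GERMLINE_DB) for e in shared + a_only)
    cat_b = Catalogue(_make_variant(e, SOMATIC_DB) for e in shared + b_only)

    truths = [
        TruthRecord(
            key=(chrom, pos, ref, alt), planted_tier=tier, planted_reason=reason
        )
        for (pos, ref, alt), tier, reason in planted
    ]
    return cat_a, cat_b, truths


# ---------------------------------------------------------------------------
# pileups with homopolymer-dependent indel noise
# ---------------------------------------------------------------------------


def _split_strands(rng: np.random.Generator, n: int) -> tuple[int, int]:
    fwd = int(rng.binomial(n, 0.5)) if n else 0
    return fwd, n - fwd


def simulate_pileups(
    config: SimConfig,
    genome: SimulatedGenome,
    catalogue: Catalogue,
    truths: Sequence[TruthRecord],
    n_samples: int | None = None,
) -> list[dict[tuple[str, int], PileupColumn]]:
    """Per-sample pileups at every catalogue locus.

    Depth is Poisson around ``depth_mean``; strands split binomially
    except at planted strand-bias loci where alt reads are single-
    stranded; loci inside or abutting a homopolymer run of length L
    acquire spurious 1-bp indel reads at rate ``min(rate_base * L, cap)``;
    uncovered (in-gap) loci have depth 0.
    """
    rng = _rng(config, 2)
    n_samples = n_samples if n_samples is not None else config.n_audit_samples
    chrom = config.chrom
    truth_by_key = {t.key: t for t in truths}

    gap_positions: set[int] = set()
    for g in genome.gap_intervals:
        gap_positions.update(range(g.start, g.end))
    # positions whose locus overlaps or abuts a run, with the run's length/base
    hp_adjacent: dict[int, tuple[int, str]] = {}
    for run in genome.runs:
        for p in range(run.interval.start - 1, run.interval.end + 1):
            current = hp_adjacent.get(p)
            if current is None or run.length > current[0]:
                hp_adjacent[p] = (run.length, run.base)

    # collate per-position metadata from the catalogue
    meta: dict[int, dict] = {}
    for v in catalogue:
        m = meta.setdefault(
            v.start, {"ref_base": v.ref[0], "biased_alts": [], "snv_alts": []}
        )
        truth = truth_by_key.get(v.key)
        alt_key = pileup_allele_key(v)
        if truth is not None and truth.planted_reason == STRAND_BIAS:
            m["biased_alts"].append(alt_key)
        elif v.var_type == "SNV":
            m["snv_alts"].append(alt_key)

    samples: list[dict[tuple[str, int], PileupColumn]] = []
    for _ in range(n_samples):
        columns: dict[tuple[str, int], PileupColumn] = {}
        for pos in sorted(meta):
            m = meta[pos]
            bq = float(np.clip(30.0 + rng.normal(0.0, 1.5), 0.0, 45.0))
            mq = float(np.clip(55.0 + rng.normal(0.0, 2.0), 0.0, 60.0))
            if pos in gap_positions:
                columns[(chrom, pos)] = PileupColumn(chrom, pos, {}, bq, mq)
                continue
            depth = int(rng.poisson(config.depth_mean))
            counts: dict[str, tuple[int, int]] = {}
            used = 0
            for alt_key in m["biased_alts"]:
                n_alt = int(rng.binomial(depth, config.biased_vaf))
                if n_alt:
                    counts[alt_key] = (n_alt, 0)  # all reads on one strand
                    used += n_alt
            if m["snv_alts"] and rng.random() < config.variant_present_prob:
                alt_key = m["snv_alts"][int(rng.integers(len(m["snv_alts"])))]
                n_alt = int(rng.binomial(depth, config.present_vaf))
                if n_alt:
                    counts[alt_key] = _split_strands(rng, n_alt)
                    used += n_alt
            hp = hp_adjacent.get(pos)
            if hp is not None:
                run_len, run_base = hp
                rate = min(config.hp_indel_rate_base * run_len, config.hp_indel_rate_cap)
                n_noise = int(rng.binomial(depth, rate))
                if n_noise:
                    key = "-" + run_base
                    fwd, rev = _split_strands(rng, n_noise)
                    prev = counts.get(key, (0, 0))
                    counts[key] = (prev[0] + fwd, prev[1] + rev)
                    used += n_noise
            if config.deamination_rate > 0 and m["ref_base"] == "C":
                n_deam = int(rng.binomial(depth, config.deamination_rate))
                if n_deam:
                    prev = counts.get("T", (0, 0))
                    fwd, rev = _split_strands(rng, n_deam)
                    counts["T"] = (prev[0] + fwd, prev[1] + rev)
                    used += n_deam
            n_ref = max(0, depth - used)
            if n_ref:
                counts[m["ref_base"]] = _split_strands(rng, n_ref)
            columns[(chrom, pos)] = PileupColumn(chrom, pos, counts, bq, mq)
        samples.append(columns)
    return samples


# ---------------------------------------------------------------------------
# tumour/normal cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[ObservedVariant], list[TruthRecord]]:
    """Observed tumour/normal variants for a cohort with planted origins.

    Germline heterozygous variants sit near VAF 0.5 in both samples
    (0.5 + purity/2 in the tumour under loss of heterozygosity); somatic
    heterozygous variants sit near purity/2 in the tumour and are absent
    from the matched normal.
    """
    rng = _rng(config, 3)
    genes = list(config.exon_sizes_by_gene)
    sample_ids = [f"case_{i:03d}" for i in range(1, config.n_samples + 1)]
    mutated_idx = sorted(rng.choice(config.n_samples, size=config.n_mutated, replace=False))
    gene_labels = [
        gene
        for gene, n_carriers in zip(genes, config.mutated_gene_split)
        for _ in range(n_carriers)
    ]
    gene_labels = [gene_labels[i] for i in rng.permutation(len(gene_labels))]
    last_gene_carriers = [i for i, g in enumerate(gene_labels) if g == genes[-1]]
    somatic_set = set(
        int(i)
        for i in rng.choice(last_gene_carriers, size=config.n_somatic, replace=False)
    )
    depth = max(1, round(config.depth_mean))

    observed: list[ObservedVariant] = []
    truths: list[TruthRecord] = []
    for carrier, sample_pos in enumerate(mutated_idx):
        sample_id = sample_ids[sample_pos]
        gene = gene_labels[carrier]
        codon = int(rng.integers(50, 1800))
        aa = _AA3[int(rng.integers(len(_AA3)))]
        cpos = codon * 3 - 2
        if rng.random() < 0.25:  # nonsense point mutation
            hgvs_c = f"c.{cpos}G>T"
            hgvs_p = f"p.{aa}{codon}Ter"
        else:  # frameshift by a 1-2 bp deletion
            k = int(rng.integers(1, 3))
            aa2 = _AA3[int(rng.integers(len(_AA3)))]
            hgvs_c = f"c.{cpos}del" if k == 1 else f"c.{cpos}_{cpos + 1}del"
            hgvs_p = f"p.{aa}{codon}{aa2}fsTer{int(rng.integers(2, 40))}"
        somatic = carrier in somatic_set
        if somatic:
            t_true, n_true = config.purity / 2, 0.0
        else:
            loh = rng.random() < config.loh_prob
            t_true = 0.5 + config.purity / 2 if loh else 0.5
            n_true = 0.5
        tumour_vaf = int(rng.binomial(depth, t_true)) / depth
        normal_vaf = int(rng.binomial(depth, n_true)) / depth
        observed.append(
            ObservedVariant(
                sample_id=sample_id,
                gene=gene,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                tumour_vaf=tumour_vaf,
                normal_vaf=normal_vaf,
            )
        )
        truths.append(
            TruthRecord(
                key=(sample_id, gene, hgvs_c),
                planted_origin=SOMATIC if somatic else GERMLINE,
                planted_vafs=(t_true, n_true),
            )
        )
    return observed, truths


# ---------------------------------------------------------------------------
# file emission (for the CLI and for external tooling)
# ---------------------------------------------------------------------------


def write_simulation(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate one full simulation and write every artefact as text files."""
    from .callability import write_pileups_tsv
    from .catalogue import merge_catalogues, write_catalogue_vcf, write_hotspot_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    cat_a, cat_b, truths = generate_catalogues(config, genome)
    merged = merge_catalogues(cat_a, cat_b)
    pileups = simulate_pileups(config, genome, merged, truths)
    observed, cohort_truths = simulate_cohort(config)

    paths: dict[str, Path] = {}
    contig_lengths = {name: len(seq) for name, seq in genome.reference.items()}

    paths["reference"] = out / "reference.fasta"
    write_reference_fasta(genome.reference, paths["reference"])
    paths["panel"] = out / "panel.bed"
    write_panel_bed(genome.panel, paths["panel"])
    paths["exons"] = out / "exons.tsv"
    write_exon_table(genome.transcripts, paths["exons"])
    paths["gaps"] = out / "gaps.bed"
    with open(paths["gaps"], "w") as handle:
        for g in genome.gap_intervals:
            handle.write(f"{g.chrom}\t{g.start}\t{g.end}\n")
    paths["catalogue_a"] = out / "catalogue_a.vcf"
    write_catalogue_vcf(cat_a, paths["catalogue_a"], contig_lengths)
    paths["catalogue_b"] = out / "catalogue_b.vcf"
    write_catalogue_vcf(cat_b, paths["catalogue_b"], contig_lengths)
    paths["hotspots"] = out / "hotspots.tsv"
    write_hotspot_tsv(merged, paths["hotspots"])
    for i, sample in enumerate(pileups, start=1):
        path = out / f"pileups_sample{i}.tsv"
        write_pileups_tsv(sample, path)
        paths[f"pileups_{i}"] = path
    paths["truth_catalogue"] = out / "truth_catalogue.tsv"
    with open(paths["truth_catalogue"], "w") as handle:
        handle.write("chrom\tpos\tref\talt\tplanted_tier\tplanted_reason\n")
        for t in truths:
            chrom, pos, ref, alt = t.key
            handle.write(
                f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t{t.planted_tier}\t{t.planted_reason}\n"
            )
    paths["cohort"] = out / "cohort_observed.tsv"
    with open(paths["cohort"], "w") as handle:
        handle.write("sample_id\tgene\thgvs_c\thgvs_p\ttumour_vaf\tnormal_vaf\n")
        for v in observed:
            handle.write(
                f"{v.sample_id}\t{v.gene}\t{v.hgvs_c}\t{v.hgvs_p}\t"
                f"{v.tumour_vaf:.4f}\t{v.normal_vaf:.4f}\n"
            )
    paths["truth_cohort"] = out / "truth_cohort.tsv"
    with open(paths["truth_cohort"], "w") as handle:
        handle.write("sample_id\tgene\thgvs_c\tplanted_origin\ttumour_vaf\tnormal_vaf\n")
        for t in cohort_truths:
            sample_id, gene, hgvs_c = t.key
            tv, nv = t.planted_vafs or (float("nan"), float("nan"))
            handle.write(
                f"{sample_id}\t{gene}\t{hgvs_c}\t{t.planted_origin}\t{tv:.4f}\t{nv:.4f}\n"
            )
    return paths
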