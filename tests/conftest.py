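"""Shared fixtures: small simulated datasets and hand-built panels."""

from __future__ import annotations

import pytest

from brcaudit.catalogue import merge_catalogues
from brcaudit.reference_panel import AmpliconPanel, GenomicInterval
from brcaudit.synthetic_data import (
    SimConfig,
    generate_catalogues,
    generate_genome,
    simulate_pileups,
)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A quick two-gene configuration for unit tests."""
    settings = dict(
        seed=seed,
        exon_sizes_by_gene={"GENE1": (400,) * 3, "GENE2": (400,) * 4},
        hp_run_lengths=(4, 5, 6, 7),
        n_catalogue_a=60,
        n_catalogue_b=25,
        n_overlap=10,
        frac_review=0.15,
        frac_hp_indel=0.04,
        frac_gap=0.05,
        gap_fraction=0.02,
        n_gap_segments=2,
        n_samples=8,
        n_mutated=3,
        mutated_gene_split=(2, 1),
        n_somatic=1,
        n_audit_samples=2,
    )
    settings.update(overrides)
    return SimConfig(**settings)


@pytest.fixture(scope="session")
def small_sim():
    """Genome + catalogues + pileups + truth for the small configuration."""
    config = small_config(seed=7)
    genome = generate_genome(config)
    cat_a, cat_b, truths = generate_catalogues(config, genome)
    merged = merge_catalogues(cat_a, cat_b)
    pileups = simulate_pileups(config, genome, merged, truths)
    return {
        "config": config,
        "genome": genome,
        "cat_a": cat_a,
        "cat_b": cat_b,
        "catalogue": merged,
        "pileups": pileups,
        "truths": truths,
    }


@pytest.fixture()
def flat_panel():
    """One-chromosome panel of two overlapping amplicons over [10, 290)."""
    return AmpliconPanel(
        (
            (GenomicInterval("chr1", 10, 160), 1),
            (GenomicInterval("chr1", 130, 290), 2),
        ),
        n_pools=2,
    )
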