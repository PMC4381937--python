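"""Shared fixtures: small synthetic genomes and one end-to-end pipeline run.

Everything is generated programmatically at fixed seeds; session scope
keeps the heavier simulations to a single run each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from methylib.calling import assign_reads, call_site_methylation, fragment_methylation
from methylib.cg_model import DEFAULT_B, DEFAULT_C, SigmoidModel, cg_density, cg_positions
from methylib.library_design import (
    DEFAULT_ENZYMES,
    build_reference_set,
    digest,
    extract_sequences,
    size_select,
)
from methylib.studies import SIZE_RANGE, dynamics_conditions, prokaryotic_library_conditions
from methylib.synthetic import (
    generate_genome,
    generate_ground_truth,
    simulate_bisulfite_reads,
)


@pytest.fixture(scope="session")
def model() -> SigmoidModel:
    return SigmoidModel(DEFAULT_B, DEFAULT_C)


@pytest.fixture(scope="session")
def small_genome():
    """A small island genome with TF sites (both factors)."""
    from methylib.synthetic import SyntheticGenomeSpec

    spec = SyntheticGenomeSpec(n_contigs=2, contig_length=30_000, n_islands=6, n_tf_sites=10, seed=5)
    genome, islands, sites = generate_genome(spec)
    return spec, genome, islands, sites


@pytest.fixture(scope="session")
def dynamics_genome():
    spec = dynamics_conditions(seed=21)
    genome, islands, sites = generate_genome(spec)
    truth, cuts = generate_ground_truth(genome, sites, seed=22)
    return genome, islands, sites, truth, cuts


@dataclass
class PipelineRun:
    genome: dict
    islands: object
    truth: object
    reference: object
    sequences: dict
    calls: object
    fragment_table: object
    true_meth: dict


@pytest.fixture(scope="session")
def pipeline() -> PipelineRun:
    """End-to-end run on the TF-free (prokaryotic-library-like) conditions:
    generate -> digest -> size-select -> reference set -> simulate reads ->
    assign -> call."""
    spec = prokaryotic_library_conditions(seed=11)
    genome, islands, sites = generate_genome(spec)
    truth, _ = generate_ground_truth(genome, sites, seed=12)
    lib = digest(genome, [DEFAULT_ENZYMES["MspI"]])
    ref = build_reference_set(size_select(lib, *SIZE_RANGE))
    seqs = extract_sequences(genome, ref)
    reads = simulate_bisulfite_reads(
        genome, ref, truth, target_coverage=50, read_length=80, seed=13
    )
    assignments, observations = assign_reads(reads, seqs, max_mismatches=0)
    calls = call_site_methylation(observations, min_coverage=10)
    inventory = {fid: cg_positions(s) for fid, s in seqs.items()}
    fragment_table = fragment_methylation(calls, inventory)
    true_meth = {
        (c, p): m
        for c, p, m in zip(truth["contig"], truth["pos"], truth["true_methylation"])
    }
    return PipelineRun(genome, islands, truth, ref, seqs, calls, fragment_table, true_meth)
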