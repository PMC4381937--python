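#!/usr/bin/env python
"""Simulate bisulfite sequencing of the library and call methylation.

Reads at 50x coverage are simulated over the reference fragments,
assigned against the converted references, and filtered: >=10 reads per
CG, then fragment averages over fragments with >50% of CGs and >=4 CGs
covered.  Writes per-CG calls and the fragment table.
"""

from pathlib import Path

import numpy as np

from methylib.calling import assign_reads, call_site_methylation, fragment_methylation
from methylib.cg_model import cg_positions
from methylib.library_design import (
    DEFAULT_ENZYMES,
    build_reference_set,
    digest,
    extract_sequences,
    size_select,
)
from methylib.studies import SIZE_RANGE, prokaryotic_library_conditions
from methylib.synthetic import generate_genome, generate_ground_truth, simulate_bisulfite_reads

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = prokaryotic_library_conditions(seed=11)
    genome, _, sites = generate_genome(spec)
    truth, _ = generate_ground_truth(genome, sites, seed=12)
    reference = build_reference_set(
        size_select(digest(genome, [DEFAULT_ENZYMES["MspI"]]), *SIZE_RANGE)
    )
    sequences = extract_sequences(genome, reference)

    reads = simulate_bisulfite_reads(
        genome, reference, truth, target_coverage=50, read_length=80, seed=13
    )
    assignments, observations = assign_reads(reads, sequences)
    n_assigned = int((assignments["status"] == "assigned").sum())
    print(f"{len(reads)} reads simulated; {n_assigned} assigned "
          f"({100 * n_assigned / len(reads):.1f}%)")

    calls = call_site_methylation(observations, min_coverage=10)
    inventory = {fid: cg_positions(s) for fid, s in sequences.items()}
    fragments = fragment_methylation(calls, inventory)
    SCRATCH.mkdir(exist_ok=True)
    calls.to_csv(SCRATCH / "site_calls.tsv", sep="\t", index=False)
    fragments.to_csv(OUT / "fragment_methylation.tsv", sep="\t", index=False)

    true_meth = {
        (c, p): m for c, p, m in zip(truth["contig"], truth["pos"], truth["true_methylation"])
    }
    deltas = []
    for fid, pos, meth in zip(calls["fragment"], calls["pos"], calls["methylation"]):
        contig, span = fid.split(":")
        deltas.append(abs(meth - true_meth[(contig, int(span.split("-")[0]) + pos)]))
    print(
        f"{len(calls)} CGs called (median coverage {calls['n_total'].median():.0f}x); "
        f"mean |call - truth| = {np.mean(deltas):.2f} points"
    )
    print(f"{int(fragments['pass'].sum())}/{len(fragments)} fragments pass the CG filters")


if __name__ == "__main__":
    main()
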