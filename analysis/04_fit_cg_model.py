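#!/usr/bin/env python
"""Fit the CG-only sigmoid to fragment methylation and screen dinucleotides.

Reproduces the core modelling step on the synthetic library: fragment
methylation averages against fragment CG density, fitted by fixed-asymptote
nonlinear least squares (fragments >=250 bp only), plus the 16-dinucleotide
regression screen showing that CG carries the signal.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methylib.calling import assign_reads, call_site_methylation, fragment_methylation
from methylib.cg_model import cg_density, cg_positions, dinucleotide_screen, fit_sigmoid
from methylib.library_design import (
    DEFAULT_ENZYMES,
    build_reference_set,
    digest,
    extract_sequences,
    size_select,
)
from methylib.studies import SIZE_RANGE, prokaryotic_library_conditions
from methylib.synthetic import generate_genome, generate_ground_truth, simulate_bisulfite_reads

OUT = Path(__file__).resolve().parent.parent / "results"


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
    _, observations = assign_reads(reads, sequences)
    calls = call_site_methylation(observations, min_coverage=10)
    inventory = {fid: cg_positions(s) for fid, s in sequences.items()}
    fragments = fragment_methylation(calls, inventory)
    passing = fragments[fragments["pass"]]

    dens = np.array([cg_density(sequences[f]) for f in passing["fragment"]])
    lengths = np.array([len(sequences[f]) for f in passing["fragment"]])
    meth = passing["mean_methylation"].to_numpy()
    model = fit_sigmoid(dens, meth, fragment_lengths=lengths, min_fragment_length=250)
    model.to_json(OUT / "cg_model.json")
    kept = int((lengths >= 250).sum())
    print(
        f"fitted on {kept} fragments >=250 bp: b = {model.b:.3f} per CGs/100 bp, "
        f"c = {model.c:.3f} CGs/100 bp, R^2 = {model.r_squared:.3f}"
    )

    table = pd.DataFrame(
        {"fragment": passing["fragment"], "cg_density": dens, "length": lengths,
         "methylation": meth}
    )
    table.to_csv(OUT / "fragment_density_methylation.tsv", sep="\t", index=False)

    screen = dinucleotide_screen([sequences[f] for f in passing["fragment"]], meth)
    screen.to_csv(OUT / "dinucleotide_screen.tsv", sep="\t", index=False)
    ranked = screen.dropna().reindex(screen["r"].abs().sort_values(ascending=False).index)
    top = ranked.iloc[0]
    print(
        f"strongest dinucleotide correlate: {top['dinucleotide']} "
        f"(R = {top['r']:.2f}, p = {top['p_value']:.2e})"
    )


if __name__ == "__main__":
    main()
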