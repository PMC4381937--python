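#!/usr/bin/env python
"""Generate the synthetic study data: genomes, ground truths, DNase tracks.

Three genomes are produced, one per experiment: a TF-free genome standing
in for the prokaryotic fragment library (density is the only methylation
determinant), a density-uniform genome for the DNase collection-window
scan (binding is the only determinant), and an island genome with dense
TF binding for the dynamics analyses.  Each is written to results/data as
FASTA plus BED/bedGraph-like annotations.
"""

from pathlib import Path

from methylib import io
from methylib.studies import (
    dynamics_conditions,
    prokaryotic_library_conditions,
    window_scan_conditions,
)
from methylib.synthetic import generate_genome, generate_ground_truth

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "data"  # full exports are bulky; results/ keeps summaries
RESULTS = ROOT / "results"

STUDIES = {
    "prokaryotic": (prokaryotic_library_conditions(seed=11), 12),
    "window_scan": (window_scan_conditions(seed=201), 1201),
    "dynamics": (dynamics_conditions(seed=21), 22),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    summary = []
    for name, (spec, truth_seed) in STUDIES.items():
        genome, islands, sites = generate_genome(spec)
        truth, cuts = generate_ground_truth(genome, sites, seed=truth_seed)
        io.write_fasta(genome, OUT / f"{name}.genome.fa")
        io.write_bed(islands, OUT / f"{name}.islands.bed")
        io.write_bed(sites, OUT / f"{name}.tf_sites.bed")
        track = truth.assign(start=truth["pos"], end=truth["pos"] + 2)
        io.write_bedgraph(track, OUT / f"{name}.methylome.tsv", ["true_methylation"])
        io.write_bedgraph(track, OUT / f"{name}.dhs.tsv", ["dhs_cuts"])
        n_bound = int((truth["bound_factors"] != "").sum())
        summary.append(
            {
                "study": name,
                "n_contigs": spec.n_contigs,
                "contig_length": spec.contig_length,
                "n_cgs": len(truth),
                "n_bound_cgs": n_bound,
                "n_islands": len(islands),
                "n_tf_sites": len(sites),
            }
        )
        print(
            f"{name}: {spec.n_contigs} contigs x {spec.contig_length} bp, "
            f"{len(truth)} CGs ({n_bound} TF-bound), "
            f"{len(islands)} islands, {len(sites)} TF sites"
        )
    import pandas as pd

    pd.DataFrame(summary).to_csv(RESULTS / "study_data_summary.tsv", sep="\t", index=False)
    print(f"full data exports under {OUT}; summary in results/study_data_summary.tsv")


if __name__ == "__main__":
    main()
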