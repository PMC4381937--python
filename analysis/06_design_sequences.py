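#!/usr/bin/env python
"""Design the synthetic constructs: CG-preserving mutants and the motif pair.

Takes island fragments from the synthetic genome, rewrites every non-CG
position from a CG-free template (destroying TF motifs at constant CG
density), and derives the best/lowest-score REST motif pair for cassette
insertion.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methylib import io
from methylib.cg_model import cg_density
from methylib.design import (
    cg_preserving_mutant,
    design_motif_pair,
    insert_motif,
    load_rest_pwm,
    pwm_score,
)
from methylib.studies import dynamics_conditions
from methylib.synthetic import generate_genome

OUT = Path(__file__).resolve().parent.parent / "results"


def _cg_free_template(length: int, seed: int) -> str:
    """A CG-free pseudo-bacterial template: random bases, no C before G."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(length):
        bases = "ACT" if out and out[-1] == "C" else "ACGT"
        out.append(bases[rng.integers(0, len(bases))])
    return "".join(out)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = dynamics_conditions(seed=21)
    genome, islands, _ = generate_genome(spec)

    # mutate the first island fragment of each contig
    rows = []
    mutants = {}
    template = _cg_free_template(3000, seed=71)
    for contig, grp in islands.groupby("contig"):
        isl = grp.iloc[0]
        frag = genome[contig][int(isl["start"]) : int(isl["start"]) + 400]
        mut = cg_preserving_mutant(frag, template)
        mutants[f"{contig}:{isl['start']}-{isl['start'] + 400}"] = mut
        rows.append(
            {
                "fragment": f"{contig}:{isl['start']}-{isl['start'] + 400}",
                "cg_density": cg_density(frag),
                "mutant_cg_density": cg_density(mut),
                "identity_to_original": np.mean([a == b for a, b in zip(frag, mut)]),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "cg_preserving_mutants.tsv", sep="\t", index=False)
    io.write_fasta(mutants, OUT / "cg_preserving_mutants.fa")
    print(table.round(3).to_string(index=False))
    assert (table["cg_density"] == table["mutant_cg_density"]).all()
    print("CG density preserved exactly in every mutant")

    pwm = load_rest_pwm()
    best, lowest = design_motif_pair(pwm, n_samples=5000, seed=72)
    print(f"best REST motif   : {best}  (score {pwm_score(best, pwm):.2f})")
    print(f"lowest-score motif: {lowest}  (score {pwm_score(lowest, pwm):.2f})")

    # insert both into the middle of a methylated island fragment (cassette)
    isl = islands.iloc[0]
    cassette = genome[isl["contig"]][int(isl["start"]) : int(isl["start"]) + 300]
    constructs = {
        "cassette_best": insert_motif(cassette, best, len(cassette) // 2),
        "cassette_lowest": insert_motif(cassette, lowest, len(cassette) // 2),
    }
    io.write_fasta(constructs, OUT / "motif_constructs.fa")
    print(f"constructs written to {OUT / 'motif_constructs.fa'}")


if __name__ == "__main__":
    main()
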