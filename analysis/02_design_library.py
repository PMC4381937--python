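#!/usr/bin/env python
"""Design the fragment library by in-silico methylation-sensitive digestion.

Screens enzyme subsets and size ranges for CpG-island enrichment on the
TF-free genome, then builds the non-overlapping reference fragment set
used by the downstream methylation calling.
"""

from pathlib import Path

from methylib import io
from methylib.library_design import (
    DEFAULT_ENZYMES,
    build_reference_set,
    digest,
    screen_enzyme_sets,
    size_select,
)
from methylib.studies import SIZE_RANGE, prokaryotic_library_conditions
from methylib.synthetic import generate_genome

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = prokaryotic_library_conditions(seed=11)
    genome, islands, _ = generate_genome(spec)

    screen = screen_enzyme_sets(
        genome, None, DEFAULT_ENZYMES, [SIZE_RANGE, (200, 400)], islands
    )
    screen.to_csv(OUT / "enzyme_screen.tsv", sep="\t", index=False)
    top = screen.iloc[0]
    print(
        f"top enzyme set: {top['enzymes']} at {top['min_size']}-{top['max_size']} bp "
        f"-> {top['n_fragments']} fragments, "
        f"{100 * top['cgi_overlap_fraction']:.0f}% overlapping islands"
    )

    lib = digest(genome, [DEFAULT_ENZYMES["MspI"]])
    selected = size_select(lib, *SIZE_RANGE)
    reference = build_reference_set(selected)
    io.write_bed(reference.to_dataframe(), OUT / "reference_fragments.bed")
    lengths = [f.length for f in reference]
    print(
        f"MspI digest: {len(lib)} fragments, {len(selected)} in "
        f"{SIZE_RANGE[0]}-{SIZE_RANGE[1]} bp, {len(reference)} in the "
        f"non-overlapping reference set "
        f"(median length {sorted(lengths)[len(lengths) // 2]} bp)"
    )


if __name__ == "__main__":
    main()
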