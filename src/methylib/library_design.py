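"""In-silico digestion with methylation-sensitive restriction enzymes.

A library of genomic fragments is produced by digesting a genome with
CpG-methylation-sensitive enzymes: a recognition site is only cut when the
CGs it contains are unmethylated, so digestion of a methylome-masked
genome enriches for fragments from unmethylated, CG-rich regions.
Fragments are then size-selected, enzyme/size combinations screened for
CpG-island enrichment, and a non-overlapping reference set built so that
read assignment is never ambiguous.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .io import revcomp

#: Sentinel enzyme name for fragment boundaries at contig ends.
CONTIG_END = "contig-end"


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    site: str
    cut_offset: int
    methylation_sensitive: bool = True

    def __post_init__(self) -> None:
        if set(self.site) - set("ACGT"):
            raise ValueError(f"{self.name}: site must be A/C/G/T")
        if self.site != revcomp(self.site):
            raise ValueError(
                f"{self.name}: non-palindromic site; double-strand cut semantics undefined"
            )
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut offset outside site")
        if self.methylation_sensitive and "CG" not in self.site:
            raise ValueError(f"{self.name}: methylation-sensitive site must contain a CG")


#: Canonical cut offsets: NarI GG^CGCC, BstUI CG^CG, BssHII G^CGCGC, MspI C^CGG.
DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in (
        RestrictionEnzyme("NarI", "GGCGCC", 2),
        RestrictionEnzyme("BstUI", "CGCG", 2),
        RestrictionEnzyme("BssHII", "GCGCGC", 1),
        RestrictionEnzyme("MspI", "CCGG", 1),
    )
}


def load_enzymes(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """User-extensible enzyme table: TSV with name, site, cut_offset[, sensitive]."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[row["name"]] = RestrictionEnzyme(
            row["name"],
            row["site"],
            int(row["cut_offset"]),
            bool(row.get("methylation_sensitive", True)),
        )
    return out


@dataclass(frozen=True, order=True)
class Fragment:
    contig: str
    start: int
    end: int
    left_enzyme: str = CONTIG_END
    right_enzyme: str = CONTIG_END

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("fragment requires 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


@dataclass
class FragmentLibrary:
    fragments: list[Fragment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fragments = sorted(self.fragments, key=lambda f: (f.contig, f.start, f.end))

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contig": f.contig,
                    "start": f.start,
                    "end": f.end,
                    "left_enzyme": f.left_enzyme,
                    "right_enzyme": f.right_enzyme,
                }
                for f in self.fragments
            ],
            columns=["contig", "start", "end", "left_enzyme", "right_enzyme"],
        )


def _site_occurrences(seq: str, site: str):
    """All (possibly overlapping) forward-strand occurrences of a site.
    Palindromic sites occur identically on the reverse strand, so forward
    scanning finds every cut locus."""
    i = seq.find(site)
    while i != -1:
        yield i
        i = seq.find(site, i + 1)


def digest(
    genome: dict[str, str],
    enzymes,
    methylome: pd.DataFrame | None = None,
    mask_threshold: float = 50.0,
) -> FragmentLibrary:
    """Cut every unmasked enzyme site; fragments are the intervals between
    consecutive cuts (contig ends included).

    With a methylome given (contig/start/methylation per CG), a site of a
    methylation-sensitive enzyme is NOT cut when any CG inside the site
    has methylation above ``mask_threshold``.
    """
    enzymes = list(enzymes.values() if isinstance(enzymes, dict) else enzymes)
    if not enzymes:
        raise ValueError("empty enzyme set")
    meth_lookup: dict[str, dict[int, float]] = {}
    if methylome is not None:
        pos_col = "pos" if "pos" in methylome.columns else "start"
        for contig, grp in methylome.groupby("contig"):
            meth_lookup[contig] = dict(zip(grp[pos_col], grp["methylation"]))
    fragments = []
    for contig, seq in genome.items():
        meth = meth_lookup.get(contig, {})
        cuts: dict[int, str] = {}
        for enz in enzymes:
            cg_offsets = [k for k in range(len(enz.site) - 1) if enz.site[k : k + 2] == "CG"]
            for occ in _site_occurrences(seq, enz.site):
                if methylome is not None and enz.methylation_sensitive:
                    if any(meth.get(occ + k, 0.0) > mask_threshold for k in cg_offsets):
                        continue
                cut = occ + enz.cut_offset
                if 0 < cut < len(seq) and cut not in cuts:
                    cuts[cut] = enz.name
        boundaries = [(0, CONTIG_END)] + sorted(cuts.items()) + [(len(seq), CONTIG_END)]
        for (a, left), (b, right) in zip(boundaries[:-1], boundaries[1:]):
            if b > a:
                fragments.append(Fragment(contig, a, b, left, right))
    return FragmentLibrary(
        fragments,
        provenance={
            "enzymes": [e.name for e in enzymes],
            "mask_threshold": mask_threshold if methylome is not None else None,
        },
    )


def size_select(lib: FragmentLibrary, min_bp: int, max_bp: int) -> FragmentLibrary:
    """Keep fragments with min_bp <= length <= max_bp (inclusive both ends)."""
    if min_bp > max_bp:
        raise ValueError("min size must not exceed max size")
    kept = [f for f in lib.fragments if min_bp <= f.length <= max_bp]
    prov = dict(lib.provenance)
    prov["size_range"] = (min_bp, max_bp)
    return FragmentLibrary(kept, prov)


def _overlap_fraction(lib: FragmentLibrary, cgi: pd.DataFrame) -> float:
    if len(lib) == 0:
        return 0.0
    by_contig = {
        contig: sorted(zip(grp["start"], grp["end"])) for contig, grp in cgi.groupby("contig")
    }
    n_overlap = 0
    for f in lib.fragments:
        for s, e in by_contig.get(f.contig, ()):  # few islands; linear scan is fine
            if f.start < e and s < f.end:
                n_overlap += 1
                break
    return n_overlap / len(lib)


def screen_enzyme_sets(
    genome: dict[str, str],
    methylome: pd.DataFrame | None,
    candidate_enzymes,
    candidate_size_ranges,
    cgi_annotation: pd.DataFrame,
    mask_threshold: float = 50.0,
) -> pd.DataFrame:
    """Screen every non-empty enzyme subset against every size range.

    Reports unique fragment counts and the fraction of fragments
    overlapping the CpG-island annotation, ranked by (overlap fraction,
    fragment count) descending; ranking is deterministic.
    """
    candidate_enzymes = list(
        candidate_enzymes.values() if isinstance(candidate_enzymes, dict) else candidate_enzymes
    )
    if not candidate_enzymes:
        raise ValueError("need at least one candidate enzyme")
    if len(cgi_annotation) == 0:
        warnings.warn("empty CGI annotation: overlap fractions are all 0", stacklevel=2)
    rows = []
    for r in range(1, len(candidate_enzymes) + 1):
        for subset in itertools.combinations(candidate_enzymes, r):
            lib = digest(genome, list(subset), methylome, mask_threshold)
            for lo, hi in candidate_size_ranges:
                sel = size_select(lib, lo, hi)
                unique = {(f.contig, f.start, f.end) for f in sel}
                rows.append(
                    {
                        "enzymes": ",".join(sorted(e.name for e in subset)),
                        "min_size": lo,
                        "max_size": hi,
                        "n_fragments": len(unique),
                        "cgi_overlap_fraction": _overlap_fraction(sel, cgi_annotation),
                    }
                )
    table = pd.DataFrame(rows).sort_values(
        by=["cgi_overlap_fraction", "n_fragments", "enzymes", "min_size"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return table.reset_index(drop=True)


def build_reference_set(lib: FragmentLibrary) -> FragmentLibrary:
    """Drop EVERY member of any overlapping cluster (same-contig, any
    shared base over half-open intervals); the result is pairwise disjoint
    so read assignment is unambiguous."""
    kept = []
    frags = lib.fragments  # already sorted by (contig, start)
    i = 0
    while i < len(frags):
        j = i + 1
        max_end = frags[i].end
        while (
            j < len(frags)
            and frags[j].contig == frags[i].contig
            and frags[j].start < max_end
        ):
            max_end = max(max_end, frags[j].end)
            j += 1
        if j == i + 1:
            kept.append(frags[i])
        i = j
    prov = dict(lib.provenance)
    prov["reference_set"] = True
    return FragmentLibrary(kept, prov)


def extract_sequences(genome: dict[str, str], fragments) -> dict[str, str]:
    """Fragment id -> sequence, for reference construction and simulation."""
    frag_iter = fragments.fragments if hasattr(fragments, "fragments") else fragments
    return {f.id: genome[f.contig][f.start : f.end] for f in frag_iter}
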