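"""Design of synthetic constructs: CG-preserving mutants and PWM motif pairs.

Two sequence manipulations isolate the contributions of CG density and
transcription-factor motifs: (1) mutants that keep every CG dinucleotide
of a sequence in place while replacing all other positions from a CG-free
template, destroying TF motifs at constant CG density; (2) a matched pair
of motifs for a position weight matrix — the consensus (best score) and a
composition-matched shuffle with the lowest score — to insert into a
receiving cassette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 4 x L nonnegative counts in A,C,G,T row order."""

    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix")
        if np.any(c < 0) or np.any(c.sum(axis=0) <= 0):
            raise ValueError("every position needs nonnegative weights with positive total")
        object.__setattr__(self, "counts", c)

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        """Most frequent base per column; ties break alphabetically (A<C<G<T)."""
        return "".join(_BASES[i] for i in np.argmax(self.counts, axis=0))


def load_pwm(path: str | Path) -> PWM:
    """Read a JASPAR-format text PWM."""
    with open(path) as fh:
        m = bio_motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in _BASES], dtype=float)
    return PWM(name=m.name or m.matrix_id or Path(path).stem, counts=counts)


def load_rest_pwm() -> PWM:
    """Bundled REST matrix (a synthetic stand-in pinned so that its
    consensus equals the published REST best-score motif)."""
    with resources.as_file(
        resources.files("methylib").joinpath("data/rest_synthetic.jaspar")
    ) as p:
        return load_pwm(p)


def pwm_score(seq: str, pwm: PWM, pseudocount: float = 0.01) -> float:
    """Sum over positions of log(frequency + pseudocount) of the observed
    base (column-normalised frequencies); deterministic."""
    if len(seq) != len(pwm):
        raise ValueError(f"sequence length {len(seq)} != PWM length {len(pwm)}")
    freq = pwm.frequencies
    return float(
        sum(np.log(freq[_BASE_INDEX[b], i] + pseudocount) for i, b in enumerate(seq))
    )


def pwm_score_range(pwm: PWM, pseudocount: float = 0.01) -> tuple[float, float]:
    """(min, max) attainable scores, for normalised hit thresholds."""
    lf = np.log(pwm.frequencies + pseudocount)
    return float(lf.min(axis=0).sum()), float(lf.max(axis=0).sum())


def design_motif_pair(pwm: PWM, n_samples: int = 2000, seed: int = 0) -> tuple[str, str]:
    """(best_motif, lowest_motif) for a PWM.

    Best: the consensus.  Lowest: among ``n_samples`` seeded random
    shuffles of the consensus letters — which preserves mononucleotide
    composition exactly — only those with the same CG dinucleotide count
    are admissible, and the minimal-scoring one is returned.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    best = pwm.consensus()
    target_cg = best.count("CG")
    letters = np.array(list(best))
    rng = np.random.default_rng(seed)
    lowest, lowest_score = None, np.inf
    for _ in range(n_samples):
        cand = "".join(rng.permutation(letters))
        if cand.count("CG") != target_cg:
            continue
        s = pwm_score(cand, pwm)
        if s < lowest_score:
            lowest, lowest_score = cand, s
    if lowest is None:
        raise ValueError(
            "no shuffle matched the CG-count constraint; increase n_samples"
        )
    return best, lowest


def cg_preserving_mutant(seq: str, template: str) -> str:
    """Replace every non-CG position of ``seq`` with the template base.

    Positions covered by any CG dinucleotide of ``seq`` keep their base;
    all others take the template base at the same offset.  If a junction
    would create a CG absent from the original, the offending template
    base becomes 'A' (logged).  The mutant's CG start set equals the
    original's exactly.
    """
    if "CG" in template:
        raise ValueError("template must be CG-free")
    if len(template) < len(seq):
        raise ValueError("template shorter than sequence")
    orig_cg = {i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"}
    keep = {p for i in orig_cg for p in (i, i + 1)}
    out = [seq[i] if i in keep else template[i] for i in range(len(seq))]
    while True:
        new_cg = [
            i
            for i in range(len(out) - 1)
            if out[i] == "C" and out[i + 1] == "G" and i not in orig_cg
        ]
        if not new_cg:
            break
        for i in new_cg:
            j = i if i not in keep else i + 1  # at least one side is template-derived
            out[j] = "A"
            logger.info("junction CG at %d removed by substituting A at %d", i, j)
    mutant = "".join(out)
    assert {i for i in range(len(mutant) - 1) if mutant[i : i + 2] == "CG"} == orig_cg
    return mutant


def insert_motif(cassette_seq: str, motif: str, entry_offset: int) -> str:
    """Insert a motif at the entry site, preserving both flanks verbatim."""
    if not 0 <= entry_offset <= len(cassette_seq):
        raise ValueError("entry offset outside cassette")
    return cassette_seq[:entry_offset] + motif + cassette_seq[entry_offset:]
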