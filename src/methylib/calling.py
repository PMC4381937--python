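"""Bisulfite read assignment and methylation calling with coverage filters.

Reads are assigned to a non-overlapping reference fragment set by matching
the fully converted read against in-silico converted fragment references
(C->T for the forward frame, G->A seen as the C->T of the reverse
complement), allowing a bounded number of mismatches.  Because the
reference set is small and pairwise disjoint by construction, a seeded
exact/k-mismatch matcher is sufficient; reads matching more than one
fragment are discarded as ambiguous.

Calls then pass the study's filters: a CG needs >=10 reads to be called,
SNP positions are masked, and a fragment average requires >50% of its CGs
and at least four CGs to be covered.  Observations from the two strands of
one CpG are pooled (symmetric methylation assumed).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cg_model import cg_positions
from .io import Read, revcomp


def convert_reference(sequences):
    """In-silico bisulfite-converted copies: (C->T reference, G->A reference)."""

    def _one(s: str):
        if set(s) - set("ACGTN"):
            raise ValueError("reference must be A/C/G/T/N")
        return s.replace("C", "T"), s.replace("G", "A")

    if isinstance(sequences, str):
        return _one(sequences)
    ct, ga = {}, {}
    for name, s in sequences.items():
        ct[name], ga[name] = _one(s)
    return ct, ga


class _Matcher:
    """Pigeonhole seed-and-verify substring matcher with <=k mismatches.

    The read is split into k+1 seeds; at least one seed must be
    mismatch-free, so exact seed hits enumerate every candidate placement.
    'N' never matches anything.
    """

    def __init__(self, targets: dict[tuple, str], seed_len: int = 16):
        self.targets = targets
        self.seed_len = seed_len
        self.index: dict[str, list] = defaultdict(list)
        for key, text in targets.items():
            for i in range(0, max(len(text) - seed_len + 1, 0)):
                self.index[text[i : i + seed_len]].append((key, i))

    @staticmethod
    def _mismatches(a: str, b: str, limit: int) -> int:
        n = 0
        for x, y in zip(a, b):
            if x != y or x == "N":
                n += 1
                if n > limit:
                    return n
        return n

    def find(self, read: str, max_mismatches: int):
        """All (target_key, offset, mismatches) placements of the read."""
        k = max_mismatches
        n_seeds = k + 1
        sl = min(self.seed_len, max(len(read) // n_seeds, 1))
        hits = {}
        for s in range(n_seeds):
            start = min(s * sl, max(len(read) - sl, 0))
            seed = read[start : start + sl]
            if sl < self.seed_len:
                # short reads: fall back to scanning all targets directly
                for key, text in self.targets.items():
                    for off in range(len(text) - len(read) + 1):
                        mm = self._mismatches(read, text[off : off + len(read)], k)
                        if mm <= k:
                            hits.setdefault((key, off), mm)
                break
            for key, i in self.index.get(seed, ()):
                off = i - start
                text = self.targets[key]
                if off < 0 or off + len(read) > len(text):
                    continue
                if (key, off) in hits:
                    continue
                mm = self._mismatches(read, text[off : off + len(read)], k)
                if mm <= k:
                    hits[(key, off)] = mm
        return [(key, off, mm) for (key, off), mm in hits.items()]


def assign_reads(reads: list[Read], reference_fragments: dict[str, str], max_mismatches: int = 0):
    """Assign bisulfite reads to converted fragment references.

    Returns ``(assignments, observations)``: per-read assignment status and
    pooled per-CG methylated/unmethylated observation counts (a C read at a
    CG position of the appropriate frame is methylated, a T unmethylated).
    """
    if not reference_fragments:
        raise ValueError("empty reference fragment set")
    targets = {}
    frag_cgs = {}
    for fid, seq in reference_fragments.items():
        targets[(fid, "fwd")] = seq.replace("C", "T")
        targets[(fid, "rev")] = revcomp(seq).replace("C", "T")
        frag_cgs[fid] = cg_positions(seq)
    matcher = _Matcher(targets)
    obs: dict[tuple, list] = defaultdict(lambda: [0, 0])
    rows = []
    for read in reads:
        conv = read.sequence.replace("C", "T")
        placements = matcher.find(conv, max_mismatches)
        frag_ids = {key[0] for key, _, _ in placements}
        if not placements:
            rows.append({"read": read.name, "status": "unmapped", "fragment": None,
                         "frame": None, "offset": -1, "mismatches": -1})
            continue
        if len(frag_ids) > 1:
            rows.append({"read": read.name, "status": "ambiguous", "fragment": None,
                         "frame": None, "offset": -1, "mismatches": -1})
            continue
        (fid, frame), off, mm = min(placements, key=lambda h: (h[2], h[0][1], h[1]))
        rows.append({"read": read.name, "status": "assigned", "fragment": fid,
                     "frame": frame, "offset": off, "mismatches": mm})
        fseq = reference_fragments[fid]
        flen = len(fseq)
        rlen = len(read.sequence)
        for p in frag_cgs[fid]:
            if frame == "fwd":
                q = p  # C of the CG on the forward frame
            else:
                q = flen - p - 2  # reverse-strand C sits opposite the G
            if off <= q < off + rlen:
                ch = read.sequence[q - off]
                if ch == "C":
                    obs[(fid, p)][0] += 1
                    obs[(fid, p)][1] += 1
                elif ch == "T":
                    obs[(fid, p)][1] += 1
                # anything else (incl. N) yields no observation
    assignments = pd.DataFrame(
        rows, columns=["read", "status", "fragment", "frame", "offset", "mismatches"]
    )
    observations = pd.DataFrame(
        [
            {"fragment": fid, "pos": int(p), "n_methylated": m, "n_total": t}
            for (fid, p), (m, t) in sorted(obs.items())
        ],
        columns=["fragment", "pos", "n_methylated", "n_total"],
    )
    return assignments, observations


def call_site_methylation(
    observations: pd.DataFrame, min_coverage: int = 10, snp_mask=None
) -> pd.DataFrame:
    """Per-CG methylation calls: only CGs with >= ``min_coverage`` reads and
    not in the SNP mask are called."""
    mask = set(snp_mask) if snp_mask is not None else set()
    calls = observations[observations["n_total"] >= min_coverage].copy()
    if mask:
        keep = [
            (fid, pos) not in mask for fid, pos in zip(calls["fragment"], calls["pos"])
        ]
        calls = calls[keep]
    calls["methylation"] = 100.0 * calls["n_methylated"] / calls["n_total"]
    return calls.reset_index(drop=True)


def fragment_methylation(
    site_calls: pd.DataFrame, fragment_cg_inventory: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Unweighted fragment averages with the coverage filters.

    A fragment passes only when >50% of its CGs AND at least four CGs are
    covered by calls; failing fragments are still reported.  Fragments
    without any CG are reported flagged with pass False.
    """
    by_frag = dict(tuple(site_calls.groupby("fragment")))
    rows = []
    for fid, cg_pos in fragment_cg_inventory.items():
        n_total = len(cg_pos)
        grp = by_frag.get(fid)
        n_cov = 0 if grp is None else int(grp["pos"].isin(list(cg_pos)).sum())
        mean = float("nan")
        if grp is not None and n_cov > 0:
            mean = float(grp.loc[grp["pos"].isin(list(cg_pos)), "methylation"].mean())
        rows.append(
            {
                "fragment": fid,
                "n_cg_total": n_total,
                "n_cg_covered": n_cov,
                "mean_methylation": mean,
                "pass": n_cov > 0.5 * n_total and n_cov >= 4,
                "zero_cg": n_total == 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["fragment", "n_cg_total", "n_cg_covered", "mean_methylation", "pass", "zero_cg"],
    )


def call_insertions(
    native_reads: list[Read], fragment_seqs: dict[str, str], max_mismatches: int = 0
) -> pd.DataFrame:
    """Insertion calls from native (unconverted) reads.

    A fragment is called inserted when strictly more than 50% of its bases
    are covered by at least one assigned read.  Reads are matched against
    both strands of each fragment; multi-fragment matches are discarded.
    """
    targets = {}
    for fid, seq in fragment_seqs.items():
        targets[(fid, "fwd")] = seq
        targets[(fid, "rev")] = revcomp(seq)
    matcher = _Matcher(targets)
    coverage = {fid: np.zeros(len(seq), dtype=bool) for fid, seq in fragment_seqs.items()}
    for read in native_reads:
        placements = matcher.find(read.sequence, max_mismatches)
        frag_ids = {key[0] for key, _, _ in placements}
        if len(frag_ids) != 1:
            continue
        (fid, frame), off, _mm = min(placements, key=lambda h: (h[2], h[0][1], h[1]))
        rlen = len(read.sequence)
        if frame == "fwd":
            coverage[fid][off : off + rlen] = True
        else:
            flen = len(fragment_seqs[fid])
            coverage[fid][flen - off - rlen : flen - off] = True
    rows = []
    for fid, cov in coverage.items():
        frac = float(cov.mean()) if cov.size else 0.0
        rows.append({"fragment": fid, "covered_fraction": frac, "inserted": frac > 0.5})
    return pd.DataFrame(rows, columns=["fragment", "covered_fraction", "inserted"])
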