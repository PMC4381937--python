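"""Synthetic genomes, ground-truth methylomes, DNase tracks and bisulfite reads.

The generator emulates the statistical structure the downstream analyses
assume: CG-dense island-like regions embedded in a CG-poor background,
a ground-truth methylome following the sigmoidal CG-density law locally
modulated by transcription-factor binding, DNase cuts concentrated in a
footprint around bound sites, bisulfite read sets over library fragments,
and paired condition methylomes (differentiation-like factor loss and
cancer-like density-independent gain).

CG density is controlled directly: CG dinucleotides are planted at evenly
spaced, jittered positions to hit each region's target density, and all
remaining bases are drawn so that no further CG is ever created.  Realised
density therefore matches the target almost exactly, which matters because
density is the modelled covariate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cg_model import SigmoidModel, DEFAULT_B, DEFAULT_C, cg_positions, site_density_track
from .combined import collect_cuts
from .io import Read, revcomp

logger = logging.getLogger(__name__)

#: Consensus of the REST position weight matrix; the default motif planted
#: at synthetic TF sites (contains one CG, which the density accounting
#: includes).
DEFAULT_TF_MOTIF = "GACTTTCAGCACCATGGACAGCGCCACTG"


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome.

    Densities are CG starts per 100 bp; ``n_islands`` and ``n_tf_sites``
    are per contig.  TF motif instances are planted anywhere on the
    contig — background sites emulate CG-poor distal regulatory regions,
    island sites emulate bound CpG islands — and are assigned factor
    identities round-robin from ``tf_factors``.
    """

    n_contigs: int = 3
    contig_length: int = 50_000
    n_islands: int = 10
    island_length_range: tuple[int, int] = (800, 2000)
    island_density_range: tuple[float, float] = (3.0, 20.0)
    background_density: float = 1.0
    n_tf_sites: int = 8
    tf_motif: str = DEFAULT_TF_MOTIF
    tf_factors: tuple[str, ...] = ("Oct4", "REST")
    min_island_gap: int = 300
    seed: int = 0

    def validate(self) -> None:
        lo_d, hi_d = self.island_density_range
        for d in (lo_d, hi_d, self.background_density):
            if not 0.0 <= d <= 50.0:
                raise ValueError("densities must lie in [0, 50]")
        lo_l, hi_l = self.island_length_range
        if not 0 < lo_l <= hi_l <= self.contig_length:
            raise ValueError("island lengths must be positive and <= contig length")
        if lo_d > hi_d:
            raise ValueError("island density range must be ordered")
        if set(self.tf_motif) - set("ACGT"):
            raise ValueError("tf_motif must be A/C/G/T")


def _plant_cgs(chars, fixed, start, end, density, rng) -> None:
    """Plant CG dinucleotides in [start, end) to reach the target density,
    counting CGs already present in fixed (motif) positions."""
    length = end - start
    existing = sum(
        1
        for p in range(start, end - 1)
        if fixed[p] and fixed[p + 1] and chars[p] == "C" and chars[p + 1] == "G"
    )
    target = int(round(density * length / 100.0))
    need = target - existing
    if need <= 0:
        return
    slot = length / need
    prev = start - 2
    for k in range(need):
        lo = start + int(np.floor(k * slot))
        hi = min(start + int(np.floor((k + 1) * slot)), end - 1)
        cands = [
            p
            for p in range(max(lo, prev + 2), hi)
            if not fixed[p] and not fixed[p + 1]
        ]
        if not cands:
            continue  # rare shortfall near planted motifs; tolerated
        p = cands[rng.integers(0, len(cands))]
        chars[p], chars[p + 1] = "C", "G"
        fixed[p] = fixed[p + 1] = True
        prev = p


_FILL_BASES = "ACGT"
_FILL_WEIGHTS = np.array([0.3, 0.2, 0.2, 0.3])


def _fill_background(chars, fixed, rng) -> None:
    """Fill unfixed positions left to right without ever creating a CG:
    no G directly after a C, no C directly before a fixed G."""
    n = len(chars)
    r = rng.random(n)
    for i in range(n):
        if fixed[i]:
            continue
        ban_g = i > 0 and chars[i - 1] == "C"
        ban_c = i + 1 < n and fixed[i + 1] and chars[i + 1] == "G"
        w = _FILL_WEIGHTS.copy()
        if ban_g:
            w[2] = 0.0
        if ban_c:
            w[1] = 0.0
        cum = np.cumsum(w / w.sum())
        chars[i] = _FILL_BASES[int(np.searchsorted(cum, r[i], side="right"))]


def generate_genome(spec: SyntheticGenomeSpec):
    """Generate (genome, island annotation, TF-site annotation).

    Islands are placed non-overlapping with at least ``min_island_gap`` bp
    between them; annotations use 0-based half-open coordinates.  The same
    spec and seed always yield byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    island_rows, site_rows = [], []
    site_counter = 0
    for ci in range(spec.n_contigs):
        name = f"chr{ci + 1}"
        L = spec.contig_length
        n_isl = spec.n_islands
        lengths = (
            rng.integers(spec.island_length_range[0], spec.island_length_range[1] + 1, n_isl)
            if n_isl
            else np.array([], dtype=int)
        )
        dens = rng.uniform(*spec.island_density_range, n_isl)
        gap = spec.min_island_gap
        free = L - int(lengths.sum()) - gap * (n_isl + 1)
        if free < 0:
            raise ValueError(f"requested islands do not fit contig {name}")
        extra = rng.multinomial(free, np.ones(n_isl + 1) / (n_isl + 1)) if n_isl else [free]
        islands = []
        pos = 0
        for k in range(n_isl):
            pos += gap + int(extra[k])
            islands.append((pos, pos + int(lengths[k]), float(dens[k])))
            pos += int(lengths[k])

        chars = [""] * L
        fixed = np.zeros(L, dtype=bool)

        # TF sites anywhere on the contig (CG-poor background sites emulate
        # distal low-methylated regions, island sites bound CGIs), pairwise
        # non-overlapping
        placed_sites = []
        mlen = len(spec.tf_motif)
        for _ in range(spec.n_tf_sites):
            for _attempt in range(1000):
                s = int(rng.integers(0, L - mlen))
                if all(s + mlen <= a or b <= s for a, b, _f in placed_sites):
                    factor = spec.tf_factors[site_counter % len(spec.tf_factors)]
                    placed_sites.append((s, s + mlen, factor))
                    site_counter += 1
                    break
            else:  # pragma: no cover - pathological spec
                raise ValueError(f"could not place TF sites on contig {name}")
        for s, e, factor in placed_sites:
            chars[s:e] = list(spec.tf_motif)
            fixed[s:e] = True
            site_rows.append({"contig": name, "start": s, "end": e, "factor": factor})

        # plant CGs region by region (islands, then background spans)
        for s, e, d in islands:
            _plant_cgs(chars, fixed, s, e, d, rng)
        bounds = [0] + [x for s, e, _ in islands for x in (s, e)] + [L]
        for s, e in zip(bounds[::2], bounds[1::2]):
            if e > s:
                _plant_cgs(chars, fixed, s, e, spec.background_density, rng)
        _fill_background(chars, fixed, rng)
        genome[name] = "".join(chars)
        island_rows.extend(
            {"contig": name, "start": s, "end": e, "target_density": d} for s, e, d in islands
        )
    islands_df = pd.DataFrame(island_rows, columns=["contig", "start", "end", "target_density"])
    sites_df = pd.DataFrame(site_rows, columns=["contig", "start", "end", "factor"])
    return genome, islands_df, sites_df


def generate_ground_truth(
    genome: dict[str, str],
    tf_sites: pd.DataFrame | None = None,
    *,
    b: float = DEFAULT_B,
    c: float = DEFAULT_C,
    tf_effect: float = 90.0,
    tf_halfwidth: int = 150,
    dhs_rate_bound: float = 15.0,
    dhs_rate_unbound: float = 15.0,
    dhs_footprint: int = 150,
    window: int = 300,
    seed: int = 0,
):
    """Ground-truth methylome and DNase cut track for a genome.

    Unbound CGs follow the sigmoid of their local CG density (``window``
    bp); CGs within ``tf_halfwidth`` bp of a bound TF site have their
    methylation reduced multiplicatively by ``tf_effect`` percent, which
    keeps values inside [0, 100] without clipping.  DNase cut events are
    Poisson: ``dhs_rate_bound`` expected cuts per bound site, spread
    uniformly over a +/- ``dhs_footprint`` bp footprint, on top of a
    uniform background of ``dhs_rate_unbound`` expected cuts per
    ``window`` bp.  Per-CG ``dhs_cuts`` are the track collected in a
    ``window`` bp window around each CG.

    Returns ``(truth, cut_track)``; ``truth`` has one row per CG
    (contig, pos, cg_density, true_methylation, bound_factors, dhs_cuts).
    """
    if b >= 0:
        raise ValueError("slope b must be negative for methylation data")
    if not 0.0 <= tf_effect <= 100.0:
        raise ValueError("tf_effect must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    model = SigmoidModel(b=b, c=c)
    truth_rows = []
    cut_rows = []
    for contig, seq in genome.items():
        pos = cg_positions(seq)
        sites = (
            tf_sites[tf_sites["contig"] == contig]
            if tf_sites is not None
            else pd.DataFrame(columns=["start", "end", "factor"])
        )
        if pos.size:
            dens = site_density_track(seq, pos, window=window)
            meth = model.predict(dens)
            bound: list[set] = [set() for _ in range(pos.size)]
            for _, site in sites.iterrows():
                lo, hi = site["start"] - tf_halfwidth, site["end"] + tf_halfwidth
                for i in np.nonzero((pos >= lo) & (pos < hi))[0]:
                    bound[i].add(site["factor"])
            is_bound = np.array([len(s) > 0 for s in bound])
            meth = np.where(is_bound, meth * (1.0 - tf_effect / 100.0), meth)
            meth = np.clip(meth, 0.0, 100.0)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": pos,
                        "cg_density": dens,
                        "true_methylation": meth,
                        "bound_factors": [";".join(sorted(s)) for s in bound],
                    }
                )
            )
        # DNase cut events
        events = []
        for _, site in sites.iterrows():
            n = rng.poisson(dhs_rate_bound)
            mid = (site["start"] + site["end"]) // 2
            events.append(
                np.clip(mid + rng.integers(-dhs_footprint, dhs_footprint + 1, n), 0, len(seq) - 1)
            )
        n_bg = rng.poisson(dhs_rate_unbound / window * len(seq))
        events.append(rng.integers(0, len(seq), n_bg))
        ev = np.concatenate(events) if events else np.array([], dtype=int)
        if ev.size:
            upos, ucnt = np.unique(ev, return_counts=True)
            cut_rows.append(pd.DataFrame({"contig": contig, "pos": upos, "cuts": ucnt}))
    cut_track = (
        pd.concat(cut_rows, ignore_index=True)
        if cut_rows
        else pd.DataFrame(columns=["contig", "pos", "cuts"])
    )
    if not truth_rows:
        warnings.warn("genome contains no CG dinucleotides: empty ground truth", stacklevel=2)
        truth = pd.DataFrame(
            columns=["contig", "pos", "cg_density", "true_methylation", "bound_factors", "dhs_cuts"]
        )
        return truth, cut_track
    truth = pd.concat(truth_rows, ignore_index=True)
    truth["dhs_cuts"] = collect_cuts(cut_track, truth, window=window)
    return truth, cut_track


def simulate_bisulfite_reads(
    genome: dict[str, str],
    fragments,
    truth: pd.DataFrame,
    *,
    reads_per_fragment: int = 50,
    target_coverage: float | None = None,
    read_length: int = 80,
    conversion_rate: float = 1.0,
    seed: int = 0,
) -> list[Read]:
    """Simulate bisulfite reads over library fragments.

    With ``target_coverage`` given, the read count per fragment is scaled
    to its length so that mean per-base coverage hits the target;
    otherwise every fragment receives ``reads_per_fragment`` reads.

    At each CG the cytosine survives conversion with probability
    true_methylation/100; unmethylated and non-CG cytosines convert C->T
    with probability ``conversion_rate``.  Reads come from both strands;
    reverse-strand reads show the G->A pattern on the forward frame and
    are emitted as the reverse-strand sequence (reverse complement).  Read
    names encode the fragment of origin, strand and start for oracle use.
    """
    if not 0.0 <= conversion_rate <= 1.0:
        raise ValueError("conversion_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    meth_by_contig = {
        contig: dict(zip(grp["pos"], grp["true_methylation"]))
        for contig, grp in truth.groupby("contig")
    }
    reads: list[Read] = []
    frag_iter = fragments.fragments if hasattr(fragments, "fragments") else fragments
    for frag in frag_iter:
        contig, start, end = frag.contig, frag.start, frag.end
        gseq = genome[contig]
        fseq = gseq[start:end]
        flen = len(fseq)
        frag_id = f"{contig}:{start}-{end}"
        mmap = meth_by_contig.get(contig, {})
        # per-position methylation probability on the forward frame
        mp_c = np.zeros(flen)  # for C of a CG
        mp_g = np.zeros(flen)  # for G of a CG (symmetric methylation)
        arr = np.frombuffer(fseq.encode(), dtype=np.uint8)
        for i in range(flen):
            g = start + i
            if fseq[i] == "C" and g + 1 < len(gseq) and gseq[g + 1] == "G":
                mp_c[i] = mmap.get(g, 0.0) / 100.0
            elif fseq[i] == "G" and g > 0 and gseq[g - 1] == "C":
                mp_g[i] = mmap.get(g - 1, 0.0) / 100.0
        rl = read_length
        if rl > flen:
            logger.warning("read length %d exceeds fragment %s; truncated", rl, frag_id)
            rl = flen
        n_reads = (
            reads_per_fragment
            if target_coverage is None
            else max(1, int(np.ceil(target_coverage * flen / rl)))
        )
        for _ in range(n_reads):
            off = int(rng.integers(0, flen - rl + 1))
            sub = arr[off : off + rl].copy()
            if rng.random() < 0.5:  # forward strand
                idx = np.nonzero(sub == ord("C"))[0]
                keep_m = rng.random(idx.size) < mp_c[off + idx]
                conv = rng.random(idx.size) < conversion_rate
                sub[idx[~keep_m & conv]] = ord("T")
                seq_out = sub.tobytes().decode()
                strand = "+"
            else:  # reverse strand: G->A on the forward frame, then revcomp
                idx = np.nonzero(sub == ord("G"))[0]
                keep_m = rng.random(idx.size) < mp_g[off + idx]
                conv = rng.random(idx.size) < conversion_rate
                sub[idx[~keep_m & conv]] = ord("A")
                seq_out = revcomp(sub.tobytes().decode())
                strand = "-"
            reads.append(Read(f"{frag_id}|{strand}|{start + off}", seq_out))
    return reads


def generate_condition_variant(
    truth: pd.DataFrame,
    mode: str,
    *,
    model: SigmoidModel | None = None,
    lost_factors=None,
    epsilon: float | None = None,
    islands: pd.DataFrame | None = None,
    dhs_rate_unbound: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Second-condition methylome derived from a ground truth.

    ``differentiation``: CGs bound only by lost factors revert to the
    sigmoid prediction of their density (a gain, since binding had reduced
    them) and their DNase cuts reset to the unbound rate; all other CGs
    are unchanged.  ``cancer``: every island CG gains ``epsilon`` points
    (clipped at 100) regardless of density; DNase is unchanged.
    """
    out = truth.copy(deep=True)
    rng = np.random.default_rng(seed)
    if mode == "differentiation":
        lost = set(lost_factors or ())
        known = set()
        for s in truth["bound_factors"]:
            known.update(f for f in s.split(";") if f)
        unknown = lost - known
        if unknown:
            raise ValueError(f"unknown factor ids: {sorted(unknown)}")
        if not lost:
            return out
        sets = [set(f for f in s.split(";") if f) for s in out["bound_factors"]]
        mask = np.array([bool(s) and s <= lost for s in sets])
        if model is None:
            model = SigmoidModel(b=DEFAULT_B, c=DEFAULT_C)
        out.loc[mask, "true_methylation"] = model.predict(
            out.loc[mask, "cg_density"].to_numpy()
        )
        out.loc[mask, "dhs_cuts"] = rng.poisson(dhs_rate_unbound, int(mask.sum())).astype(float)
        out.loc[mask, "bound_factors"] = ""
        return out
    if mode == "cancer":
        if epsilon is None or islands is None:
            raise ValueError("cancer mode needs epsilon and an island annotation")
        mask = np.zeros(len(out), dtype=bool)
        for _, isl in islands.iterrows():
            mask |= (
                (out["contig"] == isl["contig"])
                & (out["pos"] >= isl["start"])
                & (out["pos"] < isl["end"])
            ).to_numpy()
        out.loc[mask, "true_methylation"] = np.clip(
            out.loc[mask, "true_methylation"] + epsilon, 0.0, 100.0
        )
        return out
    raise ValueError(f"unknown mode {mode!r}")
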