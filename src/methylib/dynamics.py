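"""Condition-pair methylation dynamics relative to the CG-density prediction.

The CG-only model caps how far methylation can move: when a factor stops
binding during differentiation, the freed CGs drift up toward — but not
beyond — the methylation their CG density predicts, whereas cancer-like
hypermethylation gains ground even at CGs whose density predicts an
unmethylated state.  This module provides a simplified rule-based
methylome segmentation (UMR/LMR/FMR), per-prediction-bin change-percentile
profiles, the DHS-change association table, density-matched motif
enrichment around changing CGs, constitutive low-prediction patches inside
islands, and composite methylation profiles around annotated sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cg_model import site_density_track
from .design import PWM, pwm_score_range

SEGMENT_CLASSES = ("UMR", "LMR", "FMR")


def _runs(mask: np.ndarray):
    """(start_idx, end_idx) of maximal True runs (half-open on indices)."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def segment_methylome(
    site_calls: pd.DataFrame,
    hypo_threshold: float = 30.0,
    min_run: int = 3,
    umr_min_cgs: int = 30,
) -> pd.DataFrame:
    """Rule-based segmentation into UMR / LMR / FMR.

    Maximal runs of >= ``min_run`` consecutive CGs at <= ``hypo_threshold``
    % methylation become hypomethylated segments — UMR when they hold >=
    ``umr_min_cgs`` CGs (CG-rich islands), LMR otherwise (CG-poor distal
    sites).  All remaining CGs are grouped into FMR segments.  Every
    called CG belongs to exactly one segment.
    """
    seg_rows = []
    for contig, grp in site_calls.groupby("contig", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        meth = grp["methylation"].to_numpy(dtype=float)
        hypo = meth <= hypo_threshold
        assigned = np.zeros(len(pos), dtype=bool)
        for a, b in _runs(hypo):
            if b - a >= min_run:
                assigned[a:b] = True
                seg_rows.append(
                    {
                        "contig": contig,
                        "start": int(pos[a]),
                        "end": int(pos[b - 1]) + 2,
                        "class": "UMR" if b - a >= umr_min_cgs else "LMR",
                        "n_cgs": int(b - a),
                        "mean_methylation": float(meth[a:b].mean()),
                    }
                )
        for a, b in _runs(~assigned):
            seg_rows.append(
                {
                    "contig": contig,
                    "start": int(pos[a]),
                    "end": int(pos[b - 1]) + 2,
                    "class": "FMR",
                    "n_cgs": int(b - a),
                    "mean_methylation": float(meth[a:b].mean()),
                }
            )
    cols = ["contig", "start", "end", "class", "n_cgs", "mean_methylation"]
    return (
        pd.DataFrame(seg_rows, columns=cols)
        .sort_values(["contig", "start"])
        .reset_index(drop=True)
    )


def _join_tracks(a: pd.DataFrame, b: pd.DataFrame, cols=("methylation",)):
    left = a[["contig", "pos", *cols]].rename(columns={c: f"{c}_a" for c in cols})
    right = b[["contig", "pos", *cols]].rename(columns={c: f"{c}_b" for c in cols})
    return left.merge(right, on=["contig", "pos"], how="inner")


def _filter_to_segments(df: pd.DataFrame, segments: pd.DataFrame, klass: str) -> pd.DataFrame:
    segs = segments[segments["class"] == klass]
    mask = np.zeros(len(df), dtype=bool)
    for _, s in segs.iterrows():
        mask |= (
            (df["contig"] == s["contig"]) & (df["pos"] >= s["start"]) & (df["pos"] < s["end"])
        ).to_numpy()
    return df[mask]


def change_percentile_profile(
    methylome_a: pd.DataFrame,
    methylome_b: pd.DataFrame,
    cg_predictions: pd.DataFrame,
    restrict_to: tuple[pd.DataFrame, str] | None = None,
    bin_width: float = 10.0,
    percentile: float = 99.0,
) -> pd.DataFrame:
    """Per-CG change (B - A) binned by the CG-density-predicted methylation.

    Reports the requested upper percentile of changes per bin (a proxy for
    the maximal amplitude of change at that predicted level), the median,
    and the bin occupancy.  Bins cover [0, 100] in ``bin_width`` steps.
    """
    merged = _join_tracks(methylome_a, methylome_b)
    if merged.empty:
        raise ValueError("methylomes share no CG coordinates")
    merged = merged.merge(
        cg_predictions[["contig", "pos", "predicted"]], on=["contig", "pos"], how="inner"
    )
    if merged.empty:
        raise ValueError("predictions cover none of the shared CGs")
    if restrict_to is not None:
        segments, klass = restrict_to
        merged = _filter_to_segments(merged, segments, klass)
    change = merged["methylation_b"].to_numpy() - merged["methylation_a"].to_numpy()
    pred = merged["predicted"].to_numpy(dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(pred, edges) - 1, 0, len(edges) - 2)
    rows = []
    for k in range(len(edges) - 1):
        sel = change[idx == k]
        rows.append(
            {
                "bin_lo": edges[k],
                "bin_hi": edges[k + 1],
                "bin_mid": (edges[k] + edges[k + 1]) / 2.0,
                "n": int(sel.size),
                "percentile_change": float(np.percentile(sel, percentile)) if sel.size else np.nan,
                "median_change": float(np.median(sel)) if sel.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def dhs_change_association(
    methylome_a: pd.DataFrame,
    methylome_b: pd.DataFrame,
    dhs_a: pd.DataFrame,
    dhs_b: pd.DataFrame,
    density: pd.DataFrame,
    density_bins,
    dhs_delta_bins,
) -> pd.DataFrame:
    """Methylation-change distribution per (CG-density bin x DHS-change bin).

    All four tracks must share CG coordinates; per cell the median and
    quartiles of methylation change are reported, keeping empty cells as
    n = 0 rows.
    """
    meth = _join_tracks(methylome_a, methylome_b)
    dhs = _join_tracks(dhs_a, dhs_b, cols=("cuts",))
    merged = meth.merge(dhs, on=["contig", "pos"], how="inner").merge(
        density[["contig", "pos", "cg_density"]], on=["contig", "pos"], how="inner"
    )
    if merged.empty:
        raise ValueError("tracks share no CG coordinates")
    dmeth = merged["methylation_b"].to_numpy() - merged["methylation_a"].to_numpy()
    ddhs = merged["cuts_b"].to_numpy(dtype=float) - merged["cuts_a"].to_numpy(dtype=float)
    dens = merged["cg_density"].to_numpy(dtype=float)
    density_bins = np.asarray(density_bins, dtype=float)
    dhs_delta_bins = np.asarray(dhs_delta_bins, dtype=float)
    di = np.clip(np.digitize(dens, density_bins) - 1, 0, len(density_bins) - 2)
    hi = np.clip(np.digitize(ddhs, dhs_delta_bins) - 1, 0, len(dhs_delta_bins) - 2)
    rows = []
    for a in range(len(density_bins) - 1):
        for b in range(len(dhs_delta_bins) - 1):
            sel = dmeth[(di == a) & (hi == b)]
            rows.append(
                {
                    "density_lo": density_bins[a],
                    "density_hi": density_bins[a + 1],
                    "dhs_delta_lo": dhs_delta_bins[b],
                    "dhs_delta_hi": dhs_delta_bins[b + 1],
                    "n": int(sel.size),
                    "median_change": float(np.median(sel)) if sel.size else np.nan,
                    "q25_change": float(np.percentile(sel, 25)) if sel.size else np.nan,
                    "q75_change": float(np.percentile(sel, 75)) if sel.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _scan_hits(window_seq: str, pwm: PWM, threshold_frac: float) -> int:
    """Motif hits on both strands: placements whose normalised score
    (score - min) / (max - min) reaches the threshold fraction."""
    from .io import revcomp

    L = len(pwm)
    smin, smax = pwm_score_range(pwm)
    if smax <= smin:
        return 0
    logf = np.log(pwm.frequencies + 0.01)
    n_hits = 0
    for strand_seq in (window_seq, revcomp(window_seq)):
        arr = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
        idx = np.full(arr.shape, -1, dtype=np.int64)
        for j, b in enumerate("ACGT"):
            idx[arr == ord(b)] = j
        if len(arr) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(idx, L)
        valid = (win >= 0).all(axis=1)
        if not valid.any():
            continue
        scores = logf[win[valid], np.arange(L)].sum(axis=1)
        norm = (scores - smin) / (smax - smin)
        n_hits += int((norm >= threshold_frac).sum())
    return n_hits


def motif_enrichment(
    changing_cg_positions: pd.DataFrame,
    stable_cg_positions: pd.DataFrame,
    genome: dict[str, str],
    pwms: dict[str, PWM],
    flank: int = 300,
    hit_threshold_frac: float = 0.8,
    n_density_bins: int = 10,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif counts around changing CGs versus density-matched controls.

    Controls are subsampled (without replacement, seeded) from the stable
    set to match the changing set's CG-density histogram over
    ``n_density_bins`` equal-width bins; density bins without control
    candidates are dropped with a warning.  Per PWM the hit counts in each
    set, the log2 ratio and a label-permutation p-value are reported.
    """
    if changing_cg_positions.empty or stable_cg_positions.empty:
        raise ValueError("both CG sets must be non-empty")
    rng = np.random.default_rng(seed)

    def _density(df):
        out = np.empty(len(df))
        for contig, grp in df.groupby("contig", sort=False):
            out[grp.index.to_numpy()] = site_density_track(
                genome[contig], grp["pos"].to_numpy(), window=2 * flank
            )
        return out

    chg = changing_cg_positions.reset_index(drop=True)
    stb = stable_cg_positions.reset_index(drop=True)
    d_chg, d_stb = _density(chg), _density(stb)
    lo = min(d_chg.min(), d_stb.min())
    hi = max(d_chg.max(), d_stb.max()) + 1e-9
    edges = np.linspace(lo, hi, n_density_bins + 1)
    chg_bin = np.clip(np.digitize(d_chg, edges) - 1, 0, n_density_bins - 1)
    stb_bin = np.clip(np.digitize(d_stb, edges) - 1, 0, n_density_bins - 1)
    keep_chg = np.zeros(len(chg), dtype=bool)
    control_idx = []
    for k in range(n_density_bins):
        n_need = int((chg_bin == k).sum())
        if n_need == 0:
            continue
        cand = np.flatnonzero(stb_bin == k)
        if cand.size == 0:
            warnings.warn(f"density bin {k}: no control candidates, bin dropped", stacklevel=2)
            continue
        keep_chg |= chg_bin == k
        control_idx.append(rng.choice(cand, size=min(n_need, cand.size), replace=False))
    controls = stb.iloc[np.concatenate(control_idx)] if control_idx else stb.iloc[[]]
    chg = chg[keep_chg]

    def _windows(df):
        seqs = []
        for _, row in df.iterrows():
            s = genome[row["contig"]]
            p = int(row["pos"])
            seqs.append(s[max(0, p - flank) : min(len(s), p + flank + 2)])
        return seqs

    win_chg, win_ctl = _windows(chg), _windows(controls)
    rows = []
    for name, pwm in pwms.items():
        hits_chg = np.array([_scan_hits(w, pwm, hit_threshold_frac) for w in win_chg])
        hits_ctl = np.array([_scan_hits(w, pwm, hit_threshold_frac) for w in win_ctl])
        n_c, n_s = int(hits_chg.sum()), int(hits_ctl.sum())
        obs = np.log2((n_c + 1) / (n_s + 1))
        pooled = np.concatenate([hits_chg, hits_ctl])
        n1 = len(hits_chg)
        more_extreme = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            stat = np.log2((perm[:n1].sum() + 1) / (perm[n1:].sum() + 1))
            if abs(stat) >= abs(obs):
                more_extreme += 1
        pval = (1 + more_extreme) / (1 + n_permutations)
        rows.append(
            {
                "pwm": name,
                "n_changing_hits": n_c,
                "n_control_hits": n_s,
                "log2_ratio": float(obs),
                "p_value": float(pval),
                "absent": n_c == 0 and n_s == 0,
            }
        )
    return pd.DataFrame(rows)


def constitutive_patches(
    cg_predictions: pd.DataFrame,
    islands: pd.DataFrame,
    pred_threshold: float = 20.0,
    min_run: int = 2,
):
    """Stretches of successive island CGs predicted below threshold.

    These are the CGs kept unmethylated by density alone, independent of
    TF binding.  Returns (patches, summary) with the fraction of islands
    containing at least one patch and the fraction of island CGs inside
    patches.
    """
    patch_rows = []
    n_islands_with = 0
    n_island_cgs = 0
    n_patch_cgs = 0
    for _, isl in islands.iterrows():
        sel = cg_predictions[
            (cg_predictions["contig"] == isl["contig"])
            & (cg_predictions["pos"] >= isl["start"])
            & (cg_predictions["pos"] < isl["end"])
        ].sort_values("pos")
        pos = sel["pos"].to_numpy()
        pred = sel["predicted"].to_numpy(dtype=float)
        n_island_cgs += len(pos)
        found = False
        for a, b in _runs(pred < pred_threshold):
            if b - a >= min_run:
                found = True
                n_patch_cgs += b - a
                patch_rows.append(
                    {
                        "contig": isl["contig"],
                        "start": int(pos[a]),
                        "end": int(pos[b - 1]) + 2,
                        "n_cgs": int(b - a),
                    }
                )
        n_islands_with += found
    patches = pd.DataFrame(patch_rows, columns=["contig", "start", "end", "n_cgs"])
    summary = {
        "fraction_islands_with_patch": n_islands_with / len(islands) if len(islands) else np.nan,
        "fraction_island_cgs_in_patches": n_patch_cgs / n_island_cgs if n_island_cgs else np.nan,
    }
    return patches, summary


def composite_profile(
    methylome: pd.DataFrame, sites: pd.DataFrame, max_dist: int = 1000, bin_width: int = 50
) -> pd.DataFrame:
    """Average methylation in signed distance bins around site midpoints."""
    rows = []
    for _, site in sites.iterrows():
        mid = (site["start"] + site["end"]) // 2
        sel = methylome[methylome["contig"] == site["contig"]]
        d = sel["pos"].to_numpy() - mid
        keep = np.abs(d) <= max_dist
        rows.append(pd.DataFrame({"dist": d[keep], "methylation": sel["methylation"].to_numpy()[keep]}))
    if not rows:
        return pd.DataFrame(columns=["dist_bin_mid", "n", "mean_methylation"])
    df = pd.concat(rows, ignore_index=True)
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width)
    idx = np.clip(np.digitize(df["dist"], edges) - 1, 0, len(edges) - 2)
    out = []
    for k in range(len(edges) - 1):
        sel = df["methylation"].to_numpy()[idx == k]
        out.append(
            {
                "dist_bin_mid": (edges[k] + edges[k + 1]) / 2.0,
                "n": int(sel.size),
                "mean_methylation": float(sel.mean()) if sel.size else np.nan,
            }
        )
    return pd.DataFrame(out)
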