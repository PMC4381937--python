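"""Combined prediction of methylation from CG density and DNase hypersensitivity.

DNase-seq cut counts are an indirect readout of transcription-factor
binding.  Raw per-CG cut counts (collected in a window around each CG,
300 bp by default) are preprocessed — winsorised at an upper quantile to
remove outliers, log-transformed and binned into ordered categories with
"zero cuts" as its own category — and then combined with the CG-only
sigmoid prediction in an ordinary least-squares model.  Models are fitted
on two contigs and evaluated on the remainder of the genome (held-out
R-squared), optionally across a range of collection-window sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANTS = ("CG", "DHS", "CG+DHS")


def collect_cuts(cut_track: pd.DataFrame, sites: pd.DataFrame, window: int = 300) -> np.ndarray:
    """Sum DNase cuts within a window centred on each site.

    ``cut_track`` holds per-position cut counts (contig, pos, cuts);
    ``sites`` holds the positions to collect at (contig, pos).  Returns an
    array aligned with ``sites`` rows.
    """
    out = np.zeros(len(sites), dtype=float)
    for contig, grp in sites.groupby("contig", sort=False):
        track = cut_track[cut_track["contig"] == contig]
        pos = np.sort(track["pos"].to_numpy())
        w = track.set_index("pos")["cuts"].reindex(pos).to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(w)])
        p = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, p - window // 2)
        hi = np.searchsorted(pos, p + window - window // 2)
        out[grp.index.to_numpy()] = csum[hi] - csum[lo]
    return out


def preprocess_dhs(
    counts, winsor_quantile: float = 0.99, n_categories: int = 5
) -> pd.DataFrame:
    """Winsorise, log-transform and categorise per-CG DNase cut counts.

    Counts above the winsor quantile are capped; log2(count+1) is computed
    on the capped values; zero counts form category 0 and the nonzero
    values are split into ``n_categories - 1`` quantile bins (categories
    monotone in the winsorised value).
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("cut counts must be nonnegative")
    cap = float(np.quantile(c, winsor_quantile))
    winsorised = np.minimum(c, cap)
    logv = np.log2(winsorised + 1.0)
    category = np.zeros(len(c), dtype=int)
    nonzero = c > 0
    if not nonzero.any():
        warnings.warn("all-zero DNase track: single category", stacklevel=2)
    else:
        edges = np.unique(
            np.quantile(logv[nonzero], np.linspace(0, 1, n_categories)[1:-1])
        )
        category[nonzero] = 1 + np.searchsorted(edges, logv[nonzero], side="right").clip(
            max=n_categories - 2
        )
    return pd.DataFrame(
        {"cuts": c, "winsorized": winsorised, "log2_winsorized": logv, "category": category}
    )


@dataclass
class CombinedModel:
    """A fitted CG+DHS (or DHS-only) linear model and its evaluation."""

    variant: str
    intercept: float
    cg_coefficient: float | None
    category_coefficients: dict[int, float]
    train_contigs: tuple[str, ...]
    heldout_r2: float
    insample_r2: float


@dataclass
class EvaluationReport:
    """Held-out evaluation of the model variants, plus optional window scan."""

    models: dict[str, CombinedModel]
    heldout_r2: dict[str, float]
    insample_r2: dict[str, float]
    train_contigs: tuple[str, ...]
    window_scan: pd.DataFrame | None = None
    predictions: pd.DataFrame | None = field(default=None, repr=False)


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def _design(cg_pred, categories, n_categories, variant):
    cols = [np.ones(len(categories))]
    if variant in ("CG", "CG+DHS"):
        cols.append(np.asarray(cg_pred, dtype=float))
    if variant in ("DHS", "CG+DHS"):
        for k in range(1, n_categories):  # category 0 absorbed by intercept
            cols.append((np.asarray(categories) == k).astype(float))
    return np.column_stack(cols)


def _fit_variant(data, cg_pred, categories, n_categories, train_mask, variant, train_contigs):
    obs = data["methylation"].to_numpy(dtype=float)
    if variant == "CG":
        # the sigmoid prediction is used directly, no refit
        pred = np.asarray(cg_pred, dtype=float)
        model = CombinedModel(
            variant, 0.0, 1.0, {}, train_contigs,
            _r2(obs[~train_mask], pred[~train_mask]),
            _r2(obs[train_mask], pred[train_mask]),
        )
        return model, pred
    X = _design(cg_pred, categories, n_categories, variant)
    beta, *_ = np.linalg.lstsq(X[train_mask], obs[train_mask], rcond=None)
    pred = X @ beta
    j = 1
    cg_coef = None
    if variant == "CG+DHS":
        cg_coef = float(beta[1])
        j = 2
    cat_coefs = {k: float(beta[j + k - 1]) for k in range(1, n_categories)}
    model = CombinedModel(
        variant, float(beta[0]), cg_coef, cat_coefs, train_contigs,
        _r2(obs[~train_mask], pred[~train_mask]),
        _r2(obs[train_mask], pred[train_mask]),
    )
    return model, pred


def fit_and_evaluate(
    data: pd.DataFrame,
    *,
    train_contigs,
    dhs_counts=None,
    cut_track: pd.DataFrame | None = None,
    variants=VARIANTS,
    windows=None,
    window: int = 300,
    winsor_quantile: float = 0.99,
    n_categories: int = 5,
) -> EvaluationReport:
    """Fit CG / DHS / CG+DHS variants on two contigs, evaluate on the rest.

    ``data`` needs columns contig, pos, methylation, cg_pred.  Per-CG DNase
    cut counts come either from ``dhs_counts`` (aligned array) or are
    collected from a positional ``cut_track`` at ``window`` bp.  With
    ``windows`` given, DHS features are recomputed from ``cut_track`` at
    each window size and held-out R-squared reported per window for the
    DHS-containing variants.
    """
    train_contigs = tuple(train_contigs)
    if len(train_contigs) != 2:
        raise ValueError("training uses exactly two contigs")
    contigs = set(data["contig"])
    missing = [c for c in train_contigs if c not in contigs]
    if missing:
        raise ValueError(f"train contigs not found: {missing}")
    if not contigs - set(train_contigs):
        raise ValueError("no held-out contigs: need >=3 contigs")
    data = data.reset_index(drop=True)
    train_mask = data["contig"].isin(train_contigs).to_numpy()
    cg_pred = data["cg_pred"].to_numpy(dtype=float)

    needs_dhs = any(v != "CG" for v in variants) or windows is not None
    if needs_dhs and dhs_counts is None:
        if cut_track is None:
            raise ValueError("provide dhs_counts or a positional cut_track")
        dhs_counts = collect_cuts(cut_track, data, window=window)

    models: dict[str, CombinedModel] = {}
    preds = {}
    categories = None
    if needs_dhs:
        categories = preprocess_dhs(dhs_counts, winsor_quantile, n_categories)["category"].to_numpy()
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
        model, pred = _fit_variant(
            data, cg_pred, categories, n_categories, train_mask, v, train_contigs
        )
        models[v] = model
        preds[v] = pred

    window_scan = None
    if windows is not None:
        if cut_track is None:
            raise ValueError("window scan requires a positional cut_track")
        rows = []
        for w in windows:
            counts_w = collect_cuts(cut_track, data, window=int(w))
            cats_w = preprocess_dhs(counts_w, winsor_quantile, n_categories)["category"].to_numpy()
            for v in variants:
                if v == "CG":
                    continue
                model, _ = _fit_variant(
                    data, cg_pred, cats_w, n_categories, train_mask, v, train_contigs
                )
                rows.append({"window": int(w), "variant": v, "heldout_r2": model.heldout_r2})
        window_scan = pd.DataFrame(rows)

    pred_df = data[["contig", "pos", "methylation"]].copy()
    for v, p in preds.items():
        pred_df[f"pred_{v}"] = p
    return EvaluationReport(
        models=models,
        heldout_r2={v: m.heldout_r2 for v, m in models.items()},
        insample_r2={v: m.insample_r2 for v, m in models.items()},
        train_contigs=train_contigs,
        window_scan=window_scan,
        predictions=pred_df,
    )


def accuracy_within(
    predictions, observations, tol: float = 20.0, context_labels=None
) -> pd.DataFrame:
    """Proportion of CGs predicted within ``tol`` methylation points (inclusive),
    overall and per genomic context label (e.g. UMR/LMR/FMR)."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations must have equal length")
    hit = np.abs(pred - obs) <= tol
    rows = [{"context": "all", "n": len(hit), "accuracy": float(hit.mean()) if len(hit) else np.nan}]
    if context_labels is not None:
        labels = pd.Series(context_labels)
        cats = labels.cat.categories if isinstance(labels.dtype, pd.CategoricalDtype) else sorted(labels.unique())
        for ctx in cats:
            m = (labels == ctx).to_numpy()
            rows.append(
                {
                    "context": ctx,
                    "n": int(m.sum()),
                    "accuracy": float(hit[m].mean()) if m.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)
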