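"""CG-density computation and the fixed-asymptote sigmoidal "CG-only" model.

The local density of CG dinucleotides is the single covariate of the
CG-only model of DNA methylation: a fragment of prokaryotic DNA inserted
into a mammalian genome acquires methylation that decreases sigmoidally
with its CG density.  Because methylation is a percentage with known
saturation behaviour, both asymptotes are fixed before fitting (100%
methylation at low density, 0% at high density), leaving only the slope
``b`` and the inflection density ``c`` free::

    y(x) = y_min + (y_max - y_min) / (1 + exp(-b * (x - c)))

with ``b < 0`` for methylation data.  Density is expressed as CG
dinucleotide starts per 100 bp, either over a whole fragment or over a
300 bp window centred on an individual CG.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Slope and inflection of the CG-only model fitted to the prokaryotic
#: fragment library (per CGs/100 bp and CGs/100 bp respectively).
DEFAULT_B = -0.337
DEFAULT_C = 6.917

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class SigmoidModel:
    """Fixed-asymptote sigmoid mapping CG density to % methylation."""

    b: float
    c: float
    y_min: float = 0.0
    y_max: float = 100.0
    rss: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not self.y_max > self.y_min:
            raise ValueError("upper asymptote must exceed lower asymptote")

    def predict(self, density):
        """Predicted % methylation at the given CG density (vectorised)."""
        x = np.asarray(density, dtype=float)
        y = self.y_min + (self.y_max - self.y_min) / (1.0 + np.exp(-self.b * (x - self.c)))
        return float(y) if np.ndim(density) == 0 else y

    def inverse(self, methylation: float) -> float:
        """Density at which the model predicts the given % methylation."""
        y = float(methylation)
        if not self.y_min < y < self.y_max:
            raise ValueError("methylation must lie strictly between the asymptotes")
        return self.c - np.log((self.y_max - self.y_min) / (y - self.y_min) - 1.0) / self.b

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"b": self.b, "c": self.c, "y_min": self.y_min, "y_max": self.y_max}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SigmoidModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def cg_count(seq: str) -> int:
    """Number of CG dinucleotide starts (CpG is its own reverse complement,
    so forward-strand counting covers both strands without double counting)."""
    return seq.count("CG")


def cg_density(seq: str, pos: int | None = None, window: int = 300) -> float:
    """CG density in CGs per 100 bp.

    Fragment mode (``pos is None``): CG starts over the whole sequence,
    normalised by its length.  Site mode: CG starts within a ``window`` bp
    window centred on the C at ``pos``, truncated at contig edges and
    normalised by the actual window length.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if pos is None:
        return 100.0 * cg_count(seq) / len(seq)
    lo = max(0, pos - window // 2)
    hi = min(len(seq), pos + window - window // 2)
    return 100.0 * seq.count("CG", lo, hi) / (hi - lo)


def cg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every forward-strand CG."""
    return np.array([m.start() for m in re.finditer("CG", seq)], dtype=np.int64)


def site_density_track(seq: str, positions: np.ndarray, window: int = 300) -> np.ndarray:
    """Vectorised site-mode ``cg_density`` for many positions on one contig."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    positions = np.asarray(positions, dtype=np.int64)
    starts = cg_positions(seq)
    lo = np.maximum(0, positions - window // 2)
    hi = np.minimum(len(seq), positions + window - window // 2)
    # a CG start at p is inside [lo, hi) iff lo <= p <= hi - 2
    n = np.searchsorted(starts, hi - 1) - np.searchsorted(starts, lo)
    return 100.0 * n / (hi - lo)


def fit_sigmoid(
    densities,
    methylations,
    *,
    min_fragment_length: int = 250,
    fragment_lengths=None,
    y_min: float = 0.0,
    y_max: float = 100.0,
    p0: tuple[float, float] = (-0.3, 7.0),
    xtol: float = 1e-8,
) -> SigmoidModel:
    """Nonlinear least squares for (b, c) with asymptotes fixed.

    When ``fragment_lengths`` is given, fragments shorter than
    ``min_fragment_length`` are dropped before fitting: size-normalised CG
    counts of short fragments are unstable.
    """
    x = np.asarray(densities, dtype=float)
    y = np.asarray(methylations, dtype=float)
    if x.shape != y.shape:
        raise ValueError("densities and methylations must have equal length")
    if fragment_lengths is not None:
        keep = np.asarray(fragment_lengths) >= min_fragment_length
        x, y = x[keep], y[keep]
    if x.size < 3 or np.ptp(x) <= 1.0:
        raise ValueError("need >=3 retained points spanning >1 density unit")
    if np.ptp(y) == 0.0:
        raise ValueError("no identifiable inflection: methylation is constant")

    def f(xv, b, c):
        return y_min + (y_max - y_min) / (1.0 + np.exp(-b * (xv - c)))

    try:
        popt, _ = optimize.curve_fit(f, x, y, p0=p0, xtol=xtol, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise ValueError(f"sigmoid fit did not converge: {exc}") from exc
    b, c = (float(v) for v in popt)
    resid = y - f(x, b, c)
    rss = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else float("nan")
    return SigmoidModel(b=b, c=c, y_min=y_min, y_max=y_max, rss=rss, r_squared=r2)


def _dinucleotide_frequencies(seq: str) -> np.ndarray:
    """Overlapping dinucleotide counts per 100 bp, in DINUCLEOTIDES order."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    a, b = arr[:-1], arr[1:]
    out = np.empty(16, dtype=float)
    for i, d in enumerate(DINUCLEOTIDES):
        out[i] = np.count_nonzero((a == ord(d[0])) & (b == ord(d[1])))
    return 100.0 * out / len(seq)


def dinucleotide_screen(fragment_sequences, methylations) -> pd.DataFrame:
    """Per-dinucleotide linear regression against fragment methylation.

    For each of the 16 dinucleotides, its frequency per fragment (per
    100 bp) is regressed on fragment methylation; Pearson R and the slope
    p-value are reported.  Dinucleotides with zero frequency variance are
    flagged and their R left undefined.
    """
    y = np.asarray(methylations, dtype=float)
    if len(fragment_sequences) < 3:
        raise ValueError("need >=3 fragments")
    freqs = np.vstack([_dinucleotide_frequencies(s) for s in fragment_sequences])
    rows = []
    for i, d in enumerate(DINUCLEOTIDES):
        f = freqs[:, i]
        if np.ptp(f) == 0.0:
            rows.append({"dinucleotide": d, "r": np.nan, "p_value": np.nan, "degenerate": True})
            continue
        res = stats.linregress(f, y)
        rows.append(
            {"dinucleotide": d, "r": res.rvalue, "p_value": res.pvalue, "degenerate": False}
        )
    return pd.DataFrame(rows)
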