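"""Plot-ready summaries of simulated null distributions."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["summarize_null", "null_vectors_frame"]


def null_vectors_frame(m_ratios, d_ratios) -> pd.DataFrame:
    """The two null vectors as a tidy two-column table (histogram-ready)."""
    return pd.DataFrame({"m_ratio": np.asarray(m_ratios, dtype=float),
                         "d_ratio": np.asarray(d_ratios, dtype=float)})


def summarize_null(null: np.ndarray, observed: float,
                   n_bins: int = 50) -> dict:
    """Histogram bin counts plus the observed value's quantile in the null.

    The quantile is the fraction of null values <= observed (1.0 when the
    observed value sits at or beyond the null maximum).  Bin counts sum to
    the null sample size.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null vector")
    lo = min(null.min(), observed)
    hi = max(null.max(), observed)
    if hi == lo:
        hi = lo + 1.0
    counts, edges = np.histogram(null, bins=n_bins, range=(lo, hi))
    return {
        "observed": float(observed),
        "quantile": float(np.mean(null <= observed)),
        "n": int(null.size),
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
    }
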