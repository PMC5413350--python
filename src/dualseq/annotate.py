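"""HSSP-distance filtering of homology-based functional annotations.

Short or low-identity alignments do not reliably imply shared function.
The HSSP curve gives, for each alignment length L, the percent identity
above which homology is considered structurally informative:

    L <= 11         : 100
    11 < L <= 450   : n + 480 * L^(-0.32 * (1 + exp(-L/1000)))
    L > 450         : n + 19.5

with curve offset ``n`` (0 by default). A hit's HSSP distance is its
percent identity minus the curve value at its alignment length; only hits
with distance strictly greater than a margin (default 5) are retained,
and each gene receives the retained hit with maximal distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def hssp_curve(alignment_length, n_offset: float = 0.0):
    """Percent-identity threshold at the given alignment length(s)."""
    L = np.asarray(alignment_length, dtype=float)
    scalar = L.ndim == 0
    L = np.atleast_1d(L)
    if np.any(L < 1):
        raise ValueError("alignment length must be >= 1")
    out = np.empty_like(L)
    short = L <= 11
    mid = (L > 11) & (L <= 450)
    long_ = L > 450
    out[short] = 100.0
    out[mid] = n_offset + 480.0 * L[mid] ** (-0.32 * (1.0 + np.exp(-L[mid] / 1000.0)))
    out[long_] = n_offset + 19.5
    return float(out[0]) if scalar else out


def score_annotations(
    hits: pd.DataFrame, n_offset: float = 0.0, min_dist: float = 5.0
) -> pd.DataFrame:
    """Add ``hssp_dist`` and ``retained`` columns to an annotation hit table.

    Expects columns qseqid, sseqid, pident, length (outfmt-6 naming).
    """
    out = hits.copy()
    out["hssp_dist"] = out["pident"].to_numpy(dtype=float) - hssp_curve(
        out["length"].to_numpy(), n_offset=n_offset
    )
    out["retained"] = out["hssp_dist"] > min_dist
    return out


def filter_annotations(
    hits: pd.DataFrame, min_dist: float = 5.0, n_offset: float = 0.0
) -> pd.DataFrame:
    """One annotation per gene: the retained hit with maximal HSSP distance.

    Hits at or below ``min_dist`` are discarded (strict >). Ties on the
    distance are broken by subject id (lexicographic).
    """
    scored = score_annotations(hits, n_offset=n_offset, min_dist=min_dist)
    surv = scored[scored["retained"]]
    if surv.empty:
        return surv.drop(columns=["retained"])
    surv = surv.sort_values(
        ["qseqid", "hssp_dist", "sseqid"], ascending=[True, False, True]
    )
    best = surv.groupby("qseqid", sort=False).head(1).drop(columns=["retained"])
    return best.reset_index(drop=True)
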