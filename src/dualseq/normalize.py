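"""Between-sample normalization and GC-bias handling.

Library-size scaling uses the trimmed mean of M-values (TMM): pairwise
log-ratios against a reference sample are doubly trimmed (by M and by
average abundance A) and combined with inverse-variance weights, making
the factors robust to composition differences between libraries.

GC bias across library preparations is (i) diagnosed with a two-sample
Kolmogorov–Smirnov test on GC-content distributions and (ii) corrected by
additive per-sample log-scale offsets estimated in GC deciles — a
median-polish approximation to conditional quantile normalization that
feeds the downstream NB GLM as per-observation offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors."""

    sample_ids: np.ndarray
    library_size: np.ndarray
    tmm_factor: np.ndarray
    reference_sample: str

    @property
    def effective_size(self) -> np.ndarray:
        return self.library_size * self.tmm_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_size": self.library_size,
                "tmm_factor": self.tmm_factor,
                "effective_size": self.effective_size,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = m.size
    if n == 0:
        return 1.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    f = (w[keep2] * m[keep2]).sum() / w[keep2].sum()
    return float(2.0**f)


def tmm_factors(
    counts, trim_M: float = DEFAULT_TRIM_M, trim_A: float = DEFAULT_TRIM_A
) -> NormFactors:
    """TMM scaling factors, rescaled to geometric mean 1.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the cross-sample mean of that quantity. Genes with a zero
    count in either member of a pair are excluded from its M/A values.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    y = df.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need at least two samples")
    if np.any(y < 0):
        raise ValueError("negative counts")
    libsize = y.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(f"sample {df.columns[zero[0]]!r} has all-zero counts")
    q75 = np.array([np.quantile(y[:, j][y[:, j] >= 0], 0.75) for j in range(y.shape[1])])
    frac = q75 / libsize
    ref_idx = int(np.argmin(np.abs(frac - frac.mean())))
    factors = np.array(
        [
            _tmm_pair(y[:, j], y[:, ref_idx], libsize[j], libsize[ref_idx], trim_M, trim_A)
            for j in range(y.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        sample_ids=np.asarray(df.columns),
        library_size=libsize,
        tmm_factor=factors,
        reference_sample=str(df.columns[ref_idx]),
    )


def gc_bias_test(gc_shared, gc_exclusive):
    """Two-sample Kolmogorov–Smirnov test for GC-distribution shift.

    Compares the GC fractions of transcripts detected in both library
    preparations against those detected in only one; a large D with small
    p indicates prep-dependent GC bias. Returns ``(D, p)``.
    """
    a = np.asarray(gc_shared, dtype=float)
    b = np.asarray(gc_exclusive, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GCOffsetModel:
    """Additive per-sample log2-CPM offsets in GC (and optional length) bins.

    Offsets are zero-sum across bins within each sample (weighted by the
    number of genes per bin), so applying them leaves per-sample totals
    unchanged on the log scale.
    """

    gc_edges: np.ndarray
    gc_offsets: pd.DataFrame  # bins × samples, log2 units
    bin_counts: np.ndarray
    gc_centers: np.ndarray | None = None
    length_edges: np.ndarray | None = None
    length_offsets: pd.DataFrame | None = None

    def gene_bins(self, gc_values) -> np.ndarray:
        return np.clip(
            np.digitize(np.asarray(gc_values, dtype=float), self.gc_edges[1:-1]),
            0,
            len(self.gc_edges) - 2,
        )

    def offset_matrix(
        self, gc_values, log_base: str = "e", interpolate: bool = True
    ) -> np.ndarray:
        """Genes × samples offset matrix for the GLM (natural log by default).

        By default offsets are linearly interpolated between bin centers so
        that steep within-bin trends are tracked; ``interpolate=False``
        gives piecewise-constant decile offsets.
        """
        gc = np.asarray(gc_values, dtype=float)
        off = self.gc_offsets.to_numpy()
        if interpolate and self.gc_centers is not None:
            c = self.gc_centers
            cols = []
            for j in range(off.shape[1]):
                v = np.interp(gc, c, off[:, j])
                # linear extrapolation beyond the outer bin centers
                lo = gc < c[0]
                hi = gc > c[-1]
                v[lo] = off[0, j] + (gc[lo] - c[0]) * (off[1, j] - off[0, j]) / (c[1] - c[0])
                v[hi] = off[-1, j] + (gc[hi] - c[-1]) * (off[-1, j] - off[-2, j]) / (
                    c[-1] - c[-2]
                )
                cols.append(v)
            out = np.column_stack(cols)
        else:
            out = off[self.gene_bins(gc), :]
        if log_base == "e":
            out = out * np.log(2.0)
        elif log_base != "2":
            raise ValueError("log_base must be 'e' or '2'")
        return out


def _smooth_adjacent(mat: np.ndarray) -> np.ndarray:
    """[1, 2, 1]/4 smoothing across bins (rows), edges renormalized."""
    padded = np.vstack([mat[:1], mat, mat[-1:]])
    return 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]


def fit_gc_offsets(
    counts,
    gc,
    lengths_bp=None,
    n_bins: int = 10,
    prior_count: float = 0.5,
    smooth: bool = False,
) -> GCOffsetModel:
    """Per-sample GC-decile offsets on the log2-CPM scale.

    For each sample, every gene's log2 CPM deviation from its cross-sample
    median is computed; the per-bin median deviation, recentred to zero
    sum, is that sample's offset for the bin (per-gene offsets are then
    interpolated between bin centers, which regularizes adjacent bins;
    ``smooth=True`` additionally pre-smooths the bin offsets, at the cost
    of blurring sharp bias onsets). Optional length-decile offsets are
    fitted the same way.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    y = df.to_numpy(dtype=float)
    G, S = y.shape
    gc = np.asarray(gc, dtype=float)
    if gc.shape[0] != G:
        raise ValueError("gc must have one value per gene")
    if G / n_bins < 10:
        raise ValueError("too few genes per GC bin")
    libsize = y.sum(axis=0)
    logcpm = np.log2((y + prior_count) * 1e6 / libsize[None, :])
    dev = logcpm - np.median(logcpm, axis=1, keepdims=True)

    def _bin_offsets(values):
        edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
        bins = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
        off = np.zeros((n_bins, S))
        cnt = np.zeros(n_bins, dtype=int)
        centers = np.zeros(n_bins)
        for b in range(n_bins):
            mask = bins == b
            cnt[b] = mask.sum()
            if cnt[b]:
                off[b] = np.median(dev[mask], axis=0)
                centers[b] = np.median(values[mask])
            else:
                centers[b] = 0.5 * (edges[b] + edges[b + 1])
        if smooth:
            off = _smooth_adjacent(off)
        w = cnt / cnt.sum()
        off = off - (w[:, None] * off).sum(axis=0, keepdims=True)
        return edges, off, cnt, centers

    gc_edges, gc_off, cnt, centers = _bin_offsets(gc)
    model = GCOffsetModel(
        gc_edges=gc_edges,
        gc_offsets=pd.DataFrame(gc_off, columns=df.columns),
        bin_counts=cnt,
        gc_centers=centers,
    )
    if lengths_bp is not None:
        le, lo, _, _ = _bin_offsets(np.log10(np.asarray(lengths_bp, dtype=float)))
        model.length_edges = le
        model.length_offsets = pd.DataFrame(lo, columns=df.columns)
    return model


def cpm(counts, norm: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million of TMM-effective library size."""
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    y = df.to_numpy(dtype=float)
    eff = norm.effective_size if norm is not None else y.sum(axis=0)
    eff = np.asarray(eff, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("non-positive effective library size")
    return pd.DataFrame(y * 1e6 / eff[None, :], index=df.index, columns=df.columns)


def gc_logfc_correlation(
    counts, gc, cols_a, cols_b, offset_model: GCOffsetModel | None = None
) -> float:
    """Pearson r between per-gene log2FC (group A vs B mean CPM) and GC.

    The bin-slope analogue of a quantile-regression-fit diagnostic: a
    large |r| indicates residual GC-dependent bias between the two sample
    groups; applying a fitted :class:`GCOffsetModel` first should shrink
    it toward 0.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    y = df.to_numpy(dtype=float)
    libsize = y.sum(axis=0)
    logcpm = np.log2((y + 0.5) * 1e6 / libsize[None, :])
    if offset_model is not None:
        logcpm = logcpm - offset_model.offset_matrix(gc, log_base="2")
    ia = [df.columns.get_loc(c) for c in cols_a]
    ib = [df.columns.get_loc(c) for c in cols_b]
    logfc = logcpm[:, ia].mean(axis=1) - logcpm[:, ib].mean(axis=1)
    return float(np.corrcoef(np.asarray(gc, dtype=float), logfc)[0, 1])
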