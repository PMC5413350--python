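"""Data-driven expression-depth filters.

Two thresholds are learned from the data rather than fixed a priori:

* a **lower-limit FPKM** per condition — the expression level above which
  the two conditions' sliding-window median expressions become positively
  correlated, below which low counts are dominated by sampling noise; and
* an **absence-call threshold** — when one condition is sequenced much
  more shallowly, the reference-condition FPKM above which a gene that is
  undetected in the shallow condition can be believed biologically absent
  rather than dropped out.

Both are built from a sliding window (default 100 genes, step 1) over
genes sorted by mean FPKM in a reference condition.  The correlation-onset
rule replaces visual inspection of the window curve with a run-of-positive
Kendall-tau criterion, which is rank-based and scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WindowCurve:
    """Sliding-window summary: reference medians vs a companion statistic.

    ``mode`` is ``"median"`` (companion = other condition's window median)
    or ``"proportion"`` (companion = detected-gene fraction per window).
    """

    ref_median: np.ndarray
    companion: np.ndarray
    window: int
    step: int
    mode: str

    def __post_init__(self):
        if np.any(np.diff(self.ref_median) < 0):
            raise ValueError("reference medians must be non-decreasing")
        if self.mode == "proportion" and np.any(
            (self.companion < 0) | (self.companion > 1)
        ):
            raise ValueError("proportions must lie in [0, 1]")

    def __len__(self):
        return len(self.ref_median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_index": np.arange(len(self)) * self.step,
                "ref_median": self.ref_median,
                "companion": self.companion,
            }
        )


@dataclass
class ThresholdDetection:
    """A learned FPKM threshold plus the evidence behind it."""

    value: float
    window_index: int | None
    failed: bool
    curve: WindowCurve | None = field(default=None, repr=False)
    taus: np.ndarray | None = field(default=None, repr=False)

    def __float__(self):
        return float(self.value)


@dataclass
class ThresholdSet:
    """Lower-limit FPKM per condition plus the absence-call threshold."""

    lower_limit_fpkm: dict
    absence_threshold_fpkm: float | None = None
    detection_target: float = 0.95
    window: int = 100

    def __post_init__(self):
        for cond, v in self.lower_limit_fpkm.items():
            if not np.isfinite(v) and v != np.inf:
                raise ValueError(f"bad threshold for {cond}")
            if v < 0:
                raise ValueError("thresholds must be >= 0")


def fpkm(counts, lengths_bp, library_sizes=None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    ``FPKM = count / (length_kb × library_size_millions)``.  Library sizes
    default to column sums.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    arr = df.to_numpy(dtype=float)
    L = np.asarray(lengths_bp, dtype=float)
    if np.any(L <= 0):
        raise ValueError("lengths must be positive")
    if library_sizes is None:
        library_sizes = arr.sum(axis=0)
    N = np.asarray(library_sizes, dtype=float)
    if np.any(N <= 0):
        raise ValueError("zero library size")
    vals = arr * 1e9 / (L[:, None] * N[None, :])
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def window_curve(
    values_ref,
    companion,
    window: int = 100,
    step: int = 1,
    mode: str = "median",
) -> WindowCurve:
    """Sliding-window curve over genes sorted by the reference statistic.

    Genes are sorted ascending by ``values_ref`` (stable, ties broken by
    gene id); each window of ``window`` consecutive genes contributes its
    reference median and either the companion median (``mode="median"``)
    or the companion mean — i.e. the detected proportion for a boolean
    companion (``mode="proportion"``).
    """
    ref = pd.Series(values_ref).astype(float)
    comp = pd.Series(companion).reindex(ref.index).astype(float)
    if comp.isna().any():
        raise ValueError("companion missing genes present in reference")
    n = len(ref)
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > n:
        raise ValueError("window larger than gene count")
    if step < 1:
        raise ValueError("step must be >= 1")
    ids = ref.index.astype(str).to_numpy()
    order = np.lexsort((ids, ref.to_numpy()))
    r = ref.to_numpy()[order]
    c = comp.to_numpy()[order]
    rwin = np.lib.stride_tricks.sliding_window_view(r, window)[::step]
    cwin = np.lib.stride_tricks.sliding_window_view(c, window)[::step]
    ref_med = np.median(rwin, axis=1)
    comp_stat = cwin.mean(axis=1) if mode == "proportion" else np.median(cwin, axis=1)
    return WindowCurve(ref_med, comp_stat, window, step, mode)


def _sliding_kendall_tau(x: np.ndarray, y: np.ndarray, run_length: int) -> np.ndarray:
    """Kendall tau-b of (x, y) over every run of ``run_length`` points.

    Vectorized over run starts; a run with zero variance in either
    variable yields NaN.
    """
    n = len(x)
    R = run_length
    xs = np.lib.stride_tricks.sliding_window_view(x, R)
    ys = np.lib.stride_tricks.sliding_window_view(y, R)
    i, j = np.triu_indices(R, k=1)
    dx = np.sign(xs[:, j] - xs[:, i])
    dy = np.sign(ys[:, j] - ys[:, i])
    s = (dx * dy).sum(axis=1)
    n0 = R * (R - 1) / 2.0
    tx = (dx == 0).sum(axis=1)
    ty = (dy == 0).sum(axis=1)
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, s / denom, np.nan)


def detect_lower_limit(curve: WindowCurve, run_length: int = 20) -> ThresholdDetection:
    """Correlation-onset lower limit from a median-mode window curve.

    Returns the reference median of the earliest window ``w*`` such that
    Kendall's tau between reference and companion medians is positive over
    *every* subsequent run of ``run_length`` consecutive windows.  If no
    such window exists the detection is flagged failed and the value is
    ``+inf``.
    """
    if curve.mode != "median":
        raise ValueError("lower-limit detection needs a median-mode curve")
    n = len(curve)
    if run_length > n:
        raise ValueError("run_length exceeds number of windows")
    if run_length < 2:
        raise ValueError("run_length must be >= 2")
    taus = _sliding_kendall_tau(curve.ref_median, curve.companion, run_length)
    bad = ~(taus > 0)  # NaN counts as not-positive
    if not bad.any():
        w = 0
    else:
        last_bad = int(np.flatnonzero(bad)[-1])
        w = last_bad + 1
        if w > len(taus) - 1:
            return ThresholdDetection(np.inf, None, True, curve, taus)
    return ThresholdDetection(float(curve.ref_median[w]), w, False, curve, taus)


def detect_absence_threshold(
    fpkm_ref,
    detected,
    window: int = 100,
    step: int = 1,
    detection_target: float = 0.95,
) -> ThresholdDetection:
    """Absence-call threshold from the detection-proportion curve.

    ``fpkm_ref`` is per-gene mean FPKM in the deeply sequenced condition;
    ``detected`` a per-gene boolean (nonzero in every shallow sample).
    Returns the smallest window reference median ``v`` such that every
    window whose reference median is ≥ ``v`` attains the detection target.
    Returns 0 when no window falls short, ``+inf`` (flagged) when even the
    highest-expression window falls short.
    """
    if window < 10:
        raise ValueError("window must be >= 10")
    if not 0 < detection_target <= 1:
        raise ValueError("detection_target in (0, 1]")
    det = pd.Series(detected).astype(bool)
    if det.all():
        return ThresholdDetection(0.0, None, False, None, None)
    curve = window_curve(
        fpkm_ref, det.astype(float), window=window, step=step, mode="proportion"
    )
    failing = curve.companion < detection_target
    if not failing.any():
        return ThresholdDetection(0.0, None, False, curve, None)
    r_fail_max = curve.ref_median[failing].max()
    above = np.flatnonzero(curve.ref_median > r_fail_max)
    if above.size == 0:
        return ThresholdDetection(np.inf, None, True, curve, None)
    w = int(above[0])
    return ThresholdDetection(float(curve.ref_median[w]), w, False, curve, None)


def apply_absence_filter(genes, fpkm_ref, detected, threshold: float):
    """Retain genes unless undetected *and* strictly below the threshold.

    Undetected genes at or above the threshold are kept: their absence in
    the shallow condition is treated as biological, not dropout.
    """
    genes = pd.Index(genes)
    ref = pd.Series(fpkm_ref).reindex(genes).to_numpy(dtype=float)
    det = pd.Series(detected).reindex(genes).to_numpy(dtype=bool)
    remove = (~det) & (ref < float(threshold))
    return set(genes[~remove])
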