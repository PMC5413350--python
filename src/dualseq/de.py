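"""Paired negative-binomial differential expression.

The testing contract mirrors the classic count-GLM workflow for bulk
RNA-seq: per-gene NB log-linear models with log library-size (plus optional
GC) offsets, a blocking factor for paired samples, empirical-Bayes-shrunk
dispersions, likelihood-ratio tests on the condition coefficient, and
Benjamini–Hochberg FDR control.

The user-facing entry point is statsmodels-style::

    model = PairedNBModel(counts, conditions, pairs=pairs, offset=offsets)
    res = model.fit()
    print(res.summary())
    sig = res.significant(alpha=0.05)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .glm import adjusted_profile_loglik, fit_nb_glm, nb_loglik

DEFAULT_PRIOR_DF = 40.0
_GRID = np.concatenate([[1e-6], np.geomspace(1e-4, 5.0, 14)])


@dataclass
class DispersionEstimates:
    """Common and per-gene (tagwise) NB dispersions."""

    common: float
    tagwise: np.ndarray
    prior_df: float


def build_design(conditions, pairs=None):
    """Design matrix: intercept, pair blocks, condition indicator (last col).

    ``conditions`` must have exactly two levels; the second (sorted) level is
    the "treatment" whose coefficient is reported as the log fold change.
    """
    cond = pd.Categorical(conditions)
    if len(cond.categories) != 2:
        raise ValueError("exactly two condition levels required")
    cols = [np.ones(len(cond))]
    names = ["intercept"]
    if pairs is not None:
        pair = pd.Categorical(pairs)
        counts = pd.Series(conditions).groupby([pair, cond], observed=False).size()
        if (counts.unstack().fillna(0) < 1).any().any():
            raise ValueError("paired mode requires both conditions in every pair")
        for lev in pair.categories[1:]:
            cols.append((pair == lev).astype(float))
            names.append(f"pair[{lev}]")
    cols.append((cond == cond.categories[1]).astype(float))
    names.append(f"condition[{cond.categories[1]}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    return X, names


def fit_gene_glm(counts_row, design, dispersion, offset=0.0):
    """Fit one gene's NB GLM; returns (coefficients, log-likelihood).

    The last design column is the condition contrast; its coefficient is
    returned in log2 units alongside the natural-log coefficient vector.
    Non-convergence is flagged, not raised; an all-zero gene yields zero
    coefficients.
    """
    y = np.asarray(counts_row, dtype=float)[None, :]
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("counts must be finite and non-negative")
    if not y.any():
        p = np.asarray(design).shape[1]
        return {
            "coefficients": np.zeros(p),
            "log2_fold_change": 0.0,
            "loglik": nb_loglik(y, np.full_like(y, 1e-8), dispersion)[0],
            "converged": True,
            "all_zero": True,
        }
    fit = fit_nb_glm(y, design, dispersion, offset=offset)
    beta = fit["beta"][0]
    return {
        "coefficients": beta,
        "log2_fold_change": float(beta[-1] / np.log(2.0)),
        "loglik": float(fit["loglik"][0]),
        "converged": bool(fit["converged"][0]),
        "all_zero": False,
    }


def estimate_dispersions(
    counts, design, prior_df: float = DEFAULT_PRIOR_DF, offset=0.0
) -> DispersionEstimates:
    """Common + tagwise dispersions via CR-adjusted profile likelihood.

    The common value maximizes the summed adjusted profile likelihood (APL)
    over a log-spaced grid, refined by bounded scalar optimization. Tagwise
    values maximize ``APL_g + prior_n * mean_g(APL)`` where
    ``prior_n = prior_df / residual_df``, so tagwise → common as
    ``prior_df → ∞``.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    G, n = y.shape
    resid_df = n - X.shape[1]
    if resid_df < 1:
        raise ValueError("no residual degrees of freedom for dispersion")
    keep = y.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("all genes have zero counts")
    yk = y[keep]
    off = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))[keep]

    apl = np.empty((yk.shape[0], _GRID.size))
    for j, phi in enumerate(_GRID):
        apl[:, j] = adjusted_profile_loglik(yk, X, phi, offset=off)

    total = apl.sum(axis=0)
    j0 = int(np.argmax(total))
    lo = _GRID[max(j0 - 1, 0)]
    hi = _GRID[min(j0 + 1, _GRID.size - 1)]
    if lo == hi:
        common = float(lo)
    else:
        res = minimize_scalar(
            lambda lg: -adjusted_profile_loglik(
                yk, X, float(np.exp(lg)), offset=off
            ).sum(),
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        common = float(np.exp(res.x))

    prior_n = prior_df / resid_df
    mean_apl = apl.mean(axis=0)
    weighted = apl + prior_n * mean_apl[None, :]
    jbest = np.argmax(weighted, axis=1)
    # quadratic interpolation in log-phi around the grid maximum
    lg = np.log(_GRID)
    tag = np.empty(yk.shape[0])
    for i, j in enumerate(jbest):
        if j == 0 or j == _GRID.size - 1:
            tag[i] = _GRID[j]
            continue
        x0, x1, x2 = lg[j - 1], lg[j], lg[j + 1]
        f0, f1, f2 = weighted[i, j - 1], weighted[i, j], weighted[i, j + 1]
        denom = (f0 - 2 * f1 + f2)
        if denom >= -1e-12:
            tag[i] = _GRID[j]
        else:
            xs = x1 - 0.5 * ((x1 - x0) ** 2 * (f1 - f2) - (x1 - x2) ** 2 * (f1 - f0)) / (
                (x1 - x0) * (f1 - f2) - (x1 - x2) * (f1 - f0)
            )
            xs = float(np.clip(xs, x0, x2))
            tag[i] = np.exp(xs)
    tagwise = np.full(G, common)
    tagwise[keep] = tag
    return DispersionEstimates(common=common, tagwise=tagwise, prior_df=prior_df)


def likelihood_ratio_test(loglik_full, loglik_reduced, df: int = 1):
    """LR statistic and chi-square p-value for nested NB GLM fits."""
    stat = 2.0 * (np.asarray(loglik_full) - np.asarray(loglik_reduced))
    if np.any(stat < -1e-4):
        raise ValueError("negative LR statistic: full model fit failed")
    stat = np.clip(stat, 0.0, None)
    p = stats.chi2.sf(stat, df)
    return stat, p


def bh_adjust(p_values):
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResults:
    """Per-gene DE table plus fitted-model metadata."""

    table: pd.DataFrame
    dispersion: DispersionEstimates
    design_names: list
    alpha: float = 0.05
    coefficients: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.table[self.table["fdr"] < a]

    @property
    def n_up(self) -> int:
        sig = self.significant()
        return int((sig["log2_fold_change"] > 0).sum())

    @property
    def n_down(self) -> int:
        sig = self.significant()
        return int((sig["log2_fold_change"] <= 0).sum())

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "Paired NB GLM differential expression",
            f"  genes tested          : {len(self.table)}",
            f"  common dispersion     : {self.dispersion.common:.4g}",
            f"  dispersion prior df   : {self.dispersion.prior_df:g}",
            f"  significant (FDR<{self.alpha:g}): {len(sig)}"
            f" ({self.n_up} up, {self.n_down} down)",
        ]
        return "\n".join(lines)


class PairedNBModel:
    """NB log-linear model for a two-condition (optionally paired) design.

    Parameters
    ----------
    counts : DataFrame (genes × samples) or 2-D array of non-negative counts
    conditions : per-sample condition labels, exactly two levels
    pairs : optional per-sample blocking labels; each pair must contain
        both conditions
    offset : natural-log per-observation offset — typically
        ``log(effective library size)`` plus any GC-bias offset; scalar,
        per-sample vector, or genes × samples matrix
    """

    def __init__(self, counts, conditions, pairs=None, offset=None):
        if isinstance(counts, pd.DataFrame):
            self.gene_ids = counts.index.to_numpy()
            self.counts = counts.to_numpy(dtype=float)
        else:
            self.counts = np.atleast_2d(np.asarray(counts, dtype=float))
            self.gene_ids = np.arange(self.counts.shape[0])
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self.design, self.design_names = build_design(conditions, pairs)
        if offset is None:
            libsize = self.counts.sum(axis=0)
            if np.any(libsize <= 0):
                bad = np.flatnonzero(libsize <= 0)
                raise ValueError(f"sample {bad[0]} has all-zero counts")
            offset = np.log(libsize)
        self.offset = np.broadcast_to(
            np.asarray(offset, dtype=float), self.counts.shape
        )

    def fit(
        self,
        dispersion=None,
        prior_df: float = DEFAULT_PRIOR_DF,
        alpha: float = 0.05,
    ) -> DEResults:
        y = self.counts
        X = self.design
        if dispersion is None:
            disp = estimate_dispersions(y, X, prior_df=prior_df, offset=self.offset)
        elif isinstance(dispersion, DispersionEstimates):
            disp = dispersion
        else:
            disp = DispersionEstimates(
                common=float(np.mean(dispersion)),
                tagwise=np.broadcast_to(
                    np.asarray(dispersion, dtype=float), (y.shape[0],)
                ).copy(),
                prior_df=np.inf,
            )
        phi = disp.tagwise
        full = fit_nb_glm(y, X, phi, offset=self.offset)
        reduced = fit_nb_glm(y, X[:, :-1], phi, offset=self.offset)
        ll_full = full["loglik"]
        ll_red = reduced["loglik"]
        nonzero = y.sum(axis=1) > 0
        ok = full["converged"] & reduced["converged"] & (ll_full + 1e-4 >= ll_red)
        stat = np.where(ok, np.clip(2.0 * (ll_full - ll_red), 0.0, None), 0.0)
        p = np.where(ok & nonzero, stats.chi2.sf(stat, 1), 1.0)
        log2fc = np.where(nonzero, full["beta"][:, -1] / np.log(2.0), 0.0)
        fdr = bh_adjust(p)
        table = pd.DataFrame(
            {
                "log2_fold_change": log2fc,
                "lr_statistic": stat,
                "p_value": p,
                "fdr": fdr,
                "direction": np.where(log2fc > 0, "up", "down"),
                "converged": ok,
            },
            index=pd.Index(self.gene_ids, name="gene"),
        )
        return DEResults(
            table=table,
            dispersion=disp,
            design_names=self.design_names,
            alpha=alpha,
            coefficients=full["beta"],
        )


def run_de(
    counts,
    conditions,
    pairs=None,
    norm=None,
    offsets=None,
    alpha: float = 0.05,
    prior_df: float = DEFAULT_PRIOR_DF,
    dispersion=None,
) -> DEResults:
    """One-call DE analysis: offsets from norm factors (+ optional GC
    offsets), dispersion estimation, per-gene LRT, BH adjustment.

    ``norm`` is a :class:`dualseq.normalize.NormFactors`; ``offsets`` an
    optional genes × samples natural-log offset matrix added on top of
    ``log(effective library size)``.
    """
    counts_arr = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    if norm is not None:
        base = np.log(np.asarray(norm.effective_size, dtype=float))
    else:
        base = np.log(np.clip(counts_arr.sum(axis=0), 1.0, None))
    off = np.broadcast_to(base, counts_arr.shape).copy()
    if offsets is not None:
        off = off + np.asarray(offsets, dtype=float)
    model = PairedNBModel(counts, conditions, pairs=pairs, offset=off)
    return model.fit(dispersion=dispersion, prior_df=prior_df, alpha=alpha)
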