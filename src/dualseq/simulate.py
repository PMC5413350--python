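"""Synthetic dual RNA-seq data with known ground truth.

Emulates the structure of a mixed host/endosymbiont sequencing study: a
two-organism transcript catalog whose GC-content distributions differ
(low-GC vertebrate host, median ≈ 0.43, versus high-GC green alga,
median ≈ 0.62, plus minor fungal/mite contaminants); a paired design of
host-only and host-plus-symbiont samples alongside capsule (symbiont-only)
and optional cultured-symbiont samples; negative-binomial counts whose
symbiont component inside host cells is sequenced at a small fraction of
the nominal depth (producing expression-dependent dropout); a
library-prep-dependent GC bias; planted differential expression of known
sign and magnitude; and homology hit tables with controllable error.

Every operation is deterministic given the integer seed; sub-streams are
derived by stable hashing of (operation, sample) names.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOST = "host"
SYMBIONT = "symbiont"
CONTAMINANT_FUNGUS = "contaminant_fungus"
CONTAMINANT_MITE = "contaminant_mite"
ORGANISMS = (HOST, SYMBIONT, CONTAMINANT_FUNGUS, CONTAMINANT_MITE)

SAMPLE_CLASSES = (
    "host_only",
    "host_plus_symbiont",
    "capsule_symbiont",
    "cultured_symbiont",
)

TAXON_GROUP_OF = {
    HOST: "animal_or_vertebrate",
    SYMBIONT: "plant_or_green_alga",
    CONTAMINANT_FUNGUS: "fungal",
    CONTAMINANT_MITE: "mite",
}
TAXON_GROUPS = ("plant_or_green_alga", "animal_or_vertebrate", "fungal", "mite", "other")

# GC distributions: beta rescaled to [0.2, 0.8], parameterized by median
GC_RANGE = (0.2, 0.8)
GC_MEDIANS = {HOST: 0.43, SYMBIONT: 0.62, CONTAMINANT_FUNGUS: 0.50, CONTAMINANT_MITE: 0.45}
GC_CONCENTRATION = 20.0


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic sub-stream from a base seed and string tokens."""
    keys = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tokens
    ]
    return np.random.default_rng(np.random.SeedSequence(keys))


def _beta_params_for_median(median: float, concentration: float = GC_CONCENTRATION):
    lo, hi = GC_RANGE
    m = (median - lo) / (hi - lo)
    if not 0 < m < 1:
        raise ValueError(f"median {median} outside GC range {GC_RANGE}")
    # beta median ~ (a - 1/3) / (a + b - 2/3) for a, b > 1
    a = m * (concentration - 2.0 / 3.0) + 1.0 / 3.0
    return a, concentration - a


def simulate_catalog(
    n_host: int = 10_000,
    n_symbiont: int = 5_000,
    n_contaminant: int = 200,
    gc_medians: dict | None = None,
    length_log_mean: float = np.log(1000.0),
    length_log_sd: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Transcript catalog: id, organism, length_bp, gc_fraction.

    GC fractions are beta-distributed on [0.2, 0.8] with per-organism target
    medians; lengths are log-normal, floored at 100 bp. Contaminants split
    evenly between fungal and mite transcripts.
    """
    if min(n_host, n_symbiont, n_contaminant) < 0:
        raise ValueError("counts must be >= 0")
    if n_host + n_symbiont + n_contaminant == 0:
        raise ValueError("empty catalog")
    medians = dict(GC_MEDIANS)
    if gc_medians:
        medians.update(gc_medians)
    n_fungus = n_contaminant // 2
    n_mite = n_contaminant - n_fungus
    blocks = []
    for organism, n, prefix in (
        (HOST, n_host, "HOST"),
        (SYMBIONT, n_symbiont, "ALG"),
        (CONTAMINANT_FUNGUS, n_fungus, "FUN"),
        (CONTAMINANT_MITE, n_mite, "MITE"),
    ):
        if n == 0:
            continue
        rng = _rng(seed, "catalog", organism)
        a, b = _beta_params_for_median(medians[organism])
        lo, hi = GC_RANGE
        gc = lo + (hi - lo) * rng.beta(a, b, size=n)
        length = np.maximum(
            np.round(rng.lognormal(length_log_mean, length_log_sd, size=n)), 100
        ).astype(int)
        blocks.append(
            pd.DataFrame(
                {
                    "transcript_id": [f"{prefix}_{i:06d}" for i in range(n)],
                    "organism": organism,
                    "length_bp": length,
                    "gc_fraction": gc,
                }
            )
        )
    catalog = pd.concat(blocks, ignore_index=True)
    return catalog


def default_design(
    n_pairs: int = 4,
    n_capsule: int = 3,
    n_cultured: int = 0,
    host_depth: int = 20_000_000,
    capsule_depth: int = 30_000_000,
    cultured_depth: int = 30_000_000,
) -> pd.DataFrame:
    """Study design emulating the paired host ± symbiont sampling.

    Quadruplicate paired host-only / host-plus-symbiont samples (wild
    collection, low-input prep) and triplicate capsule-symbiont samples;
    cultured-symbiont samples, when present, use the standard prep.
    """
    rows = []
    for i in range(n_pairs):
        rows.append((f"host_only_{i+1}", "host_only", f"P{i+1}", "low_input", host_depth))
        rows.append(
            (f"host_plus_{i+1}", "host_plus_symbiont", f"P{i+1}", "low_input", host_depth)
        )
    for i in range(n_capsule):
        rows.append((f"capsule_{i+1}", "capsule_symbiont", None, "low_input", capsule_depth))
    for i in range(n_cultured):
        rows.append((f"culture_{i+1}", "cultured_symbiont", None, "standard", cultured_depth))
    return pd.DataFrame(
        rows, columns=["sample_id", "sample_class", "pair_id", "library_prep", "target_depth"]
    )


def validate_design(design: pd.DataFrame) -> None:
    if (design["target_depth"] < 0).any():
        raise ValueError("negative target depth")
    paired = design[design["sample_class"].isin(["host_only", "host_plus_symbiont"])]
    for pid, grp in paired.dropna(subset=["pair_id"]).groupby("pair_id"):
        classes = sorted(grp["sample_class"])
        if classes != ["host_only", "host_plus_symbiont"]:
            raise ValueError(f"pair {pid} must contain exactly one sample of each class")


@dataclass
class SimTruth:
    """Planted simulation parameters and per-gene ground truth.

    ``condition_means`` holds per-gene baseline relative expression (TPM
    scale) per sample class; ``de_indicator``/``log2_effect`` record the
    planted contrasts; ``gc_bias`` maps library prep to a
    (breakpoint, log-slope) pair applied above the GC breakpoint;
    ``symbiont_depth_fraction`` is the per-sample fraction of nominal depth
    reaching symbiont transcripts inside host cells.
    """

    condition_means: pd.DataFrame
    de_indicator: dict
    log2_effect: dict
    nb_dispersion: np.ndarray
    gc_bias: dict
    symbiont_depth_fraction: dict
    seed: int
    pair_log_sd: float = 0.0
    contaminant_fraction: float = 0.01

    def __post_init__(self):
        if (self.condition_means.to_numpy() < 0).any():
            raise ValueError("negative mean expression")
        for contrast, ind in self.de_indicator.items():
            eff = self.log2_effect[contrast]
            if np.any((ind != 0) != (np.abs(eff) > 0)):
                raise ValueError("log2_effect must be nonzero exactly where DE planted")


# contrast name -> (reference class, treatment class, organism whose genes move)
CONTRASTS = {
    "host_response": ("host_only", "host_plus_symbiont", HOST),
    "algal_response": ("capsule_symbiont", "host_plus_symbiont", SYMBIONT),
    "culture_response": ("capsule_symbiont", "cultured_symbiont", SYMBIONT),
}


def make_sim_truth(
    catalog: pd.DataFrame,
    de_fraction: dict | float = 0.0,
    log2_effect_size: float = 2.0,
    dispersion: float = 0.1,
    dispersion_log_sd: float = 0.3,
    gc_bias: dict | None = None,
    symbiont_depth_fraction: float = 0.05,
    design: pd.DataFrame | None = None,
    pair_log_sd: float = 0.0,
    expr_log_mean: float = np.log(20.0),
    expr_log_sd: float = 1.5,
    seed: int = 0,
) -> SimTruth:
    """Draw per-gene baselines, planted DE, dispersions and bias parameters.

    ``de_fraction`` may be a single fraction applied to the host and algal
    contrasts or a dict keyed by contrast name. GC bias defaults to the
    study conditions: the low-input prep loses high-GC transcripts
    (log-linear with slope −8 above a 0.60 GC breakpoint), the standard
    prep is unbiased.
    """
    genes = catalog["transcript_id"].to_numpy()
    organism = catalog["organism"].to_numpy()
    G = len(genes)
    rng = _rng(seed, "truth")
    base = rng.lognormal(expr_log_mean, expr_log_sd, size=G)
    means = pd.DataFrame(
        {cls: base.copy() for cls in SAMPLE_CLASSES}, index=pd.Index(genes, name="gene")
    )
    if not isinstance(de_fraction, dict):
        de_fraction = {"host_response": de_fraction, "algal_response": de_fraction}
    de_indicator, log2_effect = {}, {}
    for contrast, frac in de_fraction.items():
        ref_cls, trt_cls, org = CONTRASTS[contrast]
        ind = np.zeros(G, dtype=int)
        eff = np.zeros(G)
        eligible = np.flatnonzero(organism == org)
        n_de = int(round(frac * eligible.size))
        if n_de:
            chosen = rng.choice(eligible, size=n_de, replace=False)
            sign = rng.choice([-1, 1], size=n_de)
            ind[chosen] = sign
            eff[chosen] = sign * log2_effect_size
            means.loc[means.index[chosen], trt_cls] = (
                means.iloc[chosen][ref_cls].to_numpy() * 2.0 ** eff[chosen]
            )
        de_indicator[contrast] = ind
        log2_effect[contrast] = eff
    nb_disp = dispersion * rng.lognormal(0.0, dispersion_log_sd, size=G) if dispersion > 0 else np.zeros(G)
    if gc_bias is None:
        gc_bias = {"low_input": (0.60, -8.0), "standard": (0.60, 0.0)}
    sdf = {}
    if design is not None:
        for _, row in design.iterrows():
            if row["sample_class"] == "host_plus_symbiont":
                sdf[row["sample_id"]] = symbiont_depth_fraction
    sdf["default"] = symbiont_depth_fraction
    return SimTruth(
        condition_means=means,
        de_indicator=de_indicator,
        log2_effect=log2_effect,
        nb_dispersion=np.asarray(nb_disp, dtype=float),
        gc_bias=gc_bias,
        symbiont_depth_fraction=sdf,
        seed=int(seed),
        pair_log_sd=pair_log_sd,
    )


def _gc_multiplier(gc: np.ndarray, prep: str, gc_bias: dict) -> np.ndarray:
    breakpoint_, slope = gc_bias.get(prep, (0.6, 0.0))
    return np.exp(slope * np.clip(gc - breakpoint_, 0.0, None))


def expected_mean_matrix(
    catalog: pd.DataFrame, design: pd.DataFrame, truth: SimTruth
) -> pd.DataFrame:
    """Programmed NB mean for every (gene, sample) cell.

    Per sample, each organism block receives a share of the target depth
    (host 1, symbiont 1 or the intracellular depth fraction, contaminants
    ``contaminant_fraction``), distributed over its genes proportionally to
    relative expression × length × GC-bias multiplier.
    """
    genes = catalog["transcript_id"].to_numpy()
    if not set(genes) <= set(truth.condition_means.index):
        missing = set(genes) - set(truth.condition_means.index)
        raise ValueError(f"transcripts missing from truth: {sorted(missing)[:3]}")
    organism = catalog["organism"].to_numpy()
    length = catalog["length_bp"].to_numpy(dtype=float)
    gc = catalog["gc_fraction"].to_numpy(dtype=float)
    means = np.zeros((len(genes), len(design)))
    cm = truth.condition_means.loc[genes]
    is_host = organism == HOST
    is_sym = organism == SYMBIONT
    is_cont = ~is_host & ~is_sym
    for j, row in enumerate(design.itertuples(index=False)):
        cls, depth, prep = row.sample_class, row.target_depth, row.library_prep
        if depth <= 0:
            continue
        expr = cm[cls].to_numpy()
        w = expr * length * _gc_multiplier(gc, prep, truth.gc_bias)
        col = np.zeros(len(genes))
        host_scale = 1.0 if cls in ("host_only", "host_plus_symbiont") else 0.0
        if cls == "host_plus_symbiont":
            sym_scale = truth.symbiont_depth_fraction.get(
                row.sample_id, truth.symbiont_depth_fraction["default"]
            )
        elif cls in ("capsule_symbiont", "cultured_symbiont"):
            sym_scale = 1.0
        else:
            sym_scale = 0.0
        for mask, scale in ((is_host, host_scale), (is_sym, sym_scale), (is_cont, truth.contaminant_fraction)):
            tot = w[mask].sum()
            if scale > 0 and tot > 0:
                col[mask] = depth * scale * w[mask] / tot
        means[:, j] = col
    return pd.DataFrame(means, index=pd.Index(genes, name="gene"), columns=design["sample_id"])


def simulate_counts(
    catalog: pd.DataFrame, design: pd.DataFrame, truth: SimTruth
) -> pd.DataFrame:
    """Negative-binomial count matrix (genes × samples) under the truth.

    Counts are gamma-Poisson draws around :func:`expected_mean_matrix`,
    with optional per-(gene, pair) multiplicative block effects
    (``truth.pair_log_sd``). Reproducible: sub-streams are keyed by
    sample id.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    validate_design(design)
    mu = expected_mean_matrix(catalog, design, truth).to_numpy()
    genes = catalog["transcript_id"].to_numpy()
    G = len(genes)
    phi = truth.nb_dispersion
    pair_effects = {}
    if truth.pair_log_sd > 0:
        for pid in design["pair_id"].dropna().unique():
            pair_effects[pid] = _rng(truth.seed, "pair", pid).normal(
                0.0, truth.pair_log_sd, size=G
            )
    counts = np.zeros((G, len(design)), dtype=np.int64)
    for j, row in enumerate(design.itertuples(index=False)):
        m = mu[:, j].copy()
        if row.pair_id in pair_effects:
            m = m * np.exp(pair_effects[row.pair_id])
        rng = _rng(truth.seed, "counts", row.sample_id)
        pos = m > 0
        lam = np.zeros(G)
        over = pos & (phi > 0)
        lam[pos & ~over] = m[pos & ~over]
        if over.any():
            shape = 1.0 / phi[over]
            lam[over] = rng.gamma(shape, phi[over] * m[over])
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(
        counts, index=pd.Index(genes, name="gene"), columns=design["sample_id"]
    )


def simulate_correlation_onset(
    n_genes: int = 5000,
    floor_fpkm: float = 1.0,
    ref_log_sd: float = 2.0,
    noise_level: float = 0.2,
    noise_log_sd: float = 0.8,
    signal_log_sd: float = 0.4,
    seed: int = 0,
):
    """Planted correlation-onset pair of per-gene mean FPKM vectors.

    Below ``floor_fpkm`` the companion condition is i.i.d. noise
    (log-normal around ``noise_level × floor``); above it the companion
    tracks the reference up to multiplicative log-normal noise.  Returns
    ``(ref, companion)`` Series indexed by gene id — ground truth for
    validating the lower-limit detector.
    """
    rng = _rng(seed, "onset")
    ref = rng.lognormal(np.log(floor_fpkm), ref_log_sd, n_genes)
    noise = rng.lognormal(np.log(noise_level * floor_fpkm), noise_log_sd, n_genes)
    comp = np.where(
        ref < floor_fpkm, noise, ref * rng.lognormal(0.0, signal_log_sd, n_genes)
    )
    idx = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    return pd.Series(ref, index=idx), pd.Series(comp, index=idx)


def simulate_detection_dropout(
    n_genes: int = 5000,
    midpoint_fpkm: float = 10.0,
    slope: float = 1.5,
    ref_log_sd: float = 2.0,
    seed: int = 0,
):
    """Logistic expression-dependent dropout for the absence-call detector.

    Detection in the shallow condition is Bernoulli with probability
    ``sigmoid(slope × (ln f − ln midpoint))`` of the deep-condition FPKM
    ``f``. Returns ``(fpkm_ref, detected)`` Series.
    """
    rng = _rng(seed, "dropout")
    ref = rng.lognormal(np.log(midpoint_fpkm), ref_log_sd, n_genes)
    p = 1.0 / (1.0 + np.exp(-slope * (np.log(ref) - np.log(midpoint_fpkm))))
    detected = rng.random(n_genes) < p
    idx = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    return pd.Series(ref, index=idx), pd.Series(detected, index=idx)


def simulate_hit_table(
    catalog: pd.DataFrame,
    assignment_error_rate: float = 0.0,
    no_hit_rate: float = 0.0,
    seed: int = 0,
):
    """Homology hit table (BLAST outfmt-6 dialect) plus subject→taxon map.

    With probability ``1 − error − no_hit`` a transcript's best-scoring hit
    carries the taxon group of its true organism; with probability
    ``error`` the best hit is mislabeled; otherwise the transcript has no
    hits. Lower-scoring decoy hits with random groups are added.

    Returns ``(hits, taxon_map)`` DataFrames; ``hits`` uses outfmt-6 column
    order (qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore).
    """
    if not (0 <= assignment_error_rate < 1 and 0 <= no_hit_rate <= 1):
        raise ValueError("rates must lie in [0, 1)")
    if assignment_error_rate + no_hit_rate > 1:
        raise ValueError("error + no-hit rates must not exceed 1")
    rng = _rng(seed, "hits")
    rows = []
    subjects = {}

    def subject_for(group, k):
        sid = f"{group}|ref{k:04d}"
        subjects[sid] = group
        return sid

    groups = list(TAXON_GROUPS[:4])
    for t in catalog.itertuples(index=False):
        u = rng.random()
        if u < no_hit_rate:
            continue
        true_group = TAXON_GROUP_OF[t.organism]
        if u < no_hit_rate + assignment_error_rate:
            best_group = rng.choice([g for g in groups if g != true_group])
        else:
            best_group = true_group
        best_score = rng.uniform(100.0, 500.0)
        n_decoys = rng.integers(0, 3)
        hit_specs = [(best_group, best_score)]
        for _ in range(n_decoys):
            hit_specs.append(
                (rng.choice(groups + ["other"]), best_score * rng.uniform(0.3, 0.95))
            )
        for group, score in hit_specs:
            aln_len = int(max(30, min(t.length_bp, rng.integers(60, 900))))
            pident = rng.uniform(45.0, 99.0)
            mismatch = int(round(aln_len * (1 - pident / 100.0)))
            rows.append(
                (
                    t.transcript_id,
                    subject_for(group, rng.integers(0, 5000)),
                    round(pident, 2),
                    aln_len,
                    mismatch,
                    rng.integers(0, 3),
                    1,
                    aln_len,
                    1,
                    aln_len,
                    10.0 ** -rng.uniform(5, 180),
                    round(score, 1),
                )
            )
    hits = pd.DataFrame(
        rows,
        columns=[
            "qseqid",
            "sseqid",
            "pident",
            "length",
            "mismatch",
            "gapopen",
            "qstart",
            "qend",
            "sstart",
            "send",
            "evalue",
            "bitscore",
        ],
    )
    taxon_map = pd.DataFrame(
        sorted(subjects.items()), columns=["subject_id", "taxon_group"]
    )
    return hits, taxon_map
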