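"""End-to-end orchestration of the dual RNA-seq analysis.

A single configuration drives either a fully synthetic run (catalog,
counts and hit tables simulated with known truth) or a run on user files:
partition → expression thresholds → gene-set construction → normalization
→ paired NB GLM differential expression → annotation filtering, with a
stage-by-stage audit trail of gene counts in the run report.

Also hosts the small summary conversions used when reporting results:
differential-expression proportions, their cross-compartment ratio, and
the isometric cross-sectional-area → volume conversion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml

from . import filters, normalize, partition, simulate
from .annotate import filter_annotations, score_annotations
from .de import run_de
from .filters import ThresholdSet


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place; YAML round-trippable.

    Exactly one input mode: either ``counts_path``/``design_path``/... point
    at files, or ``simulate=True`` and the ``sim_*`` parameters define a
    synthetic study.
    """

    simulate: bool = True
    counts_path: str | None = None
    design_path: str | None = None
    catalog_path: str | None = None
    hits_path: str | None = None
    taxon_map_path: str | None = None

    sim_n_host: int = 4000
    sim_n_symbiont: int = 2000
    sim_n_contaminant: int = 100
    sim_n_pairs: int = 4
    sim_n_capsule: int = 3
    sim_n_cultured: int = 0
    sim_host_depth: int = 2_000_000
    sim_capsule_depth: int = 3_000_000
    sim_de_fraction: float = 0.1
    sim_log2_effect: float = 2.0
    sim_dispersion: float = 0.1
    sim_symbiont_depth_fraction: float = 0.05
    sim_assignment_error: float = 0.0
    sim_no_hit_rate: float = 0.1

    window: int = 100
    step: int = 1
    lower_limit_step: int = 10
    run_length: int = 20
    detection_target: float = 0.95
    trim_M: float = 0.30
    trim_A: float = 0.05
    prior_df: float = 40.0
    alpha: float = 0.05
    min_dist: float = 5.0
    seed: int = 0
    stages: tuple = ("partition", "filter", "normalize", "de", "annotate")

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        has_files = self.counts_path is not None
        if self.simulate == has_files:
            raise ValueError("provide exactly one of simulation spec or input files")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RunReport:
    """Auditable per-stage tallies, learned thresholds and DE summaries."""

    seed: int
    stages: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_input: int, n_retained: int, **extra):
        if not 0 <= n_retained <= n_input:
            raise ValueError(f"stage {name}: retained outside [0, input]")
        self.stages[name] = {
            "input": int(n_input),
            "retained": int(n_retained),
            "removed": int(n_input - n_retained),
            **extra,
        }

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": self.stages,
            "thresholds": self.thresholds,
            "de": self.de,
            "summaries": self.summaries,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _round_half_up(x: float, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def de_proportions(n_de: int, n_tested: int) -> float:
    """Percentage of tested genes called DE, rounded half-up to 2 decimals."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if n_de > n_tested:
        raise ValueError("n_de cannot exceed n_tested")
    return _round_half_up(100.0 * n_de / n_tested, 2)


def de_proportion_ratio(n_de_a, n_tested_a, n_de_b, n_tested_b) -> float:
    """Ratio of two DE proportions, rounded to 1 decimal."""
    if min(n_de_a, n_tested_a, n_de_b, n_tested_b) <= 0:
        raise ValueError("all counts must be positive")
    ratio = (n_de_a / n_tested_a) / (n_de_b / n_tested_b)
    return _round_half_up(ratio, 1)


def area_to_volume_fraction(area_fraction: float) -> float:
    """Isometric conversion of a relative cross-sectional area to volume.

    A relative area a corresponds to a relative linear dimension a^(1/2)
    and hence a relative volume a^(3/2).
    """
    if not 0 < area_fraction <= 1:
        raise ValueError("area_fraction must lie in (0, 1]")
    return float(area_fraction) ** 1.5


def estimate_thresholds(
    fpkm_df: pd.DataFrame,
    design: pd.DataFrame,
    genes_by_label: dict,
    window: int = 100,
    step: int = 1,
    lower_limit_step: int = 10,
    run_length: int = 20,
    detection_target: float = 0.95,
) -> tuple[ThresholdSet, dict]:
    """Learn per-condition lower limits and the absence-call threshold.

    Lower limits are estimated per sample class by sorting that class's
    genes (host-labeled for the host classes, symbiont-labeled for the
    algal classes) on mean FPKM and finding the correlation onset against
    the partner class.  The onset curves use spaced windows
    (``lower_limit_step``) so that consecutive window medians carry
    information; the detection-proportion curve keeps ``step``.  The
    absence threshold uses capsule FPKM as the deep reference and
    detection in every host-plus-symbiont sample.
    """
    cols = {
        cls: list(design.loc[design["sample_class"] == cls, "sample_id"])
        for cls in design["sample_class"].unique()
    }
    pairs = [
        ("host_only", "host_plus_symbiont", "host"),
        ("host_plus_symbiont", "host_only", "host"),
        ("capsule_symbiont", "host_plus_symbiont", "symbiont"),
        ("host_plus_symbiont", "capsule_symbiont", "symbiont"),
    ]
    lower, detections = {}, {}
    for ref_cls, comp_cls, label in pairs:
        if ref_cls not in cols or comp_cls not in cols:
            continue
        genes = fpkm_df.index.intersection(pd.Index(genes_by_label.get(label, [])))
        n_windows = (len(genes) - window) // lower_limit_step + 1
        if len(genes) < window or n_windows < run_length:
            continue
        ref = fpkm_df.loc[genes, cols[ref_cls]].mean(axis=1)
        comp = fpkm_df.loc[genes, cols[comp_cls]].mean(axis=1)
        curve = filters.window_curve(ref, comp, window=window, step=lower_limit_step)
        det = filters.detect_lower_limit(curve, run_length=run_length)
        key = ref_cls if label == "host" else f"{ref_cls}:symbiont"
        # the symbiont-side host_plus_symbiont limit is the intracellular one
        if label == "symbiont" and ref_cls == "host_plus_symbiont":
            name = "intracellular"
        else:
            name = ref_cls
        lower[name] = det.value
        detections[key] = det
    absence = None
    sym_genes = fpkm_df.index.intersection(
        pd.Index(genes_by_label.get("symbiont", []))
    )
    if (
        len(sym_genes) >= window
        and "capsule_symbiont" in cols
        and "host_plus_symbiont" in cols
    ):
        ref = fpkm_df.loc[sym_genes, cols["capsule_symbiont"]].mean(axis=1)
        detected = (fpkm_df.loc[sym_genes, cols["host_plus_symbiont"]] > 0).all(axis=1)
        absence = filters.detect_absence_threshold(
            ref, detected, window=window, step=step, detection_target=detection_target
        )
        detections["absence"] = absence
    ts = ThresholdSet(
        lower_limit_fpkm=lower,
        absence_threshold_fpkm=None if absence is None else absence.value,
        detection_target=detection_target,
        window=window,
    )
    return ts, detections


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; deterministic given ``config.seed``."""
    report = RunReport(seed=config.seed)
    truth = None
    if config.simulate:
        catalog = simulate.simulate_catalog(
            config.sim_n_host,
            config.sim_n_symbiont,
            config.sim_n_contaminant,
            seed=config.seed,
        )
        design = simulate.default_design(
            n_pairs=config.sim_n_pairs,
            n_capsule=config.sim_n_capsule,
            n_cultured=config.sim_n_cultured,
            host_depth=config.sim_host_depth,
            capsule_depth=config.sim_capsule_depth,
        )
        truth = simulate.make_sim_truth(
            catalog,
            de_fraction=config.sim_de_fraction,
            log2_effect_size=config.sim_log2_effect,
            dispersion=config.sim_dispersion,
            symbiont_depth_fraction=config.sim_symbiont_depth_fraction,
            design=design,
            seed=config.seed,
        )
        counts = simulate.simulate_counts(catalog, design, truth)
        hits, taxon_map = simulate.simulate_hit_table(
            catalog,
            assignment_error_rate=config.sim_assignment_error,
            no_hit_rate=config.sim_no_hit_rate,
            seed=config.seed,
        )
        hits = partition.attach_taxon_groups(hits, taxon_map)
    else:
        from . import io as dio

        counts = dio.read_counts(config.counts_path)
        design = dio.read_design(config.design_path)
        catalog = dio.read_catalog_metadata(config.catalog_path)
        hits = partition.attach_taxon_groups(
            dio.read_hit_table(config.hits_path), dio.read_taxon_map(config.taxon_map_path)
        )
    report.add_stage("input", len(catalog), len(catalog))
    report.summaries["n_samples"] = int(len(design))

    if "partition" not in config.stages:
        return report

    assignments = partition.classify_by_besthit(
        hits, transcript_ids=catalog["transcript_id"]
    )
    tally = partition.assignment_counts(assignments)
    n_contam = tally.get(partition.LABEL_CONTAMINANT, 0)
    n_ambig = tally.get(partition.LABEL_AMBIGUOUS, 0)
    report.add_stage(
        "partition", len(catalog), len(catalog) - n_contam - n_ambig, labels=tally
    )

    lengths = catalog.set_index("transcript_id")["length_bp"].reindex(counts.index)
    fpkm_df = filters.fpkm(counts, lengths.to_numpy())

    if "filter" not in config.stages:
        return report

    genes_by_label = {
        lab: assignments.loc[assignments["label"] == lab, "transcript_id"].tolist()
        for lab in (partition.LABEL_HOST, partition.LABEL_SYMBIONT)
    }
    thresholds, detections = estimate_thresholds(
        fpkm_df,
        design,
        genes_by_label,
        window=config.window,
        step=config.step,
        lower_limit_step=config.lower_limit_step,
        run_length=config.run_length,
        detection_target=config.detection_target,
    )
    report.thresholds = {
        "lower_limit_fpkm": dict(thresholds.lower_limit_fpkm),
        "absence_threshold_fpkm": thresholds.absence_threshold_fpkm,
    }

    unknown_ids = assignments.loc[
        assignments["label"] == partition.LABEL_UNKNOWN, "transcript_id"
    ]
    if "capsule_symbiont" in thresholds.lower_limit_fpkm and "host_only" in thresholds.lower_limit_fpkm:
        rescued = partition.rescue_unknowns(unknown_ids, fpkm_df, design, thresholds)
        upd = rescued[rescued["label"] != partition.LABEL_UNKNOWN]
        assignments = assignments.set_index("transcript_id")
        assignments.loc[upd["transcript_id"], ["label", "evidence"]] = upd.set_index(
            "transcript_id"
        )[["label", "evidence"]]
        assignments = assignments.reset_index()
        report.add_stage("rescue", len(unknown_ids), len(unknown_ids) - len(upd), rescued=len(upd))

    sym_set = partition.build_symbiont_gene_set(
        counts, fpkm_df, design, assignments, thresholds
    )
    n_sym_labeled = int((assignments["label"] == partition.LABEL_SYMBIONT).sum())
    report.add_stage("symbiont_gene_set", n_sym_labeled, len(sym_set))

    # absence filter on the symbiont set
    cap_cols = list(design.loc[design["sample_class"] == "capsule_symbiont", "sample_id"])
    cell_cols = list(
        design.loc[design["sample_class"] == "host_plus_symbiont", "sample_id"]
    )
    sym_idx = fpkm_df.index.intersection(pd.Index(sorted(sym_set)))
    if thresholds.absence_threshold_fpkm is not None and cap_cols and cell_cols:
        ref = fpkm_df.loc[sym_idx, cap_cols].mean(axis=1)
        detected = (counts.loc[sym_idx, cell_cols] > 0).all(axis=1)
        retained = filters.apply_absence_filter(
            sym_idx, ref, detected, thresholds.absence_threshold_fpkm
        )
        report.add_stage("absence_filter", len(sym_idx), len(retained))
        sym_idx = fpkm_df.index.intersection(pd.Index(sorted(retained)))

    host_ids = assignments.loc[
        assignments["label"] == partition.LABEL_HOST, "transcript_id"
    ]
    host_idx = counts.index.intersection(pd.Index(host_ids))
    ho_cols = list(design.loc[design["sample_class"] == "host_only", "sample_id"])
    hp_cols = cell_cols
    if ho_cols and hp_cols:
        present = (counts.loc[host_idx, ho_cols + hp_cols] > 0).all(axis=1)
        lim_ho = thresholds.lower_limit_fpkm.get("host_only", 0.0)
        lim_hp = thresholds.lower_limit_fpkm.get("host_plus_symbiont", 0.0)
        if np.isfinite(lim_ho) and np.isfinite(lim_hp):
            above = (fpkm_df.loc[host_idx, ho_cols].mean(axis=1) > lim_ho) & (
                fpkm_df.loc[host_idx, hp_cols].mean(axis=1) > lim_hp
            )
        else:
            above = present
        host_kept = host_idx[(present & above).to_numpy()]
        report.add_stage("host_gene_set", len(host_idx), len(host_kept))
        host_idx = host_kept

    if "normalize" not in config.stages or "de" not in config.stages:
        return report

    de_results = {}
    # host contrast: paired host_only vs host_plus_symbiont
    if len(ho_cols) and len(hp_cols) and len(host_idx):
        sub_design = design[design["sample_id"].isin(ho_cols + hp_cols)]
        sub = counts.loc[host_idx, sub_design["sample_id"]]
        norm = normalize.tmm_factors(sub, trim_M=config.trim_M, trim_A=config.trim_A)
        res = run_de(
            sub,
            conditions=sub_design["sample_class"].to_numpy(),
            pairs=sub_design["pair_id"].to_numpy(),
            norm=norm,
            alpha=config.alpha,
            prior_df=config.prior_df,
        )
        de_results["host_response"] = res
    # algal contrast: capsule vs intracellular (unpaired)
    if len(cap_cols) and len(cell_cols) and len(sym_idx):
        sub_design = design[design["sample_id"].isin(cap_cols + cell_cols)]
        sub = counts.loc[sym_idx, sub_design["sample_id"]]
        norm = normalize.tmm_factors(sub, trim_M=config.trim_M, trim_A=config.trim_A)
        res = run_de(
            sub,
            conditions=sub_design["sample_class"].to_numpy(),
            norm=norm,
            alpha=config.alpha,
            prior_df=config.prior_df,
        )
        de_results["algal_response"] = res

    for contrast, res in de_results.items():
        sig = res.significant()
        report.de[contrast] = {
            "n_tested": int(len(res.table)),
            "total": int(len(sig)),
            "up": res.n_up,
            "down": res.n_down,
            "percent_de": de_proportions(len(sig), len(res.table)),
        }
    if {"host_response", "algal_response"} <= set(report.de):
        a = report.de["algal_response"]
        h = report.de["host_response"]
        if a["total"] > 0 and h["total"] > 0:
            report.summaries["algal_vs_host_de_ratio"] = de_proportion_ratio(
                a["total"], a["n_tested"], h["total"], h["n_tested"]
            )

    if truth is not None and "algal_response" in de_results:
        report.summaries["validation"] = _score_against_truth(
            de_results, catalog, truth
        )

    if "annotate" in config.stages:
        scored = score_annotations(hits, min_dist=config.min_dist)
        best = filter_annotations(hits, min_dist=config.min_dist)
        report.add_stage(
            "annotation_filter",
            int(scored["qseqid"].nunique()),
            int(best["qseqid"].nunique()) if len(best) else 0,
        )
    return report


def _score_against_truth(de_results, catalog, truth) -> dict:
    """FDP and sensitivity of each contrast's significant set vs. truth."""
    out = {}
    gene_pos = {g: i for i, g in enumerate(catalog["transcript_id"])}
    for contrast, res in de_results.items():
        if contrast not in truth.de_indicator:
            continue
        ind = truth.de_indicator[contrast]
        sig = res.significant().index
        idx = np.array([gene_pos[g] for g in res.table.index])
        true_de = set(res.table.index[(ind[idx] != 0)])
        called = set(sig)
        fp = len(called - true_de)
        out[contrast] = {
            "n_true_de_tested": len(true_de),
            "n_called": len(called),
            "fdp": fp / max(len(called), 1),
            "sensitivity": len(called & true_de) / max(len(true_de), 1),
        }
    return out
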