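"""Taxonomic partitioning of a mixed two-organism transcript catalog.

Transcripts are assigned to host, symbiont or contaminant by a best-hit
taxon vote over homology hit tables (maximal bitscore; plant/green-algal
best hits are symbiont, animal/vertebrate hits are host, fungal and mite
hits are contaminants to discard). Transcripts without homology evidence
can be rescued by their expression pattern across sample classes: present
in every symbiont-only sample and absent from every host-only sample (or
the mirror image).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filters import ThresholdSet

LABEL_HOST = "host"
LABEL_SYMBIONT = "symbiont"
LABEL_CONTAMINANT = "contaminant"
LABEL_UNKNOWN = "unknown"
LABEL_AMBIGUOUS = "ambiguous"

GROUP_TO_LABEL = {
    "plant_or_green_alga": LABEL_SYMBIONT,
    "animal_or_vertebrate": LABEL_HOST,
    "fungal": LABEL_CONTAMINANT,
    "mite": LABEL_CONTAMINANT,
    "other": LABEL_UNKNOWN,
}


def attach_taxon_groups(hits: pd.DataFrame, taxon_map: pd.DataFrame) -> pd.DataFrame:
    """Join a subject→taxon_group map onto an outfmt-6 hit table."""
    merged = hits.merge(
        taxon_map.rename(columns={"subject_id": "sseqid"}), on="sseqid", how="left"
    )
    missing = merged["taxon_group"].isna()
    if missing.any():
        bad = merged.loc[missing, "sseqid"].iloc[0]
        raise ValueError(f"subject {bad!r} missing from taxon map")
    return merged


def classify_by_besthit(hits: pd.DataFrame, transcript_ids=None) -> pd.DataFrame:
    """Best-bitscore taxon vote per query.

    ``hits`` needs columns qseqid, sseqid, taxon_group, bitscore (plus
    optional length/pident, validated when present). ``transcript_ids``
    supplies the universe so hit-less transcripts are labeled unknown.
    An exact bitscore tie across hits that imply conflicting labels yields
    ``ambiguous``.

    Returns an assignment table (transcript_id, label, evidence).
    """
    h = hits.copy()
    if not np.isfinite(h["bitscore"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite bitscore")
    if "length" in h.columns and (h["length"].to_numpy() < 1).any():
        bad = h.loc[h["length"] < 1, "qseqid"].iloc[0]
        raise ValueError(f"malformed record for query {bad!r}: alignment length < 1")
    if "pident" in h.columns and (
        (h["pident"] < 0) | (h["pident"] > 100)
    ).any():
        bad = h.loc[(h["pident"] < 0) | (h["pident"] > 100), "qseqid"].iloc[0]
        raise ValueError(f"malformed record for query {bad!r}: percent identity")
    rows = []
    for qid, grp in h.groupby("qseqid", sort=False):
        best = grp[grp["bitscore"] == grp["bitscore"].max()]
        labels = {GROUP_TO_LABEL.get(g, LABEL_UNKNOWN) for g in best["taxon_group"]}
        labels.discard(LABEL_UNKNOWN)
        if len(labels) == 0:
            label, evidence = LABEL_UNKNOWN, "best_hit_other"
        elif len(labels) == 1:
            label = labels.pop()
            evidence = str(best.sort_values("sseqid")["sseqid"].iloc[0])
        else:
            label, evidence = LABEL_AMBIGUOUS, "bitscore_tie"
        rows.append((qid, label, evidence))
    table = pd.DataFrame(rows, columns=["transcript_id", "label", "evidence"])
    if transcript_ids is not None:
        universe = pd.Index(transcript_ids, name="transcript_id")
        table = (
            table.set_index("transcript_id")
            .reindex(universe)
            .fillna({"label": LABEL_UNKNOWN, "evidence": "no_hits"})
            .reset_index()
        )
    return table


def rescue_unknowns(
    unknown_ids,
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    thresholds: ThresholdSet,
) -> pd.DataFrame:
    """Expression-pattern rescue of no-homology transcripts.

    A transcript is ``symbiont`` when expressed above the capsule lower
    limit in *every* capsule-symbiont sample and below the host lower
    limit in *every* host-only sample; ``host`` for the mirror pattern;
    otherwise it stays ``unknown``.
    """
    cap_cols = design.loc[design["sample_class"] == "capsule_symbiont", "sample_id"]
    host_cols = design.loc[design["sample_class"] == "host_only", "sample_id"]
    if len(cap_cols) == 0 or len(host_cols) == 0:
        raise ValueError("design must include capsule_symbiont and host_only samples")
    lim_cap = thresholds.lower_limit_fpkm["capsule_symbiont"]
    lim_host = thresholds.lower_limit_fpkm["host_only"]
    ids = pd.Index(unknown_ids)
    sub = fpkm.loc[fpkm.index.intersection(ids)]
    cap = sub[list(cap_cols)].to_numpy()
    hst = sub[list(host_cols)].to_numpy()
    sym_like = (cap > lim_cap).all(axis=1) & (hst < lim_host).all(axis=1)
    host_like = (hst > lim_host).all(axis=1) & (cap < lim_cap).all(axis=1)
    label = np.where(sym_like, LABEL_SYMBIONT, np.where(host_like, LABEL_HOST, LABEL_UNKNOWN))
    out = pd.DataFrame(
        {
            "transcript_id": sub.index,
            "label": label,
            "evidence": "expression_pattern",
        }
    )
    missing = ids.difference(sub.index)
    if len(missing):
        out = pd.concat(
            [
                out,
                pd.DataFrame(
                    {
                        "transcript_id": missing,
                        "label": LABEL_UNKNOWN,
                        "evidence": "not_quantified",
                    }
                ),
            ],
            ignore_index=True,
        )
    return out


def build_symbiont_gene_set(
    counts: pd.DataFrame,
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    assignments: pd.DataFrame,
    thresholds: ThresholdSet,
) -> set:
    """Symbiont genes eligible for differential expression analysis.

    A symbiont-labeled gene is included when, in at least one symbiont
    compartment (capsule samples, or the symbiont component of
    host-plus-symbiont samples), it has ≥ 1 read pair in *every* sample of
    that compartment and FPKM above that compartment's lower limit in
    every sample — and additionally sits below the host-only lower limit
    in all host-only samples.
    """
    if len(assignments) == 0:
        raise ValueError("empty assignment table")
    sym_ids = assignments.loc[assignments["label"] == LABEL_SYMBIONT, "transcript_id"]
    sym_ids = fpkm.index.intersection(pd.Index(sym_ids))
    cols = {
        cls: list(design.loc[design["sample_class"] == cls, "sample_id"])
        for cls in ("capsule_symbiont", "host_plus_symbiont", "host_only")
    }
    lim_host = thresholds.lower_limit_fpkm.get("host_only", 0.0)
    ok_any = np.zeros(len(sym_ids), dtype=bool)
    for cls in ("capsule_symbiont", "host_plus_symbiont"):
        cc = cols[cls]
        if not cc:
            continue
        lim = thresholds.lower_limit_fpkm.get(cls, 0.0)
        present = (counts.loc[sym_ids, cc].to_numpy() >= 1).all(axis=1)
        expressed = (fpkm.loc[sym_ids, cc].to_numpy() > lim).all(axis=1)
        ok_any |= present & expressed
    hc = cols["host_only"]
    if hc:
        ok_any &= (fpkm.loc[sym_ids, hc].to_numpy() < lim_host).all(axis=1)
    return set(sym_ids[ok_any])


def assignment_counts(assignments: pd.DataFrame) -> dict:
    """Tally of labels; sums to the number of input transcripts."""
    return assignments["label"].value_counts().to_dict()
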