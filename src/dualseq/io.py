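"""Readers and writers for the pipeline's tab-separated artifacts.

Counts, designs, catalogs, hit tables, thresholds, normalization factors
and DE results all round-trip through plain TSV; catalogs can also be
written as FASTA (synthetic sequences matching each transcript's length
and GC fraction) via Biopython.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

OUTFMT6_COLUMNS = [
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
]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pair_id": "string"})


def write_catalog_metadata(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_catalog_fasta(catalog: pd.DataFrame, path, seed: int = 0) -> None:
    """Synthetic sequences matching each transcript's length and GC."""
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    records = []
    bases = np.array(list("ACGT"))
    for t in catalog.itertuples(index=False):
        g = t.gc_fraction / 2.0
        a = (1.0 - t.gc_fraction) / 2.0
        seq = rng.choice(bases, size=int(t.length_bp), p=[a, g, g, a])
        records.append(
            SeqRecord(
                Seq("".join(seq)),
                id=str(t.transcript_id),
                description=f"organism={t.organism} gc={t.gc_fraction:.3f}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def catalog_from_fasta(path, organism_of=None) -> pd.DataFrame:
    """Derive (id, length, GC) catalog metadata from a FASTA file."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        gc = (s.count("G") + s.count("C")) / max(len(s), 1)
        org = organism_of(rec.id) if organism_of else "unknown"
        rows.append((rec.id, org, len(s), gc))
    return pd.DataFrame(
        rows, columns=["transcript_id", "organism", "length_bp", "gc_fraction"]
    )


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[OUTFMT6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_hit_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, header=None)


def write_taxon_map(taxon_map: pd.DataFrame, path) -> None:
    taxon_map.to_csv(path, sep="\t", index=False, header=False)


def read_taxon_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["subject_id", "taxon_group"], header=None)


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
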