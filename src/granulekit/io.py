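"""Readers/writers for the package's plain-text interchange formats.

Tabular outputs are TSV with a fixed 9-significant-digit float format
so pipeline runs are byte-stable; JSON is written sorted and with the
same float rounding. Counts travel as a long-format TSV
(gene, library, count) plus a library-design TSV; coverage as a
bedGraph-like TSV (gene, start, end, count; 0-based half-open); gene
sets as one-ID-per-line text; sequences as FASTA.
"""

from __future__ import annotations

import hashlib
import json
import math

import numpy as np
import pandas as pd
from Bio import SeqIO

from .targets import CountExperiment, CoverageSet

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_json",
    "write_counts",
    "read_counts",
    "write_coverage",
    "read_coverage",
    "write_gene_set",
    "read_gene_set",
    "write_fasta",
    "read_fasta",
    "sha256_file",
]

FLOAT_FMT = "%.9g"


def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isfinite(v):
            return float(FLOAT_FMT % v)
        return str(v)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, lineterminator="\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_counts(experiment: CountExperiment, counts_path, design_path) -> None:
    long = (
        experiment.counts.rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="library", value_name="count")
        .sort_values(["library", "gene"], kind="mergesort")
    )
    write_tsv(long, counts_path)
    design = experiment.design.copy()
    design["library_size"] = experiment.library_sizes
    write_tsv(design.rename_axis("library").reset_index(), design_path)


def read_counts(counts_path, design_path) -> CountExperiment:
    long = read_tsv(counts_path)
    counts = long.pivot(index="gene", columns="library", values="count").fillna(0)
    design = read_tsv(design_path).set_index("library")
    sizes = design.pop("library_size") if "library_size" in design else None
    counts = counts[design.index]
    return CountExperiment(counts, design, sizes)


def write_coverage(coverage: CoverageSet, path) -> None:
    """bedGraph-like TSV: gene, start, end, count (0-based half-open),
    run-length encoded over constant-count stretches."""
    rows = []
    for gene in sorted(coverage.per_gene):
        arr = np.asarray(coverage.per_gene[gene])
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        for s, e in zip(starts, ends):
            if arr[s] != 0:
                rows.append((gene, int(s), int(e), int(arr[s])))
    df = pd.DataFrame(rows, columns=["gene", "start", "end", "count"])
    header = pd.DataFrame(
        [(g, 0, L, 0) for g, L in sorted(coverage.gene_lengths.items())],
        columns=["gene", "start", "end", "count"],
    )
    # zero rows declare gene lengths; non-zero rows carry coverage
    write_tsv(pd.concat([header, df], ignore_index=True), path)


def read_coverage(path) -> CoverageSet:
    df = read_tsv(path)
    lengths = (
        df[df["count"] == 0].set_index("gene")["end"].astype(int).to_dict()
    )
    per_gene = {g: np.zeros(L, dtype=np.int64) for g, L in lengths.items()}
    for row in df[df["count"] != 0].itertuples(index=False):
        per_gene[row.gene][row.start : row.end] = row.count
    return CoverageSet(per_gene=per_gene, gene_lengths=lengths)


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_set(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_fasta(records, path) -> None:
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list:
    return list(SeqIO.parse(path, "fasta"))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
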