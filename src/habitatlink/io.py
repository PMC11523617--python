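"""Readers, writers and input validation for the pipeline's file formats.

Formats are deliberately plain text: OTU tables as TSV (rows = OTUs, columns
= samples, optional trailing ``taxonomy`` column), sample metadata and
feature/injection tables as CSV, distance matrices as square TSV, association
graphs as GraphML plus a flat TSV edge list.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .otu import OtuTable
from .chem import FeatureMatrix

__all__ = [
    "read_otu_tsv",
    "write_otu_tsv",
    "read_feature_csv",
    "write_feature_csv",
    "write_distance_tsv",
    "export_graphml",
    "import_graphml",
    "validate_inputs",
]


# ---------------------------------------------------------------------------
# OTU tables


def read_otu_tsv(path, sample_meta_path=None) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"]
        df = df.drop(columns="taxonomy")
    meta = None
    if sample_meta_path is not None:
        meta = pd.read_csv(sample_meta_path, index_col="sample_id")
    return OtuTable(df, taxonomy=taxonomy, sample_meta=meta)


def write_otu_tsv(table: OtuTable, path, sample_meta_path=None) -> None:
    out = table.counts.copy()
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t", index_label="otu_id")
    if sample_meta_path is not None and table.sample_meta is not None:
        table.sample_meta.to_csv(sample_meta_path, index_label="sample_id")


# ---------------------------------------------------------------------------
# feature matrices


def read_feature_csv(matrix_path, injections_path) -> FeatureMatrix:
    intensities = pd.read_csv(matrix_path, index_col=0)
    injections = pd.read_csv(injections_path, index_col="injection_id")
    return FeatureMatrix(intensities, injections)


def write_feature_csv(matrix: FeatureMatrix, matrix_path, injections_path) -> None:
    matrix.intensities.to_csv(matrix_path, index_label="feature_id")
    matrix.injections.to_csv(injections_path, index_label="injection_id")


def write_distance_tsv(dist, path) -> None:
    df = pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# association graphs


def export_graphml(graph: nx.Graph, path) -> None:
    """GraphML with node ``kind`` and edge zhang/rho/support/p/n attributes."""
    nx.write_graphml(graph, path)


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# validation


def _check_numeric(df, cols, file, report, nonneg=False):
    for col in cols:
        if col not in df.columns:
            report.append({"file": file, "where": col, "problem": "missing column"})
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        for idx in bad:
            report.append({"file": file, "where": f"{col}[{idx}]", "problem": "not numeric"})
        if nonneg:
            for idx in df.index[vals < 0]:
                report.append({"file": file, "where": f"{col}[{idx}]", "problem": "negative value"})


def validate_inputs(paths: dict) -> list[dict]:
    """Schema and cross-file consistency checks for pipeline inputs.

    ``paths`` maps table kinds (``gardens``, ``samples``, ``otu_<marker>``,
    ``features``, ``injections``) to file paths.  All violations are
    collected (never aborting on the first), each with file and row/column
    context.  An empty list means the inputs are well formed.
    """
    report: list[dict] = []
    frames: dict = {}
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        sep = "\t" if p.suffix in (".tsv", ".txt") else ","
        frames[kind] = pd.read_csv(p, sep=sep)

    if "gardens" in frames:
        g = frames["gardens"]
        need = {"garden_id", "d_highway", "d_agri", "d_indus"}
        for col in sorted(need - set(g.columns)):
            report.append({"file": "gardens", "where": col, "problem": "missing column"})
        _check_numeric(g, [c for c in ("d_highway", "d_agri", "d_indus") if c in g.columns],
                       "gardens", report, nonneg=True)

    sample_ids = None
    if "samples" in frames:
        s = frames["samples"]
        if "sample_id" not in s.columns:
            report.append({"file": "samples", "where": "sample_id", "problem": "missing column"})
        else:
            sample_ids = set(s["sample_id"])
            dup = s["sample_id"][s["sample_id"].duplicated()]
            for idx in dup.index:
                report.append({"file": "samples", "where": f"sample_id[{idx}]",
                               "problem": "duplicate sample id"})
        if "status" in s.columns:
            bad = s.index[~s["status"].isin(["NC", "C", "L", "NEG"])]
            for idx in bad:
                report.append({"file": "samples", "where": f"status[{idx}]",
                               "problem": "status must be NC/C/L/NEG"})

    for kind, df in frames.items():
        if not kind.startswith("otu"):
            continue
        counts = df.set_index(df.columns[0])
        if "taxonomy" in counts.columns:
            counts = counts.drop(columns="taxonomy")
        for col in counts.columns:
            vals = pd.to_numeric(counts[col], errors="coerce")
            for idx in counts.index[vals.isna()]:
                report.append({"file": kind, "where": f"{col}[{idx}]", "problem": "not numeric"})
            for idx in counts.index[vals < 0]:
                report.append({"file": kind, "where": f"{col}[{idx}]", "problem": "negative count"})
            frac = vals.dropna() % 1
            for idx in frac.index[frac != 0]:
                report.append({"file": kind, "where": f"{col}[{idx}]", "problem": "non-integer count"})
        if sample_ids is not None:
            for col in counts.columns:
                if col not in sample_ids:
                    report.append({"file": kind, "where": col,
                                   "problem": "sample missing from metadata"})

    if "features" in frames and "injections" in frames:
        feats = frames["features"].set_index(frames["features"].columns[0])
        inj = frames["injections"]
        if "injection_id" in inj.columns:
            known = set(inj["injection_id"])
            for col in feats.columns:
                if col not in known:
                    report.append({"file": "features", "where": col,
                                   "problem": "injection missing from injections table"})
        if "role" in inj.columns:
            bad = inj.index[~inj["role"].isin(["study", "QC", "blank"])]
            for idx in bad:
                report.append({"file": "injections", "where": f"role[{idx}]",
                               "problem": "role must be study/QC/blank"})
    return report
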