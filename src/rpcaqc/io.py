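"""Readers and writers for the plain-text formats the tool touches.

Count tables follow the HTSeq-count convention on disk (genes as rows,
samples as columns, first column gene ids); the samples x genes
orientation the PCA needs is purely internal.  Parsers reject rather
than coerce malformed input and name the offending line.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import TransformedMatrix
from .outlier_map import OutlierDiagnostics
from .simulate import CountMatrix, SimulationTruth

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_truth",
    "write_report",
    "write_transformed",
]

logger = logging.getLogger("rpcaqc")

REPORT_COLUMNS = ["sample_id", "sd", "od", "c_sd", "c_od",
                  "category", "is_outlier", "method", "k", "crit"]


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_counts(path: str | Path, dialect: str = "tsv",
                groups: dict[str, str] | None = None) -> CountMatrix:
    """Read an HTSeq-style count table (first column gene ids).

    Special summary rows whose id starts with ``__`` (e.g.
    ``__no_feature``) are dropped with a log line.  Duplicate ids,
    ragged rows, negative or non-integer cells are parse errors that
    name the offending line.
    """
    path = Path(path)
    sep = _sep(dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"{path}:1: duplicate sample ids in header")
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        n_special = 0
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            gid = parts[0]
            if gid.startswith("__"):
                n_special += 1
                continue
            if len(parts) - 1 != len(sample_ids):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(sample_ids)} values, "
                    f"got {len(parts) - 1}"
                )
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            vals = []
            for cell in parts[1:]:
                try:
                    v = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count {cell!r}"
                    ) from None
                if v < 0:
                    raise ValueError(f"{path}:{lineno}: negative count {v}")
                vals.append(v)
            gene_ids.append(gid)
            rows.append(vals)
    if n_special:
        logger.info("dropped %d HTSeq special rows from %s", n_special, path)
    if not rows:
        raise ValueError(f"{path}: no gene rows found")
    grp = [groups.get(s, "unknown") for s in sample_ids] if groups else \
        ["unknown"] * len(sample_ids)
    return CountMatrix(np.array(rows, dtype=np.int64), gene_ids, sample_ids, grp)


def write_counts(cm: CountMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a count matrix in the canonical gene-rows layout."""
    sep = _sep(dialect)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["gene_id", *cm.sample_ids]) + "\n")
        for i, gid in enumerate(cm.gene_ids):
            fh.write(sep.join([gid, *map(str, cm.counts[i])]) + "\n")


def read_metadata(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a sample metadata table (sample_id, group[, batch])."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: metadata needs sample_id and group columns")
    if df.sample_id.duplicated().any():
        dup = df.sample_id[df.sample_id.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return df


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Write simulation ground truth as two stacked TSV tables."""
    path = Path(path)
    gene_ids = truth.gene_ids or sorted(truth.de_genes)
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tis_de\n")
        for gid in gene_ids:
            lfc = truth.de_genes.get(gid, 0.0)
            fh.write(f"{gid}\t{lfc:.6g}\t{int(gid in truth.de_genes)}\n")
        fh.write("\nsample_id\tis_outlier\n")
        for sid, flag in truth.outlier_labels.items():
            fh.write(f"{sid}\t{int(flag)}\n")


def write_transformed(tm: TransformedMatrix, path: str | Path) -> None:
    """Write a transformed matrix (rows samples, columns genes)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", *tm.gene_ids]) + "\n")
        for i, sid in enumerate(tm.sample_ids):
            vals = "\t".join(f"{v:.6g}" for v in tm.values[i])
            fh.write(f"{sid}\t{vals}\n")


def diagnostics_frame(diag: OutlierDiagnostics) -> pd.DataFrame:
    ids = diag.sample_ids or [f"sample_{i + 1}" for i in range(len(diag.sd))]
    return pd.DataFrame({
        "sample_id": ids,
        "sd": diag.sd,
        "od": diag.od,
        "c_sd": diag.c_sd,
        "c_od": diag.c_od,
        "category": diag.category,
        "is_outlier": diag.is_outlier,
        "method": diag.metadata.get("method", ""),
        "k": diag.metadata.get("k", ""),
        "crit": diag.crit,
    })[REPORT_COLUMNS]


def write_report(diag: OutlierDiagnostics, path: str | Path) -> None:
    """Write the per-sample report as TSV plus a JSON twin with provenance."""
    path = Path(path)
    df = diagnostics_frame(diag)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    payload = {
        "samples": df.assign(is_outlier=df.is_outlier.astype(bool))
                     .to_dict(orient="records"),
        "cutoffs": {"c_sd": float(diag.c_sd), "c_od": float(diag.c_od)},
        "crit": diag.crit,
        "od_informative": diag.od_informative,
        "metadata": {k: _jsonable(v) for k, v in diag.metadata.items()},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v
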