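"""Readers and writers for the formats the pipeline consumes.

Expression matrices arrive as an MTX triplet directory (matrix.mtx,
barcodes.tsv, features.tsv; genes x cells orientation), an .h5ad file, or
a dense CSV (cells x genes). Cell metadata is a CSV with required columns
cell_id, cell_type, group. Networks are two-column edge-list TSVs, pathway
collections are GMT files, and all result writers emit deterministic
tab-separated UTF-8 with 6-significant-digit floats.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

__all__ = [
    "read_expression",
    "read_metadata",
    "read_gmt",
    "read_network",
    "read_pairs",
    "read_mr_table",
    "write_table",
    "write_expression_mtx",
    "write_manifest",
]

logger = logging.getLogger(__name__)

META_REQUIRED = ["cell_id", "cell_type", "group"]


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in META_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    meta["cell_id"] = meta["cell_id"].astype(str)
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids in metadata: {dups[:5]}")
    return meta


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "mtx"
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.suffix in {".csv", ".tsv", ".txt"}:
        return "csv"
    raise ValueError(f"cannot auto-detect expression format of {path}")


def read_expression(counts_path, meta_path=None, fmt: str = "auto",
                    feature_column: int = 0) -> ad.AnnData:
    """Counts plus per-cell labels as an AnnData.

    MTX triplets are read genes x cells (CellRanger orientation) and
    transposed; ``feature_column`` selects the id column of features.tsv.
    Duplicate gene names are suffixed deterministically. Every matrix
    barcode must appear in the metadata.
    """
    path = Path(counts_path)
    fmt = _detect_format(path) if fmt == "auto" else fmt
    if fmt == "mtx":
        X = scio.mmread(path / "matrix.mtx").tocsr().T.tocsr()
        barcodes = pd.read_csv(path / "barcodes.tsv", header=None,
                               sep="\t")[0].astype(str).tolist()
        features = pd.read_csv(path / "features.tsv", header=None, sep="\t")
        genes = features[feature_column].astype(str).tolist()
        adata = ad.AnnData(X=X, obs=pd.DataFrame(index=barcodes),
                           var=pd.DataFrame(index=genes))
    elif fmt == "h5ad":
        adata = ad.read_h5ad(path)
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        adata = ad.AnnData(X=df.to_numpy(dtype=np.float64),
                           obs=pd.DataFrame(index=df.index.astype(str)),
                           var=pd.DataFrame(index=df.columns.astype(str)))
    else:
        raise ValueError(f"unknown expression format {fmt!r}")

    if adata.var_names.duplicated().any():
        n = int(adata.var_names.duplicated().sum())
        logger.warning("%d duplicate gene names suffixed deterministically", n)
        adata.var_names_make_unique()

    if meta_path is not None:
        meta = read_metadata(meta_path)
        missing = sorted(set(map(str, adata.obs_names)) - set(meta["cell_id"]))
        if missing:
            raise ValueError(
                f"{len(missing)} barcodes absent from metadata, e.g. "
                f"{missing[:5]}"
            )
        meta = meta.set_index("cell_id")
        aligned = meta.loc[list(map(str, adata.obs_names))]
        for col in aligned.columns:
            adata.obs[col] = aligned[col].to_numpy()
        adata.obs["cell_id"] = list(map(str, adata.obs_names))
    return adata


def read_gmt(path) -> dict[str, list[str]]:
    """GMT pathway file: name TAB description TAB gene...; empty sets skipped."""
    pathways: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line {ln}: {line[:60]!r}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                warnings.warn(f"pathway {name!r} has no genes; skipped "
                              f"(line {ln})")
                continue
            pathways[name] = genes
    return pathways


def read_network(path) -> nx.Graph:
    """Two-column edge-list TSV; self-loops and duplicate edges dropped."""
    g = nx.Graph()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed network line {ln}: {line[:60]!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loop edges", n_self)
    return g


def read_pairs(path) -> pd.DataFrame:
    """Activity table (raw records or aggregated kb output)."""
    df = pd.read_csv(path, sep="\t")
    if "metabolite_id" not in df.columns or "sensor_id" not in df.columns:
        raise ValueError("pairs table needs metabolite_id and sensor_id columns")
    return df


def read_mr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "metabolite_id" not in df.columns or "fdr" not in df.columns:
        raise ValueError("MR table needs metabolite_id and fdr columns")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV: fixed column order, 6-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_expression_mtx(adata: ad.AnnData, out_dir) -> None:
    """MTX triplet (genes x cells) plus a metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = sparse.csr_matrix(X) if not sparse.issparse(X) else X.tocsr()
    scio.mmwrite(out / "matrix.mtx", X.T.tocoo())
    pd.Series(list(adata.obs_names)).to_csv(out / "barcodes.tsv", sep="\t",
                                            header=False, index=False)
    pd.Series(list(adata.var_names)).to_csv(out / "features.tsv", sep="\t",
                                            header=False, index=False)
    meta = adata.obs.copy()
    if "cell_id" not in meta.columns:
        meta.insert(0, "cell_id", list(adata.obs_names))
    meta.to_csv(out / "metadata.csv", index=False)


def _digest(path) -> str:
    h = hashlib.sha256()
    p = Path(path)
    if p.is_dir():
        for f in sorted(p.rglob("*")):
            if f.is_file():
                h.update(f.read_bytes())
    else:
        h.update(p.read_bytes())
    return h.hexdigest()


def write_manifest(path, subcommand: str, params: dict, seed,
                   inputs: dict | None = None,
                   attrition: dict | None = None) -> None:
    """JSON run manifest: version, parameters, seed, input digests, attrition."""
    from . import __version__
    manifest = {
        "tool": "scfumes",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "params": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                       else str(v)) for k, v in params.items()},
        "inputs": {k: {"path": str(v), "sha256": _digest(v)}
                   for k, v in (inputs or {}).items()},
        "attrition": attrition or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
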