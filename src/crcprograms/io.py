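"""Readers and writers for the formats the pipeline exchanges.

Count matrices travel either as a Matrix Market triplet directory
(``matrix.mtx`` genes x cells, with ``genes.tsv`` and ``barcodes.tsv``
sidecars, per the droplet-sequencing convention) or as a dense TSV (genes
as rows, cells as columns). Gene sets travel as GMT or two-column TSV.
All writes are atomic: content goes to a temporary file in the target
directory which is renamed into place, so a failure never leaves a partial
output behind.

Gene identifiers are case-sensitive symbols matched by exact string.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .factorize import Signature
from .scoring import MetaSignature


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a sibling temp file, rename into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _check_genes(genes: pd.Index) -> None:
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifiers: {list(dup[:5])}")


def read_counts(
    path: str | Path, fmt: str = "mtx", metadata: str | Path | None = None
) -> ad.AnnData:
    """Load a count matrix (cells x genes AnnData) from MTX triplet or TSV.

    ``path`` is the triplet directory for ``fmt='mtx'`` or the dense TSV
    file (genes as rows) for ``fmt='tsv'``. ``metadata`` is an optional
    per-cell TSV (index = cell barcodes) merged into ``obs``.
    """
    path = Path(path)
    if fmt == "mtx":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(mtx)
        try:
            mat = spio.mmread(mtx)
        except ValueError as exc:
            raise ValueError(f"malformed MTX file {mtx}: {exc}") from exc
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(cells)):
            raise ValueError(
                f"MTX dimensions {dense.shape} do not match sidecars "
                f"({len(genes)} genes, {len(cells)} barcodes)"
            )
        counts = dense.T
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes, cells = df.index, df.columns
        counts = df.to_numpy().T
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if not np.allclose(counts, np.round(counts)) or (counts < 0).any():
        raise ValueError("counts must be non-negative integers")
    genes = pd.Index(genes.astype(str))
    _check_genes(genes)
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(cells.astype(str), name="cell")),
        var=pd.DataFrame(index=genes),
    )
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", index_col=0)
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise ValueError(f"metadata missing for cells: {list(missing[:5])}")
        adata.obs = meta.loc[adata.obs_names].copy()
    return adata


def write_counts(adata: ad.AnnData, path: str | Path, fmt: str = "mtx") -> None:
    """Write counts as MTX triplet directory or dense TSV (genes x cells)."""
    path = Path(path)
    X = np.asarray(adata.X)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        with atomic_write(path / "matrix.mtx", "wb") as fh:
            spio.mmwrite(fh, sparse.coo_matrix(X.T))
        with atomic_write(path / "genes.tsv") as fh:
            fh.write("\n".join(adata.var_names) + "\n")
        with atomic_write(path / "barcodes.tsv") as fh:
            fh.write("\n".join(adata.obs_names) + "\n")
        if len(adata.obs.columns):
            write_table(adata.obs, path / "metadata.tsv")
    elif fmt == "tsv":
        df = pd.DataFrame(X.T, index=adata.var_names, columns=adata.obs_names)
        write_table(df, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=index)


def read_gmt(path: str | Path) -> list[Signature]:
    """Read gene sets from GMT (name, description, genes...)."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with <3 fields: {line[:60]!r}")
        sigs.append(Signature(name=parts[0], genes=parts[2:], source_factor=None))
    return sigs


def write_gmt(signatures: list[Signature | MetaSignature], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for sig in signatures:
            desc = getattr(sig, "source_factor", "") or ""
            fh.write("\t".join([sig.name, str(desc), *sig.genes]) + "\n")


def read_signature_tsv(path: str | Path) -> list[Signature]:
    """Two-column TSV (signature, gene), ordered within signature."""
    df = pd.read_csv(path, sep="\t")
    if not {"signature", "gene"}.issubset(df.columns):
        raise ValueError("signature TSV needs 'signature' and 'gene' columns")
    return [
        Signature(name=str(name), genes=list(sub["gene"].astype(str)))
        for name, sub in df.groupby("signature", sort=False)
    ]


def write_signature_tsv(signatures: list[Signature | MetaSignature], path: str | Path) -> None:
    rows = [(s.name, g) for s in signatures for g in s.genes]
    write_table(pd.DataFrame(rows, columns=["signature", "gene"]), path, index=False)


def write_factor_model(model, w_path: str | Path, h_path: str | Path) -> None:
    write_table(model.W, w_path)
    write_table(model.H, h_path)


def read_bulk_cohort(expression_path: str | Path, survival_path: str | Path):
    """Bulk cohort from a samples x genes TSV and a survival TSV."""
    from .simulate import BulkCohort

    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    surv = pd.read_csv(survival_path, sep="\t", index_col=0)
    if not {"time", "event"}.issubset(surv.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    common = expr.index.intersection(surv.index)
    if len(common) < 2:
        raise ValueError("degenerate cohort: <2 samples shared between tables")
    cluster = surv["cluster"] if "cluster" in surv.columns else None
    return BulkCohort(
        expression=expr.loc[common],
        survival=surv.loc[common, ["time", "event"]],
        cluster=cluster.loc[common] if cluster is not None else None,
    )
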