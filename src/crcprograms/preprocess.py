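"""QC filtering, normalization, gene filtering, per-patient centering and DE.

The expression scale throughout is ``E = log2(CPM/10 + 1)`` computed per
cell against the library total at input; the per-gene aggregate is
``Ea = log2(mean_cells(E) + 1)`` and genes below a cutoff are dropped to
focus on intermediately-to-highly expressed genes. Inter-patient shifts are
removed by subtracting, per patient and per gene, the patient mean (the
centered values are signed).

Matrices are AnnData, cells x genes; per-cell metadata lives in ``obs``
(``patient``, ``total_reads``, ``mito_fraction``).
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

QC_META_COLUMNS = ("patient", "total_reads", "mito_fraction")


class EmptyResultError(ValueError):
    """All cells (or genes) were removed by a filtering step."""


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def qc_filter(
    m: ad.AnnData,
    min_reads: int = 100_000,
    min_genes: int = 1000,
    max_mito: float = 0.15,
    top_read_quantile: float = 0.05,
    pca_outlier_sd: float | None = None,
) -> ad.AnnData:
    """Remove low-quality cell libraries.

    A cell passes only with strictly more than ``min_reads`` reads, strictly
    more than ``min_genes`` detected genes and strictly less than
    ``max_mito`` mitochondrial read fraction. Among the survivors the
    top ``top_read_quantile`` fraction of libraries by reads is removed
    within each patient independently (``floor(q*n)`` cells per patient,
    ties broken by stable cell order). PCA-outlier removal (cells further
    than ``pca_outlier_sd`` SDs from the centroid distance in top-10 PC
    space of log expression) runs only when that parameter is set.

    Removal counts per rule are logged in ``uns['qc_log']``.
    """
    for col in QC_META_COLUMNS:
        if col not in m.obs.columns:
            raise KeyError(f"QC metadata column {col!r} missing from obs")
    X = _dense(m)
    reads = m.obs["total_reads"].to_numpy(dtype=float)
    mito = m.obs["mito_fraction"].to_numpy(dtype=float)
    detected = (X > 0).sum(axis=1)

    ok_reads = reads > min_reads
    ok_genes = detected > min_genes
    ok_mito = mito < max_mito
    keep = ok_reads & ok_genes & ok_mito

    log = {
        "cells_in": m.n_obs,
        "removed_low_reads": int((~ok_reads).sum()),
        "removed_few_genes": int((~ok_genes).sum()),
        "removed_high_mito": int((~ok_mito).sum()),
    }

    # Top-read removal per patient on the survivors of the hard criteria.
    surv_idx = np.flatnonzero(keep)
    drop = np.zeros(m.n_obs, dtype=bool)
    patients = m.obs["patient"].to_numpy()
    for pat in pd.unique(patients[surv_idx]):
        cells = surv_idx[patients[surv_idx] == pat]
        n_remove = int(np.floor(top_read_quantile * len(cells)))
        if n_remove == 0:
            continue
        order = np.argsort(-reads[cells], kind="stable")
        drop[cells[order[:n_remove]]] = True
    log["removed_top_reads"] = int(drop.sum())
    keep &= ~drop

    if pca_outlier_sd is not None:
        keep_idx = np.flatnonzero(keep)
        if len(keep_idx) > 10:
            from sklearn.decomposition import PCA

            sub = X[keep_idx]
            totals = sub.sum(axis=1, keepdims=True)
            e = np.log2(sub / totals * 1e6 / 10 + 1)
            pcs = PCA(n_components=min(10, min(e.shape) - 1), random_state=0).fit_transform(e)
            dist = np.linalg.norm(pcs - pcs.mean(axis=0), axis=1)
            outlier = dist > dist.mean() + pca_outlier_sd * dist.std()
            log["removed_pca_outliers"] = int(outlier.sum())
            keep[keep_idx[outlier]] = False
        else:
            log["removed_pca_outliers"] = 0

    if not keep.any():
        raise EmptyResultError("QC filtering removed every cell")
    out = m[keep].copy()
    log["cells_out"] = out.n_obs
    out.uns["qc_log"] = log
    return out


def normalize_cpm_log(m: ad.AnnData) -> ad.AnnData:
    """Expression values E = log2(CPM/10 + 1) with per-gene aggregates.

    CPM denominators are the per-cell totals over all genes present at
    input, i.e. normalization precedes any gene filtering. Per-gene
    aggregate expression Ea = log2(mean_cells(E) + 1) is stored in
    ``var['Ea']``.
    """
    X = _dense(m).astype(float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = m.obs_names[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    cpm = X / totals[:, None] * 1e6
    e = np.log2(cpm / 10.0 + 1.0)
    out = ad.AnnData(X=e, obs=m.obs.copy(), var=m.var.copy())
    out.var["Ea"] = aggregate_expression(e)
    return out


def aggregate_expression(e: np.ndarray) -> np.ndarray:
    """Per-gene aggregate Ea = log2(mean over cells of E + 1)."""
    return np.log2(e.mean(axis=0) + 1.0)


def filter_low_expression(e: ad.AnnData, min_ea: float = 3.5) -> ad.AnnData:
    """Retain genes whose aggregate expression Ea is >= ``min_ea``.

    The exclusion is strict (< ``min_ea`` removed); a gene sitting exactly
    on the cutoff is retained.
    """
    ea = (
        e.var["Ea"].to_numpy(dtype=float)
        if "Ea" in e.var.columns
        else aggregate_expression(_dense(e))
    )
    keep = ea >= min_ea
    if not keep.any():
        raise EmptyResultError(f"no gene reaches Ea >= {min_ea}")
    out = e[:, keep].copy()
    out.var["Ea"] = ea[keep]
    return out


def mean_center_by_patient(
    e: ad.AnnData, patients: pd.Series | None = None
) -> ad.AnnData:
    """Subtract, per patient and per gene, the patient mean expression.

    Removes global inter-patient shifts; output values are signed and have
    zero mean per gene within every patient. Idempotent.
    """
    if patients is None:
        if "patient" not in e.obs.columns:
            raise KeyError("no patient labels provided and none in obs")
        patients = e.obs["patient"]
    patients = pd.Series(np.asarray(patients), index=e.obs_names)
    X = _dense(e).astype(float)
    er = np.empty_like(X)
    for pat, idx in patients.groupby(patients).groups.items():
        rows = e.obs_names.get_indexer(idx)
        if len(rows) == 0:
            raise ValueError(f"patient {pat!r} has zero cells")
        er[rows] = X[rows] - X[rows].mean(axis=0, keepdims=True)
    out = ad.AnnData(X=er, obs=e.obs.copy(), var=e.var.copy())
    return out


def lgr5_gate(scores: pd.Series, threshold: float = 1.0) -> pd.DataFrame:
    """Strict-threshold positivity calls on per-culture LGR5 scores."""
    scores = scores.astype(float)
    if (scores < 0).any():
        raise ValueError("LGR5 scores must be >= 0")
    return pd.DataFrame({"lgr5_score": scores, "is_positive": scores > threshold})


def lgr5_score(
    m: ad.AnnData, gene: str = "LGR5", threshold: float = 1.0
) -> pd.DataFrame:
    """Per-patient LGR5 score = total transcript counts / cell number.

    A culture is called positive when its score strictly exceeds
    ``threshold``. A missing gene yields score 0 with a warning.
    """
    patients = m.obs["patient"]
    if gene in m.var_names:
        counts = pd.Series(
            np.asarray(m[:, gene].X).ravel().astype(float), index=m.obs_names
        )
    else:
        warnings.warn(f"gene {gene!r} not found; scores set to 0")
        counts = pd.Series(0.0, index=m.obs_names)
    score = counts.groupby(patients, observed=True).sum() / patients.value_counts()
    score = score.sort_index()
    return lgr5_gate(score, threshold)


def de_genes_per_patient(
    e: ad.AnnData,
    patients: pd.Series | None = None,
    alpha: float = 0.05,
    min_lfc: float = 0.25,
    top_n: int = 10,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per patient.

    Per patient, every gene is tested against all other patients' cells
    (two-sided Wilcoxon rank-sum), p-values are Benjamini-Hochberg adjusted
    within the contrast, and genes pass with adjusted p strictly < ``alpha``
    and log fold-change (mean E in patient minus mean E in the rest)
    strictly > ``min_lfc``; marker lists are up-regulated genes. Results are ranked by adjusted p, then |log fold-change|, and
    the top ``top_n`` per patient returned as one tidy frame.
    """
    if patients is None:
        patients = e.obs["patient"]
    patients = pd.Series(np.asarray(patients), index=e.obs_names)
    if patients.nunique() < 2:
        raise ValueError("differential expression needs >= 2 patients")
    X = _dense(e).astype(float)
    frames = []
    for pat in patients.unique():
        mask = (patients == pat).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"patient {pat!r} has <3 cells; skipped")
            continue
        x, y = X[mask], X[~mask]
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided")
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        lfc = x.mean(axis=0) - y.mean(axis=0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "patient": pat,
                "gene": e.var_names,
                "p_value": pvals,
                "p_adj": padj,
                "log_fc": lfc,
            }
        )
        df = df[(df["p_adj"] < alpha) & (df["log_fc"] > min_lfc)]
        df = df.assign(abs_lfc=df["log_fc"].abs()).sort_values(
            ["p_adj", "abs_lfc"], ascending=[True, False], kind="stable"
        )
        frames.append(df.drop(columns="abs_lfc").head(top_n))
    if not frames:
        return pd.DataFrame(columns=["patient", "gene", "p_value", "p_adj", "log_fc"])
    return pd.concat(frames, ignore_index=True)
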