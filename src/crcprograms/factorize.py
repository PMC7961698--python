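"""Non-negative matrix factorization of centered expression and signatures.

The centered expression matrix (negatives clipped to zero) is factorized as
``X ~ W @ H`` with gene loadings ``W`` (genes x k) and cell scores ``H``
(k x cells), both non-negative. Fitting uses Frobenius multiplicative
updates, which make the reconstruction error non-increasing across
iterations; the best of several seeded random restarts is kept, so a fit is
fully deterministic given its seed.

Factors dominated by a single patient are flagged by comparing, per factor,
the per-patient distributions of cell scores: histograms on shared
equal-width bins, pairwise histogram-intersection overlap, and exclusion of
factors for which enough patients show low median overlap with the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd


@dataclass
class FactorModel:
    """NNMF decomposition with provenance."""

    W: pd.DataFrame  # genes x k, non-negative loadings
    H: pd.DataFrame  # k x cells, non-negative scores
    k: int
    reconstruction_error: float
    error_history: list[float]
    seed: int
    n_restarts: int
    restart_errors: list[float] = field(default_factory=list)

    @property
    def factor_ids(self) -> list[str]:
        return list(self.W.columns)


@dataclass
class Signature:
    """Ranked top-gene list extracted from one factor."""

    name: str
    genes: list[str]
    source_factor: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


def _mu_factorize(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float):
    """Multiplicative-update NNMF of one restart; returns W, H, error history."""
    eps = 1e-12
    m, n = X.shape
    scale = np.sqrt(max(X.mean(), eps) / k)
    W = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale
    norm_x = np.linalg.norm(X)
    history: list[float] = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ (W @ H) + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        err = float(np.linalg.norm(X - W @ H))
        history.append(err)
        if prev is not None and (prev - err) <= tol * max(norm_x, eps):
            break
        prev = err
    return W, H, history


def fit_nnmf(
    er: ad.AnnData,
    k: int = 25,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> FactorModel:
    """Best-of-restarts NNMF of the clipped centered matrix.

    Negative centered values are set to zero before factorization (so a
    pre-clipped input gives an identical result). The matrix is factorized
    genes x cells; the restart with the lowest final Frobenius error wins.
    """
    X = np.asarray(er.X, dtype=float).T.copy()  # genes x cells
    if not np.isfinite(X).all():
        raise ValueError("centered matrix contains non-finite values")
    np.clip(X, 0.0, None, out=X)
    if X.max() == 0:
        raise ValueError("matrix is all zero after clipping negatives")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(genes, cells)={min(X.shape)}")

    child_seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    restart_errors = []
    for ss in child_seeds:
        W, H, history = _mu_factorize(X, k, np.random.default_rng(ss), max_iter, tol)
        restart_errors.append(history[-1])
        if best is None or history[-1] < best[2][-1]:
            best = (W, H, history)
    W, H, history = best
    factor_ids = [f"F{i + 1}" for i in range(k)]
    return FactorModel(
        W=pd.DataFrame(W, index=er.var_names, columns=factor_ids),
        H=pd.DataFrame(H, index=factor_ids, columns=er.obs_names),
        k=k,
        reconstruction_error=history[-1],
        error_history=history,
        seed=seed,
        n_restarts=n_restarts,
        restart_errors=restart_errors,
    )


def histogram_overlap(a: np.ndarray, b: np.ndarray, bins: np.ndarray) -> float:
    """Intersection of two normalized histograms on shared bin edges."""
    ha, _ = np.histogram(a, bins=bins)
    hb, _ = np.histogram(b, bins=bins)
    if ha.sum() == 0 or hb.sum() == 0:
        return 0.0
    return float(np.minimum(ha / ha.sum(), hb / hb.sum()).sum())


def factor_patient_overlaps(
    model: FactorModel, patients: pd.Series, n_bins: int = 50
) -> dict[str, pd.DataFrame]:
    """Pairwise per-patient histogram overlaps of cell scores, per factor."""
    patients = pd.Series(np.asarray(patients), index=model.H.columns)
    groups = {p: np.flatnonzero((patients == p).to_numpy()) for p in patients.unique()}
    out = {}
    for fid in model.factor_ids:
        h = model.H.loc[fid].to_numpy()
        lo, hi = float(h.min()), float(h.max())
        if hi <= lo:
            hi = lo + 1.0  # constant factor: all mass in one bin, overlap 1
        bins = np.linspace(lo, hi, n_bins + 1)
        pats = list(groups)
        mat = np.ones((len(pats), len(pats)))
        for i, pa in enumerate(pats):
            for j in range(i + 1, len(pats)):
                ov = histogram_overlap(h[groups[pa]], h[groups[pats[j]]], bins)
                mat[i, j] = mat[j, i] = ov
        out[fid] = pd.DataFrame(mat, index=pats, columns=pats)
    return out


def filter_patient_specific_factors(
    model: FactorModel,
    patients: pd.Series,
    overlap_threshold: float = 0.5,
    min_patients: int = 5,
    n_bins: int = 50,
) -> list[str]:
    """Retained factor ids after excluding patient-specific factors.

    A patient *fails* for a factor when its median pairwise score-histogram
    overlap with the other patients is below ``overlap_threshold``; the
    factor is excluded when at least ``min_patients`` patients fail. With
    ``min_patients=1`` the rule becomes "any single dominated patient
    excludes the factor", which targets strictly patient-specific factors.
    """
    patients = pd.Series(np.asarray(patients), index=model.H.columns)
    n_pat = patients.nunique()
    if n_pat < 2:
        raise ValueError("factor filtering needs >= 2 patients")
    if n_pat < min_patients:
        warnings.warn(
            f"only {n_pat} patients < min_patients={min_patients}; rule inapplicable, "
            "all factors retained"
        )
        return list(model.factor_ids)
    overlaps = factor_patient_overlaps(model, patients, n_bins=n_bins)
    retained = []
    for fid, mat in overlaps.items():
        med = _median_offdiag(mat)
        n_fail = int((med < overlap_threshold).sum())
        if n_fail < min_patients:
            retained.append(fid)
    return retained


def _median_offdiag(mat: pd.DataFrame) -> pd.Series:
    vals = mat.to_numpy().copy()
    np.fill_diagonal(vals, np.nan)
    return pd.Series(np.nanmedian(vals, axis=1), index=mat.index)


def extract_signature(
    model: FactorModel, factor_id: str, top_n: int = 200, name: str | None = None
) -> Signature:
    """Top-loading gene list of a retained factor.

    Genes are ranked by loading descending with ties broken by gene
    identifier, so the ranking is stable under permutations of the input
    gene order. A signature whose meaningful (non-zero-loading) prefix is
    shorter than ``top_n`` is flagged degenerate.
    """
    if factor_id not in model.W.columns:
        raise KeyError(f"unknown factor {factor_id!r}")
    if top_n > model.W.shape[0]:
        raise ValueError(f"top_n={top_n} exceeds gene count {model.W.shape[0]}")
    w = model.W[factor_id]
    order = sorted(w.index, key=lambda g: (-w[g], g))
    top = order[:top_n]
    n_nonzero = int((w.loc[top] > 0).sum())
    return Signature(
        name=name or factor_id,
        genes=list(top),
        source_factor=factor_id,
        degenerate=n_nonzero < top_n,
    )


def extract_signatures(
    model: FactorModel, factor_ids: list[str] | None = None, top_n: int = 200
) -> list[Signature]:
    ids = factor_ids if factor_ids is not None else model.factor_ids
    return [extract_signature(model, fid, top_n=top_n) for fid in ids]
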