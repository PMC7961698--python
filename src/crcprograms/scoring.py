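"""Background-controlled signature scoring, meta-signatures and assignment.

A cell's raw score for a signature is its mean expression over the
signature genes. Because library complexity alone moves such means, every
signature gene is matched by control genes drawn from the same
aggregate-expression bin, and the control mean is subtracted: a signature
drawn at random from its own bins has corrected score ~0. Scores are
computed on the uncentered log expression by default; the centered matrix
can be passed instead where relative scores are wanted.

Cell-type programs are *active* in a cell when the corrected score exceeds
the across-cells mean by more than one (population) standard deviation; a
cell's assigned type is the highest-scoring active type program, or
``unassigned`` when none is active.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .factorize import Signature

UNASSIGNED = "unassigned"


@dataclass
class CellScoreTable:
    """Raw and background-corrected per-cell signature scores."""

    raw: pd.DataFrame  # cells x signatures
    corrected: pd.DataFrame  # cells x signatures

    @property
    def signatures(self) -> list[str]:
        return list(self.corrected.columns)

    def summary(self) -> pd.DataFrame:
        c = self.corrected
        return pd.DataFrame({"mean": c.mean(), "sd": c.std(ddof=0)})


@dataclass
class MetaSignature:
    """Union signature of factor signatures with similar score patterns."""

    name: str
    genes: list[str]
    members: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"meta-signature {self.name!r} is empty")


def expression_bins(e: ad.AnnData, n_bins: int = 25) -> pd.Series:
    """Equal-size aggregate-expression bins over all genes (rank bins)."""
    X = np.asarray(e.X, dtype=float)
    agg = pd.Series(X.mean(axis=0), index=e.var_names)
    ranks = agg.rank(method="first")
    bins = np.ceil(ranks / len(agg) * n_bins).astype(int).clip(1, n_bins)
    return bins


def score_cells(
    e: ad.AnnData,
    sig: Signature | MetaSignature,
    n_bins: int = 25,
    n_control_per_gene: int = 100,
    seed: int = 0,
    gene_bins: pd.Series | None = None,
) -> pd.DataFrame:
    """Raw and corrected scores of every cell for one signature.

    Control genes are sampled (deterministically from ``seed``) from the
    same aggregate-expression bin as each signature gene, without
    replacement within a bin where possible, with replacement otherwise.
    Returns a frame with ``raw`` and ``corrected`` columns indexed by cell.
    """
    present = [g for g in sig.genes if g in e.var_names]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    if len(present) < 0.5 * len(sig.genes):
        raise ValueError(
            f"only {len(present)}/{len(sig.genes)} genes of {sig.name!r} present (<50%)"
        )
    bins = gene_bins if gene_bins is not None else expression_bins(e, n_bins=n_bins)
    X = np.asarray(e.X, dtype=float)
    col = {g: i for i, g in enumerate(e.var_names)}
    raw = X[:, [col[g] for g in present]].mean(axis=1)

    rng = np.random.default_rng(seed)
    bin_members = {b: idx.to_numpy() for b, idx in bins.groupby(bins).groups.items()}
    control_cols: list[np.ndarray] = []
    for g in present:
        pool = bin_members[bins[g]]
        if len(pool) >= n_control_per_gene:
            chosen = rng.choice(pool, size=n_control_per_gene, replace=False)
        else:
            chosen = rng.choice(pool, size=n_control_per_gene, replace=True)
        control_cols.append(np.array([col[c] for c in chosen]))
    ctrl_idx = np.concatenate(control_cols)
    ctrl = X[:, ctrl_idx].mean(axis=1)

    return pd.DataFrame({"raw": raw, "corrected": raw - ctrl}, index=e.obs_names)


def score_table(
    e: ad.AnnData,
    signatures: list[Signature | MetaSignature],
    n_bins: int = 25,
    n_control_per_gene: int = 100,
    seed: int = 0,
) -> CellScoreTable:
    """Score every cell against every signature (shared bins, seeded)."""
    bins = expression_bins(e, n_bins=n_bins)
    raw, corr = {}, {}
    for i, sig in enumerate(signatures):
        df = score_cells(
            e,
            sig,
            n_bins=n_bins,
            n_control_per_gene=n_control_per_gene,
            seed=seed + i,
            gene_bins=bins,
        )
        raw[sig.name] = df["raw"]
        corr[sig.name] = df["corrected"]
    return CellScoreTable(raw=pd.DataFrame(raw), corrected=pd.DataFrame(corr))


def combine_meta_signatures(
    scores: CellScoreTable,
    signatures: list[Signature],
    r_threshold: float = 0.6,
) -> list[MetaSignature]:
    """Merge signatures with similar per-cell score patterns.

    Signatures are clustered by complete linkage on 1 - Pearson r between
    corrected score vectors and the tree is cut at ``1 - r_threshold``;
    each group becomes one meta-signature over the union gene list (ordered
    by best per-factor rank, duplicates dropped).
    """
    if len(signatures) < 2:
        return [
            MetaSignature(name=s.name, genes=list(s.genes), members=[s.name])
            for s in signatures
        ]
    by_name = {s.name: s for s in signatures}
    cols = [s.name for s in signatures]
    corr = scores.corrected[cols].corr().to_numpy()
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=1.0 - r_threshold, criterion="distance")
    metas = []
    for lab in np.unique(labels):
        members = [cols[i] for i in np.flatnonzero(labels == lab)]
        genes = _rank_union([by_name[m] for m in members])
        name = members[0] if len(members) == 1 else "+".join(members)
        metas.append(MetaSignature(name=name, genes=genes, members=members))
    return metas


def _rank_union(sigs: list[Signature]) -> list[str]:
    """Union of member gene lists ordered by the best rank across members."""
    best: dict[str, tuple[int, str]] = {}
    for s in sigs:
        for rank, g in enumerate(s.genes):
            if g not in best or rank < best[g][0]:
                best[g] = (rank, g)
    return [g for g, _ in sorted(best.items(), key=lambda kv: kv[1])]


@dataclass
class CellTypeAssignment:
    """Per-cell program activity and unique type label."""

    active: pd.DataFrame  # cells x type signatures, boolean
    assigned: pd.Series  # cells -> type name or 'unassigned'
    thresholds: pd.Series  # per-signature activity cutoffs (mean + 1 SD)


def assign_cell_types(type_scores: pd.DataFrame) -> CellTypeAssignment:
    """Assign each cell to its strongest active cell-type program.

    A program is active in a cell when the corrected score strictly exceeds
    the across-cells mean plus one population SD. A zero-SD (constant)
    score column activates no cell. Cells with several active programs take
    the argmax of the corrected score; cells with none are ``unassigned``.
    """
    mean = type_scores.mean()
    sd = type_scores.std(ddof=0)
    thresholds = mean + sd
    active = type_scores.gt(thresholds, axis=1) & (sd > 0)
    masked = type_scores.where(active, -np.inf)
    assigned = masked.idxmax(axis=1).where(active.any(axis=1), UNASSIGNED)
    assigned.name = "cell_type"
    return CellTypeAssignment(active=active, assigned=assigned, thresholds=thresholds)


def compare_states_across_types(
    assignment: CellTypeAssignment | pd.Series,
    state_scores: pd.DataFrame,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Pairwise two-tailed Mann-Whitney tests of state scores between types.

    For every state signature and every pair of assigned types the U
    statistic, two-tailed p and descriptive quartiles are reported. Groups
    with fewer than ``min_cells`` cells raise.
    """
    assigned = assignment.assigned if isinstance(assignment, CellTypeAssignment) else assignment
    types = [t for t in pd.unique(assigned) if t != UNASSIGNED]
    groups = {t: state_scores.index[assigned == t] for t in types}
    for t, idx in groups.items():
        if len(idx) < min_cells:
            raise ValueError(f"type {t!r} has {len(idx)} cells (< {min_cells})")
    rows = []
    for state in state_scores.columns:
        for ta, tb in combinations(types, 2):
            a = state_scores.loc[groups[ta], state].to_numpy()
            b = state_scores.loc[groups[tb], state].to_numpy()
            rows.append(
                {
                    "state": state,
                    "type_a": ta,
                    "type_b": tb,
                    "n_a": len(a),
                    "n_b": len(b),
                    **_mwu(a, b),
                    **_quartiles(a, "a"),
                    **_quartiles(b, "b"),
                }
            )
    return pd.DataFrame(rows)


def _mwu(a: np.ndarray, b: np.ndarray) -> dict:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return {"U": len(a) * len(b) / 2.0, "p_value": 1.0}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(res.statistic), "p_value": float(res.pvalue)}


def _quartiles(x: np.ndarray, tag: str) -> dict:
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return {f"median_{tag}": med, f"q25_{tag}": q25, f"q75_{tag}": q75}
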