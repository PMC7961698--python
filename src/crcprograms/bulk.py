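"""Bulk-cohort signature scoring, progressive clustering and survival.

Bulk samples are scored as the mean log expression of each signature's
genes. The cohort is then partitioned into six clusters by a fixed sequence
of binary splits, each a complete-linkage hierarchical clustering (cut at
two branches) on the scores of the signatures that define the split:

1. {OXPHOS_1, G1/S, G2/M, stem} separate the high branch {cl2, cl3} from
   the rest (Euclidean).
2. {hypoxia/glycolysis_1, TNFa_2} split the high branch into cl2 (low)
   and cl3 (high) (Euclidean).
3. {fatty acid, TNFa_1} split the rest into cl1 (high) vs {cl4, cl5, cl6}
   (Euclidean).
4. {stem, TA} split by correlation distance into cl6 (stem-low) vs
   {cl4, cl5}.
5. {G1/S, G2/M, OXPHOS_1} split cl4 (medium) from cl5 (low) (Euclidean).

Survival contrasts use Kaplan-Meier curves with the log-rank test, and
nested Cox proportional-hazards models compared by a likelihood-ratio
chi-square on the added cluster terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .factorize import Signature
from .scoring import MetaSignature

CLUSTER_LABELS = ("cl1", "cl2", "cl3", "cl4", "cl5", "cl6")

STEP1_SIGS = ["OXPHOS_1", "G1/S", "G2/M", "stem"]
STEP2_SIGS = ["hypoxia_glycolysis_1", "TNFa_2"]
STEP3_SIGS = ["fatty_acid", "TNFa_1"]
STEP4_SIGS = ["stem", "TA"]
STEP5_SIGS = ["G1/S", "G2/M", "OXPHOS_1"]


def score_bulk(
    expression: pd.DataFrame,
    signatures: list[Signature | MetaSignature] | dict[str, list[str]],
    min_present: float = 0.5,
) -> pd.DataFrame:
    """Per-sample mean expression of each signature's present genes.

    ``expression`` is samples x genes (log scale). A signature with fewer
    than ``min_present`` of its genes in the cohort raises; the missing-gene
    fraction per signature is recorded in ``result.attrs['missing']``.
    """
    if isinstance(signatures, dict):
        sig_items = list(signatures.items())
    else:
        sig_items = [(s.name, list(s.genes)) for s in signatures]
    scores = {}
    missing = {}
    for name, genes in sig_items:
        present = [g for g in genes if g in expression.columns]
        if not present:
            raise ValueError(f"signature {name!r} absent from cohort")
        frac_missing = 1.0 - len(present) / len(genes)
        if len(present) < min_present * len(genes):
            raise ValueError(
                f"signature {name!r}: only {len(present)}/{len(genes)} genes present"
            )
        missing[name] = frac_missing
        scores[name] = expression[present].mean(axis=1)
    out = pd.DataFrame(scores)
    out.attrs["missing"] = missing
    return out


def _cut2(scores: pd.DataFrame, features: list[str], metric: str) -> tuple[pd.Index, pd.Index]:
    """Complete-linkage two-branch cut on the given score columns."""
    if len(scores) < 2:
        raise ValueError(f"split on {features} received {len(scores)} sample(s)")
    sub = scores[features].to_numpy()
    Z = linkage(sub, method="complete", metric=metric)
    labels = fcluster(Z, t=2, criterion="maxclust")
    a = scores.index[labels == 1]
    b = scores.index[labels == 2]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"degenerate split on {features}")
    return a, b


def _order_by_mean(scores, features, a, b):
    """Return (higher, lower) branch by mean score over the features."""
    ma = scores.loc[a, features].to_numpy().mean()
    mb = scores.loc[b, features].to_numpy().mean()
    return (a, b) if ma >= mb else (b, a)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample -> cl1..cl6
    profile: pd.DataFrame  # cluster x signature mean scores


def progressive_cluster(scores: pd.DataFrame) -> ClusterAssignment:
    """Six-cluster stratification by five sequential binary splits."""
    needed = set(STEP1_SIGS + STEP2_SIGS + STEP3_SIGS + STEP4_SIGS + STEP5_SIGS)
    missing = needed - set(scores.columns)
    if missing:
        raise KeyError(f"score matrix missing signatures: {sorted(missing)}")

    labels = pd.Series(index=scores.index, dtype=object, name="cluster")

    a, b = _cut2(scores, STEP1_SIGS, "euclidean")
    high, rest = _order_by_mean(scores, STEP1_SIGS, a, b)

    a, b = _cut2(scores.loc[high], STEP2_SIGS, "euclidean")
    cl3, cl2 = _order_by_mean(scores, STEP2_SIGS, a, b)
    labels[cl2], labels[cl3] = "cl2", "cl3"

    a, b = _cut2(scores.loc[rest], STEP3_SIGS, "euclidean")
    cl1, low = _order_by_mean(scores, STEP3_SIGS, a, b)
    labels[cl1] = "cl1"

    a, b = _cut2(scores.loc[low], STEP4_SIGS, "correlation")
    stem_high, cl6 = _order_by_mean(scores, ["stem"], a, b)
    labels[cl6] = "cl6"

    a, b = _cut2(scores.loc[stem_high], STEP5_SIGS, "euclidean")
    cl4, cl5 = _order_by_mean(scores, STEP5_SIGS, a, b)
    labels[cl4], labels[cl5] = "cl4", "cl5"

    profile = scores.groupby(labels).mean()
    return ClusterAssignment(labels=labels, profile=profile)


# ---------------------------------------------------------------------------
# Survival


@dataclass
class KmLogrankResult:
    curves: dict[str, pd.DataFrame]  # group -> KM estimate with 95% CI
    statistic: float
    p_value: float
    df: int


def km_logrank(
    groups: pd.Series,
    survival: pd.DataFrame,
    group_map: dict[str, str] | None = None,
) -> KmLogrankResult:
    """Kaplan-Meier curves and log-rank test between groups.

    ``group_map`` merges labels before testing (e.g. ``{"cl4": "poor",
    "cl5": "poor", ...}``) to reproduce merged-cluster contrasts.
    """
    if group_map:
        groups = groups.map(lambda g: group_map.get(g, g))
    common = groups.index.intersection(survival.index)
    groups = groups.loc[common]
    surv = survival.loc[common]
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if surv["event"].sum() < 1:
        raise ValueError("log-rank needs >= 1 event")
    curves = {}
    for g in uniq:
        idx = groups.index[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[idx, "time"], surv.loc[idx, "event"], label=str(g))
        curves[str(g)] = pd.concat([kmf.survival_function_, kmf.confidence_interval_], axis=1)
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return KmLogrankResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(uniq) - 1,
    )


@dataclass
class CoxComparison:
    statistic: float
    df: int
    p_value: float
    ll_base: float
    ll_full: float
    dropped_covariates: list[str]


def cox_model_comparison(
    survival: pd.DataFrame,
    base_covariates: pd.DataFrame | None,
    clusters: pd.Series,
) -> CoxComparison:
    """Likelihood-ratio comparison of Cox models with vs without clusters.

    The base model holds the provided covariates (constant columns are
    dropped with a warning); the full model adds cluster indicator terms.
    The statistic is twice the partial-log-likelihood difference on a
    chi-square with df = number of added cluster terms. Non-convergence is
    raised, not ignored.
    """
    clusters = clusters.astype(str)
    dummies = pd.get_dummies(clusters, prefix="cluster", drop_first=True).astype(float)
    base = pd.DataFrame(index=survival.index) if base_covariates is None else base_covariates.copy()
    dropped = [c for c in base.columns if base[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}")
        base = base.drop(columns=dropped)

    full = _cox_fit(survival, pd.concat([base, dummies], axis=1))
    ll_full = float(full.log_likelihood_)
    if base.shape[1] == 0:
        # Base model is the null model; lifelines' own LR test provides the
        # null partial likelihood consistently with its tie handling.
        lr = full.log_likelihood_ratio_test()
        ll_base = ll_full - float(lr.test_statistic) / 2.0
    else:
        ll_base = float(_cox_fit(survival, base).log_likelihood_)
    stat = max(0.0, 2.0 * (ll_full - ll_base))
    df = dummies.shape[1]
    return CoxComparison(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        ll_base=ll_base,
        ll_full=ll_full,
        dropped_covariates=dropped,
    )


def _cox_fit(survival: pd.DataFrame, covariates: pd.DataFrame) -> CoxPHFitter:
    df = pd.concat([survival[["time", "event"]], covariates], axis=1)
    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    return cph
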