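"""Limiting-dilution frequency estimation under the single-hit Poisson model.

A well (or mouse) seeded with ``d`` cells is negative with probability
``exp(-f * d)`` where ``f`` is the frequency of active cells
(spheroid-forming or tumor-initiating). The log-likelihood over dose rows
``(d, n, r)`` (dose, tested, positive) is

    l(f) = sum_d [ r_d * log(1 - exp(-f d)) - (n_d - r_d) * f * d ].

``estimate_frequency`` maximizes l on the log-f scale and inverts the
likelihood-ratio statistic against chi-square(1) for 95% confidence limits,
which remains well-behaved at the small well counts typical of these
assays. A Wald interval on log f is available for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

_CHI2_95 = stats.chi2.ppf(0.95, df=1)  # 3.841...
_F_MIN = 1e-12


@dataclass
class DilutionAssay:
    """Dose/response table of a limiting-dilution experiment."""

    table: pd.DataFrame  # columns: dose, tested, positive
    condition: str = ""

    def __post_init__(self) -> None:
        t = self.table
        for col in ("dose", "tested", "positive"):
            if col not in t.columns:
                raise ValueError(f"assay table missing column {col!r}")
        if len(t) == 0:
            raise ValueError("assay table is empty")
        if (t["dose"] <= 0).any():
            raise ValueError("doses must be positive")
        if ((t["positive"] < 0) | (t["positive"] > t["tested"])).any():
            raise ValueError("need 0 <= positive <= tested in every row")

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str = "") -> "DilutionAssay":
        df = pd.read_csv(path, sep="\t")
        cond = condition or (str(df["condition"].iloc[0]) if "condition" in df else "")
        return cls(table=df[["dose", "tested", "positive"]].copy(), condition=cond)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["condition"] = self.condition
        out.to_csv(path, sep="\t", index=False)


@dataclass
class FrequencyEstimate:
    """Maximum-likelihood frequency with 95% confidence limits.

    ``boundary`` is ``None`` for interior optima, ``"all_negative"`` (f_hat
    pinned at 0, one-sided upper limit) or ``"all_positive"`` (f_hat pinned
    at the upper edge, one-sided lower limit).
    """

    f_hat: float
    ci_low: float
    ci_high: float
    loglik: float
    boundary: str | None = None
    condition: str = ""

    @property
    def one_in(self) -> float:
        """Frequency displayed the conventional way, as 1/N cells."""
        return np.inf if self.f_hat == 0 else 1.0 / self.f_hat


def loglik(f: float, dose: np.ndarray, tested: np.ndarray, positive: np.ndarray) -> float:
    """Single-hit Poisson log-likelihood at frequency ``f``."""
    f = float(f)
    if f < 0:
        return -np.inf
    if f == 0:
        return -np.inf if positive.sum() > 0 else 0.0
    fd = f * dose
    with np.errstate(divide="ignore"):
        log_p_pos = np.log(-np.expm1(-fd))
    ll = positive * log_p_pos - (tested - positive) * fd
    return float(ll.sum())


def estimate_frequency(assay: DilutionAssay) -> FrequencyEstimate:
    """MLE of the active-cell frequency with likelihood-ratio 95% CI."""
    t = assay.table
    dose = t["dose"].to_numpy(dtype=float)
    tested = t["tested"].to_numpy(dtype=float)
    positive = t["positive"].to_numpy(dtype=float)
    nd_sum = float((tested * dose).sum())

    if positive.sum() == 0:
        # l(f) = -f * sum(n d); maximum at f = 0. Upper limit from
        # 2*(l(0) - l(f)) = chi2 => f_up = chi2 / (2 * sum(n d)).
        upper = min(1.0, _CHI2_95 / (2.0 * nd_sum))
        return FrequencyEstimate(0.0, 0.0, upper, 0.0, "all_negative", assay.condition)

    if (positive == tested).all():
        # Likelihood increases without bound in f; pin at the upper edge.
        ll_sup = 0.0
        lo = _invert_lr(dose, tested, positive, ll_sup, 1.0, side="lower")
        return FrequencyEstimate(1.0, lo, 1.0, ll_sup, "all_positive", assay.condition)

    res = optimize.minimize_scalar(
        lambda t_: -loglik(np.exp(t_), dose, tested, positive),
        bounds=(np.log(_F_MIN), 0.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    f_hat = float(np.exp(res.x))
    ll_max = -float(res.fun)
    lo = _invert_lr(dose, tested, positive, ll_max, f_hat, side="lower")
    hi = _invert_lr(dose, tested, positive, ll_max, f_hat, side="upper")
    return FrequencyEstimate(f_hat, lo, hi, ll_max, None, assay.condition)


def _invert_lr(dose, tested, positive, ll_max, f_hat, side):
    """Root of 2*(ll_max - l(f)) = chi2(1, 0.95) on one side of f_hat."""

    def g(f: float) -> float:
        return 2.0 * (ll_max - loglik(f, dose, tested, positive)) - _CHI2_95

    if side == "lower":
        lo_bracket = _F_MIN
        if g(lo_bracket) <= 0:
            return 0.0
        return float(optimize.brentq(g, lo_bracket, f_hat, xtol=1e-15, rtol=1e-12))
    hi_bracket = 1.0
    if g(hi_bracket) <= 0:
        return 1.0
    return float(optimize.brentq(g, f_hat, hi_bracket, xtol=1e-15, rtol=1e-12))


def wald_interval(assay: DilutionAssay) -> tuple[float, float]:
    """Wald 95% interval on log f, for cross-checking the LR interval."""
    est = estimate_frequency(assay)
    if est.boundary is not None:
        raise ValueError("Wald interval undefined at a boundary estimate")
    t = assay.table
    dose = t["dose"].to_numpy(dtype=float)
    tested = t["tested"].to_numpy(dtype=float)
    f = est.f_hat
    # Fisher information for log f under the complementary log-log model.
    p = -np.expm1(-f * dose)
    info = float((tested * (f * dose) ** 2 * np.exp(-f * dose) ** 2 / (p * (1 - p))).sum())
    se = 1.0 / np.sqrt(info)
    z = stats.norm.ppf(0.975)
    return float(f * np.exp(-z * se)), float(f * np.exp(z * se))


@dataclass
class FrequencyComparison:
    estimate_a: FrequencyEstimate
    estimate_b: FrequencyEstimate
    statistic: float
    p_value: float

    @property
    def ratio(self) -> float:
        return self.estimate_a.f_hat / self.estimate_b.f_hat


def compare_frequencies(a: DilutionAssay, b: DilutionAssay) -> FrequencyComparison:
    """Likelihood-ratio test of equal frequency between two assays."""
    if a.table["positive"].sum() == 0 and b.table["positive"].sum() == 0:
        raise ValueError("both assays are all-negative; frequencies not comparable")
    est_a = estimate_frequency(a)
    est_b = estimate_frequency(b)
    pooled_table = (
        pd.concat([a.table, b.table], ignore_index=True)
        .sort_values(["dose", "tested", "positive"], kind="stable")
        .reset_index(drop=True)
    )  # canonical row order keeps the test symmetric in its arguments
    pooled = DilutionAssay(table=pooled_table, condition="pooled")
    est_p = estimate_frequency(pooled)
    stat = max(0.0, 2.0 * (est_a.loglik + est_b.loglik - est_p.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    return FrequencyComparison(est_a, est_b, stat, p)


def normalize_to_bulk(
    estimates: list[FrequencyEstimate], bulk: FrequencyEstimate
) -> pd.DataFrame:
    """Frequencies relative to a bulk estimate, CI by log-scale propagation."""
    if bulk.f_hat <= 0:
        raise ValueError("bulk frequency must be positive")
    z = stats.norm.ppf(0.975)
    se_b = _log_se(bulk, z)
    rows = []
    for est in estimates:
        if est.f_hat <= 0:
            rows.append((est.condition, 0.0, 0.0, np.nan))
            continue
        ratio = est.f_hat / bulk.f_hat
        se = np.sqrt(_log_se(est, z) ** 2 + se_b**2)
        rows.append((est.condition, ratio, ratio * np.exp(-z * se), ratio * np.exp(z * se)))
    return pd.DataFrame(rows, columns=["condition", "ratio", "ci_low", "ci_high"])


def _log_se(est: FrequencyEstimate, z: float) -> float:
    if est.ci_low <= 0 or est.ci_high <= 0:
        warnings.warn("boundary CI in ratio propagation; treating spread as one-sided")
        return float(np.log(est.ci_high / est.f_hat) / z)
    return float(np.log(est.ci_high / est.ci_low) / (2 * z))


def estimates_table(estimates: list[FrequencyEstimate]) -> pd.DataFrame:
    """Tidy table of estimates formatted both as f and as 1/N."""
    return pd.DataFrame(
        [
            {
                "condition": e.condition,
                "frequency": e.f_hat,
                "one_in": e.one_in,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "boundary": e.boundary or "",
            }
            for e in estimates
        ]
    )
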