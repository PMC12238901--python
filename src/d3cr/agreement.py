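"""Method-comparison machinery: Pearson correlation, Bland-Altman, group tests.

Agreement between an estimator and the MRI reference is summarised the
standard Bland-Altman way: per-participant differences d = estimate -
reference (positive bias = overestimation), bias = mean(d), limits of
agreement bias +/- 1.96 SD(d).  Confidence intervals use the t distribution
for the bias (SE = SD/sqrt(n)) and, for each limit of agreement, the
large-sample SE = SD * sqrt(3/n) with either a t ("t", default) or normal
("z") multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import METHODS

__all__ = [
    "AgreementResult",
    "CorrelationSummary",
    "pearson",
    "bland_altman",
    "compare_algorithms",
    "compare_groups",
]


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary (units of the compared series, here litres)."""

    bias: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    sd: float
    n: int
    loa_ci_method: str = "t"

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class CorrelationSummary:
    """One estimator's correlations against the reference standards."""

    method: str
    r_vs_mri: float | None
    p_vs_mri: float | None
    r_vs_handgrip: float | None
    p_vs_handgrip: float | None
    n: int


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value.

    Finite pairs only; requires n >= 3 and non-degenerate variance in both
    series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("Pearson correlation needs >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(
    estimate,
    reference,
    ci_level: float = 0.95,
    loa_multiplier: float = 1.96,
    loa_ci_method: str = "t",
) -> AgreementResult:
    """Bland-Altman agreement of ``estimate`` against ``reference``.

    Parameters
    ----------
    estimate, reference
        Paired series in the same units (length >= 3).
    ci_level
        Confidence level of the intervals around bias and limits.
    loa_multiplier
        SD multiplier for the limits of agreement (1.96 by convention).
    loa_ci_method
        't' (default) or 'z' multiplier applied to the limit-of-agreement
        SE = SD*sqrt(3/n).
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("paired series must have equal length")
    keep = np.isfinite(est) & np.isfinite(ref)
    d = est[keep] - ref[keep]
    n = d.size
    if n < 3:
        raise ValueError("Bland-Altman needs >= 3 pairs for confidence intervals")
    if loa_ci_method not in ("t", "z"):
        raise ValueError("loa_ci_method must be 't' or 'z'")

    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - loa_multiplier * sd
    loa_high = bias + loa_multiplier * sd

    alpha = 1.0 - ci_level
    tq = stats.t.ppf(1 - alpha / 2, df=n - 1)
    zq = stats.norm.ppf(1 - alpha / 2)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    q_loa = tq if loa_ci_method == "t" else zq

    return AgreementResult(
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - tq * se_bias, bias + tq * se_bias),
        ci_loa_low=(loa_low - q_loa * se_loa, loa_low + q_loa * se_loa),
        ci_loa_high=(loa_high - q_loa * se_loa, loa_high + q_loa * se_loa),
        sd=sd,
        n=n,
        loa_ci_method=loa_ci_method,
    )


def compare_algorithms(
    estimates: pd.DataFrame,
    cohort: pd.DataFrame,
    reference: str = "mri_volume_l",
    handgrip: str = "handgrip_kg",
    ci_level: float = 0.95,
) -> tuple[list[CorrelationSummary], dict[str, AgreementResult]]:
    """Correlate every estimator with the MRI reference (and handgrip).

    ``estimates`` is the long table from
    :func:`~d3cr.estimators.estimate_cohort`; ``cohort`` supplies the
    reference columns keyed by participant_id.  Bland-Altman results are
    produced only for estimators measured in the reference's units (the
    volume methods); mass methods (kg) are correlated but not compared in
    absolute terms against a volume in litres.

    Returns summaries sorted by descending r vs MRI, plus the per-method
    agreement results.
    """
    wide = estimates.pivot(index="participant_id", columns="method", values="value")
    merged = wide.join(
        cohort.set_index("participant_id")[
            [c for c in (reference, handgrip) if c in cohort.columns]
        ]
    )
    if reference not in merged.columns or merged[reference].notna().sum() == 0:
        raise ValueError(f"no reference values in column {reference!r}")

    summaries: list[CorrelationSummary] = []
    agreements: dict[str, AgreementResult] = {}
    for method, unit in METHODS.items():
        if method not in merged.columns:
            continue
        pair = merged[[method, reference]].dropna()
        r, p = pearson(pair[method], pair[reference])
        r_hg = p_hg = None
        if handgrip in merged.columns and merged[handgrip].notna().sum() >= 3:
            hg = merged[[method, handgrip]].dropna()
            r_hg, p_hg = pearson(hg[method], hg[handgrip])
        summaries.append(
            CorrelationSummary(
                method=method, r_vs_mri=r, p_vs_mri=p,
                r_vs_handgrip=r_hg, p_vs_handgrip=p_hg, n=len(pair),
            )
        )
        if unit == "L":  # reference is a volume; kg methods are unit-mismatched
            agreements[method] = bland_altman(
                pair[method], pair[reference], ci_level=ci_level
            )
    summaries.sort(key=lambda s: s.r_vs_mri, reverse=True)
    return summaries, agreements


def compare_groups(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Descriptive train-vs-validation comparison table.

    Continuous variables: independent-samples t-test (pooled variance by
    default; ``equal_var=False`` for Welch).  Categorical variables:
    Pearson chi-square on the contingency table, without continuity
    correction.  All p-values two-sided.
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for var in continuous or []:
        a = train[var].dropna().astype(float)
        b = validation[var].dropna().astype(float)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"variable": var, "test": "t", "statistic": float(t), "p": float(p)})
    for var in categorical or []:
        groups = np.repeat(["train", "validation"], [len(train), len(validation)])
        values = pd.concat([train[var], validation[var]], ignore_index=True)
        table = pd.crosstab(groups, values)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {"variable": var, "test": "chi2", "statistic": float(chi2), "p": float(p)}
        )
    return pd.DataFrame(rows)
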