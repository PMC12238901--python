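"""Model development: cohort splitting, OLS, VIF screening, stepwise selection.

The calibration pipeline regresses MRI fat-free thigh + erector-spinae
volume on creatine pool size and anthropometrics in a training split,
screens candidate predictors by stepwise p-value selection with a variance
inflation factor (VIF) check, and emits the fitted coefficient set as
:class:`~d3cr.config.AlgorithmCoefficients` for the estimators.

Ethnicity is expanded to indicator terms with Chinese as the reference
level.  All p-values are two-sided.  OLS fits go through statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AlgorithmCoefficients

__all__ = [
    "SplitSpec",
    "FittedModel",
    "split_cohort",
    "design_matrix",
    "fit_ols",
    "vif",
    "stepwise_select",
    "calibrate",
    "ETHNICITIES",
    "ETHNICITY_REFERENCE",
]

log = logging.getLogger(__name__)

ETHNICITIES = ("Chinese", "Malay", "Indian", "Other")
ETHNICITY_REFERENCE = "Chinese"

#: Candidate predictor sets for the two calibration modes.
MODE_PREDICTORS = {
    "d3cr_ht_wt": ["pool_g", "weight_kg", "height_m"],
    "mv_ht_wt": ["weight_kg", "height_m"],
}


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split parameters.

    ``method='exact'`` draws a fixed-size random partition with
    round(n * train_fraction) training records.  ``method='bernoulli'``
    assigns each record independently with probability ``train_fraction``
    (the behaviour of classic menu-driven statistics packages' "select
    approximately p% of cases"), so realised sizes fluctuate around n*f.
    """

    train_fraction: float = 0.8
    seed: int = 0
    method: str = "exact"

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.method not in ("exact", "bernoulli"):
            raise ValueError("method must be 'exact' or 'bernoulli'")


def split_cohort(
    cohort: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly partition a cohort into (train, validation).

    The partition is disjoint and exhaustive, and reproducible for a fixed
    :class:`SplitSpec`.
    """
    n = len(cohort)
    if n < 10:
        raise ValueError("cohort too small to split (need >= 10 records)")
    rng = np.random.default_rng(spec.seed)
    if spec.method == "exact":
        n_train = int(round(n * spec.train_fraction))
        if n_train in (0, n):
            raise ValueError("degenerate split: one side would be empty")
        idx = rng.permutation(n)
        train_idx, val_idx = idx[:n_train], idx[n_train:]
    else:
        mask = rng.random(n) < spec.train_fraction
        if mask.all() or not mask.any():
            raise ValueError("degenerate Bernoulli split; re-seed or use exact")
        train_idx = np.flatnonzero(mask)
        val_idx = np.flatnonzero(~mask)
    return cohort.iloc[train_idx].copy(), cohort.iloc[val_idx].copy()


def design_matrix(records: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Build the numeric design matrix, expanding 'ethnicity' to indicators.

    The reference level (Chinese) is dropped; indicator columns are named
    ``ethnicity_Malay`` etc.  Other predictors pass through unchanged.
    """
    cols = []
    for term in predictors:
        if term == "ethnicity":
            cats = pd.Categorical(records["ethnicity"], categories=ETHNICITIES)
            if cats.isna().any():
                bad = set(records["ethnicity"]) - set(ETHNICITIES)
                raise ValueError(f"unknown ethnicity labels: {sorted(bad)}")
            dummies = pd.get_dummies(cats, prefix="ethnicity", dtype=float)
            dummies.index = records.index
            cols.append(dummies.drop(columns=f"ethnicity_{ETHNICITY_REFERENCE}"))
        else:
            cols.append(records[[term]].astype(float))
    X = pd.concat(cols, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in predictor columns: {bad}")
    return X


@dataclass(frozen=True)
class FittedModel:
    """An OLS fit: per-term slopes with p-values, intercept, fit statistics."""

    terms: tuple[tuple[str, float, float], ...]  # (name, beta, p)
    intercept: float
    intercept_p: float
    adj_r2: float
    r2: float
    n: int
    vif: dict[str, float] = field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        d = {name: beta for name, beta, _ in self.terms}
        d["intercept"] = self.intercept
        return d

    def p_value(self, term: str) -> float:
        for name, _, p in self.terms:
            if name == term:
                return p
        raise KeyError(term)


def fit_ols(
    records: pd.DataFrame, predictors: list[str], response: str
) -> FittedModel:
    """Ordinary least squares of ``response`` on ``predictors``.

    Categorical ethnicity is expanded with Chinese as reference.  Raises on
    rank-deficient designs, naming the collinear columns.
    """
    X = design_matrix(records, predictors)
    y = records[response].astype(float)
    if y.isna().any():
        raise ValueError(f"missing values in response column {response!r}")
    k = X.shape[1]
    if len(records) <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {Xc.shape[1]}): "
            f"collinear terms among {list(X.columns)}"
        )
    res = sm.OLS(y, Xc).fit()
    terms = tuple(
        (name, float(res.params[name]), float(res.pvalues[name]))
        for name in X.columns
    )
    vifs = vif(records, predictors) if k >= 2 else {}
    return FittedModel(
        terms=terms,
        intercept=float(res.params["const"]),
        intercept_p=float(res.pvalues["const"]),
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        n=int(res.nobs),
        vif=vifs,
    )


def vif(records: pd.DataFrame, predictors: list[str]) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from the auxiliary OLS of predictor j on the remaining
    predictors (with intercept).  Values above ~3 signal collinearity for
    this calibration's screening rule.
    """
    X = design_matrix(records, predictors)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out: dict[str, float] = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def stepwise_select(
    records: pd.DataFrame,
    candidates: list[str],
    response: str,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_iter: int = 100,
    audit: list[str] | None = None,
) -> FittedModel:
    """Bidirectional stepwise OLS selection by p-value thresholds.

    Repeatedly adds the candidate with the smallest p-value below
    ``entry_p`` (tested in the current model), then removes any included
    term whose p-value rises to ``removal_p`` or above, until stable.
    ``candidates`` may include 'ethnicity', which enters or leaves as a
    block (smallest indicator p decides entry; the block is removed when
    *all* its indicators exceed the removal threshold).

    An empty final model returns an intercept-only :class:`FittedModel`.
    """
    if audit is None:
        audit = []
    included: list[str] = []
    for it in range(max_iter):
        changed = False
        # --- entry step
        best_term, best_p = None, entry_p
        for cand in candidates:
            if cand in included:
                continue
            trial = fit_ols(records, included + [cand], response)
            names = (
                [t[0] for t in trial.terms if t[0].startswith("ethnicity_")]
                if cand == "ethnicity"
                else [cand]
            )
            p = min(trial.p_value(nm) for nm in names)
            if p < best_p:
                best_term, best_p = cand, p
        if best_term is not None:
            included.append(best_term)
            audit.append(f"step {it}: enter {best_term} (p={best_p:.4g})")
            changed = True
        # --- removal step
        if included:
            model = fit_ols(records, included, response)
            worst_term, worst_p = None, removal_p
            for term in included:
                names = (
                    [t[0] for t in model.terms if t[0].startswith("ethnicity_")]
                    if term == "ethnicity"
                    else [term]
                )
                p = min(model.p_value(nm) for nm in names)  # block leaves only
                if p >= worst_p:                            # if its best p is bad
                    worst_term, worst_p = term, p
            if worst_term is not None:
                included.remove(worst_term)
                audit.append(f"step {it}: remove {worst_term} (p={worst_p:.4g})")
                changed = True
        if not changed:
            audit.append(f"step {it}: stable with {included}")
            break
    else:
        raise RuntimeError(
            f"stepwise selection did not stabilise in {max_iter} iterations; "
            f"last model: {included}"
        )
    if not included:
        y = records[response].astype(float)
        return FittedModel(
            terms=(),
            intercept=float(y.mean()),
            intercept_p=0.0,
            adj_r2=0.0,
            r2=0.0,
            n=len(y),
        )
    return fit_ols(records, included, response)


def calibrate(
    records: pd.DataFrame,
    mode: str = "d3cr_ht_wt",
    response: str = "mri_volume_l",
) -> tuple[AlgorithmCoefficients, FittedModel]:
    """Fit a mode's coefficient set on training records with MRI reference.

    Records missing the response are dropped (complete-case) with a logged
    count.  Returns the coefficients in estimator form plus the full fit.
    """
    if mode not in MODE_PREDICTORS:
        raise ValueError(f"mode must be one of {sorted(MODE_PREDICTORS)}")
    usable = records.dropna(subset=[response])
    dropped = len(records) - len(usable)
    if dropped:
        log.info("calibrate: dropped %d records without %s", dropped, response)
    model = fit_ols(usable, MODE_PREDICTORS[mode], response)
    p = model.params
    coef = AlgorithmCoefficients(
        beta_pool=p.get("pool_g", 0.0),
        beta_weight=p["weight_kg"],
        beta_height=p["height_m"],
        intercept=p["intercept"],
    )
    return coef, model
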