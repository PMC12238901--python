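"""Synthetic cohort generator.

Emulates the statistical structure the calibration and agreement layers
assume, so the whole pipeline is exercisable without any real data:

* anthropometrics from a correlated bivariate normal (height 1.56 +/- 0.06 m,
  weight 59.5 +/- 10.8 kg, correlation 0.4), age 62.6 +/- 5.9 y, ethnicity
  drawn from the cohort's observed proportions;
* a true creatine pool size ~ N(75, 12) g truncated above 20 g (the pool
  distribution is an assumption back-derived from the published mean muscle
  mass, not an observed marginal);
* a true MRI fat-free thigh + erector-spinae volume generated from the
  pool/weight/height linear model plus Gaussian noise whose SD is solved so
  the population R^2 matches a target (0.576 by default);
* self-consistent urinary chemistry: enrichment ratio = dose / pool, so the
  dilution identity pool = dose/er holds exactly; creatinine is log-normal
  and D3-creatinine follows from the enrichment identity; the urinary
  Cr/Crn ratio is a two-component log-normal mixture whose rare heavy
  component pushes some ratios past the point where the original spillage
  correction exceeds the ingested dose.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AlgorithmCoefficients, COEF_D3CR_HT_WT, DoseSpec
from .estimators import negative_mass_ratio_threshold

__all__ = ["CohortParams", "solve_noise_sd", "generate_cohort", "make_stepwise_cohort"]

COHORT_COLUMNS = [
    "participant_id",
    "crn_ngml",
    "d3crn_ngml",
    "cr_ngml",
    "height_m",
    "weight_kg",
    "age_y",
    "ethnicity",
    "mri_volume_l",
    "handgrip_kg",
]


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; defaults mirror the calibration cohort."""

    n: int = 451
    seed: int = 0
    height_mean_sd: tuple[float, float] = (1.56, 0.06)
    weight_mean_sd: tuple[float, float] = (59.5, 10.8)
    height_weight_corr: float = 0.4
    age_mean_sd: tuple[float, float] = (62.6, 5.9)
    ethnicity_probs: dict = field(
        default_factory=lambda: {
            "Chinese": 0.816, "Malay": 0.060, "Indian": 0.082, "Other": 0.042
        }
    )
    pool_mean_sd: tuple[float, float] = (75.0, 12.0)
    pool_floor_g: float = 20.0
    generating_coefficients: AlgorithmCoefficients = COEF_D3CR_HT_WT
    target_adj_r2: float = 0.576
    cr_crn_logmean_logsd: tuple[float, float] = (float(np.log(0.05)), 1.0)
    heavy_tail_prob: float = 0.01
    heavy_tail_logmean_logsd: tuple[float, float] = (float(np.log(0.8)), 0.5)
    crn_logmean_logsd: tuple[float, float] = (float(np.log(1.0e6)), 0.6)
    handgrip_mean_sd: tuple[float, float] = (22.0, 5.0)
    handgrip_mri_corr: float = 0.5
    dose: DoseSpec = field(default_factory=DoseSpec)

    def __post_init__(self) -> None:
        if abs(sum(self.ethnicity_probs.values()) - 1.0) > 1e-9:
            raise ValueError("ethnicity probabilities must sum to 1")
        if not (0 < self.target_adj_r2 < 1):
            raise ValueError("target_adj_r2 must lie in (0, 1)")
        for name in ("height_mean_sd", "weight_mean_sd", "age_mean_sd",
                     "pool_mean_sd"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} SD must be positive")


def signal_variance(params: CohortParams) -> float:
    """Population variance of the noiseless generated MRI volume."""
    c = params.generating_coefficients
    sh = params.height_mean_sd[1]
    sw = params.weight_mean_sd[1]
    sp = params.pool_mean_sd[1]
    cov_wh = params.height_weight_corr * sw * sh
    return (
        c.beta_pool**2 * sp**2
        + c.beta_weight**2 * sw**2
        + c.beta_height**2 * sh**2
        + 2.0 * c.beta_weight * c.beta_height * cov_wh
    )


def solve_noise_sd(params: CohortParams) -> float:
    """Noise SD (L) giving the target population R^2.

    Solves Var(signal) / (Var(signal) + sd^2) = target, i.e.
    sd = sqrt(Var(signal) * (1 - target) / target); monotone decreasing in
    the target, -> 0 as target -> 1.
    """
    var_sig = signal_variance(params)
    if var_sig <= 0:
        raise ValueError("zero predictor variance: target R^2 infeasible")
    t = params.target_adj_r2
    return float(np.sqrt(var_sig * (1.0 - t) / t))


def _draw_truncated(rng, mean, sd, size, lower):
    """Normal draws with sub-``lower`` values redrawn (not clipped)."""
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= lower
    return out


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort plus its ground-truth table.

    Returns
    -------
    cohort : DataFrame
        One row per participant with the analysis-facing columns
        (:data:`COHORT_COLUMNS`).
    truth : DataFrame
        The generating quantities per participant: true pool size,
        enrichment ratio, MRI noise draw, Cr/Crn ratio with its mixture
        component and spillage tier, and whether the ratio exceeds the
        negative-mass threshold of the original algorithm.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    if n < 1:
        raise ValueError("n must be >= 1")

    (mh, sh), (mw, sw) = params.height_mean_sd, params.weight_mean_sd
    cov = params.height_weight_corr * sh * sw
    hw = rng.multivariate_normal([mh, mw], [[sh**2, cov], [cov, sw**2]], size=n)
    # redraw physically implausible anthropometrics (rare at the defaults)
    bad = (hw[:, 0] <= 1.2) | (hw[:, 1] <= 30.0)
    while bad.any():
        hw[bad] = rng.multivariate_normal(
            [mh, mw], [[sh**2, cov], [cov, sw**2]], size=int(bad.sum())
        )
        bad = (hw[:, 0] <= 1.2) | (hw[:, 1] <= 30.0)
    height, weight = hw[:, 0], hw[:, 1]

    age = rng.normal(*params.age_mean_sd, n)
    labels = list(params.ethnicity_probs)
    ethnicity = rng.choice(labels, size=n, p=[params.ethnicity_probs[k] for k in labels])

    pool = _draw_truncated(rng, *params.pool_mean_sd, n, params.pool_floor_g)

    noise_sd = solve_noise_sd(params)
    noise = rng.normal(0.0, noise_sd, n)
    coef = params.generating_coefficients
    mri = coef.beta_pool * pool + coef.beta_weight * weight \
        + coef.beta_height * height + coef.intercept + noise

    # urinary chemistry, self-consistent with the dilution identity
    er = params.dose.dose_g / pool
    crn = rng.lognormal(*params.crn_logmean_logsd, n)
    d3crn = crn * er / (1.0 - er)
    heavy = rng.random(n) < params.heavy_tail_prob
    ratio = np.where(
        heavy,
        rng.lognormal(*params.heavy_tail_logmean_logsd, n),
        rng.lognormal(*params.cr_crn_logmean_logsd, n),
    )
    cr = ratio * crn

    # handgrip correlated with the realised MRI volume
    mri_sd = float(np.sqrt(signal_variance(params) + noise_sd**2))
    hg_m, hg_s = params.handgrip_mean_sd
    rho = params.handgrip_mri_corr
    hg_noise_sd = hg_s * np.sqrt(max(1.0 - rho**2, 0.0))
    mri_mean = coef.beta_pool * params.pool_mean_sd[0] \
        + coef.beta_weight * mw + coef.beta_height * mh + coef.intercept
    handgrip = hg_m + rho * hg_s * (mri - mri_mean) / mri_sd \
        + rng.normal(0.0, hg_noise_sd, n)

    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "crn_ngml": crn,
            "d3crn_ngml": d3crn,
            "cr_ngml": cr,
            "height_m": height,
            "weight_kg": weight,
            "age_y": age,
            "ethnicity": ethnicity,
            "mri_volume_l": mri,
            "handgrip_kg": handgrip,
        }
    )

    threshold = negative_mass_ratio_threshold(dose=params.dose)
    tier = np.where(ratio < 0.015, 1, np.where(ratio <= 0.15, 2, 3))
    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "pool_g": pool,
            "enrichment_ratio": er,
            "mri_noise_l": noise,
            "cr_crn_ratio": ratio,
            "heavy_tail": heavy,
            "ratio_tier": tier,
            "exceeds_negative_mass_threshold": ratio > threshold,
        }
    )
    return cohort, truth


def make_stepwise_cohort(
    n: int = 367,
    seed: int = 0,
    target_p: dict[str, float] | None = None,
    params: CohortParams | None = None,
) -> pd.DataFrame:
    """A cohort whose realised age/ethnicity p-values hit chosen targets.

    The base cohort has true pool/weight/height effects only.  Because OLS
    is linear in the response, adding ``X @ delta`` to the response shifts
    each coefficient estimate by exactly ``delta`` while leaving residuals
    and standard errors unchanged; the deltas are solved so that the
    realised partial t statistics of age and the ethnicity indicators in
    the full model equal chosen targets (defaults: age p = 0.076 with a
    negative slope, Indian p = 0.317, Malay p = 0.942).

    This makes stepwise-selection behaviour on the fixture deterministic: a
    borderline-insignificant age effect is borderline by construction, not
    by the luck of one noise draw.
    """
    import statsmodels.api as sm
    from scipy import stats as _st

    from .calibration import design_matrix  # local import avoids a cycle

    if target_p is None:
        target_p = {"age_y": 0.076, "ethnicity_Indian": 0.317,
                    "ethnicity_Malay": 0.942}
    signs = {"age_y": -1.0, "ethnicity_Indian": 1.0, "ethnicity_Malay": -1.0}

    base = params if params is not None else CohortParams(n=n, seed=seed)
    cohort, truth = generate_cohort(base)
    cohort = cohort.merge(truth[["participant_id", "pool_g"]], on="participant_id")

    predictors = ["pool_g", "age_y", "ethnicity", "height_m", "weight_kg"]
    X = design_matrix(cohort, predictors)
    Xc = sm.add_constant(X, has_constant="add")
    y = cohort["mri_volume_l"].to_numpy(dtype=float)
    res = sm.OLS(y, Xc).fit()
    dof = int(res.df_resid)
    for term, p_target in target_p.items():
        se = float(res.bse[term])
        t_target = signs.get(term, 1.0) * _st.t.ppf(1 - p_target / 2, dof)
        delta = t_target * se - float(res.params[term])
        y = y + delta * X[term].to_numpy(dtype=float)
    out = cohort.copy()
    out["mri_volume_l"] = y
    return out
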