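"""Versioned configuration for the D3Cr dilution pipeline.

Every physical and statistical constant used by the estimators lives here, in
a named :class:`ConfigProfile`, so that the method can be recalibrated for a
new population without touching code.  The default profile, ``iwhp2025``,
carries the constants of the published calibration in midlife Singaporean
women: the 30 mg oral D3-creatine dose, the M+2/M+0 creatinine response
ratio, both spillage-correction parameterisations, and the fitted
muscle-volume coefficient sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "DoseSpec",
    "CorrectionFactor",
    "SpillageTier",
    "SpillageModel",
    "AlgorithmCoefficients",
    "ConfigProfile",
    "DEFAULT_PROFILE",
    "get_profile",
    "load_profile",
    "save_profile",
]


@dataclass(frozen=True)
class DoseSpec:
    """Tracer dose and the physiological conversion constants.

    Attributes
    ----------
    dose_g
        Ingested D3-creatine dose in grams (30 mg oral dose by default).
    mw_ratio
        Molecular-weight ratio creatine/D3-creatine (131.1/134.1), used to
        convert spilled D3-creatine mass into unlabelled-equivalent grams.
    muscle_creatine_gkg
        Assumed skeletal-muscle creatine concentration, g creatine per kg
        wet muscle; 4.3 g/kg is the conventional value.
    """

    dose_g: float = 0.03
    mw_ratio: float = 131.1 / 134.1
    muscle_creatine_gkg: float = 4.3

    def __post_init__(self) -> None:
        if not (self.dose_g > 0):
            raise ValueError("dose_g must be positive")
        if not (0 < self.mw_ratio < 1):
            raise ValueError("mw_ratio must lie in (0, 1)")
        if not (self.muscle_creatine_gkg > 0):
            raise ValueError("muscle_creatine_gkg must be positive")

    @property
    def dose_mg(self) -> float:
        return 1000.0 * self.dose_g


@dataclass(frozen=True)
class CorrectionFactor:
    """M+2/M+0 creatinine response ratio of the LC-MS instrument.

    The endogenous creatinine signal is ~1000-fold more intense than the
    D3-creatinine signal, so creatinine is quantified on its weak M+2
    isotopologue transition and rescaled to M+0-equivalent by this
    experimentally determined response ratio (instrument specific).
    """

    value: float = 0.002469
    rsd_pct: float = 2.7

    def __post_init__(self) -> None:
        if not (0 < self.value < 1):
            raise ValueError("correction factor must lie in (0, 1)")


@dataclass(frozen=True)
class SpillageTier:
    """One piece of a piecewise log-linear spillage model.

    Spillage (mg) = exp(slope * ln(r) + intercept) * dose_mg for Cr/Crn
    ratio r at or above ``lower_bound`` (and below the next tier's bound).
    ``slope is None`` encodes a zero-spillage tier.
    """

    lower_bound: float
    slope: float | None
    intercept: float | None


@dataclass(frozen=True)
class SpillageModel:
    """Ordered spillage tiers plus the dose the formulas are scaled to."""

    tiers: tuple[SpillageTier, ...]
    dose_mg: float = 30.0

    def __post_init__(self) -> None:
        bounds = [t.lower_bound for t in self.tiers]
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError("tier lower bounds must be strictly increasing")
        if not self.tiers:
            raise ValueError("at least one tier required")


#: Single-tier log-linear spillage of the original algorithm.
SPILLAGE_ORIGINAL = SpillageModel(
    tiers=(SpillageTier(0.0, 1.2913, 0.7783),),
    dose_mg=30.0,
)

#: Three-tier spillage of the modified algorithm.  Ratios below 0.015 get no
#: correction; [0.015, 0.15] uses the middle tier; above 0.15 the steep tier.
SPILLAGE_MODIFIED = SpillageModel(
    tiers=(
        SpillageTier(0.0, None, None),
        SpillageTier(0.015, 0.9424, -0.1314),
        SpillageTier(0.15, 1.6246, -1.895),
    ),
    dose_mg=30.0,
)


@dataclass(frozen=True)
class AlgorithmCoefficients:
    """Linear muscle-volume estimator: L = b_pool*pool_g + b_w*kg + b_h*m + c."""

    beta_pool: float
    beta_weight: float
    beta_height: float
    intercept: float

    def predict(self, pool_g: float, weight_kg: float, height_m: float) -> float:
        return (
            self.beta_pool * pool_g
            + self.beta_weight * weight_kg
            + self.beta_height * height_m
            + self.intercept
        )

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: Fat-free thigh + erector-spinae volume from creatine pool size, weight
#: and height (the pool-augmented anthropometric estimator).
COEF_D3CR_HT_WT = AlgorithmCoefficients(
    beta_pool=0.032, beta_weight=0.030, beta_height=4.336, intercept=-4.134
)

#: Anthropometric-only muscle volume estimator (no urinary input).
COEF_MV_HT_WT = AlgorithmCoefficients(
    beta_pool=0.0, beta_weight=0.045, beta_height=6.266, intercept=-5.438
)


@dataclass(frozen=True)
class ConfigProfile:
    """A complete, named parameter set for the whole pipeline."""

    name: str = "iwhp2025"
    dose: DoseSpec = field(default_factory=DoseSpec)
    correction_factor: CorrectionFactor = field(default_factory=CorrectionFactor)
    spillage_original: SpillageModel = SPILLAGE_ORIGINAL
    spillage_modified: SpillageModel = SPILLAGE_MODIFIED
    coefficients: Mapping[str, AlgorithmCoefficients] = field(
        default_factory=lambda: {
            "d3cr_ht_wt": COEF_D3CR_HT_WT,
            "mv_ht_wt": COEF_MV_HT_WT,
        }
    )
    # Internal-standard final concentrations in the extraction mixture (ng/mL).
    is_d5crn_ngml: float = 250.0
    is_d5cr_ngml: float = 2500.0
    # QC thresholds (percent) and statistical defaults.
    qc_precision_max_pct: float = 15.0
    qc_between_run_max_pct: float = 8.0
    qc_bias_max_pct: float = 15.0
    vif_threshold: float = 3.0
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10
    # Floor below which spillage_original treats the Cr/Crn ratio as zero
    # spillage (the formula's r->0 limit) instead of evaluating ln(r).
    small_ratio_floor: float = 1e-6
    # Fraction of whole-body muscle volume contained in thigh + erector
    # spinae, used to scale compartment volume up to whole body.
    thigh_es_fraction: float = 0.45

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_PROFILE = ConfigProfile()

_PROFILES: dict[str, ConfigProfile] = {DEFAULT_PROFILE.name: DEFAULT_PROFILE}


def get_profile(name: str = "iwhp2025") -> ConfigProfile:
    """Look up a registered profile by name."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; known: {sorted(_PROFILES)}"
        ) from None


def save_profile(profile: ConfigProfile, path) -> None:
    """Serialise a profile to YAML (lossless: full float repr)."""
    with open(path, "w") as fh:
        yaml.safe_dump(profile.to_dict(), fh, sort_keys=False)


def _spillage_from_dict(d: dict) -> SpillageModel:
    tiers = tuple(SpillageTier(**t) for t in d["tiers"])
    return SpillageModel(tiers=tiers, dose_mg=d["dose_mg"])


def load_profile(path) -> ConfigProfile:
    """Load a profile written by :func:`save_profile`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ConfigProfile(
        name=d["name"],
        dose=DoseSpec(**d["dose"]),
        correction_factor=CorrectionFactor(**d["correction_factor"]),
        spillage_original=_spillage_from_dict(d["spillage_original"]),
        spillage_modified=_spillage_from_dict(d["spillage_modified"]),
        coefficients={
            k: AlgorithmCoefficients(**v) for k, v in d["coefficients"].items()
        },
        is_d5crn_ngml=d["is_d5crn_ngml"],
        is_d5cr_ngml=d["is_d5cr_ngml"],
        qc_precision_max_pct=d["qc_precision_max_pct"],
        qc_between_run_max_pct=d["qc_between_run_max_pct"],
        qc_bias_max_pct=d["qc_bias_max_pct"],
        vif_threshold=d["vif_threshold"],
        stepwise_entry_p=d["stepwise_entry_p"],
        stepwise_removal_p=d["stepwise_removal_p"],
        small_ratio_floor=d["small_ratio_floor"],
        thigh_es_fraction=d["thigh_es_fraction"],
    )
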