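"""The four muscle estimators and their shared dilution primitives.

The D3-creatine dilution principle: an ingested tracer dose distributes into
the whole-body creatine pool, is converted to labelled creatinine at a
constant fractional rate, and appears in urine.  At isotopic steady state
(~96 h post dose) the urinary enrichment ratio

    er = D3Crn / (D3Crn + Crn)

equals the tracer fraction of the creatine pool, so pool size ~= dose / er.
Part of the dose is "spilled" — excreted directly without entering muscle —
and two empirical corrections exist, both log-linear in the urinary
creatine/creatinine (Cr/Crn) ratio:

* original: a single curve, which can exceed the full dose at high Cr/Crn
  ratios and then yields negative pool sizes (reported, flagged, not
  clipped);
* modified: a three-tier curve that never exceeds the dose.

Mass estimators divide the pool by the muscle creatine concentration
(4.3 g/kg).  The spillage-free volume estimators are linear models on pool
size (uncorrected dose/er), weight and height — or on weight and height only
— calibrated against MRI fat-free thigh + erector-spinae volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .config import (
    AlgorithmCoefficients,
    ConfigProfile,
    DEFAULT_PROFILE,
    DoseSpec,
    SpillageModel,
)

__all__ = [
    "UrineMeasurement",
    "MuscleEstimate",
    "enrichment_ratio",
    "spillage_original",
    "spillage_modified",
    "pool_size_original",
    "pool_size_simple",
    "muscle_mass_from_pool",
    "d3cr_ht_wt",
    "mv_ht_wt",
    "whole_body_volume",
    "negative_mass_ratio_threshold",
    "estimate_all",
    "estimate_cohort",
    "METHODS",
]

#: method label -> unit of its estimate
METHODS = {
    "d3cr_original": "kg",
    "d3cr_modified": "kg",
    "d3cr_ht_wt": "L",
    "mv_ht_wt": "L",
}


@dataclass(frozen=True)
class UrineMeasurement:
    """Corrected urinary concentrations (ng/mL) of the three analytes."""

    crn: float
    d3crn: float
    cr: float

    def __post_init__(self) -> None:
        for name in ("crn", "d3crn", "cr"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def cr_crn_ratio(self) -> float:
        if self.crn == 0:
            raise ValueError("Cr/Crn ratio undefined: creatinine is zero")
        return self.cr / self.crn


@dataclass(frozen=True)
class MuscleEstimate:
    """One estimator's output for one participant."""

    method: str
    value: float | None
    unit: str
    pool_g: float | None = None
    spillage_mg: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def available(self) -> bool:
        return self.value is not None


def enrichment_ratio(u: UrineMeasurement) -> float:
    """Tracer fraction of urinary creatinine, D3Crn / (D3Crn + Crn)."""
    total = u.d3crn + u.crn
    if total <= 0:
        raise ValueError(
            "enrichment undefined: no detectable creatinine or D3-creatinine"
        )
    return u.d3crn / total


def _eval_loglinear(r: float, slope: float, intercept: float, dose_mg: float) -> float:
    return math.exp(slope * math.log(r) + intercept) * dose_mg


def spillage_original(
    cr_crn_ratio: float,
    model: SpillageModel | None = None,
    small_ratio_floor: float = 1e-6,
) -> float:
    """Single-curve spillage (mg): exp(1.2913 ln r + 0.7783) * 30.

    Ratios below ``small_ratio_floor`` return 0 mg with a warning (the
    formula's limit as r -> 0); negative ratios are rejected.
    """
    model = model or DEFAULT_PROFILE.spillage_original
    r = float(cr_crn_ratio)
    if not math.isfinite(r) or r < 0:
        raise ValueError(f"Cr/Crn ratio must be finite and >= 0, got {r!r}")
    if r < small_ratio_floor:
        warnings.warn(
            f"Cr/Crn ratio {r:g} below floor {small_ratio_floor:g}; "
            "treating spillage as 0 mg",
            stacklevel=2,
        )
        return 0.0
    tier = model.tiers[0]
    return _eval_loglinear(r, tier.slope, tier.intercept, model.dose_mg)


def spillage_modified(
    cr_crn_ratio: float, model: SpillageModel | None = None
) -> float:
    """Three-tier spillage (mg).

    r < 0.015: 0 mg; 0.015 <= r <= 0.15: exp(0.9424 ln r - 0.1314)*30;
    r > 0.15: exp(1.6246 ln r - 1.895)*30.  The boundary 0.15 belongs to the
    middle tier, matching the printed inequality directions; the map is
    total for all r >= 0 (r = 0 falls in the zero tier, so no ln(0)).
    """
    model = model or DEFAULT_PROFILE.spillage_modified
    r = float(cr_crn_ratio)
    if not math.isfinite(r) or r < 0:
        raise ValueError(f"Cr/Crn ratio must be finite and >= 0, got {r!r}")
    # Tier selection: last tier whose lower bound is <= r, except that the
    # top tier opens *strictly above* its bound (r == 0.15 stays in tier 2).
    chosen = model.tiers[0]
    for tier in model.tiers[1:]:
        is_last = tier is model.tiers[-1]
        if (r > tier.lower_bound) or (not is_last and r >= tier.lower_bound):
            chosen = tier
    if chosen.slope is None:
        return 0.0
    return _eval_loglinear(r, chosen.slope, chosen.intercept, model.dose_mg)


def pool_size_original(
    er: float, spillage_mg: float, dose: DoseSpec | None = None
) -> float:
    """Spillage-corrected creatine pool size (g).

    pool = (dose_g - (spillage_mg/1000) * mw_ratio) / er.  May be negative
    when the calculated spillage exceeds the ingested dose; callers flag,
    never clip.
    """
    dose = dose or DEFAULT_PROFILE.dose
    if not (0 < er <= 1):
        raise ValueError(f"enrichment ratio must lie in (0, 1], got {er!r}")
    if spillage_mg < 0:
        raise ValueError("spillage must be >= 0")
    return (dose.dose_g - (spillage_mg / 1000.0) * dose.mw_ratio) / er


def pool_size_simple(er: float, dose: DoseSpec | None = None) -> float:
    """Uncorrected creatine pool size (g): dose_g / er."""
    dose = dose or DEFAULT_PROFILE.dose
    if not (0 < er <= 1):
        raise ValueError(f"enrichment ratio must lie in (0, 1], got {er!r}")
    return dose.dose_g / er


def muscle_mass_from_pool(pool_g: float, dose: DoseSpec | None = None) -> float:
    """Total-body muscle mass (kg) = pool_g / muscle creatine g/kg."""
    dose = dose or DEFAULT_PROFILE.dose
    if not math.isfinite(pool_g):
        raise ValueError("pool size must be finite")
    return pool_g / dose.muscle_creatine_gkg


def d3cr_ht_wt(
    pool_g: float,
    weight_kg: float,
    height_m: float,
    coef: AlgorithmCoefficients | None = None,
) -> float:
    """Fat-free thigh + erector-spinae volume (L) from pool, weight, height."""
    coef = coef or DEFAULT_PROFILE.coefficients["d3cr_ht_wt"]
    return coef.predict(pool_g, weight_kg, height_m)


def mv_ht_wt(
    weight_kg: float,
    height_m: float,
    coef: AlgorithmCoefficients | None = None,
) -> float:
    """Anthropometric-only muscle volume (L); no urinary input."""
    coef = coef or DEFAULT_PROFILE.coefficients["mv_ht_wt"]
    return coef.predict(0.0, weight_kg, height_m)


def whole_body_volume(thigh_es_volume_l: float, fraction: float = 0.45) -> float:
    """Scale thigh + erector-spinae volume to whole-body muscle volume (L).

    The compartment holds a roughly constant ~45% of whole-body muscle in
    healthy adults, so whole body = compartment / 0.45.
    """
    if thigh_es_volume_l < 0:
        raise ValueError("volume must be >= 0")
    return thigh_es_volume_l / fraction


def negative_mass_ratio_threshold(
    model: SpillageModel | None = None, dose: DoseSpec | None = None
) -> float:
    """Cr/Crn ratio above which the original algorithm goes negative.

    Solves exp(slope*ln r + intercept) * dose_mg * mw_ratio / 1000 = dose_g
    for r; approximately 0.557 at the default constants.
    """
    model = model or DEFAULT_PROFILE.spillage_original
    dose = dose or DEFAULT_PROFILE.dose
    tier = model.tiers[0]
    # dose_mg * mw_ratio * exp(slope ln r + intercept) = 1000 * dose_g
    target = math.log(1000.0 * dose.dose_g / (model.dose_mg * dose.mw_ratio))
    return math.exp((target - tier.intercept) / tier.slope)


def _flags_for(value: float, spillage_mg: float | None, dose: DoseSpec) -> frozenset[str]:
    flags = set()
    if value < 0:
        flags.add("NEGATIVE_MASS")
    if spillage_mg is not None and spillage_mg > dose.dose_mg:
        flags.add("SPILLAGE_EXCEEDS_DOSE")
    return frozenset(flags)


def estimate_all(
    u: UrineMeasurement | None,
    weight_kg: float,
    height_m: float,
    profile: ConfigProfile = DEFAULT_PROFILE,
) -> list[MuscleEstimate]:
    """Run all four estimators for one participant.

    With no urine measurement (or no detectable tracer) only the
    anthropometric MV_Ht-Wt estimate is produced; the urinary methods are
    returned as unavailable with a ``NO_URINARY_DATA`` flag.
    """
    dose = profile.dose
    mv = MuscleEstimate(
        method="mv_ht_wt",
        value=mv_ht_wt(weight_kg, height_m, profile.coefficients["mv_ht_wt"]),
        unit="L",
    )
    if u is None or (u.d3crn + u.crn) == 0 or u.d3crn == 0:
        unavailable = [
            MuscleEstimate(m, None, METHODS[m], flags=frozenset({"NO_URINARY_DATA"}))
            for m in ("d3cr_original", "d3cr_modified", "d3cr_ht_wt")
        ]
        return unavailable + [mv]

    er = enrichment_ratio(u)
    r = u.cr_crn_ratio

    s_orig = spillage_original(
        r, profile.spillage_original, profile.small_ratio_floor
    )
    pool_orig = pool_size_original(er, s_orig, dose)
    mass_orig = muscle_mass_from_pool(pool_orig, dose)

    s_mod = spillage_modified(r, profile.spillage_modified)
    pool_mod = pool_size_original(er, s_mod, dose)
    mass_mod = muscle_mass_from_pool(pool_mod, dose)

    pool_simple = pool_size_simple(er, dose)
    vol_htwt = d3cr_ht_wt(
        pool_simple, weight_kg, height_m, profile.coefficients["d3cr_ht_wt"]
    )

    return [
        MuscleEstimate(
            "d3cr_original", mass_orig, "kg", pool_orig, s_orig,
            _flags_for(mass_orig, s_orig, dose),
        ),
        MuscleEstimate(
            "d3cr_modified", mass_mod, "kg", pool_mod, s_mod,
            _flags_for(mass_mod, s_mod, dose),
        ),
        MuscleEstimate(
            "d3cr_ht_wt", vol_htwt, "L", pool_simple, None,
            _flags_for(vol_htwt, None, dose),
        ),
        mv,
    ]


def estimate_cohort(
    cohort: pd.DataFrame, profile: ConfigProfile = DEFAULT_PROFILE
) -> pd.DataFrame:
    """Vectorised :func:`estimate_all` over a cohort table.

    Expects columns crn_ngml, d3crn_ngml, cr_ngml, height_m, weight_kg (NaN
    urinary values allowed).  Returns the long estimates table: one row per
    participant x method with value, unit, pool_g, spillage_mg, flags.
    """
    rows = []
    for _, rec in cohort.iterrows():
        urinary = (rec.get("crn_ngml"), rec.get("d3crn_ngml"), rec.get("cr_ngml"))
        u = None
        if all(v is not None and pd.notna(v) for v in urinary):
            u = UrineMeasurement(crn=urinary[0], d3crn=urinary[1], cr=urinary[2])
        for est in estimate_all(u, rec["weight_kg"], rec["height_m"], profile):
            rows.append(
                {
                    "participant_id": rec["participant_id"],
                    "method": est.method,
                    "value": est.value,
                    "unit": est.unit,
                    "pool_g": est.pool_g,
                    "spillage_mg": est.spillage_mg,
                    "flags": ";".join(sorted(est.flags)),
                }
            )
    return pd.DataFrame(rows)
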