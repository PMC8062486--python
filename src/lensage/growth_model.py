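"""Deterministic growth equations for lens-weight-based age estimation.

The dry weight of the mammalian eye lens accumulates monotonically over an
animal's life, which makes it a robust age indicator that is largely
insensitive to nutrition, sex and habitat.  For the European wild rabbit
(*Oryctolagus cuniculus*) lens growth is well described by the asymptotic
logistic curve

    LDW(A) = a * 10 ** (-b / (A + c))

where ``LDW`` is the lens dry weight in mg, ``A`` the postnatal age in days,
``a`` the maximum asymptotic lens weight (mg), ``b`` the growth-rate constant
(days; a larger ``b`` means a slower approach to the asymptote) and ``c`` the
prenatal growth time (days), so that ``A + c`` is the total elapsed growth
time.  Taking log10 of both sides gives the linearised form

    log10(LDW) = log10(a) - b / (A + c)

This module houses the curve, its inversion (age from lens weight), the
linear juvenile weight-age relation used to date live-trapped young rabbits,
and the cross-curve bias table that quantifies what happens when a curve
calibrated on one population is applied to lenses grown under another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurveParams",
    "JuvenileGrowthParams",
    "AgeFromWeight",
    "predict_ldw",
    "predict_log_ldw",
    "age_from_ldw",
    "age_from_weight",
    "age_bias_table",
    "OCA_IBERIAN",
    "OCC_IBERIAN",
    "OCC_AUSTRALIA_COMBINED",
]


@dataclass(frozen=True)
class GrowthCurveParams:
    """Parameters (a, b, c) of one lens-growth curve.

    a : asymptotic lens dry weight, mg (a > 0)
    b : growth-rate constant, days (b > 0)
    c : prenatal growth offset, days (c >= 0); elapsed growth time is A + c
    label : free-text curve name for reports
    """

    a: float
    b: float
    c: float = 32.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"asymptote a must be > 0, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"growth rate b must be > 0, got {self.b}")
        if self.c < 0:
            raise ValueError(f"prenatal offset c must be >= 0, got {self.c}")


#: Subspecies-specific curves for the Iberian Peninsula (c fixed at 32 days)
#: and the combined east/west Australian curve, all on the same c convention.
OCA_IBERIAN = GrowthCurveParams(240.0, 64.9, 32.0, "Oca (Iberian Peninsula)")
OCC_IBERIAN = GrowthCurveParams(273.0, 64.9, 32.0, "Occ (Iberian Peninsula)")
OCC_AUSTRALIA_COMBINED = GrowthCurveParams(276.0, 51.7, 32.0, "Occ (Australia, combined)")


@dataclass(frozen=True)
class JuvenileGrowthParams:
    """Constants of the linear juvenile body-weight/age relation.

    Body weight grows linearly from weaning:  W = wi + r * (A - weaning_age).
    The relation holds only for juveniles; above ``weight_cap`` (default
    500 g, roughly half adult weight) adult growth flattens and the equation
    must refuse to estimate an age.
    """

    wi: float = 200.0          # weight at weaning, g
    r: float = 9.77            # body growth rate, g/day
    weaning_age: float = 21.0  # days
    weight_cap: float = 500.0  # g; equation not applied at or above this

    def __post_init__(self) -> None:
        bad = []
        if not self.wi > 0:
            bad.append(f"wi={self.wi} (must be > 0)")
        if not self.r > 0:
            bad.append(f"r={self.r} (must be > 0)")
        if not self.weaning_age > 0:
            bad.append(f"weaning_age={self.weaning_age} (must be > 0)")
        if not self.weight_cap > self.wi:
            bad.append(f"weight_cap={self.weight_cap} (must exceed wi={self.wi})")
        if bad:
            raise ValueError("invalid juvenile growth parameters: " + "; ".join(bad))


def predict_ldw(params: GrowthCurveParams, age_days):
    """Lens dry weight (mg) at ``age_days`` under ``params``.

    Strictly increasing in age, bounded above by the asymptote ``a``.
    Accepts a scalar or array of ages; the elapsed growth time
    ``age + c`` must be positive.
    """
    age = np.asarray(age_days, dtype=float)
    elapsed = age + params.c
    if np.any(elapsed <= 0):
        raise ValueError(
            f"age + c must be > 0 (c={params.c}); got elapsed growth time "
            f"min {elapsed.min() if elapsed.ndim else elapsed}"
        )
    out = params.a * 10.0 ** (-params.b / elapsed)
    return float(out) if np.isscalar(age_days) else out


def predict_log_ldw(params: GrowthCurveParams, age_days):
    """log10 lens dry weight at ``age_days``: log10(a) - b/(age + c).

    Identical to ``log10(predict_ldw(...))``; provided so that fitting may
    optionally minimise residuals on the linearised scale.
    """
    age = np.asarray(age_days, dtype=float)
    elapsed = age + params.c
    if np.any(elapsed <= 0):
        raise ValueError(f"age + c must be > 0 (c={params.c})")
    out = np.log10(params.a) - params.b / elapsed
    return float(out) if np.isscalar(age_days) else out


def age_from_ldw(params: GrowthCurveParams, ldw_mg: float) -> float:
    """Invert the growth curve: postnatal age (days) at lens weight ``ldw_mg``.

        A = b / log10(a / LDW) - c

    Only lens weights strictly between 0 and the asymptote ``a`` are
    invertible; the asymptote itself is reached only at infinite age.
    """
    if ldw_mg <= 0:
        raise ValueError(f"lens weight must be > 0 mg, got {ldw_mg}")
    if ldw_mg >= params.a:
        raise ValueError(
            f"lens weight {ldw_mg} mg is at or above the asymptote "
            f"a={params.a} mg; age is undefined under this curve"
        )
    return params.b / np.log10(params.a / ldw_mg) - params.c


@dataclass(frozen=True)
class AgeFromWeight:
    """Age estimated from juvenile body weight, with provenance flags.

    ``estimated`` is always True (this path never yields an exactly known
    age); ``below_weaning`` marks extrapolation below the weaning weight.
    """

    age_days: float
    estimated: bool = True
    below_weaning: bool = False


def age_from_weight(jparams: JuvenileGrowthParams, weight_g: float) -> AgeFromWeight:
    """Juvenile age (days) from body weight: A = weaning_age + (W - wi) / r.

    Refuses weights at or above ``weight_cap`` — the linear relation breaks
    down for adults, so aging heavier animals this way would be biased.
    Weights below the weaning weight return an age under the weaning age,
    flagged as a below-weaning extrapolation.
    """
    if weight_g <= 0:
        raise ValueError(f"body weight must be > 0 g, got {weight_g}")
    if weight_g >= jparams.weight_cap:
        raise ValueError(
            f"body weight {weight_g} g is >= the {jparams.weight_cap} g cap: "
            "the linear juvenile relation does not apply to adults, refusing "
            "to estimate an age"
        )
    age = jparams.weaning_age + (weight_g - jparams.wi) / jparams.r
    below = weight_g < jparams.wi
    if below:
        warnings.warn(
            f"body weight {weight_g} g is below the weaning weight "
            f"{jparams.wi} g; age estimate extrapolates below weaning",
            stacklevel=2,
        )
    return AgeFromWeight(age_days=age, estimated=True, below_weaning=below)


def age_bias_table(
    true_params: GrowthCurveParams,
    assumed_params: GrowthCurveParams,
    ages,
) -> pd.DataFrame:
    """Bias from aging lenses grown under one curve with another curve.

    For each true age, the lens weight is generated under ``true_params``
    and then inverted under ``assumed_params``; the bias is the estimated
    minus the true age.  Rows where the lens weight is not invertible under
    the assumed curve (at or above its asymptote) carry NaN estimates
    instead of aborting the table.

    Returns a DataFrame with columns ``age_days``, ``ldw_true_mg``,
    ``age_est_days``, ``bias_days``, in the order of the input ages.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    ldw = predict_ldw(true_params, ages)
    est = np.full_like(ages, np.nan)
    for i, w in enumerate(ldw):
        try:
            est[i] = age_from_ldw(assumed_params, float(w))
        except ValueError:
            pass  # undefined-age row: lens heavier than the assumed asymptote
    return pd.DataFrame(
        {
            "age_days": ages,
            "ldw_true_mg": ldw,
            "age_est_days": est,
            "bias_days": est - ages,
        }
    )
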