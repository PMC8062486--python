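"""Synthetic observation datasets with the study's statistical structure.

The original lens-weight data are not publicly deposited, so every pipeline
stage is exercised on simulated datasets that emulate the study design: two
subspecies groups (Oca n=112, Occ n=173), ages spanning 17-1392 days drawn
from a three-class mixture (<3 months, 3-12 months, >12 months with
probabilities 138/285, 76/285, 71/285; uniform within class), lens weights
generated from the asymptotic growth curve of each group's published
constants plus additive Gaussian noise (default sd 19 mg) truncated by
resampling to stay above 0.1 mg, and juvenile body weights following the
linear weaning-growth relation.

Defaults ARE the study conditions; change them only to explore departures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ObservationRecord, ObservationSet
from .growth_model import (
    OCA_IBERIAN,
    OCC_IBERIAN,
    GrowthCurveParams,
    JuvenileGrowthParams,
    predict_ldw,
)

__all__ = ["GroupSpec", "GeneratorConfig", "generate_dataset", "simulate_juvenile_weights"]

#: Study age classes, days: <3 months, 3-12 months, >12 months.
DEFAULT_AGE_CLASSES: tuple[tuple[float, float], ...] = (
    (17.0, 90.0),
    (90.0, 365.0),
    (365.0, 1392.0),
)
#: Observed class counts 138/76/71 of n=285, as probabilities.
DEFAULT_CLASS_PROBS: tuple[float, ...] = (138 / 285, 76 / 285, 71 / 285)

_AGE_SPAN = (17.0, 1392.0)
_LDW_FLOOR_MG = 0.1


@dataclass(frozen=True)
class GroupSpec:
    """One group to simulate: label, sample size, generating curve."""

    label: str
    n: int
    params: GrowthCurveParams


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one simulated dataset.

    Defaults reproduce the study design: Oca n=112 with a=240, Occ n=173
    with a=273, both with b=64.9 and c=32; additive lens-weight noise
    sd 19 mg; the observed three-class age mixture.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("Oca", 112, OCA_IBERIAN),
        GroupSpec("Occ", 173, OCC_IBERIAN),
    )
    age_classes: tuple[tuple[float, float], ...] = DEFAULT_AGE_CLASSES
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS
    noise_sd_mg: float = 19.0
    weight_noise_sd_g: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        problems: list[str] = []
        if not self.groups:
            problems.append("groups: at least one group required")
        for g in self.groups:
            if g.n <= 0:
                problems.append(f"groups[{g.label}].n={g.n}: must be > 0")
        if len(self.age_classes) != len(self.class_probs):
            problems.append(
                f"age_classes ({len(self.age_classes)}) and class_probs "
                f"({len(self.class_probs)}) differ in length"
            )
        for i, (lo, hi) in enumerate(self.age_classes):
            if not lo < hi:
                problems.append(f"age_classes[{i}]=({lo}, {hi}): need lo < hi")
            if lo < _AGE_SPAN[0] or hi > _AGE_SPAN[1]:
                problems.append(
                    f"age_classes[{i}]=({lo}, {hi}): outside the study span "
                    f"{_AGE_SPAN} days"
                )
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            problems.append(f"class_probs sum to {sum(self.class_probs)}, not 1")
        if any(p < 0 for p in self.class_probs):
            problems.append("class_probs must be nonnegative")
        if self.noise_sd_mg < 0:
            problems.append(f"noise_sd_mg={self.noise_sd_mg}: must be >= 0")
        if self.weight_noise_sd_g < 0:
            problems.append(f"weight_noise_sd_g={self.weight_noise_sd_g}: must be >= 0")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))


def _draw_ages(rng, n, classes, probs) -> np.ndarray:
    cls = rng.choice(len(classes), size=n, p=probs)
    lo = np.array([classes[i][0] for i in cls])
    hi = np.array([classes[i][1] for i in cls])
    return rng.uniform(lo, hi)


def generate_dataset(config: GeneratorConfig) -> ObservationSet:
    """Draw one synthetic observation set under ``config``.

    Ages come from the class mixture, lens weights from each group's curve
    plus truncated Gaussian noise (resampled until above 0.1 mg so the
    noise stays honestly Gaussian-conditional-on-positive).  Reproducible
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ObservationRecord] = []
    for g in config.groups:
        ages = _draw_ages(rng, g.n, config.age_classes, config.class_probs)
        mean_ldw = predict_ldw(g.params, ages)
        ldw = mean_ldw + rng.normal(0.0, config.noise_sd_mg, g.n) if config.noise_sd_mg > 0 else mean_ldw.copy()
        bad = ldw <= _LDW_FLOOR_MG
        while bad.any():  # truncate by resampling, not clipping
            ldw[bad] = mean_ldw[bad] + rng.normal(0.0, config.noise_sd_mg, bad.sum())
            bad = ldw <= _LDW_FLOOR_MG
        for i in range(g.n):
            records.append(
                ObservationRecord(
                    id=f"{g.label}-{i + 1:04d}",
                    group=g.label,
                    age_days=float(ages[i]),
                    ldw_mg=float(ldw[i]),
                    age_known=True,
                )
            )
    return ObservationSet(
        records=tuple(records), groups=tuple(g.label for g in config.groups)
    )


def simulate_juvenile_weights(
    records: ObservationSet,
    jparams: JuvenileGrowthParams = JuvenileGrowthParams(),
    weight_noise_sd_g: float = 0.0,
    seed: int | None = None,
) -> ObservationSet:
    """Attach body weights from the linear juvenile growth relation.

    Every record gets W = wi + r*(age - weaning_age) + noise (truncated
    positive), so animals old enough to exceed the 500 g cap naturally
    receive weights the weight-aging path must refuse.  Noise-free weights
    below the cap round-trip exactly through the weight-to-age inversion.
    """
    rng = np.random.default_rng(seed)
    out: list[ObservationRecord] = []
    for r in records.records:
        w = jparams.wi + jparams.r * (r.age_days - jparams.weaning_age)
        if weight_noise_sd_g > 0:
            draw = w + rng.normal(0.0, weight_noise_sd_g)
            while draw <= 0:
                draw = w + rng.normal(0.0, weight_noise_sd_g)
            w = draw
        out.append(
            ObservationRecord(
                id=r.id,
                group=r.group,
                age_days=r.age_days,
                ldw_mg=r.ldw_mg,
                body_weight_g=float(w),
                age_known=r.age_known,
            )
        )
    return ObservationSet(records=tuple(out), groups=records.groups)
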