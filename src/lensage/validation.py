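"""Repeated stratified k-fold cross-validation of a fitted growth model.

Predictive performance is summarised by the coefficient of determination
R² = 1 - Σ(o - p)² / Σ(o - ō)², computed once per repeat on the pooled
held-out predictions (every record is held out exactly once per repeat).
Folds are stratified by group so that every training set contains both
subspecies and can identify group-specific parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset import ObservationSet
from .fitting import FitSpec, fit_curve

__all__ = ["CVResult", "r_squared", "repeated_kfold_cv"]


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-d vectors of equal length")
    if len(o) < 2:
        raise ValueError("need at least 2 observations")
    sst = float(((o - o.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("R² undefined: observed vector is constant")
    return 1.0 - float(((o - p) ** 2).sum()) / sst


@dataclass(frozen=True)
class CVResult:
    """Per-repeat R² of repeated k-fold cross-validation."""

    repeats: int
    folds: int
    r2_per_repeat: np.ndarray
    seed: int | None
    n_heldout_per_repeat: np.ndarray

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_per_repeat))

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "folds": self.folds,
            "r2_mean": self.r2_mean,
            "r2_per_repeat": [float(v) for v in self.r2_per_repeat],
            "seed": self.seed,
        }


def repeated_kfold_cv(
    data: ObservationSet,
    spec: FitSpec,
    repeats: int = 100,
    folds: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation of the model described by ``spec``.

    Per repeat the records are partitioned into ``folds`` folds stratified
    by group; the model is refit on each training complement, held-out
    records are predicted, and one R² is computed on the pooled held-out
    predictions.  A repeat whose partition leaves a training fold without
    an entire group is redrawn (up to 10 times) before erroring out.
    Reproducible under a fixed seed.
    """
    y = data.ldw()
    if spec.scale == "log":
        y = np.log10(y)
    groups = data.group_labels()
    counts = data.group_counts()
    short = [g for g, c in counts.items() if c < folds]
    if short:
        raise ValueError(
            f"groups {short} have fewer records than folds={folds}; "
            "stratified folding impossible"
        )
    ss = np.random.SeedSequence(seed)
    r2s = np.empty(repeats)
    heldout = np.empty(repeats, dtype=int)
    for rep, child in enumerate(ss.spawn(repeats)):
        states = child.generate_state(11)  # primary state + up to 10 redraws
        for attempt in range(11):
            try:
                r2s[rep], heldout[rep] = _one_repeat(
                    data, spec, y, groups, folds, int(states[attempt] % (2**31))
                )
                break
            except _DegenerateFold:
                if attempt == 10:
                    raise RuntimeError(
                        "cross-validation repeat failed 10 redraws: folds keep "
                        "losing an entire group"
                    )
                warnings.warn(
                    f"repeat {rep}: fold lost an entire group, redrawing",
                    stacklevel=2,
                )
    return CVResult(
        repeats=repeats,
        folds=folds,
        r2_per_repeat=r2s,
        seed=seed,
        n_heldout_per_repeat=heldout,
    )


class _DegenerateFold(Exception):
    pass


def _one_repeat(data, spec, y, groups, folds, random_state):
    kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    pred = np.full(len(data), np.nan)
    for train_idx, test_idx in kf.split(np.zeros(len(data)), groups):
        if set(groups[train_idx]) != set(data.groups):
            raise _DegenerateFold
        fit = fit_curve(data.subset(train_idx), spec)
        ages_test = data.ages()[test_idx]
        pred[test_idx] = fit.predict(ages_test, groups[test_idx])
    assert not np.any(np.isnan(pred)), "every record must be held out exactly once"
    return r_squared(y, pred), len(pred)
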