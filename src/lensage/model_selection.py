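"""AICc multimodel comparison of the four parameter-sharing candidates.

Four candidate models describe how the curve parameters may differ between
the two subspecies: everything shared (Model 1), everything distinct
(Model 2), asymptote shared / growth rate distinct (Model 3), asymptote
distinct / growth rate shared (Model 4).  Models are ranked by the
small-sample-corrected Akaike information criterion

    AICc = -2 loglik + 2K + 2K(K+1) / (n - K - 1)

with K counting every estimated parameter including the residual standard
deviation.  Akaike weights w_i = exp(-Δ_i/2) / Σ exp(-Δ_j/2) express the
relative evidence for each model; models within 2 AICc units of the best
are flagged as equally plausible and the table never auto-discards one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ObservationSet
from .fitting import FitResult, FitSpec, fit_curve

__all__ = [
    "MODEL_SPECS",
    "aicc",
    "akaike_weights",
    "ModelComparisonTable",
    "fit_candidate_models",
]

#: Sharing pattern of each candidate model (share_a, share_b).
MODEL_SPECS: dict[int, tuple[bool, bool]] = {
    1: (True, True),
    2: (False, False),
    3: (True, False),
    4: (False, True),
}

_SHARING_TEXT = {
    1: "a shared, b shared",
    2: "a by group, b by group",
    3: "a shared, b by group",
    4: "a by group, b shared",
}


def aicc(loglik: float, K: int, n: int) -> float:
    """Second-order Akaike information criterion.

    Requires n > K + 1 (otherwise the small-sample correction is undefined).
    """
    if n <= K + 1:
        raise ValueError(
            f"AICc correction undefined for n={n}, K={K} (need n > K + 1)"
        )
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from a vector of AICc values; sums to 1."""
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0:
        raise ValueError("akaike_weights requires at least one AICc value")
    if not np.all(np.isfinite(vals)):
        raise ValueError("akaike_weights requires finite AICc values")
    rel = np.exp(-(vals - vals.min()) / 2.0)
    return rel / rel.sum()


@dataclass(frozen=True)
class ModelRow:
    model: int
    sharing: str
    fit: FitResult
    K: int
    aicc: float
    delta_aicc: float
    weight: float
    cum_weight: float
    plausible: bool


@dataclass(frozen=True)
class ModelComparisonTable:
    """Candidate models ordered by ascending AICc.

    Weights are computed over the converged candidates only; a
    non-converged candidate keeps its row (NaN criteria) at the bottom
    rather than aborting the comparison.
    """

    rows: tuple[ModelRow, ...]
    n: int

    @property
    def best(self) -> ModelRow:
        return self.rows[0]

    def row_for(self, model: int) -> ModelRow:
        for row in self.rows:
            if row.model == model:
                return row
        raise KeyError(f"no model {model} in table")

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {
                "model": row.model,
                "sharing": row.sharing,
                "K": row.K,
                "AICc": row.aicc,
                "dAICc": row.delta_aicc,
                "weight": row.weight,
                "cum_weight": row.cum_weight,
                "plausible": row.plausible,
                "converged": row.fit.converged,
            }
            rec.update(row.fit.estimates)
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "models": [
                {
                    "model": r.model,
                    "sharing": r.sharing,
                    "K": r.K,
                    "AICc": r.aicc,
                    "dAICc": r.delta_aicc,
                    "weight": r.weight,
                    "cum_weight": r.cum_weight,
                    "plausible": r.plausible,
                    "fit": r.fit.to_dict(),
                }
                for r in self.rows
            ],
        }


def fit_candidate_models(
    data: ObservationSet,
    c_fixed: float = 32.0,
    scale: str = "linear",
) -> ModelComparisonTable:
    """Fit Models 1-4 to a two-group dataset and rank them by AICc.

    Deterministic given the data.  Each candidate's nonconvergence is
    recorded in its row and excluded from the weights instead of aborting
    the whole comparison.
    """
    if len(data.groups) != 2:
        raise ValueError(
            f"candidate-model comparison requires exactly 2 groups, got "
            f"{list(data.groups)}"
        )
    fits: dict[int, FitResult] = {}
    for model, (share_a, share_b) in MODEL_SPECS.items():
        spec = FitSpec(share_a=share_a, share_b=share_b, c_fixed=c_fixed, scale=scale)
        fits[model] = fit_curve(data, spec)

    ok = [m for m in MODEL_SPECS if fits[m].converged and np.isfinite(fits[m].loglik)]
    crit = {m: aicc(fits[m].loglik, fits[m].K, fits[m].n) for m in ok}
    if crit:
        order = sorted(ok, key=lambda m: crit[m])
        best = crit[order[0]]
        weights = akaike_weights([crit[m] for m in order])
    else:
        order, best, weights = [], np.nan, np.array([])

    rows: list[ModelRow] = []
    cum = 0.0
    for rank, m in enumerate(order):
        cum += float(weights[rank])
        delta = crit[m] - best
        rows.append(
            ModelRow(
                model=m,
                sharing=_SHARING_TEXT[m],
                fit=fits[m],
                K=fits[m].K,
                aicc=crit[m],
                delta_aicc=delta,
                weight=float(weights[rank]),
                cum_weight=cum,
                plausible=delta < 2.0,
            )
        )
    for m in MODEL_SPECS:
        if m not in order:  # nonconverged candidates sit below the ranking
            rows.append(
                ModelRow(
                    model=m,
                    sharing=_SHARING_TEXT[m],
                    fit=fits[m],
                    K=fits[m].K,
                    aicc=np.nan,
                    delta_aicc=np.nan,
                    weight=0.0,
                    cum_weight=np.nan,
                    plausible=False,
                )
            )
    return ModelComparisonTable(rows=tuple(rows), n=len(data))
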