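"""Constrained nonlinear least-squares fitting of lens-growth curves.

The asymptote ``a`` and growth-rate constant ``b`` are estimated for one or
two groups (subspecies), optionally constrained to be equal across groups;
the prenatal offset ``c`` is held fixed (32 days by default, the convention
under which the published constants are comparable).  Residuals may be
minimised on the lens-weight scale (mg; the default) or on the linearised
log10 scale.

The parameter-sharing combinations map one-to-one onto the four candidate
models of the model-selection stage:

    Model 1: a shared,   b shared      (2 curve parameters)
    Model 2: a by group, b by group    (4)
    Model 3: a shared,   b by group    (3)
    Model 4: a by group, b shared      (3)

The reported parameter count K adds one for the residual standard
deviation, so K is 3/5/4/4 for Models 1/2/3/4 with two groups.

Standard errors come from the curvature of the least-squares surface at the
optimum: cov = s² (JᵀJ)⁻¹ with s² = RSS / (n − p), J the Jacobian of the
predictions and p the number of curve parameters.  The Gaussian
log-likelihood is evaluated at the maximum-likelihood variance RSS/n, the
standard choice when ranking least-squares fits by information criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .dataset import ObservationSet
from .growth_model import GrowthCurveParams

__all__ = ["FitSpec", "FitResult", "fit_curve", "standard_errors", "gaussian_loglik"]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class FitSpec:
    """Which parameters are shared across groups, and on what scale to fit.

    share_a / share_b : equality constraints on the asymptote / growth rate
    c_fixed : prenatal offset held fixed during fitting, days
    scale : 'linear' (residuals in mg) or 'log' (residuals in log10 mg)
    """

    share_a: bool
    share_b: bool
    c_fixed: float = 32.0
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")

    @property
    def model_number(self) -> int:
        """The candidate-model id this sharing pattern corresponds to."""
        return {
            (True, True): 1,
            (False, False): 2,
            (True, False): 3,
            (False, True): 4,
        }[(self.share_a, self.share_b)]

    def param_names(self, groups: tuple[str, ...]) -> list[str]:
        names = ["a"] if self.share_a else [f"a_{g}" for g in groups]
        names += ["b"] if self.share_b else [f"b_{g}" for g in groups]
        return names


@dataclass(frozen=True)
class FitResult:
    """Constrained NLS estimates with uncertainty and likelihood summaries.

    ``K`` counts all estimated parameters including the residual standard
    deviation; ``loglik`` is the Gaussian log-likelihood at the optimum.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    rss: float
    n: int
    K: int
    loglik: float
    converged: bool
    n_iter: int
    scale: str
    spec: FitSpec
    groups: tuple[str, ...]

    def curve_for(self, group: str) -> GrowthCurveParams:
        """The fitted growth curve of one group."""
        a = self.estimates["a"] if self.spec.share_a else self.estimates[f"a_{group}"]
        b = self.estimates["b"] if self.spec.share_b else self.estimates[f"b_{group}"]
        return GrowthCurveParams(a=a, b=b, c=self.spec.c_fixed, label=str(group))

    def predict(self, ages, group_labels) -> np.ndarray:
        """Predicted lens weight (mg, or log10 mg for log-scale fits)."""
        ages = np.asarray(ages, dtype=float)
        labels = np.asarray(group_labels, dtype=object)
        out = np.empty_like(ages)
        for g in self.groups:
            mask = labels == g
            if not mask.any():
                continue
            p = self.curve_for(g)
            pred = p.a * 10.0 ** (-p.b / (ages[mask] + p.c))
            out[mask] = np.log10(pred) if self.scale == "log" else pred
        return out

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "standard_errors": dict(self.standard_errors),
            "rss": self.rss,
            "n": self.n,
            "K": self.K,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "scale": self.scale,
            "model": self.spec.model_number,
            "share_a": self.spec.share_a,
            "share_b": self.spec.share_b,
            "c_fixed": self.spec.c_fixed,
            "groups": list(self.groups),
        }


def gaussian_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood at the ML variance estimate rss/n."""
    if rss <= 0:
        return np.inf  # perfect fit: likelihood unbounded
    return -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)


def _design(data: ObservationSet, spec: FitSpec):
    """Map records onto the packed parameter vector [a-params..., b-params...]."""
    ages = data.ages()
    y = data.ldw()
    labels = data.group_labels()
    groups = data.groups
    g_index = np.array([groups.index(g) for g in labels])
    n_groups = len(groups)
    n_a = 1 if spec.share_a else n_groups
    a_idx = np.zeros(len(y), dtype=int) if spec.share_a else g_index.copy()
    b_idx = (
        np.full(len(y), n_a, dtype=int)
        if spec.share_b
        else n_a + g_index
    )
    elapsed = ages + spec.c_fixed
    if np.any(elapsed <= 0):
        raise ValueError(f"ages must satisfy age + c_fixed > 0 (c_fixed={spec.c_fixed})")
    return y, elapsed, a_idx, b_idx, n_a


def _default_init(data: ObservationSet, spec: FitSpec) -> np.ndarray:
    """a0 = 1.05 x max observed lens weight (per group, or pooled when
    shared), so the asymptote starts above every observation; b0 = 60 days,
    near typical published growth rates."""
    y = data.ldw()
    labels = data.group_labels()
    if spec.share_a:
        a0 = [1.05 * y.max()]
    else:
        a0 = [1.05 * y[labels == g].max() for g in data.groups]
    b0 = [60.0] if spec.share_b else [60.0] * len(data.groups)
    return np.array(a0 + b0, dtype=float)


def _residuals_and_jac(theta, y, elapsed, a_idx, b_idx, n_params, scale):
    a = theta[a_idx]
    b = theta[b_idx]
    decay = 10.0 ** (-b / elapsed)
    if scale == "linear":
        pred = a * decay
        r = y - pred
        # dr/da = -decay ; dr/db = a*decay*ln10/elapsed
        jac = np.zeros((len(y), n_params))
        rows = np.arange(len(y))
        np.add.at(jac, (rows, a_idx), -decay)
        np.add.at(jac, (rows, b_idx), a * decay * LN10 / elapsed)
    else:
        r = np.log10(y) - (np.log10(a) - b / elapsed)
        jac = np.zeros((len(y), n_params))
        rows = np.arange(len(y))
        np.add.at(jac, (rows, a_idx), -1.0 / (a * LN10))
        np.add.at(jac, (rows, b_idx), 1.0 / elapsed)
    return r, jac


def fit_curve(
    data: ObservationSet,
    spec: FitSpec,
    init: dict[str, float] | None = None,
) -> FitResult:
    """Fit the growth curve(s) to ``data`` under the constraints in ``spec``.

    Minimises the sum of squared residuals on the chosen scale by
    trust-region least squares with an analytic Jacobian.  Deterministic
    given (data, spec, init).  A failed optimisation is returned with
    ``converged=False`` rather than silently wrong values.

    ``init`` optionally maps parameter names (as in
    ``spec.param_names(data.groups)``) to starting values.
    """
    names = spec.param_names(data.groups)
    p = len(names)
    if len(data) < 3 * p:
        raise ValueError(
            f"need at least 3 observations per free parameter "
            f"({3 * p} for {p} parameters), got {len(data)}"
        )
    ages = data.ages()
    y = data.ldw()
    if np.all(ages == ages[0]) or np.all(y == y[0]):
        raise ValueError(
            "singular design: all ages equal or all lens weights equal; "
            "the curve parameters are not identifiable"
        )
    y, elapsed, a_idx, b_idx, n_a = _design(data, spec)

    theta0 = _default_init(data, spec)
    if init is not None:
        for i, name in enumerate(names):
            if name in init:
                theta0[i] = float(init[name])

    res = least_squares(
        lambda th: _residuals_and_jac(th, y, elapsed, a_idx, b_idx, p, spec.scale)[0],
        theta0,
        jac=lambda th: _residuals_and_jac(th, y, elapsed, a_idx, b_idx, p, spec.scale)[1],
        bounds=(np.full(p, 1e-8), np.full(p, np.inf)),
        ftol=1e-12,
        xtol=1e-10,
        gtol=1e-12,
        max_nfev=200 * (p + 1),
    )
    rss = float(res.fun @ res.fun)
    estimates = {name: float(v) for name, v in zip(names, res.x)}
    converged = bool(res.success)

    result = FitResult(
        estimates=estimates,
        standard_errors={},
        rss=rss,
        n=len(data),
        K=p + 1,
        loglik=gaussian_loglik(rss, len(data)),
        converged=converged,
        n_iter=int(res.nfev),
        scale=spec.scale,
        spec=spec,
        groups=data.groups,
    )
    if converged:
        try:
            result = replace(result, standard_errors=standard_errors(result, data, spec))
        except np.linalg.LinAlgError:
            pass  # SEs unavailable; estimates still reported
    return result


def standard_errors(
    fit: FitResult, data: ObservationSet, spec: FitSpec
) -> dict[str, float]:
    """Per-parameter standard errors from the least-squares curvature.

    cov = s² (JᵀJ)⁻¹ with the unbiased residual variance
    s² = RSS / (n − p); p = K − 1 curve parameters.  Raises
    ``numpy.linalg.LinAlgError`` naming the unidentifiable parameter when
    the Jacobian is rank deficient.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    names = spec.param_names(data.groups)
    p = len(names)
    dof = fit.n - p
    if dof <= 0:
        raise ValueError(f"no residual degrees of freedom (n={fit.n}, p={p})")
    y, elapsed, a_idx, b_idx, _ = _design(data, spec)
    theta = np.array([fit.estimates[name] for name in names])
    _, jac = _residuals_and_jac(theta, y, elapsed, a_idx, b_idx, p, spec.scale)
    jtj = jac.T @ jac
    u, s, vt = np.linalg.svd(jtj)
    if s[-1] < 1e-12 * s[0]:
        worst = names[int(np.argmax(np.abs(vt[-1])))]
        raise np.linalg.LinAlgError(
            f"rank-deficient Jacobian: parameter {worst!r} is not identifiable "
            "from this design"
        )
    s2 = fit.rss / dof
    cov = s2 * (vt.T @ np.diag(1.0 / s) @ u.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return {name: float(v) for name, v in zip(names, se)}
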