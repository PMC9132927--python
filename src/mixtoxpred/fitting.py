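"""Nonlinear least-squares fitting of dose-response curves.

Fitting is deliberately deterministic: five starting points are derived
from data quantiles (no random restarts), the best converged optimum by
residual sum of squares wins.  The parameter covariance from the Jacobian
at the optimum is stored on the returned curve and later feeds the
parametric bootstrap for confidence intervals.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .drc import FittedDRC, get_model

__all__ = ["FitError", "fit_drc"]


class FitError(RuntimeError):
    """Insufficient data or non-convergence for the named model."""


def _link_starts(model_id: str, conc: np.ndarray, eff: np.ndarray) -> list[np.ndarray]:
    """Starting points from a linearized fit on the model's own link scale.

    For the log10-concentration families the curve is linear in
    (alpha, beta) after applying the link (logit or complementary
    log-log) to the effect, so an ordinary linear regression on interior
    points gives a near-optimal start; the remaining starts perturb the
    slope and asymptote to guard against link mismatch.
    """
    model = get_model(model_id)
    logc = np.log10(conc)
    emax_obs = float(np.max(eff))
    # candidate upper asymptotes for 3/4-parameter models
    gammas = [min(1.0, max(emax_obs * f, 1e-3)) for f in (1.02, 1.15)] + [1.0]

    def lin_ab(link, gamma=1.0, delta=0.0):
        f = (eff - delta) / max(gamma - delta, 1e-9)
        mask = (f > 0.005) & (f < 0.995)
        if mask.sum() < 2:
            return np.array([0.0, 1.0])
        y = np.array([link(v) for v in f[mask]])
        A = np.vstack([np.ones(mask.sum()), logc[mask]]).T
        ab, *_ = np.linalg.lstsq(A, y, rcond=None)
        if not ab[1] > 0:
            ab[1] = 1.0
        return ab

    logit = lambda v: math.log(v / (1 - v))
    cloglog = lambda v: math.log(-math.log(1 - v))
    link = cloglog if model_id.startswith(("Weibull", "BCW")) else logit

    starts: list[np.ndarray] = []
    if model_id in ("Hill", "Hill_three", "Hill_four"):
        # EC50-style location: concentration nearest half of the asymptote
        for g in gammas[: 2 if model.n_params >= 3 else 1] + ([1.0] if model.n_params == 2 else []):
            half = g / 2.0
            loc = float(conc[np.argmin(np.abs(eff - half))])
            for slope in (1.0, 2.0):
                p = [loc, slope]
                if model.n_params >= 3:
                    p.append(g)
                if model.n_params == 4:
                    p.append(max(float(np.min(eff)) * 0.5, 0.0))
                starts.append(np.array(p))
    elif model_id == "Hill_two":
        loc = float(np.quantile(conc, 0.5))
        for g in gammas:
            for q in (0.25, 0.5, 0.75):
                starts.append(np.array([float(np.quantile(conc, q)), g]))
    elif model_id in ("BCW", "BCL"):
        ab = lin_ab(link)
        for shape in (0.1, 0.3, 1.0):
            # refit on the Box-Cox abscissa for this shape
            u = (conc**shape - 1.0) / shape
            f = eff
            mask = (f > 0.005) & (f < 0.995)
            if mask.sum() >= 2:
                y = np.array([link(v) for v in f[mask]])
                A = np.vstack([np.ones(mask.sum()), u[mask]]).T
                ab2, *_ = np.linalg.lstsq(A, y, rcond=None)
                if ab2[1] > 0:
                    starts.append(np.array([ab2[0], ab2[1], shape]))
            starts.append(np.array([ab[0], max(ab[1], 0.1), shape]))
    elif model_id == "GL":
        ab = lin_ab(logit)
        for shape in (0.5, 1.0, 2.0):
            starts.append(np.array([ab[0], ab[1], shape]))
    else:  # Weibull/Logit families
        for g in gammas[: 2 if model.n_params >= 3 else 1] + ([1.0] if model.n_params == 2 else []):
            ab = lin_ab(link, gamma=g)
            for scale in (1.0, 0.6):
                p = [ab[0], ab[1] * scale]
                if model.n_params >= 3:
                    p.append(g)
                if model.n_params == 4:
                    p.append(max(float(np.min(eff)) * 0.5, 0.0))
                starts.append(np.array(p))
    return starts[:6]


def _bounds(model_id: str, n_params: int, conc: np.ndarray):
    big = np.inf
    if model_id.startswith("Hill"):
        lo = [1e-12, 1e-6]
        hi = [big, 50.0]
        if model_id == "Hill_two":
            lo, hi = [1e-12, 1e-6], [big, 1.0]
    else:
        lo = [-big, 1e-6]
        hi = [big, 200.0]
    if n_params >= 3 and model_id in ("Hill_three", "Hill_four", "Weibull_three",
                                      "Weibull_four", "Logit_three", "Logit_four"):
        lo.append(1e-6)
        hi.append(1.0)
    elif n_params >= 3:
        lo.append(1e-6)
        hi.append(20.0)
    if n_params == 4:
        lo.append(0.0)
        hi.append(1.0 - 1e-9)
    return np.array(lo), np.array(hi)


def fit_drc(
    points: Sequence[tuple[float, float]],
    model_id: str,
    conc_unit: str = "uM",
) -> FittedDRC:
    """Least-squares fit of ``model_id`` to (concentration, effect) points.

    Requires at least arity + 1 points with strictly positive
    concentrations.  Raises :class:`FitError` when no start converges.
    """
    model = get_model(model_id)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, effect) pairs")
    if pts.shape[0] < model.n_params + 1:
        raise FitError(
            f"{model_id} needs at least {model.n_params + 1} points, got {pts.shape[0]}"
        )
    conc, eff = pts[:, 0], pts[:, 1]
    if not np.all(conc > 0):
        raise ValueError("concentrations must be strictly positive")

    def residuals(p):
        return np.array([model.forward(p, c) for c in conc]) - eff

    lo, hi = _bounds(model_id, model.n_params, conc)
    best = None
    for start in _link_starts(model_id, conc, eff):
        p0 = np.clip(start, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except (ValueError, FloatingPointError):
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1] - 1e-15:
            best = (sol, rss)
    if best is None:
        raise FitError(f"fit did not converge for model {model_id}")
    sol, rss = best

    cov = None
    dof = pts.shape[0] - model.n_params
    if dof > 0:
        J = sol.jac
        try:
            jtj_inv = np.linalg.pinv(J.T @ J)
            cov = tuple(map(tuple, jtj_inv * max(rss / dof, 1e-18)))
        except np.linalg.LinAlgError:
            cov = None

    return FittedDRC(model_id, tuple(sol.x), conc_unit, param_cov=cov, rss=rss)
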