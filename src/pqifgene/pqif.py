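"""SCAD-penalized QIF: simultaneous estimation and gene selection.

The penalized objective is U_n(beta) = Q_n(beta) + n sum_j p_lam(|beta_j|)
with Q_n on the chi-square scale (n times the quadratic form), so that the
lack-of-fit and penalty terms grow at the same rate.  The non-convex SCAD
penalty is handled by local quadratic approximation (LQA): around the current
iterate the penalty is replaced by a quadratic with curvature
p'_lam(|beta_j|)/|beta_j|, giving a penalized Newton update on the active
coordinates; coordinates whose magnitude falls below a hard threshold are set
to exactly zero and removed from the active set for the current lambda.

The tuning parameter is selected on a grid by the BIC-type criterion
BIQIF = Q_n(beta-hat) + df log(n), df being the number of nonzero
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qif import (
    LongitudinalDesign,
    QIFError,
    QIFFit,
    WorkingCorrelationBasis,
    fit_qif,
    pooled_logistic,
    qif_objective,
    qif_quadratics,
)

DEFAULT_A = 3.7          # Fan-Li convention
DEFAULT_DELTA = 1e-4     # hard-zero threshold on standardized covariates


def scad_derivative(theta, lam: float, a: float = DEFAULT_A):
    """SCAD penalty derivative p'_lam(theta) for theta >= 0.

    lam on (0, lam], linearly decaying to zero on (lam, a*lam], and exactly
    zero beyond a*lam (no shrinkage of large coefficients).
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0):
        raise ValueError("SCAD derivative takes a magnitude; pass |beta_j|")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if a <= 2:
        raise ValueError("SCAD requires a > 2")
    if lam == 0:
        out = np.zeros_like(th)
    else:
        out = np.where(
            th <= lam,
            lam,
            np.maximum(a * lam - th, 0.0) / (a - 1.0),
        )
    return float(out) if np.isscalar(theta) else out


def scad_penalty(theta, lam: float, a: float = DEFAULT_A):
    """SCAD penalty value (the integral of `scad_derivative`)."""
    th = np.abs(np.asarray(theta, dtype=float))
    if lam == 0:
        out = np.zeros_like(th)
    else:
        mid = (2.0 * a * lam * th - th**2 - lam**2) / (2.0 * (a - 1.0))
        out = np.where(
            th <= lam,
            lam * th,
            np.where(th <= a * lam, mid, (a + 1.0) * lam**2 / 2.0),
        )
    return float(out) if np.isscalar(theta) else out


@dataclass
class SCADSpec:
    """SCAD penalty configuration; the intercept is never penalized."""

    lam: float
    a: float = DEFAULT_A
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.a <= 2:
            raise ValueError("SCAD requires a > 2")
        if self.delta <= 0:
            raise ValueError("zero threshold delta must be positive")


def lqa_weights(beta, spec: SCADSpec, penalize=None) -> np.ndarray:
    """Diagonal of the LQA penalty matrix: p'(|b_j|)/|b_j| for penalized coords.

    Unpenalized coordinates get weight 0; a penalized coordinate at or below
    the zero threshold must be shrunk to exact zero by the caller first.
    """
    b = np.abs(np.asarray(beta, dtype=float))
    pen = (
        np.ones(b.shape, dtype=bool)
        if penalize is None
        else np.asarray(penalize, dtype=bool)
    )
    if np.any(pen & (b <= spec.delta)) and spec.lam > 0:
        raise ValueError(
            "penalized coordinate at/below the zero threshold: shrink it to "
            "exactly zero before forming LQA weights"
        )
    out = np.zeros_like(b)
    out[pen] = scad_derivative(b[pen], spec.lam, spec.a) / b[pen]
    return out


@dataclass
class PQIFFit:
    """SCAD-penalized fit at one lambda; zeros are exact."""

    beta: np.ndarray
    columns: list[str]
    active: np.ndarray          # bool, includes unpenalized coords
    q_n: float                  # unscaled quadratic form, full dimension
    lam: float
    df: int
    biqif: float
    n_iter: int
    converged: bool
    structure: str
    n_subjects: int

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns, name="estimate")

    @property
    def active_names(self) -> list[str]:
        return [c for c, a in zip(self.columns, self.active) if a]


def biqif(q: float, df: int, n: int) -> float:
    """BIQIF = Q_n(beta-hat) + df log(n), Q_n on the chi-square scale (n Q_n)."""
    return float(q) + df * math.log(n)


def fit_pqif(
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
    spec: SCADSpec,
    init: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PQIFFit:
    """Penalized Newton iteration with LQA and active-set shrinkage.

    The update solves [H + Pi] step = g + Pi b over the active coordinates,
    where (g, H) are the gradient/Hessian of the unscaled Q_n and Pi the LQA
    weights (the n factors of the chi-square-scale objective and the n-scaled
    penalty cancel).  Coordinates falling below ``spec.delta`` are zeroed and
    stay out for this lambda.  At lam = 0 the iteration reduces exactly to
    the unpenalized QIF fit.
    """
    p = design.p
    pen = design.penalize
    if init is None:
        try:
            init = fit_qif(design, basis).beta
        except QIFError:
            init = pooled_logistic(design)
    beta = np.asarray(init, dtype=float).copy()
    if beta.shape != (p,):
        raise ValueError(f"init has shape {beta.shape}, expected ({p},)")

    active = np.ones(p, dtype=bool)
    if spec.lam > 0:
        dead = pen & (np.abs(beta) < spec.delta)
        active[dead] = False
        beta[dead] = 0.0

    def penalty_sum(b):
        return float(np.sum(scad_penalty(np.abs(b[pen]), spec.lam, spec.a)))

    def residual(grad_b, b, act):
        # merit residual of the penalized estimating equation; the LQA weight
        # denominator is floored at delta so it is defined everywhere
        mag = np.maximum(np.abs(b[act]), spec.delta)
        pi_safe = np.zeros(int(act.sum()))
        pa = pen[act]
        pi_safe[pa] = scad_derivative(mag[pa], spec.lam, spec.a) / mag[pa]
        return np.max(np.abs(grad_b[act] + pi_safe * b[act]))

    converged = False
    it = 0
    q, grad, hess = qif_quadratics(design, basis, beta)
    for it in range(1, max_iter + 1):
        if not active.any():
            converged = True
            break
        pi = lqa_weights(beta[active], spec, penalize=pen[active])
        Ha = hess[np.ix_(active, active)] + np.diag(pi)
        ga = grad[active] + pi * beta[active]
        try:
            step = np.linalg.solve(Ha, ga)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Ha, ga, rcond=None)[0]
        if not np.isfinite(step).all():
            raise QIFError("penalized Newton step is not finite")
        obj0 = q + penalty_sum(beta)
        res0 = residual(grad, beta, active)
        scale = 1.0
        accepted = None
        for _ in range(21):
            cand = beta.copy()
            cand[active] = beta[active] - scale * step
            try:
                q2, g2, h2 = qif_quadratics(design, basis, cand)
            except QIFError:
                q2 = np.inf
            if np.isfinite(q2) and (
                q2 + penalty_sum(cand) <= obj0 + 1e-12 * (1.0 + abs(obj0))
                or residual(g2, cand, active) <= res0
            ):
                accepted = (cand, q2, g2, h2)
                break
            scale *= 0.5
        if accepted is None:
            break
        beta_new, q, grad, hess = accepted
        if spec.lam > 0:
            kill = active & pen & (np.abs(beta_new) < spec.delta)
            if kill.any():
                beta_new[kill] = 0.0
                active[kill] = False
                q, grad, hess = qif_quadratics(design, basis, beta_new)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    q_final = qif_objective(design, basis, beta)
    df = int(np.count_nonzero(beta))
    return PQIFFit(
        beta=beta,
        columns=list(design.columns),
        active=beta != 0.0,
        q_n=q_final,
        lam=spec.lam,
        df=df,
        biqif=biqif(design.n * q_final, df, design.n),
        n_iter=it,
        converged=converged,
        structure=basis.structure,
        n_subjects=design.n,
    )


def lambda_grid(lam_max: float, size: int = 100, lam_min: float = 0.01) -> np.ndarray:
    """Equally spaced inclusive grid on [lam_min, lam_max]."""
    if lam_max <= lam_min:
        raise ValueError(f"lambda_max ({lam_max}) must exceed lambda_min ({lam_min})")
    if size < 2:
        raise ValueError("grid needs at least two points")
    return np.linspace(lam_min, lam_max, size)


def find_lambda_max(
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
    a: float = DEFAULT_A,
    delta: float = DEFAULT_DELTA,
    init: np.ndarray | None = None,
    bisect_steps: int = 20,
) -> float:
    """Smallest lambda at which the penalized active set is empty (bisection)."""
    if init is None:
        init = fit_qif(design, basis).beta
    pen = design.penalize

    def empty_at(lam: float) -> bool:
        fit = fit_pqif(design, basis, SCADSpec(lam, a, delta), init=init)
        return not np.any(fit.active & pen)

    hi = 0.5
    for _ in range(8):
        if empty_at(hi):
            break
        hi *= 2.0
    else:
        raise QIFError("could not bracket lambda_max (active set never empties)")
    lo = 0.01
    for _ in range(bisect_steps):
        mid = 0.5 * (lo + hi)
        if empty_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class LambdaPath:
    """Fits along a lambda grid with the BIQIF-selected model."""

    lams: np.ndarray
    fits: list[PQIFFit]
    selected_index: int
    qif_fit: QIFFit | None = None

    @property
    def selected(self) -> PQIFFit:
        return self.fits[self.selected_index]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lams,
                "biqif": [f.biqif for f in self.fits],
                "df": [f.df for f in self.fits],
                "q_n": [f.q_n for f in self.fits],
                "converged": [f.converged for f in self.fits],
                "active": [",".join(f.active_names) for f in self.fits],
            }
        )


def select_model(
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
    lams,
    a: float = DEFAULT_A,
    delta: float = DEFAULT_DELTA,
    tol: float = 1e-10,
    max_iter: int = 500,
    qif_init: QIFFit | None = None,
) -> LambdaPath:
    """Fit the full lambda path and select the BIQIF-minimizing model.

    Fits are warm-started from the previous lambda's solution; coordinates
    that were zeroed there are re-activated at the unpenalized QIF estimate
    (an exact zero cannot re-enter an LQA iteration).  BIQIF ties are broken
    toward the larger lambda, i.e. the sparser model.
    """
    lams = np.asarray(lams, dtype=float)
    if lams.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(np.diff(lams) <= 0):
        raise ValueError("lambda grid must be strictly increasing")
    qif_fit = qif_init if qif_init is not None else fit_qif(design, basis)
    prev = qif_fit.beta
    fits: list[PQIFFit] = []
    for lam in lams:
        init = np.where(np.abs(prev) > delta, prev, qif_fit.beta)
        fit = fit_pqif(
            design, basis, SCADSpec(float(lam), a, delta),
            init=init, tol=tol, max_iter=max_iter,
        )
        fits.append(fit)
        prev = fit.beta
    usable = [i for i, f in enumerate(fits) if f.converged]
    if not usable:
        raise QIFError("no lambda on the grid produced a convergent fit")
    best = usable[0]
    for i in usable[1:]:
        if fits[i].biqif <= fits[best].biqif:
            best = i
    return LambdaPath(lams=lams, fits=fits, selected_index=best, qif_fit=qif_fit)
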