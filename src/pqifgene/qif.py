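"""Quadratic inference functions for marginal longitudinal models.

The marginal model is E(Y_it) = mu_it with g(mu_it) = x_it' beta for a
binary (logit link) or continuous (identity link) response observed over a
grid of T visits.  Instead of estimating the intra-subject correlation, the
inverse working correlation is expanded on basis matrices,

    R^{-1}(rho) ~ a_0 I + a_1 M_1 + ... + a_S M_S,

and the extended per-subject score stacks the quasi-score contribution of
each basis block.  The estimator minimizes the generalized method of moments
quadratic form

    Q_n(beta) = psibar_n' Cbar_n^{-1} psibar_n,

whose minimizer is efficient within the span of the basis even when the
working correlation is misspecified.  Unbalanced panels are handled by
selection ("transformation") matrices that restrict each subject's score to
the observed visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import expit

STRUCTURES = ("independent", "ar1", "exchangeable")

# Ridge added to Cbar before inversion, relative to its mean eigenvalue.
_CBAR_RIDGE = 1e-8
_MAX_COND = 1e12


class QIFError(RuntimeError):
    pass


@dataclass
class WorkingCorrelationBasis:
    """Basis matrices M_1..M_S for the inverse working correlation.

    The identity is always the implicit first block; ``matrices`` holds only
    the non-identity members, so S = 0 for independence and S = 1 for the
    exchangeable and AR(1) structures used here.
    """

    structure: str
    matrices: list[np.ndarray]

    @property
    def n_blocks(self) -> int:
        return 1 + len(self.matrices)


def basis_matrices(structure: str, T: int) -> WorkingCorrelationBasis:
    """Construct the working-correlation basis for a T-visit grid.

    independent: identity only; exchangeable: ones off the diagonal; AR(1):
    ones on the first sub/super-diagonal (the common two-term expansion,
    without the corner-correction matrix).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown working correlation structure {structure!r}")
    if structure == "independent":
        return WorkingCorrelationBasis(structure, [])
    if T < 2:
        raise ValueError(f"{structure!r} basis requires at least T=2 visits")
    if structure == "exchangeable":
        m = np.ones((T, T)) - np.eye(T)
    else:  # ar1
        m = np.zeros((T, T))
        idx = np.arange(T - 1)
        m[idx, idx + 1] = 1.0
        m[idx + 1, idx] = 1.0
    return WorkingCorrelationBasis(structure, [m])


def transformation_matrix(mask, T: int) -> np.ndarray:
    """0/1 selector mapping the full T-visit grid to the observed visits.

    ``mask`` is the set of observed visit numbers (1-based).  A fully
    observed subject gets the T x T identity; otherwise the |mask| x T
    matrix selecting the observed rows, so A* = H A H' stays invertible.
    """
    obs = sorted(set(int(t) for t in mask))
    if not obs:
        raise QIFError("empty visit mask: subject must be dropped upstream")
    if obs[0] < 1 or obs[-1] > T:
        raise ValueError(f"visit mask {obs} outside 1..{T}")
    h = np.zeros((len(obs), T))
    h[np.arange(len(obs)), np.array(obs) - 1] = 1.0
    return h


@dataclass
class LongitudinalDesign:
    """Responses and covariates on a common T-visit grid.

    ``y`` and ``X`` are padded over the full grid; ``mask`` marks observed
    visits.  The first covariate column is the intercept, which is never
    penalized.
    """

    y: np.ndarray            # (n, T), NaN at unobserved visits
    X: np.ndarray            # (n, T, p)
    mask: np.ndarray         # (n, T) bool
    columns: list[str]
    subjects: list[str] = field(default_factory=list)
    link: str = "logit"
    penalize: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, T = self.y.shape
        if self.X.shape[:2] != (n, T):
            raise ValueError("X and y shapes disagree")
        if self.mask.shape != (n, T):
            raise ValueError("mask shape disagrees with y")
        if len(self.columns) != self.X.shape[2]:
            raise ValueError("column names do not match X")
        if not self.subjects:
            self.subjects = [str(i) for i in range(n)]
        if self.link not in ("logit", "identity"):
            raise ValueError(f"unsupported link {self.link!r}")
        if not self.mask.any(axis=1).all():
            bad = [self.subjects[i] for i in np.flatnonzero(~self.mask.any(axis=1))]
            raise QIFError(f"subjects with no observed visits: {bad}")
        if self.penalize is None:
            pen = np.ones(self.p, dtype=bool)
            pen[0] = False
            self.penalize = pen
        else:
            self.penalize = np.asarray(self.penalize, dtype=bool)
        obs = self.mask
        if not np.isfinite(self.X[obs]).all():
            raise ValueError("non-finite covariates at observed visits")
        if not np.isfinite(self.y[obs]).all():
            raise ValueError("non-finite responses at observed visits")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[2]

    @property
    def balanced(self) -> bool:
        return bool(self.mask.all())

    def subset(self, columns: list[str]) -> "LongitudinalDesign":
        """Design restricted to the given covariate columns (intercept kept)."""
        keep = [c for c in self.columns if c == self.columns[0] or c in columns]
        idx = [self.columns.index(c) for c in keep]
        return LongitudinalDesign(
            y=self.y,
            X=self.X[:, :, idx],
            mask=self.mask,
            columns=keep,
            subjects=list(self.subjects),
            link=self.link,
            penalize=self.penalize[idx],
        )

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject_col: str = "subject_id",
        time_col: str = "visit",
        response_col: str = "response",
        covariates: list[str] | None = None,
        T: int | None = None,
        standardize: bool = True,
        link: str = "logit",
    ) -> "LongitudinalDesign":
        """Build a padded design from a long-format table.

        Missing visits are simply absent as rows.  Covariates are
        standardized (mean 0, sd 1 over the observed rows) unless disabled.
        """
        if covariates is None:
            covariates = [
                c for c in df.columns if c not in (subject_col, time_col, response_col)
            ]
        visits = df[time_col].astype(int)
        T = int(T or visits.max())
        subjects = list(dict.fromkeys(df[subject_col].astype(str)))
        sidx = {s: i for i, s in enumerate(subjects)}
        n, p = len(subjects), len(covariates) + 1
        y = np.full((n, T), np.nan)
        X = np.zeros((n, T, p))
        X[:, :, 0] = 1.0
        mask = np.zeros((n, T), dtype=bool)
        cov = df[covariates].to_numpy(dtype=float)
        if standardize:
            mu = cov.mean(axis=0)
            sd = cov.std(axis=0)
            if np.any(sd == 0):
                flat = [covariates[j] for j in np.flatnonzero(sd == 0)]
                raise ValueError(f"constant covariates cannot be standardized: {flat}")
            cov = (cov - mu) / sd
        rows = df[subject_col].astype(str).map(sidx).to_numpy()
        tcol = visits.to_numpy() - 1
        if tcol.min() < 0 or tcol.max() >= T:
            raise ValueError(f"visit numbers outside 1..{T}")
        y[rows, tcol] = df[response_col].to_numpy(dtype=float)
        mask[rows, tcol] = True
        X[rows, tcol, 1:] = cov
        return cls(
            y=y, X=X, mask=mask, columns=["intercept"] + list(covariates),
            subjects=subjects, link=link,
        )


# ---------------------------------------------------------------------------
# Score machinery


def _mask_groups(design: LongitudinalDesign):
    """Group subject indices by identical observation masks (vectorization)."""
    if design.balanced:
        return [(np.arange(design.n), np.arange(design.T))]
    patterns: dict[tuple, list[int]] = {}
    for i, row in enumerate(design.mask):
        patterns.setdefault(tuple(row.tolist()), []).append(i)
    return [
        (np.array(idx), np.flatnonzero(np.array(key)))
        for key, idx in patterns.items()
    ]


def _mean_var(design, Xg, beta):
    eta = Xg @ beta
    if design.link == "logit":
        mu = expit(eta)
        a = mu * (1.0 - mu)
    else:
        mu = eta
        a = np.ones_like(eta)
    return mu, a


def extended_scores(
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
    beta: np.ndarray,
    jacobian: bool = False,
):
    """Per-subject extended scores psi_i (n x (1+S)p), optionally with Jbar.

    Each block is mudot*' A*^{-1/2} M_s A*^{-1/2} (Y* - mu*) with starred
    quantities restricted to the observed visits; Jbar is the averaged
    Gauss-Newton Jacobian d psibar / d beta.
    """
    beta = np.asarray(beta, dtype=float)
    n, p, S = design.n, design.p, len(basis.matrices)
    d = (1 + S) * p
    psi = np.zeros((n, d))
    jbar = np.zeros((d, p)) if jacobian else None
    for idx, obs in _mask_groups(design):
        if len(idx) == n and len(obs) == design.T:
            Xg, Yg = design.X, design.y          # balanced: no copy
        else:
            Xg = design.X[np.ix_(idx, obs)]      # (ng, k, p)
            Yg = design.y[np.ix_(idx, obs)]      # (ng, k)
        mu, a = _mean_var(design, Xg, beta)
        if np.min(a) < 1e-12:
            i_bad = idx[int(np.argmin(np.min(a, axis=1)))]
            raise QIFError(
                f"fitted mean numerically 0 or 1 for subject "
                f"{design.subjects[i_bad]!r}; A_i is not invertible"
            )
        r = Yg - mu
        b = np.sqrt(a)
        ng, k = Yg.shape
        Xf = Xg.reshape(ng * k, p)
        psi[idx, :p] = np.einsum("ntp,nt->np", Xg, r)
        if jacobian:
            jbar[:p] -= Xf.T @ (a.reshape(-1, 1) * Xf)
        for s, M in enumerate(basis.matrices):
            Ms = M[np.ix_(obs, obs)]
            w = b * ((r / b) @ Ms.T)
            psi[idx, (s + 1) * p : (s + 2) * p] = np.einsum("ntp,nt->np", Xg, w)
            if jacobian:
                U = b[..., None] * Xg
                V = np.matmul(Ms, U)           # (ng, k, p), broadcast over subjects
                jbar[(s + 1) * p : (s + 2) * p] -= (
                    U.reshape(ng * k, p).T @ V.reshape(ng * k, p)
                )
    if jacobian:
        jbar /= n
        return psi, jbar
    return psi


def extended_score(
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
    beta: np.ndarray,
    subject: int,
) -> np.ndarray:
    """Extended score vector of a single subject."""
    return extended_scores(design, basis, beta)[subject]


def _cbar_solve(psi: np.ndarray, check_cond: bool = False):
    """Factor Cbar (with relative ridge) and return a solve closure + Cbar.

    The explicit condition-number check is reserved for user-facing entry
    points; inner Newton iterations rely on the Cholesky factorization
    itself to reject an unusable Cbar.
    """
    n, d = psi.shape
    cbar = psi.T @ psi / n
    scale = np.trace(cbar) / d
    if scale <= 0.0:
        scale = 1.0  # all scores exactly zero (perfect fit): any PD ridge works
    cbar = cbar + _CBAR_RIDGE * scale * np.eye(d)
    try:
        factor = cho_factor(cbar)
    except LinAlgError as exc:
        raise QIFError("Cbar_n is singular beyond ridge repair") from exc
    if check_cond and np.linalg.cond(cbar) > _MAX_COND:
        raise QIFError("Cbar_n condition number exceeds 1e12 after ridging")
    return lambda b: cho_solve(factor, b), cbar


def qif_objective(
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
    beta: np.ndarray,
) -> float:
    """Q_n(beta) = psibar' Cbar^{-1} psibar (n * Q_n is on the chi-square scale)."""
    psi = extended_scores(design, basis, beta)
    solve, _ = _cbar_solve(psi, check_cond=True)
    psibar = psi.mean(axis=0)
    return float(psibar @ solve(psibar))


def _objective_or_inf(design, basis, beta) -> float:
    try:
        return qif_objective(design, basis, beta)
    except (QIFError, FloatingPointError):
        return np.inf


def qif_quadratics(design, basis, beta):
    """Objective, gradient 2 Jbar' Cinv psibar and Hessian 2 Jbar' Cinv Jbar."""
    psi, jbar = extended_scores(design, basis, beta, jacobian=True)
    solve, _ = _cbar_solve(psi)
    psibar = psi.mean(axis=0)
    ci_psibar = solve(psibar)
    q = float(psibar @ ci_psibar)
    grad = 2.0 * jbar.T @ ci_psibar
    hess = 2.0 * jbar.T @ solve(jbar)
    return q, grad, hess


@dataclass
class QIFFit:
    """Result of minimizing Q_n."""

    beta: np.ndarray
    columns: list[str]
    q_n: float
    n_iter: int
    converged: bool
    structure: str
    n_subjects: int
    stderr: np.ndarray | None = None

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns, name="estimate")


def pooled_logistic(design: LongitudinalDesign) -> np.ndarray:
    """Pooled regression on the stacked observed rows (independence init)."""
    obs = design.mask
    X = design.X[obs]
    y = design.y[obs]
    if design.link == "identity":
        return np.linalg.lstsq(X, y, rcond=None)[0]
    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        beta = np.asarray(res.params, dtype=float)
        if np.isfinite(beta).all():
            return beta
    except Exception:
        pass
    return np.zeros(design.p)


def _solve_step(hess, grad):
    try:
        return np.linalg.solve(hess, grad)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(hess, grad, rcond=None)[0]


def fit_qif(
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
    init: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> QIFFit:
    """Minimize Q_n by damped Newton-Raphson.

    Gradient and Hessian use the Gauss-Newton forms 2 Jbar' Cinv psibar and
    2 Jbar' Cinv Jbar with Cbar re-evaluated at each iterate.  The Newton
    step is halved (up to 20 times) unless it decreases the objective or the
    gradient residual: near the fixed point of the estimating equation Q_n
    itself can rise by rounding-level amounts, so monotonicity of the
    residual norm is accepted as progress.  Initialization defaults to the
    pooled (independence) regression estimate.
    """
    beta = np.asarray(init, dtype=float) if init is not None else pooled_logistic(design)
    if beta.shape != (design.p,):
        raise ValueError(f"init has shape {beta.shape}, expected ({design.p},)")

    q, grad, hess = qif_quadratics(design, basis, beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        step = _solve_step(hess, grad)
        if not np.isfinite(step).all():
            raise QIFError("Newton step is not finite (exploding objective)")
        gnorm = np.max(np.abs(grad))
        scale = 1.0
        accepted = None
        for _ in range(21):
            cand = beta - scale * step
            try:
                q2, g2, h2 = qif_quadratics(design, basis, cand)
            except QIFError:
                q2 = np.inf
            if np.isfinite(q2) and (
                q2 <= q + 1e-12 * (1.0 + abs(q)) or np.max(np.abs(g2)) <= gnorm
            ):
                accepted = (cand, q2, g2, h2)
                break
            scale *= 0.5
        if accepted is None:
            # no productive direction left: stop at the current iterate
            break
        cand, q, grad, hess = accepted
        delta = np.max(np.abs(cand - beta))
        beta = cand
        if delta < tol:
            converged = True
            break

    q_final = qif_objective(design, basis, beta)
    if not np.isfinite(q_final):
        raise QIFError("objective diverged during QIF fit")
    return QIFFit(
        beta=beta,
        columns=list(design.columns),
        q_n=q_final,
        n_iter=n_iter,
        converged=converged,
        structure=basis.structure,
        n_subjects=design.n,
    )


def qif_stderr(
    fit: QIFFit,
    design: LongitudinalDesign,
    basis: WorkingCorrelationBasis,
) -> np.ndarray:
    """Sandwich standard errors sqrt(diag((n Jbar' Cinv Jbar)^{-1})) at beta-hat."""
    psi, jbar = extended_scores(design, basis, fit.beta, jacobian=True)
    solve, _ = _cbar_solve(psi)
    info = design.n * (jbar.T @ solve(jbar))
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise QIFError("singular information matrix; standard errors unavailable") from exc
    var = np.diag(cov)
    if np.any(var <= 0):
        raise QIFError("non-positive variance estimate; information not PD")
    se = np.sqrt(var)
    fit.stderr = se
    return se
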