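"""Replicate-level experiment runner and evaluation metrics.

For each replicate the harness simulates a dataset, fits the unpenalized
QIF, the SCAD-penalized QIF with BIQIF-tuned lambda, and the oracle QIF
(true support known), then aggregates estimation and selection metrics:

* TMSE: replicate-averaged ||beta-hat - beta||^2 / p over all p covariates;
* NMSE: the same restricted to the zero-effect noise-gene coordinates;
* TP / FP rates: per-replicate fractions of true-support (resp. null)
  coordinates selected, averaged over replicates;
* per-variable selection frequencies.

Replicates are independent given per-replicate seeds derived from the master
seed, so results do not depend on execution order.  Non-convergent
replicates are counted and excluded from the averages (mirroring how
small-sample, high-dimension cells are treated), and the run errors out if
more than half of the replicates fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pqif import select_model, lambda_grid
from .qif import QIFError, basis_matrices, fit_qif
from .simulate import SimulationScenario, build_dataset, default_lambda_max


def tmse(estimates, truth) -> float:
    """Mean over replicates of ||beta-hat - beta||^2 / p."""
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if est.shape[1] != truth.size:
        raise ValueError(
            f"estimate dimension {est.shape[1]} does not match truth {truth.size}"
        )
    return float(np.mean(np.sum((est - truth) ** 2, axis=1)) / truth.size)


def nmse(estimates, truth, noise_indices) -> float:
    """TMSE restricted to the zero-effect noise-gene coordinates."""
    idx = np.asarray(noise_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty noise-coordinate set")
    est = np.atleast_2d(np.asarray(estimates, dtype=float))[:, idx]
    truth = np.asarray(truth, dtype=float)[idx]
    return tmse(est, truth)


def tp_fp_rates(active_sets, support, p: int) -> tuple[float, float]:
    """Averaged per-replicate fractions of selected true/null coordinates."""
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise ValueError("empty true support")
    null = np.setdiff1d(np.arange(p), support)
    tps, fps = [], []
    for act in active_sets:
        act = np.asarray(act)
        if act.dtype != bool:
            sel = np.zeros(p, dtype=bool)
            sel[np.asarray(act, dtype=int)] = True
        else:
            sel = act
        tps.append(sel[support].mean())
        fps.append(sel[null].mean() if null.size else 0.0)
    return float(np.mean(tps)), float(np.mean(fps))


@dataclass
class ReplicateResult:
    seed: int
    beta_qif: np.ndarray | None
    beta_pqif: np.ndarray | None
    beta_oracle: np.ndarray | None
    active: np.ndarray | None            # bool over the p covariates
    converged: dict = field(default_factory=dict)
    selected_lambda: float | None = None


@dataclass
class StudySummary:
    """Aggregated metrics over replicates for each fitted method."""

    scenario: SimulationScenario
    working: str
    tmse: dict
    nmse: dict
    tp_rate: float | None
    fp_rate: float | None
    mean_fp_count: float | None
    selection_freq: pd.Series | None
    n_replicates: int
    n_failed: dict
    estimates: dict = field(repr=False, default_factory=dict)
    replicates: list = field(repr=False, default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "working_correlation": self.working,
            "n": self.scenario.n,
            "p": self.scenario.p,
            "rho": self.scenario.rho,
            "replicate_count": self.n_replicates,
            "failed": self.n_failed,
            "tmse": self.tmse,
            "nmse": self.nmse,
            "tp_rate": self.tp_rate,
            "fp_rate": self.fp_rate,
            "mean_fp_count": self.mean_fp_count,
        }


def replicate_seeds(master_seed: int, replicates: int) -> np.ndarray:
    """Deterministic per-replicate integer seeds (independent of order)."""
    return np.random.default_rng(master_seed).integers(
        0, 2**31 - 1, size=replicates
    )


def run_study(
    scenario: SimulationScenario,
    replicates: int | None = None,
    seed: int | None = None,
    working: str | None = None,
    methods: tuple = ("qif", "pqif", "oracle"),
    grid_size: int | None = None,
    tol_qif: float = 1e-12,
    tol_pqif: float = 1e-10,
    max_iter_qif: int = 200,
    max_iter_pqif: int = 500,
) -> StudySummary:
    """Run the full replicate study for one scenario cell."""
    replicates = int(replicates or scenario.replicates)
    seed = scenario.seed if seed is None else seed
    working = working or scenario.structure
    lam_max = scenario.lambda_max or default_lambda_max(scenario.n)
    lams = lambda_grid(lam_max, grid_size or scenario.grid_size, scenario.lambda_min)
    basis = basis_matrices(working, scenario.T)
    truth = scenario.truth
    support = scenario.support
    p = scenario.p

    results: list[ReplicateResult] = []
    for rep_seed in replicate_seeds(seed, replicates):
        rep_seed = int(rep_seed)
        ds = build_dataset(scenario, np.random.default_rng(rep_seed))
        res = ReplicateResult(seed=rep_seed, beta_qif=None, beta_pqif=None,
                              beta_oracle=None, active=None)
        qif_fit = None
        if "qif" in methods or "pqif" in methods:
            try:
                qif_fit = fit_qif(ds.design, basis, tol=tol_qif, max_iter=max_iter_qif)
                res.converged["qif"] = qif_fit.converged
                if qif_fit.converged:
                    res.beta_qif = qif_fit.beta[1:]
            except QIFError:
                res.converged["qif"] = False
        if "pqif" in methods:
            try:
                path = select_model(
                    ds.design, basis, lams, tol=tol_pqif, max_iter=max_iter_pqif,
                    qif_init=qif_fit if (qif_fit and qif_fit.converged) else None,
                )
                sel = path.selected
                res.converged["pqif"] = sel.converged
                res.beta_pqif = sel.beta[1:]
                res.active = sel.active[1:]
                res.selected_lambda = sel.lam
            except QIFError:
                res.converged["pqif"] = False
        if "oracle" in methods:
            sub = ds.design.subset(scenario.support_names)
            try:
                ofit = fit_qif(sub, basis, tol=tol_qif, max_iter=max_iter_qif)
                res.converged["oracle"] = ofit.converged
                if ofit.converged:
                    full = np.zeros(p)
                    for name, b in zip(ofit.columns[1:], ofit.beta[1:]):
                        full[scenario.columns.index(name)] = b
                    res.beta_oracle = full
            except QIFError:
                res.converged["oracle"] = False
        results.append(res)

    estimates = {
        "qif": [r.beta_qif for r in results if r.beta_qif is not None],
        "pqif": [r.beta_pqif for r in results if r.beta_pqif is not None],
        "oracle": [r.beta_oracle for r in results if r.beta_oracle is not None],
    }
    n_failed = {
        m: sum(1 for r in results if r.converged.get(m) is False)
        for m in methods
    }
    for m in methods:
        if n_failed[m] > replicates / 2:
            raise QIFError(
                f"{m} failed to converge in {n_failed[m]}/{replicates} replicates"
            )

    tmses = {m: tmse(estimates[m], truth) for m in methods if estimates[m]}
    noise_idx = scenario.noise_gene_indices
    nmses = {m: nmse(estimates[m], truth, noise_idx) for m in methods if estimates[m]}

    tp = fp = mean_fp = sel_freq = None
    actives = [r.active for r in results if r.active is not None]
    if actives:
        tp, fp = tp_fp_rates(actives, support, p)
        n_null = p - support.size
        mean_fp = fp * n_null
        sel_freq = pd.Series(
            np.mean(np.vstack(actives), axis=0), index=scenario.columns,
            name="selection_frequency",
        )

    return StudySummary(
        scenario=scenario,
        working=working,
        tmse=tmses,
        nmse=nmses,
        tp_rate=tp,
        fp_rate=fp,
        mean_fp_count=mean_fp,
        selection_freq=sel_freq,
        n_replicates=replicates,
        n_failed=n_failed,
        estimates={m: np.vstack(v) for m, v in estimates.items() if v},
        replicates=results,
    )
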