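"""Calibration of the translation models to Se-titration expression data.

Fitting works on the *normalized* steady-state dose-response: per condition,
the model's steady-state total mRNA divided by its own prediction at the
no-added-selenium (NoSe) reference is compared with the observed condition
mean of the NoSe-normalized replicates, weighted by the standard error.  Only
normalized observables are fitted, so the absolute transcription/decay scale
(``v_txn``, ``d_bg``) is fixed at literature-scale defaults and the free
parameters default to the competition rates at the UGA:
``k_bind``, ``k_nmd``, ``k_sec`` (plus ``k_drop`` for M2/M3), on a log scale.

Optimization mirrors a multistart hybrid strategy: each start samples a
log-uniform point within bounds and then alternates one global evolutionary
phase (differential evolution seeded around the incumbent) with one
bound-constrained local least-squares phase (trust-region reflective), until
the objective improves by less than a relative tolerance or a round limit is
hit.  Model variants fitted to the same data slice are ranked by the Bayesian
information criterion ``BIC = chi^2 + k_free * ln(n_data)`` (Gaussian
likelihood with known standard errors, constants dropped) — absolute BIC
values are therefore comparable only within one run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .datasets import ExpressionDataset
from .features import TranscriptFeatures
from .models import (
    ModelError,
    RateParameters,
    SeCondition,
    SeMap,
    SteadyStateError,
    steady_state_total,
)

__all__ = [
    "CalibrationError",
    "DEFAULT_FREE_PARAMS",
    "DEFAULT_BOUNDS",
    "FitProblem",
    "StartRecord",
    "FitResult",
    "make_fit_problem",
    "weighted_residuals",
    "chi_squared",
    "multistart_fit",
    "bic_score",
    "compare_models",
]

#: Default free parameters by model variant (log-scale fitting).
DEFAULT_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "M1": ("k_bind", "k_nmd", "k_sec"),
    "M1B": ("k_bind", "k_nmd", "k_sec"),
    "M2": ("k_bind", "k_nmd", "k_sec", "k_drop"),
    "M3": ("k_bind", "k_nmd", "k_sec", "k_drop"),
}

#: Default physiological ranges (natural scale).  The NMD commitment rate is
#: bounded at 3/h (decay committed on the minutes-to-hours scale); all ranges
#: are config-exposed and can be overridden per problem.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_bind": (1e-1, 1e3),
    "k_nmd": (1e-4, 3.0),
    "k_sec": (0.5, 200.0),
    "k_drop": (1e-4, 200.0),
}

_PENALTY_RESIDUAL = 1e6


class CalibrationError(ValueError):
    """Invalid fit setup (zero errors, missing conditions, mixed datasets...)."""


@dataclass(frozen=True)
class FitProblem:
    """One gene x model fitting task on a fixed dataset slice."""

    gene_id: str
    model_id: str
    features: TranscriptFeatures
    base_params: RateParameters
    free_names: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    conditions: tuple[SeCondition, ...]
    obs_mean: np.ndarray  # NoSe-normalized condition means
    obs_se: np.ndarray
    dataset_hash: str

    @property
    def n_data(self) -> int:
        return len(self.conditions)

    @property
    def k_free(self) -> int:
        return len(self.free_names)

    @property
    def reference_index(self) -> int:
        for i, c in enumerate(self.conditions):
            if c.selenite_nM == 0:
                return i
        raise CalibrationError("no 0 nM reference condition in problem")


def make_fit_problem(
    dataset: ExpressionDataset,
    gene_id: str,
    model_id: str,
    features: TranscriptFeatures | None = None,
    se_map: SeMap | None = None,
    free: Sequence[str] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    base_params: RateParameters | None = None,
    pool_variance: bool = False,
) -> FitProblem:
    """Build a fit problem from a dataset slice for one gene and model.

    Observed normalized means/SEs are derived from the raw replicate
    abundances: ``mean_c / mean_0`` with SE ``sd_c / (mean_0 * sqrt(n))``
    (delta method, reference uncertainty neglected).  A condition with zero
    replicate spread makes the weights ill-defined; pass ``pool_variance=True``
    to use the pooled across-condition SD instead.
    """
    if model_id not in DEFAULT_FREE_PARAMS:
        raise CalibrationError(f"unsupported model_id {model_id!r}")
    if features is None:
        raise CalibrationError("make_fit_problem requires the gene's TranscriptFeatures")
    if features.gene_id != gene_id:
        raise CalibrationError(
            f"features are for gene {features.gene_id!r}, expected {gene_id!r}"
        )
    se_map = se_map or SeMap()
    base_params = base_params or RateParameters()
    if model_id in ("M1", "M1B") and base_params.k_drop != 0:
        base_params = base_params.replace(k_drop=0.0)

    stats = dataset.condition_stats()
    stats = stats[stats["gene_id"] == gene_id].sort_values("selenite_nM")
    if stats.empty:
        raise CalibrationError(f"gene {gene_id!r} not present in dataset")
    concs = stats["selenite_nM"].to_numpy(float)
    if 0.0 not in concs:
        raise CalibrationError(f"gene {gene_id!r}: missing 0 nM reference condition")
    means = stats["abundance_mean"].to_numpy(float)
    sds = stats["abundance_sd"].to_numpy(float)
    ns = stats["n"].to_numpy(float)
    if (ns < 2).any():
        raise CalibrationError(f"gene {gene_id!r}: need >= 2 replicates per condition")
    if (sds == 0).any():
        if not pool_variance:
            bad = concs[sds == 0]
            raise CalibrationError(
                f"gene {gene_id!r}: zero replicate SD at condition(s) {bad.tolist()} nM; "
                "weights undefined — consider pool_variance=True"
            )
        pooled = float(np.sqrt(np.mean(sds[sds > 0] ** 2))) if (sds > 0).any() else 1.0
        sds = np.where(sds == 0, pooled, sds)

    ref_mean = means[concs == 0.0][0]
    obs_mean = means / ref_mean
    obs_se = sds / (ref_mean * np.sqrt(ns))

    free_names = tuple(free) if free is not None else DEFAULT_FREE_PARAMS[model_id]
    merged_bounds = dict(DEFAULT_BOUNDS)
    merged_bounds.update(dict(base_params.bounds))
    if bounds:
        merged_bounds.update(dict(bounds))
    for name in free_names:
        if name not in merged_bounds:
            raise CalibrationError(f"free parameter {name!r} has no bounds")
        lo, hi = merged_bounds[name]
        if not (0 < lo < hi) or not np.isfinite(hi):
            raise CalibrationError(f"free parameter {name!r} needs finite positive bounds")

    conditions = tuple(
        SeCondition(float(c), se_map.level(float(c))) for c in concs
    )
    return FitProblem(
        gene_id=gene_id,
        model_id=model_id,
        features=features,
        base_params=base_params,
        free_names=free_names,
        bounds={k: merged_bounds[k] for k in free_names},
        conditions=conditions,
        obs_mean=obs_mean,
        obs_se=obs_se,
        dataset_hash=dataset.content_hash(),
    )


def weighted_residuals(problem: FitProblem, values: Mapping[str, float]) -> np.ndarray:
    """SE-weighted residuals of the normalized steady-state dose-response."""
    params = problem.base_params.replace(**{k: float(v) for k, v in values.items()})
    try:
        totals = np.array(
            [
                steady_state_total(problem.model_id, params, problem.features, c.trna_sec_level)
                for c in problem.conditions
            ]
        )
    except (SteadyStateError, ModelError):
        return np.full(problem.n_data, _PENALTY_RESIDUAL)
    ref = totals[problem.reference_index]
    if not np.isfinite(ref) or ref <= 0:
        return np.full(problem.n_data, _PENALTY_RESIDUAL)
    model_norm = totals / ref
    return (model_norm - problem.obs_mean) / problem.obs_se


def chi_squared(problem: FitProblem, values: Mapping[str, float]) -> float:
    r = weighted_residuals(problem, values)
    return float(r @ r)


@dataclass(frozen=True)
class StartRecord:
    start_values: dict[str, float]
    chi2: float
    converged: bool


@dataclass
class FitResult:
    """Best-fit parameters with objective, BIC and multistart provenance."""

    gene_id: str
    model_id: str
    params: RateParameters
    features: TranscriptFeatures
    values: dict[str, float]
    chi2: float
    n_data: int
    k_free: int
    bic: float
    starts: list[StartRecord]
    seed: int | None
    dataset_hash: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_id": self.gene_id,
            "model_id": self.model_id,
            "values": self.values,
            "chi2": self.chi2,
            "n_data": self.n_data,
            "k_free": self.k_free,
            "bic": self.bic,
            "seed": self.seed,
            "dataset_hash": self.dataset_hash,
            "starts": [dataclasses.asdict(s) for s in self.starts],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _log_bounds(problem: FitProblem) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([problem.bounds[n][0] for n in problem.free_names])
    hi = np.array([problem.bounds[n][1] for n in problem.free_names])
    return np.log10(lo), np.log10(hi)


def _values_from_log(problem: FitProblem, x: np.ndarray) -> dict[str, float]:
    return {n: float(10.0**xi) for n, xi in zip(problem.free_names, x)}


def multistart_fit(
    problem: FitProblem,
    n_starts: int = 100,
    seed: int | None = None,
    max_rounds: int = 5,
    improve_tol: float = 1e-6,
    de_maxiter: int = 12,
    de_popsize: int = 7,
) -> FitResult:
    """Multistart hybrid fit: log-uniform starts, each alternating a global
    evolutionary phase and a local trust-region least-squares phase."""
    if n_starts < 1:
        raise CalibrationError("n_starts must be >= 1")
    lo, hi = _log_bounds(problem)
    n_par = len(problem.free_names)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_starts)

    def resid_log(x: np.ndarray) -> np.ndarray:
        return weighted_residuals(problem, _values_from_log(problem, x))

    def chi2_log(x: np.ndarray) -> float:
        r = resid_log(x)
        return float(r @ r)

    best_x: np.ndarray | None = None
    best_f = np.inf
    starts: list[StartRecord] = []
    for child in children:
        rng = np.random.default_rng(child)
        de_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        x = rng.uniform(lo, hi)
        f = chi2_log(x)
        x0_values = _values_from_log(problem, x)
        converged = False
        for _ in range(max_rounds):
            f_before = f
            # Global phase: small evolutionary search seeded around the incumbent.
            pop = rng.uniform(lo, hi, size=(max(5, de_popsize) * n_par, n_par))
            pop[0] = x
            de = differential_evolution(
                chi2_log,
                bounds=list(zip(lo, hi)),
                init=pop,
                maxiter=de_maxiter,
                tol=0.01,
                seed=de_seed,
                polish=False,
            )
            if de.fun < f:
                x, f = de.x, float(de.fun)
            # Local phase: bound-constrained trust-region least squares.
            ls = least_squares(resid_log, np.clip(x, lo, hi), bounds=(lo, hi),
                               method="trf", xtol=1e-12, ftol=1e-12)
            f_ls = float(ls.cost * 2.0)
            if f_ls < f:
                x, f = ls.x, f_ls
            rel_improve = (f_before - f) / max(f_before, 1e-300)
            if rel_improve < improve_tol:
                converged = True
                break
        starts.append(StartRecord(x0_values, f, converged))
        if f < best_f:
            best_x, best_f = x.copy(), f

    if best_x is None or not np.isfinite(best_f):
        raise CalibrationError(
            f"all {n_starts} starts failed for {problem.gene_id}/{problem.model_id}; "
            f"start objectives: {[s.chi2 for s in starts]}"
        )

    values = _values_from_log(problem, best_x)
    params = problem.base_params.replace(**values)
    bic = bic_score(best_f, problem.n_data, problem.k_free)
    return FitResult(
        gene_id=problem.gene_id,
        model_id=problem.model_id,
        params=params,
        features=problem.features,
        values=values,
        chi2=best_f,
        n_data=problem.n_data,
        k_free=problem.k_free,
        bic=bic,
        starts=starts,
        seed=seed,
        dataset_hash=problem.dataset_hash,
    )


def bic_score(chi2: float, n_data: int, k_free: int) -> float:
    """``BIC = chi^2 + k_free * ln(n_data)`` (Gaussian errors with known SEs,
    additive constants dropped; comparable only within one dataset slice)."""
    if n_data <= 0:
        raise ValueError("n_data must be positive")
    if k_free < 0:
        raise ValueError("k_free must be >= 0")
    return float(chi2 + k_free * np.log(n_data))


def compare_models(fits: Sequence[FitResult], tie_delta: float = 2.0):
    """Rank fits of the same data slice by ascending BIC.

    Returns a DataFrame with ``delta_bic`` relative to the best model and an
    ``equivalent`` flag for ties (ΔBIC below ``tie_delta``, where the model
    with fewer parameters is preferred by the ordering).
    """
    import pandas as pd

    if not fits:
        raise CalibrationError("no fits to compare")
    hashes = {f.dataset_hash for f in fits}
    genes = {f.gene_id for f in fits}
    if len(hashes) > 1 or len(genes) > 1:
        raise CalibrationError("fits computed on different dataset slices cannot be compared")
    df = pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "model_id": [f.model_id for f in fits],
            "chi2": [f.chi2 for f in fits],
            "k_free": [f.k_free for f in fits],
            "n_data": [f.n_data for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
    df = df.sort_values(["bic", "k_free"], kind="stable").reset_index(drop=True)
    df["delta_bic"] = df["bic"] - df["bic"].iloc[0]
    df["equivalent"] = df["delta_bic"] < tie_delta
    return df
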