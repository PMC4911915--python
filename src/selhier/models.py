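"""Kinetic models of selenoprotein translation coupled to mRNA decay.

Four deterministic mass-action models of the fate of a selenoprotein mRNA are
implemented.  All of them share a core reaction chain per transcript state
(abundances in arbitrary units, time in hours):

``M``
    free (translatable) mRNA, produced by transcription at rate ``v_txn``;
``R0``
    mRNA with an initiated ribosome (``M -> R0``, rate ``k_init``);
``R1``
    ribosome paused at the Sec-encoding UGA after elongating the first
    segment (``R0 -> R1``, rate ``k_el1 = r_elong / codons_start_to_uga``);
``R2``
    UGA with tRNA-Sec bound (``R1 -> R2``, pseudo-first-order rate
    ``k_bind * trna_sec_level``);
``R3``
    post-insertion elongating ribosome (``R2 -> R3``, rate ``k_sec``; the
    tRNA dissociates on insertion), which completes the message and releases
    the mRNA (``R3 -> M``, rate ``k_el2 = r_elong / codons_uga_to_stop``).

At the paused state ``R1`` the outcome of PTC recognition is decided:
binding of a release factor commits the transcript to nonsense-mediated
decay (``R1 -> 0``, rate ``k_nmd``), in competition with tRNA-Sec binding.
More selenium means a larger aminoacylated tRNA-Sec pool, faster passage
through ``R1``, and therefore *less* NMD: steady-state total mRNA is
non-decreasing in the tRNA-Sec level for every positive parameter set
(Model 1 can only produce a rise of mRNA with selenium).

The model variants:

* **M1** — the competition above, one gene at a time.
* **M1B** — several M1 copies coupled through one finite pool of free
  tRNA-Sec (``R1 + tRNA -> R2``, mass action); the tRNA is returned on Sec
  insertion and on decay of the bound state, so ``free tRNA + sum(R2)`` is
  conserved.
* **M2** — adds ribosome drop-off at the paused state (``R1 -> M``, rate
  ``k_drop``): PTC recognition may end in plain termination that releases an
  intact mRNA instead of NMD.
* **M3** — adds deadenylation-coupled turnover: every species carries a
  poly(A)-tail level (70, 60, ..., 10 a.u.); each completed translation
  shortens the tail by one step (``R3(l) -> M(l-10)``), drop-off preserves
  the tail (``R1(l) -> M(l)``), and completion at the critical level
  destroys the transcript (``R3(10) -> 0``).  With frequent drop-off and
  weak NMD this produces an *inverse* selenium response: more tRNA-Sec means
  more completed translations, faster tail shortening and less mRNA.

Background first-order decay ``d_bg`` applies to every transcript-containing
state, so with no NMD and no critical-level loss the total steady state is
exactly ``v_txn / d_bg``.

Selenium enters through a saturating map from selenite concentration to the
aminoacylated tRNA-Sec level (:func:`se_to_trna_level`), with a basal level
``s0 > 0`` because cells express selenoproteins even without added selenium.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .features import TranscriptFeatures

__all__ = [
    "MODEL_IDS",
    "POLYA_LEVELS",
    "SELENITE_CONDITIONS",
    "ModelError",
    "SteadyStateError",
    "SeMap",
    "SeCondition",
    "RateParameters",
    "Reaction",
    "ModelSpec",
    "SimulationResult",
    "SteadyState",
    "se_to_trna_level",
    "make_conditions",
    "elongation_rates",
    "build_model",
    "simulate_timecourse",
    "solve_steady_state",
    "model1_steady_state_closed_form",
    "steady_state_total",
    "m1b_steady_state_totals",
]

MODEL_IDS = ("M1", "M1B", "M2", "M3")

#: Poly(A)-tail levels tracked by Model 3 (a.u.); completion at the last
#: level triggers degradation.
POLYA_LEVELS = (70, 60, 50, 40, 30, 20, 10)

#: Selenite concentrations (nM added sodium selenite) of the titration design.
SELENITE_CONDITIONS = (0.0, 5.0, 10.0, 20.0, 40.0)

#: Reference segment length (codons) used when the first-segment elongation
#: rate is configured *not* to scale with transcript length.
REFERENCE_SEGMENT_CODONS = 100


class ModelError(ValueError):
    """Invalid model construction (unknown id, inconsistent parameters...)."""


class SteadyStateError(RuntimeError):
    """No finite/valid steady state (e.g. the system has no transcript sink)."""


# ---------------------------------------------------------------------------
# Selenium -> tRNA-Sec map
# ---------------------------------------------------------------------------

def se_to_trna_level(
    selenite_nM: float, s0: float = 0.1, smax: float = 1.0, k_half: float = 10.0
) -> float:
    """Saturating map from added selenite (nM) to aminoacylated tRNA-Sec level.

    ``level = s0 + smax * c / (c + k_half)`` — monotone non-decreasing in the
    selenite concentration ``c``, equal to the basal level ``s0`` at ``c = 0``
    and saturating at ``s0 + smax``.
    """
    if selenite_nM < 0 or s0 < 0 or smax < 0:
        raise ValueError("selenite_nM, s0 and smax must be non-negative")
    if k_half <= 0:
        raise ValueError("k_half must be positive")
    return s0 + smax * selenite_nM / (selenite_nM + k_half)


@dataclass(frozen=True)
class SeMap:
    """Parameters of the selenite -> tRNA-Sec level map, shared across genes."""

    s0: float = 0.1
    smax: float = 1.0
    k_half: float = 10.0

    def level(self, selenite_nM: float) -> float:
        return se_to_trna_level(selenite_nM, self.s0, self.smax, self.k_half)


@dataclass(frozen=True)
class SeCondition:
    """One selenium culture condition: selenite dose and derived tRNA-Sec level."""

    selenite_nM: float
    trna_sec_level: float

    def __post_init__(self) -> None:
        if self.selenite_nM < 0:
            raise ValueError("selenite_nM must be >= 0")
        if self.trna_sec_level < 0:
            raise ValueError("trna_sec_level must be >= 0")


def make_conditions(
    selenite_nM: Sequence[float] = SELENITE_CONDITIONS, se_map: SeMap | None = None
) -> list[SeCondition]:
    se_map = se_map or SeMap()
    return [SeCondition(float(c), se_map.level(float(c))) for c in selenite_nM]


# ---------------------------------------------------------------------------
# Rate parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateParameters:
    """Process rates of one transcript (hours, arbitrary abundance units).

    ``v_txn``      transcription rate (mRNA/h)
    ``k_init``     translation initiation rate per free mRNA (1/h)
    ``r_elong``    per-codon elongation rate (codons/h); the two segment rates
                   are derived as ``k_el1 = r_elong / codons_start_to_uga`` and
                   ``k_el2 = r_elong / codons_uga_to_stop``
    ``k_bind``     second-order tRNA-Sec binding constant (1/(a.u. h))
    ``k_nmd``      NMD commitment rate at the occupied UGA (1/h)
    ``k_sec``      Sec-insertion rate once the tRNA is bound (1/h)
    ``k_drop``     ribosome drop-off rate at the occupied UGA (1/h; models
                   M2/M3 only, must be 0 for M1/M1B)
    ``d_bg``       background first-order mRNA decay, all states (1/h)

    ``free`` and ``bounds`` carry the default fitting configuration: which
    parameters are free and their (lo, hi) ranges on the natural scale.
    """

    v_txn: float = 2.0
    k_init: float = 8.0
    r_elong: float = 7200.0
    k_bind: float = 50.0
    k_nmd: float = 1.0
    k_sec: float = 5.0
    k_drop: float = 0.0
    d_bg: float = 0.1
    scale_el1_with_length: bool = True
    free: tuple[str, ...] = ()
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    RATE_NAMES = ("v_txn", "k_init", "r_elong", "k_bind", "k_nmd", "k_sec", "k_drop", "d_bg")

    def __post_init__(self) -> None:
        for name in self.RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name, (lo, hi) in dict(self.bounds).items():
            if name not in self.RATE_NAMES:
                raise ValueError(f"bounds given for unknown parameter {name!r}")
            if not (0 < lo <= hi):
                raise ValueError(f"bounds for {name!r} must satisfy 0 < lo <= hi")
            value = getattr(self, name)
            if name not in self.free and not (lo <= value <= hi):
                raise ValueError(f"fixed parameter {name!r}={value} outside its bounds [{lo}, {hi}]")

    def replace(self, **updates) -> "RateParameters":
        return dataclasses.replace(self, **updates)


def elongation_rates(params: RateParameters, features: TranscriptFeatures) -> tuple[float, float]:
    """Segment elongation rates (1/h) derived from the per-codon rate."""
    n1 = features.codons_start_to_uga if params.scale_el1_with_length else REFERENCE_SEGMENT_CODONS
    k_el1 = params.r_elong / n1
    k_el2 = params.r_elong / features.codons_uga_to_stop
    return k_el1, k_el2


# ---------------------------------------------------------------------------
# Reaction networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: rate = rate_constant * prod(reactant levels)."""

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float


@dataclass
class ModelSpec:
    """A concrete reaction network for one model variant and one Se condition."""

    model_id: str
    species: list[str]
    reactions: list[Reaction]
    gene_ids: list[str]
    condition: SeCondition
    params: list[RateParameters]
    features: list[TranscriptFeatures]
    pool_total: float | None = None  # M1B only

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self._index[name]

    def transcript_species(self, gene_id: str) -> list[str]:
        prefix = f"{gene_id}:"
        return [s for s in self.species if s.startswith(prefix)]

    def is_linear(self) -> bool:
        return all(len(r.reactants) <= 1 for r in self.reactions)


def _gene_reactions(
    gene: str,
    params: RateParameters,
    features: TranscriptFeatures,
    trna_level: float,
    drop: float,
) -> tuple[list[str], list[Reaction]]:
    """Single-gene, single-ribosome chain (M1/M2) at a fixed tRNA-Sec level."""
    k_el1, k_el2 = elongation_rates(params, features)
    sp = [f"{gene}:{s}" for s in ("M", "R0", "R1", "R2", "R3")]
    M, R0, R1, R2, R3 = sp
    rx = [
        Reaction("transcription", (), (M,), params.v_txn),
        Reaction("initiation", (M,), (R0,), params.k_init),
        Reaction("elongation_to_uga", (R0,), (R1,), k_el1),
        Reaction("nmd", (R1,), (), params.k_nmd),
        Reaction("trna_binding", (R1,), (R2,), params.k_bind * trna_level),
        Reaction("sec_insertion", (R2,), (R3,), params.k_sec),
        Reaction("elongation_to_stop", (R3,), (M,), k_el2),
    ]
    if drop > 0:
        rx.insert(4, Reaction("drop_off", (R1,), (M,), drop))
    rx += [Reaction(f"decay_{s.split(':')[1]}", (s,), (), params.d_bg) for s in sp]
    return sp, rx


def _m3_reactions(
    gene: str, params: RateParameters, features: TranscriptFeatures, trna_level: float
) -> tuple[list[str], list[Reaction]]:
    k_el1, k_el2 = elongation_rates(params, features)
    species: list[str] = []
    rx: list[Reaction] = []
    name = lambda state, lvl: f"{gene}:{state}({lvl})"
    for lvl in POLYA_LEVELS:
        species += [name(s, lvl) for s in ("M", "R0", "R1", "R2", "R3")]
    rx.append(Reaction("transcription", (), (name("M", POLYA_LEVELS[0]),), params.v_txn))
    for i, lvl in enumerate(POLYA_LEVELS):
        M, R0, R1, R2, R3 = (name(s, lvl) for s in ("M", "R0", "R1", "R2", "R3"))
        rx += [
            Reaction(f"initiation({lvl})", (M,), (R0,), params.k_init),
            Reaction(f"elongation_to_uga({lvl})", (R0,), (R1,), k_el1),
            Reaction(f"nmd({lvl})", (R1,), (), params.k_nmd),
            Reaction(f"drop_off({lvl})", (R1,), (M,), params.k_drop),
            Reaction(f"trna_binding({lvl})", (R1,), (R2,), params.k_bind * trna_level),
            Reaction(f"sec_insertion({lvl})", (R2,), (R3,), params.k_sec),
        ]
        if lvl == POLYA_LEVELS[-1]:
            # Completion at the critical tail length destroys the transcript.
            rx.append(Reaction(f"termination_critical({lvl})", (R3,), (), k_el2))
        else:
            nxt = POLYA_LEVELS[i + 1]
            rx.append(Reaction(f"elongation_to_stop({lvl})", (R3,), (name("M", nxt),), k_el2))
        rx += [
            Reaction(f"decay_{s.split(':')[1]}", (s,), (), params.d_bg)
            for s in (M, R0, R1, R2, R3)
        ]
    return species, rx


def build_model(
    model_id: str,
    features: TranscriptFeatures | Sequence[TranscriptFeatures],
    params: RateParameters | Sequence[RateParameters],
    condition: SeCondition,
    pool_total: float | None = None,
) -> ModelSpec:
    """Assemble the reaction network of one model variant.

    For M1/M2/M3 ``features``/``params`` describe a single gene; for M1B they
    are parallel sequences (>= 2 genes) and ``pool_total`` is the total
    tRNA-Sec pool (free + sequestered), which replaces the per-condition
    constant tRNA level.
    """
    if model_id not in MODEL_IDS:
        raise ModelError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")

    if model_id == "M1B":
        if isinstance(features, TranscriptFeatures) or isinstance(params, RateParameters):
            raise ModelError("M1B requires sequences of features and params (>= 2 genes)")
        features_list = list(features)
        params_list = list(params)
        if len(features_list) < 2 or len(features_list) != len(params_list):
            raise ModelError("M1B requires >= 2 genes with matching params")
        if pool_total is None or pool_total <= 0:
            raise ModelError("M1B requires a positive total tRNA pool size")
        for p in params_list:
            if p.k_drop != 0:
                raise ModelError("k_drop must be 0 for model M1B")
        species = ["tRNA"]
        reactions: list[Reaction] = []
        for f, p in zip(features_list, params_list):
            k_el1, k_el2 = elongation_rates(p, f)
            g = f.gene_id
            sp = [f"{g}:{s}" for s in ("M", "R0", "R1", "R2", "R3")]
            M, R0, R1, R2, R3 = sp
            species += sp
            reactions += [
                Reaction("transcription", (), (M,), p.v_txn),
                Reaction("initiation", (M,), (R0,), p.k_init),
                Reaction("elongation_to_uga", (R0,), (R1,), k_el1),
                Reaction("nmd", (R1,), (), p.k_nmd),
                # Mass-action sequestration of the shared pool.
                Reaction("trna_binding", (R1, "tRNA"), (R2,), p.k_bind),
                # The tRNA is returned on insertion and on decay of the bound state.
                Reaction("sec_insertion", (R2,), (R3, "tRNA"), p.k_sec),
                Reaction("elongation_to_stop", (R3,), (M,), k_el2),
                Reaction("decay_M", (M,), (), p.d_bg),
                Reaction("decay_R0", (R0,), (), p.d_bg),
                Reaction("decay_R1", (R1,), (), p.d_bg),
                Reaction("decay_R2", (R2,), ("tRNA",), p.d_bg),
                Reaction("decay_R3", (R3,), (), p.d_bg),
            ]
        return ModelSpec(
            model_id, species, reactions, [f.gene_id for f in features_list],
            condition, params_list, features_list, pool_total=float(pool_total),
        )

    if not isinstance(features, TranscriptFeatures) or not isinstance(params, RateParameters):
        raise ModelError(f"model {model_id} takes a single gene's features and params")
    if model_id in ("M1",) and params.k_drop != 0:
        raise ModelError("k_drop must be 0 for model M1")

    s = condition.trna_sec_level
    if model_id == "M1":
        species, reactions = _gene_reactions(features.gene_id, params, features, s, drop=0.0)
    elif model_id == "M2":
        species, reactions = _gene_reactions(features.gene_id, params, features, s, drop=params.k_drop)
    else:  # M3
        species, reactions = _m3_reactions(features.gene_id, params, features, s)
    return ModelSpec(model_id, species, reactions, [features.gene_id], condition, [params], [features])


# ---------------------------------------------------------------------------
# Simulation and steady states
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    times: np.ndarray
    states: np.ndarray  # species x time
    species: list[str]
    total_mrna: dict[str, np.ndarray]
    converged: bool
    residual_norm: float
    message: str = ""


@dataclass
class SteadyState:
    species: list[str]
    values: np.ndarray
    total_mrna: dict[str, float]
    residual_norm: float

    @property
    def total(self) -> float:
        """Total mRNA summed over genes (convenience for single-gene models)."""
        return float(sum(self.total_mrna.values()))


def _rhs_factory(spec: ModelSpec):
    n = spec.n_species
    terms = []
    for r in spec.reactions:
        ridx = tuple(spec.species_index(x) for x in r.reactants)
        deltas: dict[int, float] = {}
        for x in r.reactants:
            deltas[spec.species_index(x)] = deltas.get(spec.species_index(x), 0.0) - 1.0
        for x in r.products:
            deltas[spec.species_index(x)] = deltas.get(spec.species_index(x), 0.0) + 1.0
        terms.append((r.rate_constant, ridx, tuple(deltas.items())))

    def rhs(t, x):
        dx = np.zeros(n)
        for k, ridx, deltas in terms:
            rate = k
            for i in ridx:
                rate *= x[i]
            for i, c in deltas:
                dx[i] += c * rate
        return dx

    return rhs


def _gene_totals(spec: ModelSpec, values: np.ndarray) -> dict[str, np.ndarray | float]:
    totals = {}
    for g in spec.gene_ids:
        idx = [spec.species_index(s) for s in spec.transcript_species(g)]
        totals[g] = values[idx].sum(axis=0)
    return totals


def simulate_timecourse(
    spec: ModelSpec,
    init: np.ndarray | None = None,
    t_end: float = 100.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 201,
    method: str = "LSODA",
) -> SimulationResult:
    """Deterministic ODE time course of the mass-action network.

    Starts from zero abundances by default (fresh induction); for M1B the free
    tRNA species starts at the configured pool total.  Non-convergence of the
    integrator is flagged in the result, never silent.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if init is None:
        init = np.zeros(spec.n_species)
        if spec.pool_total is not None:
            init[spec.species_index("tRNA")] = spec.pool_total
    init = np.asarray(init, dtype=float)
    if init.shape != (spec.n_species,):
        raise ValueError(f"init must have shape ({spec.n_species},)")
    if (init < 0).any():
        raise ValueError("init must be non-negative componentwise")

    rhs = _rhs_factory(spec)
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), init, t_eval=times, method=method, rtol=rtol, atol=atol)
    states = sol.y if sol.success else np.full((spec.n_species, len(times)), np.nan)
    residual = float(np.linalg.norm(rhs(t_end, states[:, -1]))) if sol.success else np.inf
    return SimulationResult(
        times=times,
        states=states,
        species=list(spec.species),
        total_mrna=_gene_totals(spec, states) if sol.success else {},
        converged=bool(sol.success),
        residual_norm=residual,
        message=sol.message,
    )


def _linear_system(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    if not spec.is_linear():
        raise ModelError("network is not linear in the state (bimolecular reaction present)")
    n = spec.n_species
    A = np.zeros((n, n))
    b = np.zeros(n)
    for r in spec.reactions:
        if not r.reactants:
            for p in r.products:
                b[spec.species_index(p)] += r.rate_constant
            continue
        i = spec.species_index(r.reactants[0])
        A[i, i] -= r.rate_constant
        for p in r.products:
            A[spec.species_index(p), i] += r.rate_constant
    return A, b


def solve_steady_state(spec: ModelSpec, tol: float = 1e-9) -> SteadyState:
    """Steady state of the network: direct linear solve for M1/M2/M3,
    fixed-point (bracketed root) over the free tRNA pool for M1B."""
    if spec.model_id == "M1B":
        return _solve_m1b(spec)
    A, b = _linear_system(spec)
    try:
        x = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as exc:
        raise SteadyStateError(
            "singular steady-state system: the network has no transcript sink "
            "(is d_bg > 0 or another loss present?)"
        ) from exc
    scale = max(1.0, float(np.abs(x).max()))
    if x.min() < -tol * scale:
        raise SteadyStateError(f"steady state has a negative component (min {x.min():.3g})")
    x = np.clip(x, 0.0, None)
    residual = float(np.linalg.norm(A @ x + b))
    totals = {g: float(v) for g, v in _gene_totals(spec, x).items()}
    return SteadyState(list(spec.species), x, totals, residual)


# -- closed-form chains (independent oracle & fast path) --------------------

def _chain_occupancies(
    params: RateParameters, features: TranscriptFeatures, trna_level: float, drop: float
) -> tuple[float, tuple[float, float, float, float]]:
    """Occupancy coefficients c_i with R_i = c_i * M for the single-gene chain,
    and the free-mRNA steady state M (transcription source v_txn)."""
    d = params.d_bg
    if d <= 0:
        raise ModelError("d_bg must be positive for a finite steady state")
    k_el1, k_el2 = elongation_rates(params, features)
    kb = params.k_bind * trna_level
    c0 = params.k_init / (k_el1 + d)
    c1 = c0 * k_el1 / (params.k_nmd + drop + kb + d)
    c2 = c1 * kb / (params.k_sec + d)
    c3 = c2 * params.k_sec / (k_el2 + d)
    denom = (params.k_init + d) - k_el2 * c3 - drop * c1
    if denom <= 0:
        raise SteadyStateError("degenerate chain: no finite free-mRNA steady state")
    M = params.v_txn / denom
    return M, (c0, c1, c2, c3)


def model1_steady_state_closed_form(
    params: RateParameters, features: TranscriptFeatures, trna_sec_level: float
) -> float:
    """Explicit Model 1 steady-state total mRNA (independent of the ODE path).

    Solves the five chained first-order balances symbolically: each occupied
    state is a fixed multiple of the free mRNA, and the free-mRNA balance
    closes the loop.  With ``k_nmd = 0`` the only sink is background decay and
    the total reduces to ``v_txn / d_bg`` exactly.
    """
    if params.k_drop != 0:
        raise ModelError("Model 1 closed form requires k_drop = 0")
    M, cs = _chain_occupancies(params, features, trna_sec_level, drop=0.0)
    return M * (1.0 + sum(cs))


def _m2_chain_total(params: RateParameters, features: TranscriptFeatures, trna_level: float) -> float:
    M, cs = _chain_occupancies(params, features, trna_level, drop=params.k_drop)
    return M * (1.0 + sum(cs))


def _m3_chain_total(params: RateParameters, features: TranscriptFeatures, trna_level: float) -> float:
    """Model 3 steady state by cascading the per-level chain downward.

    Levels only feed the next-lower tail level (via completed translation), so
    the 35-species linear system factorizes into 7 sequential chain solves.
    """
    d = params.d_bg
    if d <= 0:
        raise ModelError("d_bg must be positive for a finite steady state")
    k_el1, k_el2 = elongation_rates(params, features)
    kb = params.k_bind * trna_level
    drop = params.k_drop
    c0 = params.k_init / (k_el1 + d)
    c1 = c0 * k_el1 / (params.k_nmd + drop + kb + d)
    c2 = c1 * kb / (params.k_sec + d)
    c3 = c2 * params.k_sec / (k_el2 + d)
    denom = (params.k_init + d) - drop * c1  # completed translation leaves the level
    if denom <= 0:
        raise SteadyStateError("degenerate chain: no finite free-mRNA steady state")
    occupancy = 1.0 + c0 + c1 + c2 + c3
    total = 0.0
    src = params.v_txn
    for _ in POLYA_LEVELS:
        M = src / denom
        total += M * occupancy
        src = k_el2 * c3 * M  # feeds the next tail level (lost at the last one)
    return total


def steady_state_total(
    model_id: str,
    params: RateParameters,
    features: TranscriptFeatures,
    trna_sec_level: float,
) -> float:
    """Fast steady-state total mRNA for the per-gene models (chain algebra)."""
    if model_id == "M1":
        if params.k_drop != 0:
            raise ModelError("k_drop must be 0 for model M1")
        return model1_steady_state_closed_form(params, features, trna_sec_level)
    if model_id == "M2":
        return _m2_chain_total(params, features, trna_sec_level)
    if model_id == "M3":
        return _m3_chain_total(params, features, trna_sec_level)
    raise ModelError(f"steady_state_total supports M1/M2/M3, got {model_id!r}")


def _solve_m1b(spec: ModelSpec) -> SteadyState:
    """M1B steady state: root-find the free tRNA level such that
    free + sum(R2) equals the pool, each gene solved by its linear chain."""
    pool = spec.pool_total
    assert pool is not None

    def bound_trna(T: float) -> float:
        total = 0.0
        for p, f in zip(spec.params, spec.features):
            M, (c0, c1, c2, c3) = _chain_occupancies(p, f, T, drop=0.0)
            total += c2 * M
        return total

    h = lambda T: T + bound_trna(T) - pool
    # h(0) = -pool < 0 and h(pool) = bound(pool) >= 0: bracketed root.
    T_free = brentq(h, 0.0, pool, xtol=1e-15 * max(1.0, pool), rtol=1e-15)

    values = np.zeros(spec.n_species)
    values[spec.species_index("tRNA")] = T_free
    for p, f in zip(spec.params, spec.features):
        M, (c0, c1, c2, c3) = _chain_occupancies(p, f, T_free, drop=0.0)
        g = f.gene_id
        for state, v in zip(("M", "R0", "R1", "R2", "R3"), (M, c0 * M, c1 * M, c2 * M, c3 * M)):
            values[spec.species_index(f"{g}:{state}")] = v
    rhs = _rhs_factory(spec)
    residual = float(np.linalg.norm(rhs(0.0, values)))
    totals = {g: float(v) for g, v in _gene_totals(spec, values).items()}
    return SteadyState(list(spec.species), values, totals, residual)


def m1b_steady_state_totals(
    params: Sequence[RateParameters],
    features: Sequence[TranscriptFeatures],
    pool_total: float,
    condition: SeCondition | None = None,
) -> dict[str, float]:
    """Per-gene steady-state totals of the pooled-tRNA model (fast path)."""
    cond = condition or SeCondition(0.0, pool_total)
    spec = build_model("M1B", features, params, cond, pool_total=pool_total)
    return solve_steady_state(spec).total_mrna
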