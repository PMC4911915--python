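"""Synthetic Se-titration expression data emulating the Caco-2 study design.

The generator reproduces the *design* of the selenium titration experiment:
a panel of ~11 selenoprotein genes measured by qPCR at added sodium-selenite
concentrations {0, 5, 10, 20, 40} nM with n = 8 replicates.  Each gene is
assigned a hierarchy class defined by its plateau fold change relative to the
no-added-selenium (NoSe) reference:

``strong_up``    2.5-3.5x rise (GPX1/SEPW1/SELH-like; low in the hierarchy),
``moderate_up``  1.3-1.5x rise (GPX4/TXNRD2-like),
``flat``         0.95-1.05x (SELK/SEP15-like; high in the hierarchy),
``inverse``      ~0.7x, a ~30% *decrease* with selenium (GPX2/SPS2-like).

Ground-truth kinetic parameters are rejection-sampled per class so that the
*solved* steady-state dose-response of the generating model lands inside the
class window — strong/moderate/flat classes use Model 1 (NMD vs Sec-insertion
competition, ``k_drop = 0``), the inverse class uses Model 3 (frequent
ribosome drop-off plus poly(A)-dependent turnover).  Replicate noise is
multiplicative lognormal (qPCR errors are multiplicative), default CV 0.15.

Everything is reproducible from a stored seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, read_dataset, write_dataset
from .features import TranscriptFeatures, nmd_rule_classifier
from .models import (
    SELENITE_CONDITIONS,
    RateParameters,
    SeCondition,
    SeMap,
    make_conditions,
    steady_state_total,
)

__all__ = [
    "HierarchyClass",
    "HIERARCHY_CLASSES",
    "DEFAULT_PANEL_CLASSES",
    "GeneTruth",
    "GroundTruth",
    "GenerationError",
    "make_gene_panel",
    "simulate_dataset",
    "read_dataset",
    "write_dataset",
    "nmd_rule_classifier",
]


class GenerationError(RuntimeError):
    """Raised when a hierarchy-class target cannot be met by sampling."""


@dataclass(frozen=True)
class HierarchyClass:
    """One hierarchy class: target plateau fold-change window and the model
    variant whose parameters generate it."""

    label: str
    fold_lo: float
    fold_hi: float
    model_id: str

    def contains(self, ratio: float) -> bool:
        return self.fold_lo <= ratio <= self.fold_hi


HIERARCHY_CLASSES: dict[str, HierarchyClass] = {
    "strong_up": HierarchyClass("strong_up", 2.5, 3.5, "M1"),
    "moderate_up": HierarchyClass("moderate_up", 1.3, 1.5, "M1"),
    "flat": HierarchyClass("flat", 0.95, 1.05, "M1"),
    "inverse": HierarchyClass("inverse", 0.60, 0.75, "M3"),
}

#: Default 11-gene panel: class assignment mirroring the observed hierarchy
#: (gene symbols are used as labels for synthetic stand-in transcripts).
DEFAULT_PANEL_CLASSES: dict[str, str] = {
    "GPX1": "strong_up",
    "SEPW1": "strong_up",
    "SELH": "strong_up",
    "GPX4": "moderate_up",
    "TXNRD2": "moderate_up",
    "SEPP1": "moderate_up",
    "TXNRD1": "moderate_up",
    "SELK": "flat",
    "SEP15": "flat",
    "GPX2": "inverse",
    "SPS2": "inverse",
}

#: Per-class log-uniform sampling ranges for the free kinetic rates (1/h or
#: 1/(a.u. h)); ``k_drop`` for the inverse class is sampled as a multiple of
#: ``k_nmd`` so that drop-off dominates NMD at the paused ribosome.
CLASS_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "strong_up": {"k_nmd": (0.8, 2.5), "k_bind": (5.0, 120.0), "k_sec": (2.0, 10.0)},
    "moderate_up": {"k_nmd": (0.05, 0.8), "k_bind": (10.0, 300.0), "k_sec": (2.0, 10.0)},
    "flat": {"k_nmd": (1e-3, 2e-2), "k_bind": (1.0, 100.0), "k_sec": (2.0, 10.0)},
    "inverse": {
        "k_nmd": (0.5, 2.5),
        "k_drop_over_k_nmd": (8.0, 30.0),
        "k_bind": (10.0, 200.0),
        "k_sec": (2.0, 10.0),
    },
}

MAX_REJECTION_DRAWS = 2000

#: Per-gene transcription rate range (a.u./h), log-uniform.  Absolute
#: abundances vary widely between selenoprotein mRNAs and are independent of
#: the hierarchy class; only normalized observables are fitted downstream.
V_TXN_RANGE = (0.3, 10.0)


@dataclass(frozen=True)
class GeneTruth:
    """Generating model, parameters and class label for one synthetic gene."""

    features: TranscriptFeatures
    params: RateParameters
    model_id: str
    class_label: str
    solved_ratio: float  # steady-state 40 nM / NoSe ratio of the noiseless model


@dataclass
class GroundTruth:
    """Everything needed to regenerate a synthetic study from its seed."""

    genes: list[GeneTruth]
    se_map: SeMap = field(default_factory=SeMap)
    noise_cv: float = 0.15
    seed: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return [g.features.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> GeneTruth:
        for g in self.genes:
            if g.features.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "se_map": dataclasses.asdict(self.se_map),
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "genes": [
                {
                    "features": dataclasses.asdict(g.features),
                    "params": {
                        k: v
                        for k, v in dataclasses.asdict(g.params).items()
                        if k not in ("free", "bounds")
                    },
                    "model_id": g.model_id,
                    "class_label": g.class_label,
                    "solved_ratio": g.solved_ratio,
                }
                for g in self.genes
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        genes = [
            GeneTruth(
                features=TranscriptFeatures(**g["features"]),
                params=RateParameters(**g["params"]),
                model_id=g["model_id"],
                class_label=g["class_label"],
                solved_ratio=g["solved_ratio"],
            )
            for g in payload["genes"]
        ]
        return cls(
            genes=genes,
            se_map=SeMap(**payload["se_map"]),
            noise_cv=payload["noise_cv"],
            seed=payload["seed"],
        )


def _sample_features(gene_id: str, class_label: str, rng: np.random.Generator) -> TranscriptFeatures:
    """Plausible structural features; classes with an active NMD/drop-off fate
    get a PTC well upstream of a downstream junction, flat genes do not."""
    n1 = int(rng.integers(60, 350))
    n2 = int(rng.integers(15, 250))
    if class_label == "flat":
        ptc = 0 if rng.random() < 0.5 else int(rng.integers(5, 45))
    else:
        ptc = int(rng.integers(55, 200))
    return TranscriptFeatures(gene_id, n1, n2, ptc)


def _solved_dose_ratio(
    model_id: str,
    params: RateParameters,
    features: TranscriptFeatures,
    se_map: SeMap,
    high_nM: float = 40.0,
    low_nM: float = 0.0,
) -> float:
    hi = steady_state_total(model_id, params, features, se_map.level(high_nM))
    lo = steady_state_total(model_id, params, features, se_map.level(low_nM))
    return hi / lo


def _sample_gene(
    gene_id: str,
    class_label: str,
    se_map: SeMap,
    rng: np.random.Generator,
    base_params: RateParameters,
) -> GeneTruth:
    if class_label not in HIERARCHY_CLASSES:
        raise GenerationError(
            f"unknown hierarchy class {class_label!r}; expected {sorted(HIERARCHY_CLASSES)}"
        )
    cls = HIERARCHY_CLASSES[class_label]
    ranges = CLASS_PARAM_RANGES[class_label]
    features = _sample_features(gene_id, class_label, rng)

    def draw(name: str) -> float:
        lo, hi = ranges[name]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    v_txn = float(np.exp(rng.uniform(np.log(V_TXN_RANGE[0]), np.log(V_TXN_RANGE[1]))))
    for _ in range(MAX_REJECTION_DRAWS):
        updates = {
            "v_txn": v_txn,
            "k_nmd": draw("k_nmd"),
            "k_bind": draw("k_bind"),
            "k_sec": draw("k_sec"),
        }
        if cls.model_id == "M3":
            updates["k_drop"] = updates["k_nmd"] * draw("k_drop_over_k_nmd")
        else:
            updates["k_drop"] = 0.0
        params = base_params.replace(**updates)
        ratio = _solved_dose_ratio(cls.model_id, params, features, se_map)
        if cls.contains(ratio):
            return GeneTruth(features, params, cls.model_id, class_label, float(ratio))
    raise GenerationError(
        f"could not realize class {class_label!r} for gene {gene_id!r} within "
        f"{MAX_REJECTION_DRAWS} draws; widen the class parameter ranges"
    )


def make_gene_panel(
    n_genes: int = 11,
    classes: Mapping[str, str] | None = None,
    seed: int = 0,
    se_map: SeMap | None = None,
    noise_cv: float = 0.15,
    base_params: RateParameters | None = None,
) -> tuple[list[TranscriptFeatures], GroundTruth]:
    """Sample a gene panel with ground-truth parameters realizing each class.

    ``classes`` maps gene id -> class label; by default the 11-gene panel in
    :data:`DEFAULT_PANEL_CLASSES` (truncated or cyclically extended to
    ``n_genes``).  Parameters are rejection-sampled until the *solved*
    dose-response ratio (40 nM vs NoSe) of the generating model lands in the
    class window, so class fidelity holds by construction.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    se_map = se_map or SeMap()
    base_params = base_params or RateParameters()
    if classes is None:
        defaults = list(DEFAULT_PANEL_CLASSES.items())
        classes = {}
        labels = list(HIERARCHY_CLASSES)
        for i in range(n_genes):
            if i < len(defaults):
                classes[defaults[i][0]] = defaults[i][1]
            else:
                classes[f"SYN{i + 1}"] = labels[i % len(labels)]
    elif len(classes) != n_genes:
        raise ValueError(f"classes maps {len(classes)} genes but n_genes={n_genes}")

    rng = np.random.default_rng(seed)
    genes = [
        _sample_gene(gene_id, label, se_map, rng, base_params)
        for gene_id, label in classes.items()
    ]
    truth = GroundTruth(genes=genes, se_map=se_map, noise_cv=noise_cv, seed=seed)
    return [g.features for g in genes], truth


def simulate_dataset(
    truth: GroundTruth,
    conditions: Sequence[float] | Sequence[SeCondition] | None = None,
    n_reps: int = 8,
    seed: int = 0,
    cv: float | None = None,
) -> ExpressionDataset:
    """Draw a replicate-level qPCR-like dataset around the model steady states.

    Per gene x condition, ``n_reps`` multiplicative lognormal deviates are
    drawn around the noiseless steady-state abundance (mean-preserving, i.e.
    the expected value of a replicate equals the model output).  The returned
    dataset carries both raw abundances and NoSe-normalized values (divided by
    the per-gene sample mean at 0 nM, so the normalized NoSe mean is exactly 1).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    cv = truth.noise_cv if cv is None else cv
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if conditions is None:
        conds = make_conditions(SELENITE_CONDITIONS, truth.se_map)
    elif conditions and isinstance(conditions[0], SeCondition):
        conds = list(conditions)  # type: ignore[arg-type]
    else:
        conds = make_conditions([float(c) for c in conditions], truth.se_map)  # type: ignore[arg-type]
    if not conds:
        raise ValueError("conditions must be non-empty")
    if not any(c.selenite_nM == 0 for c in conds):
        raise ValueError("conditions must include the 0 nM (NoSe) reference")

    sigma = float(np.sqrt(np.log1p(cv**2)))
    rng = np.random.default_rng(seed)
    rows = []
    for g in truth.genes:
        for cond in conds:
            ss = steady_state_total(g.model_id, g.params, g.features, cond.trna_sec_level)
            if sigma == 0.0:
                draws = np.full(n_reps, ss)
            else:
                z = rng.standard_normal(n_reps)
                draws = ss * np.exp(sigma * z - 0.5 * sigma**2)
            for rep, value in enumerate(draws, start=1):
                rows.append(
                    {
                        "gene_id": g.features.gene_id,
                        "selenite_nM": cond.selenite_nM,
                        "replicate": rep,
                        "abundance": float(value),
                    }
                )
    df = pd.DataFrame(rows)
    ref_means = (
        df[df["selenite_nM"] == 0].groupby("gene_id")["abundance"].mean().rename("ref_mean")
    )
    df = df.join(ref_means, on="gene_id")
    df["normalized"] = df["abundance"] / df["ref_mean"]
    df = df.drop(columns="ref_mean")
    return ExpressionDataset(df)
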