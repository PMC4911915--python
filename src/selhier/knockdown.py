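"""Prediction of selenoprotein mRNA responses to UPF1 knockdown.

UPF1 is the core NMD helicase; its knockdown attenuates NMD.  The modelling
assumption is linear: a knockdown fraction ``kd`` scales the NMD commitment
rate to ``k_nmd * (1 - kd)``, with ``kd = 1`` abolishing NMD entirely.  For a
calibrated gene, predicted steady states are recomputed under each scenario
and reported as fold changes relative to the unperturbed model at the same
selenium condition.  For a Model-1 gene at full knockdown the only transcript
sink left is uniform background decay, so the predicted abundance is
``v_txn / d_bg`` at every selenium level.

The default knockdown levels {0, 0.25, 0.52, 1.0} combine the measured siRNA
efficiencies (25% at 48 h, 52% at 72 h) with the full-knockdown extrapolation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import FitResult
from .models import RateParameters, SeCondition, steady_state_total

__all__ = [
    "DEFAULT_KD_LEVELS",
    "apply_upf1_kd",
    "predict_kd_fold_changes",
    "compare_kd_observations",
]

DEFAULT_KD_LEVELS = (0.0, 0.25, 0.52, 1.0)


def apply_upf1_kd(params: RateParameters, kd_fraction: float) -> RateParameters:
    """Scale the NMD rate by ``(1 - kd_fraction)``; everything else unchanged."""
    if not 0.0 <= kd_fraction <= 1.0:
        raise ValueError(f"kd_fraction must be in [0, 1], got {kd_fraction}")
    return params.replace(k_nmd=params.k_nmd * (1.0 - kd_fraction))


def predict_kd_fold_changes(
    fits: Mapping[str, FitResult],
    conditions: Sequence[SeCondition],
    kd_levels: Sequence[float] = DEFAULT_KD_LEVELS,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Predicted abundances and fold changes per gene x condition x KD level.

    ``fits`` maps gene id to its calibrated :class:`FitResult` (any of
    M1/M2/M3).  Fold change is relative to the ``kd = 0`` prediction at the
    same selenium condition, so the ``kd = 0`` rows are exactly 1.
    """
    genes = list(genes) if genes is not None else sorted(fits)
    missing = [g for g in genes if g not in fits]
    if missing:
        raise KeyError(f"no calibrated fit for gene(s) {missing}")
    for kd in kd_levels:
        if not 0.0 <= kd <= 1.0:
            raise ValueError(f"kd level {kd} outside [0, 1]")

    rows = []
    for g in genes:
        fit = fits[g]
        baseline = {
            c.selenite_nM: steady_state_total(
                fit.model_id, fit.params, fit.features, c.trna_sec_level
            )
            for c in conditions
        }
        for kd in kd_levels:
            kd_params = apply_upf1_kd(fit.params, kd)
            for c in conditions:
                pred = steady_state_total(
                    fit.model_id, kd_params, fit.features, c.trna_sec_level
                )
                rows.append(
                    {
                        "gene_id": g,
                        "selenite_nM": c.selenite_nM,
                        "kd_fraction": float(kd),
                        "predicted_abundance": pred,
                        "fold_change": pred / baseline[c.selenite_nM],
                    }
                )
    return pd.DataFrame(rows)


def compare_kd_observations(
    predictions: pd.DataFrame,
    observed: pd.DataFrame,
    z_flag: float = 2.0,
) -> pd.DataFrame:
    """Flag genes whose observed knockdown response leaves the prediction band.

    ``observed`` is replicate-level with columns ``gene_id, selenite_nM,
    kd_fraction, replicate, abundance`` where abundance is already expressed
    as fold change vs the unperturbed control at the same condition.  Rows are
    matched on (gene, condition, kd level); a row is discordant when the
    predicted fold change lies more than ``z_flag`` standard errors from the
    observed mean, and a gene is flagged when more than half of its matched
    rows are discordant (an SPS2-like disagreement pattern)."""
    required = {"gene_id", "selenite_nM", "kd_fraction", "replicate", "abundance"}
    missing = required - set(observed.columns)
    if missing:
        raise ValueError(f"observed table missing column(s) {sorted(missing)}")
    stats = (
        observed.groupby(["gene_id", "selenite_nM", "kd_fraction"])["abundance"]
        .agg(["mean", "std", "size"])
        .reset_index()
    )
    stats["se"] = stats["std"] / np.sqrt(stats["size"])
    merged = stats.merge(
        predictions, on=["gene_id", "selenite_nM", "kd_fraction"], how="inner"
    )
    if merged.empty:
        raise ValueError("no overlapping (gene, condition, kd) rows between tables")
    merged["z"] = (merged["fold_change"] - merged["mean"]) / merged["se"].replace(0.0, np.nan)
    merged["discordant"] = merged["z"].abs() > z_flag
    summary = (
        merged.groupby("gene_id")["discordant"]
        .mean()
        .rename("discordant_fraction")
        .reset_index()
    )
    summary["flagged"] = summary["discordant_fraction"] > 0.5
    return merged.merge(summary, on="gene_id")
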