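"""Per-transcript structural features of selenoprotein mRNAs.

Selenoprotein mRNAs carry an in-frame UGA codon that is either recoded as
selenocysteine (Sec) or read as a premature termination codon (PTC).  Two
structural quantities enter the kinetic models: the number of codons from the
start codon to the Sec UGA, and from the UGA to the stop codon (they set the
length-dependent elongation rates of the two segments).  A third quantity, the
distance in nucleotides from the UGA to the nearest downstream exon-exon
junction, determines whether the transcript is a predicted target of
nonsense-mediated decay (NMD) under the canonical positional rule: a PTC lying
at least ~50 nt upstream of an exon junction marks the transcript for NMD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TranscriptFeatures",
    "PanelSchemaError",
    "nmd_rule_classifier",
    "read_gene_panel",
    "write_gene_panel",
    "NMD_RULE_THRESHOLD_NT",
]

#: Default positional-rule threshold (nt). The canonical rule is a 50-55 nt
#: band; the lower edge is used by default and is configurable everywhere.
NMD_RULE_THRESHOLD_NT = 50

PANEL_COLUMNS = (
    "gene_id",
    "codons_start_to_uga",
    "codons_uga_to_stop",
    "ptc_to_junction_nt",
)


class PanelSchemaError(ValueError):
    """Raised when a gene-panel table violates the expected CSV schema."""


@dataclass(frozen=True)
class TranscriptFeatures:
    """Structural description of one selenoprotein transcript.

    Parameters
    ----------
    gene_id:
        Unique gene label within a panel.
    codons_start_to_uga:
        Codons from the initiation codon to the Sec UGA (>= 1).
    codons_uga_to_stop:
        Codons from the Sec UGA to the stop codon (>= 1).
    ptc_to_junction_nt:
        Distance (nt) from the Sec UGA to the nearest *downstream* exon-exon
        junction; ``0`` encodes "no downstream junction".
    """

    gene_id: str
    codons_start_to_uga: int
    codons_uga_to_stop: int
    ptc_to_junction_nt: int = 0

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be a non-empty string")
        for name in ("codons_start_to_uga", "codons_uga_to_stop"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if int(self.ptc_to_junction_nt) != self.ptc_to_junction_nt or self.ptc_to_junction_nt < 0:
            raise ValueError(
                f"ptc_to_junction_nt must be a non-negative integer, got {self.ptc_to_junction_nt!r}"
            )

    @property
    def is_predicted_nmd_target(self) -> bool:
        return nmd_rule_classifier(self.ptc_to_junction_nt)


def nmd_rule_classifier(ptc_to_junction_nt: int, threshold: int = NMD_RULE_THRESHOLD_NT) -> bool:
    """Positional NMD rule: is the transcript a predicted NMD target?

    Returns ``True`` iff a downstream exon junction exists
    (``ptc_to_junction_nt > 0``) and the UGA lies at least ``threshold`` nt
    upstream of it.
    """
    if ptc_to_junction_nt < 0:
        raise ValueError(f"ptc_to_junction_nt must be >= 0, got {ptc_to_junction_nt}")
    return ptc_to_junction_nt > 0 and ptc_to_junction_nt >= threshold


def read_gene_panel(path: str | Path) -> list[TranscriptFeatures]:
    """Read a gene panel from CSV (columns ``gene_id,codons_start_to_uga,codons_uga_to_stop,ptc_to_junction_nt``)."""
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"gene panel {path}: missing column(s) {missing}")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise PanelSchemaError(f"gene panel {path}: duplicated gene_id(s) {dupes}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                TranscriptFeatures(
                    gene_id=str(row["gene_id"]),
                    codons_start_to_uga=int(row["codons_start_to_uga"]),
                    codons_uga_to_stop=int(row["codons_uga_to_stop"]),
                    ptc_to_junction_nt=int(row["ptc_to_junction_nt"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise PanelSchemaError(f"gene panel {path}, row {idx}: {exc}") from exc
    return out


def write_gene_panel(features: Iterable[TranscriptFeatures], path: str | Path) -> None:
    rows: Sequence[TranscriptFeatures] = list(features)
    df = pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in rows],
            "codons_start_to_uga": [f.codons_start_to_uga for f in rows],
            "codons_uga_to_stop": [f.codons_uga_to_stop for f in rows],
            "ptc_to_junction_nt": [f.ptc_to_junction_nt for f in rows],
        }
    )
    df.to_csv(path, index=False)
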