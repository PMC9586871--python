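"""Genomic feature encoding: oncogenic-alteration indicators and TMB.

The gene panel covers alterations commonly studied in NSCLC immunotherapy
response: oncogenes (EGFR, ALK, ROS1, RET, ERBB2, BRAF, MET), the tumor
suppressor STK11 and the transcription regulator ARID1A.  A gene's bit is set
iff the patient carries at least one alteration flagged oncogenic/driver by
the annotation source (e.g. OncoKB); variants not so flagged are ignored.
TMB is the mutation count divided by the megabases of coding region captured
by the panel; >= 10 mutations/Mb is the conventional TMB-high stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed gene order of the alteration-bit vector.
GENE_PANEL = ("EGFR", "ALK", "ROS1", "RET", "ERBB2", "BRAF", "MET", "STK11", "ARID1A")

#: TMB-high cut, mutations per megabase.
TMB_HIGH = 10.0

#: Alteration types that count toward the bits but not toward the TMB
#: mutation count.
NON_MUTATION_TYPES = {"CNA", "FUSION"}


@dataclass
class GenomicBlock:
    """Alteration bits over :data:`GENE_PANEL` plus TMB (mutations/Mb)."""

    alteration_bits: np.ndarray
    tmb: float

    def __post_init__(self) -> None:
        self.alteration_bits = np.asarray(self.alteration_bits, dtype=int)
        if self.alteration_bits.shape != (len(GENE_PANEL),):
            raise ValueError(f"alteration bits must have length {len(GENE_PANEL)}")
        if not np.isin(self.alteration_bits, (0, 1)).all():
            raise ValueError("alteration bits must be binary")
        if self.tmb < 0:
            raise ValueError("TMB must be nonnegative")

    @property
    def tmb_high(self) -> bool:
        return self.tmb >= TMB_HIGH

    def to_vector(self) -> np.ndarray:
        """Concatenated model input: bits then TMB (TMB last by convention)."""
        return np.concatenate([self.alteration_bits.astype(float), [self.tmb]])


def encode_alterations(mutation_table: pd.DataFrame, gene_panel=GENE_PANEL) -> np.ndarray:
    """Binary oncogenic-alteration vector over ``gene_panel``.

    ``mutation_table`` needs ``gene`` and ``oncogenic`` columns; rows for
    genes outside the panel are ignored (logged once per call).
    """
    for col in ("gene", "oncogenic"):
        if col not in mutation_table.columns:
            raise ValueError(f"mutation table lacks column {col!r}")
    bits = np.zeros(len(gene_panel), dtype=int)
    unknown = set()
    for _, row in mutation_table.iterrows():
        gene = str(row["gene"])
        if gene not in gene_panel:
            unknown.add(gene)
            continue
        if bool(row["oncogenic"]):
            bits[gene_panel.index(gene)] = 1
    if unknown:
        logger.info("ignored %d gene symbols outside panel: %s", len(unknown), sorted(unknown))
    return bits


def compute_tmb(n_mutations: int, panel_mb: float) -> float:
    """Tumor mutational burden: mutations per megabase captured."""
    if panel_mb <= 0:
        raise ValueError("panel_mb must be positive")
    if n_mutations < 0:
        raise ValueError("mutation count must be nonnegative")
    return n_mutations / panel_mb


def genomic_block(mutation_table: pd.DataFrame, panel_mb: float, gene_panel=GENE_PANEL) -> GenomicBlock:
    """Build the full genomic block for one patient.

    Copy-number alterations and fusions count toward alteration bits when
    flagged oncogenic but are excluded from the TMB mutation count.
    """
    bits = encode_alterations(mutation_table, gene_panel)
    if "alteration_type" in mutation_table.columns:
        is_mut = ~mutation_table["alteration_type"].astype(str).str.upper().isin(NON_MUTATION_TYPES)
        n_mut = int(is_mut.sum())
    else:
        n_mut = len(mutation_table)
    return GenomicBlock(alteration_bits=bits, tmb=compute_tmb(n_mut, panel_mb))
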