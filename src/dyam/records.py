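"""Core data containers shared across modules.

A patient in the multimodal cohort carries up to five feature blocks
("modalities"): radiomics texture from CT lesions at three anatomical sites
(lung parenchyma, pleura, lymph node), a PD-L1 immunohistochemistry texture
block plus the tumor proportion score (TPS), and a genomic block (oncogenic
alteration indicators + tumor mutational burden).  Radiology and pathology
blocks may be absent — not every patient has segmentable disease or a
PD-L1-positive slide — while the genomic block is always present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Anatomical sites a CT lesion can be annotated with.
LESION_SITES = ("parenchymal", "pleural", "node")

#: Ordered modality names of the fusion model.  CT sites come first so the
#: three radiology blocks keep their Fig-style grouping; order is otherwise a
#: convention (model outputs are invariant to it).
MODALITIES = ("ct_parenchymal", "ct_pleural", "ct_node", "ihc", "genomics")

#: Cap on the number of target lesions per patient (RECIST-style target-lesion
#: selection, relaxed to six).
MAX_LESIONS = 6


@dataclass
class Lesion:
    """One segmented lesion: its site label, feature vector and volume."""

    site: str
    features: np.ndarray
    volume_cm3: float = 1.0

    def __post_init__(self) -> None:
        if self.site not in LESION_SITES:
            raise ValueError(f"unknown lesion site {self.site!r}; expected one of {LESION_SITES}")
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("lesion features must be a 1-D vector")
        if self.volume_cm3 <= 0:
            raise ValueError("lesion volume must be positive")


@dataclass
class LesionBag:
    """Variable-length set of per-lesion radiomics vectors with site labels.

    Bags hold between 1 and :data:`MAX_LESIONS` lesions; all lesions at the
    same site must share a feature length.
    """

    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.lesions) <= MAX_LESIONS:
            raise ValueError(f"a lesion bag holds 1..{MAX_LESIONS} lesions, got {len(self.lesions)}")
        for site in LESION_SITES:
            lengths = {len(les.features) for les in self.lesions if les.site == site}
            if len(lengths) > 1:
                raise ValueError(f"unequal feature lengths within site {site!r}: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def sites(self) -> set[str]:
        return {les.site for les in self.lesions}

    def site_features(self, site: str) -> np.ndarray:
        """Stack feature vectors of lesions at ``site`` into a (k, d) array."""
        rows = [les.features for les in self.lesions if les.site == site]
        if not rows:
            raise KeyError(f"no lesions at site {site!r}")
        return np.stack(rows)

    def site_mean(self, site: str) -> np.ndarray:
        """Lesion-averaged feature vector for one site (the site-block input)."""
        return self.site_features(site).mean(axis=0)


@dataclass
class MultimodalRecord:
    """One patient's modality feature blocks, presence mask and outcomes."""

    patient_id: str
    response: int
    pfs_months: float
    pfs_event: int
    lesion_bag: Optional[LesionBag] = None
    ihc_features: Optional[np.ndarray] = None
    tps: Optional[float] = None
    genomic_features: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError("response must be binary")
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be nonnegative")
        if self.pfs_event not in (0, 1):
            raise ValueError("pfs_event must be binary")
        if self.tps is None and self.ihc_features is not None:
            raise ValueError("ihc_features present without a TPS")
        if self.ihc_features is not None:
            self.ihc_features = np.asarray(self.ihc_features, dtype=float)
        self.genomic_features = np.asarray(self.genomic_features, dtype=float)

    @property
    def tmb(self) -> float:
        """Tumor mutational burden, stored as the last genomic feature."""
        return float(self.genomic_features[-1])

    @property
    def presence_mask(self) -> dict[str, bool]:
        """Which of the five modality blocks this patient carries."""
        sites = self.lesion_bag.sites() if self.lesion_bag is not None else set()
        return {
            "ct_parenchymal": "parenchymal" in sites,
            "ct_pleural": "pleural" in sites,
            "ct_node": "node" in sites,
            "ihc": self.ihc_features is not None,
            "genomics": self.genomic_features.size > 0,
        }

    def modality_vector(self, modality: str) -> np.ndarray:
        """Feature vector for one modality block (KeyError if absent)."""
        if modality == "ihc":
            if self.ihc_features is None:
                raise KeyError("ihc block absent")
            # TPS rides along with the texture block when available.
            return np.concatenate([self.ihc_features, [self.tps]])
        if modality == "genomics":
            if self.genomic_features.size == 0:
                raise KeyError("genomics block absent")
            return self.genomic_features
        if modality.startswith("ct_"):
            site = modality[3:]
            if self.lesion_bag is None:
                raise KeyError("no lesion bag")
            return self.lesion_bag.site_mean(site)
        raise KeyError(f"unknown modality {modality!r}")


def cohort_labels(cohort: Sequence[MultimodalRecord]) -> np.ndarray:
    return np.array([rec.response for rec in cohort], dtype=int)


def cohort_survival(cohort: Sequence[MultimodalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([rec.pfs_months for rec in cohort], dtype=float)
    events = np.array([rec.pfs_event for rec in cohort], dtype=int)
    return times, events
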