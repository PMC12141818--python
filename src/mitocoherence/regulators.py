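"""Within-tissue regulator associations and proliferation-coupled discrepancy.

Two questions, both answered per tissue and then compared across tissues:

1. Is the expression of an energy-sensing regulator (PGC-1alpha, the ISR
   genes, NRF1/NRF2/TFAM/POLG) associated with mitochondrial gene
   expression (mito-nDNA% or mtDNA%) across individuals within a tissue?
2. Is the within-tissue coupling of mtDNA% with mito-nDNA% explained by
   the tissue's proliferative activity?  Post-mitotic tissues can hold
   abundant mitochondria with little ongoing nuclear biogenesis, while
   dividing tissues must transcribe both genomes to replenish dilution —
   predicting a positive across-tissue relation between the coupling and
   the proliferation score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import UndefinedCorrelationError
from .coherence import spearman

logger = logging.getLogger(__name__)


def intra_tissue_association(
    table: pd.DataFrame,
    regulator: str,
    mito: str,
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-tissue Spearman association of a regulator feature with a mito index.

    Tissues with fewer than ``min_n`` subjects (complete on both features)
    are skipped with a log entry.  Returns a DataFrame with columns
    ``tissue, r, p, n`` sorted by r descending (ranked presentation).
    """
    rows = []
    for tissue, sub in table.groupby("tissue"):
        pairs = sub[[regulator, mito]].dropna()
        if len(pairs) < min_n:
            logger.info("tissue %s below min_n (%d < %d)", tissue, len(pairs), min_n)
            continue
        try:
            r, p = spearman(pairs[regulator], pairs[mito])
        except UndefinedCorrelationError as exc:
            logger.info("tissue %s: %s", tissue, exc)
            continue
        rows.append((tissue, r, p, len(pairs)))
    out = pd.DataFrame(rows, columns=["tissue", "r", "p", "n"])
    return out.sort_values("r", ascending=False).reset_index(drop=True)


def compare_profiles(profile_a: pd.Series, profile_b: pd.Series) -> tuple[float, float]:
    """Spearman correlation across tissues of two per-tissue r profiles.

    Both inputs are Series indexed by tissue; only common tissues enter.
    """
    common = profile_a.index.intersection(profile_b.index)
    if len(common) < 3:
        raise UndefinedCorrelationError(f"only {len(common)} common tissues")
    return spearman(profile_a.loc[common], profile_b.loc[common])


@dataclass
class CouplingByProliferation:
    """Per-tissue mtDNA%–mito-nDNA% coupling and its relation to proliferation."""

    per_tissue: pd.DataFrame  # tissue, coupling_r, coupling_p, n, proliferation
    meta_r: float
    meta_p: float


def coupling_by_proliferation(
    table: pd.DataFrame,
    min_n: int = 10,
    mtdna: str = "mtdna_pct",
    mito_ndna: str = "mito_ndna_pct",
    proliferation: str = "proliferation_score",
) -> CouplingByProliferation:
    """Relate within-tissue mtDNA/nuclear coupling to tissue proliferation.

    For each tissue with at least ``min_n`` complete subjects, computes the
    Spearman coupling r(mtDNA%, mito-nDNA%) and the tissue-level
    proliferation score (mean over the tissue's rows).  The meta-correlation
    is the Spearman correlation over tissues of coupling r versus
    proliferation — one point per tissue, never per subject.
    """
    coupling = intra_tissue_association(table, mtdna, mito_ndna, min_n=min_n)
    coupling = coupling.rename(columns={"r": "coupling_r", "p": "coupling_p"})
    prolif = table.groupby("tissue")[proliferation].mean()
    per_tissue = coupling.merge(
        prolif.rename("proliferation"), left_on="tissue", right_index=True
    )
    if len(per_tissue) < 3:
        raise UndefinedCorrelationError("fewer than 3 eligible tissues")
    meta_r, meta_p = spearman(per_tissue["coupling_r"], per_tissue["proliferation"])
    return CouplingByProliferation(
        per_tissue=per_tissue.reset_index(drop=True), meta_r=meta_r, meta_p=meta_p
    )


class RegulatorAssociation:
    """Model: per-tissue association profile of a regulator with a mito index."""

    def __init__(self, table: pd.DataFrame, regulator: str, mito: str = "mito_ndna_pct",
                 min_n: int = 10, alpha: float = 0.05):
        self.table = table
        self.regulator = regulator
        self.mito = mito
        self.min_n = min_n
        self.alpha = alpha

    def fit(self) -> "RegulatorAssociationResults":
        profile = intra_tissue_association(
            self.table, self.regulator, self.mito, min_n=self.min_n
        )
        return RegulatorAssociationResults(model=self, profile=profile)


@dataclass
class RegulatorAssociationResults:
    model: RegulatorAssociation
    profile: pd.DataFrame

    @property
    def r_by_tissue(self) -> pd.Series:
        return self.profile.set_index("tissue")["r"]

    def n_significant(self, sign: int) -> int:
        """Count tissues with significant association of the given sign."""
        sig = self.profile["p"] < self.model.alpha
        if sign > 0:
            return int((sig & (self.profile["r"] > 0)).sum())
        return int((sig & (self.profile["r"] < 0)).sum())

    def compare(self, other: "RegulatorAssociationResults") -> tuple[float, float]:
        """Spearman agreement of this profile with another regulator's profile."""
        return compare_profiles(self.r_by_tissue, other.r_by_tissue)

    def summary(self) -> pd.DataFrame:
        out = self.profile.copy()
        out["significant"] = out["p"] < self.model.alpha
        return out


class ProliferationCoupling:
    """Model: tissue proliferation as the driver of mtDNA/nuclear coupling."""

    def __init__(self, table: pd.DataFrame, min_n: int = 10):
        self.table = table
        self.min_n = min_n

    def fit(self) -> CouplingByProliferation:
        return coupling_by_proliferation(self.table, min_n=self.min_n)
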