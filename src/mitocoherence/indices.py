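"""Transcriptome-based mitochondrial indices.

For every sample the transcriptome is split by gene origin:

* mtDNA% — share of *all* transcripts encoded on the mitochondrial genome,
  a proxy for mitochondrial content;
* mito-nDNA% — share of the *nuclear* transcriptome (all non-mtDNA
  transcripts) mapping to nuclear-encoded mitochondrial genes, a proxy for
  nuclear investment in mitochondrial biogenesis;
* set percentages — the same nuclear-share construction for any named gene
  set (PGC-1alpha, ISR, NRF1/NRF2/TFAM/POLG, pathway subsets);
* proliferation score — the mean TPM-like abundance of KI67, TOP2A and
  RRM2, a proxy for replicative activity.

All percentages are scale-free: multiplying a sample's profile by a
constant leaves them unchanged.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CatalogError, DegenerateInputError, MetadataError
from .io import ExpressionMatrix, FEATURE_KEY, GeneCatalog


def mtdna_percent(profile: pd.Series, catalog: GeneCatalog) -> float:
    """Percentage of all transcripts derived from mtDNA-encoded genes."""
    total = float(profile.sum())
    if total <= 0:
        raise DegenerateInputError("zero total abundance")
    mt = float(profile[profile.index.isin(catalog.mtdna_genes)].sum())
    return 100.0 * mt / total


def nuclear_set_percent(profile: pd.Series, catalog: GeneCatalog, set_name: str) -> float:
    """Percentage of the nuclear transcriptome in a named nuclear gene set.

    All mtDNA transcripts are removed first; the set total is expressed as a
    percentage of the remaining (nuclear) transcripts.  ``set_name`` of
    ``"mito_nuclear"`` yields mito-nDNA%.
    """
    genes = catalog.get_set(set_name)
    bad = genes & catalog.mtdna_genes
    if bad:
        raise CatalogError(f"set {set_name!r} contains mtDNA genes: {sorted(bad)[:5]}")
    is_mt = profile.index.isin(catalog.mtdna_genes)
    nuclear_total = float(profile[~is_mt].sum())
    if nuclear_total <= 0:
        raise DegenerateInputError("zero nuclear abundance")
    subset = float(profile[profile.index.isin(genes) & ~is_mt].sum())
    return 100.0 * subset / nuclear_total


def proliferation_score(profile: pd.Series, catalog: GeneCatalog) -> float:
    """Mean abundance of the proliferation marker genes (KI67, TOP2A, RRM2)."""
    genes = sorted(catalog.get_set("proliferation"))
    missing = [g for g in genes if g not in profile.index]
    if missing:
        raise CatalogError(f"proliferation gene missing from matrix: {missing[0]!r}")
    return float(profile[genes].mean())


def build_index_table(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    catalog: GeneCatalog,
    set_names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Compute all indices per sample and collapse to one row per (subject, tissue).

    ``set_names`` defaults to every named set in the catalog except
    ``proliferation`` (which feeds the score, not a percentage).  When a
    subject has several samples of one tissue the indices are averaged.
    """
    data = matrix.data
    annotated = set(samples["sample_id"])
    unknown = [s for s in matrix.sample_ids if s not in annotated]
    if unknown:
        raise MetadataError(f"sample not annotated in metadata: {unknown[0]!r}")

    values = data.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise DegenerateInputError("sample with zero total abundance")
    is_mt = data.index.isin(catalog.mtdna_genes)
    mt_totals = values[is_mt].sum(axis=0)
    nuclear_totals = totals - mt_totals
    if (nuclear_totals <= 0).any():
        raise DegenerateInputError("sample with zero nuclear abundance")

    out = pd.DataFrame(index=data.columns)
    out["mtdna_pct"] = 100.0 * mt_totals / totals
    is_nmito = data.index.isin(catalog.mito_nuclear_genes) & ~is_mt
    out["mito_ndna_pct"] = 100.0 * values[is_nmito].sum(axis=0) / nuclear_totals

    if set_names is None:
        set_names = [n for n in catalog.named_sets if n != "proliferation"]
    for name in set_names:
        genes = catalog.get_set(name)
        bad = genes & catalog.mtdna_genes
        if bad:
            raise CatalogError(f"set {name!r} contains mtDNA genes: {sorted(bad)[:5]}")
        mask = data.index.isin(genes) & ~is_mt
        out[f"{name}_pct"] = 100.0 * values[mask].sum(axis=0) / nuclear_totals

    if "proliferation" in catalog.named_sets:
        genes = sorted(catalog.get_set("proliferation"))
        missing = [g for g in genes if g not in data.index]
        if missing:
            raise CatalogError(f"proliferation gene missing from matrix: {missing[0]!r}")
        out["proliferation_score"] = values[data.index.isin(genes)].mean(axis=0)

    out = out.reset_index(names="sample_id")
    merged = out.merge(
        samples[["sample_id", "subject_id", "tissue"]], on="sample_id", how="left"
    )
    feature_cols = [c for c in out.columns if c != "sample_id"]
    table = (
        merged.groupby(list(FEATURE_KEY), as_index=False, sort=True)[feature_cols]
        .mean()
    )
    return table


def tissue_means(table: pd.DataFrame, feature: str) -> pd.Series:
    """Mean of a feature per tissue (one value per subject first)."""
    return table.groupby("tissue")[feature].mean().sort_values(ascending=False)


def fold_range(means: Mapping[str, float] | pd.Series) -> float:
    """Ratio of the highest to the lowest tissue mean."""
    vals = np.asarray(pd.Series(means), dtype=float)
    if vals.size == 0 or (vals <= 0).any():
        raise DegenerateInputError("fold range requires strictly positive means")
    return float(vals.max() / vals.min())
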