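"""Reading, validation and filtering of the tabular inputs.

Three kinds of tables flow through the pipeline:

* expression matrices — genes x samples, TPM-like units, wide or long layout;
* sample metadata — one row per RNAseq sample with subject, tissue, tissue
  class (brain / body / cell_line) and RIN;
* feature tables — one row per (subject, tissue) carrying any per-tissue
  quantity: transcript-based indices, enzymatic activities, mtDNA copy
  number, protein percentages.

The same feature-table carrier serves every downstream analysis, so
correlation structure can be computed for transcript indices and for
externally measured features with no code change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CatalogError, MetadataError, ParameterError, ParseError

SAMPLE_COLUMNS = ("sample_id", "subject_id", "tissue", "tissue_class", "rin")
TISSUE_CLASSES = ("brain", "body", "cell_line")

#: column names marking the row key of a feature table
FEATURE_KEY = ("subject_id", "tissue")


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


class ExpressionMatrix:
    """Genes x samples abundance matrix in TPM-like units.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by gene ID, columns by sample ID, non-negative values.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ParseError(f"duplicate gene ID: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ParseError(f"duplicate sample ID: {dup!r}")
        if data.size == 0:
            raise ParseError("empty expression table")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            gene = data.index[np.isnan(values).any(axis=1)][0]
            raise ParseError(f"missing value in gene row {gene!r}")
        if (values < 0).any():
            gene = data.index[(values < 0).any(axis=1)][0]
            raise ParseError(f"negative abundance in gene row {gene!r}")
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            sample = data.columns[np.flatnonzero(totals <= 0)[0]]
            raise ParseError(f"sample {sample!r} has zero total abundance")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    @classmethod
    def from_file(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a wide (gene x sample) or long (gene, sample, value) table.

        The layout is detected from the header: a table whose first three
        column names are gene/sample/value-like is treated as long format.
        """
        sep = _sep_for(path)
        try:
            df = pd.read_csv(path, sep=sep, header=0, dtype={0: str})
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"cannot read expression table {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: malformed header")
        cols = [c.lower() for c in df.columns]
        if len(cols) == 3 and cols[0] in ("gene", "gene_id") and cols[1] in ("sample", "sample_id"):
            wide = df.pivot_table(
                index=df.columns[0], columns=df.columns[1],
                values=df.columns[2], aggfunc="first",
            )
            wide.index.name = None
            wide.columns.name = None
            return cls(wide)
        first = df.columns[0]
        dup_mask = df[first].duplicated()
        if dup_mask.any():
            raise ParseError(f"duplicate gene ID: {df[first][dup_mask].iloc[0]!r}")
        wide = df.set_index(first)
        wide.index.name = None
        return cls(wide)

    def to_file(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep=_sep_for(path))


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata and validate its required columns."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "subject_id": str})
    return validate_sample_table(df)


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ParseError(f"sample table missing columns: {', '.join(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MetadataError(f"duplicate sample_id: {dup!r}")
    bad = set(samples["tissue_class"].dropna()) - set(TISSUE_CLASSES)
    if bad:
        raise MetadataError(f"unknown tissue_class values: {sorted(bad)}")
    return samples.reset_index(drop=True)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep=_sep_for(path), index=False)


@dataclass(frozen=True)
class GeneCatalog:
    """Partition of gene IDs into mtDNA / nuclear-mito / other, plus named sets.

    ``named_sets`` carries the regulator and pathway gene sets used by the
    index computations: ``isr`` (ATF4, ATF5, DDIT3, GDF15), ``proliferation``
    (KI67, TOP2A, RRM2) and singleton sets for PPARGC1A, NRF1, NRF2, TFAM
    and POLG by convention, with arbitrary extra pathway subsets allowed.
    """

    mtdna_genes: frozenset[str]
    mito_nuclear_genes: frozenset[str]
    named_sets: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        overlap = self.mtdna_genes & self.mito_nuclear_genes
        if overlap:
            raise CatalogError(
                f"genes in both mtDNA and nuclear-mito sets: {sorted(overlap)[:5]}"
            )
        for name, genes in self.named_sets.items():
            inter = frozenset(genes) & self.mtdna_genes
            if inter:
                raise CatalogError(
                    f"named set {name!r} contains mtDNA genes: {sorted(inter)[:5]}"
                )

    def get_set(self, name: str) -> frozenset[str]:
        if name == "mito_nuclear":
            return self.mito_nuclear_genes
        if name == "mtdna":
            return self.mtdna_genes
        try:
            return frozenset(self.named_sets[name])
        except KeyError:
            raise CatalogError(f"unknown gene set: {name!r}") from None

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneCatalog":
        """Read a two-column (gene_id, set_name) table; multiple memberships allowed."""
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
        if not {"gene_id", "set_name"} <= set(df.columns):
            raise ParseError("gene catalog needs columns gene_id, set_name")
        groups = {name: frozenset(sub["gene_id"]) for name, sub in df.groupby("set_name")}
        return cls(
            mtdna_genes=groups.pop("mtdna", frozenset()),
            mito_nuclear_genes=groups.pop("mito_nuclear", frozenset()),
            named_sets=groups,
        )

    def to_file(self, path: str | Path) -> None:
        rows = [(g, "mtdna") for g in sorted(self.mtdna_genes)]
        rows += [(g, "mito_nuclear") for g in sorted(self.mito_nuclear_genes)]
        for name in sorted(self.named_sets):
            rows += [(g, name) for g in sorted(self.named_sets[name])]
        pd.DataFrame(rows, columns=["gene_id", "set_name"]).to_csv(
            path, sep=_sep_for(path), index=False
        )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"subject_id": str, "tissue": str})
    missing = [c for c in FEATURE_KEY if c not in df.columns]
    if missing:
        raise ParseError(f"feature table missing key columns: {', '.join(missing)}")
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep=_sep_for(path), index=False)


def apply_sample_filters(
    samples: pd.DataFrame,
    rin_cutoff: float = 5.5,
    exclude_classes: Iterable[str] = ("cell_line",),
) -> pd.DataFrame:
    """Apply the sample eligibility rules: RIN cutoff and tissue-class removal.

    Samples with RIN below ``rin_cutoff`` are dropped; samples with missing
    RIN are retained only when the cutoff is 0 (fail-safe toward exclusion).
    Original row order is preserved.
    """
    if rin_cutoff < 0:
        raise ParameterError("rin_cutoff must be >= 0")
    excl = set(exclude_classes)
    keep = ~samples["tissue_class"].isin(excl)
    if rin_cutoff > 0:
        keep &= samples["rin"].notna() & (samples["rin"] >= rin_cutoff)
    return samples.loc[keep].reset_index(drop=True)


def shared_subject_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Count subjects observed in both tissues for every unordered tissue pair."""
    present = (
        table[list(FEATURE_KEY)]
        .drop_duplicates()
        .assign(one=1)
        .pivot(index="subject_id", columns="tissue", values="one")
        .notna()
    )
    tissues = sorted(present.columns)
    rows = []
    for a, b in itertools.combinations(tissues, 2):
        rows.append((a, b, int((present[a] & present[b]).sum())))
    return pd.DataFrame(rows, columns=["tissue_a", "tissue_b", "n_shared"])


def eligible_tissue_pairs(
    table: pd.DataFrame,
    min_shared: int = 10,
    tissue_fraction: float = 0.5,
) -> pd.DataFrame:
    """Determine eligible tissue pairs and tissues.

    A pair is eligible when at least ``min_shared`` subjects are observed in
    both tissues.  A tissue is retained only when it forms eligible pairs
    with strictly more than ``tissue_fraction`` of the other retained
    tissues; removal is iterated to a fixed point because dropping one
    tissue can disqualify another.

    Returns a DataFrame of all pairs among retained tissues with columns
    ``tissue_a, tissue_b, n_shared, eligible``.
    """
    if min_shared < 2:
        raise ParameterError("min_shared must be >= 2")
    if not 0 <= tissue_fraction <= 1:
        raise ParameterError("tissue_fraction must be in [0, 1]")
    counts = shared_subject_counts(table)
    counts["eligible"] = counts["n_shared"] >= min_shared
    tissues = sorted(set(counts["tissue_a"]) | set(counts["tissue_b"]))
    retained = set(tissues)
    while True:
        if len(retained) < 2:
            retained = set() if len(retained) < 2 else retained
            break
        sub = counts[counts["tissue_a"].isin(retained) & counts["tissue_b"].isin(retained)]
        deg = {t: 0 for t in retained}
        for _, row in sub[sub["eligible"]].iterrows():
            deg[row["tissue_a"]] += 1
            deg[row["tissue_b"]] += 1
        n_other = len(retained) - 1
        drop = {t for t in retained if deg[t] <= tissue_fraction * n_other}
        if not drop:
            break
        retained -= drop
    out = counts[
        counts["tissue_a"].isin(retained) & counts["tissue_b"].isin(retained)
    ].reset_index(drop=True)
    return out


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows per (subject, tissue) by the arithmetic mean.

    Missing cells are ignored in the mean; non-numeric columns other than
    the key are dropped.
    """
    value_cols = [
        c for c in table.columns
        if c not in FEATURE_KEY and pd.api.types.is_numeric_dtype(table[c])
    ]
    out = (
        table.groupby(list(FEATURE_KEY), as_index=False, sort=False)[value_cols]
        .mean()
    )
    return out
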