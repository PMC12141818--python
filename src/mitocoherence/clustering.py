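"""Multi-tissue mitochondrial phenotyping by k-means on inter-tissue ratios.

Subjects with complete data across a selected tissue panel are described by
log2 ratios of a mitochondrial index between every unordered tissue pair,
z-scored per feature.  k-means on these ratio features identifies subgroups
with distinct multi-tissue mitochondrial distribution patterns; the
subgroups are then characterized by per-tissue contrasts (two-way ANOVA,
Hedges' g) and by enrichment of binary clinical variables (z-scored
prevalence per cluster).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RatioFeatures:
    """Per-subject inter-tissue log2-ratio features.

    ``features`` is z-scored per column; ``raw`` keeps the un-standardized
    log2 ratios.  Column names are ``"<a>/<b>"`` for the unordered tissue
    pair (a, b) in panel order.
    """

    features: pd.DataFrame
    raw: pd.DataFrame
    tissues: tuple[str, ...]
    dropped_subjects: tuple[str, ...]


def compute_ratio_features(
    table: pd.DataFrame, feature: str, tissues: Sequence[str]
) -> RatioFeatures:
    """Build z-scored log2 inter-tissue ratio features for complete-case subjects.

    Subjects missing any selected tissue, or with a non-positive index in
    one, are dropped (logged).  With T tissues each subject gets C(T, 2)
    features.
    """
    tissues = list(tissues)
    if len(tissues) < 2:
        raise ParameterError("need at least 2 tissues")
    wide = (
        table[table["tissue"].isin(tissues)]
        .pivot(index="subject_id", columns="tissue", values=feature)
        .reindex(columns=tissues)
    )
    complete = wide.dropna()
    positive = complete[(complete > 0).all(axis=1)]
    dropped = tuple(sorted(set(wide.index) - set(positive.index)))
    if dropped:
        logger.info("dropped %d subjects (missing tissue or non-positive index)", len(dropped))
    raw = pd.DataFrame(index=positive.index)
    for a, b in itertools.combinations(tissues, 2):
        raw[f"{a}/{b}"] = np.log2(positive[a] / positive[b])
    sd = raw.std(ddof=0)
    z = (raw - raw.mean()) / sd.replace(0, np.nan)
    z = z.fillna(0.0)
    return RatioFeatures(
        features=z, raw=raw, tissues=tuple(tissues), dropped_subjects=dropped
    )


def kmeans_cluster(
    features: RatioFeatures | pd.DataFrame,
    k: int,
    seed: int,
    n_restarts: int = 10,
) -> pd.Series:
    """k-means (k-means++ seeding, Lloyd iterations, best of ``n_restarts``).

    Deterministic for a fixed seed and restart count.  Returns labels
    (0..k-1) indexed by subject.
    """
    x = features.features if isinstance(features, RatioFeatures) else features
    if not 2 <= k <= len(x):
        raise ParameterError(f"k must be in [2, {len(x)}]")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(x.to_numpy())
    return pd.Series(labels, index=x.index, name="cluster")


def pca_variance(features: RatioFeatures | pd.DataFrame) -> np.ndarray:
    """Fractions of variance per principal component (descending, sum 1)."""
    x = features.features if isinstance(features, RatioFeatures) else features
    arr = x.to_numpy(dtype=float)
    if arr.shape[0] < 3 or arr.shape[1] < 2:
        raise ParameterError("need >= 3 subjects and >= 2 features")
    cov = np.cov(arr, rowvar=False)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0, None)
    total = eig.sum()
    if total <= 0:
        raise DegenerateInputError("zero total variance")
    return eig / total


def hedges_g(x: Sequence[float], y: Sequence[float]) -> float:
    """Bias-corrected standardized mean difference J * (mean_x - mean_y) / s_pooled.

    J = 1 - 3 / (4 * df - 1) with df = n_x + n_y - 2.  NaN when the pooled
    variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    if df <= 0:
        raise ParameterError("each group needs at least one value; df must be > 0")
    pooled = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled <= 0:
        return float("nan")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(j * (x.mean() - y.mean()) / np.sqrt(pooled))


def cluster_anova(
    table: pd.DataFrame,
    labels: pd.Series,
    tissues: Sequence[str],
    feature: str = "mito_ndna_pct",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA of an index on cluster and tissue, plus pairwise Hedges' g.

    Fits a fixed-effects model ``value ~ cluster * tissue`` (type II sums of
    squares) over the labelled subjects, and computes Hedges' g for every
    cluster pair within every tissue.  Returns ``(anova_table, g_table)``.
    """
    long = table[table["tissue"].isin(list(tissues))][
        ["subject_id", "tissue", feature]
    ].dropna()
    long = long.merge(
        labels.rename("cluster"), left_on="subject_id", right_index=True
    )
    if long["cluster"].nunique() < 2:
        raise ParameterError("need at least 2 clusters")
    counts = long.groupby(["cluster", "tissue"]).size()
    if (counts < 2).any():
        raise ParameterError("each cluster x tissue cell needs n >= 2")
    model = smf.ols(f"Q('{feature}') ~ C(cluster) * C(tissue)", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = [
        idx.replace(f"C(cluster)", "cluster").replace("C(tissue)", "tissue")
        for idx in anova.index
    ]

    g_rows = []
    clusters = sorted(long["cluster"].unique())
    for tissue in tissues:
        sub = long[long["tissue"] == tissue]
        for c1, c2 in itertools.combinations(clusters, 2):
            x = sub.loc[sub["cluster"] == c1, feature]
            y = sub.loc[sub["cluster"] == c2, feature]
            g = hedges_g(x, y)
            if np.isnan(g):
                logger.info("zero pooled variance: tissue %s clusters %s/%s", tissue, c1, c2)
            g_rows.append((tissue, c1, c2, g, len(x), len(y)))
    g_table = pd.DataFrame(
        g_rows, columns=["tissue", "cluster_a", "cluster_b", "hedges_g", "n_a", "n_b"]
    )
    return anova, g_table


def clinical_enrichment(labels: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """z-scored prevalence of binary clinical variables per cluster.

    ``clinical`` has one row per subject (indexed or with a ``subject_id``
    column) and binary columns with possible missing values.  For each
    variable the percent positive per cluster (among non-missing subjects)
    is z-scored across the cluster values using the population (n
    denominator) SD.  A variable entirely missing within a cluster yields
    NaN for that cell; equal prevalence across clusters yields all zeros.
    """
    clin = clinical.copy()
    if "subject_id" in clin.columns:
        clin = clin.set_index("subject_id")
    clin = clin.loc[clin.index.intersection(labels.index)]
    lab = labels.loc[clin.index]
    clusters = sorted(lab.unique())
    rows = {}
    for var in clin.columns:
        prevalences = []
        for c in clusters:
            vals = clin.loc[lab == c, var].dropna()
            prevalences.append(100.0 * vals.mean() if len(vals) else np.nan)
        arr = np.asarray(prevalences, dtype=float)
        ok = ~np.isnan(arr)
        if ok.sum() >= 2:
            mu = arr[ok].mean()
            sd = arr[ok].std(ddof=0)
            z = (arr - mu) / sd if sd > 0 else np.where(ok, 0.0, np.nan)
        else:
            z = np.full_like(arr, np.nan)
        rows[var] = z
    out = pd.DataFrame(rows, index=pd.Index(clusters, name="cluster")).T
    out.index.name = "variable"
    return out


class MitoClustering:
    """Model: k-means phenotyping of multi-tissue mitochondrial distribution.

    Parameters
    ----------
    table : DataFrame
        Index table with one row per (subject, tissue).
    feature : str
        Index to cluster on (e.g. ``mito_ndna_pct`` or ``mtdna_pct``).
    tissues : sequence of str
        Tissue panel; only complete-case subjects enter.
    k : int
        Number of clusters (default 3).
    seed, n_restarts
        k-means reproducibility controls.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        feature: str,
        tissues: Sequence[str],
        k: int = 3,
        seed: int = 0,
        n_restarts: int = 10,
    ):
        self.table = table
        self.feature = feature
        self.tissues = list(tissues)
        self.k = k
        self.seed = seed
        self.n_restarts = n_restarts

    def fit(self) -> "ClusterResults":
        ratios = compute_ratio_features(self.table, self.feature, self.tissues)
        labels = kmeans_cluster(ratios, self.k, seed=self.seed, n_restarts=self.n_restarts)
        variance = pca_variance(ratios)
        return ClusterResults(
            model=self, ratio_features=ratios, labels=labels, pca_variance_=variance
        )

    def model_selection_report(self, k_range: Sequence[int] = (2, 3, 4, 5, 6)) -> pd.DataFrame:
        """Within-cluster sum of squares and silhouette across candidate k."""
        ratios = compute_ratio_features(self.table, self.feature, self.tissues)
        x = ratios.features.to_numpy()
        rows = []
        for k in k_range:
            km = KMeans(n_clusters=k, n_init=self.n_restarts,
                        random_state=self.seed, algorithm="lloyd").fit(x)
            sil = silhouette_score(x, km.labels_) if k < len(x) else np.nan
            rows.append((k, km.inertia_, sil))
        return pd.DataFrame(rows, columns=["k", "wcss", "silhouette"])


@dataclass
class ClusterResults:
    """Fitted multi-tissue phenotype clusters."""

    model: MitoClustering
    ratio_features: RatioFeatures
    labels: pd.Series
    pca_variance_: np.ndarray
    _anova: pd.DataFrame | None = field(default=None, repr=False)
    _g: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def per_tissue_means(self) -> pd.DataFrame:
        long = self.model.table[
            self.model.table["tissue"].isin(self.model.tissues)
        ][["subject_id", "tissue", self.model.feature]]
        long = long.merge(self.labels.rename("cluster"),
                          left_on="subject_id", right_index=True)
        return long.pivot_table(
            index="cluster", columns="tissue", values=self.model.feature, aggfunc="mean"
        )

    def anova(self) -> pd.DataFrame:
        self._fit_anova()
        return self._anova

    def hedges(self) -> pd.DataFrame:
        self._fit_anova()
        return self._g

    def _fit_anova(self) -> None:
        if self._anova is None:
            self._anova, self._g = cluster_anova(
                self.model.table, self.labels, self.model.tissues, self.model.feature
            )

    def clinical_enrichment(self, clinical: pd.DataFrame) -> pd.DataFrame:
        return clinical_enrichment(self.labels, clinical)

    def summary(self) -> str:
        var2 = float(self.pca_variance_[:2].sum()) * 100
        lines = [
            f"MitoClustering: k={self.model.k} on {self.model.feature} "
            f"across {len(self.model.tissues)} tissues",
            f"subjects clustered: {len(self.labels)} "
            f"(dropped: {len(self.ratio_features.dropped_subjects)})",
            "cluster sizes: "
            + ", ".join(f"{c}: {n}" for c, n in self.cluster_sizes.items()),
            f"variance explained by first two PCs: {var2:.1f}%",
        ]
        return "\n".join(lines)
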