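"""Inter-tissue coherence: pairwise Spearman structure, class summaries, network.

"Coherence" is the degree to which an individual's relative level of a
mitochondrial feature in one tissue predicts their relative level in other
tissues.  It is quantified by the Spearman rank correlation of the feature
across subjects for every eligible tissue pair, stratified into
brain–brain, body–body and brain–body pair classes.

The model object :class:`CoherenceAnalysis` wraps the functional layer:
eligibility, per-pair correlations (pooled over features), class-stratified
summaries, per-tissue mean coherence and the thresholded coherence network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedCorrelationError
from .io import eligible_tissue_pairs

logger = logging.getLogger(__name__)

PAIR_CLASSES = ("brain_brain", "body_body", "brain_body")
#: fixed histogram bin edges of width 0.1 over [-1, 1]
HIST_EDGES = np.round(np.arange(-1.0, 1.0001, 0.1), 10)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Pairs with a missing value in either argument are dropped.  Ties get
    mid-ranks; the p-value uses the t approximation with n-2 degrees of
    freedom, and |r| = 1 yields p = 0.

    Raises
    ------
    UndefinedCorrelationError
        Fewer than 3 complete pairs, or zero rank variance in either input.
    """
    return _correlate(x, y, method="spearman")


def _correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Shared correlation core; ``method`` is spearman (default) or pearson.

    Pearson is offered only as a flagged alternative — every headline
    output uses Spearman.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UndefinedCorrelationError(f"only {x.size} complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero rank variance")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method: {method!r}")
    r = float(res.statistic)
    p = float(res.pvalue)
    if abs(r) >= 1.0:
        p = 0.0
    return r, p


def classify_pair(tissue_a: str, tissue_b: str, brain_set: Iterable[str]) -> str:
    brain = set(brain_set)
    n_brain = (tissue_a in brain) + (tissue_b in brain)
    return {2: "brain_brain", 1: "brain_body", 0: "body_body"}[n_brain]


def pairwise_structure(
    table: pd.DataFrame,
    feature: str,
    pairs: pd.DataFrame,
    brain_set: Iterable[str],
    method: str = "spearman",
) -> pd.DataFrame:
    """Spearman correlation of one feature across every eligible tissue pair.

    ``pairs`` is the output of :func:`mitocoherence.io.eligible_tissue_pairs`;
    only rows flagged eligible are correlated.  Pairs whose correlation is
    undefined (too few complete subjects, constant ranks) are skipped and
    logged.  Returns a long DataFrame with columns
    ``tissue_a, tissue_b, feature, r, p, n, pair_class``.
    """
    wide = table.pivot(index="subject_id", columns="tissue", values=feature)
    rows = []
    for _, pair in pairs.iterrows():
        if "eligible" in pairs.columns and not pair["eligible"]:
            continue
        a, b = pair["tissue_a"], pair["tissue_b"]
        if a not in wide.columns or b not in wide.columns:
            continue
        sub = wide[[a, b]].dropna()
        try:
            r, p = _correlate(sub[a], sub[b], method=method)
        except UndefinedCorrelationError as exc:
            logger.info("skipping pair (%s, %s) for %s: %s", a, b, feature, exc)
            continue
        rows.append((a, b, feature, r, p, len(sub), classify_pair(a, b, brain_set)))
    return pd.DataFrame(
        rows, columns=["tissue_a", "tissue_b", "feature", "r", "p", "n", "pair_class"]
    )


@dataclass
class CoherenceSummary:
    """Class-stratified summary of an inter-tissue correlation structure."""

    per_class: pd.DataFrame
    histogram: pd.DataFrame
    tissue_mean_r: pd.Series
    alpha: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.per_class.to_string()


def summarize(corrs: pd.DataFrame, alpha: float = 0.05) -> CoherenceSummary:
    """Summarize pair correlations per pair class.

    Reports, for each class and overall: the median r, pair count, percent
    positive / negative, percent significantly positive / negative at the
    uncorrected two-sided level ``alpha``, and the percent not statistically
    different from zero (p >= alpha).  A histogram of r over fixed bins of
    width 0.1 on [-1, 1] and the per-tissue mean r are attached.
    """
    if corrs.empty:
        raise ParameterError("no pair correlations to summarize")

    def _stats(sub: pd.DataFrame) -> dict:
        if sub.empty:
            return {"n_pairs": 0, "median_r": np.nan, "pct_positive": np.nan,
                    "pct_negative": np.nan, "pct_sig_positive": np.nan,
                    "pct_sig_negative": np.nan, "pct_ns": np.nan}
        n = len(sub)
        sig = sub["p"] < alpha
        return {
            "n_pairs": n,
            "median_r": float(sub["r"].median()),
            "pct_positive": 100.0 * float((sub["r"] > 0).sum()) / n,
            "pct_negative": 100.0 * float((sub["r"] < 0).sum()) / n,
            "pct_sig_positive": 100.0 * float((sig & (sub["r"] > 0)).sum()) / n,
            "pct_sig_negative": 100.0 * float((sig & (sub["r"] < 0)).sum()) / n,
            "pct_ns": 100.0 * float((~sig).sum()) / n,
        }

    rows = {}
    for cls in PAIR_CLASSES:
        rows[cls] = _stats(corrs[corrs["pair_class"] == cls])
    rows["all"] = _stats(corrs)
    per_class = pd.DataFrame(rows).T
    per_class.index.name = "pair_class"

    counts, _ = np.histogram(corrs["r"].to_numpy(), bins=HIST_EDGES)
    histogram = pd.DataFrame(
        {"bin_left": HIST_EDGES[:-1], "bin_right": HIST_EDGES[1:], "count": counts}
    )
    return CoherenceSummary(
        per_class=per_class,
        histogram=histogram,
        tissue_mean_r=tissue_mean_coherence(corrs),
        alpha=alpha,
    )


def tissue_mean_coherence(corrs: pd.DataFrame) -> pd.Series:
    """Mean r over all pairs containing each tissue."""
    if corrs.empty:
        raise ParameterError("no pair correlations")
    stacked = pd.concat(
        [
            corrs[["tissue_a", "r"]].rename(columns={"tissue_a": "tissue"}),
            corrs[["tissue_b", "r"]].rename(columns={"tissue_b": "tissue"}),
        ]
    )
    return stacked.groupby("tissue")["r"].mean().sort_values(ascending=False)


def build_network(corrs: pd.DataFrame, threshold: float = 0.2) -> nx.Graph:
    """Coherence network: tissues as nodes, edges where r >= threshold.

    Edge weights carry r; node attribute ``degree`` is the incident edge
    count.  When several features contribute a correlation for the same
    tissue pair, the mean r decides the edge (one edge per pair).
    """
    if not -1 < threshold < 1:
        raise ParameterError("threshold must be in (-1, 1)")
    g = nx.Graph()
    tissues = sorted(set(corrs["tissue_a"]) | set(corrs["tissue_b"]))
    g.add_nodes_from(tissues)
    mean_r = corrs.groupby(["tissue_a", "tissue_b"])["r"].mean()
    for (a, b), r in mean_r.items():
        if r >= threshold:
            g.add_edge(a, b, weight=float(r))
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return g


class CoherenceAnalysis:
    """Model: inter-tissue coherence of one or more features of a cohort.

    Parameters
    ----------
    table : DataFrame
        Feature table with one row per (subject, tissue).
    features : sequence of str
        Feature columns to correlate; per-pair correlations are pooled over
        features, mirroring the multi-feature enzymatic analyses.
    brain_set : iterable of str
        Tissues classified as brain; everything else is body.
    min_shared, tissue_fraction
        Pair/tissue eligibility rules (defaults: 10 shared subjects, >50%
        of other tissues).
    alpha : float
        Uncorrected two-sided significance level for summaries.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: Sequence[str] | str,
        brain_set: Iterable[str],
        min_shared: int = 10,
        tissue_fraction: float = 0.5,
        alpha: float = 0.05,
    ):
        self.table = table
        self.features = [features] if isinstance(features, str) else list(features)
        self.brain_set = frozenset(brain_set)
        self.min_shared = min_shared
        self.tissue_fraction = tissue_fraction
        self.alpha = alpha

    def fit(self) -> "CoherenceResults":
        pairs = eligible_tissue_pairs(
            self.table, min_shared=self.min_shared, tissue_fraction=self.tissue_fraction
        )
        parts = [
            pairwise_structure(self.table, f, pairs, self.brain_set)
            for f in self.features
        ]
        corrs = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        return CoherenceResults(model=self, pairs=pairs, pair_correlations=corrs)


@dataclass
class CoherenceResults:
    """Fitted inter-tissue correlation structure."""

    model: CoherenceAnalysis
    pairs: pd.DataFrame
    pair_correlations: pd.DataFrame
    _summary: CoherenceSummary | None = field(default=None, repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_correlations)

    def summary(self) -> CoherenceSummary:
        if self._summary is None:
            self._summary = summarize(self.pair_correlations, alpha=self.model.alpha)
        return self._summary

    def tissue_mean_coherence(self) -> pd.Series:
        return tissue_mean_coherence(self.pair_correlations)

    def network(self, threshold: float = 0.2) -> nx.Graph:
        return build_network(self.pair_correlations, threshold=threshold)

    def correlation_matrix(self, feature: str) -> pd.DataFrame:
        """Square symmetric r matrix for one feature (NaN where no pair)."""
        sub = self.pair_correlations[self.pair_correlations["feature"] == feature]
        tissues = sorted(set(sub["tissue_a"]) | set(sub["tissue_b"]))
        mat = pd.DataFrame(np.nan, index=tissues, columns=tissues)
        for _, row in sub.iterrows():
            mat.loc[row["tissue_a"], row["tissue_b"]] = row["r"]
            mat.loc[row["tissue_b"], row["tissue_a"]] = row["r"]
        np.fill_diagonal(mat.values, 1.0)
        return mat
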