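"""Downstream statistics on the characteristics table.

Two standard analyses close the pipeline: agglomerative hierarchical
clustering of samples (Ward's criterion on squared Euclidean distances,
with an automatic truncation at the largest gap between successive merge
heights) and one-way fixed-effects ANOVA of a single characteristic across
groups, reported with the fraction of variance explained
(eta-squared = SS_between / SS_total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = ["Dendrogram", "AnovaResult", "cluster", "anova"]


@dataclass
class Dendrogram:
    """A Ward merge tree over samples.

    ``linkage`` is in scipy format, except that merge heights are the raw
    Ward criterion increments (the growth of total within-cluster sum of
    squares caused by each merge), which are non-decreasing.
    """

    linkage: np.ndarray
    labels: list[str]
    _assignments: pd.Series | None = field(default=None, repr=False)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def truncate(self) -> pd.Series:
        """Cluster assignment at the automatic truncation: the cut placed in
        the largest gap between successive merge heights (guaranteeing at
        least two clusters; ties broken at the earliest merge)."""
        h = self.heights
        if len(h) < 2:
            n_clusters = 2
        else:
            gaps = np.diff(h)
            n_clusters = len(h) - int(np.argmax(gaps))
        flat = hierarchy.fcluster(self._scipy_linkage(), t=n_clusters,
                                  criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def _scipy_linkage(self) -> np.ndarray:
        # scipy utilities expect its own (euclidean-scale) heights; the
        # monotone map h -> sqrt(2 h) restores them.
        z = self.linkage.copy()
        z[:, 2] = np.sqrt(2.0 * z[:, 2])
        return z

    def to_newick(self) -> str:
        """Newick serialisation with branch lengths equal to merge-height
        differences (leaf branches run from height 0)."""
        from skbio.tree import TreeNode

        n = len(self.labels)
        z = self.linkage
        heights = {i: 0.0 for i in range(n)}
        nodes: dict[int, TreeNode] = {
            i: TreeNode(name=str(lab)) for i, lab in enumerate(self.labels)
        }
        for k in range(z.shape[0]):
            a, b, h = int(z[k, 0]), int(z[k, 1]), float(z[k, 2])
            for child in (a, b):
                nodes[child].length = h - heights[child]
            parent = TreeNode(children=[nodes[a], nodes[b]])
            nodes[n + k] = parent
            heights[n + k] = h
        root = nodes[n + z.shape[0] - 1]
        root.length = None
        return str(root).strip() if str(root).endswith("\n") else str(root)


def cluster(table: pd.DataFrame, linkage: str = "ward",
            distance: str = "sqeuclidean") -> Dendrogram:
    """Hierarchically cluster samples of a characteristics table.

    Ward's method on squared Euclidean distances is the only supported
    combination; heights are reported as raw Ward criterion increments.
    The merge order is deterministic (ties resolved by scipy's
    nearest-neighbour chain, which is stable in the input order).
    """
    if linkage != "ward" or distance not in ("sqeuclidean", "squared_euclidean"):
        raise ValueError("only Ward linkage on squared Euclidean distances "
                         "is supported")
    if table.shape[0] < 2:
        raise ValueError("clustering requires at least two samples")
    x = table.to_numpy(dtype=float)
    z = hierarchy.linkage(x, method="ward")
    z = z.copy()
    # scipy reports h with h^2/2 = Ward criterion increment
    z[:, 2] = z[:, 2] ** 2 / 2.0
    return Dendrogram(linkage=z, labels=list(table.index))


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA with variance-explained reporting."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    variance_explained: float  #: SS_between / SS_total (eta squared)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"F": self.f_statistic, "df_between": self.df_between,
             "df_within": self.df_within, "p_value": self.p_value,
             "variance_explained": self.variance_explained}
        )


def anova(values, groups) -> AnovaResult:
    """One-way ANOVA of ``values`` across the levels of ``groups``.

    Requires at least two non-empty groups and more observations than
    groups.  A zero within-group variance is legitimate (F becomes infinite
    when means differ, 0/0 -> nan when they do not).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("ANOVA requires at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    n = len(values)
    k = len(levels)
    if n <= k:
        raise ValueError("ANOVA requires more observations than groups")
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_between = float(sum(len(s) * (s.mean() - grand) ** 2 for s in samples))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    f, p = stats.f_oneway(*samples)
    return AnovaResult(
        f_statistic=float(f),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        variance_explained=eta2,
    )
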