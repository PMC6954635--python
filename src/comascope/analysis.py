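"""Variance-based separability analysis of the embedding space.

The embeddings of one headset's epoch pairs form one cluster; the analysis
asks whether the *spread* of that cluster — the variance of the Euclidean
distance between each embedding and the cluster center (the coordinatewise
mean) — differs between Glasgow Coma Scale groups.  Rare "atypical" signal
states are mapped far from the center, so a GCS-dependent rate of such
states shows up as variance heterogeneity rather than as a mean shift.

The omnibus test transforms each group's distances to absolute deviations
from the group center, ``x -> |x - x̄|``, and runs a one-way ANOVA on the
transformed values (the Brown–Forsythe construction; the group *mean* is
the default center here, with the classical median available as an
option).  Pairwise follow-up uses Dunn's rank-based z comparisons on the
same transformed values, unadjusted by default with Holm correction
available.  PCA is used for visualization only; all statistics are
computed in the full embedding space.

`EmbeddingVarianceModel` bundles these steps statsmodels-style: build it
from embeddings plus labels, call :meth:`~EmbeddingVarianceModel.fit`, and
read the results object's tables or ``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cluster_center",
    "distances_to_center",
    "group_variances",
    "brown_forsythe",
    "dunn_posthoc",
    "pca_view",
    "pearson_gcs",
    "VarianceTestResult",
    "EmbeddingVarianceModel",
    "EmbeddingVarianceResults",
]

#: GCS component name -> label column.
COMPONENT_COLUMNS = {
    "sum": "gcs_sum",
    "eyes": "gcs_eye",
    "motor": "gcs_motor",
    "verbal": "gcs_verbal",
}


def cluster_center(embeddings: np.ndarray) -> np.ndarray:
    """Coordinatewise mean of a headset's embeddings (the cluster center)."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.size == 0:
        raise ValueError("cannot take the center of an empty embedding set")
    return embeddings.mean(axis=0)


def distances_to_center(embeddings: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Euclidean distance of each embedding from the center, order-preserving."""
    embeddings = np.asarray(embeddings, dtype=float)
    center = np.asarray(center, dtype=float)
    if embeddings.shape[-1] != center.shape[-1]:
        raise ValueError(
            f"dimension mismatch: embeddings are {embeddings.shape[-1]}-d, "
            f"center is {center.shape[-1]}-d"
        )
    return np.linalg.norm(embeddings - center, axis=-1)


def group_variances(
    distances: np.ndarray, labels: np.ndarray, component: str = "sum", ddof: int = 1
) -> pd.DataFrame:
    """Sample variance (divisor n-1) of distances per unique label value.

    Groups with fewer than two points get a missing variance and a flag
    instead of a degenerate estimate.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    if len(distances) != len(labels):
        raise ValueError("labels must align with distances")
    rows = []
    for value in np.unique(labels):
        d = distances[labels == value]
        rows.append(
            {
                "gcs_component": component,
                "gcs_value": value,
                "variance": float(np.var(d, ddof=ddof)) if len(d) > ddof else np.nan,
                "n_ex": int(len(d)),
                "degenerate": len(d) < 2,
            }
        )
    return pd.DataFrame(rows)


def _transform(groups: list[np.ndarray], center: str) -> list[np.ndarray]:
    """Absolute deviation from the group center (mean by default)."""
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        c = np.median(g) if center == "median" else np.mean(g)
        out.append(np.abs(g - c))
    return out


def brown_forsythe(groups: list[np.ndarray], center: str = "mean") -> tuple[float, float]:
    """Variance-heterogeneity omnibus test.

    Each group is transformed to absolute deviations from its own center
    and a one-way ANOVA F statistic is computed on the transformed values;
    the p value comes from F(k-1, N-k).  ``center='mean'`` follows the
    published transform; ``center='median'`` gives the classical
    Brown–Forsythe variant.  If every transformed value is identical, the
    degenerate case is reported as (0.0, 1.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two observations")
    z = _transform(groups, center)
    n = np.array([len(g) for g in z])
    means = np.array([g.mean() for g in z])
    grand = np.concatenate(z).mean()
    k, big_n = len(z), int(n.sum())
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(z, means)))
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_between / (k - 1)) / (ss_within / (big_n - k))
    p = float(stats.f.sf(f_stat, k - 1, big_n - k))
    return float(f_stat), p


def dunn_posthoc(
    groups: list[np.ndarray],
    center: str = "mean",
    adjust: str | None = None,
) -> np.ndarray:
    """Pairwise variance comparisons: Dunn's z test on transformed values.

    The groups are transformed as in :func:`brown_forsythe`, pooled and
    ranked (average ranks for ties, with the standard tie correction), and
    each pair is compared through the normal approximation of the rank-sum
    difference.  Returns a symmetric matrix of two-sided p values with a
    unit diagonal; ``adjust='holm'`` applies Holm's step-down correction,
    the default reports raw p values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    z = _transform(groups, center)
    pooled = np.concatenate(z)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    i = 0
    for g in z:
        mean_ranks.append(ranks[i : i + len(g)].mean())
        i += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = n_tot * (n_tot + 1) / 12.0
    if n_tot > 1:
        var_factor -= tie_term / (12.0 * (n_tot - 1))

    k = len(z)
    pmat = np.ones((k, k))
    raw = {}
    for i, j in itertools.combinations(range(k), 2):
        se_sq = var_factor * (1.0 / len(z[i]) + 1.0 / len(z[j]))
        if se_sq <= 0:
            p = 1.0  # all pooled values tied: no evidence of any difference
        else:
            zij = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se_sq)
            p = min(1.0, 2.0 * float(stats.norm.sf(abs(zij))))
        raw[(i, j)] = p
    if adjust == "holm":
        pairs = sorted(raw, key=raw.get)
        m = len(pairs)
        running = 0.0
        for rank, pair in enumerate(pairs):
            adj = min(1.0, (m - rank) * raw[pair])
            running = max(running, adj)
            raw[pair] = running
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (i, j), p in raw.items():
        pmat[i, j] = pmat[j, i] = p
    return pmat


def pca_view(embeddings: np.ndarray, labels: np.ndarray | None = None, label_name: str = ""):
    """Project embeddings to the plane of the top two principal components.

    The PCA is fit on all embeddings jointly (both headset clusters in one
    plane).  Returns ``(coordinates, figure)`` where the scatter is
    colored by ``labels`` when given.  Inputs with fewer than two usable
    components return the available ones (second coordinate zero-filled).
    """
    from sklearn.decomposition import PCA
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.shape[0] < 3:
        raise ValueError("need at least three embeddings for a PCA view")
    n_comp = min(2, embeddings.shape[0], embeddings.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(embeddings)
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])

    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=8)
    else:
        labels = np.asarray(labels)
        for value in np.unique(labels):
            sel = labels == value
            ax.scatter(coords[sel, 0], coords[sel, 1], s=8, label=str(value))
        ax.legend(title=label_name or None, fontsize="small")
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.set_title("Embedding space (PCA projection)")
    return coords, fig


def pearson_gcs(parameter: np.ndarray, gcs: np.ndarray) -> float:
    """Pearson correlation between a derived parameter and GCS scores."""
    parameter = np.asarray(parameter, dtype=float)
    gcs = np.asarray(gcs, dtype=float)
    if len(parameter) != len(gcs) or len(parameter) < 3:
        raise ValueError("need at least three paired observations")
    if np.std(parameter) == 0 or np.std(gcs) == 0:
        raise ValueError("zero variance in one of the vectors")
    return float(stats.pearsonr(parameter, gcs).statistic)


@dataclass
class VarianceTestResult:
    """Omnibus and pairwise variance tests for one headset and component."""

    headset: int
    gcs_component: str
    bf_statistic: float
    bf_p: float
    group_values: tuple
    pairwise_p: pd.DataFrame
    alpha_levels: tuple[float, float] = (0.05, 0.001)

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.bf_p < alpha)


class EmbeddingVarianceModel:
    """GCS-separability model over autoencoder embeddings.

    Parameters
    ----------
    embeddings
        (n, d) embedding vectors (one per epoch pair).
    labels
        DataFrame aligned with the embeddings carrying ``headset`` plus the
        GCS columns ``gcs_sum, gcs_eye, gcs_motor, gcs_verbal`` (and
        optionally ``participant_id``).
    """

    def __init__(self, embeddings: np.ndarray, labels: pd.DataFrame):
        self.embeddings = np.asarray(embeddings, dtype=float)
        if len(self.embeddings) != len(labels):
            raise ValueError("labels must align with embeddings")
        self.labels = labels.reset_index(drop=True)
        if "headset" not in self.labels.columns:
            raise ValueError("labels need a 'headset' column")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EmbeddingVarianceModel":
        """Build from a single table with ``e1..eD`` embedding columns."""
        emb_cols = [c for c in frame.columns if c.startswith("e") and c[1:].isdigit()]
        emb_cols.sort(key=lambda c: int(c[1:]))
        if not emb_cols:
            raise ValueError("no embedding columns e1..eD found")
        return cls(frame[emb_cols].to_numpy(float), frame.drop(columns=emb_cols))

    def fit(
        self,
        center: str = "mean",
        components: tuple[str, ...] = ("sum", "eyes", "motor", "verbal"),
        posthoc_adjust: str | None = None,
    ) -> "EmbeddingVarianceResults":
        """Run the full per-headset analysis and return a results object."""
        var_rows = []
        tests: dict[tuple[int, str], VarianceTestResult] = {}
        distances = np.empty(len(self.embeddings))
        centers: dict[int, np.ndarray] = {}
        for headset in sorted(self.labels["headset"].unique()):
            sel = (self.labels["headset"] == headset).to_numpy()
            emb = self.embeddings[sel]
            ctr = cluster_center(emb)
            centers[int(headset)] = ctr
            dist = distances_to_center(emb, ctr)
            distances[sel] = dist
            for comp in components:
                col = COMPONENT_COLUMNS[comp]
                if col not in self.labels.columns:
                    continue
                vals = self.labels.loc[sel, col].to_numpy()
                table = group_variances(dist, vals, component=comp)
                table.insert(0, "headset", headset)
                var_rows.append(table)
                groups = [dist[vals == v] for v in np.unique(vals)]
                usable = [(v, g) for v, g in zip(np.unique(vals), groups) if len(g) >= 2]
                if len(usable) >= 2:
                    gvals = tuple(v for v, _ in usable)
                    garrs = [g for _, g in usable]
                    f_stat, p = brown_forsythe(garrs, center=center)
                    pmat = dunn_posthoc(garrs, center=center, adjust=posthoc_adjust)
                    tests[(int(headset), comp)] = VarianceTestResult(
                        headset=int(headset),
                        gcs_component=comp,
                        bf_statistic=f_stat,
                        bf_p=p,
                        group_values=gvals,
                        pairwise_p=pd.DataFrame(pmat, index=gvals, columns=gvals),
                    )
        variance_table = (
            pd.concat(var_rows, ignore_index=True)
            if var_rows
            else pd.DataFrame(
                columns=["headset", "gcs_component", "gcs_value", "variance", "n_ex", "degenerate"]
            )
        )
        return EmbeddingVarianceResults(
            model=self,
            variance_table=variance_table,
            tests=tests,
            distances=distances,
            centers=centers,
        )


@dataclass
class EmbeddingVarianceResults:
    """Fitted separability analysis: variance tables, tests, projections."""

    model: EmbeddingVarianceModel
    variance_table: pd.DataFrame
    tests: dict[tuple[int, str], VarianceTestResult]
    distances: np.ndarray
    centers: dict[int, np.ndarray] = field(default_factory=dict)

    def pearson_by_headset(self, component: str = "sum") -> pd.DataFrame:
        """Pearson r between per-participant distance variance and GCS."""
        col = COMPONENT_COLUMNS[component]
        labels = self.model.labels
        rows = []
        if "participant_id" not in labels.columns:
            return pd.DataFrame(columns=["headset", "r", "n_participants"])
        for headset in sorted(labels["headset"].unique()):
            sel = labels["headset"] == headset
            df = pd.DataFrame(
                {
                    "pid": labels.loc[sel, "participant_id"],
                    "gcs": labels.loc[sel, col],
                    "dist": self.distances[sel.to_numpy()],
                }
            )
            per = df.groupby("pid").agg(gcs=("gcs", "first"), var=("dist", "var")).dropna()
            if len(per) >= 3 and per["gcs"].std() > 0 and per["var"].std() > 0:
                r = pearson_gcs(per["var"].to_numpy(), per["gcs"].to_numpy())
            else:
                r = np.nan
            rows.append({"headset": int(headset), "r": r, "n_participants": len(per)})
        return pd.DataFrame(rows)

    def pca(self, color_by: str | None = "gcs_sum"):
        labels = None
        if color_by is not None and color_by in self.model.labels.columns:
            labels = self.model.labels[color_by].to_numpy()
        return pca_view(self.model.embeddings, labels, label_name=color_by or "")

    def summary(self) -> str:
        """Readable report: variance per group plus test outcomes.

        p values at or above 0.05 are flagged ``(ns)``.
        """
        lines = ["Embedding distance-variance analysis", "=" * 48]
        for (headset, comp), t in sorted(self.tests.items()):
            lines.append(f"\nheadset {headset} electrodes, GCS ({comp})")
            sub = self.variance_table.query(
                "headset == @headset and gcs_component == @comp"
            )
            for _, row in sub.iterrows():
                v = "   n<2" if row["degenerate"] else f"{row['variance']:8.3f}"
                lines.append(f"  GCS {row['gcs_value']!s:>3}: variance {v}  (n_ex={row['n_ex']})")
            flag = "" if t.bf_p < 0.05 else "  (ns)"
            lines.append(f"  Brown-Forsythe F = {t.bf_statistic:.3f}, p = {t.bf_p:.4g}{flag}")
            pm = t.pairwise_p
            for i, a in enumerate(pm.index):
                for b in pm.columns[i + 1 :]:
                    p = pm.loc[a, b]
                    mark = "" if p < 0.05 else "  (ns)"
                    lines.append(f"    Dunn {a} vs {b}: p = {p:.4g}{mark}")
        return "\n".join(lines)
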