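"""Phylogenetic profiling and coevolution clustering of conserved features.

After a gene duplication, each duplicate copy retains a subset of the
ancestral features.  Encoding presence (1) / absence (0) of every feature
across the duplicated gene copies gives a binary phylogenetic profile per
feature; features that subfunctionalized to the same paralogue class have
correlated profiles, features that segregated to opposite copies are
anti-correlated.  Co-segregation is read out by Pearson correlation r
between profile columns, the Pearson distance d = 1 - r, and average-linkage
(UPGMA) clustering of d.

Constant profile columns (a feature present in every copy or in none) have
undefined Pearson correlation; they are excluded from the correlation matrix
and clustering, and reported separately rather than silently coerced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import FeatureHit, SequenceRecord

logger = logging.getLogger("confeax")


@dataclass
class FeatureProfileMatrix:
    """Binary presence/absence of features (columns) across gene copies (rows)."""

    matrix: np.ndarray                 # (n_copies, n_features) of {0,1}
    copy_ids: list[str]
    feature_ids: list[str]
    paralogue_labels: list[str | None] = field(default_factory=list)
    clade_labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("profile entries must be binary")
        if len(set(self.copy_ids)) != len(self.copy_ids):
            raise ValueError("duplicate copy ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.matrix.shape != (len(self.copy_ids), len(self.feature_ids)):
            raise ValueError("profile matrix shape mismatch")
        if not self.paralogue_labels:
            self.paralogue_labels = [None] * len(self.copy_ids)
        if not self.clade_labels:
            self.clade_labels = [None] * len(self.copy_ids)

    def constant_features(self) -> list[str]:
        """Features that are all-present or all-absent (Pearson undefined)."""
        out = []
        for j, fid in enumerate(self.feature_ids):
            col = self.matrix[:, j]
            if col.min() == col.max():
                out.append(fid)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.copy_ids,
                          columns=self.feature_ids)
        df.insert(0, "paralogue", [p or "" for p in self.paralogue_labels])
        df.insert(1, "clade", [c or "" for c in self.clade_labels])
        return df

    def write_tsv(self, dest: str | Path) -> None:
        self.to_frame().to_csv(dest, sep="\t", index_label="copy_id")

    @classmethod
    def read_tsv(cls, source: str | Path) -> "FeatureProfileMatrix":
        df = pd.read_csv(source, sep="\t", index_col="copy_id",
                         keep_default_na=False)
        paralogues = [p or None for p in df.pop("paralogue").astype(str)]
        clades = [c or None for c in df.pop("clade").astype(str)]
        return cls(matrix=df.to_numpy(dtype=int),
                   copy_ids=[str(i) for i in df.index],
                   feature_ids=[str(c) for c in df.columns],
                   paralogue_labels=paralogues, clade_labels=clades)


def build_profiles(hits: list[FeatureHit],
                   gene_copies: list[SequenceRecord],
                   features: list[str],
                   min_hits: int = 1) -> FeatureProfileMatrix:
    """Presence matrix: entry 1 iff a copy has >= min_hits hits for a feature.

    All-zero feature columns are retained (flagged via
    :meth:`FeatureProfileMatrix.constant_features`).
    """
    copy_index = {rec.id: i for i, rec in enumerate(gene_copies)}
    feat_index = {f: j for j, f in enumerate(features)}
    counts = np.zeros((len(gene_copies), len(features)), dtype=int)
    for h in hits:
        if h.seq_id not in copy_index:
            raise ValueError(f"hit references unknown sequence id {h.seq_id!r}")
        if h.feature_id not in feat_index:
            raise ValueError(f"hit references unknown feature id {h.feature_id!r}")
        counts[copy_index[h.seq_id], feat_index[h.feature_id]] += 1
    matrix = (counts >= min_hits).astype(int)
    for fid in features:
        if matrix[:, feat_index[fid]].sum() == 0:
            logger.warning("feature %r has an all-zero profile column", fid)
    return FeatureProfileMatrix(
        matrix=matrix,
        copy_ids=[r.id for r in gene_copies],
        feature_ids=list(features),
        paralogue_labels=[r.paralogue_label for r in gene_copies],
        clade_labels=[r.clade_label for r in gene_copies],
    )


def pearson_matrix(profiles: FeatureProfileMatrix) -> np.ndarray:
    """Pearson r between all feature-column pairs; NaN where undefined."""
    m = profiles.matrix
    if m.shape[0] < 2:
        raise ValueError("need at least 2 gene copies")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(m.astype(float), rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, np.where(np.isnan(np.diag(r)), np.nan, 1.0))
    return r


def pearson_distance(r: np.ndarray) -> np.ndarray:
    """d = 1 - r, elementwise; zero diagonal where r is defined."""
    return 1.0 - np.asarray(r, dtype=float)


# --- UPGMA -------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` lists, in order, (members_a, members_b, height) with members as
    tuples of leaf labels and height = average inter-cluster distance / 2
    (the ultrametric convention: a leaf sits at height 0, a merge node at
    half the average distance between its two clusters).
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    newick: str

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment after stopping at k clusters."""
        n = len(self.labels)
        if k > n:
            raise ValueError(f"cannot cut {n} items into {k} clusters")
        clusters = [frozenset([lab]) for lab in self.labels]
        for a, b, _ in self.merges:
            if len(clusters) <= k:
                break
            sa, sb = frozenset(a), frozenset(b)
            clusters = [c for c in clusters if c != sa and c != sb]
            clusters.append(sa | sb)
        assignment: dict[str, int] = {}
        for idx, cluster in enumerate(sorted(clusters, key=lambda c: sorted(c)[0])):
            for lab in cluster:
                assignment[lab] = idx
        return assignment


def average_linkage_cluster(d: np.ndarray, labels: list[str]) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    Repeatedly merges the cluster pair with the minimal average inter-cluster
    distance (Lance-Williams update).  Ties are broken by the
    lexicographically smallest sorted tuple of member labels of the merged
    pair.  Merge height = average distance / 2.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if d.shape != (n, n) or not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN; drop undefined items first")
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    members: list[tuple[str, ...]] = [(lab,) for lab in labels]
    sizes = [1] * n
    newicks = [lab for lab in labels]
    heights = [0.0] * n
    dist = d.astype(float).copy()
    active = list(range(n))
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                key = (dist[a, b], tuple(sorted(members[a] + members[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (avg_dist, _), a, b = best
        height = avg_dist / 2.0
        merges.append((members[a], members[b], height))
        # Lance-Williams average-linkage update, written into slot a
        for k in active:
            if k in (a, b):
                continue
            dist[a, k] = dist[k, a] = (
                sizes[a] * dist[a, k] + sizes[b] * dist[b, k]
            ) / (sizes[a] + sizes[b])
        newicks[a] = (f"({newicks[a]}:{height - heights[a]:.10g},"
                      f"{newicks[b]}:{height - heights[b]:.10g})")
        heights[a] = height
        members[a] = tuple(sorted(members[a] + members[b]))
        sizes[a] += sizes[b]
        active.remove(b)
    root = active[0]
    return Dendrogram(labels=list(labels), merges=merges,
                      newick=newicks[root] + ";")


# --- full analysis -----------------------------------------------------------

@dataclass
class CoevolutionResult:
    feature_ids: list[str]             # features entering r / clustering
    dropped_features: list[str]        # constant columns, excluded
    r: np.ndarray
    d: np.ndarray
    dendrogram: Dendrogram
    cluster_assignments: dict[str, int]


def coevolution_analysis(profiles: FeatureProfileMatrix,
                         k: int = 2) -> CoevolutionResult:
    """Pearson coevolution matrix, UPGMA dendrogram and a k-cluster cut."""
    dropped = profiles.constant_features()
    if dropped:
        logger.warning("excluding constant-profile features from clustering: %s",
                       ", ".join(dropped))
    keep = [f for f in profiles.feature_ids if f not in dropped]
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant features; nothing to cluster")
    idx = [profiles.feature_ids.index(f) for f in keep]
    sub = FeatureProfileMatrix(
        matrix=profiles.matrix[:, idx], copy_ids=profiles.copy_ids,
        feature_ids=keep, paralogue_labels=profiles.paralogue_labels,
        clade_labels=profiles.clade_labels)
    r = pearson_matrix(sub)
    d = pearson_distance(r)
    np.fill_diagonal(d, 0.0)
    dendro = average_linkage_cluster(d, keep)
    assignments = dendro.cut(min(k, len(keep)))
    return CoevolutionResult(feature_ids=keep, dropped_features=dropped,
                             r=r, d=d, dendrogram=dendro,
                             cluster_assignments=assignments)


def cosegregation_report(profiles: FeatureProfileMatrix,
                         result: CoevolutionResult,
                         k: int = 2) -> dict:
    """Feature clusters at a k-cut plus per-cluster paralogue enrichment.

    For every cluster the report gives, per paralogue label, the mean
    presence of the cluster's features across copies carrying that label —
    the red/blue block structure of a subfunctionalization heatmap.
    """
    if k > len(result.feature_ids):
        raise ValueError(f"k={k} exceeds number of clusterable features "
                         f"({len(result.feature_ids)})")
    assignments = result.dendrogram.cut(k)
    labels = sorted({p for p in profiles.paralogue_labels if p})
    clusters = []
    for c in sorted(set(assignments.values())):
        feats = sorted(f for f, ci in assignments.items() if ci == c)
        enrichment = {}
        for lab in labels:
            rows = [i for i, p in enumerate(profiles.paralogue_labels) if p == lab]
            cols = [profiles.feature_ids.index(f) for f in feats]
            enrichment[lab] = float(profiles.matrix[np.ix_(rows, cols)].mean()) \
                if rows and cols else float("nan")
        clusters.append({"cluster": c, "features": feats,
                         "mean_presence_by_paralogue": enrichment})
    return {"k": k, "clusters": clusters,
            "excluded_constant_features": result.dropped_features}


def write_matrix_tsv(m: np.ndarray, labels: list[str], dest: str | Path) -> None:
    pd.DataFrame(m, index=labels, columns=labels).to_csv(dest, sep="\t")
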