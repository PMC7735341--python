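"""Hierarchical clustering of similarity matrices with bootstrap edge support.

Similarity matrices are clustered agglomeratively on dissimilarity
d = 1 − similarity (UPGMA by default; single linkage and WPGMA are provided
for comparison, selected via the cophenetic correlation coefficient).  The
stability of each dendrogram edge is assessed by multiscale bootstrap:
member strings are resampled with replacement within their groups at several
resampling ratios r, the similarity matrix and dendrogram are recomputed,
and the bootstrap proportion BP(r) of each observed edge is recorded.  The
approximately unbiased (AU) support corrects BP for the curvature bias of
the plain bootstrap by fitting

    Phi^-1(1 − BP(r)) = v * sqrt(r) + c / sqrt(r)

by weighted least squares over the scale profile and reporting
AU = 1 − Phi(v − c), where v is the signed distance and c the curvature of
the cluster boundary.  AU > 0.95 is conventionally read as a stable edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm, pearsonr
from sklearn.base import BaseEstimator, ClusterMixin

from .corpus import SimilarityMatrix, SongString
from .metrics import _encode_all, _pairwise_lsi

__all__ = [
    "Dendrogram",
    "EdgeSupport",
    "LINKAGE_METHODS",
    "DEFAULT_SCALES",
    "linkage_cluster",
    "cophenetic_correlation",
    "select_linkage",
    "bootstrap_support",
    "BootstrapUPGMA",
]

logger = logging.getLogger(__name__)

#: spec'd linkage vocabulary -> scipy method names
LINKAGE_METHODS = {
    "average": "average",           # UPGMA (unweighted)
    "single": "single",
    "weighted_average": "weighted",  # WPGMA
}

#: 11 resampling ratios evenly log-spaced on [1/1.4, 1.4]; the odd count puts
#: r = 1.0 (the plain bootstrap) exactly in the middle of the grid.
DEFAULT_SCALES = tuple(float(x) for x in np.exp(np.linspace(-1, 1, 11) * np.log(1.4)))


@dataclass
class Dendrogram:
    """An agglomerative merge tree over labelled items.

    ``linkage`` is a scipy linkage matrix; heights are dissimilarities
    (1 − similarity) at which clusters merge.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic_distances(self) -> np.ndarray:
        """Condensed matrix of heights at which each item pair first joins."""
        return hierarchy.cophenet(self.linkage)

    def clades(self, include_root: bool = True) -> list[frozenset]:
        """Leaf-label set of every internal node, in merge order."""
        return [
            frozenset(self.labels[i] for i in c)
            for c in _clade_indices(self.linkage, self.n_leaves)
        ][: None if include_root else -1]

    def to_newick(self, support: Mapping[frozenset, float] | None = None,
                  digits: int = 4) -> str:
        """Newick string; internal nodes labelled with ``support`` values."""
        tree = hierarchy.to_tree(self.linkage)
        idx_clades = _clade_indices(self.linkage, self.n_leaves)
        clade_of_node = {self.n_leaves + k: c for k, c in enumerate(idx_clades)}

        def esc(label: str) -> str:
            return label.replace(" ", "_").replace(",", "_").replace(":", "_") \
                        .replace("(", "_").replace(")", "_").replace(";", "_")

        def rec(node, parent_height):
            blen = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{esc(self.labels[node.id])}:{blen:.{digits}f}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            name = ""
            if support is not None:
                cl = frozenset(self.labels[i] for i in clade_of_node[node.id])
                if cl in support:
                    name = f"{support[cl]:.{digits}f}"
            return f"({left},{right}){name}:{blen:.{digits}f}"

        root = rec(tree, tree.dist)
        return root + ";"


def _clade_indices(Z: np.ndarray, n: int) -> list[frozenset]:
    members: list[frozenset] = [frozenset([i]) for i in range(n)]
    clades = []
    for row in Z:
        s = members[int(row[0])] | members[int(row[1])]
        members.append(s)
        clades.append(s)
    return clades


def _check_monotone(Z: np.ndarray, method: str) -> None:
    # average-family linkages cannot produce inversions; assert on every run
    if method in ("average", "weighted") and np.any(np.diff(Z[:, 2]) < -1e-10):
        raise AssertionError("non-monotone merge heights in average-family linkage")


def linkage_cluster(sim: SimilarityMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of a similarity matrix on d = 1 − s.

    ``method`` is one of 'average' (UPGMA), 'single', 'weighted_average'
    (WPGMA).  Merge ties are broken deterministically by scipy's cluster
    index order (smallest pair first).
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=LINKAGE_METHODS[method])
    _check_monotone(Z, LINKAGE_METHODS[method])
    return Dendrogram(linkage=Z, labels=list(sim.labels))


def cophenetic_correlation(dend: Dendrogram, sim: SimilarityMatrix) -> float:
    """Pearson correlation between cophenetic and input distances (CCC).

    Values above 0.8 are conventionally considered a good representation of
    the original distance structure.
    """
    if dend.labels != list(sim.labels):
        raise ValueError("dendrogram and similarity matrix label mismatch")
    coph = dend.cophenetic_distances()
    orig = squareform(1.0 - sim.values, checks=False)
    if np.ptp(orig) == 0 or np.ptp(coph) == 0:
        return 1.0 if np.allclose(coph, orig) else 0.0
    return float(pearsonr(coph, orig)[0])


def select_linkage(
    sim: SimilarityMatrix, methods: Sequence[str] = ("average", "single", "weighted_average")
) -> dict:
    """CCC per linkage method plus the best method (highest CCC)."""
    ccc = {m: cophenetic_correlation(linkage_cluster(sim, m), sim) for m in methods}
    return {"ccc": ccc, "best": max(ccc, key=ccc.get)}


def phrase_ccc_comparison(phrases) -> dict:
    """CCC of UPGMA / single / WPGMA clustering of a phrase-string LSI matrix.

    ``phrases`` is a collection of :class:`~songculture.corpus.PhraseString`;
    the matrix is built over their unit sequences.  Returns
    ``{"average": ..., "single": ..., "weighted_average": ...}``.
    """
    from .metrics import similarity_matrix

    sim = similarity_matrix([p.units for p in phrases])
    return select_linkage(sim)["ccc"]


@dataclass
class EdgeSupport:
    """Bootstrap support for one dendrogram edge (an observed leaf set)."""

    clade: frozenset
    bp: float                      # bootstrap proportion at r = 1
    au: float                      # approximately unbiased support
    v: float = float("nan")        # fitted signed distance
    c: float = float("nan")        # fitted curvature
    bp_profile: dict = field(default_factory=dict)  # scale r -> BP(r)
    flag: str = ""                 # '', 'all_present', 'absent', 'degenerate'


def _fit_au(scales: np.ndarray, counts: np.ndarray, B: int) -> tuple:
    """Fit the multiscale model to one edge's BP profile; return (au, v, c, flag)."""
    if np.all(counts == B):
        return 1.0, float("-inf"), 0.0, "all_present"
    if np.all(counts == 0):
        return 0.0, float("inf"), 0.0, "absent"
    # only scales with 0 < count < B carry information about the profile
    # shape; counts at the ceiling/floor would need clipping and make the
    # two basis functions collinear, so they are excluded from the fit
    usable = (counts > 0) & (counts < B)
    i1 = int(np.argmin(np.abs(scales - 1.0)))
    if usable.sum() < 2 or len(np.unique(scales[usable])) < 2:
        # cannot separate distance from curvature: fall back to the plain
        # bootstrap proportion at r = 1
        return float(counts[i1] / B), float("nan"), float("nan"), "degenerate"
    s, p = scales[usable], counts[usable] / B
    z = norm.ppf(1.0 - p)
    # sigma^2 = 1/r; the model is sigma * z linear in sigma^2, i.e.
    # z(r) = v*sqrt(r) + c/sqrt(r)
    X = np.column_stack([np.sqrt(s), 1.0 / np.sqrt(s)])
    w = B * norm.pdf(z) ** 2 / (p * (1.0 - p))
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    if not np.isfinite(v) or not np.isfinite(c):
        return float(counts[i1] / B), v, c, "degenerate"
    return float(norm.cdf(c - v)), v, c, ""


def _group_arrays(
    groups: Mapping[str, Sequence[Sequence[Hashable]]]
) -> tuple[list[str], list[np.ndarray], np.ndarray]:
    labels = list(groups)
    flat: list = []
    idx: list[np.ndarray] = []
    for g in labels:
        members = [tuple(s) for s in groups[g]]
        if not members:
            raise ValueError(f"group {g!r} has no member strings")
        if any(not m for m in members):
            raise ValueError(f"group {g!r} contains an empty string")
        idx.append(np.arange(len(flat), len(flat) + len(members)))
        flat.extend(members)
    W = _pairwise_lsi(_encode_all(flat))
    return labels, idx, W


def _group_matrix(W: np.ndarray, selections: list[np.ndarray], target: str) -> np.ndarray:
    """Group-level similarity from per-group member selections (global indices)."""
    G = len(selections)
    M = np.ones((G, G))
    if target == "median":
        meds = np.empty(G, dtype=int)
        for g, sel in enumerate(selections):
            sums = W[np.ix_(sel, sel)].sum(axis=1)
            meds[g] = sel[int(np.argmax(sums))]
        M = W[np.ix_(meds, meds)].copy()
        np.fill_diagonal(M, 1.0)
    else:  # 'full': mean pairwise LSI between the groups' member strings
        for i in range(G):
            for j in range(i + 1, G):
                M[i, j] = M[j, i] = W[np.ix_(selections[i], selections[j])].mean()
    return M


def bootstrap_support(
    observations: Mapping[str, Sequence[Sequence[Hashable]]],
    cluster_target: str = "median",
    B: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int | None = None,
    linkage_method: str = "average",
) -> tuple[Dendrogram, list[EdgeSupport]]:
    """Multiscale bootstrap of group-level clustering.

    ``observations`` maps a group label (e.g. location_year_recording) to its
    member strings.  At each resampling ratio r, every group's members are
    resampled with replacement to round(r·n); the group similarity matrix
    (median-string LSI for ``cluster_target='median'``, mean cross-group LSI
    for ``'full'``) and its dendrogram are recomputed, and each observed
    edge's occurrence is counted.  Returns the observed dendrogram and one
    :class:`EdgeSupport` per internal edge.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if cluster_target not in ("median", "full"):
        raise ValueError("cluster_target must be 'median' or 'full'")
    scales = np.asarray(sorted(float(s) for s in scales))
    if np.any(scales <= 0):
        raise ValueError("scales must be positive resampling ratios")
    if not np.any(np.isclose(scales, 1.0)):
        raise ValueError("scales must include the plain-bootstrap ratio 1.0")
    rng = np.random.default_rng(seed)
    method = LINKAGE_METHODS[linkage_method]

    labels, group_idx, W = _group_arrays(observations)
    G = len(labels)
    if G < 3:
        raise ValueError("bootstrap support needs at least 3 groups")

    M_obs = _group_matrix(W, group_idx, cluster_target)
    sim_obs = SimilarityMatrix(labels, M_obs)
    dend = linkage_cluster(sim_obs, linkage_method)
    observed = _clade_indices(dend.linkage, G)
    observed_set = {c: k for k, c in enumerate(observed)}
    n_edges = len(observed)

    # per-scale streams spawned in sorted-scale order: results are identical
    # for identical seed regardless of how scales are executed
    streams = rng.spawn(len(scales))
    counts = np.zeros((n_edges, len(scales)), dtype=np.int64)
    used = np.zeros(len(scales), dtype=bool)
    sizes = [len(gi) for gi in group_idx]
    for si, (r, stream) in enumerate(zip(scales, streams)):
        m = [int(round(r * n)) for n in sizes]
        if min(m) < 1:
            logger.warning("scale %.3f skipped: a group would resample to 0 members", r)
            continue
        used[si] = True
        for _ in range(B):
            sels = [gi[stream.integers(0, n, mm)]
                    for gi, n, mm in zip(group_idx, sizes, m)]
            Mb = _group_matrix(W, sels, cluster_target)
            D = squareform(1.0 - Mb, checks=False)
            np.maximum(D, 0.0, out=D)
            Zb = hierarchy.linkage(D, method=method)
            for c in _clade_indices(Zb, G):
                k = observed_set.get(c)
                if k is not None:
                    counts[k, si] += 1

    if not used.any():
        raise ValueError("every scale was skipped; groups too small for given scales")
    used_scales = scales[used]
    i1 = int(np.argmin(np.abs(used_scales - 1.0)))
    supports = []
    for k, clade_idx in enumerate(observed):
        ck = counts[k, used]
        au, v, c, flag = _fit_au(used_scales, ck, B)
        supports.append(
            EdgeSupport(
                clade=frozenset(labels[i] for i in clade_idx),
                bp=float(ck[i1] / B),
                au=au,
                v=v,
                c=c,
                bp_profile={float(r): float(n) / B for r, n in zip(used_scales, ck)},
                flag=flag,
            )
        )
    return dend, supports


class BootstrapUPGMA(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of grouped strings with bootstrap support.

    The estimator clusters groups of symbol sequences (song or phrase
    strings) on 1 − LSI, selects or applies a linkage method, and attaches
    multiscale-bootstrap BP/AU support to every dendrogram edge.

    Parameters
    ----------
    linkage_method : 'average' | 'single' | 'weighted_average'
        Agglomeration rule (UPGMA default).
    cluster_target : 'median' | 'full'
        Whether groups are represented by their median string or by the mean
        pairwise LSI between their member strings.
    n_boot : int
        Bootstrap replicates per scale.
    scales : sequence of float or None
        Resampling ratios (must include 1.0); None uses :data:`DEFAULT_SCALES`.
    random_state : int or None
        Seed for the bootstrap resampling streams.

    Attributes
    ----------
    labels_ : ndarray of cluster assignments for the fitted groups (flat cut
        at ``cut_height`` if given, else each group's index in the dendrogram
        leaf order — provided for sklearn API compatibility).
    group_labels_ : list of group names in input order.
    similarity_ : SimilarityMatrix over groups.
    dendrogram_ : Dendrogram.
    ccc_ : cophenetic correlation of the fitted dendrogram.
    supports_ : list of EdgeSupport per internal edge.
    """

    def __init__(
        self,
        linkage_method: str = "average",
        cluster_target: str = "median",
        n_boot: int = 1000,
        scales=None,
        cut_height: float | None = None,
        random_state: int | None = None,
    ):
        self.linkage_method = linkage_method
        self.cluster_target = cluster_target
        self.n_boot = n_boot
        self.scales = scales
        self.cut_height = cut_height
        self.random_state = random_state

    @staticmethod
    def _as_groups(X) -> Mapping[str, list]:
        if isinstance(X, Mapping):
            return X
        if all(isinstance(s, SongString) for s in X):
            from .matching import group_label

            groups: dict[str, list] = {}
            for s in X:
                groups.setdefault(group_label(s.group_key), []).append(s.themes)
            return groups
        raise ValueError(
            "X must be a mapping {group: [strings]} or a list of SongString"
        )

    def fit(self, X, y=None):
        groups = self._as_groups(X)
        scales = DEFAULT_SCALES if self.scales is None else self.scales
        dend, supports = bootstrap_support(
            groups,
            cluster_target=self.cluster_target,
            B=self.n_boot,
            scales=scales,
            seed=self.random_state,
            linkage_method=self.linkage_method,
        )
        labels, idx, W = _group_arrays(groups)
        self.group_labels_ = labels
        self.similarity_ = SimilarityMatrix(
            labels, _group_matrix(W, idx, self.cluster_target)
        )
        self.dendrogram_ = dend
        self.ccc_ = cophenetic_correlation(dend, self.similarity_)
        self.supports_ = supports
        if self.cut_height is not None:
            self.labels_ = hierarchy.fcluster(
                dend.linkage, t=self.cut_height, criterion="distance"
            ) - 1
        else:
            self.labels_ = np.arange(len(labels))
        return self

    def support_for(self, clade: frozenset) -> EdgeSupport | None:
        """Support record for an exact leaf set, or None if not an edge."""
        for s in self.supports_:
            if s.clade == clade:
                return s
        return None

    def to_newick(self, value: str = "au") -> str:
        support = {s.clade: getattr(s, value) for s in self.supports_}
        return self.dendrogram_.to_newick(support=support)

    def support_table(self):
        import pandas as pd

        rows = []
        for s in self.supports_:
            row = {
                "clade": "|".join(sorted(s.clade)),
                "bp": s.bp,
                "au": s.au,
                "v": s.v,
                "c": s.c,
                "flag": s.flag,
            }
            row.update({f"bp_r{r:.3f}": p for r, p in s.bp_profile.items()})
            rows.append(row)
        return pd.DataFrame(rows)
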