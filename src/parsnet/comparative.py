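"""Between-sample comparison of metagenome metabolic profiles.

Distances (Bray-Curtis on enzyme abundances, Jaccard on enzyme or reaction
presence, Euclidean on reaction marginal probabilities), Ward hierarchical
clustering, per-reaction differential tests between two groups of samples
(Fisher's exact test on presence/absence, pooled two-sample t-test on
marginal probabilities), and the shared-metabolite reaction graph whose
connected components are chains of metabolic reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import false_discovery_control, fisher_exact, ttest_ind

from .network import AnnotatedMetabolicNetwork
from .sampler import MarginalProfile

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "GroupComparison",
    "ReactionChain",
    "bray_curtis",
    "jaccard_distance",
    "euclidean_marginal_distance",
    "distance_matrix",
    "ward_cluster",
    "fisher_presence_test",
    "two_sample_ttest",
    "differential_reactions",
    "build_reaction_graph",
    "reaction_chains",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _align_counts(
    x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(x.keys() | y.keys())
    xv = np.array([x.get(k, 0.0) for k in keys], dtype=float)
    yv = np.array([y.get(k, 0.0) for k in keys], dtype=float)
    if (xv < 0).any() or (yv < 0).any():
        raise ValueError("abundance counts must be non-negative")
    return xv, yv


def bray_curtis(counts_i: Mapping[str, float], counts_j: Mapping[str, float]) -> float:
    """Bray-Curtis dissimilarity between two enzyme abundance vectors.

    D_BC = 1 - 2*C_ij / (S_i + S_j), where C_ij sums the lesser abundance of
    each enzyme present in both samples and S_i, S_j are the total counts.
    """
    xv, yv = _align_counts(counts_i, counts_j)
    si, sj = xv.sum(), yv.sum()
    if si + sj == 0:
        raise ValueError("both samples have zero total abundance")
    c = np.minimum(xv, yv).sum()
    return float(1.0 - 2.0 * c / (si + sj))


def jaccard_distance(set_i: Iterable[str], set_j: Iterable[str]) -> float:
    """Binary (Jaccard) distance 1 - |i ∩ j| / |i ∪ j| between presence sets."""
    a, b = set(set_i), set(set_j)
    union = a | b
    if not union:
        raise ValueError("both sets are empty")
    return 1.0 - len(a & b) / len(union)


def euclidean_marginal_distance(
    profile_i: MarginalProfile | Mapping[str, float],
    profile_j: MarginalProfile | Mapping[str, float],
) -> float:
    """Euclidean distance between marginal-probability vectors.

    Profiles are aligned on the union of their reaction ids; a reaction
    absent from a sample's annotated network has marginal 0 there.
    """
    pi = profile_i.probabilities if isinstance(profile_i, MarginalProfile) else profile_i
    pj = profile_j.probabilities if isinstance(profile_j, MarginalProfile) else profile_j
    keys = sorted(pi.keys() | pj.keys())
    xv = np.array([pi.get(k, 0.0) for k in keys], dtype=float)
    yv = np.array([pj.get(k, 0.0) for k in keys], dtype=float)
    return float(np.linalg.norm(xv - yv))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a fixed sample order."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )


_METRICS = {
    "braycurtis": bray_curtis,
    "jaccard": jaccard_distance,
    "euclidean-marginal": euclidean_marginal_distance,
}


def distance_matrix(samples: Mapping[str, object], metric: str) -> DistanceMatrix:
    """Pairwise distances between named samples under one metric.

    ``metric`` is one of ``braycurtis`` (abundance dicts), ``jaccard``
    (presence sets) or ``euclidean-marginal`` (marginal profiles).
    """
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(_METRICS)}"
        ) from None
    ids = tuple(samples.keys())
    n = len(ids)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(samples[ids[i]], samples[ids[j]])
    return DistanceMatrix(ids, out)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) over named leaves."""

    sample_ids: tuple[str, ...]
    linkage_matrix: np.ndarray

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Cluster labels (1..n_clusters) from cutting the merge tree."""
        labels = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"


def ward_cluster(matrix: DistanceMatrix, method: str = "ward") -> Dendrogram:
    """Hierarchical clustering of a precomputed distance matrix.

    Default linkage is Ward's minimum-variance criterion in the
    squared-distance (ward.D2) dialect: the Lance-Williams update operates on
    squared distances internally and reported heights are on the input
    distance scale.  Other scipy linkage methods are accepted.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("clustering needs at least 2 samples")
    condensed = squareform(matrix.values, checks=False)
    z = linkage(condensed, method=method)
    return Dendrogram(matrix.sample_ids, z)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------


def fisher_presence_test(
    present_in_group1: int, n1: int, present_in_group2: int, n2: int
) -> float:
    """Two-sided Fisher exact p for a presence/absence 2x2 table.

    Two-sided by the point-probability rule: the p-value sums the
    hypergeometric probabilities of all tables no more probable than the
    observed one.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not 0 <= present_in_group1 <= n1 or not 0 <= present_in_group2 <= n2:
        raise ValueError("presence counts must lie in [0, group size]")
    table = [
        [present_in_group1, n1 - present_in_group1],
        [present_in_group2, n2 - present_in_group2],
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False


def two_sample_ttest(
    values_group1: Sequence[float], values_group2: Sequence[float]
) -> TTestResult:
    """Independent pooled-variance (equal-variance) two-sample t-test.

    df = n1 + n2 - 2.  A zero pooled variance cannot be tested and returns a
    flagged degenerate result (NaN statistic and p) rather than a silent 0.
    """
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 values")
    df = len(g1) + len(g2) - 2
    pooled = ((len(g1) - 1) * g1.var(ddof=1) + (len(g2) - 1) * g2.var(ddof=1)) / df
    if pooled == 0:
        return TTestResult(float("nan"), float("nan"), df, degenerate=True)
    t, p = ttest_ind(g1, g2, equal_var=True)
    return TTestResult(float(t), float(p), df)


@dataclass
class GroupComparison:
    """Per-reaction differential results between two sample groups."""

    table: pd.DataFrame
    alpha: float
    group_names: tuple[str, str] = ("group1", "group2")

    @property
    def fisher_significant(self) -> set[str]:
        return set(self.table.index[self.table["fisher_sig"]])

    @property
    def ttest_significant(self) -> set[str]:
        return set(self.table.index[self.table["ttest_sig"]])

    @property
    def both_significant(self) -> set[str]:
        return self.fisher_significant & self.ttest_significant

    @property
    def ttest_only(self) -> set[str]:
        return self.ttest_significant - self.fisher_significant

    @property
    def fisher_only(self) -> set[str]:
        return self.fisher_significant - self.ttest_significant

    def summary(self) -> dict[str, int]:
        return {
            "n_reactions": len(self.table),
            "fisher_significant": len(self.fisher_significant),
            "ttest_significant": len(self.ttest_significant),
            "both_significant": len(self.both_significant),
            "ttest_only": len(self.ttest_only),
            "fisher_only": len(self.fisher_only),
        }


def _as_prob_dict(profile) -> dict[str, float]:
    if isinstance(profile, MarginalProfile):
        return profile.probabilities
    return dict(profile)


def differential_reactions(
    group1_profiles: Mapping[str, MarginalProfile | Mapping[str, float]],
    group2_profiles: Mapping[str, MarginalProfile | Mapping[str, float]],
    alpha: float = 0.05,
    correction: str | None = None,
) -> GroupComparison:
    """Fisher and t tests per reaction between two groups of samples.

    Presence of a reaction in a sample means the reaction exists in that
    sample's annotated network (i.e. appears in its marginal profile); the
    t-test compares marginal probabilities, with absent reactions counted as
    probability 0.  ``correction`` is ``None`` (raw p < alpha, the default)
    or ``"bh"`` for Benjamini-Hochberg.

    A reaction present in all samples of both groups has Fisher p = 1 — its
    occurrence carries no signal — yet may still differ sharply in marginal
    probability; the t-test is what detects those.
    """
    if len(group1_profiles) < 2 or len(group2_profiles) < 2:
        raise ValueError("each group needs at least 2 samples")
    if correction not in (None, "none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    g1 = {sid: _as_prob_dict(p) for sid, p in group1_profiles.items()}
    g2 = {sid: _as_prob_dict(p) for sid, p in group2_profiles.items()}
    universe = sorted(set().union(*g1.values(), *g2.values()))
    n1, n2 = len(g1), len(g2)
    rows = []
    for rid in universe:
        pres1 = sum(rid in p for p in g1.values())
        pres2 = sum(rid in p for p in g2.values())
        vals1 = [p.get(rid, 0.0) for p in g1.values()]
        vals2 = [p.get(rid, 0.0) for p in g2.values()]
        fisher_p = fisher_presence_test(pres1, n1, pres2, n2)
        tt = two_sample_ttest(vals1, vals2)
        mean1 = float(np.mean(vals1))
        mean2 = float(np.mean(vals2))
        if mean2 > 0:
            fold = mean1 / mean2
        else:
            fold = math.inf if mean1 > 0 else math.nan
        rows.append(
            {
                "reaction": rid,
                "present_group1": pres1,
                "present_group2": pres2,
                "fisher_p": fisher_p,
                "t_stat": tt.statistic,
                "t_p": tt.pvalue,
                "t_degenerate": tt.degenerate,
                "mean_p_group1": mean1,
                "mean_p_group2": mean2,
                "fold_change": fold,
            }
        )
    df = pd.DataFrame(rows).set_index("reaction")
    fisher_p = df["fisher_p"].to_numpy()
    t_p = df["t_p"].to_numpy()
    if correction == "bh":
        fisher_adj = false_discovery_control(fisher_p, method="bh")
        t_adj = t_p.copy()
        ok = ~np.isnan(t_p)
        t_adj[ok] = false_discovery_control(t_p[ok], method="bh")
        df["fisher_p_adj"] = fisher_adj
        df["t_p_adj"] = t_adj
        df["fisher_sig"] = fisher_adj < alpha
        df["ttest_sig"] = np.nan_to_num(t_adj, nan=1.0) < alpha
    else:
        df["fisher_sig"] = fisher_p < alpha
        df["ttest_sig"] = np.nan_to_num(t_p, nan=1.0) < alpha
    return GroupComparison(table=df, alpha=alpha)


# ---------------------------------------------------------------------------
# Shared-metabolite reaction graph
# ---------------------------------------------------------------------------


def build_reaction_graph(
    reaction_ids: Iterable[str],
    network: AnnotatedMetabolicNetwork,
    exclude_metabolites: Iterable[str] | None = None,
) -> nx.Graph:
    """Graph on reactions with edges between reactions sharing a metabolite.

    Metabolites in ``exclude_metabolites`` (e.g. currency compounds such as
    water or ATP) are ignored when intersecting.  Node attribute
    ``component`` labels connected components (0-based, by decreasing size).
    """
    rids = list(reaction_ids)
    unknown = set(rids) - network.reactions.keys()
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
    excl = frozenset(exclude_metabolites or ())
    g = nx.Graph()
    g.add_nodes_from(rids)
    by_metabolite: dict[str, list[str]] = {}
    for rid in rids:
        for m in network.reactions[rid].metabolites - excl:
            by_metabolite.setdefault(m, []).append(rid)
    for members in by_metabolite.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    for label, comp in enumerate(components):
        for rid in comp:
            g.nodes[rid]["component"] = label
    return g


@dataclass(frozen=True)
class ReactionChain:
    """One connected component of the shared-metabolite reaction graph."""

    members: tuple[str, ...]
    ttest_only_members: tuple[str, ...] = ()
    both_sig_members: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def only_marginal_evidence(self) -> bool:
        """True when every member was found only by the marginal t-test."""
        return len(self.ttest_only_members) == self.size


def reaction_chains(
    graph: nx.Graph,
    ttest_only: Iterable[str] = (),
    both_significant: Iterable[str] = (),
) -> list[ReactionChain]:
    """Connected components as reaction chains, largest first.

    Each chain records which members were significant only by the t-test on
    marginal probabilities versus by both tests.
    """
    t_only = set(ttest_only)
    both = set(both_significant)
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)))
    return [
        ReactionChain(
            members=tuple(sorted(comp)),
            ttest_only_members=tuple(sorted(comp & t_only)),
            both_sig_members=tuple(sorted(comp & both)),
        )
        for comp in comps
    ]
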