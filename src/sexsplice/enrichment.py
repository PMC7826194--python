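"""Gene-set overlap statistics and bootstrap hierarchical clustering.

The representation factor (RF) is the observed overlap of two gene sets
divided by the overlap expected under independence,
|A|·|B|/n; under-enrichment is scored with the lower tail of the exact
hypergeometric distribution. Multi-set intersections (e.g. differentially
spliced orthologs shared across species) use the exact distribution of the
k-way intersection of independent uniform fixed-size draws, obtained by
iterated hypergeometric convolution, with a Monte-Carlo cross-check.

Sample clustering is average-linkage on Euclidean distances over per-gene
mean PSI, with clade support from feature (gene) bootstrap resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("sexsplice")


def representation_factor_test(n_total: int, dsg_set: Iterable[str],
                               deg_set: Iterable[str]) -> dict:
    """RF and one-sided hypergeometric p for under-enrichment.

    ``p_under`` is P(overlap <= observed) when |DSG| genes are drawn
    uniformly from a universe of ``n_total`` containing |DEG| marked genes.
    """
    if n_total <= 0:
        raise ValueError("universe size must be positive")
    dsg = set(dsg_set)
    deg = set(deg_set)
    if len(dsg) > n_total or len(deg) > n_total:
        raise ValueError("set larger than universe")
    n_overlap = len(dsg & deg)
    expected = len(dsg) * len(deg) / n_total
    rf = n_overlap / expected if expected > 0 else np.nan
    p_under = float(stats.hypergeom.cdf(n_overlap, n_total, len(deg), len(dsg)))
    return {
        "n_total": n_total,
        "n_dsg": len(dsg),
        "n_deg": len(deg),
        "n_overlap": n_overlap,
        "expected": expected,
        "rf": rf,
        "p_under": p_under,
    }


def adjust_overlap_family(results: Sequence[dict]) -> list[dict]:
    """BH adjustment across a family of overlap tests (species × tissues)."""
    ps = [r["p_under"] for r in results]
    fdrs = multipletests(ps, method="fdr_bh")[1]
    out = []
    for r, q in zip(results, fdrs):
        r = dict(r)
        r["fdr"] = float(q)
        out.append(r)
    return out


def _intersection_pmf(n: int, sizes: Sequence[int]) -> np.ndarray:
    """Exact pmf of |S_1 ∩ … ∩ S_k| for independent uniform draws of the
    given sizes from an n-element universe.

    The intersection of the first j sets is uniform given its size, so the
    next set's overlap with it is hypergeometric; iterate the convolution.
    """
    sizes = list(sizes)
    pmf = np.zeros(n + 1)
    pmf[sizes[0]] = 1.0
    for m in sizes[1:]:
        new = np.zeros(n + 1)
        for t in np.flatnonzero(pmf > 0):
            support = np.arange(0, min(t, m) + 1)
            new[support] += pmf[t] * stats.hypergeom.pmf(support, n, t, m)
        pmf = new
    return pmf


def multiset_overlap_test(sets: Sequence[Iterable[str]], universe: Iterable[str],
                          method: str = "exact", n_draws: int = 100_000,
                          seed: int = 0) -> dict:
    """P(upper tail) of the observed k-way intersection.

    ``method`` is "exact" (iterated hypergeometric convolution) or
    "montecarlo" (``n_draws`` independent uniform draws).
    """
    universe = list(universe)
    n = len(universe)
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    for s in sets:
        if not s <= set(universe):
            raise ValueError("set not contained in universe")
    observed = len(set.intersection(*sets))
    sizes = [len(s) for s in sets]
    expected = n * float(np.prod([m / n for m in sizes])) if n else 0.0

    if method == "exact":
        pmf = _intersection_pmf(n, sizes)
        p = float(pmf[observed:].sum())
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        idx = np.arange(n)
        for _ in range(n_draws):
            inter = None
            for m in sizes:
                draw = set(rng.choice(idx, size=m, replace=False))
                inter = draw if inter is None else inter & draw
                if not inter:
                    break
            if len(inter or ()) >= observed:
                hits += 1
        p = hits / n_draws
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "k": len(sets),
        "n_universe": n,
        "observed": observed,
        "expected": expected,
        "p": min(1.0, p),
    }


# ---------------------------------------------------------------------------
# bootstrap hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Sample dendrogram with bootstrap clade support."""

    labels: list[str]
    linkage_matrix: np.ndarray
    support: dict[frozenset, float]
    distance: str = "euclidean"
    linkage_method: str = "average"
    n_boot: int = 0

    def newick(self) -> str:
        """Newick string with bootstrap support as internal node labels."""
        n = len(self.labels)
        Z = self.linkage_matrix

        def leaves(i: int) -> frozenset:
            if i < n:
                return frozenset([self.labels[i]])
            row = Z[i - n]
            return leaves(int(row[0])) | leaves(int(row[1]))

        def build(i: int, parent_dist: float) -> str:
            if i < n:
                return f"{self.labels[i]}:{parent_dist:.6g}"
            row = Z[i - n]
            height = row[2]
            left = build(int(row[0]), height - (Z[int(row[0]) - n][2] if row[0] >= n else 0.0))
            right = build(int(row[1]), height - (Z[int(row[1]) - n][2] if row[1] >= n else 0.0))
            sup = self.support.get(leaves(i))
            label = f"{sup:.3g}" if sup is not None else ""
            return f"({left},{right}){label}:{parent_dist:.6g}"

        root = 2 * n - 2
        return build(root, 0.0) + ";"


def _clades(Z: np.ndarray, labels: Sequence[str]) -> set[frozenset]:
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for i, row in enumerate(Z):
        merged = sets[int(row[0])] | sets[int(row[1])]
        sets[n + i] = merged
        out.add(merged)
    return out


def bootstrap_hclust(features: pd.DataFrame, distance: str = "euclidean",
                     linkage_method: str = "average", n_boot: int = 1000,
                     seed: int = 0) -> ClusterTree:
    """Cluster samples (rows) over features (columns, e.g. per-gene mean
    PSI), with clade support from ``n_boot`` feature resamples.

    Columns with any missing value are dropped listwise.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 samples")
    X = features.dropna(axis=1)
    if X.shape[1] == 0:
        raise ValueError("no complete features after listwise deletion")
    if np.allclose(X.to_numpy().var(axis=0), 0):
        raise ValueError("feature matrix is constant; distances are degenerate")
    labels = list(X.index)
    arr = X.to_numpy(dtype=float)
    Z = linkage(pdist(arr, metric=distance), method=linkage_method)
    observed = _clades(Z, labels)

    rng = np.random.default_rng(seed)
    tally = {c: 0 for c in observed}
    p = arr.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, p, p)
        Zb = linkage(pdist(arr[:, cols], metric=distance), method=linkage_method)
        for c in _clades(Zb, labels):
            if c in tally:
                tally[c] += 1
    support = {c: tally[c] / n_boot for c in observed}
    return ClusterTree(labels, Z, support, distance, linkage_method, n_boot)
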