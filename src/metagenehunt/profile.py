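"""Community analytics over domain and taxon count tables.

Bray–Curtis dissimilarity, complete-linkage hierarchical clustering,
Shannon α-diversity, and the pairwise structure-vs-function comparison:
the dissimilarity of two samples' taxonomic profiles plotted against the
dissimilarity of their functional (domain) profiles, pooled within sample
groups (e.g. gut location), with a per-group Pearson correlation and
fitted line.  Tables are expected rarefied; pass relative abundances if
depth was already equalized elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quantify import CountTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "GroupCorrelation",
    "bray_curtis",
    "distance_matrix",
    "complete_linkage",
    "shannon",
    "structure_function_correlation",
]


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity: 1 − 2·Σmin(x,y) / (Σx + Σy), in [0, 1]."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (xv < 0).any() or (yv < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = xv.sum() + yv.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(xv, yv).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="sample"
        )


def distance_matrix(
    table: CountTable, metric: Callable[[np.ndarray, np.ndarray], float] = bray_curtis
) -> DistanceMatrix:
    """All pairwise dissimilarities between sample rows."""
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    rows = table.data.to_numpy(dtype=float)
    n = rows.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = metric(rows[i], rows[j])
    return DistanceMatrix(labels=table.samples, values=out)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: (cluster_a, cluster_b, height) triples.

    Clusters are referenced scipy-style: indices < n are the leaves (in
    ``labels`` order), index n + k is the cluster created by merge k.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        """Serialize with branch lengths = parent height − child height
        (leaves sit at height 0)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            left = f"{rep[a]}:{h - height[a]:g}"
            right = f"{rep[b]}:{h - height[b]:g}"
            rep[node] = f"({left},{right})"
            height[node] = h
        return rep[n + len(self.merges) - 1] + ";"


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Complete-linkage (farthest-neighbor) agglomerative clustering.

    Merge heights are non-decreasing (complete linkage is monotone); on an
    ultrametric input the heights reproduce the ultrametric exactly.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least 2 samples to cluster")
    z = hierarchy.linkage(d.condensed(), method="complete")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(labels=list(d.labels), merges=merges)


def shannon(x: Sequence[float]) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ in natural-log units (0·ln0 = 0)."""
    xv = np.asarray(x, dtype=float)
    if (xv < 0).any():
        raise ValueError("abundances must be non-negative")
    total = xv.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an all-zero vector")
    p = xv[xv > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class GroupCorrelation:
    """Within-group correlation of paired taxonomic vs functional
    dissimilarities, with the fitted regression line."""

    group: str
    n_samples: int
    n_pairs: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    taxa_bc: list[float]
    func_bc: list[float]


def structure_function_correlation(
    taxa: CountTable,
    domains: CountTable,
    grouping: Mapping[str, str],
) -> dict[str, GroupCorrelation]:
    """Correlate community-structure change with functional-potential change.

    For every group of samples (same gut location, say) all within-group
    sample pairs contribute one point: (Bray–Curtis of the two taxonomic
    rows, Bray–Curtis of the two domain rows).  Groups with fewer than 3
    samples yield fewer than 2 pairs and are skipped with a warning.
    """
    from scipy.stats import linregress

    if set(taxa.samples) != set(domains.samples):
        raise ValueError("taxa and domain tables must cover the same samples")
    groups: dict[str, list[str]] = {}
    for s in taxa.samples:
        groups.setdefault(grouping[s], []).append(s)
    out: dict[str, GroupCorrelation] = {}
    for name in sorted(groups):
        members = groups[name]
        if len(members) < 3:
            warnings.warn(
                f"group {name!r} has {len(members)} samples; need >=3 for a "
                "correlation — skipped",
                stacklevel=2,
            )
            continue
        t_bc, f_bc = [], []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                t_bc.append(bray_curtis(taxa.row(a), taxa.row(b)))
                f_bc.append(bray_curtis(domains.row(a), domains.row(b)))
        fit = linregress(t_bc, f_bc)
        out[name] = GroupCorrelation(
            group=name,
            n_samples=len(members),
            n_pairs=len(t_bc),
            pearson_r=float(fit.rvalue),
            p_value=float(fit.pvalue),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            taxa_bc=t_bc,
            func_bc=f_bc,
        )
    return out
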