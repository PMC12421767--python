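"""Temporal ratio clustering of salt-responsive genes.

For every gene and time point the salt/control expression ratio is summarised
as the difference of mean log2(TPM + 1) between salt and control samples,
computed within each ecotype; the two ecotypes' time profiles are
concatenated column-wise so a gene is described by one joint temporal ratio
vector.  Genes are then grouped by agglomerative hierarchical clustering
(Euclidean distance, complete linkage by default) and the tree is cut at a
fixed height (default 14) to delineate clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_model import SaltnetError, SampleSheet, TpmMatrix, align_check

DEFAULT_CUT_HEIGHT = 14.0


def salt_log_ratio(
    tpm: TpmMatrix,
    sheet: SampleSheet,
    genes: list[str] | None = None,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
    per_ecotype: bool = True,
) -> pd.DataFrame:
    """Gene x (ecotype, time) matrix of salt-minus-control mean log TPM.

    Entry = mean log(TPM + pseudocount) over salt samples at time t minus the
    same mean over control samples, per ecotype.  With ``per_ecotype=False``
    ecotypes are pooled into a single profile.
    """
    align_check(tpm, sheet)
    mat = tpm if genes is None else tpm.subset_features(genes)
    logx = np.log(mat.values + pseudocount) / np.log(log_base)
    tbl = sheet.table
    treatments = sheet.treatment_levels
    if len(treatments) != 2:
        raise SaltnetError("salt_log_ratio requires exactly 2 treatment levels")
    control, salt = treatments[0], treatments[1]
    ecotypes = sheet.ecotype_levels if per_ecotype else ["all"]
    cols: dict[str, np.ndarray] = {}
    for eco in ecotypes:
        eco_mask = (
            np.ones(len(tbl), dtype=bool)
            if eco == "all"
            else (tbl["ecotype"] == eco).to_numpy()
        )
        for t in sheet.time_levels:
            t_mask = (tbl["time"] == t).to_numpy()
            means = {}
            for treat in (salt, control):
                m = eco_mask & t_mask & (tbl["treatment"] == treat).to_numpy()
                if not m.any():
                    raise SaltnetError(
                        f"no sample for condition (ecotype={eco}, treatment={treat}, "
                        f"time={t})"
                    )
                means[treat] = logx[:, m].mean(axis=1)
            cols[f"{eco}:{t}"] = means[salt] - means[control]
    return pd.DataFrame(cols, index=mat.features)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence in scipy linkage form."""

    linkage: np.ndarray
    labels: tuple[str, ...]
    distance: str
    linkage_method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hclust_tree(
    ratios: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Hierarchical agglomeration of gene ratio profiles."""
    if ratios.shape[0] < 2:
        raise SaltnetError("need at least 2 rows to cluster")
    vals = ratios.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise SaltnetError("ratio matrix contains NA/non-finite values")
    if linkage not in {"complete", "average", "ward"}:
        raise SaltnetError(f"unsupported linkage {linkage!r}")
    if distance != "euclidean":
        raise SaltnetError(f"unsupported distance {distance!r}")
    z = hierarchy.linkage(pdist(vals, metric=distance), method=linkage)
    return Dendrogram(
        linkage=z,
        labels=tuple(str(i) for i in ratios.index),
        distance=distance,
        linkage_method=linkage,
    )


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # gene -> 1-based cluster id
    cut_height: float
    linkage: str
    distance: str

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def cut_clusters(dend: Dendrogram, height: float = DEFAULT_CUT_HEIGHT) -> ClusterAssignment:
    """Cut the tree at a fixed height.

    Clusters are the connected components formed by merges strictly below the
    cut height; labels are 1-based, numbered by first gene occurrence in the
    input order.
    """
    if height < 0:
        raise SaltnetError("cut height must be non-negative")
    n = len(dend.labels)
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k, (a, b, h, _) in enumerate(dend.linkage):
        if h < height:
            parent[find(int(a))] = n + k
            parent[find(int(b))] = n + k
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return ClusterAssignment(
        labels=pd.Series(labels, index=list(dend.labels), name="cluster"),
        cut_height=float(height),
        linkage=dend.linkage_method,
        distance=dend.distance,
    )


def cluster_genes(
    tpm: TpmMatrix,
    sheet: SampleSheet,
    genes: list[str] | None = None,
    height: float = DEFAULT_CUT_HEIGHT,
    linkage: str = "complete",
    distance: str = "euclidean",
    **ratio_kwargs,
) -> tuple[pd.DataFrame, ClusterAssignment]:
    """Convenience wrapper: ratio matrix -> tree -> fixed-height clusters."""
    ratios = salt_log_ratio(tpm, sheet, genes=genes, **ratio_kwargs)
    dend = hclust_tree(ratios, distance=distance, linkage=linkage)
    return ratios, cut_clusters(dend, height=height)


def to_newick(dend: Dendrogram) -> str:
    """Serialise the dendrogram as a Newick string with merge heights as
    branch lengths."""
    n = len(dend.labels)
    nodes: dict[int, tuple[str, float]] = {
        i: (lab, 0.0) for i, lab in enumerate(dend.labels)
    }
    for k, (a, b, h, _) in enumerate(dend.linkage):
        (sa, ha), (sb, hb) = nodes.pop(int(a)), nodes.pop(int(b))
        node = f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})"
        nodes[n + k] = (node, float(h))
    (tree, _), = nodes.values()
    return tree + ";"
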