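"""Consistent vs variable DEG partition by replicate support.

Not every differentially expressed gene responds in every replicate: some
are driven by two highly responsive individuals only. DEGs are first
clustered by expression-pattern similarity (median-centered log2 profiles,
Euclidean distance, complete linkage, tree cut at 40% of the maximum merge
height — the Trinity convention) and then labeled:

* a DEG is *regulated in a replicate* when that treatment replicate's
  log2 ratio over the control geometric mean matches the DE direction with
  magnitude >= support_lfc (default 1.0, half the DEG threshold);
* a cluster is *consistent* when its median support count exceeds half the
  treatment replicates, *variable* otherwise (so support 2 of 6 is
  variable, and 3 of 6 — not more than half — is variable too);
* genes inherit their cluster's label (a per-gene mode is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .de import ContrastSpec


def cluster_degs(
    norm_expr: pd.DataFrame,
    deg_ids,
    samples: list[str] | None = None,
    cut_fraction: float = 0.40,
    metric: str = "euclidean",
    method: str = "complete",
) -> pd.Series:
    """Cut the DEG expression dendrogram at a fraction of its height.

    Profiles are median-centered log2(TMM-TPM + 1) across ``samples`` (all
    columns when omitted). Cluster ids are renumbered by first appearance
    in lexicographic gene order, so the labeling is independent of the
    input order of ``deg_ids``.
    """
    deg_ids = sorted(str(g) for g in deg_ids)
    if len(deg_ids) < 2:
        raise ValueError("need at least two DEGs to cluster")
    missing = [g for g in deg_ids if g not in norm_expr.index]
    if missing:
        raise KeyError(f"DEGs absent from expression matrix: {missing[:5]}")
    cols = samples if samples is not None else list(norm_expr.columns)
    prof = np.log2(norm_expr.loc[deg_ids, cols].to_numpy(dtype=float) + 1.0)
    prof = prof - np.median(prof, axis=1, keepdims=True)
    link = hierarchy.linkage(pdist(prof, metric=metric), method=method)
    cut = cut_fraction * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=pd.Index(deg_ids, name="gene_id"),
                     name="cluster_id")


def replicate_support(
    norm_expr: pd.DataFrame,
    deg: str,
    contrast: ContrastSpec,
    direction: str,
    support_lfc: float = 1.0,
) -> int:
    """Count treatment replicates regulated in the DE direction.

    A replicate r is regulated when
    log2((x_r + 1) / (control geometric mean + 1)) matches ``direction``
    with magnitude >= ``support_lfc``.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be up/down, got {direction!r}")
    x = norm_expr.loc[deg, contrast.group_a].to_numpy(dtype=float)
    ctrl = norm_expr.loc[deg, contrast.group_b].to_numpy(dtype=float)
    gm = 0.0 if (ctrl <= 0).any() else float(np.exp(np.mean(np.log(ctrl))))
    ratio = np.log2((x + 1.0) / (gm + 1.0))
    if direction == "up":
        return int((ratio >= support_lfc).sum())
    return int((ratio <= -support_lfc).sum())


def support_counts(
    norm_expr: pd.DataFrame,
    de_table: pd.DataFrame,
    contrast: ContrastSpec,
    deg_ids=None,
    support_lfc: float = 1.0,
) -> pd.Series:
    """Replicate support for every DEG of a contrast (vectorized wrapper)."""
    if deg_ids is None:
        deg_ids = de_table.index[de_table.significant]
    out = {}
    for g in deg_ids:
        out[str(g)] = replicate_support(
            norm_expr, g, contrast, str(de_table.loc[g, "direction"]),
            support_lfc,
        )
    return pd.Series(out, name="support_count", dtype=int)


def label_partition(
    clusters: pd.Series,
    support: pd.Series,
    n_reps: int,
    mode: str = "cluster",
) -> pd.DataFrame:
    """Label DEGs consistent or variable from replicate support.

    ``consistent`` requires support in more than half of the treatment
    replicates; anything else — including the canonical
    regulated-in-only-2-replicates case — is ``variable``. In cluster mode
    (default) the rule is applied to the cluster-median support and genes
    inherit the cluster label; in gene mode it is applied per gene.
    """
    idx = clusters.index
    if not idx.equals(support.reindex(idx).dropna().index):
        missing = idx.difference(support.index)
        raise ValueError(
            f"support missing for DEGs: {missing[:5].tolist()}"
        )
    support = support.reindex(idx)
    if (support < 0).any() or (support > n_reps).any():
        raise ValueError("support counts outside [0, n_reps]")
    half = n_reps / 2.0
    if mode == "cluster":
        med = support.groupby(clusters).median()
        cluster_label = (med > half).map(
            {True: "consistent", False: "variable"}
        )
        label = clusters.map(cluster_label)
    elif mode == "gene":
        label = (support > half).map({True: "consistent", False: "variable"})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(
        {
            "cluster_id": clusters,
            "support_count": support.astype(int),
            "label": label,
        }
    )
    return out


def partition_summary(partition: pd.DataFrame) -> dict:
    n = len(partition)
    n_cons = int((partition.label == "consistent").sum())
    return {
        "n_degs": n,
        "n_consistent": n_cons,
        "n_variable": n - n_cons,
        "fraction_consistent": n_cons / n if n else float("nan"),
        "fraction_variable": (n - n_cons) / n if n else float("nan"),
        "n_clusters": int(partition.cluster_id.nunique()),
    }
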