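"""Constitutive vs individual-specific expression layers.

A gene is *constitutive* when it is detected (raw count > 0) in every
analyzed sample, *not expressed* when it is detected in none, and
*individual-specific* otherwise. Presence is judged on the raw count
matrix, not on normalized values, so any positive expected count marks a
gene as present in that sample. On top of the partition, constitutive genes
whose mean TMM-normalized TPM exceeds a threshold (default 10) form the
high-expression tier, and the median expression of constitutive
immune-flagged genes is compared against all other constitutive genes.

The individuality analysis quantifies the qualitative observation that
samples cluster by sponge individual, not by timepoint: presence/absence
vectors of samples over the individual-specific gene set are compared by
Jaccard distance, clone pairs (two samples of one individual) are scored as
mutual nearest neighbors, and significance comes from permuting individual
labels over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

LAYERS = ("constitutive", "individual_specific", "not_expressed")


def call_layers(
    counts: pd.DataFrame,
    norm_expr: pd.DataFrame | None = None,
    high_threshold: float = 10.0,
    high_mode: str = "mean",
) -> pd.DataFrame:
    """Assign every gene to exactly one expression layer.

    Parameters
    ----------
    counts
        Raw (or RSEM expected) counts; presence is ``count > 0``.
    norm_expr
        TMM-normalized TPM on the same genes/samples; used only for the
        high-expression tier. If omitted, ``constitutive_high`` is False.
    high_mode
        "mean": across-sample mean > threshold (default); "all": every
        sample > threshold.
    """
    if norm_expr is not None and (
        not counts.index.equals(norm_expr.index)
        or not counts.columns.equals(norm_expr.columns)
    ):
        raise ValueError("counts and normalized matrix dimensions differ")
    present = counts.to_numpy() > 0
    n_present = present.sum(axis=1)
    n_samples = counts.shape[1]
    layer = np.where(
        n_present == n_samples,
        "constitutive",
        np.where(n_present == 0, "not_expressed", "individual_specific"),
    )
    if norm_expr is None:
        high = np.zeros(len(layer), dtype=bool)
    elif high_mode == "mean":
        high = norm_expr.to_numpy().mean(axis=1) > high_threshold
    elif high_mode == "all":
        high = (norm_expr.to_numpy() > high_threshold).all(axis=1)
    else:
        raise ValueError(f"unknown high_mode {high_mode!r}")
    return pd.DataFrame(
        {
            "layer": layer,
            "n_samples_present": n_present,
            "constitutive_high": high & (layer == "constitutive"),
        },
        index=counts.index,
    )


def presence_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Boolean presence (count > 0) matrix, genes x samples."""
    return counts > 0


def layer_summary(
    assignment: pd.DataFrame, gene_subset: pd.Index | list | None = None
) -> dict:
    """Layer fractions for a gene subset.

    Fractions over expressed genes (layer != not_expressed) sum to one;
    fractions over all genes in the subset are reported alongside.
    """
    if gene_subset is None:
        sub = assignment
    else:
        gene_subset = pd.Index(gene_subset)
        missing = gene_subset.difference(assignment.index)
        if len(missing):
            raise KeyError(f"genes not in assignment: {missing[:5].tolist()}")
        sub = assignment.loc[gene_subset]
    if sub.empty:
        raise ValueError("empty gene subset")
    n_total = len(sub)
    counts = sub["layer"].value_counts()
    n_expressed = n_total - int(counts.get("not_expressed", 0))
    out = {
        "n_genes": n_total,
        "n_expressed": n_expressed,
        "counts": {lay: int(counts.get(lay, 0)) for lay in LAYERS},
        "frac_of_all": {
            lay: float(counts.get(lay, 0)) / n_total for lay in LAYERS
        },
    }
    if n_expressed:
        out["frac_of_expressed"] = {
            "constitutive": counts.get("constitutive", 0) / n_expressed,
            "individual_specific": counts.get("individual_specific", 0)
            / n_expressed,
        }
    return out


def immune_median_ratio(
    norm_expr: pd.DataFrame,
    assignment: pd.DataFrame,
    immune_flags: pd.Series,
) -> dict:
    """Median expression of constitutive immune genes vs other constitutive.

    The per-gene statistic is the across-sample mean TMM-normalized TPM;
    the ratio is median(immune) / median(other) over constitutive genes.
    """
    immune_flags = immune_flags.reindex(norm_expr.index).fillna(False)
    const = assignment["layer"] == "constitutive"
    imm = const & immune_flags.astype(bool)
    other = const & ~immune_flags.astype(bool)
    if not imm.any() or not other.any():
        raise ValueError(
            "need at least one constitutive immune and one constitutive "
            "non-immune gene"
        )
    gene_means = norm_expr.mean(axis=1)
    med_imm = float(gene_means[imm].median())
    med_other = float(gene_means[other].median())
    return {
        "ratio": med_imm / med_other,
        "median_immune": med_imm,
        "median_other": med_other,
        "n_immune": int(imm.sum()),
        "n_other": int(other.sum()),
    }


@dataclass
class IndividualityResult:
    linkage: np.ndarray
    sample_ids: list[str]
    pairing_score: float
    p_value: float
    n_pairs: int
    tied: bool


def _pairing_score(
    dist: np.ndarray, pairs: list[tuple[int, int]], atol: float = 1e-12
) -> float:
    """Fraction of clone pairs that are mutual nearest neighbors."""
    n = dist.shape[0]
    mutual = 0
    for i, j in pairs:
        row_i = np.delete(dist[i], i)
        row_j = np.delete(dist[j], j)
        if dist[i, j] <= row_i.min() + atol and dist[i, j] <= row_j.min() + atol:
            mutual += 1
    return mutual / len(pairs)


def individuality_analysis(
    presence: pd.DataFrame,
    design: pd.DataFrame,
    gene_subset,
    n_permutations: int = 999,
    seed: int = 0,
) -> IndividualityResult:
    """Test whether clone pairs cluster together on presence/absence.

    Samples (columns of ``presence`` restricted to the design rows) are
    compared by Jaccard distance over ``gene_subset``; average-linkage
    clustering gives the dendrogram. The pairing score is the fraction of
    individuals with exactly two samples whose clone pair are mutual nearest
    neighbors; its null distribution comes from reshuffling individual
    labels over samples. p = (1 + #{perm >= observed}) / (1 + n_permutations).
    """
    gene_subset = pd.Index(gene_subset)
    samples = design["sample_id"].tolist()
    mat = presence.loc[gene_subset, samples].to_numpy(dtype=bool).T
    pair_of = {
        ind: grp["sample_id"].tolist()
        for ind, grp in design.groupby("individual_id")
        if len(grp) == 2
    }
    if len(pair_of) < 2:
        raise ValueError("need >= 2 individuals with two samples each")
    condensed = pdist(mat, metric="jaccard")
    link = hierarchy.linkage(condensed, method="average")
    dist = squareform(condensed)
    idx = {s: k for k, s in enumerate(samples)}
    pairs = [(idx[a], idx[b]) for a, b in pair_of.values()]
    if np.allclose(condensed, 0.0):
        return IndividualityResult(
            link, samples, float("nan"), 1.0, len(pairs), True
        )
    observed = _pairing_score(dist, pairs)
    labels = design["individual_id"].to_numpy()
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        perm_labels = labels[perm]
        groups: dict[str, list[int]] = {}
        for k, lab in enumerate(perm_labels):
            groups.setdefault(lab, []).append(k)
        perm_pairs = [(v[0], v[1]) for v in groups.values() if len(v) == 2]
        if not perm_pairs:
            continue
        if _pairing_score(dist, perm_pairs) >= observed - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return IndividualityResult(link, samples, observed, p, len(pairs), False)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
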