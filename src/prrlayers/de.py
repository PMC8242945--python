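"""Negative-binomial differential expression, one contrast per timepoint.

Each contrast compares the LPS-treated samples against the sham controls at
one timepoint. Because treatment groups contain different individuals, the
test is an unpaired two-group comparison. The engine is a desk-scale NB
Wald test: per-gene dispersions are estimated by method of moments on
within-group residuals and shrunk 50/50 toward a trimmed-mean dispersion
trend over expression deciles; the log2 fold change comes from
factor-scaled group means with a pseudocount, its standard error from the
NB variance function, and p-values from the normal reference. FDR is
Benjamini-Hochberg within the contrast, after independent filtering of
all-zero and bottom-decile genes. Significance applies the study
thresholds: FDR < 0.005 and |log2FC| >= 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class ContrastSpec:
    """One two-group comparison (LPS vs control at a timepoint)."""

    timepoint: str
    group_a: list[str]  # LPS sample ids
    group_b: list[str]  # control sample ids
    alpha: float = 0.005
    lfc_min: float = 2.0

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each contrast group needs >= 2 samples")


def contrast_from_design(
    design: pd.DataFrame,
    timepoint: str,
    alpha: float = 0.005,
    lfc_min: float = 2.0,
) -> ContrastSpec:
    sub = design[design.timepoint == timepoint]
    return ContrastSpec(
        timepoint=timepoint,
        group_a=sub.loc[sub.treatment == "LPS", "sample_id"].tolist(),
        group_b=sub.loc[sub.treatment == "control", "sample_id"].tolist(),
        alpha=alpha,
        lfc_min=lfc_min,
    )


def normalized_counts(
    counts: pd.DataFrame, norm_factors: pd.Series | None
) -> pd.DataFrame:
    """Counts on a common scale: divided by relative effective library size.

    Effective library size = column sum x TMM factor, expressed relative to
    its geometric mean so the values stay on a count-like scale.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero library for sample(s): {bad}")
    if norm_factors is None:
        eff = lib.astype(float)
    else:
        eff = lib * norm_factors.reindex(counts.columns)
        if eff.isna().any():
            raise ValueError("missing normalization factor for some samples")
    rel = eff / np.exp(np.mean(np.log(eff)))
    return counts.div(rel, axis=1)


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: list[list[str]],
    n_bins: int = 10,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion with decile-trend shrinkage.

    The raw estimate is method-of-moments on within-group residuals,
    var = mu + phi * mu**2 pooled across groups; it is then shrunk
    ``shrink_weight`` toward the 20%-trimmed mean of raw dispersions of
    genes in the same overall-expression decile, and floored at 1e-8.
    All-zero genes get NaN and are excluded from testing.
    """
    x = counts.to_numpy(dtype=float)
    cols = {s: j for j, s in enumerate(counts.columns)}
    group_idx = [[cols[s] for s in g] for g in groups]
    for g in group_idx:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 samples")
    num = np.zeros(x.shape[0])
    den = np.zeros(x.shape[0])
    dof = 0
    for g in group_idx:
        sub = x[:, g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(g) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - m) / m**2
        ok = m > 0
        num[ok] += w * phi_g[ok]
        den[ok] += w
        dof += w
    overall_mean = x.mean(axis=1)
    raw = np.full(x.shape[0], np.nan)
    tested = den > 0
    raw[tested] = np.maximum(num[tested] / den[tested], DISPERSION_FLOOR)
    # decile trend on tested genes
    shrunk = raw.copy()
    if tested.sum() >= n_bins:
        ranks = stats.rankdata(overall_mean[tested], method="average")
        bins = np.minimum(
            (ranks - 1) / tested.sum() * n_bins, n_bins - 1
        ).astype(int)
        raw_t = raw[tested]
        trend = np.empty(tested.sum())
        for b in range(n_bins):
            sel = bins == b
            if sel.any():
                trend[sel] = stats.trim_mean(raw_t[sel], 0.2)
        shrunk[tested] = np.maximum(
            (1 - shrink_weight) * raw_t + shrink_weight * trend,
            DISPERSION_FLOOR,
        )
    return pd.Series(shrunk, index=counts.index, name="dispersion")


def test_contrast(
    counts: pd.DataFrame,
    norm_factors: pd.Series | None,
    contrast: ContrastSpec,
    pseudocount: float = 0.5,
    independent_filter: bool = True,
) -> pd.DataFrame:
    """NB Wald test of one LPS-vs-control contrast.

    Returns a per-gene table with base_mean, log2fc (LPS over control),
    se_log2fc, p, fdr, significant, direction. Genes removed by independent
    filtering (all-zero, or bottom expression decile) carry NaN fdr and are
    never significant; the filter is logged so the BH denominator is
    auditable.
    """
    sub = counts[contrast.group_a + contrast.group_b]
    norm = normalized_counts(sub, norm_factors)
    disp = estimate_dispersions(
        norm, [contrast.group_a, contrast.group_b]
    ).to_numpy()
    a = norm[contrast.group_a].to_numpy()
    b = norm[contrast.group_b].to_numpy()
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    base_mean = norm.to_numpy().mean(axis=1)
    log2fc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    # delta-method SE of log2 of a group mean under var = mu + phi mu^2
    phi = np.where(np.isnan(disp), 0.0, disp)
    var_mu_a = (mu_a + phi * mu_a**2) / a.shape[1]
    var_mu_b = (mu_b + phi * mu_b**2) / b.shape[1]
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_mu_a / ((mu_a + pseudocount) ** 2 * ln2sq)
        + var_mu_b / ((mu_b + pseudocount) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    testable = ~np.isnan(disp)
    if independent_filter:
        expressed = base_mean > 0
        if expressed.sum() >= 10:
            cutoff = np.quantile(base_mean[expressed], 0.10)
            keep = testable & (base_mean > cutoff)
        else:
            keep = testable & expressed
        logger.info(
            "independent filtering: testing %d of %d genes "
            "(dropped all-zero and bottom expression decile)",
            int(keep.sum()),
            counts.shape[0],
        )
    else:
        keep = testable
    fdr = np.full(len(p), np.nan)
    if keep.any():
        fdr[keep] = multipletests(p[keep], method="fdr_bh")[1]
    significant = (
        keep
        & (fdr < contrast.alpha)
        & (np.abs(log2fc) >= contrast.lfc_min)
    )
    direction = np.where(
        significant, np.where(log2fc > 0, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "p": p,
            "fdr": fdr,
            "tested": keep,
            "significant": significant,
            "direction": direction,
        },
        index=counts.index,
    )


# the name looks like a pytest item; it is library API
test_contrast.__test__ = False  # type: ignore[attr-defined]


def timepoint_overlap(de_1: pd.DataFrame, de_2: pd.DataFrame) -> dict:
    """Cross-timepoint DEG overlap and direction-consistency report.

    Per direction, the shared fraction is |intersection| / |union| of the
    DEG sets of the two contrasts; genes significant in both contrasts with
    opposite signs are listed as conflicts.
    """
    if not de_1.index.equals(de_2.index):
        raise ValueError("contrasts cover different gene universes")
    report: dict = {"per_direction": {}, "counts": {}, "conflicts": []}
    for d in ("up", "down"):
        s1 = set(de_1.index[de_1.direction == d])
        s2 = set(de_2.index[de_2.direction == d])
        union = s1 | s2
        report["per_direction"][d] = {
            "n_1": len(s1),
            "n_2": len(s2),
            "n_shared": len(s1 & s2),
            "shared_fraction": (len(s1 & s2) / len(union)) if union else 0.0,
        }
        report["counts"][d] = {"t1": len(s1), "t2": len(s2)}
    both = de_1.index[(de_1.significant) & (de_2.significant)]
    for g in both:
        if de_1.loc[g, "direction"] != de_2.loc[g, "direction"]:
            report["conflicts"].append(str(g))
    return report
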