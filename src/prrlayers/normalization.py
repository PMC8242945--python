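"""Within- and between-sample normalization: TPM and TMM scaling factors.

The expression scale used throughout the pipeline is TMM-normalized TPM:
transcripts per million computed from counts and effective gene lengths,
then divided per sample by a trimmed-mean-of-M-values (TMM) scaling factor
estimated on the raw counts. Computing the factors on counts and applying
them to the TPM matrix follows the Trinity downstream-analysis convention.

TMM factors follow Robinson & Oshlack (2010): a reference sample is chosen
by the 75th-percentile count fraction, per-gene log ratios (M) and average
log abundances (A) are computed over genes positive in both libraries,
doubly trimmed (30% of each M tail, 5% of each A tail by default), and the
factor is two to the precision-weighted mean M, with all factors rescaled
to geometric mean one.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from counts and effective lengths.

    tpm[g, s] = (count[g, s] / length[g]) / sum_g'(count[g', s] / length[g'])
    scaled by 1e6, so every column sums to one million.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing lengths for genes: {missing}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][:5].tolist()
        raise ValueError(f"non-positive lengths for genes: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero-sum column(s): {zero.index.tolist()}")
    return rate.div(denom, axis=1) * 1e6


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
    weighted: bool,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**)."""
    lib_obs = obs.sum()
    lib_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no positive genes with the reference")
    o = obs[keep]
    r = ref[keep]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    n = len(m)
    # double trim: drop trim_m of each M tail and trim_a of each A tail
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata

    rm = rankdata(m)
    ra = rankdata(a)
    trimmed = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if trimmed.sum() < 10:
        warnings.warn(
            "fewer than 10 genes survive TMM trimming; "
            "falling back to the untrimmed M set",
            stacklevel=2,
        )
        trimmed = np.ones(n, dtype=bool)
    m = m[trimmed]
    if weighted:
        o_t = o[trimmed]
        r_t = r[trimmed]
        # delta-method precision weights (inverse asymptotic variance of M)
        var = (lib_obs - o_t) / (lib_obs * o_t) + (lib_ref - r_t) / (
            lib_ref * r_t
        )
        w = 1.0 / var
        log_f = float(np.sum(w * m) / np.sum(w))
    else:
        log_f = float(np.mean(m))
    return 2.0**log_f


def compute_tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample TMM scaling factors on counts, geometric mean one.

    The reference library is the column whose 75th-percentile count fraction
    is closest to the mean of those fractions across samples. Genes zero in
    either the sample or the reference are excluded from M/A (no
    pseudocounts).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero-sum column(s): {bad}")
    f75 = np.array(
        [np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(x[:, j], x[:, ref_idx], trim_m, trim_a, weighted)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def apply_tmm(tpm: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each TPM column by its TMM factor (exactly invertible)."""
    factors = factors.reindex(tpm.columns)
    if factors.isna().any():
        missing = factors.index[factors.isna()].tolist()
        raise ValueError(f"missing factors for samples: {missing}")
    if (factors <= 0).any():
        bad = factors.index[factors <= 0].tolist()
        raise ValueError(f"non-positive factor(s) for: {bad}")
    return tpm.div(factors, axis=1)


def tmm_normalized_tpm(
    counts: pd.DataFrame, lengths: pd.Series, **tmm_kwargs
) -> tuple[pd.DataFrame, pd.Series]:
    """Convenience: TPM from counts/lengths, scaled by TMM factors on counts."""
    tpm = compute_tpm(counts, lengths)
    factors = compute_tmm_factors(counts, **tmm_kwargs)
    return apply_tmm(tpm, factors), factors
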