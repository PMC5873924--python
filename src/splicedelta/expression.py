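"""Between-sample normalization and differential expression.

Counts are normalized with the trimmed mean of M-values (TMM): for each
sample a scaling factor is computed against a reference sample from the
library-size-adjusted log ratios (M) after trimming the most extreme 30% of
M values and 5% of average abundances (A), weighting the surviving genes by
the inverse of the asymptotic (binomial) variance of M.  Factors are
rescaled to geometric mean 1.  logCPM uses the TMM-effective library sizes
with a pseudocount, and RPKM divides the linear CPM by gene length in kb.

Differentially expressed genes are called by a two-sided Welch t-test on
per-sample RPKM with a raw p-value cutoff and a fold-change gate; no
multiple-testing correction is applied (by design — documented caveat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import welch_ttest_rows

__all__ = [
    "CountMatrix",
    "tmm_factors",
    "logcpm",
    "rpkm_from_logcpm",
    "rpkm",
    "call_degs",
]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with gene lengths and library sizes."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    gene_lengths: pd.Series  # exonic-union length (nt) per gene
    lib_sizes: pd.Series | None = None  # default: column sums

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()][:5]
            raise ValueError(f"missing gene lengths for {list(missing)}")
        if (self.gene_lengths < 1).any():
            raise ValueError("gene lengths must be >= 1")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (before rescaling)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (binomial) variance of M; genes are weighted by its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    with np.errstate(divide="ignore"):
        f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose scaled upper quartile
    (75th percentile of counts / library size) is closest to the mean
    scaled upper quartile across samples.  Genes with a zero count in
    either member of a pair are excluded from that pair's trimmed mean.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    if lib_sizes is None:
        libs = mat.sum(axis=0)
    else:
        libs = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if (libs <= 0).any():
        bad = counts.columns[np.asarray(libs) <= 0]
        raise ValueError(f"sample(s) with empty library: {list(bad)}")
    f75 = np.array(
        [np.quantile(mat[:, j], 0.75) / libs[j] for j in range(mat.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.array(
        [
            _tmm_pair(
                mat[:, j],
                mat[:, ref_idx],
                libs[j],
                libs[ref_idx],
                logratio_trim,
                abundance_trim,
            )
            for j in range(mat.shape[1])
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def logcpm(
    counts: pd.DataFrame,
    factors: pd.Series,
    lib_sizes: pd.Series | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes.

    logCPM = log2((count + prior) / (effective_lib + 2 * prior) * 1e6),
    effective_lib = library size x TMM factor.
    """
    if lib_sizes is None:
        libs = counts.sum(axis=0).astype(float)
    else:
        libs = lib_sizes.reindex(counts.columns).astype(float)
    eff = libs * factors.reindex(counts.columns)
    return np.log2(
        (counts + prior).div(eff + 2.0 * prior, axis=1) * 1e6
    )


def rpkm_from_logcpm(logcpm_mat: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """RPKM = 2**logCPM / (gene length / 1000)."""
    lengths = gene_lengths.reindex(logcpm_mat.index)
    if lengths.isna().any() or (lengths < 1).any():
        raise ValueError("every gene needs a length >= 1")
    return (2.0**logcpm_mat).div(lengths / 1000.0, axis=0)


def rpkm(cm: CountMatrix, prior: float = 0.5) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Convenience: TMM factors, logCPM and RPKM for a count matrix."""
    factors = tmm_factors(cm.counts, cm.lib_sizes)
    lc = logcpm(cm.counts, factors, cm.lib_sizes, prior=prior)
    return factors, lc, rpkm_from_logcpm(lc, cm.gene_lengths)


def call_degs(
    rpkm_mat: pd.DataFrame,
    groups: dict[str, str],
    wildtype: str = "wt",
    mutant: str = "mut",
    p_threshold: float = 0.01,
    fold_threshold: float = 2.0,
    log_transform: bool = False,
    log_eps: float = 1e-6,
) -> pd.DataFrame:
    """Call differentially expressed genes.

    Two-sided Welch t-test per gene on per-sample RPKM (or on
    log2(RPKM + eps) when ``log_transform``); fold change is
    mean(mutant)/mean(wild type).  A gene is ``up`` when FC >=
    ``fold_threshold`` and p < ``p_threshold``, ``down`` when FC <=
    1/``fold_threshold`` and p < ``p_threshold``, else ``none``.
    """
    wt_cols = [s for s, g in groups.items() if g == wildtype]
    mut_cols = [s for s, g in groups.items() if g == mutant]
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    wt = rpkm_mat[wt_cols].to_numpy(dtype=float)
    mut = rpkm_mat[mut_cols].to_numpy(dtype=float)
    if log_transform:
        _, p = welch_ttest_rows(np.log2(mut + log_eps), np.log2(wt + log_eps))
    else:
        _, p = welch_ttest_rows(mut, wt)
    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_wt > 0, mean_mut / mean_wt, np.inf)
        fc = np.where((mean_wt == 0) & (mean_mut == 0), 1.0, fc)
    call = np.full(rpkm_mat.shape[0], "none", dtype=object)
    sig = p < p_threshold
    call[sig & (fc >= fold_threshold)] = "up"
    call[sig & (fc <= 1.0 / fold_threshold)] = "down"
    return pd.DataFrame(
        {
            "mean_rpkm_wt": mean_wt,
            "mean_rpkm_mut": mean_mut,
            "fold_change": fc,
            "p_value": p,
            "call": call,
        },
        index=rpkm_mat.index,
    ).rename_axis("gene_id")
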