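"""Count normalization and differential-expression calling for trio RNA-seq.

Expression is quantified as FPKM (fragments per kilobase of exon model per
million mapped reads), computed from a raw count matrix and per-gene exon
lengths.  Differential expression between two replicate groups is tested on
log2(FPKM + 1) with an empirical-Bayes variance-moderated t-statistic
(per-gene variances shrunk toward a common prior, limma-style), which keeps
per-gene tests well-powered at the 2-3 replicates typical of field trials.
A plain Welch t-test is available behind the same interface.  Genes are
called differentially expressed when |log2 ratio| >= 1 and the
Benjamini-Hochberg FDR <= 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "compute_fpkm",
    "filter_low_expression",
    "benjamini_hochberg",
    "test_differential",
    "call_degs",
    "DEFAULT_LFC_MIN",
    "DEFAULT_FDR_MAX",
]

DEFAULT_LFC_MIN = 1.0
DEFAULT_FDR_MAX = 0.005


@dataclass
class CountMatrix:
    """Raw read counts (genes x samples) plus per-gene exon lengths in bp.

    This is the input boundary of the pipeline: alignment and quantification
    happen upstream, everything downstream starts from integer counts.
    """

    counts: pd.DataFrame
    lengths: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative integers")
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:3].tolist()
            raise ValueError(f"genes missing a length, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive (bp)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """FPKM(g, s) = counts(g, s) * 1e9 / (total_counts(s) * length(g)).

    Per-sample totals are the column sums of the count matrix (the mapped
    library size at this input boundary).  A sample with zero total counts
    is an error, named in the message.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    c = counts.counts.to_numpy(dtype=float)
    fpkm = c * 1e9 / (totals.to_numpy(dtype=float)[None, :] * counts.lengths.to_numpy(dtype=float)[:, None])
    return pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids)


def filter_low_expression(matrix: pd.DataFrame, min_expressed_fraction: float = 0.8) -> pd.DataFrame:
    """Drop genes expressed (nonzero) in fewer than ``min_expressed_fraction``
    of samples; gene order is preserved."""
    if not 0 < min_expressed_fraction <= 1:
        raise ValueError("min_expressed_fraction must be in (0, 1]")
    frac = (matrix.to_numpy() > 0).mean(axis=1)
    return matrix.loc[frac >= min_expressed_fraction]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --- empirical-Bayes variance moderation ------------------------------------

def _trigamma_inverse(x: float) -> float:
    # Newton iteration for psi1(y) = x; asymptotic starts at the extremes.
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink per-gene sample variances toward a common prior.

    Fits a scaled-F model to the observed variances by the method of moments
    on log variances and returns the posterior variances together with the
    prior degrees of freedom d0 (np.inf when the observed spread is no wider
    than chi-square sampling noise alone).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        # Too few informative genes to fit a prior: no shrinkage possible.
        return s2.copy(), 0.0
    e = np.log(s2[ok]) - digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0 = np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0 = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0)
    return post, d0


def test_differential(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    *,
    method: str = "moderated",
    pseudocount: float = 1.0,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> pd.DataFrame:
    """Per-gene differential-expression test of group B vs group A.

    Both groups are FPKM-normalized from the full matrix, the test runs on
    log2(FPKM + pseudocount), and ``log2_ratio`` is
    log2((mean FPKM_B + pseudocount) / (mean FPKM_A + pseudocount)) so B > A
    gives positive ratios.  Returns a DataFrame with columns
    ``log2_ratio, p_value, fdr, direction`` indexed by gene; ``direction``
    applies the supplied thresholds.  Genes with zero counts throughout both
    groups get p = 1 and log2_ratio = 0.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    fpkm = compute_fpkm(counts)
    fa = fpkm[list(group_a)].to_numpy()
    fb = fpkm[list(group_b)].to_numpy()
    la = np.log2(fa + pseudocount)
    lb = np.log2(fb + pseudocount)
    lfc = np.log2(fb.mean(axis=1) + pseudocount) - np.log2(fa.mean(axis=1) + pseudocount)

    na, nb = la.shape[1], lb.shape[1]
    mean_diff = lb.mean(axis=1) - la.mean(axis=1)
    if method == "moderated":
        df = na + nb - 2
        s2 = (la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)) / df
        s2_post, d0 = squeeze_variances(s2, df)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        df_total = df + min(d0, 1e6)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        # se can still be 0 when every variance is exactly 0 (no prior fit)
        p = np.where(np.isnan(p), np.where(mean_diff == 0, 1.0, 0.0), p)
    elif method == "welch":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.where(np.isnan(p), np.where(mean_diff == 0, 1.0, 0.0), p)
    else:
        raise ValueError(f"unknown method {method!r}; use 'moderated' or 'welch'")

    allzero = (counts.counts[list(group_a) + list(group_b)].to_numpy() == 0).all(axis=1)
    p = np.where(allzero, 1.0, p)
    lfc = np.where(allzero, 0.0, lfc)

    fdr = benjamini_hochberg(p)
    direction = np.where(
        (lfc >= lfc_min) & (fdr <= fdr_max), "up",
        np.where((lfc <= -lfc_min) & (fdr <= fdr_max), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2_ratio": lfc, "p_value": p, "fdr": fdr, "direction": direction},
        index=counts.gene_ids,
    )


def call_degs(
    results: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> tuple[set, set]:
    """Split a differential test table into (up, down) gene sets.

    Thresholds are inclusive: |log2 ratio| >= lfc_min and FDR <= fdr_max.
    """
    if lfc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    if results.empty:
        return set(), set()
    sig = results["fdr"] <= fdr_max
    up = set(results.index[sig & (results["log2_ratio"] >= lfc_min)])
    down = set(results.index[sig & (results["log2_ratio"] <= -lfc_min)])
    return up, down
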