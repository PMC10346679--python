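"""Additive-dominance decomposition of trio expression and inheritance mode.

Treating the expression of each gene as a quantitative trait measured on the
two parents and their hybrid, the replicated trio fits the linear model

    y = u + GA + GD + SR + e

where u is the overall (mid-parent) mean, GA the composite additive effect
[a], GD the composite dominance effect [d], SR a replicate-block effect
(estimable only when replicates are paired across genotypes), and e the
residual.  With genotype means this reduces to

    [a] = (mean(P1) - mean(P2)) / 2
    [d] = mean(F1) - (mean(P1) + mean(P2)) / 2

The potency (dominance) ratio Hp = [d]/[a] classifies the mode of
inheritance:

    additive            -0.2 < Hp <= 0.2
    partial dominance   -0.8 < Hp <= -0.2  or  0.2 < Hp <= 0.8
    dominance           -1.2 < Hp <= -0.8  or  0.8 < Hp <= 1.2
    over-dominance       Hp <= -1.2  or  Hp > 1.2   (incl. +-inf)

The intervals are half-open the same way on both sides, so the boundary
points themselves are classified asymmetrically (e.g. Hp = 0.2 is additive
while Hp = -0.2 is partial dominance) — this mirrors the interval
convention exactly rather than smoothing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODES",
    "GeneEffectEstimate",
    "potency_ratio",
    "classify_mode",
    "estimate_effects",
    "effects_table",
    "breakdown",
]

MODES = ("additive", "partial_dominance", "dominance", "over_dominance")
DEFAULT_HP_BOUNDS = (0.2, 0.8, 1.2)


def potency_ratio(d_hat: float, a_hat: float) -> float:
    """Hp = [d]/[a]; signed infinity when [a] = 0 and [d] != 0, 0 when both 0."""
    if a_hat == 0:
        return 0.0 if d_hat == 0 else float(np.sign(d_hat)) * np.inf
    return d_hat / a_hat


def classify_mode(hp, bounds: tuple[float, float, float] = DEFAULT_HP_BOUNDS):
    """Map a potency ratio (scalar or array) to its inheritance mode.

    ``bounds = (b1, b2, b3)`` must be strictly increasing; the default is
    the (0.2, 0.8, 1.2) convention documented above.
    """
    b1, b2, b3 = bounds
    if not 0 < b1 < b2 < b3:
        raise ValueError("hp bounds must be strictly increasing and positive")
    h = np.asarray(hp, dtype=float)
    out = np.select(
        [
            (-b1 < h) & (h <= b1),
            ((-b2 < h) & (h <= -b1)) | ((b1 < h) & (h <= b2)),
            ((-b3 < h) & (h <= -b2)) | ((b2 < h) & (h <= b3)),
        ],
        ["additive", "partial_dominance", "dominance"],
        default="over_dominance",
    )
    if np.isscalar(hp) or np.ndim(hp) == 0:
        return str(out)
    return out


@dataclass
class GeneEffectEstimate:
    gene_id: str
    a_hat: float
    d_hat: float
    mu_hat: float
    rep_effects: np.ndarray
    residual_var: float
    se_a: float
    se_d: float
    hp: float
    mode: str


def _estimate_arrays(p1: np.ndarray, p2: np.ndarray, f1: np.ndarray, paired: bool):
    """Vectorized trio decomposition; inputs are genes x replicates."""
    m1, m2, mf = p1.mean(axis=1), p2.mean(axis=1), f1.mean(axis=1)
    a = (m1 - m2) / 2.0
    d = mf - (m1 + m2) / 2.0
    mu = (m1 + m2) / 2.0
    n1, n2, nf = p1.shape[1], p2.shape[1], f1.shape[1]
    ntot = n1 + n2 + nf
    if paired:
        # replicate-block effect: mean over genotypes of replicate k, centered
        blocks = (p1 + p2 + f1) / 3.0
        rep = blocks - blocks.mean(axis=1, keepdims=True)
        resid = np.concatenate(
            [p1 - m1[:, None] - rep, p2 - m2[:, None] - rep, f1 - mf[:, None] - rep], axis=1
        )
        df = ntot - 3 - (n1 - 1)
    else:
        rep = np.zeros_like(p1)
        resid = np.concatenate([p1 - m1[:, None], p2 - m2[:, None], f1 - mf[:, None]], axis=1)
        df = ntot - 3
    if df <= 0:
        s2 = np.full_like(a, np.nan)
    else:
        s2 = (resid**2).sum(axis=1) / df
    se_a = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2) / 4.0)
    se_d = np.sqrt(s2 * (1.0 / nf + 1.0 / (4 * n1) + 1.0 / (4 * n2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        hp = np.where(a == 0, np.where(d == 0, 0.0, np.sign(d) * np.inf), d / np.where(a == 0, 1.0, a))
    return a, d, mu, rep, s2, se_a, se_d, hp, df


def estimate_effects(p1_reps, p2_reps, f1_reps, *, paired: bool | None = None,
                     gene_id: str = "gene") -> GeneEffectEstimate:
    """Decompose one gene's replicated trio expression into [a], [d], Hp.

    Expression should already be on the analysis scale (log2(FPKM+1) in the
    pipeline).  ``paired=None`` pairs replicates into blocks when all three
    genotypes have equally many; unpaired data drops the SR term.
    """
    p1 = np.atleast_2d(np.asarray(p1_reps, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2_reps, dtype=float))
    f1 = np.atleast_2d(np.asarray(f1_reps, dtype=float))
    if min(p1.shape[1], p2.shape[1], f1.shape[1]) < 2:
        raise ValueError("need at least 2 replicates per genotype")
    if paired is None:
        paired = p1.shape[1] == p2.shape[1] == f1.shape[1]
    if paired and not (p1.shape[1] == p2.shape[1] == f1.shape[1]):
        raise ValueError("paired fit requires equal replicate counts")
    a, d, mu, rep, s2, se_a, se_d, hp, _ = _estimate_arrays(p1, p2, f1, paired)
    return GeneEffectEstimate(
        gene_id=gene_id, a_hat=float(a[0]), d_hat=float(d[0]), mu_hat=float(mu[0]),
        rep_effects=rep[0], residual_var=float(s2[0]), se_a=float(se_a[0]),
        se_d=float(se_d[0]), hp=float(hp[0]), mode=classify_mode(float(hp[0])),
    )


def effects_table(
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    environment: str | None = None,
    timepoint: str | None = None,
    *,
    pseudocount: float = 1.0,
    paired: bool | None = None,
    calibrate: bool = True,
    ci_gate: bool = False,
    ci_level: float = 0.998,
) -> pd.DataFrame:
    """Per-gene trio decomposition for every gene of an expression matrix.

    ``fpkm`` is the linear genes x samples expression matrix; the model is
    fit on log2(FPKM + pseudocount).  ``design`` maps sample_id to genotype
    (P1/P2/F1), environment, timepoint, replicate.  Optional
    ``environment``/``timepoint`` restrict the samples used; omitting both
    pools every condition's replicates per genotype, which is appropriate
    when the effect architecture is shared across conditions.

    ``calibrate`` (default on) rescales each sample so all samples share
    the same mean log2 expression over the genes expressed everywhere,
    before the log transform.  FPKM is a within-sample relative measure,
    so genotype-wide expression shifts leak a common offset into every
    gene's contrast ("composition bias"); equalizing the geometric-mean
    expression removes that offset and is a near no-op for
    already-comparable samples.

    When ``ci_gate`` is set, a column ``ci_pass`` marks genes whose
    ``ci_level`` confidence interval for [d] - [a] (if [d] > 0) or
    [d] + [a] (if [d] < 0) excludes zero — a guard that the dominance
    deviation is resolvable before trusting its ratio.
    """
    sel = design
    if environment is not None:
        sel = sel[sel["environment"] == environment]
    if timepoint is not None:
        sel = sel[sel["timepoint"] == timepoint]
    used = [s for s in fpkm.columns if s in set(sel["sample_id"])]
    sub = fpkm[used].to_numpy(dtype=float)
    pos = (sub > 0).all(axis=1)
    if calibrate and pos.sum() >= 10:
        logf = np.log2(sub[pos])
        offsets = logf.mean(axis=0) - logf.mean()
        sub = sub * np.exp2(-offsets)[None, :]
    sub = np.log2(sub + pseudocount)
    subdf = pd.DataFrame(sub, index=fpkm.index, columns=used)
    mats = {}
    for g in ("P1", "P2", "F1"):
        ids = sel.loc[sel["genotype"] == g].sort_values(["environment", "timepoint", "replicate"])["sample_id"]
        ids = [i for i in ids if i in subdf.columns]
        if len(ids) < 2:
            raise ValueError(f"genotype {g}: need at least 2 replicates, found {len(ids)}")
        mats[g] = subdf[list(ids)].to_numpy(dtype=float)
    p1, p2, f1 = mats["P1"], mats["P2"], mats["F1"]
    if paired is None:
        paired = p1.shape[1] == p2.shape[1] == f1.shape[1]
    a, d, mu, _, s2, se_a, se_d, hp, df = _estimate_arrays(p1, p2, f1, paired)
    out = pd.DataFrame(
        {"a_hat": a, "d_hat": d, "mu_hat": mu, "residual_var": s2,
         "se_a": se_a, "se_d": se_d, "hp": hp, "mode": classify_mode(hp)},
        index=fpkm.index,
    )
    if ci_gate:
        n1, n2, nf = p1.shape[1], p2.shape[1], f1.shape[1]
        # var(d -+ a): means are independent; cov(d, a) = 0 for n1 == n2
        var_d = s2 * (1.0 / nf + 1.0 / (4 * n1) + 1.0 / (4 * n2))
        var_a = s2 * (1.0 / n1 + 1.0 / n2) / 4.0
        cov_da = s2 * (1.0 / n2 - 1.0 / n1) / 4.0
        contrast = np.where(d > 0, d - a, d + a)
        var_c = var_d + var_a + np.where(d > 0, -2.0, 2.0) * cov_da
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, max(df, 1))
        out["ci_pass"] = np.abs(contrast) > tcrit * np.sqrt(var_c)
    return out


def breakdown(estimates: pd.DataFrame | pd.Series, by: list[str] | None = None) -> pd.DataFrame:
    """Percentage of genes in each inheritance class (sums to 100).

    ``estimates`` is an ``effects_table`` output (or a Series of modes);
    ``by`` optionally names grouping columns for per-group breakdowns.
    """
    if isinstance(estimates, pd.Series):
        modes = estimates
        frame = modes.to_frame("mode")
    else:
        frame = estimates
        modes = frame["mode"]
    if len(frame) == 0:
        raise ValueError("empty estimate set")
    def pct(m: pd.Series) -> pd.Series:
        counts = m.value_counts()
        return pd.Series({c: 100.0 * counts.get(c, 0) / len(m) for c in MODES})
    if by:
        return frame.groupby(by)["mode"].apply(pct).unstack()
    return pct(modes).to_frame("percent").T
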