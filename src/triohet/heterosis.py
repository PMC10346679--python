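"""Mid-parent and high-parent heterosis of phenotypic traits.

For a trait measured on two parents (P1, P2) and their F1 hybrid:

    MPH% = 100 * (F1 - MP) / MP,   MP = (P1 + P2) / 2
    HPH% = 100 * (F1 - BP) / BP,   BP = max(P1, P2)

The "better" parent is the parent with the larger trait mean regardless of
agronomic desirability, which is what makes negative HPH entries possible.
Significance of MPH is a Welch t-test of the F1 replicates against
per-replicate mid-parent values (pairwise parental averages); HPH is tested
as F1 vs the better parent's replicates.  Stars follow the usual convention:
``**`` for p < 0.01, ``*`` for p < 0.05.

A packaged fixture (``table1_phenotypes``) carries the flag-leaf trait means
of the WFB x CHT025 rice trio in two field environments at 1 and 10 days
post-anthesis, with the originally printed MPH/HPH columns for comparison.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mid_parent",
    "mph",
    "hph",
    "significance_flag",
    "heterosis_significance",
    "heterosis_table",
    "table1_phenotypes",
]


def mid_parent(p1_mean: float, p2_mean: float) -> float:
    """Mid-parent value (P1 + P2) / 2."""
    return (p1_mean + p2_mean) / 2.0


def mph(p1_mean: float, p2_mean: float, f1_mean: float) -> float:
    """Mid-parent heterosis in percent; errors on a zero mid-parent."""
    mp = mid_parent(p1_mean, p2_mean)
    if mp == 0:
        raise ValueError("mid-parent value is zero; MPH undefined")
    return 100.0 * (f1_mean - mp) / mp


def hph(p1_mean: float, p2_mean: float, f1_mean: float) -> float:
    """High-parent (better-parent) heterosis in percent."""
    bp = max(p1_mean, p2_mean)
    if bp == 0:
        raise ValueError("better-parent value is zero; HPH undefined")
    return 100.0 * (f1_mean - bp) / bp


def significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _welch(x: np.ndarray, y: np.ndarray) -> float:
    # identical degenerate samples: no evidence of a difference
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def heterosis_significance(p1_reps, p2_reps, f1_reps) -> tuple[float, float, str, str]:
    """Test MPH and HPH of replicate-level trait data.

    Returns ``(mph_p, hph_p, mph_flag, hph_flag)``.  The mid-parent sample
    is built from per-replicate parental pairs, so both parents must have
    the same number of replicates.
    """
    p1 = np.asarray(p1_reps, dtype=float)
    p2 = np.asarray(p2_reps, dtype=float)
    f1 = np.asarray(f1_reps, dtype=float)
    if min(len(p1), len(p2), len(f1)) < 2:
        raise ValueError("need at least 2 replicates per genotype")
    if len(p1) != len(p2):
        raise ValueError("parental replicate counts must match to pair mid-parent values")
    mp = (p1 + p2) / 2.0
    better = p1 if p1.mean() >= p2.mean() else p2
    mph_p = _welch(f1, mp)
    hph_p = _welch(f1, better)
    return mph_p, hph_p, significance_flag(mph_p), significance_flag(hph_p)


def heterosis_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-trait MPH/HPH table from replicate-level phenotype records.

    ``phenotypes`` is long-format with columns
    ``trait, environment, timepoint, genotype, replicate, value`` and
    genotypes labelled P1/P2/F1.  Output has one row per
    (environment, timepoint, trait) with genotype means, MPH/HPH percent,
    p-values and star flags.
    """
    required = {"trait", "environment", "timepoint", "genotype", "value"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    rows = []
    for (env, tp, trait), grp in phenotypes.groupby(["environment", "timepoint", "trait"], sort=False):
        byg = {g: sub["value"].to_numpy(dtype=float) for g, sub in grp.groupby("genotype")}
        if not {"P1", "P2", "F1"} <= set(byg):
            raise ValueError(f"({env}, {tp}, {trait}) lacks one of P1/P2/F1")
        m1, m2, mf = byg["P1"].mean(), byg["P2"].mean(), byg["F1"].mean()
        row = {
            "environment": env, "timepoint": tp, "trait": trait,
            "p1_mean": m1, "p2_mean": m2, "f1_mean": mf,
            "mph_percent": mph(m1, m2, mf), "hph_percent": hph(m1, m2, mf),
        }
        if all(len(byg[g]) >= 2 for g in ("P1", "P2", "F1")) and len(byg["P1"]) == len(byg["P2"]):
            mp_p, hp_p, mf_, hf_ = heterosis_significance(byg["P1"], byg["P2"], byg["F1"])
            row.update(mph_p=mp_p, hph_p=hp_p, mph_flag=mf_, hph_flag=hf_)
        else:
            row.update(mph_p=np.nan, hph_p=np.nan, mph_flag="", hph_flag="")
        rows.append(row)
    return pd.DataFrame(rows)


def table1_phenotypes() -> pd.DataFrame:
    """Packaged flag-leaf trait means of the rice trio study.

    Columns: environment (early/middle season), timepoint (1D/10D post
    anthesis), trait, units, genotype means (P1 = WFB, P2 = CHT025,
    F1 = WFYT025) with sd where reported, the originally printed MPH/HPH
    percentages and significance flags, and a ``note`` column flagging
    entries whose printed percentage does not match the printed means
    (``mph_suspect_typo``, ``hph_print_mismatch``).
    """
    ref = importlib.resources.files("triohet.data").joinpath("table1_phenotypes.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    for col in ("mph_flag", "hph_flag", "note"):
        df[col] = df[col].fillna("")
    return df
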