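"""Stage-wise differential expression, stage-trend statistics and qPCR
relative quantitation.

The expression matrix is genes x samples on the log2 scale; the design
table maps each sample to an arm (control / disease), an ordered stage
label and a replicate index.  Disease samples are always compared against
stage-matched ("age-matched") controls.  The DE filter is the classic
two-fold / BH-adjusted p < 0.05 rule: |log2FC| >= 1 (inclusive) and
adjusted p strictly below alpha, with the BH family being all genes tested
at that stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP = "up"
DOWN = "down"
NONE = "none"


def _stage_columns(design: pd.DataFrame, stage: str, arm: str) -> list[str]:
    mask = (design["stage"] == stage) & (design["arm"] == arm)
    cols = list(design.index[mask])
    if not cols:
        raise ValueError(f"no {arm} samples at stage {stage!r}")
    return cols


def natural_log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform raw-scale inputs (variance stabilisation)."""
    if (values <= 0).any().any():
        raise ValueError("natural log transform requires strictly positive values")
    return np.log(values)


def stage_log2fc(expr: pd.DataFrame, design: pd.DataFrame, stage: str) -> pd.Series:
    """Per-gene mean(log2 disease) - mean(log2 control) at one stage."""
    d = expr[_stage_columns(design, stage, "disease")].mean(axis=1)
    c = expr[_stage_columns(design, stage, "control")].mean(axis=1)
    return (d - c).rename(f"log2fc_{stage}")


def de_test(
    expr: pd.DataFrame, design: pd.DataFrame, stage: str, equal_var: bool = True
) -> pd.Series:
    """Two-sample t-test p-value per gene, disease vs stage-matched control.

    Pooled-variance Student form by default (``equal_var=False`` switches
    to Welch).  Degenerate genes with zero variance in both arms get p = 1
    when the means are equal and p = 0 otherwise.
    """
    d_cols = _stage_columns(design, stage, "disease")
    c_cols = _stage_columns(design, stage, "control")
    if len(d_cols) < 2 or len(c_cols) < 2:
        raise ValueError(f"need >=2 replicates per arm at stage {stage!r}")
    d = expr[d_cols].to_numpy()
    c = expr[c_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(d, c, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(d.mean(axis=1), c.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return pd.Series(p, index=expr.index, name=f"p_{stage}")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(expr: pd.DataFrame, design: pd.DataFrame, stage: str,
             equal_var: bool = True) -> pd.DataFrame:
    """Per-gene DE summary at one stage: log2fc, raw p, BH-adjusted p."""
    fc = stage_log2fc(expr, design, stage)
    p = de_test(expr, design, stage, equal_var=equal_var)
    return pd.DataFrame(
        {"log2fc": fc, "p": p, "adj_p": bh_adjust(p.to_numpy())}, index=expr.index
    )


def select_degs(
    de: pd.DataFrame, fc_threshold: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the two-fold / BH<alpha filter and assign directions.

    A gene passes iff |log2fc| >= log2(fc_threshold) (inclusive) and
    adj_p < alpha (strict).  Returns the input with a ``direction`` column
    (up / down / none); the DEG set is the rows with direction != none.
    """
    out = de.copy()
    log2_thr = np.log2(fc_threshold)
    passed = (out["log2fc"].abs() >= log2_thr) & (out["adj_p"] < alpha)
    out["direction"] = np.where(
        passed, np.where(out["log2fc"] > 0, UP, DOWN), NONE
    )
    return out


def deg_set(de_selected: pd.DataFrame) -> dict[str, str]:
    """gene_id -> direction for genes passing the DE filter."""
    sel = de_selected[de_selected["direction"] != NONE]
    return dict(zip(sel.index, sel["direction"]))


def common_trend_genes(per_stage_degs: dict[str, dict[str, str]]) -> dict[str, str]:
    """Genes in every stage's DEG set with the same direction at all stages."""
    if len(per_stage_degs) < 2:
        raise ValueError("need DEG sets for at least two stages")
    stages = list(per_stage_degs)
    common: dict[str, str] = {}
    for gene, direction in per_stage_degs[stages[0]].items():
        if all(per_stage_degs[s].get(gene) == direction for s in stages[1:]):
            common[gene] = direction
    return common


def unique_final_stage_degs(per_stage_degs: dict[str, dict[str, str]],
                            final_stage: str) -> dict[str, str]:
    """Genes DE at the final stage but at no earlier stage.

    The substrate for the HCC-unique analysis: expression changes that
    appear only in full-fledged tumours.
    """
    earlier = set()
    for stage, degs in per_stage_degs.items():
        if stage != final_stage:
            earlier |= set(degs)
    return {g: d for g, d in per_stage_degs[final_stage].items() if g not in earlier}


@dataclass
class TrendStats:
    """Stage-dependence summary for one gene's per-stage replicate values."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, p
    slope: float
    slope_p: float


def stage_trend_stats(values_by_stage: dict[str, np.ndarray]) -> TrendStats:
    """One-way ANOVA + Tukey HSD across stages, plus an OLS trend on stage rank.

    ``values_by_stage`` maps ordered stage labels to replicate value arrays.
    Identical groups give F = 0, p = 1, slope = 0.
    """
    stages = list(values_by_stage)
    groups = [np.asarray(values_by_stage[s], dtype=float) for s in stages]
    if len(groups) < 2:
        raise ValueError("need at least two stages")
    if any(g.size < 2 for g in groups):
        raise ValueError("need >=2 replicates per stage")

    if all(np.allclose(g, groups[0].mean()) for g in groups):
        f_stat, anova_p = 0.0, 1.0
        tukey = pd.DataFrame(
            [(stages[i], stages[j], 1.0)
             for i in range(len(stages)) for j in range(i + 1, len(stages))],
            columns=["group1", "group2", "p"],
        )
        slope, slope_p = 0.0, 1.0
    else:
        f_stat, anova_p = stats.f_oneway(*groups)
        hsd = stats.tukey_hsd(*groups)
        tukey = pd.DataFrame(
            [(stages[i], stages[j], float(hsd.pvalue[i, j]))
             for i in range(len(stages)) for j in range(i + 1, len(stages))],
            columns=["group1", "group2", "p"],
        )
        x = np.concatenate([np.full(g.size, rank) for rank, g in enumerate(groups)])
        y = np.concatenate(groups)
        reg = stats.linregress(x, y)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    return TrendStats(float(f_stat), float(anova_p), tukey, slope, slope_p)


def delta_ct(ct_target, ct_reference) -> np.ndarray:
    """dCt = target Ct - reference Ct, elementwise."""
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ValueError("Ct values must be finite")
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("Ct values must be positive")
    return t - r


def ddct_fold_change(calibrator: pd.DataFrame, sample: pd.DataFrame) -> float:
    """Relative quantitation by 2^-ddCt.

    Both frames need columns ``ct_target`` and ``ct_reference``; the group
    dCt is the arithmetic mean over its measurements, ddCt = mean dCt of
    the sample group minus mean dCt of the calibrator group, and the fold
    change is 2^-ddCt (1.0 when ddCt = 0).
    """
    if len(calibrator) == 0 or len(sample) == 0:
        raise ValueError("calibrator and sample groups must be non-empty")
    dct_cal = delta_ct(calibrator["ct_target"], calibrator["ct_reference"]).mean()
    dct_sam = delta_ct(sample["ct_target"], sample["ct_reference"]).mean()
    return float(2.0 ** -(dct_sam - dct_cal))
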