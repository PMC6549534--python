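"""MeDIP-style promoter methylation quantitation and differential calls.

Percent methylation is the immunoprecipitated ("bound") quantity
normalised to the input-DNA quantity, 100 * bound / input.  Values above
100% are reported as-is but flagged rather than silently clipped, since
they indicate an assay artefact the analyst should see.

Three decision rules from the study are implemented:

* the functional-significance screen — a gene is considered only when its
  mean control-liver methylation is at least 20% (inclusive);
* per-stage differential methylation — two-sample t-test of percent
  methylation, disease vs age-matched control, reported both as an
  absolute decrease in percentage points and as a relative decrease
  (1 - disease/control);
* microarray-style DM calling — per-gene log2 enrichment ratios are
  standardised across the gene set to z-like scores and a gene is called
  when its BH-adjusted p-value is below 0.05 and |z| >= 1.5.  (The exact
  "Z-score fold-change" of the original array pipeline lives in a prior
  methods reference; standardisation across genes is this package's
  documented interpretation.)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expr import bh_adjust

HYPER = "hyper"
HYPO = "hypo"


def medip_percent(bound, input_quantity) -> np.ndarray | float:
    """Percent methylation = 100 * bound / input.

    Raises on non-positive input or negative bound quantities.  Values
    above 100 are returned unchanged (callers flag them).
    """
    b = np.asarray(bound, dtype=float)
    i = np.asarray(input_quantity, dtype=float)
    if (i <= 0).any() if i.ndim else i <= 0:
        raise ValueError("input quantity must be positive")
    if (b < 0).any() if b.ndim else b < 0:
        raise ValueError("bound quantity must be non-negative")
    out = 100.0 * b / i
    return float(out) if out.ndim == 0 else out


def percent_matrix(meth: pd.DataFrame) -> pd.DataFrame:
    """Wide percent-methylation matrix (genes x samples) from a long table.

    Expects columns gene_id, sample_id, bound, input.  Out-of-range
    (>100%) cells raise a warning and are kept; the count is stored in
    ``DataFrame.attrs['out_of_range']``.
    """
    required = {"gene_id", "sample_id", "bound", "input"}
    missing = required - set(meth.columns)
    if missing:
        raise ValueError(f"methylation table missing columns: {sorted(missing)}")
    pct = meth.assign(percent=medip_percent(meth["bound"], meth["input"]))
    wide = pct.pivot(index="gene_id", columns="sample_id", values="percent")
    n_oor = int((wide.to_numpy() > 100).sum())
    if n_oor:
        warnings.warn(f"{n_oor} percent-methylation values exceed 100%", stacklevel=2)
    wide.attrs["out_of_range"] = n_oor
    return wide


def _arm_columns(design: pd.DataFrame, arm: str, stage: str | None = None) -> list[str]:
    mask = design["arm"] == arm
    if stage is not None:
        mask &= design["stage"] == stage
    return list(design.index[mask])


def control_methylation_filter(
    percent: pd.DataFrame, design: pd.DataFrame, threshold: float = 20.0
) -> set[str]:
    """Genes whose mean control-arm percent methylation is >= threshold.

    Inclusive at the boundary (a gene at exactly 20.0% passes).  Genes
    with no control measurements are excluded with a warning.
    """
    c_cols = [c for c in _arm_columns(design, "control") if c in percent.columns]
    if not c_cols:
        raise ValueError("no control-arm samples found in the percent matrix")
    means = percent[c_cols].mean(axis=1)
    missing = means.index[means.isna()]
    if len(missing):
        warnings.warn(
            f"{len(missing)} genes lack control methylation records and are excluded",
            stacklevel=2,
        )
    return set(means.index[means >= threshold])


def dm_test(
    percent: pd.DataFrame, design: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """Per-gene differential methylation at one stage vs age-matched control.

    Returns a frame with ``delta_percent`` (control - disease, percentage
    points; positive = loss of methylation), ``relative_change``
    (1 - disease/control, the scale on which a "45% decrease" is stated)
    and the two-sample t-test ``p``.
    """
    d_cols = [c for c in _arm_columns(design, "disease", stage) if c in percent.columns]
    c_cols = [c for c in _arm_columns(design, "control", stage) if c in percent.columns]
    if len(d_cols) < 2 or len(c_cols) < 2:
        raise ValueError(f"need >=2 replicates per arm at stage {stage!r}")
    d = percent[d_cols].to_numpy()
    c = percent[c_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(d, c, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(d.mean(axis=1), c.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    c_mean = c.mean(axis=1)
    d_mean = d.mean(axis=1)
    delta = c_mean - d_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(c_mean != 0, delta / c_mean, np.nan)
    return pd.DataFrame(
        {"delta_percent": delta, "relative_change": rel, "p": p}, index=percent.index
    )


def meth_log2_ratio(
    percent: pd.DataFrame, design: pd.DataFrame, stage: str
) -> pd.Series:
    """log2(mean disease percent / mean control percent) per gene at a stage."""
    d_cols = [c for c in _arm_columns(design, "disease", stage) if c in percent.columns]
    c_cols = [c for c in _arm_columns(design, "control", stage) if c in percent.columns]
    d_mean = percent[d_cols].mean(axis=1)
    c_mean = percent[c_cols].mean(axis=1)
    if (d_mean <= 0).any() or (c_mean <= 0).any():
        raise ValueError("log2 enrichment ratio requires positive mean percents")
    return np.log2(d_mean / c_mean).rename(f"log2_ratio_{stage}")


def dm_call_microarray(
    fold_changes: pd.Series,
    pvalues: pd.Series,
    z_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Microarray-style DM calls from aligned per-gene ratios and p-values.

    ``fold_changes`` are per-gene log2 enrichment ratios (disease vs
    control); they are standardised across the gene set,
    z = (x - mean) / sd, and a gene is called when BH-adjusted p < alpha
    and |z| >= z_threshold.  Direction is hyper for positive ratios.
    """
    if not fold_changes.index.equals(pvalues.index):
        raise ValueError("fold_changes and pvalues must be aligned on the same genes")
    x = fold_changes.to_numpy(dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        raise ValueError("zero variance across genes: z-scores undefined")
    z = (x - x.mean()) / sd
    adj = bh_adjust(pvalues.to_numpy())
    called = (adj < alpha) & (np.abs(z) >= z_threshold)
    return pd.DataFrame(
        {
            "log2_ratio": x,
            "zscore": z,
            "p": pvalues.to_numpy(),
            "adj_p": adj,
            "called": called,
            "direction": np.where(x > 0, HYPER, HYPO),
        },
        index=fold_changes.index,
    )


def dmr_percent_methylated(states) -> float:
    """Percent of methylated CpG sites among all CpG sites in a region.

    ``states`` is an iterable of per-CpG calls; truthy / "methylated"
    entries count as methylated.
    """
    states = list(states)
    if not states:
        raise ValueError("region contains no CpG sites")
    def is_meth(s) -> bool:
        if isinstance(s, str):
            return s.lower() in {"methylated", "m", "1", "true"}
        return bool(s)
    n_meth = sum(1 for s in states if is_meth(s))
    return 100.0 * n_meth / len(states)
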