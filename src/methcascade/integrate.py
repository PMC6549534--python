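"""Expression / methylation / H3K4me3 integration and candidate nomination.

Two filter cascades single out genes whose expression changes are
plausibly driven by promoter methylation:

* the common-gene cascade follows genes differentially expressed with the
  same direction at every disease stage, requires a promoter CpG island,
  a control-liver methylation of at least 20%, differential methylation
  at every stage and an inverse expression-methylation correlation — the
  route that isolates a progressively hypomethylated, over-expressed
  driver;
* the HCC-unique cascade starts from genes differentially expressed only
  at the final (tumour) stage, requires a microarray-style DM call, an
  inverse relationship between the expression and methylation changes,
  and a tumour methylation level strictly above 20%.

Survivors are classified by concordance of directions:
(up, hypo) -> hypomethylated_overexpressed, (down, hyper) ->
hypermethylated_downregulated, anything else discordant.  Each gene's
report records the boolean trail through every filter; a later filter is
only evaluated when all earlier ones passed, so the trail is monotone and
survivor counts are nested along the cascade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expr import DOWN, UP
from .methyl import HYPER, HYPO

CLASS_HYPO_OVER = "hypomethylated_overexpressed"
CLASS_HYPER_DOWN = "hypermethylated_downregulated"
CLASS_DISCORDANT = "discordant"
CLASS_NOT_CANDIDATE = "not_candidate"

COMMON_FILTERS = (
    "de_all_stages",
    "cgi_present",
    "control_meth_ge_20",
    "dm_all_stages",
    "inverse_correlation",
)
HCC_FILTERS = (
    "de_hcc_unique",
    "dm_called",
    "inverse_relationship",
    "meth_gt_20",
)


def h3k4_fold_enrichment(
    h3k4: pd.DataFrame, design: pd.DataFrame, stage: str
) -> pd.Series:
    """Per-gene H3K4me3 log2 fold enrichment, disease vs stage-matched control.

    ``h3k4`` is a long table (gene_id, sample_id, chip, input); the
    statistic is mean log2(chip/input) in the disease arm minus the same
    mean in the age-matched control arm.
    """
    required = {"gene_id", "sample_id", "chip", "input"}
    missing = required - set(h3k4.columns)
    if missing:
        raise ValueError(f"H3K4me3 table missing columns: {sorted(missing)}")
    if (h3k4["input"] <= 0).any():
        raise ValueError("input quantity must be positive")
    if (h3k4["chip"] <= 0).any():
        raise ValueError("chip quantity must be positive")
    tab = h3k4.assign(log2_ratio=np.log2(h3k4["chip"] / h3k4["input"]))
    arm = design["arm"].reindex(tab["sample_id"]).to_numpy()
    st = design["stage"].reindex(tab["sample_id"]).to_numpy()
    at_stage = tab[st == stage]
    arm_at = arm[st == stage]
    d = at_stage[arm_at == "disease"].groupby("gene_id")["log2_ratio"].mean()
    c = at_stage[arm_at == "control"].groupby("gene_id")["log2_ratio"].mean()
    if d.empty or c.empty:
        raise ValueError(f"missing disease or control H3K4me3 samples at {stage!r}")
    return (d - c).rename(f"h3k4_log2fc_{stage}")


def h3k4_filter(enrichments: pd.Series, threshold_log2: float = 1.0) -> set[str]:
    """Genes with |log2 enrichment| >= threshold (two-fold rule, inclusive)."""
    return set(enrichments.index[enrichments.abs() >= threshold_log2])


def expr_meth_correlation(
    expr: pd.DataFrame,
    values: pd.DataFrame,
    design: pd.DataFrame,
    gene: str,
    stage: str | None = None,
) -> dict:
    """Pearson correlation between a gene's expression and a paired measure.

    Pairs disease-arm samples' log2 expression with the same samples'
    values (percent methylation or H3K4me3 enrichment) — pooled across
    all stages by default, or within one stage when ``stage`` is given.
    Returns a dict with r, two-sided p, n and the gene id.
    """
    mask = design["arm"] == "disease"
    if stage is not None:
        mask &= design["stage"] == stage
    samples = [s for s in design.index[mask] if s in expr.columns and s in values.columns]
    if len(samples) < 3:
        raise ValueError(f"need >=3 paired observations, have {len(samples)}")
    x = expr.loc[gene, samples].to_numpy(dtype=float)
    y = values.loc[gene, samples].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"zero variance for gene {gene}: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"gene_id": gene, "r": float(r), "p": float(p), "n": len(samples)}


def classify_concordance(expr_direction: str, meth_direction: str) -> str:
    """Concordance class of an (expression, methylation) direction pair."""
    if expr_direction == UP and meth_direction == HYPO:
        return CLASS_HYPO_OVER
    if expr_direction == DOWN and meth_direction == HYPER:
        return CLASS_HYPER_DOWN
    return CLASS_DISCORDANT


def _empty_report(genes, filters) -> pd.DataFrame:
    rep = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for f in filters:
        rep[f] = False
    rep["final_class"] = CLASS_NOT_CANDIDATE
    return rep


def common_gene_cascade(
    deg_common: dict[str, str],
    cgi_flags: dict[str, bool],
    control_filter: set[str],
    dm_results: dict[str, pd.DataFrame],
    correlations: dict[str, dict],
    gene_universe=None,
    alpha: float = 0.05,
    dm_all_stages: bool = True,
) -> pd.DataFrame:
    """Run the common-trend filter cascade over a gene universe.

    Parameters mirror the upstream computations: the common-trend DEG set
    with directions, promoter CGI flags, the >=20% control-methylation
    gene set, per-stage ``dm_test`` frames, and per-gene pooled
    correlation dicts ({gene: {r, p, n}}).  ``dm_all_stages=False``
    relaxes the DM requirement from every stage to any stage.

    Returns one row per gene with the boolean filter trail and the final
    class; survivors are classified by the common expression direction
    and the sign of the final-stage methylation change.
    """
    if gene_universe is None:
        gene_universe = list(cgi_flags)
    genes = list(gene_universe)
    missing = [g for g in deg_common if g not in set(genes)]
    if missing:
        raise ValueError(f"genes outside the declared universe: {missing[:5]}")
    rep = _empty_report(genes, COMMON_FILTERS)
    stages = list(dm_results)
    final_stage = stages[-1]
    for gene in genes:
        if gene not in deg_common:
            continue
        rep.loc[gene, "de_all_stages"] = True
        if not cgi_flags.get(gene, False):
            continue
        rep.loc[gene, "cgi_present"] = True
        if gene not in control_filter:
            continue
        rep.loc[gene, "control_meth_ge_20"] = True
        dm_p = [dm_results[s].loc[gene, "p"] for s in stages if gene in dm_results[s].index]
        if len(dm_p) != len(stages):
            continue
        dm_ok = (
            all(p < alpha for p in dm_p) if dm_all_stages else any(p < alpha for p in dm_p)
        )
        if not dm_ok:
            continue
        rep.loc[gene, "dm_all_stages"] = True
        corr = correlations.get(gene)
        if corr is None or not (corr["r"] < 0 and corr["p"] < alpha):
            continue
        rep.loc[gene, "inverse_correlation"] = True
        meth_dir = (
            HYPO if dm_results[final_stage].loc[gene, "delta_percent"] > 0 else HYPER
        )
        rep.loc[gene, "final_class"] = classify_concordance(deg_common[gene], meth_dir)
    return rep


def hcc_unique_cascade(
    de_hcc: dict[str, str],
    dm_calls: pd.DataFrame,
    meth_percent_hcc: pd.Series,
    correlations: dict[str, dict] | None = None,
    gene_universe=None,
    meth_threshold: float = 20.0,
    inverse_mode: str = "sign",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the tumour-stage-only filter cascade.

    ``de_hcc`` is the set of genes differentially expressed uniquely at
    the final stage (gene -> direction); ``dm_calls`` comes from
    ``dm_call_microarray`` at that stage; ``meth_percent_hcc`` is each
    gene's mean disease-arm percent methylation in tumours.  The inverse
    relationship is judged by opposite signs of the expression change and
    the methylation change (``inverse_mode="sign"``, default) or by a
    negative, significant per-stage Pearson correlation
    (``inverse_mode="pearson"``, requires ``correlations``).  The final
    methylation screen is strict: percent must exceed ``meth_threshold``.
    """
    if inverse_mode not in {"sign", "pearson"}:
        raise ValueError("inverse_mode must be 'sign' or 'pearson'")
    if inverse_mode == "pearson" and correlations is None:
        raise ValueError("pearson mode requires per-gene correlations")
    if gene_universe is None:
        gene_universe = list(dm_calls.index)
    genes = list(gene_universe)
    unknown = [g for g in de_hcc if g not in set(genes)]
    if unknown:
        raise ValueError(f"genes outside the declared universe: {unknown[:5]}")
    rep = _empty_report(genes, HCC_FILTERS)
    for gene in genes:
        if gene not in de_hcc:
            continue
        rep.loc[gene, "de_hcc_unique"] = True
        if gene not in dm_calls.index or not bool(dm_calls.loc[gene, "called"]):
            continue
        rep.loc[gene, "dm_called"] = True
        meth_dir = dm_calls.loc[gene, "direction"]
        if inverse_mode == "sign":
            expr_up = de_hcc[gene] == UP
            inverse = (expr_up and meth_dir == HYPO) or (not expr_up and meth_dir == HYPER)
        else:
            corr = correlations.get(gene)
            inverse = corr is not None and corr["r"] < 0 and corr["p"] < alpha
        if not inverse:
            continue
        rep.loc[gene, "inverse_relationship"] = True
        pct = meth_percent_hcc.get(gene, np.nan)
        if not (pct > meth_threshold):
            continue
        rep.loc[gene, "meth_gt_20"] = True
        rep.loc[gene, "final_class"] = classify_concordance(de_hcc[gene], meth_dir)
    return rep


def cascade_survivors(report: pd.DataFrame) -> list[str]:
    """Genes classified as candidates (any class but not_candidate)."""
    return list(report.index[report["final_class"] != CLASS_NOT_CANDIDATE])


def funnel_counts(report: pd.DataFrame, filters) -> pd.Series:
    """Survivor count after each successive filter (the paper-style funnel)."""
    counts = {}
    for f in filters:
        counts[f] = int(report[f].sum())
    counts["classified"] = len(cascade_survivors(report))
    return pd.Series(counts, name="survivors")
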