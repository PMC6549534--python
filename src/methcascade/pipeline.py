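"""End-to-end orchestration: generate (or load) inputs, run every analysis
stage in dependency order, and write reports plus a run manifest.

The flow mirrors the candidate-nomination strategy: stage-wise DE and the
common-trend gene set; CpG-island annotation of promoters; MeDIP percent
methylation, the 20% control screen and per-stage DM tests; H3K4me3
enrichment; pooled expression-methylation correlation; and finally both
filter cascades.  All thresholds default to the study's stated values
(two-fold / BH < 0.05 DE, CGI 500 bp / 55% GC / 0.65 obs-exp, 20%
methylation, z 1.5 DM calls, two-fold H3K4me3).

Results go only to files; logging goes to stderr and a run log, which
records every threshold actually applied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cgiscan, expr, integrate, io, methyl, synthio

logger = logging.getLogger("methcascade")

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Either ``generator`` (synthetic mode) or the input ``paths`` must be
    present.  Paths, when given, point to: expression matrix TSV, design
    TSV, methylation long TSV, H3K4me3 long TSV and a promoter FASTA.
    """

    outdir: str = "methcascade_run"
    seed: int = 0
    generator: synthio.GeneratorConfig | None = None
    paths: dict[str, str] = field(default_factory=dict)

    fc_threshold: float = 2.0
    alpha: float = 0.05
    meth_threshold: float = 20.0
    dm_z_threshold: float = 1.5
    h3k4_threshold_log2: float = 1.0
    cgi_criteria: cgiscan.CgiCriteria = field(default_factory=cgiscan.CgiCriteria)

    correlation_mode: str = "pooled"  # or "per_stage"
    dm_all_stages: bool = True
    hcc_inverse_mode: str = "sign"  # or "pearson"

    def validate(self) -> None:
        for name in ("fc_threshold", "alpha", "meth_threshold",
                     "dm_z_threshold", "h3k4_threshold_log2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.generator is None and not self.paths:
            raise ValueError("either a generator config or input paths are required")
        if self.correlation_mode not in {"pooled", "per_stage"}:
            raise ValueError("correlation_mode must be 'pooled' or 'per_stage'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        crit = raw.pop("cgi_criteria", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = synthio.GeneratorConfig(**gen)
        if crit is not None:
            cfg.cgi_criteria = cgiscan.CgiCriteria(**crit)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)


def _load_inputs(config: RunConfig, outdir: Path) -> dict:
    if config.generator is not None:
        gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
        data = synthio.generate_all(gen_cfg)
        io.write_promoters_fasta(data["promoters"], outdir / "promoters.fasta")
        io.write_tsv(data["truth"].table, outdir / "truth.tsv")
        io.write_tsv(data["design"], outdir / "design.tsv")
        io.write_tsv(data["expression"], outdir / "expression.tsv")
        io.write_tsv(data["methylation"], outdir / "methylation.tsv", index=False)
        io.write_tsv(data["h3k4me3"], outdir / "h3k4me3.tsv", index=False)
        io.write_tsv(data["qpcr"], outdir / "qpcr.tsv", index=False)
        data["stages"] = list(gen_cfg.stages)
        return data
    p = config.paths
    design = io.read_design_tsv(p["design"])
    stages = list(pd.unique(design["stage"]))
    return {
        "promoters": io.read_promoters_fasta(p["promoters"]),
        "design": design,
        "expression": io.read_matrix_tsv(p["expression"]),
        "methylation": io.read_long_tsv(p["methylation"], ["bound", "input"]),
        "h3k4me3": io.read_long_tsv(p["h3k4me3"], ["chip", "input"]),
        "truth": None,
        "stages": stages,
    }


def analyze(data: dict, config: RunConfig | None = None) -> dict:
    """Run every analysis stage in memory on already-loaded inputs.

    ``data`` holds the keys produced by ``synthio.generate_all`` (or by
    the file readers): promoters, expression, design, methylation,
    h3k4me3, and optionally stages and truth.  Returns reports, funnels
    and intermediate tables; writes nothing.
    """
    if config is None:
        config = RunConfig(generator=synthio.GeneratorConfig())
    expr_tab: pd.DataFrame = data["expression"]
    design: pd.DataFrame = data["design"]
    stages: list[str] = data.get("stages") or list(pd.unique(design["stage"]))
    final_stage = stages[-1]

    gene_universe = list(expr_tab.index)
    meth_genes = set(data["methylation"]["gene_id"])
    mismatch = [g for g in gene_universe if g not in meth_genes]
    if mismatch:
        raise io.DataError(
            f"gene universe mismatch between expression and methylation tables: "
            f"{mismatch[:5]}"
        )
    if len(gene_universe) == 0:
        logger.warning("empty gene set; reports will be empty")
        empty_common = integrate._empty_report([], integrate.COMMON_FILTERS)
        empty_hcc = integrate._empty_report([], integrate.HCC_FILTERS)
        return {
            "stages": stages, "final_stage": final_stage,
            "islands": {}, "cgi_flags": {},
            "de_by_stage": {}, "degs_by_stage": {s: {} for s in stages},
            "common_trend": {}, "unique_hcc": {},
            "percent_methylation": pd.DataFrame(), "control_ok": set(),
            "dm_by_stage": {}, "dm_calls": pd.DataFrame(),
            "h3k4_by_stage": {}, "h3k4_counts": {s: 0 for s in stages},
            "correlations": {},
            "common_report": empty_common, "hcc_report": empty_hcc,
            "common_funnel": integrate.funnel_counts(empty_common, integrate.COMMON_FILTERS),
            "hcc_funnel": integrate.funnel_counts(empty_hcc, integrate.HCC_FILTERS),
            "truth": data.get("truth"),
        }

    # CGI annotation
    islands = {
        rec.gene_id: cgiscan.find_cpg_islands(rec, config.cgi_criteria)
        for rec in data["promoters"]
    }
    cgi_flags = {g: len(isl) > 0 for g, isl in islands.items()}

    # Differential expression per stage, common trend, HCC-unique set
    de_by_stage: dict[str, pd.DataFrame] = {}
    degs_by_stage: dict[str, dict[str, str]] = {}
    for stage in stages:
        de = expr.select_degs(
            expr.de_table(expr_tab, design, stage),
            fc_threshold=config.fc_threshold,
            alpha=config.alpha,
        )
        de_by_stage[stage] = de
        degs_by_stage[stage] = expr.deg_set(de)
    common = expr.common_trend_genes(degs_by_stage)
    unique_hcc = expr.unique_final_stage_degs(degs_by_stage, final_stage)

    # Methylation: percent matrix, 20% control screen, per-stage DM, array calls
    pct = methyl.percent_matrix(data["methylation"])
    control_ok = methyl.control_methylation_filter(pct, design, config.meth_threshold)
    dm_by_stage = {s: methyl.dm_test(pct, design, s) for s in stages}
    dm_calls = methyl.dm_call_microarray(
        methyl.meth_log2_ratio(pct, design, final_stage),
        dm_by_stage[final_stage]["p"],
        z_threshold=config.dm_z_threshold,
        alpha=config.alpha,
    )

    # H3K4me3 enrichment and the two-fold counts per stage
    h3k4_by_stage = {
        s: integrate.h3k4_fold_enrichment(data["h3k4me3"], design, s) for s in stages
    }
    h3k4_counts = {
        s: len(integrate.h3k4_filter(h3k4_by_stage[s], config.h3k4_threshold_log2))
        for s in stages
    }

    # Expression-methylation correlation (pooled across stages by default)
    correlations: dict[str, dict] = {}
    corr_stage = None if config.correlation_mode == "pooled" else final_stage
    for gene in gene_universe:
        try:
            correlations[gene] = integrate.expr_meth_correlation(
                expr_tab, pct, design, gene, stage=corr_stage
            )
        except ValueError:
            continue  # zero-variance or underpowered gene: no correlation

    # Cascades
    common_report = integrate.common_gene_cascade(
        common, cgi_flags, control_ok, dm_by_stage, correlations,
        gene_universe=gene_universe, alpha=config.alpha,
        dm_all_stages=config.dm_all_stages,
    )
    meth_hcc = pct[
        [c for c in design.index[(design["arm"] == "disease")
                                 & (design["stage"] == final_stage)]
         if c in pct.columns]
    ].mean(axis=1)
    hcc_report = integrate.hcc_unique_cascade(
        unique_hcc, dm_calls, meth_hcc,
        correlations=correlations, gene_universe=gene_universe,
        meth_threshold=config.meth_threshold,
        inverse_mode=config.hcc_inverse_mode, alpha=config.alpha,
    )

    return {
        "stages": stages,
        "final_stage": final_stage,
        "islands": islands,
        "cgi_flags": cgi_flags,
        "de_by_stage": de_by_stage,
        "degs_by_stage": degs_by_stage,
        "common_trend": common,
        "unique_hcc": unique_hcc,
        "percent_methylation": pct,
        "control_ok": control_ok,
        "dm_by_stage": dm_by_stage,
        "dm_calls": dm_calls,
        "h3k4_by_stage": h3k4_by_stage,
        "h3k4_counts": h3k4_counts,
        "correlations": correlations,
        "common_report": common_report,
        "hcc_report": hcc_report,
        "common_funnel": integrate.funnel_counts(common_report, integrate.COMMON_FILTERS),
        "hcc_funnel": integrate.funnel_counts(hcc_report, integrate.HCC_FILTERS),
        "truth": data.get("truth"),
    }


def run_full(config: RunConfig) -> dict:
    """Execute the full flow; returns the ``analyze`` results plus manifest.

    Writes every intermediate table under ``config.outdir``.  Deterministic
    given seed and inputs (the manifest timestamp is the only field that
    varies between runs).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info(
        "thresholds: fc=%g alpha=%g meth=%g%% dm_z=%g h3k4_log2=%g cgi=%d/%g/%g",
        config.fc_threshold, config.alpha, config.meth_threshold,
        config.dm_z_threshold, config.h3k4_threshold_log2,
        config.cgi_criteria.min_length, config.cgi_criteria.min_gc,
        config.cgi_criteria.min_obs_exp,
    )

    data = _load_inputs(config, outdir)
    result = analyze(data, config)

    io.write_islands_bed(result["islands"], outdir / "islands.bed")
    io.write_tsv(
        pd.DataFrame({"cgi_present": pd.Series(result["cgi_flags"])}).rename_axis(
            "gene_id"
        ),
        outdir / "cgi_flags.tsv",
    )
    for stage, de in result["de_by_stage"].items():
        io.write_tsv(de, outdir / f"de_{stage}.tsv")
    (outdir / "common_trend_genes.txt").write_text(
        "".join(f"{g}\t{d}\n" for g, d in sorted(result["common_trend"].items()))
    )
    io.write_tsv(result["percent_methylation"], outdir / "percent_methylation.tsv")
    for stage, dm in result["dm_by_stage"].items():
        io.write_tsv(dm, outdir / f"dm_{stage}.tsv")
    io.write_tsv(result["dm_calls"], outdir / f"dm_calls_{result['final_stage']}.tsv")
    io.write_tsv(pd.DataFrame(result["h3k4_by_stage"]), outdir / "h3k4_enrichment.tsv")
    io.write_tsv(result["common_report"], outdir / "cascade_common.tsv")
    io.write_tsv(result["hcc_report"], outdir / "cascade_hcc.tsv")
    io.write_tsv(
        pd.DataFrame(
            {"common": result["common_funnel"], "hcc_unique": result["hcc_funnel"]}
        ).rename_axis("filter"),
        outdir / "funnel.tsv",
    )
    logger.info("H3K4me3 two-fold gene counts per stage: %s", result["h3k4_counts"])
    logger.info("common cascade funnel: %s", result["common_funnel"].to_dict())
    logger.info("hcc-unique cascade funnel: %s", result["hcc_funnel"].to_dict())

    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": result["stages"],
        "n_genes": len(data["expression"].index),
        "input_checksums": {
            f.name: _sha256(f)
            for f in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.fasta"))
        },
        "funnel": {
            "common": result["common_funnel"].to_dict(),
            "hcc_unique": result["hcc_funnel"].to_dict(),
        },
        "h3k4_two_fold_counts": result["h3k4_counts"],
    }
    io.write_manifest(manifest, outdir / "manifest.json")
    result["manifest"] = manifest
    return result
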