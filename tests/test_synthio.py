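"""Synthetic-data generator: seeded determinism, truth consistency,
zero-noise planted-effect fidelity and null calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcascade import cgiscan, synthio
from methcascade.expr import ddct_fold_change, de_test, stage_log2fc
from methcascade.methyl import percent_matrix


def null_config(**kw):
    base = dict(
        n_genes=60, n_drivers=0, n_passengers=0, n_late_dm=0,
        cgi_promoter_fraction=0.0, seed=7,
    )
    base.update(kw)
    return synthio.GeneratorConfig(**base)


def zero_noise_config(**kw):
    base = dict(
        n_genes=30, n_drivers=3, n_passengers=4, n_late_dm=3,
        expr_noise_sd=0.0, meth_concentration=0.0, h3k4_noise_sd=0.0,
        ct_noise_sd=0.0, seed=3,
    )
    base.update(kw)
    return synthio.GeneratorConfig(**base)


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "bad",
    [
        dict(n_genes=0),
        dict(n_drivers=100, n_passengers=100, n_late_dm=100, n_genes=200),
        dict(driver_meth_control=0.1),
        dict(driver_expr_log2fc=(3.0, 2.0, 1.0)),
        dict(driver_meth_decrease=(0.45, 0.31, 0.23)),
        dict(h3k4_log2fc=(0.5, 1.0, 2.0)),
        dict(promoter_length=500),
        dict(cgi_promoter_fraction=0.0),  # drivers need CGI-positive promoters
        dict(stages=("only",)),
    ],
)
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        synthio.GeneratorConfig(**bad)


def test_truth_roles_match_config_counts(default_config, default_data):
    truth = default_data["truth"]
    roles = truth.table["role"].value_counts()
    assert roles["driver"] == default_config.n_drivers
    assert roles["passenger"] == default_config.n_passengers
    assert roles["late_dm"] == default_config.n_late_dm
    assert roles["null"] == (
        default_config.n_genes - default_config.n_drivers
        - default_config.n_passengers - default_config.n_late_dm
    )
    assert truth.table.index.is_unique
    # drivers are always CGI-positive
    assert truth.cgi_present[truth.table["role"] == "driver"].all()


def test_every_table_covers_every_truth_gene_exactly_once(default_data):
    genes = set(default_data["truth"].gene_ids)
    assert set(default_data["expression"].index) == genes
    for key in ("methylation", "h3k4me3", "qpcr"):
        long = default_data[key]
        per_sample = long.groupby("sample_id")["gene_id"].apply(set)
        assert all(s == genes for s in per_sample)
        assert not long.duplicated(["gene_id", "sample_id"]).any()
    assert {p.gene_id for p in default_data["promoters"]} == genes


def test_table_dimensions(default_config, default_data):
    n_samples = 2 * len(default_config.stages) * default_config.n_replicates
    assert default_data["expression"].shape == (default_config.n_genes, n_samples)
    assert len(default_data["design"]) == n_samples


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------

def test_seeded_determinism_byte_identical():
    cfg = synthio.GeneratorConfig(n_genes=20, n_drivers=1, n_passengers=2,
                                  n_late_dm=2, seed=11)
    a = synthio.generate_all(cfg)
    b = synthio.generate_all(cfg)
    assert [p.sequence for p in a["promoters"]] == [p.sequence for p in b["promoters"]]
    for key in ("expression", "methylation", "h3k4me3", "qpcr"):
        pd.testing.assert_frame_equal(a[key], b[key])
    other = synthio.generate_all(dataclasses.replace(cfg, seed=12))
    assert not a["expression"].equals(other["expression"])


def test_substreams_are_independent():
    # regenerating only the methylation table must not depend on whether
    # expression was generated first
    cfg = synthio.GeneratorConfig(n_genes=15, n_drivers=1, n_passengers=1,
                                  n_late_dm=1, seed=5)
    truth = synthio.make_truth(cfg)
    meth_alone = synthio.generate_methylation(cfg, truth)
    synthio.generate_expression(cfg, truth)
    meth_after = synthio.generate_methylation(cfg, truth)
    pd.testing.assert_frame_equal(meth_alone, meth_after)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def test_cgi_flags_agree_with_scanner_on_spec_config():
    cfg = synthio.GeneratorConfig(
        n_genes=50, n_drivers=2, n_passengers=3, n_late_dm=3,
        cgi_promoter_fraction=0.5, seed=1,
    )
    truth = synthio.make_truth(cfg)
    promoters = synthio.generate_promoters(cfg, truth)
    assert int(truth.cgi_present.sum()) == 25
    flags = cgiscan.annotate_cgi_genes(promoters)
    for rec in promoters:
        assert flags[rec.gene_id] == bool(truth.cgi_present.loc[rec.gene_id])


def test_null_config_without_cgi_has_no_islands():
    cfg = null_config(n_genes=20)
    truth = synthio.make_truth(cfg)
    for rec in synthio.generate_promoters(cfg, truth):
        assert cgiscan.find_cpg_islands(rec) == []


# ---------------------------------------------------------------------------
# Zero-noise planted-effect fidelity
# ---------------------------------------------------------------------------

def test_zero_noise_expression_recovers_planted_log2fc_exactly():
    cfg = zero_noise_config(driver_expr_log2fc=(1.5, 2.5, 3.5))
    truth = synthio.make_truth(cfg)
    expr, design = synthio.generate_expression(cfg, truth)
    for stage, planted in zip(cfg.stages, (1.5, 2.5, 3.5)):
        fc = stage_log2fc(expr, design, stage)
        for g in truth.genes_with_role("driver"):
            assert fc[g] == pytest.approx(planted)
        for g in truth.genes_with_role("null"):
            assert fc[g] == pytest.approx(0.0)


def test_zero_noise_methylation_matches_paper_decreases():
    cfg = zero_noise_config(
        driver_meth_control=0.60, driver_meth_decrease=(0.23, 0.31, 0.45)
    )
    truth = synthio.make_truth(cfg)
    meth = synthio.generate_methylation(cfg, truth)
    pct = percent_matrix(meth)
    design = synthio.make_design(cfg)
    driver = truth.genes_with_role("driver")[0]
    for stage, expected in zip(cfg.stages, (46.2, 41.4, 33.0)):
        cols = design.index[(design["arm"] == "disease") & (design["stage"] == stage)]
        assert pct.loc[driver, cols].mean() == pytest.approx(expected)
    control_cols = design.index[design["arm"] == "control"]
    assert pct.loc[driver, control_cols].mean() == pytest.approx(60.0)


def test_zero_noise_h3k4_fold_changes():
    cfg = zero_noise_config(h3k4_log2fc=(2.0, 1.0, 0.5))
    truth = synthio.make_truth(cfg)
    h3k4 = synthio.generate_h3k4me3(cfg, truth)
    design = synthio.make_design(cfg)
    from methcascade.integrate import h3k4_fold_enrichment

    for stage, log2fc in zip(cfg.stages, (2.0, 1.0, 0.5)):
        enr = h3k4_fold_enrichment(h3k4, design, stage)
        for g in truth.genes_with_role("driver") + truth.genes_with_role("passenger"):
            assert 2 ** enr[g] == pytest.approx(2 ** log2fc)
        for g in truth.genes_with_role("null"):
            assert enr[g] == pytest.approx(0.0)


def test_zero_noise_qpcr_ddct_identity():
    cfg = zero_noise_config(driver_expr_log2fc=(2.0, 3.0, 4.0))
    truth = synthio.make_truth(cfg)
    qpcr = synthio.generate_qpcr(cfg, truth)
    design = synthio.make_design(cfg)
    driver = truth.genes_with_role("driver")[0]
    null = truth.genes_with_role("null")[0]
    stage = cfg.stages[0]

    def group(gene, arm):
        samples = design.index[(design["arm"] == arm) & (design["stage"] == stage)]
        return qpcr[(qpcr["gene_id"] == gene) & qpcr["sample_id"].isin(samples)]

    assert ddct_fold_change(group(driver, "control"), group(driver, "disease")) == (
        pytest.approx(4.0)  # planted log2fc 2 at stage 1
    )
    assert ddct_fold_change(group(null, "control"), group(null, "disease")) == (
        pytest.approx(1.0)
    )


# ---------------------------------------------------------------------------
# Stochastic properties
# ---------------------------------------------------------------------------

def test_methylation_fractions_always_in_unit_interval(default_data):
    pct = percent_matrix(default_data["methylation"])
    assert float(pct.min().min()) >= 0.0
    assert float(pct.max().max()) <= 100.0


def test_null_expression_t_test_rejection_rate_calibrated():
    # all-null cohort: unadjusted per-gene t-tests should reject at ~alpha
    alpha = 0.05
    pvals = []
    for seed in range(5):
        cfg = null_config(n_genes=200, seed=seed)
        truth = synthio.make_truth(cfg)
        expr, design = synthio.generate_expression(cfg, truth)
        for stage in cfg.stages:
            pvals.append(de_test(expr, design, stage).to_numpy())
    p = np.concatenate(pvals)
    rate = float((p < alpha).mean())
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / p.size)
    assert alpha - half <= rate <= alpha + half


def test_null_methylation_has_no_systematic_arm_difference():
    cfg = null_config(n_genes=100, seed=3)
    truth = synthio.make_truth(cfg)
    pct = percent_matrix(synthio.generate_methylation(cfg, truth))
    design = synthio.make_design(cfg)
    for stage in cfg.stages:
        d = pct[design.index[(design["arm"] == "disease") & (design["stage"] == stage)]]
        c = pct[design.index[(design["arm"] == "control") & (design["stage"] == stage)]]
        diff = (d.mean(axis=1) - c.mean(axis=1)).mean()
        assert abs(diff) < 0.2  # percentage points, ~3 SE of the grand mean


def test_null_h3k4_false_positive_rate_below_five_percent():
    cfg = null_config(n_genes=200, h3k4_noise_sd=0.2, seed=9)
    truth = synthio.make_truth(cfg)
    h3k4 = synthio.generate_h3k4me3(cfg, truth)
    design = synthio.make_design(cfg)
    from methcascade.integrate import h3k4_filter, h3k4_fold_enrichment

    for stage in cfg.stages:
        enr = h3k4_fold_enrichment(h3k4, design, stage)
        # normal-tail oracle: se = sd*sqrt(2/n) = 0.1414, P(|x|>=1) ~ 2e-12
        assert len(h3k4_filter(enr)) / cfg.n_genes < 0.05


def test_qpcr_recovers_planted_fold_change_across_seeds():
    folds = []
    for seed in range(40):
        cfg = synthio.GeneratorConfig(
            n_genes=5, n_drivers=1, n_passengers=0, n_late_dm=0,
            driver_expr_log2fc=(2.0, 2.5, 3.0), ct_noise_sd=0.1, seed=seed,
        )
        truth = synthio.make_truth(cfg)
        qpcr = synthio.generate_qpcr(cfg, truth)
        design = synthio.make_design(cfg)
        driver = truth.genes_with_role("driver")[0]
        stage = cfg.stages[0]
        sub = qpcr[qpcr["gene_id"] == driver]
        cal = sub[sub["sample_id"].isin(
            design.index[(design["arm"] == "control") & (design["stage"] == stage)])]
        sam = sub[sub["sample_id"].isin(
            design.index[(design["arm"] == "disease") & (design["stage"] == stage)])]
        folds.append(ddct_fold_change(cal, sam))
    assert np.mean(folds) == pytest.approx(4.0, rel=0.05)
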