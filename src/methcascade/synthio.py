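"""Synthetic multi-omics generator with planted ground truth.

Emulates a three-stage (6wk NAFL, 12wk NASH-fibrosis, 20wk HCC) two-arm
(control vs disease) mouse liver study with n replicates per arm x stage,
producing promoter sequences, a log2-scale expression table, MeDIP-style
bound/input methylation quantities, H3K4me3 ChIP/input quantities and qPCR
Ct tables, together with a truth table recording each gene's planted role:

* ``driver``   — over-expressed at every stage with progressively deeper
                 promoter hypomethylation; always CGI-positive.
* ``passenger``— over-expressed at every stage, methylation untouched.
* ``late_dm``  — down-regulated and hypermethylated at the final stage only.
* ``null``     — no planted effect anywhere.

All randomness flows from a single root seed through fixed, named
substreams (one per output table), so adding one generator can never
perturb another's output, and identical config + seed gives byte-identical
files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgiscan import (
    CgiCriteria,
    PromoterRecord,
    _base_arrays,
    _window_sums,
    find_cpg_islands,
    gc_content,
    obs_exp_cpg,
)

ROLE_DRIVER = "driver"
ROLE_PASSENGER = "passenger"
ROLE_LATE_DM = "late_dm"
ROLE_NULL = "null"

# Substream indices off the root SeedSequence; fixed part of the contract.
_STREAMS = {"promoters": 0, "expression": 1, "methylation": 2, "h3k4me3": 3,
            "qpcr": 4, "truth": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class GeneratorConfig:
    """Study-design and effect-size parameters for the synthetic cohort.

    Stage-indexed tuples run over ``stages`` in order.  Expression values
    are log2 intensities; methylation is a promoter methylation fraction
    in [0, 1]; H3K4me3 effects are log2 fold enrichments versus the
    stage-matched control mean.
    """

    n_genes: int = 200
    n_replicates: int = 4
    stages: tuple[str, ...] = ("6wk", "12wk", "20wk")
    n_drivers: int = 5
    n_passengers: int = 10
    n_late_dm: int = 10

    expr_base_mean: float = 8.0
    expr_noise_sd: float = 0.25
    driver_expr_log2fc: tuple[float, ...] = (1.8, 2.8, 3.8)
    passenger_expr_log2fc: tuple[float, ...] = (1.8, 2.2, 2.6)
    late_dm_expr_log2fc: float = -2.5  # final stage only

    driver_meth_control: float = 0.60
    driver_meth_decrease: tuple[float, ...] = (0.23, 0.31, 0.45)
    baseline_meth: float = 0.30
    null_meth_range: tuple[float, float] = (0.04, 0.90)  # per-gene null baselines
    late_dm_delta: float = 0.25  # methylation shift, final stage only
    meth_concentration: float = 2000.0  # Beta concentration; 0 disables noise

    h3k4_log2fc: tuple[float, ...] = (2.0, 1.0, 0.4)
    h3k4_noise_sd: float = 0.2

    ct_reference_mean: float = 20.0
    ct_target_base: float = 25.0
    ct_noise_sd: float = 0.1

    cgi_promoter_fraction: float = 0.6
    promoter_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n_stages = len(self.stages)
        if n_stages < 2:
            raise ValueError("need at least two stages")
        for name in ("n_genes", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_drivers", "n_passengers", "n_late_dm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_drivers + self.n_passengers + self.n_late_dm > self.n_genes:
            raise ValueError("role counts exceed n_genes")
        for name in ("driver_expr_log2fc", "passenger_expr_log2fc",
                     "driver_meth_decrease", "h3k4_log2fc"):
            if len(getattr(self, name)) != n_stages:
                raise ValueError(f"{name} must have one value per stage")
        if self.n_drivers > 0:
            if self.driver_meth_control < 0.20:
                raise ValueError(
                    "driver_meth_control below 0.20: drivers could not pass "
                    "the 20% control-methylation threshold"
                )
            if any(np.diff(self.driver_expr_log2fc) <= 0):
                raise ValueError("driver_expr_log2fc must be strictly increasing")
            if any(np.diff(self.driver_meth_decrease) <= 0):
                raise ValueError("driver_meth_decrease must be strictly increasing")
            if not all(0 <= d < 1 for d in self.driver_meth_decrease):
                raise ValueError("driver_meth_decrease values must be in [0, 1)")
        affected = self.n_drivers + self.n_passengers + self.n_late_dm
        if affected > 0 and any(np.diff(self.h3k4_log2fc) >= 0):
            raise ValueError("h3k4_log2fc must be strictly decreasing (max at stage 1)")
        if not 0 <= self.cgi_promoter_fraction <= 1:
            raise ValueError("cgi_promoter_fraction must be in [0, 1]")
        if self.cgi_promoter_fraction > 0 and self.promoter_length < 600:
            raise ValueError(
                "promoter_length < 600 cannot host a qualifying CpG island"
            )
        if self.cgi_promoter_fraction == 0 and self.n_drivers > 0:
            raise ValueError(
                "drivers must receive CGI-positive promoters; "
                "cgi_promoter_fraction cannot be 0 when n_drivers > 0"
            )
        if not 0 <= self.baseline_meth <= 1 or not 0 <= self.driver_meth_control <= 1:
            raise ValueError("methylation fractions must be in [0, 1]")
        lo, hi = self.null_meth_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("null_meth_range must satisfy 0 <= lo <= hi <= 1")

    @property
    def final_stage(self) -> str:
        return self.stages[-1]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthTable:
    """Planted role and per-stage effects for every generated gene."""

    table: pd.DataFrame = field(repr=False)
    stages: tuple[str, ...] = ()

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.table.index[self.table["role"] == role])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def cgi_present(self) -> pd.Series:
        return self.table["cgi_present"]

    def expr_log2fc(self, stage: str) -> pd.Series:
        return self.table[f"expr_log2fc_{stage}"]

    def meth_fraction(self, stage: str) -> pd.Series:
        """Planted disease-arm methylation fraction at a stage."""
        return self.table[f"meth_{stage}"]


def make_truth(config: GeneratorConfig) -> TruthTable:
    """Assign roles, planted effects and CGI flags; deterministic per seed.

    Roles are assigned in blocks (drivers, passengers, late-DM, then nulls)
    over gene ids ``g0001..``; the CGI flag is forced True for drivers and
    drawn without replacement among the remaining genes so that exactly
    ``round(cgi_promoter_fraction * n_genes)`` genes are CGI-positive.
    """
    config.validate()
    n = config.n_genes
    genes = [f"g{i + 1:04d}" for i in range(n)]
    roles = np.array([ROLE_NULL] * n, dtype=object)
    i = 0
    roles[i:i + config.n_drivers] = ROLE_DRIVER
    i += config.n_drivers
    roles[i:i + config.n_passengers] = ROLE_PASSENGER
    i += config.n_passengers
    roles[i:i + config.n_late_dm] = ROLE_LATE_DM

    cgi = np.zeros(n, dtype=bool)
    if config.cgi_promoter_fraction > 0:
        n_cgi = max(int(round(config.cgi_promoter_fraction * n)), config.n_drivers)
        cgi[:config.n_drivers] = True
        extra = n_cgi - config.n_drivers
        if extra > 0:
            rng = _rng(config.seed, "promoters")
            others = np.arange(config.n_drivers, n)
            cgi[rng.choice(others, size=min(extra, others.size), replace=False)] = True

    df = pd.DataFrame({"role": roles, "cgi_present": cgi}, index=pd.Index(genes, name="gene_id"))

    # control-arm baseline: fixed for affected roles, spread over the
    # observed 4-90% range for null genes
    baseline = np.full(n, config.baseline_meth)
    baseline[roles == ROLE_DRIVER] = config.driver_meth_control
    is_null = roles == ROLE_NULL
    if is_null.any():
        rng_truth = _rng(config.seed, "truth")
        baseline[is_null] = rng_truth.uniform(*config.null_meth_range,
                                              size=int(is_null.sum()))

    clipped = 0
    for s_idx, stage in enumerate(config.stages):
        fc = np.zeros(n)
        fc[roles == ROLE_DRIVER] = config.driver_expr_log2fc[s_idx]
        fc[roles == ROLE_PASSENGER] = config.passenger_expr_log2fc[s_idx]
        if stage == config.final_stage:
            fc[roles == ROLE_LATE_DM] = config.late_dm_expr_log2fc
        df[f"expr_log2fc_{stage}"] = fc

        meth = baseline.copy()
        meth[roles == ROLE_DRIVER] = config.driver_meth_control * (
            1 - config.driver_meth_decrease[s_idx]
        )
        if stage == config.final_stage:
            meth[roles == ROLE_LATE_DM] = config.baseline_meth + config.late_dm_delta
        clipped += int(np.sum((meth < 0) | (meth > 1)))
        df[f"meth_{stage}"] = np.clip(meth, 0.0, 1.0)

    df["meth_control"] = baseline
    truth = TruthTable(table=df, stages=config.stages)
    truth.table.attrs["clipped_cells"] = clipped
    return truth


def make_design(config: GeneratorConfig) -> pd.DataFrame:
    """Sample sheet: sample_id -> arm, stage, replicate (controls first)."""
    rows = []
    for arm in ("control", "disease"):
        for stage in config.stages:
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{arm}_{stage}_{rep}", arm, stage, rep))
    return pd.DataFrame(rows, columns=["sample_id", "arm", "stage", "replicate"]).set_index(
        "sample_id"
    )


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _depleted_sequence(rng: np.random.Generator, length: int) -> str:
    """CpG-poor background: i.i.d. bases, then 90% of CpG G's mutated to A."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3])
    is_cpg_g = np.zeros(length, dtype=bool)
    is_cpg_g[1:] = (seq[:-1] == "C") & (seq[1:] == "G")
    mutate = is_cpg_g & (rng.random(length) < 0.9)
    seq[mutate] = "A"
    return "".join(seq)


def _island_sequence(rng: np.random.Generator, length: int) -> str:
    """CpG-rich segment: token stream, 25% 'CG' dinucleotides else uniform base."""
    out: list[str] = []
    total = 0
    bases = "ACGT"
    while total < length:
        if rng.random() < 0.25:
            out.append("CG")
            total += 2
        else:
            out.append(bases[rng.integers(4)])
            total += 1
    return "".join(out)[:length]


def _windows_depleted(seq: str, width: int = 500, max_oe: float = 0.4) -> bool:
    """True iff every `width`-bp window has obs/exp CpG <= max_oe."""
    if len(seq) < width:
        width = len(seq)
    is_c, is_g, _, cpg = _base_arrays(seq)
    c = _window_sums(is_c, width)
    g = _window_sums(is_g, width)
    k = _window_sums(cpg[:-1], width - 1) if len(seq) > 1 else np.array([0])
    denom = c.astype(float) * g.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, k * width / np.maximum(denom, 1e-300), 0.0)
    return bool(np.all(oe <= max_oe))


_ISLAND_MIN_LEN = 600
_ISLAND_MIN_GC = 0.60
_ISLAND_MIN_OE = 0.80


def generate_promoters(
    config: GeneratorConfig, truth: TruthTable | None = None
) -> list[PromoterRecord]:
    """Generate one promoter per gene; CGI-positive genes carry a planted island.

    The planted island is a >=600 bp CpG-rich segment (G+C >= 0.60, obs/exp
    >= 0.8) embedded in CpG-depleted flanks; CGI-negative promoters are
    fully depleted, verified post hoc (every 500 bp window obs/exp <= 0.4)
    and regenerated on failure (<= 100 attempts).
    """
    if truth is None:
        truth = make_truth(config)
    rng = _rng(config.seed, "promoters")
    records: list[PromoterRecord] = []
    for gene in truth.gene_ids:
        has_cgi = bool(truth.cgi_present.loc[gene])
        for attempt in range(100):
            if has_cgi:
                island_len = int(rng.integers(_ISLAND_MIN_LEN + 50, max(
                    _ISLAND_MIN_LEN + 51, min(config.promoter_length, 900))))
                island_len = min(island_len, config.promoter_length)
                island = _island_sequence(rng, island_len)
                flank_total = config.promoter_length - island_len
                left = int(rng.integers(0, flank_total + 1))
                seq = (
                    _depleted_sequence(rng, left)
                    + island
                    + _depleted_sequence(rng, flank_total - left)
                )
                sub = seq[left:left + island_len]
                if gc_content(sub) >= _ISLAND_MIN_GC and obs_exp_cpg(sub) >= _ISLAND_MIN_OE:
                    break
            else:
                seq = _depleted_sequence(rng, config.promoter_length)
                if _windows_depleted(seq):
                    break
        else:
            raise RuntimeError(f"could not generate a conforming promoter for {gene}")
        records.append(PromoterRecord(gene_id=gene, sequence=seq))
    return records


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: GeneratorConfig, truth: TruthTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 expression matrix (genes x samples) plus the design table.

    measurement = expr_base_mean + planted log2FC (disease arm only)
                  + N(0, expr_noise_sd).
    """
    design = make_design(config)
    rng = _rng(config.seed, "expression")
    n = config.n_genes
    values = np.empty((n, len(design)))
    for j, (sample, row) in enumerate(design.iterrows()):
        planted = (
            truth.expr_log2fc(row["stage"]).to_numpy()
            if row["arm"] == "disease"
            else np.zeros(n)
        )
        values[:, j] = config.expr_base_mean + planted
    values += rng.normal(0.0, config.expr_noise_sd, size=values.shape)
    expr = pd.DataFrame(values, index=truth.table.index, columns=design.index)
    return expr, design.copy()


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def _beta_noise(rng: np.random.Generator, mean: np.ndarray, concentration: float) -> np.ndarray:
    """Beta draw with given mean and concentration; degenerate when conc == 0."""
    if concentration <= 0:
        return mean.copy()
    eps = 1e-6
    m = np.clip(mean, eps, 1 - eps)
    return rng.beta(m * concentration, (1 - m) * concentration)


def generate_methylation(config: GeneratorConfig, truth: TruthTable) -> pd.DataFrame:
    """Long table (gene_id, sample_id, bound, input) of MeDIP-style pairs.

    The planted methylation fraction is perturbed by a Beta noise model
    (mean = planted fraction, concentration from config) whose bounded
    support keeps every emitted fraction in [0, 1]; bound = fraction x input.
    """
    design = make_design(config)
    rng = _rng(config.seed, "methylation")
    rows = []
    for sample, srow in design.iterrows():
        if srow["arm"] == "disease":
            planted = truth.meth_fraction(srow["stage"]).to_numpy()
        else:
            planted = truth.table["meth_control"].to_numpy()
        frac = _beta_noise(rng, planted, config.meth_concentration)
        inputs = rng.uniform(50.0, 150.0, size=frac.size)
        bound = frac * inputs
        for gene, f, b, inp in zip(truth.gene_ids, frac, bound, inputs):
            rows.append((gene, sample, b, inp))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "bound", "input"])


# ---------------------------------------------------------------------------
# H3K4me3
# ---------------------------------------------------------------------------

def generate_h3k4me3(config: GeneratorConfig, truth: TruthTable) -> pd.DataFrame:
    """Long table (gene_id, sample_id, chip, input) of ChIP/input pairs.

    Affected genes (drivers and passengers) receive the stage's planted
    log2 fold enrichment in the disease arm, maximal at the first stage;
    null and late-DM genes are centred at zero.
    """
    design = make_design(config)
    rng = _rng(config.seed, "h3k4me3")
    roles = truth.table["role"].to_numpy()
    affected = (roles == ROLE_DRIVER) | (roles == ROLE_PASSENGER)
    stage_idx = {s: i for i, s in enumerate(config.stages)}
    rows = []
    for sample, srow in design.iterrows():
        log2r = np.zeros(config.n_genes)
        if srow["arm"] == "disease":
            log2r[affected] = config.h3k4_log2fc[stage_idx[srow["stage"]]]
        log2r = log2r + rng.normal(0.0, config.h3k4_noise_sd, size=log2r.size)
        inputs = rng.uniform(50.0, 150.0, size=log2r.size)
        chip = inputs * np.exp2(log2r)
        for gene, c, inp in zip(truth.gene_ids, chip, inputs):
            rows.append((gene, sample, c, inp))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "chip", "input"])


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(config: GeneratorConfig, truth: TruthTable) -> pd.DataFrame:
    """Long Ct table (gene_id, sample_id, ct_target, ct_reference).

    Target Ct drops by the planted log2 fold change in the disease arm, so
    2^-ddCt against the control-arm calibrator recovers the planted fold
    change in expectation; the reference gene is constant across arms up
    to noise (an endogenous-control design).
    """
    design = make_design(config)
    rng = _rng(config.seed, "qpcr")
    rows = []
    for sample, srow in design.iterrows():
        planted = (
            truth.expr_log2fc(srow["stage"]).to_numpy()
            if srow["arm"] == "disease"
            else np.zeros(config.n_genes)
        )
        ct_t = (
            config.ct_target_base
            - planted
            + rng.normal(0.0, config.ct_noise_sd, size=config.n_genes)
        )
        ct_r = config.ct_reference_mean + rng.normal(
            0.0, config.ct_noise_sd, size=config.n_genes
        )
        for gene, t, r in zip(truth.gene_ids, ct_t, ct_r):
            rows.append((gene, sample, t, r))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "ct_target", "ct_reference"])


def generate_all(config: GeneratorConfig) -> dict:
    """Run every generator off one config; returns a dict of named outputs."""
    truth = make_truth(config)
    promoters = generate_promoters(config, truth)
    expr, design = generate_expression(config, truth)
    meth = generate_methylation(config, truth)
    h3k4 = generate_h3k4me3(config, truth)
    qpcr = generate_qpcr(config, truth)
    return {
        "truth": truth,
        "promoters": promoters,
        "expression": expr,
        "design": design,
        "methylation": meth,
        "h3k4me3": h3k4,
        "qpcr": qpcr,
    }


def verify_promoters(
    promoters: list[PromoterRecord], truth: TruthTable, criteria: CgiCriteria = CgiCriteria()
) -> bool:
    """Check generator/scanner agreement: CGI flags match island calls."""
    for rec in promoters:
        has = len(find_cpg_islands(rec, criteria)) > 0
        if has != bool(truth.cgi_present.loc[rec.gene_id]):
            return False
    return True
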