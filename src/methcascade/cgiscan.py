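"""CpG-island detection in promoter sequences.

A promoter is called "epigenetically regulatable" when it harbours a strong
CpG island (CGI) under the classic composition criteria: a segment longer
than 500 bp with G+C content above 55% and an observed/expected CpG ratio
above 0.65, where

    obs/exp CpG = (N_CpG * L) / (N_C * N_G)

with ``N_CpG`` the count of CG dinucleotides, ``N_C``/``N_G`` the base
counts and ``L`` the (effective) segment length.  The published criteria
describe a segment, not an algorithm; here a window of exactly
``min_length + 1`` bases (so a qualifying window is itself strictly longer
than ``min_length``) slides with step 1, a window qualifies when it passes
all three thresholds strictly, and islands are the unions of overlapping
qualifying windows.  Merged islands are reported even if the union's own
aggregate statistics dip below a threshold; each island carries its
recomputed statistics so consumers can re-filter.

Coordinates are 0-based half-open throughout.  ``N`` bases are excluded
from all counts and from the effective length; windows with more than 10%
``N`` are disqualified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class CgiCriteria:
    """Strong-CGI thresholds; all inequalities are strict ("greater than")."""

    min_length: int = 500
    min_gc: float = 0.55
    min_obs_exp: float = 0.65
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not 0 < self.min_gc <= 1:
            raise ValueError("min_gc must be in (0, 1]")
        if self.min_obs_exp <= 0:
            raise ValueError("min_obs_exp must be positive")


@dataclass
class PromoterRecord:
    """A promoter sequence with optional source coordinates.

    The sequence itself is the CGI search space; genomic coordinates, when
    present, are 0-based half-open and only carried through to output.
    """

    gene_id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"empty promoter sequence for {self.gene_id}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"promoter {self.gene_id}: invalid characters {sorted(bad)}"
            )
        if self.start is not None and self.end is not None:
            if self.end - self.start != len(self.sequence):
                raise ValueError(
                    f"promoter {self.gene_id}: coordinate span "
                    f"{self.end - self.start} != sequence length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class CpGIsland:
    """One island: offsets within the promoter plus its own statistics."""

    start: int
    end: int
    length: int = field(init=False)
    gc_fraction: float = 0.0
    obs_exp_ratio: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", self.end - self.start)


def _check_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return sequence


def gc_content(sequence: str) -> float:
    """Fraction of G+C among non-N bases.

    Raises ``ValueError`` for an empty or all-N sequence.
    """
    sequence = _check_sequence(sequence)
    eff = sum(1 for b in sequence if b != "N")
    if eff == 0:
        raise ValueError("gc_content undefined for empty or all-N sequence")
    gc = sum(1 for b in sequence if b in "GC")
    return gc / eff


def obs_exp_cpg(sequence: str) -> float:
    """Observed/expected CpG ratio, (N_CpG * L) / (N_C * N_G).

    L is the effective (non-N) length.  Returns 0.0 when the sequence lacks
    C or G (degenerate denominator); raises on an empty sequence.
    """
    sequence = _check_sequence(sequence)
    if len(sequence) == 0:
        raise ValueError("obs_exp_cpg undefined for empty sequence")
    eff = sum(1 for b in sequence if b != "N")
    if eff == 0:
        raise ValueError("obs_exp_cpg undefined for all-N sequence")
    n_c = sequence.count("C")
    n_g = sequence.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cpg = sequence.count("CG")
    return (n_cpg * eff) / (n_c * n_g)


def _base_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    cpg = np.zeros(arr.size, dtype=bool)
    if arr.size > 1:
        cpg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, is_n, cpg


def _window_sums(x: np.ndarray, width: int) -> np.ndarray:
    cs = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return cs[width:] - cs[:-width]


def find_cpg_islands(
    promoter: PromoterRecord | str, criteria: CgiCriteria = CgiCriteria()
) -> list[CpGIsland]:
    """Scan one promoter and return its CpG islands, sorted by start.

    Returns an empty list when the sequence is shorter than the window
    (``min_length + 1`` bases).  Islands are maximal unions of overlapping
    qualifying windows and therefore non-overlapping by construction.
    """
    seq = promoter.sequence if isinstance(promoter, PromoterRecord) else _check_sequence(promoter)
    window = criteria.min_length + 1  # strict "> min_length" realised as window length
    n = len(seq)
    if n < window:
        return []

    is_c, is_g, is_n, cpg = _base_arrays(seq)
    c_cnt = _window_sums(is_c, window)
    g_cnt = _window_sums(is_g, window)
    n_cnt = _window_sums(is_n, window)
    # CpG dinucleotides fully inside the window: starts in [i, i+window-1)
    cpg_cnt = _window_sums(cpg[:-1] if n > 1 else cpg, window - 1) if n >= window else np.array([])

    eff_len = window - n_cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(eff_len > 0, (c_cnt + g_cnt) / np.maximum(eff_len, 1), 0.0)
        denom = c_cnt.astype(float) * g_cnt.astype(float)
        oe = np.where(denom > 0, cpg_cnt * eff_len / np.maximum(denom, 1e-300), 0.0)

    qualifies = (
        (gc > criteria.min_gc)
        & (oe > criteria.min_obs_exp)
        & (n_cnt <= criteria.max_n_fraction * window)
        & (eff_len > 0)
    )
    starts = np.flatnonzero(qualifies)
    if starts.size == 0:
        return []

    # Union of intervals [i, i+window); windows at i, j overlap iff |i-j| < window.
    islands: list[CpGIsland] = []
    block_start = int(starts[0])
    prev = int(starts[0])
    for i in starts[1:]:
        i = int(i)
        if i - prev < window:
            prev = i
        else:
            islands.append(_make_island(seq, block_start, prev + window))
            block_start = i
            prev = i
    islands.append(_make_island(seq, block_start, prev + window))
    return islands


def _make_island(seq: str, start: int, end: int) -> CpGIsland:
    sub = seq[start:end]
    return CpGIsland(
        start=start,
        end=end,
        gc_fraction=gc_content(sub),
        obs_exp_ratio=obs_exp_cpg(sub),
    )


def annotate_cgi_genes(
    promoters: Iterable[PromoterRecord], criteria: CgiCriteria = CgiCriteria()
) -> dict[str, bool]:
    """Map gene_id -> True iff the promoter contains at least one island."""
    flags: dict[str, bool] = {}
    for rec in promoters:
        if rec.gene_id in flags:
            raise ValueError(f"duplicate gene_id in promoter set: {rec.gene_id}")
        flags[rec.gene_id] = len(find_cpg_islands(rec, criteria)) > 0
    return flags


def islands_to_bed(
    islands_by_gene: Mapping[str, Sequence[CpGIsland]]
) -> list[tuple[str, int, int, str, int, str]]:
    """BED6 rows (chrom=gene_id namespace, score = 1000*obs/exp capped)."""
    rows = []
    for gene, islands in islands_by_gene.items():
        for isl in islands:
            score = min(1000, int(round(1000 * isl.obs_exp_ratio)))
            rows.append((gene, isl.start, isl.end, gene, score, "+"))
    return rows
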