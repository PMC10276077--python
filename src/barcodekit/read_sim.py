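"""Ground-truthed simulation of barcode amplicon sequencing data.

The simulator produces the benchmark data used to evaluate extraction and
error correction:

* ``simulate_true_library`` draws a library of unique random barcodes with
  abundances from a three-tier exponential mixture (a bulk of typical lineages
  plus rare high-frequency outliers), mirroring the frequency distributions
  observed in real post-transformation libraries.
* ``simulate_reads`` turns the library into an observed-sequence count table:
  per-barcode read counts are Poisson with mean f_i * total depth; reads of
  barcodes carrying a mononucleotide run of >= 5 bp first acquire run-length
  indel errors (recursively, so multi-step indels arise), then every read
  independently acquires substitutions at a per-base rate (default 0.4%).
  Every observed sequence carries a truth map back to its parent barcode.
* ``simulate_umi_experiment`` explores the template-limited vs read-limited
  sequencing regimes and the power of UMI deduplication to correct PCR bias.
* ``transformation_sampling`` models the transformation bottleneck as a
  multinomial draw of K cells over library frequencies.
* ``render_fastq`` turns simulated counts into FASTQ reads with flanks,
  indices, UMIs and offsets, for end-to-end extraction tests.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom

from .design_eval import DesignSpec, parse_design, _sample_matrix, _matrix_to_strings
from .utils import derive_seed

_BASES = "ACGT"

#: abundance mixture of the benchmark library (counts, exponential means)
DEFAULT_TIERS = ((99895, 1.0), (100, 10.0), (5, 1000.0))


@dataclass
class TrueLibrary:
    """Ground-truth barcode abundances. ``frequencies`` sum to one."""

    barcodes: list[str]
    abundances: np.ndarray
    seed: int

    def __post_init__(self):
        if len(self.barcodes) != len(set(self.barcodes)):
            raise ValueError("barcodes must be unique")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")

    @property
    def frequencies(self) -> np.ndarray:
        return self.abundances / self.abundances.sum()

    def __len__(self) -> int:
        return len(self.barcodes)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "abundance": self.abundances,
                "frequency": self.frequencies,
            }
        )


def scaled_tier_counts(n_total: int) -> tuple[int, int, int]:
    """Scale the benchmark mixture (99.895% / 0.1% / 0.005%) to ``n_total``
    barcodes by largest-remainder rounding; a leftover unit goes to the
    highest-mean tier so the outlier tier stays represented."""
    props = (0.99895, 0.001, 0.00005)
    floors = [int(p * n_total) for p in props]
    short = n_total - sum(floors)
    for i in (2, 1, 0):
        if short <= 0:
            break
        floors[i] += 1
        short -= 1
    floors[0] += short  # only if n_total tiny
    return tuple(floors)  # type: ignore[return-value]


def simulate_true_library(
    n_low: int = 99895,
    n_mid: int = 100,
    n_high: int = 5,
    means: tuple[float, float, float] = (1.0, 10.0, 1000.0),
    design: DesignSpec | None = None,
    seed: int = 0,
) -> TrueLibrary:
    """Draw a barcode library with a three-tier exponential abundance mixture.

    Defaults give the 100,000-barcode benchmark: 99,895 abundances ~ Exp(1),
    100 ~ Exp(10) and 5 ~ Exp(1000).  Barcodes are sampled from ``design``
    (default fully degenerate 20-mers), resampling on collision.
    """
    if min(n_low, n_mid, n_high) < 0:
        raise ValueError("tier counts must be >= 0")
    n_total = n_low + n_mid + n_high
    if n_total < 1:
        raise ValueError("library must contain at least one barcode")
    if design is None:
        design = parse_design("N" * 20)
    if design.information_bits < math.log2(n_total):
        raise ValueError(
            f"design space 2**{design.information_bits:.1f} cannot hold "
            f"{n_total} unique barcodes"
        )
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_total:
        need = n_total - len(barcodes)
        batch = _matrix_to_strings(_sample_matrix(design, max(need, 16), rng))
        for s in batch:
            if s not in seen:
                seen.add(s)
                barcodes.append(s)
                if len(barcodes) == n_total:
                    break
    abund = np.concatenate(
        [
            rng.exponential(mean, size=n)
            for n, mean in zip((n_low, n_mid, n_high), means)
        ]
    )
    # guard against a zero draw at float resolution
    abund = np.maximum(abund, np.finfo(float).tiny)
    return TrueLibrary(barcodes=barcodes, abundances=abund, seed=seed)


# ---------------------------------------------------------------------------
# error model
# ---------------------------------------------------------------------------

#: share of the total indel rate per event type (change in repeat count)
DEFAULT_EVENT_SHARES = {+1: 0.45, -1: 0.45, +2: 0.05, -2: 0.05}


def _default_total_rate(n: int, a: float, b: float, cap: float) -> float:
    return min(a * math.exp(b * n), cap)


@dataclass
class ErrorModel:
    """Substitution + run-dependent indel error model for barcode reads.

    ``substitution_rate`` applies per base to every read.  Barcodes with a
    mononucleotide run of at least ``min_run`` bases additionally generate
    run-length indel reads; the total per-read indel probability for a run of
    n bases is a*exp(b*n) capped at ``max_rate`` (defaults calibrated so that
    rate(10) ~ 0.05 and rate(13) ~ 0.3), split across the four event types
    (+-1 and +-2 repeats) by ``event_shares``.  ``rate_table`` overrides the
    exponential form with explicit per-run-length total rates.
    """

    substitution_rate: float = 0.004
    min_run: int = 5
    indel_a: float = 1.2731e-4
    indel_b: float = 0.5973
    max_rate: float = 0.5
    event_shares: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_SHARES)
    )
    rate_table: dict[int, float] | None = None

    def __post_init__(self):
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        if abs(sum(self.event_shares.values()) - 1.0) > 1e-9:
            raise ValueError("event_shares must sum to 1")

    def total_indel_rate(self, run_length: int) -> float:
        """Per-read probability of any indel event for a run of given length."""
        if run_length < self.min_run:
            return 0.0
        if self.rate_table is not None:
            return float(self.rate_table.get(run_length, 0.0))
        return _default_total_rate(run_length, self.indel_a, self.indel_b, self.max_rate)

    def event_rates(self, run_length: int) -> dict[int, float]:
        total = self.total_indel_rate(run_length)
        return {k: total * s for k, s in self.event_shares.items()}


def _mono_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """(start, length) of maximal mononucleotide runs of length >= min_run."""
    runs = []
    i = 0
    L = len(seq)
    while i < L:
        j = i
        while j < L and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j - i))
        i = j
    return runs


def _apply_run_change(seq: str, start: int, length: int, delta: int) -> str | None:
    """Change a mononucleotide run's length by ``delta`` repeats."""
    new_len = length + delta
    if new_len < 0:
        return None
    base = seq[start]
    return seq[:start] + base * new_len + seq[start + length :]


@dataclass
class SimulatedReads:
    """Observed-sequence read counts with full provenance.

    ``table`` has one row per (observed sequence, parent barcode, error class)
    with its read count; ``truth_map`` maps each observed sequence to its
    majority parent and that parent's error class.
    """

    table: pd.DataFrame  # columns: observed, parent, error_class, reads
    seed: int

    @property
    def counts(self) -> pd.Series:
        """Read count per unique observed sequence."""
        return self.table.groupby("observed", sort=False)["reads"].sum()

    @property
    def total_reads(self) -> int:
        return int(self.table["reads"].sum())

    @property
    def truth_map(self) -> pd.DataFrame:
        """Majority parent and error class per observed sequence."""
        t = self.table.sort_values("reads", ascending=False, kind="stable")
        return t.drop_duplicates("observed").set_index("observed")[
            ["parent", "error_class"]
        ]

    def reads_per_parent(self) -> pd.Series:
        """Total reads generated by each true barcode (pre-correction truth)."""
        return self.table.groupby("parent", sort=False)["reads"].sum()


_SUB_LUT = {b: [c for c in _BASES if c != b] for b in _BASES}

_PMF_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _truncated_sub_pmf(L: int, rate: float) -> np.ndarray:
    """Pmf of the substitution count per read, conditioned on at least one."""
    key = (L, rate)
    if key not in _PMF_CACHE:
        pmf = _binom.pmf(np.arange(1, L + 1), L, rate)
        _PMF_CACHE[key] = pmf / pmf.sum()
    return _PMF_CACHE[key]


def _substitute_reads(
    seq: str, count: int, rate: float, rng: np.random.Generator
) -> tuple[int, dict[str, int]]:
    """Apply per-base substitutions to ``count`` reads of ``seq``.

    Returns (reads left error-free, {mutated sequence: reads}).
    """
    L = len(seq)
    p_read = 1.0 - (1.0 - rate) ** L
    k = int(rng.binomial(count, p_read)) if count > 0 and p_read > 0 else 0
    if k == 0:
        return count, {}
    # number of substitutions per mutated read: Binomial(L, rate) given >= 1
    pmf = _truncated_sub_pmf(L, rate)
    n_subs = rng.choice(np.arange(1, L + 1), size=k, p=pmf)
    out: dict[str, int] = defaultdict(int)
    # single-substitution reads dominate; vectorize them
    k1 = int(np.sum(n_subs == 1))
    if k1:
        pos = rng.integers(L, size=k1)
        alt = rng.integers(3, size=k1)
        codes, code_counts = np.unique(pos * 3 + alt, return_counts=True)
        for code, c in zip(codes, code_counts):
            p, a = divmod(int(code), 3)
            mut = seq[:p] + _SUB_LUT[seq[p]][a] + seq[p + 1 :]
            out[mut] += int(c)
    for m in n_subs[n_subs > 1]:
        pos = rng.choice(L, size=int(m), replace=False)
        chars = list(seq)
        for p in pos:
            chars[p] = _SUB_LUT[chars[p]][rng.integers(3)]
        out["".join(chars)] += 1
    return count - k, dict(out)


def simulate_reads(
    lib: TrueLibrary,
    expected_total_reads: float = 25e6,
    model: ErrorModel | None = None,
    seed: int = 0,
) -> SimulatedReads:
    """Simulate an amplicon count table from a true library.

    Per-barcode read counts are Poisson(f_i * expected_total_reads).  Indel
    reads are drawn first for every qualifying mononucleotide run (Poisson per
    event type, applied recursively so multi-step indels occur), then every
    read independently receives substitutions; reads carrying both kinds of
    error are classed "both".
    """
    if expected_total_reads <= 0:
        raise ValueError("expected_total_reads must be positive")
    model = model or ErrorModel()
    rng = np.random.default_rng(seed)
    read_counts = rng.poisson(lib.frequencies * expected_total_reads)

    # rows of (observed, parent, error_class, reads) before substitutions
    pre_sub: list[tuple[str, str, str, int]] = []
    for bc, n_reads in zip(lib.barcodes, read_counts):
        if n_reads == 0:
            continue
        # queue of sequences whose reads may spawn indel variants
        queue = [(bc, int(n_reads), "none")]
        while queue:
            seq, cnt, klass = queue.pop()
            remaining = cnt
            runs = _mono_runs(seq, model.min_run)
            for start, length in runs:
                for delta, rate in model.event_rates(length).items():
                    if rate <= 0.0 or remaining <= 0:
                        continue
                    n_ev = int(rng.poisson(rate * cnt))
                    n_ev = min(n_ev, remaining)
                    if n_ev == 0:
                        continue
                    variant = _apply_run_change(seq, start, length, delta)
                    if variant is None or not variant:
                        continue
                    remaining -= n_ev
                    queue.append((variant, n_ev, "indel"))
            if remaining > 0:
                pre_sub.append((seq, bc, klass, remaining))

    rows: list[tuple[str, str, str, int]] = []
    for seq, parent, klass, cnt in pre_sub:
        clean, mutated = _substitute_reads(seq, cnt, model.substitution_rate, rng)
        if clean > 0:
            rows.append((seq, parent, klass, clean))
        sub_class = "both" if klass == "indel" else "substitution"
        for mut, c in mutated.items():
            rows.append((mut, parent, sub_class, c))

    table = pd.DataFrame(rows, columns=["observed", "parent", "error_class", "reads"])
    if not table.empty:
        table = (
            table.groupby(["observed", "parent", "error_class"], sort=False, as_index=False)[
                "reads"
            ].sum()
        )
    total = int(table["reads"].sum()) if not table.empty else 0
    assert total == int(read_counts.sum()), "read conservation violated"
    return SimulatedReads(table=table, seed=seed)


# ---------------------------------------------------------------------------
# UMI regime simulation
# ---------------------------------------------------------------------------


@dataclass
class UMISimResult:
    n_templates: int
    n_reads: int
    bias: float
    focal_frequency: float
    duplicate_fraction: float
    naive_estimate: float
    dedup_estimate: float
    bias_corrected_fraction: float | None


def simulate_umi_experiment(
    n_templates: int,
    focal_frequency: float,
    bias: float = 1.0,
    n_reads: int = 1_000_000,
    mode: str = "with_replacement",
    seed: int = 0,
) -> UMISimResult:
    """Simulate UMI-tagged sequencing of a template pool with one biased barcode.

    Every template carries a unique UMI; the focal barcode's amplification is
    multiplied by ``bias``.  ``mode="with_replacement"`` samples ``n_reads``
    reads from the biased pool; ``mode="two_per_template"`` sequences every
    template exactly twice (the regime in which UMI duplicates make up 50% of
    reads).  Reports the UMI duplicate fraction, the naive (read-count) and
    deduplicated (unique-template) estimates of the focal frequency, and the
    fraction of the bias removed by deduplication.
    """
    if not (0.0 < focal_frequency < 1.0):
        raise ValueError("focal_frequency must be in (0, 1)")
    if bias <= 0:
        raise ValueError("bias must be positive")
    if n_templates < 1 or n_reads < 1:
        raise ValueError("n_templates and n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    n_focal = int(round(focal_frequency * n_templates))
    n_focal = min(max(n_focal, 1), n_templates - 1)
    n_other = n_templates - n_focal

    if mode == "two_per_template":
        focal_reads = 2 * n_focal
        total_reads = 2 * n_templates
        uniq_focal, uniq_total = n_focal, n_templates
    elif mode == "with_replacement":
        p_focal = bias * n_focal / (bias * n_focal + n_other)
        focal_reads = int(rng.binomial(n_reads, p_focal))
        total_reads = n_reads
        # sample template identities uniformly within each tier
        focal_ids = rng.integers(n_focal, size=focal_reads)
        other_ids = rng.integers(n_other, size=n_reads - focal_reads)
        uniq_focal = len(np.unique(focal_ids))
        uniq_total = uniq_focal + len(np.unique(other_ids))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    dup_frac = 1.0 - uniq_total / total_reads
    naive = focal_reads / total_reads
    dedup = uniq_focal / uniq_total
    truth = n_focal / n_templates
    corrected = None
    if not math.isclose(naive, truth):
        corrected = float(np.clip((naive - dedup) / (naive - truth), 0.0, 1.0))
    return UMISimResult(
        n_templates=n_templates,
        n_reads=total_reads,
        bias=bias,
        focal_frequency=truth,
        duplicate_fraction=dup_frac,
        naive_estimate=naive,
        dedup_estimate=dedup,
        bias_corrected_fraction=corrected,
    )


# ---------------------------------------------------------------------------
# transformation bottleneck
# ---------------------------------------------------------------------------


@dataclass
class TransformationResult:
    cell_counts: np.ndarray  # per-barcode cells received
    n_transformed_barcodes: int  # barcodes in >= 1 cell
    fraction_multi_cell: float  # of transformed barcodes, fraction in > 1 cell


def transformation_sampling(lib: TrueLibrary, K: int, seed: int = 0) -> TransformationResult:
    """Multinomial draw of K transformed cells over library frequencies.

    The expected number of cells receiving barcode i is K * f_i; diversity is
    preserved when almost all transformed barcodes land in a single cell
    (K * fmax << 1).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(K, lib.frequencies)
    present = counts > 0
    n_present = int(present.sum())
    multi = int((counts > 1).sum())
    frac = multi / n_present if n_present else 0.0
    return TransformationResult(
        cell_counts=counts, n_transformed_barcodes=n_present, fraction_multi_cell=frac
    )


# ---------------------------------------------------------------------------
# FASTQ rendering
# ---------------------------------------------------------------------------


def render_fastq(
    sim: SimulatedReads,
    layout,
    constant_quality: int = 37,
    seed: int = 0,
) -> Iterator[tuple[str, str, str]]:
    """Render simulated counts as FASTQ records (id, sequence, quality string).

    Each read is offset + inline5 + UMI + upstream flank + observed barcode +
    downstream flank + inline3, with the optional fields populated per the
    :class:`~barcodekit.extraction.AmpliconLayout`.  Read multiplicities are
    preserved; qualities are constant.
    """
    rng = np.random.default_rng(seed)
    qchar = chr(constant_quality + 33)
    read_no = 0
    for row in sim.table.itertuples(index=False):
        for _ in range(int(row.reads)):
            read_no += 1
            parts = []
            if layout.offset_lengths:
                off = int(rng.choice(layout.offset_lengths))
                parts.append("".join(_BASES[i] for i in rng.integers(4, size=off)))
            if layout.inline5:
                parts.append(str(rng.choice(layout.inline5)))
            if layout.umi_length:
                parts.append(
                    "".join(_BASES[i] for i in rng.integers(4, size=layout.umi_length))
                )
            parts.append(layout.upstream)
            parts.append(row.observed)
            parts.append(layout.downstream)
            if layout.inline3:
                parts.append(str(rng.choice(layout.inline3)))
            seq = "".join(parts)
            yield f"sim_read_{read_no}", seq, qchar * len(seq)
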