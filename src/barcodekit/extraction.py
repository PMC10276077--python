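"""Barcode extraction from amplicon reads, demultiplexing, and UMI handling.

Two extraction strategies are provided and can be cross-validated against each
other:

* ``extract_regex`` applies an escalating ladder of five regular expressions
  (``build_regex_ladder``): exact flanks and exact barcode length first, then
  progressively allowing +-1 / +-2 bp of length variation and one edit in each
  flanking anchor, stopping at the first match.
* ``extract_by_alignment`` locates each constant flank by local alignment and
  takes the read substring strictly between them, tolerating barcodes of
  grossly abnormal length that the capped regex ladder rejects.

Demultiplexing supports redundant index schemes (paired inline and Illumina
indices) in which template switching and index hopping produce *inadmissible*
index combinations, flagged as chimeras.  UMI utilities compute per-barcode
duplicate fractions and perform deduplication only when the UMI space is large
enough for unique barcode-UMI combinations to imply unique templates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

_ACGT = set("ACGT")


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read (FASTQ record)."""

    identifier: str
    sequence: str
    qualities: tuple[int, ...] = ()

    def __post_init__(self):
        if self.qualities and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.identifier}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class AmpliconLayout:
    """Structure of the barcode amplicon read.

    ``upstream``/``downstream`` are the constant regions directly flanking the
    barcode.  Optional inline indices, UMI and variable-length read offsets
    describe the two-step PCR features upstream of the barcode region.
    """

    upstream: str
    downstream: str
    barcode_length: int
    inline5: tuple[str, ...] = ()
    inline3: tuple[str, ...] = ()
    umi_length: int = 0
    offset_lengths: tuple[int, ...] = ()

    def __post_init__(self):
        for name, flank in (("upstream", self.upstream), ("downstream", self.downstream)):
            if not flank or set(flank) - _ACGT:
                raise ValueError(f"{name} flank must be a non-empty A/C/G/T string")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of one extraction attempt."""

    status: str  # "extracted" | "no_match" | "low_quality"
    barcode: str | None = None
    level: int | None = None  # regex ladder level (1-based) or None
    details: str = ""

    def __post_init__(self):
        if (self.status == "extracted") != (self.barcode is not None):
            raise ValueError("barcode must be present iff status == extracted")

    @property
    def barcode_length(self) -> int | None:
        return None if self.barcode is None else len(self.barcode)


# ---------------------------------------------------------------------------
# regex ladder
# ---------------------------------------------------------------------------


def _one_edit_variants(anchor: str) -> list[str]:
    """All strings within edit distance 1 of ``anchor`` over A/C/G/T.

    Ordered exact first, then substitutions, deletions, insertions, so the
    compiled alternation prefers the least-mutated interpretation.
    """
    variants = [anchor]
    seen = {anchor}
    for i in range(len(anchor)):
        for b in "ACGT":
            v = anchor[:i] + b + anchor[i + 1 :]
            if v not in seen:
                seen.add(v)
                variants.append(v)
    for i in range(len(anchor)):
        v = anchor[:i] + anchor[i + 1 :]
        if v not in seen:
            seen.add(v)
            variants.append(v)
    for i in range(len(anchor) + 1):
        for b in "ACGT":
            v = anchor[:i] + b + anchor[i:]
            if v not in seen:
                seen.add(v)
                variants.append(v)
    return variants


@dataclass(frozen=True)
class LadderPattern:
    level: int
    pattern: re.Pattern
    description: str


def build_regex_ladder(
    layout: AmpliconLayout,
    anchor_width: int = 6,
    include_length_free: bool = False,
    length_free_anchor_width: int = 10,
) -> list[LadderPattern]:
    """Build the five-pattern ladder of increasingly lenient extractions.

    Level 1: exact flanks, exact length; 2: length +-1; 3: length +-2;
    4: one edit allowed in each flank, exact length; 5: one edit in each
    flank, length +-2.  With ``include_length_free`` a sixth pattern with
    wider anchors and an unconstrained middle is appended, for surveying
    barcode-length distributions.
    """
    if len(layout.upstream) < anchor_width or len(layout.downstream) < anchor_width:
        raise ValueError(
            f"flanks must be at least anchor_width={anchor_width} bp for the ladder"
        )
    up = layout.upstream[-anchor_width:]
    down = layout.downstream[:anchor_width]
    n = layout.barcode_length
    fuzzy_up = "(?:" + "|".join(_one_edit_variants(up)) + ")"
    fuzzy_down = "(?:" + "|".join(_one_edit_variants(down)) + ")"

    def mid(lo: int, hi: int) -> str:
        return f"([ACGTN]{{{lo}}})" if lo == hi else f"([ACGTN]{{{lo},{hi}}})"

    specs = [
        (1, f"({up}){mid(n, n)}({down})", "exact flanks, exact length"),
        (2, f"({up}){mid(n - 1, n + 1)}({down})", "exact flanks, length +-1"),
        (3, f"({up}){mid(n - 2, n + 2)}({down})", "exact flanks, length +-2"),
        (4, f"({fuzzy_up}){mid(n, n)}({fuzzy_down})", "1-edit flanks, exact length"),
        (5, f"({fuzzy_up}){mid(n - 2, n + 2)}({fuzzy_down})", "1-edit flanks, length +-2"),
    ]
    ladder = [
        LadderPattern(level, re.compile(pat), desc) for level, pat, desc in specs
    ]
    if include_length_free:
        w = length_free_anchor_width
        if len(layout.upstream) < w or len(layout.downstream) < w:
            raise ValueError(f"flanks must be >= {w} bp for the length-free pattern")
        pat = f"({layout.upstream[-w:]})([ACGTN]*?)({layout.downstream[:w]})"
        ladder.append(LadderPattern(6, re.compile(pat), "length-free survey"))
    return ladder


@dataclass(frozen=True)
class QualityPolicy:
    """Read-level quality filter applied around pattern matching.

    A read fails if its mean Phred score is below ``min_mean`` (checked before
    any pattern search) or if any base within the matched flank anchors is
    below ``min_flank_base`` (checked after a match is located).
    """

    min_mean: float = 20.0
    min_flank_base: int = 10

    def mean_ok(self, read: ReadRecord) -> bool:
        if not read.qualities:
            return True
        return float(np.mean(read.qualities)) >= self.min_mean

    def flanks_ok(self, read: ReadRecord, spans: Sequence[tuple[int, int]]) -> bool:
        if not read.qualities:
            return True
        for lo, hi in spans:
            if any(q < self.min_flank_base for q in read.qualities[lo:hi]):
                return False
        return True


def extract_regex(
    read: ReadRecord,
    ladder: Sequence[LadderPattern],
    quality_policy: QualityPolicy | None = QualityPolicy(),
) -> ExtractionResult:
    """Extract a barcode with the regex ladder; the first matching level wins."""
    if quality_policy is not None and not quality_policy.mean_ok(read):
        return ExtractionResult(status="low_quality", details="mean quality below cutoff")
    for rung in ladder:
        m = rung.pattern.search(read.sequence)
        if m is None:
            continue
        if quality_policy is not None and not quality_policy.flanks_ok(
            read, [m.span(1), m.span(3)]
        ):
            return ExtractionResult(
                status="low_quality", details=f"flank base quality below cutoff (level {rung.level})"
            )
        return ExtractionResult(status="extracted", barcode=m.group(2), level=rung.level)
    return ExtractionResult(status="no_match", details="no ladder pattern matched")


# ---------------------------------------------------------------------------
# alignment-based extraction
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _best_flank_alignment(
    aligner: Align.PairwiseAligner,
    read_seq: str,
    flank: str,
    prefer: str,
) -> tuple[int, int, float, int] | None:
    """Locate ``flank`` in ``read_seq``; returns (start, end, identity, cols).

    Among equal-scoring placements, takes the leftmost (``prefer="left"``, for
    the upstream flank) or rightmost (``prefer="right"``, downstream) so the
    captured barcode region is deterministic and maximal.
    """
    alignments = aligner.align(read_seq, flank)
    try:
        n = min(len(alignments), 32)
    except (OverflowError, MemoryError):  # pragma: no cover - pathological reads
        n = 1
    if n == 0:
        return None
    best = None
    best_score = alignments[0].score
    for i in range(n):
        aln = alignments[i]
        if aln.score < best_score:
            break
        tgt_blocks, qry_blocks = aln.aligned
        if len(tgt_blocks) == 0:
            continue
        start, end = int(tgt_blocks[0][0]), int(tgt_blocks[-1][1])
        matches = 0
        cols = 0
        for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
            cols += te - ts
            matches += sum(
                1 for a, b in zip(read_seq[ts:te], flank[qs:qe]) if a == b
            )
        identity = matches / cols if cols else 0.0
        key = start if prefer == "left" else -end
        if best is None or key < best[0]:
            best = (key, start, end, identity, cols)
    if best is None:
        return None
    _, start, end, identity, cols = best
    return start, end, identity, cols


def extract_by_alignment(
    read: ReadRecord,
    layout: AmpliconLayout,
    min_flank_identity: float = 0.8,
    min_flank_length: int = 6,
    quality_policy: QualityPolicy | None = QualityPolicy(),
) -> ExtractionResult:
    """Extract the barcode as the read substring strictly between the
    best-scoring local alignments of the two flanks.

    Tolerates barcodes of any length (including grossly abnormal ones) but
    fails if either flank aligns with identity below ``min_flank_identity``,
    over fewer than ``min_flank_length`` columns, or out of order.
    """
    if quality_policy is not None and not quality_policy.mean_ok(read):
        return ExtractionResult(status="low_quality", details="mean quality below cutoff")
    aligner = _make_aligner()
    up = _best_flank_alignment(aligner, read.sequence, layout.upstream, "left")
    down = _best_flank_alignment(aligner, read.sequence, layout.downstream, "right")
    if up is None or down is None:
        return ExtractionResult(status="no_match", details="flank not found")
    u_start, u_end, u_id, u_cols = up
    d_start, d_end, d_id, d_cols = down
    if u_id < min_flank_identity or d_id < min_flank_identity:
        return ExtractionResult(status="no_match", details="flank identity below threshold")
    if u_cols < min_flank_length or d_cols < min_flank_length:
        return ExtractionResult(status="no_match", details="flank alignment too short")
    if d_start <= u_end:
        return ExtractionResult(status="no_match", details="flanks out of order")
    if quality_policy is not None and not quality_policy.flanks_ok(
        read, [(u_start, u_end), (d_start, d_end)]
    ):
        return ExtractionResult(status="low_quality", details="flank base quality below cutoff")
    return ExtractionResult(
        status="extracted", barcode=read.sequence[u_end:d_start], level=None
    )


# ---------------------------------------------------------------------------
# length distribution
# ---------------------------------------------------------------------------


def length_distribution(
    counts: "pd.Series | dict[str, int]",
    expected_length: int,
    min_reads: int = 20,
    window: int = 10,
) -> pd.Series:
    """Percentage of barcodes at each length offset around the expected length.

    Computed over unique barcodes (not reads) with at least ``min_reads``
    reads, across offsets -window..+window; barcodes outside the window are
    ignored.  Returns an empty series (with a warning) if nothing qualifies.
    """
    if expected_length < 1:
        raise ValueError("expected_length must be >= 1")
    series = pd.Series(counts, dtype="int64") if not isinstance(counts, pd.Series) else counts
    offsets = np.arange(-window, window + 1)
    qualifying = series[series >= min_reads]
    if qualifying.empty:
        warnings.warn("no barcodes pass the read-count filter", stacklevel=2)
        return pd.Series(0.0, index=offsets, name="percent")
    lengths = qualifying.index.str.len() - expected_length
    in_window = (lengths >= -window) & (lengths <= window)
    lengths = lengths[in_window]
    if len(lengths) == 0:
        warnings.warn("no qualifying barcodes within the length window", stacklevel=2)
        return pd.Series(0.0, index=offsets, name="percent")
    tallies = pd.Series(0, index=offsets, dtype="int64")
    vc = pd.Series(lengths).value_counts()
    tallies.loc[vc.index] = vc.values
    return (100.0 * tallies / tallies.sum()).rename("percent")


# ---------------------------------------------------------------------------
# demultiplexing with redundant index schemes
# ---------------------------------------------------------------------------

_SLOTS = ("i5", "i7", "inline5", "inline3")


@dataclass
class IndexScheme:
    """Per-sample index 4-tuples (i5, i7, 5' inline, 3' inline).

    In a redundant scheme each 5' inline index pairs with a unique 3' Illumina
    (i7) index and each 3' inline index with a unique i5, so chimeric reads
    produce index combinations assigned to no sample.
    """

    samples: dict[str, tuple[str, str, str, str]]

    def __post_init__(self):
        tuples = list(self.samples.values())
        if len(set(tuples)) != len(tuples):
            raise ValueError("admissible index tuples must be unique per sample")
        self._admissible = {t: name for name, t in self.samples.items()}

    @property
    def admissible(self) -> dict[tuple[str, str, str, str], str]:
        return self._admissible

    def declared(self, slot: int) -> list[str]:
        return sorted({t[slot] for t in self.samples.values()})

    def is_redundant(self) -> bool:
        """True if inline5<->i7 and inline3<->i5 pairings are one-to-one."""
        for a, b in ((2, 1), (3, 0)):
            fwd: dict[str, str] = {}
            rev: dict[str, str] = {}
            for t in self.samples.values():
                if fwd.setdefault(t[a], t[b]) != t[b]:
                    return False
                if rev.setdefault(t[b], t[a]) != t[a]:
                    return False
        return True


def _hamming(a: str, b: str) -> int | None:
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def _resolve_index(observed: str, declared: list[str], max_mismatch: int) -> str | None:
    """Nearest declared index within ``max_mismatch``; ties are unresolved."""
    best, best_d, tied = None, None, False
    for cand in declared:
        d = _hamming(observed, cand)
        if d is None or d > max_mismatch:
            continue
        if best_d is None or d < best_d:
            best, best_d, tied = cand, d, False
        elif d == best_d:
            tied = True
    if best is None or tied:
        return None
    return best


def demultiplex(
    observed: tuple[str, str, str, str],
    scheme: IndexScheme,
    max_mismatch: int = 1,
) -> str:
    """Assign an observed (i5, i7, inline5, inline3) tuple to a sample.

    Returns the sample name, ``"chimera"`` when every index resolves to a
    declared index but the combination is inadmissible (the signature of
    template switching / index hopping in a redundant scheme), or
    ``"unknown"`` otherwise.
    """
    resolved = tuple(
        _resolve_index(obs, scheme.declared(i), max_mismatch)
        for i, obs in enumerate(observed)
    )
    if all(r is not None for r in resolved):
        sample = scheme.admissible.get(resolved)  # type: ignore[arg-type]
        return sample if sample is not None else "chimera"
    return "unknown"


def demultiplex_batch(
    tuples: Iterable[tuple[str, str, str, str]],
    scheme: IndexScheme,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Demultiplex many index tuples; returns per-read assignments with a
    ``chimera_fraction`` attribute in ``DataFrame.attrs``."""
    assignments = [demultiplex(t, scheme, max_mismatch) for t in tuples]
    df = pd.DataFrame({"assignment": assignments})
    n = len(df)
    df.attrs["chimera_fraction"] = (
        float((df["assignment"] == "chimera").mean()) if n else 0.0
    )
    return df


# ---------------------------------------------------------------------------
# UMI statistics and deduplication
# ---------------------------------------------------------------------------


def umi_duplicate_stats(extracted: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Per-barcode read counts, unique barcode-UMI combinations and duplicate
    fraction (1 - unique/reads) from (barcode, UMI) pairs."""
    df = pd.DataFrame(extracted, columns=["barcode", "umi"])
    if df.empty:
        return pd.DataFrame(columns=["reads", "unique_combinations", "duplicate_fraction"])
    g = df.groupby("barcode")["umi"]
    out = pd.DataFrame({"reads": g.size(), "unique_combinations": g.nunique()})
    out["duplicate_fraction"] = 1.0 - out["unique_combinations"] / out["reads"]
    return out


@dataclass(frozen=True)
class UMIDedupResult:
    """Outcome of a deduplication request; refusal is explicit, not silent."""

    performed: bool
    counts: pd.Series | None
    reason: str = ""


def umi_dedup(
    umi_counts: dict[str, dict[str, int]],
    umi_length: int,
    safety_ratio: float = 100.0,
) -> UMIDedupResult:
    """Replace read counts by unique barcode-UMI combination counts.

    Refused when 4**umi_length < safety_ratio * (highest barcode read count):
    with too few possible UMIs, the same UMI tags many distinct templates of
    an abundant barcode and deduplication would erase real abundance.
    """
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    if not umi_counts:
        return UMIDedupResult(performed=True, counts=pd.Series(dtype="int64"))
    max_reads = max(sum(c.values()) for c in umi_counts.values())
    umi_space = 4**umi_length
    if umi_space < safety_ratio * max_reads:
        return UMIDedupResult(
            performed=False,
            counts=None,
            reason=(
                f"UMI space 4^{umi_length}={umi_space} is below {safety_ratio}x "
                f"the highest barcode read count ({max_reads}); deduplication "
                f"would conflate distinct templates"
            ),
        )
    dedup = pd.Series({bc: len(c) for bc, c in umi_counts.items()}, dtype="int64")
    return UMIDedupResult(performed=True, counts=dedup)


# ---------------------------------------------------------------------------
# method concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceTable:
    both_equal: int
    both_differ: int
    only_first: int
    only_second: int
    neither: int

    @property
    def agreement_fraction(self) -> float | None:
        both = self.both_equal + self.both_differ
        return self.both_equal / both if both else None


def compare_methods(
    results_a: Sequence[ExtractionResult],
    results_b: Sequence[ExtractionResult],
) -> ConcordanceTable:
    """Four-cell concordance summary between two extraction result sets over
    the same reads, plus the agreement fraction among jointly extracted reads."""
    if len(results_a) != len(results_b):
        raise ValueError(
            f"result sets cover different reads ({len(results_a)} vs {len(results_b)})"
        )
    be = bd = oa = ob = ne = 0
    for ra, rb in zip(results_a, results_b):
        a_ok = ra.status == "extracted"
        b_ok = rb.status == "extracted"
        if a_ok and b_ok:
            if ra.barcode == rb.barcode:
                be += 1
            else:
                bd += 1
        elif a_ok:
            oa += 1
        elif b_ok:
            ob += 1
        else:
            ne += 1
    return ConcordanceTable(be, bd, oa, ob, ne)
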