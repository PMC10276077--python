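"""Deletion-Correct error correction of barcode count tables.

Sequencing and library-preparation errors scatter the reads of each true
barcode over a cloud of similar sequences.  ``deletion_correct`` collapses an
observed-sequence count table back onto inferred true barcodes ("centroids")
by deterministic greedy clustering:

1. unique sequences are visited in order of descending read count (ties
   lexicographic);
2. candidate parents for a sequence are found through a *deletion
   neighborhood* index: every centroid is indexed under all subsequences
   obtainable by deleting up to ``max_edits`` characters, which guarantees
   retrieval of every centroid within Levenshtein distance ``max_edits`` of a
   query (the query is likewise expanded); candidate distances are then
   verified exactly;
3. a sequence with count c may be attributed to a centroid p only if p has
   strictly more reads and c is consistent with being an error pile of p:
   c must not exceed the upper ``tail_quantile`` of a Poisson with mean
   ``poisson_error_rate * count(p)`` (the expected number of corrupted reads
   of p);
4. unattributed sequences found at least ``min_counts_for_centroid`` times
   become new centroids; the remainder go to an explicit unassigned pool so
   read counts are conserved and checkable.

Levenshtein (not Hamming) distance is used throughout so that indel errors
are correctable.  ``evaluate_correction`` scores a clustering against the
simulator's ground truth (false negatives, false positives, wrong-sequence
errors, and the Pearson correlation of log abundances), and
``estimate_run_indel_rates`` recovers per-run-length indel error rates from a
count table the way they are measured from empirical data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr, poisson

from .design_eval import max_run
from .read_sim import SimulatedReads


def _as_count_items(counts) -> list[tuple[str, int]]:
    """Normalize a count table (Series / dict) to [(sequence, count)]."""
    if isinstance(counts, pd.Series):
        items = list(zip(counts.index.astype(str), counts.values))
    else:
        items = [(str(k), v) for k, v in counts.items()]
    seen = set()
    out = []
    for seq, c in items:
        c = int(c)
        if c < 1:
            raise ValueError(f"count for {seq!r} must be >= 1, got {c}")
        if seq in seen:
            raise ValueError(f"duplicate sequence in count table: {seq!r}")
        seen.add(seq)
        out.append((seq, c))
    return out


@dataclass(frozen=True)
class CorrectionParams:
    """Parameters of Deletion-Correct (defaults as used in benchmarking)."""

    min_counts_for_centroid: int = 2
    max_edits: int = 3
    poisson_error_rate: float = 0.1
    tail_quantile: float = 1.0 - 1e-6

    def __post_init__(self):
        if self.max_edits < 1:
            raise ValueError("max_edits must be >= 1")
        if not (0.0 < self.poisson_error_rate < 1.0):
            raise ValueError("poisson_error_rate must be in (0, 1)")
        if self.min_counts_for_centroid < 1:
            raise ValueError("min_counts_for_centroid must be >= 1")


# ---------------------------------------------------------------------------
# deletion-neighborhood index
# ---------------------------------------------------------------------------

_KEEP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _keep_indices(L: int, k: int) -> np.ndarray:
    """(C(L,k), L-k) matrix of kept positions after deleting k of L chars."""
    key = (L, k)
    if key not in _KEEP_CACHE:
        all_pos = set(range(L))
        rows = [
            sorted(all_pos - set(drop))
            for drop in itertools.combinations(range(L), k)
        ]
        _KEEP_CACHE[key] = np.array(rows, dtype=np.intp)
    return _KEEP_CACHE[key]


def deletion_variants(seq: str, max_deletions: int) -> list[bytes]:
    """All subsequences of ``seq`` with up to ``max_deletions`` characters
    removed (the sequence itself included); may contain duplicates."""
    b = seq.encode()
    L = len(b)
    out = [b]
    arr = np.frombuffer(b, dtype=np.uint8)
    for k in range(1, min(max_deletions, L - 1) + 1):
        keep = _keep_indices(L, k)
        w = L - k
        flat = arr[keep].tobytes()
        out.extend(flat[i * w : (i + 1) * w] for i in range(keep.shape[0]))
    return out


class DeletionIndex:
    """Index of centroid sequences retrievable by Levenshtein proximity.

    If Lev(s, p) <= d, then deleting the substituted/inserted characters from
    s and the substituted/deleted ones from p yields a common subsequence
    reachable with at most d deletions on each side; indexing all deletion
    variants of the centroids and probing with all deletion variants of the
    query therefore retrieves every centroid within distance d.  Retrieved
    candidates are verified with an exact Levenshtein computation.
    """

    def __init__(self, max_edits: int):
        self.max_edits = max_edits
        self._buckets: dict[bytes, list[int]] = {}
        self._sequences: list[str] = []

    def add(self, seq: str) -> int:
        cid = len(self._sequences)
        self._sequences.append(seq)
        for v in set(deletion_variants(seq, self.max_edits)):
            self._buckets.setdefault(v, []).append(cid)
        return cid

    def sequence(self, cid: int) -> str:
        return self._sequences[cid]

    def query(self, seq: str) -> dict[int, int]:
        """{centroid id: exact Levenshtein distance} for all indexed
        sequences within ``max_edits`` of ``seq``."""
        buckets = self._buckets
        cand: set[int] = set()
        for v in deletion_variants(seq, self.max_edits):
            ids = buckets.get(v)
            if ids:
                cand.update(ids)
        out: dict[int, int] = {}
        for cid in cand:
            d = edlib.align(seq, self._sequences[cid], mode="NW", task="distance",
                            k=self.max_edits)["editDistance"]
            if d != -1:
                out[cid] = d
        return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    """Output of error correction: centroid -> members, plus unassigned pool.

    Every input sequence appears exactly once (as a centroid, a member, or
    unassigned); aggregated centroid counts include member counts, so total
    reads are conserved.
    """

    centroids: list[str]
    own_counts: dict[str, int]
    members: dict[str, list[tuple[str, int]]]
    unassigned: dict[str, int]

    def aggregated_counts(self) -> pd.Series:
        agg = {
            c: self.own_counts[c] + sum(cnt for _, cnt in self.members.get(c, []))
            for c in self.centroids
        }
        return pd.Series(agg, dtype="int64").sort_values(ascending=False, kind="stable")

    def assignment_map(self) -> dict[str, str | None]:
        """observed sequence -> centroid (None for unassigned)."""
        out: dict[str, str | None] = {c: c for c in self.centroids}
        for c, mem in self.members.items():
            for seq, _ in mem:
                out[seq] = c
        for seq in self.unassigned:
            out[seq] = None
        return out

    @property
    def total_reads(self) -> int:
        return int(self.aggregated_counts().sum() + sum(self.unassigned.values()))

    def validate(self, input_counts) -> None:
        items = _as_count_items(input_counts)
        assigned = self.assignment_map()
        if set(assigned) != {s for s, _ in items}:
            raise AssertionError("cluster output does not cover the input sequences")
        if self.total_reads != sum(c for _, c in items):
            raise AssertionError("read counts not conserved by clustering")


def _poisson_ceiling(parent_count: int, rate: float, quantile: float,
                     cache: dict[int, int]) -> int:
    if parent_count not in cache:
        cache[parent_count] = int(poisson.ppf(quantile, rate * parent_count))
    return cache[parent_count]


def deletion_correct(counts, params: CorrectionParams | None = None) -> ClusterSet:
    """Cluster an observed-sequence count table onto inferred true barcodes.

    See the module docstring for the algorithm.  Deterministic: sequence
    order, candidate choice and all tie-breaks are fully specified (nearest
    candidate, then highest parent count, then lexicographically smallest).
    """
    params = params or CorrectionParams()
    items = _as_count_items(counts)
    if not items:
        return ClusterSet(centroids=[], own_counts={}, members={}, unassigned={})
    items.sort(key=lambda sc: (-sc[1], sc[0]))

    index = DeletionIndex(params.max_edits)
    own_counts: dict[str, int] = {}
    members: dict[str, list[tuple[str, int]]] = {}
    unassigned: dict[str, int] = {}
    ceil_cache: dict[int, int] = {}

    for seq, c in items:
        best = None  # (distance, -parent_count, parent_seq)
        for cid, dist in index.query(seq).items():
            p_seq = index.sequence(cid)
            p_count = own_counts[p_seq]
            if p_count <= c:
                continue
            if c > _poisson_ceiling(p_count, params.poisson_error_rate,
                                    params.tail_quantile, ceil_cache):
                continue
            key = (dist, -p_count, p_seq)
            if best is None or key < best:
                best = key
        if best is not None:
            members.setdefault(best[2], []).append((seq, c))
        elif c >= params.min_counts_for_centroid:
            index.add(seq)
            own_counts[seq] = c
            members.setdefault(seq, [])
        else:
            unassigned[seq] = c

    centroids = [index.sequence(i) for i in range(len(own_counts))]
    return ClusterSet(
        centroids=centroids,
        own_counts=own_counts,
        members={c: m for c, m in members.items() if m},
        unassigned=unassigned,
    )


# ---------------------------------------------------------------------------
# evaluation against simulation ground truth
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Benchmark metrics for a clustering against simulation ground truth.

    Fractions use the set of true barcodes that generated at least one read
    (false negatives, wrong sequence) and the set of inferred centroids
    (false positives) as denominators.  ``pearson_r_log`` is computed over
    matched pairs on log-transformed read counts.
    """

    n_true: int
    n_inferred: int
    false_negative_fraction: float
    false_positive_fraction: float
    wrong_sequence_fraction: float
    pearson_r_log: float
    matched: pd.DataFrame  # columns: true_barcode, centroid, true_reads, inferred_reads
    n_fn_below_threshold: int  # true barcodes lost to the count threshold
    n_fn_merged: int  # true barcodes absorbed by another true barcode's cluster

    def summary(self) -> str:
        return (
            f"true barcodes (>=1 read): {self.n_true}\n"
            f"inferred centroids:       {self.n_inferred}\n"
            f"false negatives:          {self.false_negative_fraction:.4%} "
            f"(below threshold: {self.n_fn_below_threshold}, merged: {self.n_fn_merged})\n"
            f"false positives:          {self.false_positive_fraction:.4%}\n"
            f"wrong sequence:           {self.wrong_sequence_fraction:.4%}\n"
            f"Pearson R (log counts):   {self.pearson_r_log:.4f}"
        )


def evaluate_correction(
    sim: SimulatedReads,
    clusters: ClusterSet,
    match_edits: int = 3,
) -> EvaluationReport:
    """Match inferred centroids to the simulation's true barcodes and score.

    A true barcode is matched to the centroid with its exact sequence when one
    exists, otherwise to the centroid that received the plurality of the reads
    descended from it; true barcodes left unmatched (or whose cluster was
    claimed by another true barcode) are false negatives.  Centroids matched
    to no true barcode are false positives.  Matched pairs whose centroid
    sequence differs from the true sequence count as wrong-sequence errors.
    """
    true_reads = sim.reads_per_parent()
    true_reads = true_reads[true_reads > 0]
    true_set = set(true_reads.index)
    assignment = clusters.assignment_map()
    agg = clusters.aggregated_counts()

    matched_true: dict[str, str] = {}
    # pass 1: exact sequence matches
    centroid_set = set(agg.index)
    for bc in true_reads.index:
        if bc in centroid_set:
            matched_true[bc] = bc
    # pass 2: plurality of descendant reads, for the rest
    n_merged = 0
    n_below = 0
    descent = sim.table[["observed", "parent", "reads"]].copy()
    descent["centroid"] = descent["observed"].map(assignment)
    votes_all = (
        descent.dropna(subset=["centroid"])
        .groupby(["parent", "centroid"], sort=False)["reads"]
        .sum()
    )
    votes_by_parent: dict[str, dict[str, int]] = {}
    for (p, c), v in votes_all.items():
        votes_by_parent.setdefault(p, {})[c] = int(v)
    claimed = set(matched_true.values())
    # larger true barcodes claim contested clusters first
    order = true_reads.sort_values(ascending=False, kind="stable").index
    for bc in order:
        if bc in matched_true:
            continue
        votes = votes_by_parent.get(bc)
        if not votes:
            n_below += 1  # all descendant reads unassigned / below threshold
            continue
        cent = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        if cent in claimed:
            n_merged += 1  # cluster already claimed by another true barcode
            continue
        matched_true[bc] = cent
        claimed.add(cent)

    rows_out = [
        (bc, cent, int(true_reads[bc]), int(agg[cent]))
        for bc, cent in matched_true.items()
    ]
    matched = pd.DataFrame(
        rows_out, columns=["true_barcode", "centroid", "true_reads", "inferred_reads"]
    )
    n_true = len(true_set)
    n_inferred = len(agg)
    fn = n_true - len(matched_true)
    fp = n_inferred - len(set(matched_true.values()))
    ws = int((matched["true_barcode"] != matched["centroid"]).sum()) if len(matched) else 0
    if len(matched) >= 2:
        r = float(
            pearsonr(
                np.log(matched["true_reads"]), np.log(matched["inferred_reads"])
            ).statistic
        )
    else:
        r = float("nan")
    return EvaluationReport(
        n_true=n_true,
        n_inferred=n_inferred,
        false_negative_fraction=fn / n_true if n_true else 0.0,
        false_positive_fraction=fp / n_inferred if n_inferred else 0.0,
        wrong_sequence_fraction=ws / n_true if n_true else 0.0,
        pearson_r_log=r,
        matched=matched,
        n_fn_below_threshold=n_below,
        n_fn_merged=n_merged,
    )


# ---------------------------------------------------------------------------
# indel-rate estimation from count tables
# ---------------------------------------------------------------------------


def _find_run(seq: str, unit_size: int, length: int) -> tuple[int, int, str] | None:
    """Leftmost maximal run of exactly ``length`` repeats; returns
    (start, span in characters, unit string)."""
    L = len(seq)
    if unit_size == 1:
        i = 0
        while i < L:
            j = i
            while j < L and seq[j] == seq[i]:
                j += 1
            if j - i == length:
                return i, j - i, seq[i]
            i = j
        return None
    # unit_size == 2, distinct letters, maximal run of complete repeats
    for i in range(L - 1):
        if seq[i] == seq[i + 1]:
            continue
        # must be the start of a maximal run (not a continuation)
        if i >= 2 and seq[i - 2] == seq[i] and seq[i - 1] == seq[i + 1]:
            continue
        k = 1
        j = i + 2
        while j + 1 < L and seq[j] == seq[i] and seq[j + 1] == seq[i + 1]:
            k += 1
            j += 2
        if k == length:
            return i, 2 * k, seq[i : i + 2]
    return None


def _run_indel_variant(seq: str, unit_size: int, run_length: int, delta: int) -> str | None:
    """The sequence with the qualifying run's repeat count changed by delta."""
    found = _find_run(seq, unit_size, run_length)
    if found is None:
        return None
    start, span, unit = found
    new_repeats = run_length + delta
    if new_repeats < 0:
        return None
    return seq[:start] + unit * new_repeats + seq[start + span :]


def _single_sub_variants(seq: str):
    for i, b in enumerate(seq):
        for alt in "ACGT":
            if alt != b:
                yield seq[:i] + alt + seq[i + 1 :]


def estimate_run_indel_rates(
    counts,
    unit_size: int = 1,
    run_range=range(3, 14),
    top_n: int = 50,
    min_reads: int = 100,
) -> pd.Series:
    """Per-run-length indel error rate estimated from a count table.

    For each run length n, the ``top_n`` most abundant sequences whose maximal
    run (of the given unit size) is exactly n and whose count exceeds
    ``min_reads`` are treated as true barcodes.  Their putative indel error
    sequences (repeat count changed by +-1 or +-2, rest identical, fewer
    reads) and single-substitution error sequences are collected; the rate at
    n is the pooled indel reads divided by (parent + indel + substitution)
    reads.  Run lengths with no qualifying parent are reported as NaN.
    """
    if unit_size not in (1, 2):
        raise ValueError("unit_size must be 1 or 2")
    items = _as_count_items(counts)
    lookup = dict(items)
    rates = {}
    for n in run_range:
        parents = [
            (seq, c)
            for seq, c in items
            if c > min_reads and len(seq) >= unit_size and max_run(seq, unit_size) == n
        ]
        parents.sort(key=lambda sc: (-sc[1], sc[0]))
        parents = parents[:top_n]
        if not parents:
            rates[n] = float("nan")
            continue
        indel_reads = 0
        denom = 0
        for seq, c in parents:
            denom += c
            for delta in (+1, -1, +2, -2):
                v = _run_indel_variant(seq, unit_size, n, delta)
                if v and v != seq:
                    vc = lookup.get(v, 0)
                    if 0 < vc < c:
                        indel_reads += vc
                        denom += vc
            for v in _single_sub_variants(seq):
                vc = lookup.get(v, 0)
                if 0 < vc < c:
                    denom += vc
        rates[n] = indel_reads / denom if denom else float("nan")
    return pd.Series(rates, name="indel_rate").rename_axis("run_length")


# ---------------------------------------------------------------------------
# external clustering adapter
# ---------------------------------------------------------------------------


def write_clustering(clusters: ClusterSet, path) -> None:
    """Write a ClusterSet as a (member, centroid, member_count) TSV."""
    rows = []
    for c in clusters.centroids:
        rows.append((c, c, clusters.own_counts[c]))
        for seq, cnt in clusters.members.get(c, []):
            rows.append((seq, c, cnt))
    for seq, cnt in clusters.unassigned.items():
        rows.append((seq, "", cnt))
    pd.DataFrame(rows, columns=["member", "centroid", "member_count"]).to_csv(
        path, sep="\t", index=False
    )


def load_external_clustering(source) -> ClusterSet:
    """Build a ClusterSet from an external member -> centroid mapping.

    ``source`` is a TSV path or DataFrame with columns (member, centroid,
    member_count); rows with an empty centroid go to the unassigned pool.
    Every referenced centroid must itself appear as a member row (so its own
    count is known); violations are rejected listing the offenders.  Lets
    clusterings produced by external tools be scored with
    :func:`evaluate_correction`.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype={"member": str, "centroid": str},
                         keep_default_na=False)
    else:
        df = source.copy()
        df["centroid"] = df["centroid"].fillna("")
    required = {"member", "centroid", "member_count"}
    if not required <= set(df.columns):
        raise ValueError(f"clustering table must have columns {sorted(required)}")
    if df["member"].duplicated().any():
        dups = df.loc[df["member"].duplicated(), "member"].tolist()
        raise ValueError(f"duplicate member rows: {dups[:5]}")
    clustered = df[df["centroid"] != ""]
    member_set = set(clustered["member"])
    missing = sorted(set(clustered["centroid"]) - member_set)
    if missing:
        raise ValueError(
            f"{len(missing)} centroid(s) have no member row of their own: {missing[:5]}"
        )
    own_counts: dict[str, int] = {}
    members: dict[str, list[tuple[str, int]]] = {}
    for member, centroid, cnt in clustered.itertuples(index=False):
        cnt = int(cnt)
        if member == centroid:
            own_counts[member] = cnt
        else:
            members.setdefault(centroid, []).append((member, cnt))
    still_missing = sorted(set(clustered["centroid"]) - set(own_counts))
    if still_missing:
        raise ValueError(
            f"centroid(s) never mapped to themselves: {still_missing[:5]}"
        )
    unassigned = {
        m: int(c)
        for m, _, c in df[df["centroid"] == ""].itertuples(index=False)
    }
    centroids = list(dict.fromkeys(clustered["centroid"]))
    return ClusterSet(
        centroids=centroids,
        own_counts=own_counts,
        members=members,
        unassigned=unassigned,
    )
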