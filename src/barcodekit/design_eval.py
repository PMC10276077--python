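"""Quantitative evaluation of random DNA barcode designs.

A barcode *design* is a string over the degenerate alphabet {A, C, G, T, N, W, S}
describing, position by position, which nucleotides a synthesized barcode may
carry (N = any base, W = A/T, S = G/C, literal bases are fixed anchors).  This
module answers the questions that decide whether a design can support a lineage
tracking experiment with K barcoded lineages:

* how much information the design encodes (``information_content``), and how
  much is needed (``min_requirements``: Imin = log2 K bits, Lmin = Imin/2 bp);
* whether library diversity survives transformation (``diversity_check``:
  K * fmax << 1, with ``expected_fmax_exponential`` giving the expected top
  frequency of an exponentially distributed library);
* sequence-composition pathologies: GC content and homopolymer / dinucleotide
  runs, both sampled (``design_profile``) and exact worst case over the whole
  design space (``worst_case_run``, by dynamic programming);
* collision structure of a random library: the fraction of K barcodes with
  another barcode within Hamming distance d, analytically
  (``neighbor_fraction_analytic``) and by exact simulation
  (``neighbor_fraction_simulated``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import binom

EULER_GAMMA = 0.5772156649015329

#: degenerate letter -> frozenset of admissible bases
DEGENERATE_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "W": frozenset("AT"),
    "S": frozenset("GC"),
    "N": frozenset("ACGT"),
}

#: the 38-bp interspersed design: three N's between every WS pair
N3WS = "NNNWSNNNWSNNNWSNNNWSNNNWSNNNWSNNNWSNNN"

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class DesignSpec:
    """Positional grammar of a barcode locus.

    ``positions[i]`` is the set of bases allowed at position i.  The total
    information is the sum of log2(degeneracy) over positions; 2**I distinct
    sequences are producible.
    """

    positions: tuple[frozenset[str], ...]
    spec_string: str = ""

    def __post_init__(self):
        if not self.positions:
            raise ValueError("design must have at least one position")
        for i, s in enumerate(self.positions):
            if not s or not s <= frozenset("ACGT"):
                raise ValueError(f"position {i} has invalid base set {s!r}")

    @property
    def length_bp(self) -> int:
        return len(self.positions)

    @property
    def information_bits(self) -> float:
        return sum(math.log2(len(s)) for s in self.positions)

    def matches(self, seq: str) -> bool:
        """True if ``seq`` is producible by this design."""
        return len(seq) == self.length_bp and all(
            b in s for b, s in zip(seq, self.positions)
        )

    def render(self) -> str:
        """Canonical design string (inverse of :func:`parse_design`)."""
        inv = {v: k for k, v in DEGENERATE_CODES.items()}
        return "".join(inv[s] for s in self.positions)

    def concat(self, other: "DesignSpec") -> "DesignSpec":
        return DesignSpec(self.positions + other.positions)


def parse_design(spec: str) -> DesignSpec:
    """Parse a design string over {A, C, G, T, N, W, S} into a :class:`DesignSpec`.

    Raises ``ValueError`` naming the offending character and its index for any
    letter outside the supported degenerate alphabet.
    """
    if not spec:
        raise ValueError("empty design string")
    positions = []
    for i, ch in enumerate(spec.upper()):
        try:
            positions.append(DEGENERATE_CODES[ch])
        except KeyError:
            raise ValueError(
                f"unknown design letter {ch!r} at position {i}; "
                f"supported letters are A,C,G,T,N,W,S"
            ) from None
    return DesignSpec(tuple(positions), spec_string=spec.upper())


def information_content(design: DesignSpec) -> float:
    """Information I of a design in bits: sum over positions of log2(degeneracy)."""
    return design.information_bits


def min_requirements(K: int) -> tuple[float, float]:
    """Minimum information (bits) and length (bp) to tag K lineages uniquely.

    Imin = log2 K; Lmin = Imin / 2 (each fully random base carries 2 bits).
    In practice designs should exceed Imin by several bits.
    """
    if K < 1:
        raise ValueError(f"lineage count K must be >= 1, got {K}")
    imin = math.log2(K)
    return imin, imin / 2.0


def expected_fmax_exponential(I: float) -> float:
    """Expected frequency of the most common barcode in an exponential library.

    For N = 2**I barcodes with exponentially distributed frequencies summing to
    one, extreme-value theory gives E[fmax] = 2**(-I) * (gamma + I ln 2), with
    gamma the Euler-Mascheroni constant.  The result is asymptotic in N and is
    rejected for I < 5 where the Gumbel approximation is poor.
    """
    if I < 5:
        raise ValueError(
            f"I={I} too small: the extreme-value approximation requires 2**I >> 1"
        )
    return 2.0 ** (-I) * (EULER_GAMMA + I * math.log(2.0))


@dataclass(frozen=True)
class DiversityModel:
    """Diversity bookkeeping for tracking K lineages with an I-bit design."""

    K: int
    I: float
    Imin: float
    Lmin: float
    fmax: float
    gamma: float = EULER_GAMMA

    @classmethod
    def for_design(cls, K: int, design: DesignSpec) -> "DiversityModel":
        imin, lmin = min_requirements(K)
        I = design.information_bits
        return cls(K=K, I=I, Imin=imin, Lmin=lmin, fmax=expected_fmax_exponential(I))


@dataclass(frozen=True)
class DiversityCheck:
    ratio: float
    passed: bool
    threshold: float


def diversity_check(K: int, fmax: float, threshold: float = 0.1) -> DiversityCheck:
    """Check the diversity-preservation criterion K * fmax << 1.

    A typical barcode is then present in at most one transformed cell.  "Much
    less than one" is operationalized as ratio < ``threshold`` (default 0.1).
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if not (0.0 < fmax <= 1.0):
        raise ValueError(f"fmax must be in (0, 1], got {fmax}")
    ratio = K * fmax
    return DiversityCheck(ratio=ratio, passed=ratio < threshold, threshold=threshold)


# ---------------------------------------------------------------------------
# sampling and composition statistics
# ---------------------------------------------------------------------------


@dataclass
class BarcodeSet:
    sequences: list[str]
    seed: int
    design: DesignSpec


def sample_barcodes(design: DesignSpec, n: int, seed: int) -> BarcodeSet:
    """Draw n barcodes from the design, each position uniform over its base set.

    Models hand-mixed degenerate synthesis (even base ratios).  Reproducible
    for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    matrix = _sample_matrix(design, n, np.random.default_rng(seed))
    seqs = _matrix_to_strings(matrix)
    return BarcodeSet(sequences=seqs, seed=seed, design=design)


def _sample_matrix(design: DesignSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, L) uint8 matrix of base indices drawn per-position uniformly."""
    L = design.length_bp
    out = np.empty((n, L), dtype=np.uint8)
    for j, s in enumerate(design.positions):
        choices = np.array(sorted(_BASE_INDEX[b] for b in s), dtype=np.uint8)
        out[:, j] = choices[rng.integers(len(choices), size=n)]
    return out


def _matrix_to_strings(matrix: np.ndarray) -> list[str]:
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    byte_rows = lut[matrix].tobytes()
    L = matrix.shape[1]
    return [byte_rows[i * L : (i + 1) * L].decode() for i in range(matrix.shape[0])]


def gc_content(seq: str) -> float:
    """Fraction of G/C bases in an A/C/G/T sequence."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_run(seq: str, unit_size: int) -> int:
    """Longest run of complete consecutive repeats of any unit of ``unit_size``.

    unit_size 1: classical homopolymer run length ("AAAAA" -> 5).
    unit_size 2: complete repeats of a two-letter unit with *distinct* letters,
    scanned over both phases ("ACACACA" -> 3); homopolymer stretches are
    reported only under unit_size 1, so "AAAA" -> 0 here.  Returns 0 when no
    qualifying unit occurs.
    """
    if unit_size not in (1, 2):
        raise ValueError("unit_size must be 1 or 2")
    if len(seq) < unit_size:
        raise ValueError("sequence shorter than unit size")
    if unit_size == 1:
        best = cur = 1
        for a, b in zip(seq, seq[1:]):
            cur = cur + 1 if a == b else 1
            best = max(best, cur)
        return best
    best = 0
    i = 0
    L = len(seq)
    while i < L - 1:
        if seq[i] == seq[i + 1]:
            i += 1
            continue
        k = 1
        j = i + 2
        while j + 1 < L and seq[j] == seq[i] and seq[j + 1] == seq[i + 1]:
            k += 1
            j += 2
        best = max(best, k)
        i += 1
    return best


def _max_homopolymer_rows(matrix: np.ndarray) -> np.ndarray:
    """Vectorized per-row longest homopolymer run for an (n, L) base matrix."""
    n, L = matrix.shape
    best = np.ones(n, dtype=np.int64)
    cur = np.ones(n, dtype=np.int64)
    for j in range(1, L):
        eq = matrix[:, j] == matrix[:, j - 1]
        cur = np.where(eq, cur + 1, 1)
        np.maximum(best, cur, out=best)
    return best


def _max_dinucleotide_rows(matrix: np.ndarray) -> np.ndarray:
    """Vectorized per-row max complete repeats of a distinct-letter 2-unit."""
    n, L = matrix.shape
    best = np.zeros(n, dtype=np.int64)
    if L < 2:
        return best
    chain = np.zeros(n, dtype=np.int64)  # consecutive s[j] == s[j+2] before j
    for j in range(L - 1):
        # segment ending at j+1 with period 2 has length chain + 2
        distinct = matrix[:, j] != matrix[:, j + 1]
        repeats = np.where(distinct, (chain + 2) // 2, 0)
        np.maximum(best, repeats, out=best)
        if j + 2 < L:
            eq2 = matrix[:, j] == matrix[:, j + 2]
            chain = np.where(eq2, chain + 1, 0)
    return best


@dataclass
class DesignProfile:
    """Sampled composition statistics of a design (normalized frequencies)."""

    design: DesignSpec
    n_samples: int
    seed: int
    gc: pd.Series  # index: GC fraction rounded to bin, values: frequency
    homopolymer: pd.Series  # index: run length, values: frequency
    dinucleotide: pd.Series  # index: repeat count, values: frequency
    gc_range: tuple[float, float] = (0.0, 1.0)


def design_profile(
    design: DesignSpec, n_samples: int, seed: int, gc_bins: int = 20
) -> DesignProfile:
    """Distributions of GC content and max run lengths over sampled barcodes."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    matrix = _sample_matrix(design, n_samples, rng)
    gc_frac = np.isin(matrix, [_BASE_INDEX["G"], _BASE_INDEX["C"]]).mean(axis=1)
    homo = _max_homopolymer_rows(matrix)
    dinuc = _max_dinucleotide_rows(matrix)

    edges = np.linspace(0.0, 1.0, gc_bins + 1)
    hist, _ = np.histogram(gc_frac, bins=edges)
    gc_series = pd.Series(hist / n_samples, index=edges[:-1].round(6), name="frequency")
    homo_series = (
        pd.Series(homo).value_counts(normalize=True).sort_index().rename("frequency")
    )
    dinuc_series = (
        pd.Series(dinuc).value_counts(normalize=True).sort_index().rename("frequency")
    )
    return DesignProfile(
        design=design,
        n_samples=n_samples,
        seed=seed,
        gc=gc_series,
        homopolymer=homo_series,
        dinucleotide=dinuc_series,
        gc_range=(float(gc_frac.min()), float(gc_frac.max())),
    )


def worst_case_gc(design: DesignSpec) -> tuple[float, float]:
    """Exact worst-case GC range over all sequences producible by the design."""
    lo = sum(1 for s in design.positions if s <= frozenset("GC"))
    hi = sum(1 for s in design.positions if s & frozenset("GC"))
    return lo / design.length_bp, hi / design.length_bp


def worst_case_run(design: DesignSpec, unit_size: int) -> int:
    """Exact maximum run achievable by any sequence consistent with the design.

    Dynamic programming over positions.  unit_size 1 tracks, for each base b,
    the longest run of b's that can end at the current position; unit_size 2
    tracks, for each ordered distinct pair (x, y), the number of complete xy
    repeats that can end at the current position, extended two positions at a
    time (both phases arise automatically).
    """
    if unit_size not in (1, 2):
        raise ValueError("unit_size must be 1 or 2")
    sets = design.positions
    L = len(sets)
    if unit_size == 1:
        best = 0
        run = {b: 0 for b in _BASES}
        for s in sets:
            run = {b: (run[b] + 1 if b in s else 0) for b in _BASES}
            best = max(best, max(run.values()))
        return best
    if L < 2:
        return 0
    pairs = [(x, y) for x in _BASES for y in _BASES if x != y]
    # h[i][xy]: max complete xy-repeats in a periodic run ending at position i
    h_prev2 = {p: 0 for p in pairs}  # ending at i-2
    h_prev1 = {p: 0 for p in pairs}  # ending at i-1
    best = 0
    for i in range(1, L):
        h_cur = {}
        for x, y in pairs:
            if x in sets[i - 1] and y in sets[i]:
                h_cur[(x, y)] = 1 + (h_prev2[(x, y)] if i >= 3 else 0)
            else:
                h_cur[(x, y)] = 0
        best = max(best, max(h_cur.values()))
        h_prev2, h_prev1 = h_prev1, h_cur
    return best


def enumerate_sequences(design: DesignSpec):
    """Yield every sequence producible by the design (for small designs)."""
    for bases in itertools.product(*(sorted(s) for s in design.positions)):
        yield "".join(bases)


# ---------------------------------------------------------------------------
# sequencing-error arithmetic
# ---------------------------------------------------------------------------


def read_error_fraction(length_bp: int, per_base_rate: float, at_least: int = 1) -> float:
    """Fraction of reads of a ``length_bp`` barcode with >= ``at_least`` errors.

    Closed-form binomial tail at the per-base substitution rate; e.g. at 0.4%
    per base, 7.7% of 20-bp barcode reads carry at least one error.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if not (0.0 <= per_base_rate <= 1.0):
        raise ValueError("per_base_rate must be in [0, 1]")
    return float(binom.sf(at_least - 1, length_bp, per_base_rate))


# ---------------------------------------------------------------------------
# Hamming-distance collision analysis
# ---------------------------------------------------------------------------


def hamming_ball_probability(L: int, d: int) -> float:
    """Probability that a random L-mer lies within Hamming distance d of a
    fixed L-mer: sum_{i<=d} C(L,i) 3**i / 4**L."""
    if d > L:
        raise ValueError(f"radius d={d} exceeds length L={L}")
    if d < 0:
        raise ValueError("d must be >= 0")
    total = sum(comb(L, i, exact=True) * 3**i for i in range(d + 1))
    return total / 4**L


def neighbor_fraction_analytic(K: int, L: int, d: int) -> float:
    """Expected fraction of K random L-mers with another barcode within
    Hamming distance d (inclusive of exact duplicates at d=0).

    For a fully degenerate (N x L) library: 1 - (1 - p_d)**(K - 1) with p_d
    the Hamming-ball probability.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    p = hamming_ball_probability(L, d)
    return 1.0 - (1.0 - p) ** (K - 1)


@dataclass
class NeighborProfile:
    """Fraction of barcodes with a neighbor within each Hamming radius."""

    K: int
    L: int
    radii: np.ndarray  # 0..d_max
    fraction: np.ndarray  # mean over replicates
    standard_error: np.ndarray
    replicates: int

    def __post_init__(self):
        assert np.all(np.diff(self.fraction) >= -1e-12)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius": self.radii,
                "fraction": self.fraction,
                "standard_error": self.standard_error,
            }
        )


def _min_neighbor_distance(matrix: np.ndarray, d_max: int) -> np.ndarray:
    """Per-row minimum Hamming distance to any other row, capped at d_max + 1.

    Exact pigeonhole search: the L positions are split into d_max + 1 blocks;
    any pair within distance d_max agrees exactly on at least one block, so
    grouping rows by each block's content and checking pairs within groups
    examines every qualifying pair.
    """
    n, L = matrix.shape
    if d_max >= L:
        raise ValueError(f"d_max={d_max} must be < L={L}")
    n_blocks = d_max + 1
    bounds = np.linspace(0, L, n_blocks + 1).astype(int)
    mind = np.full(n, d_max + 1, dtype=np.int64)
    m64 = matrix.astype(np.int64)
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        # pack the block into a single integer key per row
        key = np.zeros(n, dtype=np.int64)
        for j in range(lo, hi):
            key = key * 4 + m64[:, j]
        order = np.argsort(key, kind="stable")
        sorted_key = key[order]
        starts = np.flatnonzero(np.r_[True, sorted_key[1:] != sorted_key[:-1]])
        ends = np.r_[starts[1:], n]
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            idx = order[s:e]
            sub = matrix[idx]
            # pairwise Hamming distances within the group
            dists = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
            np.fill_diagonal(dists, L + 1)
            gmin = dists.min(axis=1)
            np.minimum.at(mind, idx, gmin)
    return mind


def neighbor_fraction_simulated(
    K: int,
    L: int,
    d_max: int,
    replicates: int = 5,
    seed: int = 0,
) -> NeighborProfile:
    """Simulated fraction of K random L-mers with a neighbor within each
    radius d <= d_max, averaged over replicate libraries.

    Uses an exact block-partition search guaranteed not to miss any neighbor
    within d_max.
    """
    if d_max > L:
        raise ValueError(f"d_max={d_max} exceeds L={L}")
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    radii = np.arange(d_max + 1)
    search_d = min(d_max, L - 1)  # at d = L every pair is trivially a neighbor
    fracs = np.empty((replicates, d_max + 1))
    for r in range(replicates):
        matrix = rng.integers(0, 4, size=(K, L), dtype=np.uint8)
        mind = _min_neighbor_distance(matrix, search_d)
        for d in radii:
            fracs[r, d] = 1.0 if d >= L else np.mean(mind <= d)
    mean = fracs.mean(axis=0)
    se = fracs.std(axis=0, ddof=1) / math.sqrt(replicates) if replicates > 1 else np.zeros_like(mean)
    return NeighborProfile(
        K=K, L=L, radii=radii, fraction=mean, standard_error=se, replicates=replicates
    )
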