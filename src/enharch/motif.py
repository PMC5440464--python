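"""Position weight matrices, log-odds scoring and motif specificity statistics.

A PWM models a TF's binding preference as independent per-position base
frequencies ``p_i(b)``.  Against an intergenic background with composition
``q(b)``, a window of sequence is scored by the log-odds sum

    score = sum_i log2( p_i(base_i) / q(base_i) )   [bits]

The significance of a score is its p-value under the background model: the
probability that a random background window scores at least as high.  That
distribution is computed exactly by position-wise convolution of the
discretized weight columns (the Staden / Hertz–Stormo dynamic programme),
and thresholds are expressed as natural-log p-values, Patser-style.

Motif specificity is summarised by the Kullback–Leibler information content

    I = sum_i sum_b p_i(b) * log2( p_i(b) / q(b) )   [bits]

with ``p = 2**-I`` the approximate probability of a motif hit at a random
background position, and ``p_av`` the site-count-weighted mean of ``2**-I``
over the TFs hitting an enhancer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "BackgroundModel",
    "Pwm",
    "ScoreDistribution",
    "build_pwm",
    "log_odds_matrix",
    "score_sequence",
    "score_distribution",
    "information_content",
    "motif_hit_probability",
    "average_motif_hit_probability",
    "encode_sequence",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# fast byte-level encoder: A,C,G,T -> 0..3, anything else -> -1
_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode DNA to int8 codes 0..3 (ACGT); non-ACGT characters become -1."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BackgroundModel:
    """Background base composition q(b) and accessible genome size N (bp)."""

    q: np.ndarray
    N: float = 175.5e6

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,):
            raise ValueError("background composition must have 4 entries (A,C,G,T)")
        if not np.all(q > 0):
            raise ValueError("all background base frequencies must be positive")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies must sum to 1, got {q.sum()}")
        object.__setattr__(self, "q", q)

    @classmethod
    def uniform(cls, N: float = 175.5e6) -> "BackgroundModel":
        return cls(q=np.full(4, 0.25), N=N)

    @classmethod
    def from_frequencies(cls, freq_by_base: dict, N: float = 175.5e6) -> "BackgroundModel":
        q = np.array([freq_by_base[b] for b in BASES], dtype=float)
        return cls(q=q, N=N)

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], N: float = 175.5e6) -> "BackgroundModel":
        """Estimate q(b) from supplied (e.g. intergenic) sequence."""
        counts = np.zeros(4, dtype=float)
        for seq in sequences:
            codes = encode_sequence(seq)
            counts += np.bincount(codes[codes >= 0], minlength=4)
        if counts.sum() == 0:
            raise ValueError("no ACGT bases found in background sequences")
        return cls(q=counts / counts.sum(), N=N)


@dataclass(frozen=True)
class Pwm:
    """Per-position base frequencies of a motif, with optional provenance.

    ``freqs`` has shape (L, 4) with columns in A,C,G,T order; every row sums
    to 1 and is strictly positive (pseudocounting guarantees this for
    matrices built from counts).  ``training_alignment`` carries the binding
    sequences the matrix derives from, used for cutoff calibration.
    """

    name: str
    freqs: np.ndarray
    training_alignment: tuple[str, ...] | None = None
    pseudocount_total: float = 0.01

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError("freqs must be an (L, 4) matrix with L >= 1")
        if not np.all(f > 0):
            raise ValueError("all PWM frequencies must be strictly positive "
                             "(apply pseudocounting)")
        if np.max(np.abs(f.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("each PWM column must sum to 1")
        object.__setattr__(self, "freqs", f)
        if self.training_alignment is not None:
            object.__setattr__(self, "training_alignment", tuple(self.training_alignment))

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


def _counts_from_alignment(alignment: Sequence[str]) -> np.ndarray:
    if not alignment:
        raise ValueError("empty training alignment")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("alignment sequences must all have equal length")
    counts = np.zeros((L, 4), dtype=float)
    for seq in alignment:
        codes = encode_sequence(seq)
        if np.any(codes < 0):
            raise ValueError(f"ambiguity codes not allowed in alignment: {seq!r}")
        counts[np.arange(L), codes] += 1.0
    return counts


def build_pwm(
    counts_or_alignment,
    background: BackgroundModel,
    pseudocount_total: float = 0.01,
    name: str = "",
    training_alignment: Sequence[str] | None = None,
) -> Pwm:
    """Construct a pseudocounted PWM from a count matrix or an alignment.

    Pseudocounts are distributed in proportion to the background frequency
    of the corresponding base, to a total of ``pseudocount_total`` per
    column:  p_i(b) = (c_i(b) + t*q(b)) / (C_i + t).
    """
    if pseudocount_total <= 0:
        raise ValueError("pseudocount_total must be positive")
    if isinstance(counts_or_alignment, (list, tuple)) and counts_or_alignment and isinstance(
        counts_or_alignment[0], str
    ):
        alignment = [s.upper() for s in counts_or_alignment]
        counts = _counts_from_alignment(alignment)
        if training_alignment is None:
            training_alignment = alignment
    else:
        counts = np.asarray(counts_or_alignment, dtype=float)
        if counts.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if counts.shape[1] != 4 and counts.shape[0] == 4:
            counts = counts.T  # accept 4 x L row-per-base layout
        if counts.shape[1] != 4:
            raise ValueError("count matrix must have 4 base columns (A,C,G,T)")
        if np.any(counts < 0):
            raise ValueError("negative counts are not allowed")
    column_totals = counts.sum(axis=1, keepdims=True)
    if np.any(column_totals == 0):
        raise ValueError("every PWM column must have positive total count")
    t = pseudocount_total
    freqs = (counts + t * background.q) / (column_totals + t)
    return Pwm(
        name=name,
        freqs=freqs,
        training_alignment=tuple(training_alignment) if training_alignment else None,
        pseudocount_total=t,
    )


def log_odds_matrix(pwm: Pwm, background: BackgroundModel) -> np.ndarray:
    """(L, 4) matrix of per-position weights log2(p_i(b)/q(b)), in bits."""
    return np.log2(pwm.freqs / background.q)


def score_sequence(
    weights: np.ndarray, seq: str, strands: str = "both"
) -> list[tuple[int, str, float]]:
    """Score every valid window of ``seq`` with a log-odds matrix.

    One ``(offset, strand, score)`` triple per valid 0-based half-open
    window [i, i+L) per requested strand.  The reverse-strand score is the
    score of the window's reverse complement, reported at the forward
    offset.  Windows containing non-ACGT characters are skipped.
    Raises ValueError if the sequence is shorter than the motif.
    """
    weights = np.asarray(weights, dtype=float)
    L = weights.shape[0]
    codes = encode_sequence(seq)
    if codes.size < L:
        raise ValueError(
            f"sequence length {codes.size} shorter than motif width {L}"
        )
    strand_list = _strand_list(strands)
    # window x position index matrix; invalid (non-ACGT) windows masked out
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(win >= 0, axis=1)
    out: list[tuple[int, str, float]] = []
    for strand in strand_list:
        w = weights if strand == "+" else weights[::-1, ::-1]
        safe = np.where(win >= 0, win, 0)
        scores = w[np.arange(L)[None, :], safe].sum(axis=1)
        for i in np.flatnonzero(valid):
            out.append((int(i), strand, float(scores[i])))
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def _strand_list(strands: str) -> list[str]:
    if strands == "both":
        return ["+", "-"]
    if strands == "forward":
        return ["+"]
    raise ValueError("strands must be 'both' or 'forward'")


@dataclass
class ScoreDistribution:
    """Exact distribution of window log-odds scores under the background.

    Scores are discretized to an integer grid of step ``bin_width`` bits;
    ``ln_pvalue(s)`` returns ln P(score >= s) for a random background
    window.  The integer weight matrix is retained so that scans can score
    windows on exactly the grid the tail probabilities were computed on.
    """

    bin_width: float
    int_weights: np.ndarray          # (L, 4) integer bin indices
    min_score: int                   # smallest achievable integer score
    ln_tail: np.ndarray              # ln P(S >= min_score + j), j = 0..size-1
    _log_q: np.ndarray = field(repr=False, default=None)

    @property
    def width(self) -> int:
        return self.int_weights.shape[0]

    def ln_pvalue(self, score):
        """ln P(background window score >= ``score``), score in bits."""
        idx = np.rint(np.asarray(score, dtype=float) / self.bin_width).astype(int)
        idx = np.clip(idx - self.min_score, 0, self.ln_tail.size - 1)
        out = self.ln_tail[idx]
        return float(out) if np.isscalar(score) or np.ndim(score) == 0 else out

    def grid_score(self, int_score) -> np.ndarray:
        """Convert integer grid scores back to bits."""
        return np.asarray(int_score) * self.bin_width

    def window_scores(self, seq: str, strands: str = "both"):
        """Score all valid windows on the discretized grid.

        Returns a list of ``(offset, strand, score_bits, ln_pvalue)``; the
        discretized score keeps tail-probability lookups exactly consistent
        with the DP distribution (no bin-boundary drift).  Raises ValueError
        on sequences shorter than the motif.
        """
        L = self.width
        codes = encode_sequence(seq)
        if codes.size < L:
            raise ValueError(
                f"sequence length {codes.size} shorter than motif width {L}"
            )
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = np.all(win >= 0, axis=1)
        safe = np.where(win >= 0, win, 0)
        pos = np.arange(L)[None, :]
        out = []
        for strand in _strand_list(strands):
            iw = self.int_weights if strand == "+" else self.int_weights[::-1, ::-1]
            int_scores = iw[pos, safe].sum(axis=1)
            lnp = self.ln_tail[np.clip(int_scores - self.min_score, 0, self.ln_tail.size - 1)]
            for i in np.flatnonzero(valid):
                out.append(
                    (int(i), strand, float(int_scores[i] * self.bin_width), float(lnp[i]))
                )
        out.sort(key=lambda h: (h[0], h[1]))
        return out


def score_distribution(
    weights: np.ndarray, background: BackgroundModel, bin_width: float = 0.01
) -> ScoreDistribution:
    """Exact background score distribution by position-wise convolution.

    Each weight is rounded to the nearest multiple of ``bin_width``; the
    probability mass function of the window score is then built one motif
    position at a time (O(L * range * 4)).  The returned object maps score
    thresholds to natural-log tail probabilities.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    weights = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite (pseudocount the PWM)")
    iw = np.rint(weights / bin_width).astype(np.int64)
    L = iw.shape[0]
    col_min = iw.min(axis=1)
    col_max = iw.max(axis=1)
    min_score = int(col_min.sum())
    size = int((col_max - col_min).sum()) + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0
    reach = 0  # current occupied length of pmf
    q = background.q
    for i in range(L):
        new = np.zeros(size)
        for b in range(4):
            shift = int(iw[i, b] - col_min[i])
            new[shift : shift + reach + 1] += q[b] * pmf[: reach + 1]
        reach += int(col_max[i] - col_min[i])
        pmf = new
    # ln of the upper tail; accumulate from the top for accuracy
    tail = np.cumsum(pmf[::-1])[::-1]
    with np.errstate(divide="ignore"):
        ln_tail = np.log(np.maximum(tail, 0.0))
    return ScoreDistribution(
        bin_width=bin_width, int_weights=iw, min_score=min_score, ln_tail=ln_tail
    )


def information_content(pwm: Pwm, background: BackgroundModel) -> float:
    """Kullback–Leibler information content of the motif, in bits."""
    f = pwm.freqs
    return float(np.sum(f * np.log2(f / background.q)))


def motif_hit_probability(I: float) -> float:
    """Approximate probability 2**-I of a motif hit at a background position."""
    if I < 0:
        raise ValueError(f"information content must be non-negative, got {I}")
    return float(2.0 ** -I)


def average_motif_hit_probability(site_counts, contents) -> float:
    """Site-count-weighted mean of 2**-I_j over TFs: p_av = sum n_j 2^-I_j / n_total."""
    n = np.asarray(site_counts, dtype=float)
    I = np.asarray(contents, dtype=float)
    if n.shape != I.shape:
        raise ValueError("site_counts and contents must be index-aligned")
    if np.any(n < 0) or np.any(I < 0):
        raise ValueError("counts and information contents must be non-negative")
    n_total = n.sum()
    if n_total == 0:
        raise ValueError("p_av undefined: all site counts are zero")
    return float(np.sum(n * 2.0 ** -I) / n_total)
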