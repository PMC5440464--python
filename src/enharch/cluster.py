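"""Binomial model of enhancer distinguishability from genomic background.

An enhancer is a cluster of transcription-factor binding sites.  Treat each
of the ``w`` base positions of a candidate enhancer as an independent
Bernoulli trial in which a motif hit occurs with probability ``p`` (or
``m*p`` when sites of ``m`` different TFs with identical hit probability
contribute).  The point probability of observing exactly ``k`` hits is then

    P(k) = C(w, k) * (m*p)**k * (1 - m*p)**(w - k)

and the cluster is *distinguishable* from the accessible genomic background
of ``N`` base pairs when ``P(k) < 1/N`` — rarer than one expected occurrence
in the accessible genome.  This module computes P(k) underflow-safely, finds
the minimum number of sites satisfying the criterion, and sweeps that
minimum over grids of enhancer length, motif specificity, TF count and
accessible genome size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ClusterQuery",
    "GENOME_SIZES",
    "cluster_probability",
    "min_sites_for_distinguishability",
    "sweep_min_sites",
]

#: Accessible genome sizes (bp) for D. melanogaster: DNase-hypersensitivity
#: derived conservative and relaxed estimates, and the whole genome.
GENOME_SIZES: dict[str, float] = {
    "dnase_conservative": 4.1e6,
    "dnase_relaxed": 19.4e6,
    "whole_genome": 175.5e6,
}

_MAX_W = 10**6  # guard on the linear k-search


@dataclass(frozen=True)
class ClusterQuery:
    """Parameters of one distinguishability query.

    w : enhancer length in bp; k : number of binding sites; p : motif hit
    probability per position; m : number of distinct TFs contributing sites;
    N : accessible genome size in bp.
    """

    w: int
    k: int
    p: float
    m: int = 1
    N: float = GENOME_SIZES["dnase_conservative"]

    def __post_init__(self) -> None:
        _validate(self.w, self.p, self.m, self.N)
        if not 0 <= self.k <= self.w:
            raise ValueError(f"k must satisfy 0 <= k <= w, got k={self.k}, w={self.w}")


def _validate(w: int, p: float, m: int, N: float | None = None) -> None:
    if w < 1:
        raise ValueError(f"enhancer length w must be positive, got {w}")
    if w > _MAX_W:
        raise ValueError(f"w={w} exceeds supported maximum {_MAX_W}")
    if m < 1:
        raise ValueError(f"TF count m must be a positive integer, got {m}")
    if not 0.0 < m * p < 1.0:
        raise ValueError(
            f"effective hit probability m*p must lie in (0, 1), got m={m}, p={p}"
        )
    if N is not None:
        if N < w:
            raise ValueError(f"accessible genome N={N} smaller than enhancer w={w}")


def cluster_probability(q: ClusterQuery) -> float:
    """Point binomial probability of exactly ``q.k`` hits in ``q.w`` bp.

    Computed in log space via log-gamma, so it is underflow-safe for
    w up to 1e5 and probabilities down to ~1e-300.
    """
    w, k, mp = q.w, q.k, q.m * q.p
    log_p = (
        gammaln(w + 1)
        - gammaln(k + 1)
        - gammaln(w - k + 1)
        + k * math.log(mp)
        + (w - k) * math.log1p(-mp)
    )
    return math.exp(log_p)


def min_sites_for_distinguishability(
    w: int, p: float, N: float, m: int = 1
) -> int:
    """Minimum site count k at which a cluster is rarer than 1/N.

    Returns the smallest ``k >= floor(w*m*p)`` (the mode region of the
    binomial) with ``P(k) < 1/N``; beyond the mode P(k) is strictly
    decreasing, so this k is unique.
    """
    _validate(w, p, m, N)
    threshold = 1.0 / N
    k = math.floor(w * m * p)
    while k <= w:
        if cluster_probability(ClusterQuery(w=w, k=k, p=p, m=m, N=N)) < threshold:
            return k
        k += 1
    # unreachable for valid parameters: P(w) = (mp)^w < 1/N whenever N <= (1/mp)^w
    raise ArithmeticError("no k <= w satisfies the distinguishability criterion")


def sweep_min_sites(
    w_values,
    p_values,
    N_values,
    m: int = 1,
) -> pd.DataFrame:
    """Tabulate k_min over the Cartesian grid of (w, p, N) at fixed m.

    Returns a DataFrame with columns ``w p N m k_min``, one row per
    combination.  Domain errors are re-raised with the offending
    combination identified.
    """
    w_values, p_values, N_values = list(w_values), list(p_values), list(N_values)
    if not (w_values and p_values and N_values):
        raise ValueError("parameter lists must be non-empty")
    rows = []
    for w, p, N in itertools.product(w_values, p_values, N_values):
        try:
            k_min = min_sites_for_distinguishability(w, p, N, m=m)
        except ValueError as exc:
            raise ValueError(f"invalid combination (w={w}, p={p}, N={N}, m={m}): {exc}") from exc
        rows.append({"w": w, "p": p, "N": N, "m": m, "k_min": k_min})
    return pd.DataFrame(rows, columns=["w", "p", "N", "m", "k_min"])


def resolve_genome_size(value: str | float) -> float:
    """Accept either a named constant key or a numeric genome size in bp."""
    if isinstance(value, str):
        if value in GENOME_SIZES:
            return GENOME_SIZES[value]
        try:
            return float(value)
        except ValueError:
            raise ValueError(
                f"unknown genome size {value!r}; named options: {sorted(GENOME_SIZES)}"
            ) from None
    return float(value)
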