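"""Scanning enhancers with calibrated motifs and summarising their architecture.

Every sequence window whose ln(p-value) is at or below a motif's calibrated
cutoff is reported as a binding-site hit; overlapping hits are all kept
(no pruning) unless a non-overlapping greedy selection is requested.  Hits
are aggregated per enhancer into an architecture profile: length, per-TF
site counts, total sites, sites normalised by the number of motifs searched
(so cohorts scanned with different TF repertoires stay comparable), and the
average motif hit probability p_av of the TFs actually hitting the
enhancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .calibration import CalibratedMotif
from .motif import average_motif_hit_probability

__all__ = [
    "EnhancerRecord",
    "BindingSiteHit",
    "ArchitectureProfile",
    "IntervalSet",
    "find_hits",
    "profile_enhancer",
    "profile_cohort",
    "profiles_to_frame",
    "hits_to_frame",
    "overlap_fraction",
]


@dataclass(frozen=True)
class EnhancerRecord:
    id: str
    sequence: str
    group: str
    interval: tuple[str, int, int] | None = None  # (chrom, start, end), 0-based half-open

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"enhancer {self.id!r} has empty sequence")
        if not self.group:
            raise ValueError(f"enhancer {self.id!r} has empty group label")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSiteHit:
    enhancer_id: str
    tf_name: str
    offset: int          # 0-based start on the forward strand
    strand: str          # '+' or '-'
    score: float         # bits
    ln_pvalue: float


@dataclass(frozen=True)
class ArchitectureProfile:
    enhancer_id: str
    group: str
    length_bp: int
    n_total: int
    per_tf_counts: Mapping[str, int]
    n_motifs_searched: int
    normalized_sites: float
    p_av: float | None   # None when the enhancer has no hits


def find_hits(
    enhancer: EnhancerRecord,
    motifs: Sequence[CalibratedMotif],
    strands: str = "both",
    non_overlapping: bool = False,
) -> list[BindingSiteHit]:
    """All windows passing each motif's calibrated cutoff, ordered deterministically.

    Motifs wider than the enhancer contribute no hits (not an error).  With
    ``non_overlapping``, hits of the same motif are greedily selected most
    significant first, discarding any that overlap an already-kept hit.
    """
    hits: list[BindingSiteHit] = []
    for cm in motifs:
        L = cm.pwm.width
        if enhancer.length < L:
            continue
        cutoff = cm.cutoff.cutoff_ln_pvalue
        motif_hits = [
            BindingSiteHit(enhancer.id, cm.name, off, strand, score, lnp)
            for (off, strand, score, lnp) in cm.distribution.window_scores(
                enhancer.sequence, strands=strands
            )
            if lnp <= cutoff
        ]
        if non_overlapping:
            motif_hits = _greedy_non_overlapping(motif_hits, L)
        hits.extend(motif_hits)
    hits.sort(key=lambda h: (h.offset, h.tf_name, h.strand))
    return hits


def _greedy_non_overlapping(hits: list[BindingSiteHit], width: int) -> list[BindingSiteHit]:
    kept: list[BindingSiteHit] = []
    for h in sorted(hits, key=lambda h: (h.ln_pvalue, h.offset, h.strand)):
        if all(h.offset + width <= k.offset or k.offset + width <= h.offset for k in kept):
            kept.append(h)
    return kept


def profile_enhancer(
    enhancer: EnhancerRecord,
    hits: Sequence[BindingSiteHit],
    motifs_searched: Sequence[CalibratedMotif],
) -> ArchitectureProfile:
    """Aggregate hits into the per-enhancer architecture summary.

    ``normalized_sites`` divides by the number of motifs *searched*
    (including motifs with zero hits), and p_av uses the information
    contents of the TFs with at least one hit, weighted by their counts.
    """
    if not motifs_searched:
        raise ValueError("motif list must be non-empty")
    if any(h.enhancer_id != enhancer.id for h in hits):
        raise ValueError("hits belong to a different enhancer")
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.tf_name] = counts.get(h.tf_name, 0) + 1
    n_total = sum(counts.values())
    content_by_tf = {cm.name: cm.information_content for cm in motifs_searched}
    if n_total > 0:
        tfs = sorted(counts)
        p_av = average_motif_hit_probability(
            [counts[t] for t in tfs], [content_by_tf[t] for t in tfs]
        )
    else:
        p_av = None
    return ArchitectureProfile(
        enhancer_id=enhancer.id,
        group=enhancer.group,
        length_bp=enhancer.length,
        n_total=n_total,
        per_tf_counts=counts,
        n_motifs_searched=len(motifs_searched),
        normalized_sites=n_total / len(motifs_searched),
        p_av=p_av,
    )


def profile_cohort(
    enhancers: Sequence[EnhancerRecord],
    motifs_by_group: Mapping[str, Sequence[CalibratedMotif]],
    strands: str = "both",
    non_overlapping: bool = False,
) -> tuple[list[ArchitectureProfile], list[BindingSiteHit], list[str]]:
    """Scan a cohort, choosing each enhancer's motif panel by its group label.

    Enhancers whose group has no (or an empty) motif list are reported as
    unprofiled by id; the run continues for the rest.
    """
    profiles: list[ArchitectureProfile] = []
    all_hits: list[BindingSiteHit] = []
    unprofiled: list[str] = []
    for enh in enhancers:
        panel = motifs_by_group.get(enh.group)
        if not panel:
            unprofiled.append(enh.id)
            continue
        hits = find_hits(enh, panel, strands=strands, non_overlapping=non_overlapping)
        profiles.append(profile_enhancer(enh, hits, panel))
        all_hits.extend(hits)
    return profiles, all_hits, unprofiled


def profiles_to_frame(profiles: Sequence[ArchitectureProfile]) -> pd.DataFrame:
    """Tabular view with columns id, group, length_bp, n_total, n_motifs_searched,
    normalized_sites, p_av (NaN where undefined)."""
    return pd.DataFrame(
        {
            "id": [p.enhancer_id for p in profiles],
            "group": [p.group for p in profiles],
            "length_bp": [p.length_bp for p in profiles],
            "n_total": [p.n_total for p in profiles],
            "n_motifs_searched": [p.n_motifs_searched for p in profiles],
            "normalized_sites": [p.normalized_sites for p in profiles],
            "p_av": [float("nan") if p.p_av is None else p.p_av for p in profiles],
        }
    )


def hits_to_frame(hits: Sequence[BindingSiteHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "enhancer_id": [h.enhancer_id for h in hits],
            "tf_name": [h.tf_name for h in hits],
            "offset": [h.offset for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "ln_pvalue": [h.ln_pvalue for h in hits],
        }
    )


@dataclass(frozen=True)
class IntervalSet:
    """Genomic intervals, 0-based half-open, for overlap statistics."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"degenerate interval {chrom}:{start}-{end}")
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)


def overlap_fraction(a: IntervalSet, b: IntervalSet) -> tuple[float, list[float]]:
    """Fraction of intervals of ``a`` overlapping >= 1 bp of some interval of ``b``.

    Also returns, per interval of ``a``, the best single-interval overlap
    length as a fraction of the shorter of the two intervals (0 where no
    overlap), supporting "greatest amount of overlap" style statistics.
    """
    if len(a) == 0:
        raise ValueError("interval set a is empty")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in b.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    best_fracs: list[float] = []
    n_overlapping = 0
    for chrom, s, e in a.intervals:
        best = 0.0
        for bs, be in by_chrom.get(chrom, ()):
            ov = min(e, be) - max(s, bs)
            if ov > 0:
                best = max(best, ov / min(e - s, be - bs))
        if best > 0:
            n_overlapping += 1
        best_fracs.append(best)
    return n_overlapping / len(a), best_fracs
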