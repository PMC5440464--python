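"""Percentile calibration of binding-site score cutoffs.

Rather than picking an arbitrary score threshold, each motif's cutoff is
derived from its own training data: the aligned binding sequences the PWM
was built from are scored against the PWM, each sequence is assigned its
best (smallest) ln(p-value) over all offsets and strands, and the cutoff is
set at the chosen percentile of those values so that at least that fraction
of the training sequences qualify as "true" binding sites.  The default
percentile is 75.

ln(p-values) are negative with more-negative = more significant; the
percentile is the ascending nearest-rank order statistic, so percentile 75
takes the ceil(0.75 n)-th smallest value and at least 75% of training
sequences score at or below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .motif import BackgroundModel, Pwm, ScoreDistribution, log_odds_matrix, score_distribution

__all__ = ["CutoffResult", "CalibratedMotif", "calibrate_cutoff", "calibrate_all"]


@dataclass(frozen=True)
class CutoffResult:
    tf_name: str
    percentile: float
    cutoff_ln_pvalue: float
    n_training_used: int
    n_training_skipped: int


@dataclass(frozen=True)
class CalibratedMotif:
    """A PWM bundled with its score distribution and calibrated cutoff."""

    pwm: Pwm
    distribution: ScoreDistribution
    cutoff: CutoffResult
    information_content: float

    @property
    def name(self) -> str:
        return self.pwm.name


def best_ln_pvalue(dist: ScoreDistribution, seq: str, strands: str = "both") -> float:
    """Smallest (most significant) window ln(p-value) in ``seq``."""
    return min(lnp for (_, _, _, lnp) in dist.window_scores(seq, strands=strands))


def calibrate_cutoff(
    pwm: Pwm,
    background: BackgroundModel,
    percentile: float = 75.0,
    strands: str = "both",
    bin_width: float = 0.01,
) -> CutoffResult:
    """Set the ln(p-value) cutoff from the motif's own training alignment.

    Training sequences shorter than the motif cannot be scored and are
    skipped (and counted).  The cutoff is the nearest-rank ``percentile``-th
    order statistic of the per-sequence best ln(p-values), ascending, so at
    least percentile% of usable training sequences pass their own cutoff.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    if not pwm.training_alignment:
        raise ValueError(f"motif {pwm.name!r} carries no training alignment")
    L = pwm.width
    usable = [s for s in pwm.training_alignment if len(s) >= L]
    n_skipped = len(pwm.training_alignment) - len(usable)
    if not usable:
        raise ValueError(
            f"motif {pwm.name!r}: all {n_skipped} training sequences shorter than width {L}"
        )
    dist = score_distribution(log_odds_matrix(pwm, background), background, bin_width)
    lnps = sorted(best_ln_pvalue(dist, s, strands) for s in usable)
    rank = max(1, math.ceil(percentile / 100.0 * len(lnps)))  # nearest-rank (ceiling)
    cutoff = lnps[rank - 1]
    return CutoffResult(
        tf_name=pwm.name,
        percentile=percentile,
        cutoff_ln_pvalue=cutoff,
        n_training_used=len(usable),
        n_training_skipped=n_skipped,
    )


def calibrate_motif(
    pwm: Pwm,
    background: BackgroundModel,
    percentile: float = 75.0,
    strands: str = "both",
    bin_width: float = 0.01,
) -> CalibratedMotif:
    """Calibrate one motif and bundle PWM, score distribution and cutoff."""
    from .motif import information_content

    cutoff = calibrate_cutoff(pwm, background, percentile, strands, bin_width)
    dist = score_distribution(log_odds_matrix(pwm, background), background, bin_width)
    return CalibratedMotif(
        pwm=pwm,
        distribution=dist,
        cutoff=cutoff,
        information_content=information_content(pwm, background),
    )


def calibrate_all(
    pwms: list[Pwm],
    background: BackgroundModel,
    percentile: float = 75.0,
    strands: str = "both",
    bin_width: float = 0.01,
) -> tuple[list[CalibratedMotif], pd.DataFrame]:
    """Calibrate a motif panel; unusable motifs are reported, not dropped silently.

    Returns the list of calibrated motifs and a table with one row per input
    PWM (columns: tf_name, percentile, cutoff_ln_pvalue, n_training_used,
    n_training_skipped, status).
    """
    calibrated: list[CalibratedMotif] = []
    rows = []
    for pwm in pwms:
        try:
            cm = calibrate_motif(pwm, background, percentile, strands, bin_width)
        except ValueError as exc:
            rows.append(
                {
                    "tf_name": pwm.name,
                    "percentile": percentile,
                    "cutoff_ln_pvalue": float("nan"),
                    "n_training_used": 0,
                    "n_training_skipped": len(pwm.training_alignment or ()),
                    "status": f"skipped: {exc}",
                }
            )
            continue
        calibrated.append(cm)
        c = cm.cutoff
        rows.append(
            {
                "tf_name": c.tf_name,
                "percentile": c.percentile,
                "cutoff_ln_pvalue": c.cutoff_ln_pvalue,
                "n_training_used": c.n_training_used,
                "n_training_skipped": c.n_training_skipped,
                "status": "ok",
            }
        )
    if not calibrated:
        raise ValueError("no motif in the panel could be calibrated")
    return calibrated, pd.DataFrame(rows)
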