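"""End-to-end analyses: calibrate motifs, scan cohorts, compare groups.

Two workflows are provided.  The axis analysis compares exactly two
enhancer groups (e.g. anterior-posterior vs dorsal-ventral patterning) on
length, total binding sites, sites normalised per motif searched, and
average motif hit probability.  The stage analysis orders three or more
groups (e.g. developmental stage windows), summarises each, and builds
pairwise Bonferroni-adjusted Mann-Whitney matrices for length and
normalised sites.  Both emit a report bundle of data frames and,
optionally, TSV files plus a JSON manifest recording parameters and
per-stage counts, so a run is reproducible from its manifest and inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as eio
from .calibration import CalibratedMotif, calibrate_all
from .motif import BackgroundModel, Pwm
from .scan import EnhancerRecord, profile_cohort, profiles_to_frame, hits_to_frame
from .stats import (
    METRICS,
    compare_two_cohorts,
    comparisons_to_frame,
    group_summary,
    pairwise_comparisons,
    pairwise_matrix,
)

logger = logging.getLogger("enharch")

__all__ = ["RunConfig", "run_axis_analysis", "run_stage_analysis",
           "axis_analysis", "stage_analysis"]


@dataclass
class RunConfig:
    """Declarative run description; CLI flags override file values."""

    enhancers_fasta: str
    groups_tsv: str
    motif_dirs: Mapping[str, str]          # group label -> motif directory
    output_dir: str
    background: Mapping[str, float] | None = None   # base -> frequency; None = uniform
    genome_size: float | str = "whole_genome"
    percentile: float = 75.0
    strands: str = "both"
    pseudocount_total: float = 0.01
    non_overlapping: bool = False
    stage_order: Sequence[str] | None = None
    overrides: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def background_model(self) -> BackgroundModel:
        from .cluster import resolve_genome_size

        N = resolve_genome_size(self.genome_size)
        if self.background is None:
            return BackgroundModel.uniform(N=N)
        return BackgroundModel.from_frequencies(self.background, N=N)


def _calibrate_groups(
    pwms_by_group: Mapping[str, Sequence[Pwm]],
    background: BackgroundModel,
    percentile: float,
    strands: str,
) -> tuple[dict[str, list[CalibratedMotif]], pd.DataFrame]:
    motifs_by_group: dict[str, list[CalibratedMotif]] = {}
    tables = []
    for label, pwms in pwms_by_group.items():
        calibrated, table = calibrate_all(list(pwms), background, percentile, strands)
        motifs_by_group[label] = calibrated
        table.insert(0, "group", label)
        tables.append(table)
    return motifs_by_group, pd.concat(tables, ignore_index=True)


def axis_analysis(
    enhancers: Sequence[EnhancerRecord],
    pwms_by_group: Mapping[str, Sequence[Pwm]],
    background: BackgroundModel,
    percentile: float = 75.0,
    strands: str = "both",
    non_overlapping: bool = False,
) -> dict[str, pd.DataFrame]:
    """Two-group comparison bundle from in-memory inputs.

    Returns data frames: profiles, hits, cutoffs, summaries (per group and
    metric) and comparisons (one Mann-Whitney row per metric).
    """
    groups = sorted({e.group for e in enhancers})
    if len(groups) != 2:
        raise ValueError(
            f"axis analysis needs exactly two groups, found {groups}; "
            "use the stage analysis for ordered multi-group cohorts"
        )
    motifs, cutoff_table = _calibrate_groups(pwms_by_group, background, percentile, strands)
    profiles, hits, unprofiled = profile_cohort(
        enhancers, motifs, strands=strands, non_overlapping=non_overlapping
    )
    if unprofiled:
        logger.warning("unprofiled enhancers (no motif panel for group): %s", unprofiled)
    pf = profiles_to_frame(profiles)
    summaries = _summaries_frame(pf, groups)
    comparisons = comparisons_to_frame(compare_two_cohorts(pf))
    logger.info(
        "axis analysis: %d enhancers, %d hits, groups %s", len(profiles), len(hits), groups
    )
    return {
        "profiles": pf,
        "hits": hits_to_frame(hits),
        "cutoffs": cutoff_table,
        "summaries": summaries,
        "comparisons": comparisons,
    }


def stage_analysis(
    enhancers: Sequence[EnhancerRecord],
    pwms_by_group: Mapping[str, Sequence[Pwm]],
    background: BackgroundModel,
    stage_order: Sequence[str],
    percentile: float = 75.0,
    strands: str = "both",
    non_overlapping: bool = False,
) -> dict[str, pd.DataFrame]:
    """Ordered multi-group bundle with pairwise adjusted-p matrices.

    Stage order is taken from ``stage_order`` (not sorted lexically).
    Stages with zero enhancers are dropped and reported in the summaries
    frame's absence.
    """
    if len(stage_order) < 2:
        raise ValueError("need at least two ordered stages")
    present = {e.group for e in enhancers}
    stages = [s for s in stage_order if s in present]
    dropped = [s for s in stage_order if s not in present]
    if dropped:
        logger.warning("stages with zero enhancers dropped: %s", dropped)
    motifs, cutoff_table = _calibrate_groups(
        {g: pwms_by_group[g] for g in stages}, background, percentile, strands
    )
    profiles, hits, unprofiled = profile_cohort(
        enhancers, motifs, strands=strands, non_overlapping=non_overlapping
    )
    if unprofiled:
        logger.warning("unprofiled enhancers: %s", unprofiled)
    pf = profiles_to_frame(profiles)
    summaries = _summaries_frame(pf, stages)
    matrices = {}
    comparison_rows = []
    for metric in ("length_bp", "normalized_sites"):
        results, excluded = pairwise_comparisons(pf, metric, stages)
        if excluded:
            logger.warning("metric %s: groups excluded (no values): %s", metric, excluded)
        matrices[metric] = pairwise_matrix(results, stages)
        comparison_rows.append(comparisons_to_frame(results))
    bundle = {
        "profiles": pf,
        "hits": hits_to_frame(hits),
        "cutoffs": cutoff_table,
        "summaries": summaries,
        "comparisons": pd.concat(comparison_rows, ignore_index=True),
        "matrix_length_bp": matrices["length_bp"],
        "matrix_normalized_sites": matrices["normalized_sites"],
    }
    return bundle


def _summaries_frame(profiles: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    rows = []
    for g in groups:
        sub = profiles[profiles["group"] == g]
        for metric in METRICS:
            vals = sub[metric].dropna()
            if vals.empty:
                continue
            s = group_summary(vals.tolist(), g)
            rows.append(
                {
                    "group": g, "metric": metric, "n": s.n, "median": s.median,
                    "q1": s.q1, "q3": s.q3, "whisker_low": s.whisker_low,
                    "whisker_high": s.whisker_high, "n_outliers": len(s.outliers),
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(config: RunConfig):
    background = config.background_model()
    enhancers = eio.read_enhancers(config.enhancers_fasta, config.groups_tsv)
    pwms_by_group = {
        label: eio.read_motif_set(
            path, background, config.pseudocount_total,
            overrides=config.overrides.get(label),
        )
        for label, path in config.motif_dirs.items()
    }
    return enhancers, pwms_by_group, background


def _write_bundle(bundle: Mapping[str, pd.DataFrame], out_dir: Path, config: RunConfig,
                  kind: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, frame in bundle.items():
        frame.to_csv(out_dir / f"{name}.tsv", sep="\t",
                     index=name.startswith("matrix_"))
    eio.write_manifest(
        out_dir / "manifest.json",
        analysis=kind,
        parameters={
            "percentile": config.percentile,
            "strands": config.strands,
            "pseudocount_total": config.pseudocount_total,
            "genome_size": config.genome_size,
            "non_overlapping": config.non_overlapping,
            "seed": config.seed,
        },
        inputs={
            "enhancers_fasta": config.enhancers_fasta,
            "groups_tsv": config.groups_tsv,
            "motif_dirs": dict(config.motif_dirs),
        },
        counts={
            "n_profiles": int(len(bundle["profiles"])),
            "n_hits": int(len(bundle["hits"])),
        },
    )


def run_axis_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """File-based two-group analysis; writes the bundle + manifest to output_dir."""
    enhancers, pwms_by_group, background = _load_inputs(config)
    bundle = axis_analysis(
        enhancers, pwms_by_group, background,
        percentile=config.percentile, strands=config.strands,
        non_overlapping=config.non_overlapping,
    )
    _write_bundle(bundle, Path(config.output_dir), config, "axis")
    return bundle


def run_stage_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """File-based ordered-stage analysis; writes the bundle + manifest."""
    if not config.stage_order:
        raise ValueError("stage analysis requires config.stage_order")
    enhancers, pwms_by_group, background = _load_inputs(config)
    bundle = stage_analysis(
        enhancers, pwms_by_group, background, stage_order=list(config.stage_order),
        percentile=config.percentile, strands=config.strands,
        non_overlapping=config.non_overlapping,
    )
    _write_bundle(bundle, Path(config.output_dir), config, "stage")
    return bundle
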