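"""Synthetic enhancer cohorts with planted binding sites.

Everything the pipeline consumes can be generated here: PWMs annealed to a
target information content (with training alignments sampled from them),
i.i.d. background sequence of specified composition, and multi-group
enhancer cohorts with log-normally distributed lengths and Poisson numbers
of planted sites drawn from the group's motif panel.  Ground-truth planted
site tables are first-class outputs so that downstream recovery rates are
measured against the generator, never against literature values.

The default two-group cohort emulates the axis-patterning setting: a
complex-task group of 60 enhancers (median length 1300 bp, ~47 planted
sites, 24-motif panel) and a simpler-task group of 39 enhancers (median
800 bp, ~9 sites, 10-motif panel).  The default six-stage cohort has
monotonically decreasing median lengths, emulating the developmental-time
trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .motif import BASES, BackgroundModel, Pwm, information_content
from .scan import EnhancerRecord

__all__ = [
    "PwmSpec",
    "GroupSpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_pwm",
    "generate_background",
    "generate_enhancer",
    "generate_cohort",
    "ap_dv_spec",
    "stage_spec",
]


@dataclass(frozen=True)
class PwmSpec:
    name: str
    width: int
    target_information: float  # bits


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_enhancers: int
    median_length: float          # bp, log-normal median
    length_log_sd: float          # SD of log-length
    mean_sites: float             # Poisson mean of planted sites per enhancer
    motif_panel: tuple[PwmSpec, ...]


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    background: BackgroundModel
    seed: int

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.n_enhancers < 1 or g.median_length <= 0 or g.length_log_sd < 0:
                raise ValueError(f"invalid group spec {g.label!r}")
            if g.mean_sites < 0 or not g.motif_panel:
                raise ValueError(f"invalid group spec {g.label!r}")


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    enhancers: list[EnhancerRecord]
    pwms_by_group: dict[str, list[Pwm]]
    truth: pd.DataFrame  # columns: enhancer_id, group, tf_name, offset, strand, site


def _max_information(width: int, background: BackgroundModel) -> float:
    # supremum of I for this width: one deterministic base per column,
    # choosing the rarest background base
    return float(width * -np.log2(background.q.min()))


def generate_pwm(
    width: int,
    target_I: float,
    background: BackgroundModel,
    seed: int | np.random.Generator,
    name: str = "synthetic",
    n_training: int = 50,
) -> Pwm:
    """PWM with information content within 0.1 bits of ``target_I``.

    Each column is a mixture f(b) = x*1[b = consensus] + (1-x)*q(b) with a
    randomly chosen consensus base; the single mixing weight x is tuned by
    bisection (information content is continuous and increasing in x).
    ``n_training`` training sequences are sampled from the PWM and attached,
    so the motif can be cutoff-calibrated like a real one.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target_I < 0:
        raise ValueError("target information content must be non-negative")
    max_I = _max_information(width, background)
    if target_I > max_I + 1e-9:
        raise ValueError(
            f"target {target_I} bits infeasible for width {width} (max {max_I:.2f})"
        )
    consensus = rng.integers(0, 4, size=width)
    q = background.q

    def freqs_at(x: float) -> np.ndarray:
        f = np.tile(q, (width, 1)) * (1.0 - x)
        f[np.arange(width), consensus] += x
        return f

    def info_at(x: float) -> float:
        f = freqs_at(x)
        return float(np.sum(f * np.log2(f / q)))

    lo, hi = 0.0, 1.0 - 1e-12
    if target_I >= info_at(hi):
        x = hi
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if info_at(mid) < target_I:
                lo = mid
            else:
                hi = mid
        x = 0.5 * (lo + hi)
    pwm = Pwm(name=name, freqs=freqs_at(x))
    training = tuple(sample_site(pwm, rng) for _ in range(n_training))
    realized = information_content(pwm, BackgroundModel(q=q, N=background.N))
    if abs(realized - min(target_I, info_at(1.0 - 1e-12))) > 0.1:
        raise AssertionError("annealing failed to reach target information content")
    return Pwm(name=name, freqs=pwm.freqs, training_alignment=training)


def sample_site(pwm: Pwm, rng: np.random.Generator) -> str:
    """One binding sequence sampled column-wise from the PWM frequencies."""
    cum = np.cumsum(pwm.freqs, axis=1)
    u = rng.random(pwm.width)
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(BASES[i] for i in idx)


def generate_background(length: int, q, seed: int | np.random.Generator) -> str:
    """i.i.d. background sequence of the given base composition."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = np.asarray(q, dtype=float)
    codes = rng.choice(4, size=length, p=q / q.sum())
    return "".join(BASES[i] for i in codes)


def generate_enhancer(
    length: int,
    motif_panel: Sequence[Pwm],
    n_sites: int,
    background: BackgroundModel,
    seed: int | np.random.Generator,
    enhancer_id: str = "enh",
    group: str = "synthetic",
) -> tuple[EnhancerRecord, pd.DataFrame]:
    """Background sequence with ``n_sites`` non-overlapping planted sites.

    Motifs are drawn uniformly from the panel, site sequences are sampled
    from the PWM columns, strands uniformly.  Placement is exactly uniform
    over non-overlapping arrangements (gap decomposition of the free
    space).  Raises on infeasible packing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = [motif_panel[i] for i in rng.integers(0, len(motif_panel), size=n_sites)]
    widths = [p.width for p in chosen]
    free = length - sum(widths)
    if free < 0:
        raise ValueError(
            f"cannot pack {n_sites} sites of total width {sum(widths)} into {length} bp"
        )
    seq = list(generate_background(length, background.q, rng))
    # uniform non-overlapping placement: split free space into n_sites+1 gaps
    cuts = np.sort(rng.integers(0, free + 1, size=n_sites)) if n_sites else np.array([], int)
    order = rng.permutation(n_sites)
    rows = []
    pos = 0
    prev_cut = 0
    for rank, j in enumerate(order):
        gap = int(cuts[rank] - prev_cut)
        prev_cut = int(cuts[rank])
        pos += gap
        pwm = chosen[j]
        site = sample_site(pwm, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = site if strand == "+" else _revcomp(site)
        seq[pos : pos + pwm.width] = placed
        rows.append(
            {
                "enhancer_id": enhancer_id,
                "group": group,
                "tf_name": pwm.name,
                "offset": pos,
                "strand": strand,
                "site": site,
            }
        )
        pos += pwm.width
    record = EnhancerRecord(id=enhancer_id, sequence="".join(seq), group=group)
    truth = pd.DataFrame(
        rows, columns=["enhancer_id", "group", "tf_name", "offset", "strand", "site"]
    )
    return record, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate every file/object a pipeline run needs, reproducibly from the seed.

    Returns the in-memory cohort; when ``out_dir`` is given also writes
    enhancers FASTA, groups TSV, per-group motif matrices with training
    alignments, background composition YAML, and the planted-site truth
    table TSV.
    """
    rng = np.random.default_rng(spec.seed)
    pwms_by_group: dict[str, list[Pwm]] = {}
    enhancers: list[EnhancerRecord] = []
    truth_frames: list[pd.DataFrame] = []
    for g in spec.groups:
        panel = [
            generate_pwm(ps.width, ps.target_information, spec.background, rng, name=ps.name)
            for ps in g.motif_panel
        ]
        pwms_by_group[g.label] = panel
        max_w = max(p.width for p in panel)
        for i in range(g.n_enhancers):
            length = int(round(g.median_length * np.exp(rng.normal(0.0, g.length_log_sd))))
            n_sites = int(rng.poisson(g.mean_sites))
            # keep packing feasible for extreme draws
            min_len = max(max_w, n_sites * max_w + 1)
            length = max(length, min_len)
            rec, truth = generate_enhancer(
                length, panel, n_sites, spec.background, rng,
                enhancer_id=f"{g.label}_{i:04d}", group=g.label,
            )
            enhancers.append(rec)
            truth_frames.append(truth)
    truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=["enhancer_id", "group", "tf_name", "offset", "strand", "site"])
    )
    cohort = SyntheticCohort(spec=spec, enhancers=enhancers, pwms_by_group=pwms_by_group, truth=truth)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    from . import io as eio

    out_dir.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(out_dir / "enhancers.fasta", {e.id: e.sequence for e in cohort.enhancers})
    with open(out_dir / "groups.tsv", "w") as fh:
        fh.write("id\tgroup\n")
        for e in cohort.enhancers:
            fh.write(f"{e.id}\t{e.group}\n")
    motif_dir = out_dir / "motifs"
    motif_dir.mkdir(exist_ok=True)
    for label, panel in cohort.pwms_by_group.items():
        for pwm in panel:
            stem = f"{label}__{pwm.name}"
            eio.write_pwm(motif_dir / f"{stem}.pwm", pwm)
            if pwm.training_alignment:
                eio.write_fasta(
                    motif_dir / f"{stem}.fasta",
                    {f"site_{i}": s for i, s in enumerate(pwm.training_alignment)},
                )
    cohort.truth.to_csv(out_dir / "planted_sites.tsv", sep="\t", index=False)
    q = cohort.spec.background.q
    with open(out_dir / "background.yaml", "w") as fh:
        fh.write(f"seed: {cohort.spec.seed}\n")
        fh.write("composition:\n")
        for b, v in zip(BASES, q):
            fh.write(f"  {b}: {v}\n")
        fh.write(f"genome_size: {cohort.spec.background.N}\n")


def _default_panel(prefix: str, n: int, widths, contents) -> tuple[PwmSpec, ...]:
    return tuple(
        PwmSpec(name=f"{prefix}{i}", width=int(widths[i % len(widths)]),
                target_information=float(contents[i % len(contents)]))
        for i in range(n)
    )


def ap_dv_spec(seed: int, background: BackgroundModel | None = None) -> CohortSpec:
    """Two-group cohort emulating the axis-patterning comparison.

    Group A ("AP"-like, complex task): 60 enhancers, median length 1300 bp,
    ~47 planted sites each, 24-motif panel.  Group B ("DV"-like, simpler
    task): 39 enhancers, median 800 bp, ~9 sites, 10-motif panel.  Motif
    information contents span 8-14 bits in both panels.
    """
    bg = background or BackgroundModel.uniform()
    contents = (8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0)
    widths = (8, 9, 10, 11, 12)
    return CohortSpec(
        groups=(
            GroupSpec("A", 60, 1300.0, 0.35, 47.0, _default_panel("tfA", 24, widths, contents)),
            GroupSpec("B", 39, 800.0, 0.35, 9.0, _default_panel("tfB", 10, widths, contents)),
        ),
        background=bg,
        seed=seed,
    )


def stage_spec(
    seed: int,
    background: BackgroundModel | None = None,
    n_per_stage: int = 30,
) -> CohortSpec:
    """Six-stage cohort with monotonically decreasing median enhancer length."""
    bg = background or BackgroundModel.uniform()
    stages = ["4-6", "7-8", "9-10", "11-12", "13-14", "15-16"]
    medians = [1400.0, 1250.0, 1100.0, 950.0, 800.0, 650.0]
    mean_sites = [30.0, 26.0, 22.0, 18.0, 14.0, 10.0]
    contents = (9.0, 10.5, 12.0, 13.5)
    widths = (8, 10, 12)
    groups = tuple(
        GroupSpec(stages[i], n_per_stage, medians[i], 0.3, mean_sites[i],
                  _default_panel(f"tfS{i}_", 8, widths, contents))
        for i in range(6)
    )
    return CohortSpec(groups=groups, background=bg, seed=seed)
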