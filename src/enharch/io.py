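"""File formats: FASTA, PWM matrix dialects, group labels, BED and TSV output.

Two PWM matrix dialects are read: a simple whitespace-delimited layout with
one labelled row per base (``A  1 2 0 ...``), and a JASPAR-style variant
(``>name`` header, rows like ``A [ 1 2 0 ... ]``).  Training alignments are
FASTA files matched to the matrix file by stem.  Enhancers come as FASTA
with a two-column (id, group) TSV, optionally with BED intervals.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif import BASES, BackgroundModel, Pwm, build_pwm
from .scan import ArchitectureProfile, BindingSiteHit, EnhancerRecord

logger = logging.getLogger("enharch")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_enhancers",
    "read_pwm_file",
    "write_pwm",
    "read_motif_set",
    "write_hits_bed",
    "write_hits_tsv",
    "write_profiles_tsv",
    "read_profiles_tsv",
]


def read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no records in FASTA {path}")
    return records


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_groups_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "group"], dtype=str)
    if df.iloc[0, 0] == "id" and df.iloc[0, 1] == "group":
        df = df.iloc[1:]
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"duplicate ids in groups TSV: {dups}")
    return dict(zip(df["id"], df["group"]))


def read_bed(path) -> dict[str, tuple[str, int, int]]:
    """Minimal BED reader: name (column 4) -> (chrom, start, end)."""
    out: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line lacks a name column: {line!r}")
            out[parts[3]] = (parts[0], int(parts[1]), int(parts[2]))
    return out


def read_enhancers(fasta_path, groups_tsv, bed_path=None) -> list[EnhancerRecord]:
    """Enhancer records with group labels (and optional genomic intervals).

    FASTA ids must all appear in the groups TSV; offenders are listed in
    the error.  Sequences are uppercased.
    """
    seqs = read_fasta(fasta_path)
    groups = read_groups_tsv(groups_tsv)
    missing = sorted(set(seqs) - set(groups))
    if missing:
        raise ValueError(f"enhancers missing a group label: {missing}")
    intervals = read_bed(bed_path) if bed_path else {}
    return [
        EnhancerRecord(id=name, sequence=seq, group=groups[name],
                       interval=intervals.get(name))
        for name, seq in seqs.items()
    ]


_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*\[([^\]]*)\]")


def read_pwm_file(path) -> tuple[str, np.ndarray]:
    """Parse a count matrix file; returns (name, counts with shape (L, 4)).

    Accepts the simple labelled-row dialect and the JASPAR bracket dialect;
    the name comes from a ``>`` header when present, otherwise the file
    stem.
    """
    path = Path(path)
    name = path.stem
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            m = _JASPAR_ROW.match(line)
            if m:
                rows[m.group(1).upper()] = [float(x) for x in m.group(2).split()]
                continue
            parts = line.replace("|", " ").replace(":", " ").split()
            if parts and parts[0].upper() in BASES and len(parts) > 1:
                rows[parts[0].upper()] = [float(x) for x in parts[1:]]
    if set(rows) != set(BASES):
        raise ValueError(f"{path}: expected one row per base A/C/G/T, found {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: base rows have unequal lengths {lengths}")
    counts = np.array([rows[b] for b in BASES], dtype=float).T  # (L, 4)
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative matrix entries")
    return name, counts


def write_pwm(path, pwm: Pwm, scale: float = 100.0) -> None:
    """Write the simple labelled-row dialect (frequencies x scale)."""
    mat = pwm.freqs.T * scale  # (4, L)
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for b, row in zip(BASES, mat):
            fh.write(b + "  " + "  ".join(f"{v:.6g}" for v in row) + "\n")


def _find_alignment(matrix_path: Path) -> Path | None:
    for suffix in (".fasta", ".fa", ".sites.fasta"):
        cand = matrix_path.with_suffix(suffix)
        if cand.exists():
            return cand
    return None


def read_motif_set(
    motif_dir,
    background: BackgroundModel,
    pseudocount_total: float = 0.01,
    overrides: Mapping[str, str] | None = None,
) -> list[Pwm]:
    """Load every matrix in a directory, one PWM per TF.

    TF name = the part of the file stem after a ``group__`` prefix if one is
    present, else the stem (or the ``>`` header name).  When several
    matrices share a TF name, the one with the largest training alignment
    wins; an ``overrides`` map of tf_name -> filename pins a specific file
    instead (logged either way).
    """
    motif_dir = Path(motif_dir)
    matrix_files = sorted(
        p for p in motif_dir.iterdir()
        if p.suffix in (".pwm", ".txt", ".jaspar", ".pfm", ".mat")
    )
    if not matrix_files:
        raise ValueError(f"no motif matrix files in {motif_dir}")
    overrides = dict(overrides or {})
    candidates: dict[str, list[tuple[Path, Pwm]]] = {}
    for path in matrix_files:
        name, counts = read_pwm_file(path)
        aln_path = _find_alignment(path)
        training = None
        if aln_path is not None:
            training = list(read_fasta(aln_path).values())
            if training and len(training[0]) < counts.shape[0] and all(
                len(s) < counts.shape[0] for s in training
            ):
                raise ValueError(
                    f"{aln_path}: every alignment sequence is shorter than matrix width"
                )
        pwm = build_pwm(counts, background, pseudocount_total, name=name,
                        training_alignment=training)
        candidates.setdefault(name, []).append((path, pwm))
    selected: list[Pwm] = []
    for name, options in sorted(candidates.items()):
        if name in overrides:
            pinned = [(p, w) for p, w in options if p.name == overrides[name]]
            if not pinned:
                raise ValueError(
                    f"override for {name!r} names {overrides[name]!r}, not found"
                )
            path, pwm = pinned[0]
            logger.info("motif %s: pinned to %s by override", name, path.name)
        else:
            path, pwm = max(
                options, key=lambda pw: len(pw[1].training_alignment or ())
            )
            if len(options) > 1:
                logger.info(
                    "motif %s: selected %s (largest training alignment, %d seqs) "
                    "from %d candidates",
                    name, path.name, len(pwm.training_alignment or ()), len(options),
                )
        selected.append(pwm)
    return selected


def write_hits_bed(path, hits: Sequence[BindingSiteHit],
                   enhancers: Mapping[str, EnhancerRecord] | None = None,
                   widths: Mapping[str, int] | None = None) -> None:
    """BED6: chrom = enhancer id (or genomic chrom when intervals known),
    name = tf_name, score = round(100 * bits)."""
    with open(path, "w") as fh:
        for h in hits:
            chrom, base = h.enhancer_id, 0
            if enhancers is not None:
                rec = enhancers.get(h.enhancer_id)
                if rec is not None and rec.interval is not None:
                    chrom, base, _ = rec.interval
            width = (widths or {}).get(h.tf_name, 0)
            end = base + h.offset + width if width else base + h.offset + 1
            fh.write(
                f"{chrom}\t{base + h.offset}\t{end}\t{h.tf_name}\t"
                f"{round(100 * h.score)}\t{h.strand}\n"
            )


def write_hits_tsv(path, hits: Sequence[BindingSiteHit]) -> None:
    from .scan import hits_to_frame

    hits_to_frame(list(hits)).to_csv(path, sep="\t", index=False)


def write_profiles_tsv(path, profiles: Sequence[ArchitectureProfile]) -> None:
    from .scan import profiles_to_frame

    profiles_to_frame(list(profiles)).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, **fields) -> None:
    from importlib.metadata import version

    try:
        pkg_version = version("enharch")
    except Exception:
        pkg_version = "unknown"
    payload = {"package": "enharch", "version": pkg_version, **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
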