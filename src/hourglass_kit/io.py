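"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic coordinates are 0-based half-open (BED convention) internally.
Writers are deterministic: stable row order and floats formatted with six
significant digits, so outputs diff cleanly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .ocr import PWM, PeakSet

FLOAT_FMT = "%.6g"


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return FLOAT_FMT % v
    return str(v)


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Deterministic TSV writer (6 significant digits, optional # header)."""
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ (optionally name, score, strand, summit columns).

    Raises with the offending line number on malformed records.
    """
    names = ["chrom", "start", "end", "name", "score", "strand", "summit"]
    rows = []
    ncols = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line with fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: invalid interval [{start},{end})")
            if ncols is None:
                ncols = len(parts)
            rows.append(parts[:7])
    df = pd.DataFrame(rows, columns=names[: ncols or 3])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "summit" in df.columns:
        df["summit"] = df["summit"].astype(int)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand", "summit"] if c in df.columns]
    out = df[cols].sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for row in out.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_peaks(path, sample: str = "", stage: str = "") -> PeakSet:
    return PeakSet(read_bed(path), sample=sample, stage=stage)


OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_outfmt6(path, subject_species: str) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file into a hit table.

    Only query id, subject id, e-value and bitscore are consumed; the
    subject species comes from the caller's per-file tag, never from ids.
    """
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    if df[["qseqid", "sseqid", "evalue", "bitscore"]].isna().any().any():
        raise ValueError(f"{path}: malformed outfmt6 records")
    return pd.DataFrame(
        {
            "query": df["qseqid"],
            "subject_species": subject_species,
            "subject": df["sseqid"],
            "bitscore": df["bitscore"].astype(float),
            "evalue": df["evalue"].astype(float),
        }
    )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>size'")
            size = int(parts[1])
            if size <= 0:
                raise ValueError(f"{path}:{ln}: non-positive chromosome size")
            sizes[parts[0]] = size
    if not sizes:
        raise ValueError(f"{path}: empty chrom.sizes")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sorted(sizes.items()):
            fh.write(f"{chrom}\t{size}\n")


def read_expression_tsv(path, species: str = "") -> ExpressionMatrix:
    """Read a long-format expression TSV (gene, stage, replicate, tpm)."""
    df = read_tsv(path)
    return ExpressionMatrix.from_long(species or Path(path).stem, df)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    write_tsv(m.to_long(), path)


def write_wide_summary(m: ExpressionMatrix, path) -> None:
    """Gene x stage mean/SEM summary table."""
    mean = m.mean_tpm.add_prefix("mean_")
    sem = m.sem_tpm.add_prefix("sem_")
    out = pd.concat([mean, sem], axis=1).reset_index(names="gene")
    write_tsv(out, path)


def read_pwm(path) -> PWM:
    """Read a JASPAR-style PFM: an optional >header then four A/C/G/T rows.

    Count rows are normalized to per-position probabilities.
    """
    motif_id = Path(path).stem
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0]
                continue
            base = line[0].upper()
            if base not in "ACGT":
                raise ValueError(f"{path}: unexpected PWM row {line[:20]!r}")
            nums = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in nums.split()]
    if set(rows) != set("ACGT"):
        raise ValueError(f"{path}: PWM must have A, C, G and T rows")
    mat = np.array([rows["A"], rows["C"], rows["G"], rows["T"]], dtype=float).T
    total = mat.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError(f"{path}: PWM position with zero total weight")
    return PWM(motif_id=motif_id, probs=mat / total)


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.motif_id}\n")
        for k, base in enumerate("ACGT"):
            vals = " ".join(FLOAT_FMT % v for v in pwm.probs[:, k])
            fh.write(f"{base} [ {vals} ]\n")


def write_distance_matrix(values: pd.DataFrame, metric: str, path) -> None:
    out = values.reset_index(names="stage_a")
    write_tsv(out, path, header_comment=f"metric={metric}")
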