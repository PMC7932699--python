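"""Replicate aggregation, expression filtering, scaling and heterochrony detection.

The comparison of developmental gene expression between distantly related
species works on per-gene stage profiles of TPM (transcripts per million).
Replicate TPMs are aggregated to per-stage means, genes that never reach a
minimal TPM are discarded, and the remaining profiles are scaled per gene and
per species before any cross-species distance is computed.  Four scalings are
supported:

* ``max1``    — divide by the per-gene maximum over stages (peak = 1),
* ``zscore``  — standardize against the per-gene stage mean/sd,
* ``unitvec`` — divide by the per-gene Euclidean norm over stages,
* ``log10``   — log10(x + 1).

Heterochronic genes (an evolutionary shift in expression timing) are called
from the Pearson correlation between a gene's mean TPM profile and the stage
rank, separately in each species, with opposite signs required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCALING_METHODS = ("max1", "zscore", "unitvec", "log10")


def _as_pair_list(pairs) -> list[tuple[str, str]]:
    """Coerce an orthology map or an iterable of 2-tuples to a pair list."""
    if hasattr(pairs, "pairs"):  # OrthologyMap
        df = pairs.pairs
        return list(zip(df["gene_a"], df["gene_b"]))
    return [(a, b) for a, b in pairs]


@dataclass
class ExpressionMatrix:
    """Gene x stage expression summary for one species.

    ``replicate_tpm`` has shape (n_genes, n_stages, n_replicates); ``mean_tpm``
    is its arithmetic mean over replicates and ``sem_tpm`` the standard error
    (sample sd, ddof=1, divided by sqrt(n)).
    """

    species: str
    genes: pd.Index
    stages: list[str]
    replicate_tpm: np.ndarray
    mean_tpm: pd.DataFrame = field(init=False)
    sem_tpm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.stages = list(self.stages)
        if len(self.stages) == 0:
            raise ValueError("stage list must be non-empty")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage names")
        x = np.asarray(self.replicate_tpm, dtype=float)
        if x.ndim != 3:
            raise ValueError("replicate_tpm must be gene x stage x replicate")
        if x.shape[2] == 0:
            raise ValueError("empty replicate set")
        if x.shape[:2] != (len(self.genes), len(self.stages)):
            raise ValueError("replicate_tpm shape does not match genes/stages")
        if np.any(x < 0) or not np.all(np.isfinite(x)):
            raise ValueError("TPM values must be finite and non-negative")
        self.replicate_tpm = x
        self.mean_tpm = pd.DataFrame(
            x.mean(axis=2), index=self.genes, columns=self.stages
        )
        n = x.shape[2]
        sd = x.std(axis=2, ddof=1) if n > 1 else np.zeros(x.shape[:2])
        self.sem_tpm = pd.DataFrame(
            sd / np.sqrt(n), index=self.genes, columns=self.stages
        )

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def n_replicates(self) -> int:
        return self.replicate_tpm.shape[2]

    @classmethod
    def from_long(cls, species: str, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a long table with columns gene, stage, replicate, tpm.

        Stage order follows first appearance; replicate labels are sorted.
        """
        required = {"gene", "stage", "replicate", "tpm"}
        if not required.issubset(df.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        stages = list(pd.unique(df["stage"]))
        genes = pd.Index(pd.unique(df["gene"]))
        reps = sorted(pd.unique(df["replicate"]))
        cube = np.full((len(genes), len(stages), len(reps)), np.nan)
        gi = {g: i for i, g in enumerate(genes)}
        si = {s: i for i, s in enumerate(stages)}
        ri = {r: i for i, r in enumerate(reps)}
        for row in df.itertuples(index=False):
            cube[gi[row.gene], si[row.stage], ri[row.replicate]] = row.tpm
        if np.isnan(cube).any():
            raise ValueError("long table is not a complete gene x stage x replicate grid")
        return cls(species=species, genes=genes, stages=stages, replicate_tpm=cube)

    def to_long(self) -> pd.DataFrame:
        recs = []
        for i, g in enumerate(self.genes):
            for j, s in enumerate(self.stages):
                for r in range(self.n_replicates):
                    recs.append((g, s, r + 1, self.replicate_tpm[i, j, r]))
        return pd.DataFrame(recs, columns=["gene", "stage", "replicate", "tpm"])

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(list(genes))
        if np.any(idx < 0):
            raise KeyError("unknown gene in subset")
        return ExpressionMatrix(
            species=self.species,
            genes=pd.Index(list(genes)),
            stages=self.stages,
            replicate_tpm=self.replicate_tpm[idx],
        )


@dataclass
class ScaledMatrix:
    """Gene x stage values under one scaling method."""

    method: str
    values: pd.DataFrame
    species: str = ""

    def __post_init__(self) -> None:
        if self.method not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def aggregate(
    transcript_tpm: pd.DataFrame, tx2gene: Mapping[str, str]
) -> tuple[dict, pd.DataFrame]:
    """Sum transcript-level TPMs (splice variants) into per-gene TPMs.

    ``transcript_tpm`` is long format (transcript, stage, replicate, tpm).
    Returns ``(matrices_by_species_free_long, unmapped_report)`` where the
    first element is the gene-level long DataFrame; transcripts without a
    gene mapping are excluded and reported.
    """
    required = {"transcript", "stage", "replicate", "tpm"}
    if not required.issubset(transcript_tpm.columns):
        raise ValueError(f"transcript table needs columns {sorted(required)}")
    df = transcript_tpm.copy()
    df["gene"] = df["transcript"].map(lambda t: tx2gene.get(t))
    unmapped = df.loc[df["gene"].isna(), "transcript"].unique()
    df = df.dropna(subset=["gene"])
    if df.empty:
        raise ValueError("no transcript mapped to a gene")
    gene_long = (
        df.groupby(["gene", "stage", "replicate"], sort=False)["tpm"]
        .sum()
        .reset_index()
    )
    report = pd.DataFrame({"transcript": sorted(unmapped)})
    return gene_long, report


def aggregate_to_matrix(
    species: str, transcript_tpm: pd.DataFrame, tx2gene: Mapping[str, str]
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Convenience: :func:`aggregate` followed by matrix construction."""
    gene_long, report = aggregate(transcript_tpm, tx2gene)
    return ExpressionMatrix.from_long(species, gene_long), report


def filter_expressed(m: ExpressionMatrix, min_max_tpm: float = 1.0) -> pd.Index:
    """Genes whose maximal stage-mean TPM reaches ``min_max_tpm`` (inclusive).

    Genes below the floor at every stage are considered not expressed.
    """
    keep = m.mean_tpm.max(axis=1) >= min_max_tpm
    return m.genes[keep.to_numpy()]


def scale_values(values: pd.DataFrame, method: str, ddof: int = 0) -> pd.DataFrame:
    """Scale a gene x stage table per gene. See :func:`scale`."""
    x = values.to_numpy(dtype=float)
    if method == "max1":
        mx = x.max(axis=1)
        if np.any(mx <= 0):
            bad = values.index[mx <= 0][:5].tolist()
            raise ValueError(f"max1 undefined for all-zero genes, e.g. {bad}")
        out = x / mx[:, None]
    elif method == "zscore":
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=ddof)
        if np.any(sd == 0):
            bad = values.index[sd == 0][:5].tolist()
            raise ValueError(f"zscore undefined for zero-variance genes, e.g. {bad}")
        out = (x - mu[:, None]) / sd[:, None]
    elif method == "unitvec":
        nrm = np.linalg.norm(x, axis=1)
        if np.any(nrm == 0):
            bad = values.index[nrm == 0][:5].tolist()
            raise ValueError(f"unitvec undefined for all-zero genes, e.g. {bad}")
        out = x / nrm[:, None]
    elif method == "log10":
        if np.any(x < 0):
            raise ValueError("log10 scaling requires non-negative values")
        out = np.log10(x + 1.0)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def scale(m: ExpressionMatrix, method: str, ddof: int = 0) -> ScaledMatrix:
    """Per-gene scaling of the stage-mean TPM profile of one species.

    ``ddof=0`` (population sd) is the default z-score convention here; the
    replicate SEM in :class:`ExpressionMatrix` uses sample sd instead.
    """
    vals = scale_values(m.mean_tpm, method, ddof=ddof)
    return ScaledMatrix(method=method, values=vals, species=m.species)


def stage_rank_pcc(m: ExpressionMatrix) -> pd.Series:
    """Pearson correlation of each gene's mean TPM with the stage rank 1..T.

    Zero-variance profiles yield NaN (correlation undefined).
    """
    x = m.mean_tpm.to_numpy(dtype=float)
    ranks = np.arange(1, m.n_stages + 1, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    rc = ranks - ranks.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (xc @ rc) / denom
    pcc[denom == 0] = np.nan
    return pd.Series(pcc, index=m.genes, name="pcc")


def detect_heterochronic(
    ma: ExpressionMatrix,
    mb: ExpressionMatrix,
    pairs,
    thr: float = 0.5,
    direction: str = "a_up",
) -> pd.DataFrame:
    """List ortholog pairs with opposite stage trends in the two species.

    A pair qualifies when PCC against stage rank exceeds ``thr`` in one
    species and falls below ``-thr`` in the other.  ``direction`` selects
    which species rises: ``"a_up"``, ``"b_up"`` or ``"both"``.  Pairs with an
    undefined PCC (flat profile) are skipped.
    """
    if ma.n_stages < 3 or mb.n_stages < 3:
        raise ValueError("need at least 3 stages per species for stage PCC")
    if direction not in ("a_up", "b_up", "both"):
        raise ValueError("direction must be a_up, b_up or both")
    pcc_a = stage_rank_pcc(ma)
    pcc_b = stage_rank_pcc(mb)
    rows = []
    for a, b in _as_pair_list(pairs):
        if a not in pcc_a.index or b not in pcc_b.index:
            continue
        ra, rb = pcc_a[a], pcc_b[b]
        if np.isnan(ra) or np.isnan(rb):
            continue
        if ra > thr and rb < -thr and direction in ("a_up", "both"):
            rows.append((a, b, ra, rb, "a_up"))
        elif rb > thr and ra < -thr and direction in ("b_up", "both"):
            rows.append((a, b, ra, rb, "b_up"))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "pcc_a", "pcc_b", "direction"]
    )


def _rank_grid(n: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def interspecific_gene_distance(
    profile_a: np.ndarray, profile_b: np.ndarray
) -> float:
    """Euclidean distance between one gene's scaled profiles in two species.

    When stage counts differ the longer profile is linearly interpolated onto
    the shorter one's normalized stage-rank grid, so the two vectors compare
    like with like without asserting a biological stage matching.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.size != b.size:
        if a.size > b.size:
            a = np.interp(_rank_grid(b.size), _rank_grid(a.size), a)
        else:
            b = np.interp(_rank_grid(a.size), _rank_grid(b.size), b)
    return float(np.linalg.norm(a - b))


def sensitivity_ratio(
    ma: ExpressionMatrix,
    mb: ExpressionMatrix,
    pairs,
    housekeeping: Iterable[str],
    heterochronic: Iterable[str],
    method: str,
    ddof: int = 0,
) -> float:
    """Heterochronic-to-housekeeping ratio of interspecific distances.

    Scales both species with ``method``, computes the per-gene interspecific
    Euclidean distance, and returns mean(distance over heterochronic genes) /
    mean(distance over housekeeping genes).  A larger ratio means the scaling
    is more sensitive to differential regulation relative to the residual
    noise of constitutively active genes.  Gene sets are given as species-A
    gene ids; orthologs are resolved through ``pairs``.
    """
    hk = set(housekeeping)
    het = set(heterochronic)
    if not hk or not het:
        raise ValueError("housekeeping and heterochronic sets must be non-empty")
    pair_map = dict(_as_pair_list(pairs))
    sa = scale(ma, method, ddof=ddof)
    sb = scale(mb, method, ddof=ddof)

    def mean_dist(genes: set[str]) -> float:
        ds = []
        for g in sorted(genes):
            if g not in pair_map:
                raise KeyError(f"gene {g!r} has no ortholog pair")
            ds.append(
                interspecific_gene_distance(
                    sa.values.loc[g].to_numpy(), sb.values.loc[pair_map[g]].to_numpy()
                )
            )
        return float(np.mean(ds))

    denom = mean_dist(hk)
    if denom == 0:
        raise ZeroDivisionError(
            "housekeeping interspecific distance is exactly 0; ratio undefined"
        )
    return mean_dist(het) / denom
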