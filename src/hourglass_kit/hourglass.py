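"""Stage-distance matrices, PCA, clustering and specificity counts.

The developmental-hourglass question — are mid-embryonic stages more
conserved between species than early or late ones? — is asked here by
computing a distance between every pair of (species-A stage, species-B stage)
expression profiles over shared orthologs, under four metrics:

* ``euclidean``      sqrt(sum_i (u_i - v_i)^2)
* ``correlation``    1 - Pearson(u, v)
* ``shannon``        -1/2 sum_i [u_i log((u_i+v_i)/(2 u_i)) + v_i log((u_i+v_i)/(2 v_i))]
                     (a generalized Jensen-Shannon divergence; natural log,
                     0 * log(.) = 0)
* ``std_euclidean``  sqrt(sum_i (u_i - v_i)^2 / V_i), V_i the per-gene
                     variance over all stage values of both species

u and v are the two stages' value vectors over the shared expressed ortholog
genes.  Supporting analytics: per-stage minimum summaries, concatenated
cross-species gene vectors, hierarchical clustering with a pluggable
embedding, stage PCA, stage-associated gene counts (TPM and |z| floors) and
Shannon-entropy tissue specificity counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .expression import ExpressionMatrix, ScaledMatrix, _as_pair_list

METRICS = ("euclidean", "correlation", "shannon", "std_euclidean")


@dataclass
class DistanceMatrix:
    """stages_a x stages_b distances over a shared ortholog gene universe."""

    values: pd.DataFrame
    metric: str
    n_genes: int


def _paired_profiles(
    sa: ScaledMatrix, sb: ScaledMatrix, pairs
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Stage x gene arrays of both species restricted to shared pairs."""
    plist = [
        (a, b)
        for a, b in _as_pair_list(pairs)
        if a in sa.values.index and b in sb.values.index
    ]
    if not plist:
        raise ValueError("no ortholog pair present in both scaled matrices")
    ga = [a for a, _ in plist]
    gb = [b for _, b in plist]
    u = sa.values.loc[ga].to_numpy(dtype=float).T  # stages_a x genes
    v = sb.values.loc[gb].to_numpy(dtype=float).T  # stages_b x genes
    return u, v, plist


def shannon_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Generalized Jensen-Shannon divergence between non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("shannon distance requires non-negative vectors")
    m = 0.5 * (u + v)
    with np.errstate(divide="ignore", invalid="ignore"):
        tu = np.where(u > 0, u * np.log(m / np.where(u > 0, u, 1.0)), 0.0)
        tv = np.where(v > 0, v * np.log(m / np.where(v > 0, v, 1.0)), 0.0)
    return float(-(tu.sum() + tv.sum()) / 2.0)


def stage_distance(
    sa: ScaledMatrix, sb: ScaledMatrix, pairs, metric: str
) -> DistanceMatrix:
    """Distance between every species-A stage and species-B stage profile."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    u, v, plist = _paired_profiles(sa, sb, pairs)
    if metric == "euclidean":
        d = cdist(u, v, "euclidean")
    elif metric == "correlation":
        if np.any(u.std(axis=1) == 0) or np.any(v.std(axis=1) == 0):
            raise ValueError("correlation distance undefined for zero-variance stage vector")
        d = cdist(u, v, "correlation")
    elif metric == "shannon":
        d = np.array([[shannon_distance(ui, vj) for vj in v] for ui in u])
    else:  # std_euclidean
        allvals = np.vstack([u, v])  # (T_a+T_b) x genes
        var = allvals.var(axis=0)  # population convention
        keep = var > 0
        if not keep.all():
            dropped = int((~keep).sum())
            import logging

            logging.getLogger(__name__).info(
                "std_euclidean: excluded %d zero-variance genes", dropped
            )
        if not keep.any():
            raise ValueError("all genes have zero variance; std_euclidean undefined")
        d = cdist(u[:, keep], v[:, keep], "seuclidean", V=var[keep])
    values = pd.DataFrame(d, index=sa.stages, columns=sb.stages)
    return DistanceMatrix(values=values, metric=metric, n_genes=len(plist))


@dataclass
class MinDistanceSummary:
    per_b_stage: pd.DataFrame  # b_stage, best_a_stage, value, ties
    global_pair: tuple[str, str]
    global_value: float
    global_ties: list[tuple[str, str]]


def min_distance_summary(d: DistanceMatrix) -> MinDistanceSummary:
    """Per-B-stage and global minimizing stage pairs; ties reported, not broken."""
    m = d.values
    if m.empty:
        raise ValueError("empty distance matrix")
    rows = []
    for b in m.columns:
        col = m[b]
        vmin = col.min()
        ties = [a for a in m.index if col[a] == vmin]
        rows.append((b, ties[0], float(vmin), ties))
    per_b = pd.DataFrame(rows, columns=["b_stage", "best_a_stage", "value", "ties"])
    gmin = float(m.to_numpy().min())
    gties = [
        (a, b) for a in m.index for b in m.columns if m.loc[a, b] == gmin
    ]
    return MinDistanceSummary(
        per_b_stage=per_b,
        global_pair=gties[0],
        global_value=gmin,
        global_ties=gties,
    )


def concat_vectors(
    sa: ScaledMatrix, sb: ScaledMatrix, pairs, missing: str = "drop"
) -> pd.DataFrame:
    """Concatenate each ortholog pair's scaled profiles (A stages then B stages).

    ``missing="drop"`` keeps only pairs scaled in both species (the distance
    universe); ``missing="zero"`` additionally includes genes present in only
    one matrix, zero-filling the other species' block (the clustering view,
    which must keep species-specific genes).
    """
    ta, tb = len(sa.stages), len(sb.stages)
    cols = [f"{sa.species or 'A'}:{s}" for s in sa.stages] + [
        f"{sb.species or 'B'}:{s}" for s in sb.stages
    ]
    plist = _as_pair_list(pairs)
    rows, idx = [], []
    paired_a = {a for a, _ in plist}
    paired_b = {b for _, b in plist}
    for a, b in plist:
        ina, inb = a in sa.values.index, b in sb.values.index
        if ina and inb:
            rows.append(
                np.concatenate([sa.values.loc[a].to_numpy(), sb.values.loc[b].to_numpy()])
            )
            idx.append(a)
        elif missing == "zero" and ina:
            rows.append(np.concatenate([sa.values.loc[a].to_numpy(), np.zeros(tb)]))
            idx.append(a)
        elif missing == "zero" and inb:
            rows.append(np.concatenate([np.zeros(ta), sb.values.loc[b].to_numpy()]))
            idx.append(a)
    if missing == "zero":
        for a in sa.values.index:
            if a not in paired_a:
                rows.append(np.concatenate([sa.values.loc[a].to_numpy(), np.zeros(tb)]))
                idx.append(a)
        for b in sb.values.index:
            if b not in paired_b:
                rows.append(np.concatenate([np.zeros(ta), sb.values.loc[b].to_numpy()]))
                idx.append(b)
    return pd.DataFrame(rows, index=idx, columns=cols)


def cluster_genes(
    vectors: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
    embedder: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.Series:
    """Ward hierarchical clustering of gene vectors, labels 1..k.

    ``embedder`` is an injected dimensionality-reduction callable (e.g. a
    fitted UMAP transform); identity when None.  Exactly one of ``k`` (number
    of clusters) or ``height`` (dendrogram cut distance) must be given.
    """
    x = vectors.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in clustering input")
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None and len(vectors) < k:
        raise ValueError("fewer vectors than clusters")
    if embedder is not None:
        x = np.asarray(embedder(x), dtype=float)
    z = linkage(x, method="ward", metric="euclidean")
    if k is not None:
        labels = fcluster(z, t=k, criterion="maxclust")
    else:
        labels = fcluster(z, t=height, criterion="distance")
    return pd.Series(labels, index=vectors.index, name="cluster")


@dataclass
class StagePCA:
    scores: pd.DataFrame  # stage observations x PCs
    loadings: pd.DataFrame  # genes x PCs
    explained_variance_ratio: np.ndarray


def pca_stages(sa: ScaledMatrix, sb: ScaledMatrix, pairs) -> StagePCA:
    """Exact PCA of stage profiles (both species' stages as observations).

    Column-centered SVD; sign convention: the largest-magnitude gene loading
    of each component is made positive.
    """
    u, v, plist = _paired_profiles(sa, sb, pairs)
    x = np.vstack([u, v])  # observations x genes
    if x.shape[0] < 2:
        raise ValueError("need at least 2 stage observations")
    xc = x - x.mean(axis=0, keepdims=True)
    uu, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign fix per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            uu[:, i] *= -1
    scores = uu * s
    with np.errstate(invalid="ignore", divide="ignore"):
        evr = s**2 / (s**2).sum() if (s**2).sum() > 0 else np.zeros_like(s)
    obs = [f"{sa.species or 'A'}:{st}" for st in sa.stages] + [
        f"{sb.species or 'B'}:{st}" for st in sb.stages
    ]
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    return StagePCA(
        scores=pd.DataFrame(scores, index=obs, columns=pcs),
        loadings=pd.DataFrame(vt.T, index=[a for a, _ in plist], columns=pcs),
        explained_variance_ratio=evr,
    )


@dataclass
class StageAssociationTable:
    zscores: pd.DataFrame  # gene x stage (NaN where sd == 0)
    counts: pd.Series  # per-stage count of stage-associated genes


def stage_associated_counts(
    m: ExpressionMatrix, tpm_min: float = 1.0, z_min: float = 1.0, ddof: int = 0
) -> StageAssociationTable:
    """Count genes per stage with mean TPM >= tpm_min and |stage z| >= z_min.

    The z-score standardizes each gene's stage profile against its own stage
    mean and sd (population sd by default); flat genes are never counted.
    """
    if m.n_stages < 2:
        raise ValueError("need at least 2 stages")
    x = m.mean_tpm.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, np.nan)
    zdf = pd.DataFrame(z, index=m.genes, columns=m.stages)
    assoc = (x >= tpm_min) & (np.abs(z) >= z_min) & (sd > 0)
    counts = pd.Series(assoc.sum(axis=0), index=m.stages, name="stage_associated")
    return StageAssociationTable(zscores=zdf, counts=counts)


@dataclass
class EntropyTable:
    probabilities: pd.DataFrame  # tissue x gene
    entropy: pd.Series  # per gene (NaN where total TPM == 0)
    n_tissues: int
    log_base: str = "natural"


def tissue_entropy(ref: pd.DataFrame) -> EntropyTable:
    """Shannon entropy of each gene's expression across a tissue panel.

    ``ref`` is tissue x gene TPM.  p_{k,i} = TPM_{k,i} / sum_k TPM_{k,i};
    H_i = -sum_k p log p with 0*log0 = 0, natural log.  Genes expressed in a
    single tissue get H = 0 (maximally specific); uniform genes get H = ln K.
    Genes with zero total TPM are flagged undefined (NaN).
    """
    x = ref.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative TPM in tissue reference")
    tot = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, x / np.where(tot > 0, tot, 1.0), np.nan)
        plogp = np.where(np.nan_to_num(p) > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    h = -plogp.sum(axis=0)
    h = np.where(tot > 0, h, np.nan)
    return EntropyTable(
        probabilities=pd.DataFrame(p, index=ref.index, columns=ref.columns),
        entropy=pd.Series(h, index=ref.columns, name="entropy"),
        n_tissues=ref.shape[0],
    )


def tissue_associated_counts(
    m: ExpressionMatrix,
    e: EntropyTable,
    tpm_min: float = 1.0,
    h_thr: float = 0.65,
    direction: str = "ge",
) -> pd.Series:
    """Per-stage count of genes passing the TPM floor and the entropy rule.

    Default follows H >= 0.65 (broadly expressed, "tissue-associated");
    ``direction="le"`` counts the specific end instead.  Genes with undefined
    entropy are never counted.
    """
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    h = e.entropy.reindex(m.genes)
    if direction == "ge":
        pass_h = h >= h_thr
    else:
        pass_h = h <= h_thr
    pass_h = pass_h.fillna(False).to_numpy()
    tpm_ok = m.mean_tpm.to_numpy(dtype=float) >= tpm_min
    counts = (tpm_ok & pass_h[:, None]).sum(axis=0)
    return pd.Series(counts, index=m.stages, name="tissue_associated")
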