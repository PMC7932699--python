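"""Top-level driver chaining the modules into the two study workflows.

``run_pipeline(cfg, workflow)`` executes either the transcriptome comparison
(orthology -> filtering/scaling -> stage distances, PCA, clustering,
heterochrony, specificity counts) or the open-chromatin analysis (binning ->
FRiP QC -> sample distances, conservation, differential bins, tissue
specificity, motif counts) on synthetic inputs generated from the config
seed.  Outputs are deterministic TSVs, each stamped with the config hash, and
a run log that echoes every threshold used.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import hourglass as hg
from . import io as hio
from . import ocr
from .config import PipelineConfig
from .expression import detect_heterochronic, filter_expressed, scale
from .orthology import assign_orthologs, summary_counts
from .synthetic import (
    ExpressionSimConfig,
    simulate_expression,
    simulate_hit_tables,
    simulate_peak_data,
)

logger = logging.getLogger("hourglass_kit.pipeline")

WORKFLOWS = ("transcriptome", "ocr")


def _setup_log(out: Path, cfg: PipelineConfig) -> logging.Handler:
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hourglass_kit")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    logger.info("config hash %s", cfg.config_hash())
    for key, val in sorted(cfg.model_dump().items()):
        logger.info("config %s = %r", key, val)
    return handler


def _synthetic_tissue_panel(
    rng: np.random.Generator, genes: pd.Index, n_tissues: int = 20
) -> pd.DataFrame:
    """Stand-in tissue x gene TPM panel (synthetic; no external download).

    Half the genes are broadly expressed (high entropy), half are restricted
    to a few tissues (low entropy).
    """
    n = len(genes)
    broad = rng.uniform(5, 50, size=(n_tissues, n))
    x = np.where(rng.uniform(size=n) < 0.5, broad, 0.0)
    specific_idx = np.where(x[0] == 0)[0]
    for j in specific_idx:
        tissues = rng.choice(n_tissues, size=rng.integers(1, 3), replace=False)
        x[tissues, j] = rng.uniform(20, 100, size=len(tissues))
    return pd.DataFrame(x, index=[f"tissue{i:02d}" for i in range(n_tissues)], columns=genes)


def run_transcriptome(cfg: PipelineConfig, out: Path) -> dict:
    tag = f"config_hash={cfg.config_hash()}"
    sim_cfg = ExpressionSimConfig(
        stages_a=cfg.stages_a, stages_b=cfg.stages_b, seed=cfg.seed
    )
    ma, mb, truth = simulate_expression(sim_cfg)
    sim = simulate_hit_tables(
        n_orthologs=len(truth.ortholog_truth),
        panel_species=["bridge1", "bridge2", "bridge3"],
        fallback_species="fallback",
        paralog_rate=0.02,
        dropout_rate=0.05,
        seed=cfg.seed + 1,
    )
    omap = assign_orthologs(
        sim.a_hits, sim.b_hits, sim.fallback_species, evalue_max=cfg.evalue_max
    )
    # translate simulated hit-table ids onto the expression gene ids
    ordered_truth = sorted(truth.ortholog_truth)
    to_expr_a = {f"a{i:05d}": pair[0] for i, pair in enumerate(ordered_truth)}
    to_expr_b = {f"b{i:05d}": pair[1] for i, pair in enumerate(ordered_truth)}
    pairs = [
        (to_expr_a[a], to_expr_b[b])
        for a, b in omap.pair_set
        if a in to_expr_a and b in to_expr_b
    ]
    logger.info("assigned %d pairs (%d unique truth pairs)", len(pairs), len(ordered_truth))

    expr_a = filter_expressed(ma, cfg.tpm_min)
    expr_b = filter_expressed(mb, cfg.tpm_min)
    sa = scale(ma.subset(expr_a), cfg.scaling_method, ddof=cfg.zscore_ddof)
    sb = scale(mb.subset(expr_b), cfg.scaling_method, ddof=cfg.zscore_ddof)

    results: dict = {"truth": truth, "orthology": omap, "pairs": pairs}
    hio.write_tsv(omap.pairs, out / "ortholog_map.tsv", tag)
    hio.write_tsv(
        summary_counts(omap).rename_axis("class").reset_index(name="count"),
        out / "orthology_summary.tsv",
        tag,
    )
    for metric in cfg.metrics:
        dm = hg.stage_distance(sa, sb, pairs, metric)
        results[f"distance_{metric}"] = dm
        hio.write_distance_matrix(dm.values, metric, out / f"distance_{metric}.tsv")
        summ = hg.min_distance_summary(dm)
        logger.info("%s global argmin %s = %.6g", metric, summ.global_pair, summ.global_value)
    pca = hg.pca_stages(sa, sb, pairs)
    results["pca"] = pca
    hio.write_tsv(pca.scores.reset_index(names="stage"), out / "pca_scores.tsv", tag)
    hio.write_tsv(
        pca.loadings.reset_index(names="gene"), out / "pca_loadings.tsv", tag
    )
    hio.write_tsv(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pca.explained_variance_ratio))],
                "explained_variance_ratio": pca.explained_variance_ratio,
            }
        ),
        out / "pca_explained_variance.tsv",
        tag,
    )
    vectors = hg.concat_vectors(sa, sb, pairs, missing="zero")
    clusters = hg.cluster_genes(vectors, k=cfg.n_clusters)
    results["clusters"] = clusters
    hio.write_tsv(clusters.rename_axis("gene").reset_index(), out / "clusters.tsv", tag)
    het = detect_heterochronic(ma.subset(expr_a), mb.subset(expr_b), pairs,
                               thr=cfg.pcc_thr, direction="both")
    results["heterochronic"] = het
    hio.write_tsv(het, out / "heterochronic_pairs.tsv", tag)
    for name, m in (("a", ma.subset(expr_a)), ("b", mb.subset(expr_b))):
        counts = hg.stage_associated_counts(m, cfg.tpm_min, cfg.z_min, ddof=cfg.zscore_ddof)
        results[f"stage_counts_{name}"] = counts.counts
        hio.write_tsv(
            counts.counts.rename("count").rename_axis("stage").reset_index(),
            out / f"stage_associated_counts_{name}.tsv",
            tag,
        )
    rng = np.random.default_rng(cfg.seed + 2)
    panel = _synthetic_tissue_panel(rng, mb.genes)
    etab = hg.tissue_entropy(panel)
    results["entropy"] = etab
    hio.write_tsv(
        etab.entropy.rename_axis("gene").reset_index(), out / "tissue_entropy.tsv", tag
    )
    tcounts = hg.tissue_associated_counts(
        mb.subset(expr_b), etab, cfg.tpm_min, cfg.h_thr, cfg.entropy_direction
    )
    results["tissue_counts"] = tcounts
    hio.write_tsv(
        tcounts.rename("count").rename_axis("stage").reset_index(),
        out / "tissue_associated_counts.tsv",
        tag,
    )
    return results


_PIPELINE_GENOME = {"chr1": 2_000_000, "chr2": 1_500_000}


def run_ocr(cfg: PipelineConfig, out: Path) -> dict:
    tag = f"config_hash={cfg.config_hash()}"
    stages = ["E9.5", "E10.5", "E11.5", "E12.5"]
    fracs = [0.25, 0.4, 0.25, 0.2]  # mid-stage (E10.5) most conserved
    peaks, reads, hits, truth = simulate_peak_data(
        _PIPELINE_GENOME,
        n_peaks_per_stage=300,
        shared_fraction=0.5,
        conserved_fraction=fracs,
        n_reads=5000,
        seed=cfg.seed,
        stage_names=stages,
        conservation_bin_width=cfg.bin_width_conservation,
    )
    results: dict = {"truth": truth}
    grid500 = ocr.BinGrid.from_sizes(_PIPELINE_GENOME, cfg.bin_width_samples)
    grid100 = ocr.BinGrid.from_sizes(_PIPELINE_GENOME, cfg.bin_width_conservation)
    binned500 = [ocr.assign_to_bins(peaks[s], grid500, cfg.min_frac) for s in stages]
    dmat = ocr.onehot_distance_matrix(binned500)
    results["onehot_distances"] = dmat
    hio.write_tsv(dmat.reset_index(names="sample"), out / "onehot_distances.tsv", tag)

    frip_rows, cons_rows = [], []
    for s in stages:
        score, ok = ocr.frip(reads[s], peaks[s], qc_min=cfg.frip_qc_min)
        frip_rows.append((s, score, ok))
        b100 = ocr.assign_to_bins(peaks[s], grid100, cfg.min_frac)
        frac = ocr.conserved_fraction(b100, hits, cfg.score_min)
        nc = ocr.conserved_fraction(b100, hits, cfg.score_min, not_conserved=True)
        cons_rows.append((s, frac, nc))
        logger.info("stage %s FRiP=%.4f conserved=%.4f", s, score, frac)
    frip_df = pd.DataFrame(frip_rows, columns=["stage", "frip", "pass"])
    cons_df = pd.DataFrame(cons_rows, columns=["stage", "conserved_fraction", "not_conserved_fraction"])
    results["frip"] = frip_df
    results["conservation"] = cons_df
    hio.write_tsv(frip_df, out / "frip.tsv", tag)
    hio.write_tsv(cons_df, out / "conserved_fraction.tsv", tag)

    # per-bin signal with replicates for the differential test
    rng = np.random.default_rng(cfg.seed + 3)
    union_bins = sorted(set().union(*(b.bins for b in binned500)))
    sig = {}
    groups = {}
    for s, b in zip(stages, binned500):
        cols = [f"{s}_r{k+1}" for k in range(3)]
        groups[s] = cols
        base = np.where([bid in b.bins for bid in union_bins], 5.0, 1.0)
        for c in cols:
            sig[c] = base * rng.lognormal(-0.005, 0.1, size=len(union_bins))
    signal = pd.DataFrame(sig, index=pd.Index([f"{c}:{i}" for c, i in union_bins], name="bin"))
    diff = ocr.differential_bins(signal, groups, alpha=cfg.alpha)
    results["differential"] = diff
    hio.write_tsv(diff, out / "differential_bins.tsv", tag)

    shared_df = peaks[stages[0]].df.merge(peaks[stages[1]].df, how="inner")
    panel = [ocr.assign_to_bins(ocr.PeakSet(shared_df, sample="panel"), grid500, cfg.min_frac)]
    spec_rows = []
    for s, b in zip(stages, binned500):
        specific, frac = ocr.tissue_specific_peaks(b, panel)
        spec_rows.append((s, len(specific), float(frac["all"])))
    spec_df = pd.DataFrame(spec_rows, columns=["stage", "specific_bins", "specific_fraction"])
    results["tissue_specific"] = spec_df
    hio.write_tsv(spec_df, out / "tissue_specific_peaks.tsv", tag)

    pwm = ocr.PWM("synthetic_motif", _default_motif())
    seqs = {
        f"{s}:{i}": "".join(rng.choice(list("ACGT"), size=200))
        for s in stages
        for i in range(20)
    }
    counts = ocr.motif_occurrences(seqs, pwm, cfg.frac_motif)
    stage_of = {k: k.split(":")[0] for k in seqs}
    mmeans = ocr.motif_stage_means(counts, stage_of)
    results["motif_means"] = mmeans
    hio.write_tsv(
        mmeans.rename("mean_occurrences").reset_index(),
        out / "motif_stage_means.tsv",
        tag,
    )
    return results


def _default_motif() -> np.ndarray:
    """An 8-position probability matrix with a sharp consensus (TGACTCAG-like)."""
    consensus = "TGACTCAG"
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), 0.05)
    for i, b in enumerate(consensus):
        m[i, idx[b]] = 0.85
    return m


def run_pipeline(cfg: PipelineConfig, workflow: str) -> dict:
    """Run one workflow end to end; returns the in-memory result bundle.

    Deterministic given the config (seeds included); every output file
    carries the config hash and the run log records every threshold.
    """
    if workflow not in WORKFLOWS:
        raise ValueError(f"workflow must be one of {WORKFLOWS}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out, cfg)
    try:
        cfg.to_yaml(out / "config.yaml")
        if workflow == "transcriptome":
            results = run_transcriptome(cfg, out)
        else:
            results = run_ocr(cfg, out)
    finally:
        logging.getLogger("hourglass_kit").removeHandler(handler)
        handler.close()
    results["manifest"] = sorted(p.name for p in out.iterdir())
    results["result_hash"] = _hash_outputs(out)
    return results


def _hash_outputs(out: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(out.glob("*.tsv")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]
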