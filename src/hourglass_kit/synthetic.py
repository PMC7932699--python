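"""Synthetic data generators with planted ground truth.

Everything the analysis consumes can be generated here with known truth:

* two-species replicated expression matrices with planted gene classes
  (housekeeping, conserved early/late, two heterochronic classes, species-
  specific genes) and a planted mid-stage conservation signal,
* multi-species homology hit tables with known ortholog pairs, paralog
  confusion, per-species dropout and lineage-restricted genes,
* per-stage peak sets with shared/specific peaks, planted conserved bins and
  reads placed to hit a target FRiP,
* the two-gene, three-timepoint toy fixture used to compare scaling methods.

Replicate noise is multiplicative log-normal with a stated coefficient of
variation (strictly positive TPMs, CV directly interpretable).  Class
profiles are linear ramps in normalized stage rank, so trend correlations
are sharp; the planted mid-stage conservation is carried by a fraction of
the conserved genes whose profile is a matched Gaussian bump peaking at the
designated mid stage of each species, and by the heterochronic ramps, which
agree at mid ranks and disagree maximally at matched early/late stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .ocr import BinGrid, PeakSet, assign_to_bins

GENE_CLASSES = (
    "housekeeping",
    "conserved_early",
    "conserved_late",
    "heterochronic1",
    "heterochronic2",
    "species_specific_a",
    "species_specific_b",
)

DEFAULT_STAGES_A = ["st27", "st27.5", "st29", "st30", "st31", "st32"]
DEFAULT_STAGES_B = ["E9.5", "E10.5", "E11.5", "E12.5"]

DEFAULT_CLASS_COUNTS = {
    "housekeeping": 400,
    "conserved_early": 400,
    "conserved_late": 400,
    "heterochronic1": 200,
    "heterochronic2": 200,
    "species_specific_a": 200,
    "species_specific_b": 200,
}

_RAMP_FLOOR = 0.05  # baseline fraction of a ramp profile
_BUMP_WIDTH_RANGE = (0.10, 0.25)  # per-gene sd of the mid-stage bump (rank units)
_BUMP_FLOOR_RANGE = (0.0, 0.2)  # per-gene baseline of the bump profile
_WARP_STRETCH = 0.5  # max |stretch| of the cross-species time-warp
_OFF_TPM = 0.1  # mean TPM of a species-specific gene in the other species


@dataclass
class TruthLabels:
    """Planted truth emitted by the generators for oracle tests."""

    gene_class: dict[str, str] = field(default_factory=dict)
    ortholog_truth: set = field(default_factory=set)
    conserved_bins: dict = field(default_factory=dict)  # stage -> frozenset of bins
    planted_conserved_stage_pair: tuple[str, str] | None = None

    def genes_of_class(self, cls: str, prefix: str | None = None) -> list[str]:
        out = [g for g, c in self.gene_class.items() if c == cls]
        if prefix is not None:
            out = [g for g in out if g.startswith(prefix)]
        return sorted(out)


@dataclass
class ExpressionSimConfig:
    """Study conditions for the two-species expression simulation.

    Defaults mirror the real design: six fin-bud stages vs four limb-bud
    stages, three replicates, and log-normal replicate noise.
    """

    n_genes_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    stages_a: Sequence[str] = field(default_factory=lambda: list(DEFAULT_STAGES_A))
    stages_b: Sequence[str] = field(default_factory=lambda: list(DEFAULT_STAGES_B))
    n_replicates: int = 3
    noise_cv: float = 0.1
    base_tpm_range: tuple[float, float] = (5.0, 100.0)
    hourglass_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_genes_per_class) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        if any(n < 0 for n in self.n_genes_per_class.values()):
            raise ValueError("negative gene count")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates <= 0:
            raise ValueError("need at least one replicate")
        for stages in (self.stages_a, self.stages_b):
            if len(stages) == 0:
                raise ValueError("stage list must be non-empty")
            if len(set(stages)) != len(stages):
                raise ValueError("duplicate stage names")
        lo, hi = self.base_tpm_range
        if not (0 < lo <= hi):
            raise ValueError("base_tpm_range must be a positive interval")
        if not 0 <= self.hourglass_strength <= 1:
            raise ValueError("hourglass_strength must be in [0,1]")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean 1 and the stated CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def _ranks(n: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)


def mid_stage_index(n_stages: int) -> int:
    """Designated conserved mid stage: the earlier of the two central stages."""
    return (n_stages - 1) // 2


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthLabels]:
    """Two-species replicated TPM matrices with planted gene classes.

    Gene ``i`` of species A (``gA...``) is the true ortholog of gene ``i`` of
    species B (``gB...``) except for the species-specific classes, which are
    lineage-restricted (mean TPM below the expression floor in the other
    species) and carry no ortholog pair.

    Conserved genes share one underlying profile evaluated on each species'
    normalized stage ranks; the species-B copy is read through a per-gene
    linear time-warp that is exact at the designated mid stages and randomly
    stretched elsewhere (mass heterochrony around a conserved mid stage).  A
    fraction ``hourglass_strength`` of the conserved_early/late genes has its
    profile peak forced to the designated mid stage (a per-gene Gaussian
    bump), planting the mid-stage conservation signal.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    ra, rb = _ranks(len(cfg.stages_a)), _ranks(len(cfg.stages_b))
    mid_a, mid_b = mid_stage_index(len(cfg.stages_a)), mid_stage_index(len(cfg.stages_b))
    r_mid_a, r_mid_b = ra[mid_a], rb[mid_b]
    fl = _RAMP_FLOOR

    def warp(q: np.ndarray, stretch: float) -> np.ndarray:
        """Map B stage ranks onto A's rank axis; exact at the mid stages."""
        return np.clip(r_mid_a + (1.0 + stretch) * (q - r_mid_b), 0.0, 1.0)

    genes_a, genes_b = [], []
    means_a, means_b = [], []
    truth = TruthLabels(
        planted_conserved_stage_pair=(cfg.stages_a[mid_a], cfg.stages_b[mid_b])
    )
    i = 0
    for cls in GENE_CLASSES:
        n = int(cfg.n_genes_per_class.get(cls, 0))
        if n == 0:
            continue
        base = rng.uniform(*cfg.base_tpm_range, size=n)
        if cls in ("conserved_early", "conserved_late"):
            n_bump = int(round(cfg.hourglass_strength * n))
            bump_flags = np.zeros(n, dtype=bool)
            bump_flags[rng.choice(n, size=n_bump, replace=False)] = True
        else:
            bump_flags = np.zeros(n, dtype=bool)
        for j in range(n):
            ga, gb = f"gA{i:05d}", f"gB{i:05d}"
            stretch = rng.uniform(-_WARP_STRETCH, _WARP_STRETCH)
            if cls == "housekeeping":
                pa, pb = np.ones_like(ra), np.ones_like(rb)
            elif cls in ("conserved_early", "conserved_late"):
                if bump_flags[j]:
                    w = rng.uniform(*_BUMP_WIDTH_RANGE)
                    f0 = rng.uniform(*_BUMP_FLOOR_RANGE)

                    def prof(r, w=w, f0=f0):
                        return f0 + (1 - f0) * np.exp(-((r - r_mid_a) ** 2) / (2 * w * w))

                elif cls == "conserved_early":

                    def prof(r):
                        return fl + (1 - fl) * (1 - r)

                else:

                    def prof(r):
                        return fl + (1 - fl) * r

                pa, pb = prof(ra), prof(warp(rb, stretch))
            elif cls == "heterochronic1":  # rises in A, falls in B
                pa = fl + (1 - fl) * ra
                pb = fl + (1 - fl) * (1 - rb)
            elif cls == "heterochronic2":  # mirrored
                pa = fl + (1 - fl) * (1 - ra)
                pb = fl + (1 - fl) * rb
            elif cls == "species_specific_a":
                pa, pb = np.ones_like(ra), None
            else:  # species_specific_b
                pa, pb = None, np.ones_like(rb)
            ma = base[j] * pa if pa is not None else np.full(len(ra), _OFF_TPM)
            mb = base[j] * pb if pb is not None else np.full(len(rb), _OFF_TPM)
            genes_a.append(ga)
            genes_b.append(gb)
            means_a.append(ma)
            means_b.append(mb)
            truth.gene_class[ga] = cls
            truth.gene_class[gb] = cls
            if cls not in ("species_specific_a", "species_specific_b"):
                truth.ortholog_truth.add((ga, gb))
            i += 1
    mean_a = np.asarray(means_a)
    mean_b = np.asarray(means_b)
    rep_a = mean_a[:, :, None] * _lognormal_noise(
        rng, cfg.noise_cv, (*mean_a.shape, cfg.n_replicates)
    )
    rep_b = mean_b[:, :, None] * _lognormal_noise(
        rng, cfg.noise_cv, (*mean_b.shape, cfg.n_replicates)
    )
    ma = ExpressionMatrix("species_a", pd.Index(genes_a), list(cfg.stages_a), rep_a)
    mb = ExpressionMatrix("species_b", pd.Index(genes_b), list(cfg.stages_b), rep_b)
    return ma, mb, truth


@dataclass
class SimulatedHits:
    """Per-direction homology hit tables plus the planted pair truth.

    ``a_hits`` holds species-A queries against every panel species and the
    fallback lineage (subject species tagged per row); ``b_hits`` the
    species-B queries against the panel; ``a_vs_b``/``b_vs_a`` the direct
    two-species tables for the RBH baseline.
    """

    a_hits: pd.DataFrame
    b_hits: pd.DataFrame
    a_vs_b: pd.DataFrame
    b_vs_a: pd.DataFrame
    fallback_species: str
    truth: TruthLabels


def simulate_hit_tables(
    n_orthologs: int,
    panel_species: Sequence[str],
    fallback_species: str,
    paralog_rate: float,
    dropout_rate: float,
    seed: int,
    lineage_specific_fraction: float = 0.0,
    score_sigma: float = 3.0,
    paralog_delta: float = 30.0,
    bridge_offset_step: float = 15.0,
    direct_confusion_factor: float = 2.0,
) -> SimulatedHits:
    """Homology hit tables with known ortholog truth and tunable confusion.

    For each true pair the true subject scores highest in expectation
    (true ~ N(mu + offset_s, sigma), paralog ~ N(mu + offset_s - delta,
    sigma)); with probability ``paralog_rate`` the paralog is forced to
    outscore the true hit in a panel species.  Panel species carry
    decreasing score offsets in list order (``bridge_offset_step`` apart):
    the first species is the slow-evolving bridge whose hits dominate the
    cross-species maximum.  ``dropout_rate`` removes a query's hits against
    a panel species.  The direct A-vs-B tables use
    ``direct_confusion_factor`` x the panel confusion probability: distant
    direct comparisons discriminate paralogs less well, which is the premise
    of routing assignment through intermediate species.  A
    ``lineage_specific_fraction`` of A genes hits only the fallback lineage.
    """
    if not panel_species:
        raise ValueError("empty panel")
    if fallback_species in panel_species:
        raise ValueError("fallback species must not be in the bridge panel")
    for name, rate in (
        ("paralog_rate", paralog_rate),
        ("dropout_rate", dropout_rate),
        ("lineage_specific_fraction", lineage_specific_fraction),
    ):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0,1]")
    rng = np.random.default_rng(seed)
    n = int(n_orthologs)
    genes_a = [f"a{i:05d}" for i in range(n)]
    genes_b = [f"b{i:05d}" for i in range(n)]
    mu = rng.uniform(150.0, 300.0, size=n)
    n_lineage = int(round(lineage_specific_fraction * n))
    lineage = set(rng.choice(n, size=n_lineage, replace=False).tolist())

    def partner(i: int) -> int:
        return (i + 1) % n if n > 1 else i

    def subj(sp: str, i: int) -> str:
        if sp == "B":
            return genes_b[i]
        return f"{sp}_g{i:05d}"

    offsets = {
        sp: bridge_offset_step * (len(panel_species) - 1 - k)
        for k, sp in enumerate(panel_species)
    }

    def emit(
        query: str,
        i: int,
        sp: str,
        confusion: float,
        dropout: float,
        rows: list,
        offset: float = 0.0,
    ):
        if rng.uniform() < dropout:
            return
        true_score = mu[i] + offset + rng.normal(0, score_sigma)
        para_score = mu[i] + offset - paralog_delta + rng.normal(0, score_sigma)
        if rng.uniform() < confusion:
            para_score = true_score + rng.uniform(1.0, 5.0)
        for target, score in ((i, true_score), (partner(i), para_score)):
            score = max(score, 1.0)
            rows.append(
                (query, sp, subj(sp, target), score, float(2.0 ** (-score)))
            )

    direct_rate = min(1.0, direct_confusion_factor * paralog_rate)
    rows_a, rows_b, rows_ab, rows_ba = [], [], [], []
    for i in range(n):
        if i in lineage:
            emit(genes_a[i], i, fallback_species, 0.0, 0.0, rows_a)
            continue
        for sp in panel_species:
            emit(genes_a[i], i, sp, paralog_rate, dropout_rate, rows_a, offsets[sp])
            emit(genes_b[i], i, sp, paralog_rate, dropout_rate, rows_b, offsets[sp])
        emit(genes_a[i], i, fallback_species, 0.0, 0.0, rows_a)
        emit(genes_a[i], i, "B", direct_rate, 0.0, rows_ab)
        emit(genes_b[i], i, "A_self", direct_rate, 0.0, rows_ba)
    cols = ["query", "subject_species", "subject", "bitscore", "evalue"]
    a_hits = pd.DataFrame(rows_a, columns=cols)
    b_hits = pd.DataFrame(rows_b, columns=cols)
    a_vs_b = pd.DataFrame(rows_ab, columns=cols)
    b_vs_a = pd.DataFrame(rows_ba, columns=cols)
    # direct B->A table must name true species-A gene ids
    b_vs_a["subject"] = b_vs_a["subject"].str.replace("A_self_g", "a", regex=False)
    b_vs_a["subject_species"] = "A"
    truth = TruthLabels(
        ortholog_truth={(genes_a[i], genes_b[i]) for i in range(n) if i not in lineage},
        gene_class={
            genes_a[i]: ("species_specific_a" if i in lineage else "housekeeping")
            for i in range(n)
        },
    )
    return SimulatedHits(
        a_hits=a_hits,
        b_hits=b_hits,
        a_vs_b=a_vs_b,
        b_vs_a=b_vs_a,
        fallback_species=fallback_species,
        truth=truth,
    )


def simulate_peak_data(
    genome: Mapping[str, int],
    n_peaks_per_stage: int,
    shared_fraction: float,
    conserved_fraction,
    n_reads: int,
    seed: int,
    stage_names: Sequence[str] = ("E9.5", "E10.5", "E11.5", "E12.5"),
    peak_length: int = 400,
    read_length: int = 50,
    target_frip: float = 0.3,
    conservation_bin_width: int = 100,
    target_genome: str = "other_genome",
):
    """Per-stage peak sets, reads and alignment hits with planted truth.

    Peaks are placed on a non-overlapping slot lattice: a shared pool common
    to all stages plus stage-specific peaks.  Alignment hits with score >= 40
    are planted over exactly the requested conserved fraction of each stage's
    100-bp peak bins (``conserved_fraction`` may be a scalar or one value per
    stage); remaining bins receive sub-threshold hits or none.  Reads are
    Bernoulli-placed inside peaks with probability ``target_frip``.

    Returns ``(peaks_by_stage, reads_by_stage, hits, truth)``.
    """
    if not genome:
        raise ValueError("genome empty")
    if peak_length <= 0:
        raise ValueError("peak length must be positive")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0,1]")
    stages = list(stage_names)
    fracs = (
        [float(conserved_fraction)] * len(stages)
        if np.isscalar(conserved_fraction)
        else [float(f) for f in conserved_fraction]
    )
    if len(fracs) != len(stages):
        raise ValueError("one conserved fraction per stage required")
    if any(not 0 <= f <= 1 for f in fracs):
        raise ValueError("conserved fractions must be in [0,1]")
    rng = np.random.default_rng(seed)

    slot_w = peak_length + 2 * conservation_bin_width
    slots = []
    for chrom, size in sorted(genome.items()):
        # keep peaks clear of the chromosome end so every 100-bp bin is full width
        usable = size - size % max(slot_w, conservation_bin_width) - slot_w
        if usable < slot_w:
            raise ValueError(f"chromosome {chrom} too short for a peak slot")
        slots.extend((chrom, s) for s in range(0, usable, slot_w))
    n_shared = int(round(shared_fraction * n_peaks_per_stage))
    n_specific = n_peaks_per_stage - n_shared
    needed = n_shared + n_specific * len(stages)
    if needed > len(slots):
        raise ValueError("genome too small for the requested peak count")
    chosen = rng.choice(len(slots), size=needed, replace=False)
    offset = conservation_bin_width  # peak start aligned to the 100-bp grid

    def mk_peak(slot_idx: int) -> tuple[str, int, int, int]:
        chrom, s = slots[slot_idx]
        start = s + offset
        end = start + peak_length
        return chrom, start, end, start + peak_length // 2

    shared = [mk_peak(i) for i in chosen[:n_shared]]
    grid = BinGrid.from_sizes(dict(genome), conservation_bin_width)
    peaks_by_stage: dict[str, PeakSet] = {}
    reads_by_stage: dict[str, pd.DataFrame] = {}
    truth = TruthLabels()
    hit_rows = []
    # shared bins are planted at the minimum stage fraction; specific bins top up
    shared_bins = sorted(
        assign_to_bins(
            PeakSet(pd.DataFrame(shared, columns=["chrom", "start", "end", "summit"]))
            if shared
            else PeakSet(pd.DataFrame(columns=["chrom", "start", "end"])),
            grid,
        ).bins
    )
    f_shared = min(fracs)
    n_shared_cons = int(round(f_shared * len(shared_bins)))
    shared_cons = set(
        tuple(shared_bins[k])
        for k in rng.choice(len(shared_bins), size=n_shared_cons, replace=False)
    ) if shared_bins else set()

    consumed = n_shared
    for stage, f in zip(stages, fracs):
        stage_specific = [mk_peak(i) for i in chosen[consumed : consumed + n_specific]]
        consumed += n_specific
        df = pd.DataFrame(
            shared + stage_specific, columns=["chrom", "start", "end", "summit"]
        )
        pset = PeakSet(df, sample=stage, stage=stage)
        peaks_by_stage[stage] = pset
        binned = assign_to_bins(pset, grid)
        spec_bins = sorted(set(binned.bins) - set(shared_bins))
        n_total = len(binned.bins)
        n_target = int(round(f * n_total))
        n_from_spec = min(max(n_target - len(shared_cons & set(binned.bins)), 0), len(spec_bins))
        spec_cons = set(
            tuple(spec_bins[k])
            for k in rng.choice(len(spec_bins), size=n_from_spec, replace=False)
        ) if spec_bins else set()
        conserved = (shared_cons & set(binned.bins)) | spec_cons
        truth.conserved_bins[stage] = frozenset(conserved)
        for b in sorted(set(binned.bins)):
            bs, be = grid.bin_bounds(*b)
            if b in conserved:
                hit_rows.append((b[0], bs, be, target_genome, float(rng.uniform(45, 90))))
            elif rng.uniform() < 0.5:
                hit_rows.append((b[0], bs, be, target_genome, float(rng.uniform(20, 39))))
        # reads
        ivs = df[["start", "end"]].to_numpy()
        rows = []
        chroms = df["chrom"].to_numpy()
        sizes = dict(genome)
        merged_by_chrom = {
            c: df.loc[df["chrom"] == c, ["start", "end"]].to_numpy() for c in sizes
        }
        for _ in range(int(n_reads)):
            if rng.uniform() < target_frip and len(df):
                j = int(rng.integers(len(df)))
                s = int(rng.integers(ivs[j, 0], ivs[j, 1] - read_length))
                rows.append((chroms[j], s, s + read_length))
            else:
                while True:
                    chrom = sorted(sizes)[int(rng.integers(len(sizes)))]
                    s = int(rng.integers(0, sizes[chrom] - read_length))
                    m = merged_by_chrom[chrom]
                    if not np.any((m[:, 0] < s + read_length) & (m[:, 1] > s)):
                        rows.append((chrom, s, s + read_length))
                        break
        reads_by_stage[stage] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    # de-duplicate hits planted for bins occupied in several stages
    hits = (
        pd.DataFrame(hit_rows, columns=["chrom", "start", "end", "target", "score"])
        .sort_values(["chrom", "start", "score"], ascending=[True, True, False], kind="mergesort")
        .drop_duplicates(subset=["chrom", "start", "end", "target"], keep="first")
        .reset_index(drop=True)
    )
    return peaks_by_stage, reads_by_stage, hits, truth


def toy_two_gene_example() -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """The two-gene, three-timepoint scaling fixture.

    Gene 1 is constitutively active in both species (max/min <= 1.5, small
    mirrored noise around a shared peak); gene 2 is expressed at t2 in both
    species and additionally at t1 in species A / t3 in species B, so t2 is
    the planted most-similar timepoint.
    """
    stages = ["t1", "t2", "t3"]
    a = np.array([[9.0, 12.0, 8.5], [10.0, 10.0, 6.0]])[:, :, None]
    b = np.array([[8.5, 12.0, 9.0], [6.0, 10.0, 10.0]])[:, :, None]
    genes = pd.Index(["gene1", "gene2"])
    return (
        ExpressionMatrix("species1", genes, stages, a),
        ExpressionMatrix("species2", genes, stages, b),
    )
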