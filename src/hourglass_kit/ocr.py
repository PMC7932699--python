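"""Open-chromatin-region analytics on fixed-width genome bins.

ATAC-seq peak sets (half-open, 0-based intervals) are re-distributed onto a
genome partition of fixed-width bins (500 bp for sample comparison, 100 bp
for conservation analysis) under a reciprocal 40%-overlap rule, turning each
sample into a one-hot vector over occupied bins.  On top of that
representation the module computes one-hot Euclidean distances between
samples, the fraction of peak bases covered by conserved sequence (alignment
hits with score >= 40), FRiP quality control, differential-bin counts between
consecutive stages (two-sided Student's t), PWM motif occurrence counts at a
75%-of-maximum score threshold, and tissue-specific peak detection against a
panel of other tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BinId = tuple[str, int]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width partition of a genome, anchored at coordinate 0.

    Bins tile each chromosome; the last bin of a chromosome may be short.
    """

    chrom_sizes: tuple  # ((chrom, size), ...) to stay hashable
    bin_width: int

    @classmethod
    def from_sizes(cls, sizes: Mapping[str, int], bin_width: int) -> "BinGrid":
        if bin_width <= 0:
            raise ValueError("bin width must be positive")
        if not sizes:
            raise ValueError("empty genome")
        return cls(chrom_sizes=tuple(sorted(sizes.items())), bin_width=bin_width)

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.sizes[chrom] // self.bin_width)

    def bin_bounds(self, chrom: str, idx: int) -> tuple[int, int]:
        start = idx * self.bin_width
        end = min(start + self.bin_width, self.sizes[chrom])
        return start, end

    def bin_length(self, b: BinId) -> int:
        s, e = self.bin_bounds(*b)
        return e - s


@dataclass
class PeakSet:
    """Sorted, merged peak intervals of one sample/stage.

    ``df`` columns: chrom, start, end and optionally summit (absolute
    coordinate).  Intervals are half-open 0-based.
    """

    df: pd.DataFrame
    sample: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.df.columns):
            raise ValueError("peak table needs chrom, start, end")
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError("peak with non-positive length")
        self.df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge sorted-or-not half-open intervals into disjoint sorted ones."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=int)
    ivs = intervals[np.lexsort((intervals[:, 1], intervals[:, 0]))]
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=int)


def assign_to_bins(
    peaks: PeakSet, grid: BinGrid, min_frac: float = 0.4, either: bool = True
) -> "BinnedPeaks":
    """Occupy every bin a peak overlaps by >= ``min_frac`` of the bin or of the peak.

    This is the reciprocal-overlap rule of ``bedtools intersect -f 0.4 -F 0.4
    -e``: long peaks occupy every bin they cover at >= 40% of the bin; short
    peaks snap to the bin(s) holding >= 40% of the peak.  With
    ``either=False`` both fractions must be met.
    """
    sizes = grid.sizes
    occupied: set[BinId] = set()
    for r in peaks.df.itertuples(index=False):
        if r.chrom not in sizes:
            raise ValueError(f"peak chromosome {r.chrom!r} not in grid")
        peak_len = r.end - r.start
        first = r.start // grid.bin_width
        last = (r.end - 1) // grid.bin_width
        for idx in range(first, last + 1):
            bs, be = grid.bin_bounds(r.chrom, idx)
            ov = min(r.end, be) - max(r.start, bs)
            if ov <= 0:
                continue
            of_bin = ov / (be - bs)
            of_peak = ov / peak_len
            hit = (
                of_bin >= min_frac or of_peak >= min_frac
                if either
                else of_bin >= min_frac and of_peak >= min_frac
            )
            if hit:
                occupied.add((r.chrom, idx))
    return BinnedPeaks(sample=peaks.sample or peaks.stage, grid=grid, bins=frozenset(occupied))


@dataclass
class BinnedPeaks:
    """One-hot representation of a sample's peaks over a bin grid."""

    sample: str
    grid: BinGrid
    bins: frozenset = field(default_factory=frozenset)

    def total_length(self) -> int:
        return sum(self.grid.bin_length(b) for b in self.bins)


def onehot_distance(a: BinnedPeaks, b: BinnedPeaks, universe: Iterable[BinId] | None = None) -> float:
    """Euclidean distance between two one-hot bin vectors = sqrt(|A xor B|).

    Bins unoccupied in every sample contribute nothing, so restricting to an
    occupied-anywhere universe leaves the value unchanged as long as the
    universe covers both samples.
    """
    if a.grid != b.grid:
        raise ValueError("samples binned on different grids")
    sa, sb = set(a.bins), set(b.bins)
    if universe is not None:
        uni = set(universe)
        sa &= uni
        sb &= uni
    return float(np.sqrt(len(sa ^ sb)))


def onehot_distance_matrix(samples: Sequence[BinnedPeaks]) -> pd.DataFrame:
    uni = set().union(*(s.bins for s in samples)) if samples else set()
    names = [s.sample for s in samples]
    d = np.zeros((len(samples), len(samples)))
    for i, a in enumerate(samples):
        for j, b in enumerate(samples):
            if j > i:
                d[i, j] = d[j, i] = onehot_distance(a, b, uni)
    return pd.DataFrame(d, index=names, columns=names)


def _bin_best_scores(
    binned: BinnedPeaks, hits: pd.DataFrame, target: str | None = None
) -> dict[BinId, float]:
    """Best alignment score per occupied bin (hits given as source intervals)."""
    need = {"chrom", "start", "end", "target", "score"}
    if not need.issubset(hits.columns):
        raise ValueError("hit table needs chrom, start, end, target, score")
    pool = hits if target is None else hits[hits["target"] == target]
    best: dict[BinId, float] = {}
    w = binned.grid.bin_width
    occ = binned.bins
    for r in pool.itertuples(index=False):
        first = r.start // w
        last = (r.end - 1) // w
        for idx in range(first, last + 1):
            b = (r.chrom, idx)
            if b in occ and r.score > best.get(b, -np.inf):
                best[b] = r.score
    return best


def conserved_fraction(
    p100: BinnedPeaks,
    hits: pd.DataFrame,
    score_min: float = 40.0,
    target: str | None = None,
    not_conserved: bool = False,
) -> float:
    """Fraction of occupied peak bases whose best alignment score is >= score_min.

    Computed at bin resolution: (total length of occupied bins with best hit
    score >= score_min) / (total length of occupied bins).  With
    ``not_conserved=True`` returns instead the fraction of occupied bins with
    no hit at all against any target (negative control).
    """
    if not p100.bins:
        raise ValueError("empty peak set")
    best = _bin_best_scores(p100, hits, target=target)
    total = p100.total_length()
    if not_conserved:
        length = sum(p100.grid.bin_length(b) for b in p100.bins if b not in best)
    else:
        length = sum(
            p100.grid.bin_length(b)
            for b in p100.bins
            if best.get(b, -np.inf) >= score_min
        )
    return length / total


def frip(
    reads: pd.DataFrame,
    peaks: PeakSet,
    total_reads: int | None = None,
    qc_min: float = 0.2,
) -> tuple[float, bool]:
    """Fraction of reads in peaks and the QC pass flag (score >= qc_min).

    ``reads`` is an interval table (chrom, start, end); a read counts when it
    overlaps any peak by at least 1 bp.
    """
    total = len(reads) if total_reads is None else total_reads
    if total <= 0:
        raise ValueError("total_reads must be positive")
    in_peaks = 0
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, g in peaks.df.groupby("chrom"):
        merged = merge_intervals(g[["start", "end"]].to_numpy())
        starts_ends[c] = (merged[:, 0], merged[:, 1])
    for r in reads.itertuples(index=False):
        se = starts_ends.get(r.chrom)
        if se is None:
            continue
        starts, ends = se
        # merged intervals are sorted and disjoint: binary search suffices
        i = int(np.searchsorted(starts, r.end, side="left")) - 1
        if i >= 0 and ends[i] > r.start:
            in_peaks += 1
    score = in_peaks / total
    return score, score >= qc_min


def differential_bins(
    signal: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    min_fold: float | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Counts of bins with significantly changed signal between consecutive stages.

    ``signal`` is bin x sample coverage; ``groups`` maps each stage (in
    temporal order) to its replicate sample columns.  Each bin gets a
    two-sided two-sample Student t-test per consecutive stage pair; bins with
    p < alpha count as increased (later mean higher) or decreased.  Bins with
    zero variance in both groups are skipped and logged.  Optional
    Benjamini-Hochberg correction across bins per transition.
    """
    stages = list(groups)
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    for s, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"stage {s!r} has fewer than 2 replicates")
    out = []
    for early, late in zip(stages[:-1], stages[1:]):
        x = signal[list(groups[early])].to_numpy(dtype=float)
        y = signal[list(groups[late])].to_numpy(dtype=float)
        varsum = x.var(axis=1) + y.var(axis=1)
        ok = varsum > 0
        skipped = int((~ok).sum())
        if skipped:
            logger.info("differential_bins %s->%s: skipped %d zero-variance bins", early, late, skipped)
        t, p = stats.ttest_ind(y[ok], x[ok], axis=1, equal_var=True)
        if bh_correct and p.size:
            order = np.argsort(p)
            ranked = p[order] * p.size / (np.arange(p.size) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            q = np.empty_like(p)
            q[order] = np.minimum(adj, 1.0)
            p = q
        diff = y[ok].mean(axis=1) - x[ok].mean(axis=1)
        sig = p < alpha
        if min_fold is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = y[ok].mean(axis=1) / x[ok].mean(axis=1)
            sig = sig & ((fold >= min_fold) | (fold <= 1 / min_fold))
        out.append(
            {
                "transition": f"{early}->{late}",
                "increased": int((sig & (diff > 0)).sum()),
                "decreased": int((sig & (diff < 0)).sum()),
                "tested": int(ok.sum()),
                "skipped": skipped,
            }
        )
    return pd.DataFrame(out)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix with background model and pseudocount.

    ``probs`` is length x 4 (A, C, G, T); each row must sum to 1 before the
    pseudocount-regularized log-odds transform.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be length x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = (self.probs + self.pseudocount) / (1.0 + 4 * self.pseudocount)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def _scan_strand(seq: str, lod: np.ndarray, threshold: float) -> int:
    L = lod.shape[0]
    n = len(seq)
    if n < L:
        return 0
    codes = np.fromiter(
        (_BASE_INDEX.get(c, -1) for c in seq), dtype=np.int64, count=n
    )
    count = 0
    pos = np.arange(L)
    for start in range(n - L + 1):
        window = codes[start : start + L]
        if (window < 0).any():  # N scores -inf
            continue
        if lod[pos, window].sum() >= threshold:
            count += 1
    return count


def motif_occurrences(
    sequences: Mapping[str, str], pwm: PWM, frac: float = 0.75
) -> pd.Series:
    """Count motif matches per sequence at >= ``frac`` of the maximal PWM score.

    Both strands are scanned with the log-odds matrix; windows containing N
    never match.  Sequences shorter than the motif count 0.
    """
    thr = frac * pwm.max_score
    lod = pwm.log_odds
    counts = {}
    for name, seq in sequences.items():
        s = seq.upper()
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {name!r} has invalid characters {sorted(bad)}")
        rc = s.translate(_COMPLEMENT)[::-1]
        counts[name] = _scan_strand(s, lod, thr) + _scan_strand(rc, lod, thr)
    return pd.Series(counts, name=pwm.motif_id)


def motif_stage_means(counts: pd.Series, stage_of: Mapping[str, str]) -> pd.Series:
    """Mean motif occurrences per OCR for each stage."""
    df = pd.DataFrame({"count": counts, "stage": [stage_of[k] for k in counts.index]})
    return df.groupby("stage")["count"].mean()


def tissue_specific_peaks(
    focal: BinnedPeaks,
    panel: Sequence[BinnedPeaks],
    clusters: Mapping[BinId, str] | None = None,
) -> tuple[frozenset, pd.Series]:
    """Focal bins absent from every panel tissue, and the specific fraction.

    Returns the specific bin set and, per cluster label (or overall under the
    label "all"), the fraction of focal bins that are tissue-specific.  An
    empty panel makes every focal bin trivially specific (warned).
    """
    if not panel:
        logger.warning("empty tissue panel: all focal peaks trivially specific")
        panel_union: set[BinId] = set()
    else:
        for p in panel:
            if p.grid != focal.grid:
                raise ValueError("panel sample on a different grid")
        panel_union = set().union(*(p.bins for p in panel))
    specific = frozenset(focal.bins - panel_union)
    if clusters is None:
        frac = len(specific) / len(focal.bins) if focal.bins else float("nan")
        return specific, pd.Series({"all": frac})
    per: dict[str, list[int]] = {}
    for b in focal.bins:
        lab = clusters.get(b, "unlabeled")
        per.setdefault(lab, []).append(int(b in specific))
    return specific, pd.Series({k: float(np.mean(v)) for k, v in sorted(per.items())})
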