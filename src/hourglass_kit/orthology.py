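"""Cross-species best-hit ortholog assignment from homology hit tables.

Direct sequence comparison between distantly related species (here a shark
and a mouse) resolves orthologs poorly; comparisons routed through slowly
evolving intermediate species do better.  The assignment algorithm here
implements that idea:

1. For each species-A query, concatenate its hits against a panel of bridge
   species (excluding the fallback lineage) and take the single best-scoring
   subject — the *cross-species best hit*.
2. Confirm a pair from the other side: species-B genes whose best hit within
   that same bridge species is the same subject are paired with the query
   (*species-wise best hit*).
3. Queries with no cross-species best hit fall back to their best hit in a
   closely related fallback lineage (lineage-restricted genes).
4. Anything left is unassigned ("no orthology").

A plain reciprocal-best-hit (RBH) baseline on the direct A-vs-B tables is
provided for comparison.

Hit tables are pandas DataFrames with columns ``query, subject_species,
subject, bitscore, evalue`` (the consumed subset of BLAST tabular output;
the subject species is a per-file tag, not parsed from ids).  All selections
use a total order — bitscore desc, then e-value asc, then subject id, then
species id — so results are independent of row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

HIT_COLUMNS = ["query", "subject_species", "subject", "bitscore", "evalue"]

PROVENANCE_CSBH = "cross_species_best_hit"


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = set(HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    if (hits["bitscore"] < 0).any() or (hits["evalue"] < 0).any():
        raise ValueError("negative bitscore or e-value in hit table")
    return hits


def filter_evalue(hits: pd.DataFrame, evalue_max: float | None) -> pd.DataFrame:
    if evalue_max is None:
        return hits
    return hits[hits["evalue"] <= evalue_max]


def _best_per_query(hits: pd.DataFrame) -> pd.DataFrame:
    """One best row per query under the total tie order."""
    ordered = hits.sort_values(
        by=["query", "bitscore", "evalue", "subject", "subject_species"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset="query", keep="first")


def cross_species_best_hit(
    hits: pd.DataFrame, exclude: Iterable[str] = ()
) -> dict[str, tuple[str, str]]:
    """Best hit per query across all non-excluded panel species.

    Returns ``{query: (subject_species, subject)}``; queries whose hits all
    fall in excluded species are absent.
    """
    validate_hits(hits)
    excluded = set(exclude)
    pool = hits[~hits["subject_species"].isin(excluded)]
    best = _best_per_query(pool)
    return {
        r.query: (r.subject_species, r.subject) for r in best.itertuples(index=False)
    }


def fallback_best_hit(
    hits: pd.DataFrame, unassigned: Iterable[str], fallback_species: str
) -> dict[str, str]:
    """Best hit restricted to the fallback lineage, for unassigned queries.

    Queries with no fallback hit stay out of the result (no orthology).
    """
    validate_hits(hits)
    wanted = set(unassigned)
    pool = hits[
        (hits["subject_species"] == fallback_species) & hits["query"].isin(wanted)
    ]
    best = _best_per_query(pool)
    return {r.query: r.subject for r in best.itertuples(index=False)}


@dataclass
class OrthologyMap:
    """Assigned ortholog pairs plus fallback assignments and leftovers.

    ``pairs`` columns: gene_a, gene_b, via_species, provenance, uniqueness.
    A gene_a with a confirmed pair never also carries a fallback assignment.
    """

    pairs: pd.DataFrame
    fallback_assignments: dict[str, str] = field(default_factory=dict)
    unassigned: frozenset = frozenset()
    missing_tables: tuple = ()

    def __post_init__(self) -> None:
        overlap = set(self.pairs["gene_a"]) & set(self.fallback_assignments)
        if overlap:
            raise ValueError(f"paired genes also fallback-assigned: {sorted(overlap)[:5]}")

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["gene_a"], self.pairs["gene_b"]))


def _uniqueness_labels(pairs: pd.DataFrame) -> pd.Series:
    a_counts = pairs["gene_a"].value_counts()
    b_counts = pairs["gene_b"].value_counts()
    labels = []
    for r in pairs.itertuples(index=False):
        a_multi = a_counts[r.gene_a] > 1
        b_multi = b_counts[r.gene_b] > 1
        if not a_multi and not b_multi:
            labels.append("unique")
        elif a_multi and not b_multi:
            labels.append("one_to_many")  # one a confirmed by many b
        elif not a_multi and b_multi:
            labels.append("many_to_one")  # many a point at the same b
        else:
            labels.append("many_to_many")
    return pd.Series(labels, index=pairs.index)


def species_wise_confirm(
    a_best: Mapping[str, tuple[str, str]],
    b_hits: pd.DataFrame,
) -> OrthologyMap:
    """Confirm cross-species best hits from the other species' side.

    For an A query with cross-species best hit ``(S, h)``, every B gene whose
    best hit *restricted to species S* equals ``h`` is paired with it.  If a
    required species has no B-side table the affected queries are reported in
    ``missing_tables`` rather than silently dropped.
    """
    validate_hits(b_hits)
    needed = sorted({s for s, _ in a_best.values()})
    available = set(b_hits["subject_species"])
    missing = [s for s in needed if s not in available]
    # best hit of every B query within each needed species
    rows = []
    for s in needed:
        if s in missing:
            continue
        best_s = _best_per_query(b_hits[b_hits["subject_species"] == s])
        # reverse index: subject in S -> confirming B queries
        rev: dict[str, list[str]] = {}
        for r in best_s.itertuples(index=False):
            rev.setdefault(r.subject, []).append(r.query)
        for a, (sp, h) in a_best.items():
            if sp != s:
                continue
            for b in sorted(rev.get(h, ())):
                rows.append((a, b, s, PROVENANCE_CSBH))
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "via_species", "provenance"])
    pairs = pairs.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    pairs["uniqueness"] = _uniqueness_labels(pairs) if len(pairs) else pd.Series(dtype=object)
    unpaired = frozenset(a_best) - set(pairs["gene_a"])
    return OrthologyMap(
        pairs=pairs,
        unassigned=frozenset(unpaired),
        missing_tables=tuple(missing),
    )


def assign_orthologs(
    a_hits: pd.DataFrame,
    b_hits: pd.DataFrame,
    fallback_species: str,
    evalue_max: float | None = 1e-30,
) -> OrthologyMap:
    """Full assignment chain: cross-species best hit, confirmation, fallback.

    Every query ends in exactly one of: paired, fallback-assigned, unassigned.
    """
    a_hits = filter_evalue(validate_hits(a_hits), evalue_max)
    b_hits = filter_evalue(validate_hits(b_hits), evalue_max)
    a_best = cross_species_best_hit(a_hits, exclude={fallback_species})
    omap = species_wise_confirm(a_best, b_hits)
    all_queries = set(a_hits["query"])
    no_csbh = all_queries - set(a_best)
    fallback = fallback_best_hit(a_hits, no_csbh, fallback_species)
    unassigned = (all_queries - set(omap.pairs["gene_a"]) - set(fallback)) | set(
        omap.unassigned
    )
    unassigned -= set(fallback)
    return OrthologyMap(
        pairs=omap.pairs,
        fallback_assignments=fallback,
        unassigned=frozenset(unassigned - set(omap.pairs["gene_a"])),
        missing_tables=omap.missing_tables,
    )


def reciprocal_best_hit(
    a_vs_b: pd.DataFrame, b_vs_a: pd.DataFrame
) -> set[tuple[str, str]]:
    """Plain reciprocal-best-hit baseline on the direct two-species tables."""
    validate_hits(a_vs_b)
    validate_hits(b_vs_a)
    best_ab = {r.query: r.subject for r in _best_per_query(a_vs_b).itertuples(index=False)}
    best_ba = {r.query: r.subject for r in _best_per_query(b_vs_a).itertuples(index=False)}
    return {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}


def evaluate_accuracy(
    assigned, truth: Iterable[tuple[str, str]], families: Mapping[str, str] | None = None
):
    """Fraction of curated truth pairs recovered by an assignment.

    ``assigned`` may be an :class:`OrthologyMap` or a set of pairs.  With
    ``families`` (gene_a -> family label) a per-family breakdown Series is
    returned alongside the overall fraction.
    """
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("empty truth set")
    pair_set = assigned.pair_set if isinstance(assigned, OrthologyMap) else set(assigned)
    overall = len(pair_set & truth_set) / len(truth_set)
    if families is None:
        return overall
    per_fam: dict[str, list[int]] = {}
    for a, b in truth_set:
        fam = families.get(a, "unlabeled")
        per_fam.setdefault(fam, []).append(int((a, b) in pair_set))
    breakdown = pd.Series({f: float(np.mean(v)) for f, v in per_fam.items()})
    return overall, breakdown


def summary_counts(omap: OrthologyMap, uniqueness: bool = True) -> pd.Series:
    """Assignment-class counts (paired / unique / fallback / no orthology)."""
    counts = {
        "paired_queries": omap.pairs["gene_a"].nunique(),
        "pairs_total": len(omap.pairs),
        "fallback_assigned": len(omap.fallback_assignments),
        "no_orthology": len(omap.unassigned),
    }
    if uniqueness and len(omap.pairs):
        uniq_a = omap.pairs.loc[omap.pairs["uniqueness"] == "unique", "gene_a"].nunique()
        counts["uniquely_orthologous"] = uniq_a
    return pd.Series(counts)
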