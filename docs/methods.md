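# Methods

This note records the models, conventions and design choices behind
`hourglass_kit`, in the order a user meets them.

## Expression model and scaling

An `ExpressionMatrix` holds per-replicate TPMs for one species as a
gene × stage × replicate array. Transcript-level TPMs of splice variants are
summed per gene before anything else; the per-stage mean and SEM (sample sd,
ddof = 1, over √n) are derived. Genes whose maximal stage-mean TPM is below
1.0 (inclusive keep at exactly 1.0) are treated as not expressed.

Four per-gene scalings operate on the stage-mean profile of one species over
that species' stages only: Max-1 (`x / max`), z-score (`(x − mean)/sd`),
unit vector (`x / ‖x‖₂`) and log10 (`log10(x+1)`). Conventions:

* **sd convention.** The z-score scaling and the stage-association z use the
  population sd (ddof = 0); the replicate SEM uses the sample sd (ddof = 1).
  Both are configurable (`zscore_ddof`, fixed `sem` convention).
* Degenerate genes are errors, not silent fixes: z-score on a zero-variance
  gene and Max-1/unit-vector on an all-zero gene raise, so the caller filters
  first or picks another method.
* Max-1 and unit-vector scaling are idempotent and invariant to positive
  per-gene rescaling; z-score is invariant to per-gene affine maps; log10 is
  deliberately not scale-invariant. These are asserted as property tests.

## Heterochrony and the sensitivity ratio

A gene's stage trend is the Pearson correlation between its mean TPM profile
and the integer stage rank 1..T (stages are ordinal; physical ages are not
comparable across species). A pair is heterochronic when the PCC exceeds
+0.5 in one species and −0.5 in the other; both directions are available.
Mean TPM (not scaled values) enters the PCC by default, configurable.

The scaling-sensitivity diagnostic compares the mean interspecific Euclidean
distance of heterochronic genes to that of housekeeping genes under each
scaling; the ratio is oriented heterochronic/housekeeping so larger = more
sensitive to differential regulation. When the two species have different
stage counts the longer profile is linearly interpolated onto the shorter
one's normalized rank grid — a deliberate, biology-free alignment used only
by this diagnostic. An exactly-zero housekeeping distance is an error
(division guard).

The packaged two-gene, three-timepoint fixture has gene 1 constitutively
active (max/min ≤ 1.5, small mirrored noise around a shared t2 peak:
9/12/8.5 vs 8.5/12/9) and gene 2 expressed at t2 in both species plus t1 in
species A / t3 in species B (10/10/6 vs 6/10/10). The numeric values are free
parameters; they were fixed by construction so that t2 is the most similar
timepoint under every scaling and Max-1 yields the highest sensitivity ratio,
the qualitative behaviour the fixture exists to demonstrate.

## Ortholog assignment

Hit tables carry (query, subject species, subject, bitscore, e-value); only
those fields of BLAST tabular output are consumed, and the subject species is
a per-file tag. Rows with e-value above 1e-30 are dropped by default
(configurable), matching common strict search settings.

Selection is a total order — bitscore desc, e-value asc, subject id,
species id — so assignment is independent of row order. The chain is:
cross-species best hit over the non-fallback panel → species-wise
confirmation from the B side (every confirming B gene is emitted, and pairs
are labeled unique / one-to-many / many-to-one / many-to-many) → fallback
best hit for queries with no panel hit → unassigned. These four outcomes
partition the query set. A missing B-side table for a needed species is
reported in the result, never silently dropped.

The tie rule is a design choice (the selection needs a total order for
reproducibility); ties are essentially impossible under the synthetic score
model but real tables can contain them.

## Hourglass analytics

Stage distances are computed between the scaled stage vectors *u*, *v* of
the two species over shared expressed ortholog genes:

* Euclidean `√Σ(u−v)²`;
* correlation `1 − r(u, v)` (error on a zero-variance stage vector);
* Shannon `−½ Σ [u log((u+v)/(2u)) + v log((u+v)/(2v))]` with natural log and
  `0·log(·) = 0` — a generalized Jensen–Shannon divergence, verified against
  an independently coded JSD to 1e-12;
* standardized Euclidean `√Σ(u−v)²/V_i`, where `V_i` is the per-gene
  **population** variance over all `T_a + T_b` stage values of both species;
  zero-variance genes are excluded with a log notice.

Natural log is the default base for both the Shannon distance and tissue
entropy and is recorded in outputs. Both Euclidean forms take the square
root (the standard metric definitions); the argmin is unaffected either way.

Minimum summaries report per-B-stage and global argmins with ties listed,
never broken. Stage PCA is an exact SVD of the column-centered
stage × gene matrix (both species' stages as observations); signs are fixed
by making each component's largest-magnitude gene loading positive.
Concatenated gene vectors are species-A stages then species-B stages; genes
missing in one species are excluded from the distance universe by default
and zero-filled only for the clustering view, which must keep
species-specific genes. Clustering is Ward/Euclidean agglomeration behind a
pluggable embedding callable (identity by default; a UMAP/t-SNE transform can
be injected), cut by cluster count or height.

Stage-associated genes at stage *k*: mean TPM ≥ 1.0 and |z_k| ≥ 1.0 with the
population-sd z; flat genes are never counted. Tissue entropy uses
`p = TPM / ΣTPM` over the tissue panel and `H = −Σ p ln p`, unnormalized (no
division by ln K); genes with zero total TPM are flagged undefined.
Tissue-associated counting defaults to mean TPM ≥ 1.0 and H ≥ 0.65 —
i.e. the counted genes are the broadly expressed end; the threshold value,
TPM floor and direction are all configuration because the specific end
(H ≤ threshold) is the complementary question.

## Open-chromatin analytics

Genome bins are anchored at coordinate 0; the last bin of a chromosome may be
short. A bin is occupied by a peak when the overlap is ≥ 40 % of the bin *or*
≥ 40 % of the peak (inclusive bounds) — the reciprocal either-mode rule of
`bedtools intersect -f 0.4 -F 0.4 -e`, realized by direct interval
arithmetic rather than literal peak extension, so long peaks subdivide and
short peaks snap to their best-covered bin. 500-bp bins serve sample
comparison (one-hot Euclidean distance `√|A△B|`, computed over bins occupied
anywhere); 100-bp bins serve conservation, where a bin is conserved when its
best alignment hit scores ≥ 40 (best-hit reduction per bin) and the reported
value is the length fraction of occupied bins that are conserved. A
"no hit against any genome" negative-control fraction is available.

FRiP is reads overlapping any (merged) peak over total reads; QC passes at
≥ 0.2. Differential bins use a per-bin two-sided two-sample Student t-test
between consecutive stages with raw p-values by default (the volcano-plot
convention); Benjamini–Hochberg is optional. Bins with zero variance in both
groups are skipped and logged. Motif counting scans both strands with a
log-odds PWM (uniform 0.25 background, pseudocount 0.01 — fixed explicitly
because the upstream tools leave it implicit) and counts windows scoring
≥ 75 % of the maximal attainable score; windows containing N never match.
Tissue-specific peaks are focal bins absent from the union of a panel of
other tissues, computed on bins for consistency with the rest of the module.

## Synthetic data: what it emulates and what it does not

`simulate_expression` emulates a two-species developmental series (defaults:
6 vs 4 stages, 3 replicates, 2 000 genes in seven classes — 400 housekeeping,
400 conserved-early, 400 conserved-late, 200 + 200 heterochronic, 200 + 200
species-specific; base TPM uniform on 5–100). Replicate noise is
multiplicative log-normal with stated CV (default 0.1): strictly positive
TPMs and a directly interpretable noise knob. Class profiles are linear ramps
in normalized stage rank (floor 0.05), so trend correlations are near ±1 and
threshold tests are sharp; heterochronic1 rises in species A and falls in B,
heterochronic2 the mirror. Species-specific genes are flat in their own
species and held at mean TPM 0.1 in the other (below the expression floor,
no ortholog pair).

Mid-stage conservation is planted two ways. Conserved genes share one
underlying profile read through a per-gene linear time-warp of the B stage
axis that is exact at the designated mid stages (the earlier central stage of
each series: stage index `(T−1)//2`) and randomly stretched (±50 %)
elsewhere — mass heterochrony around a conserved mid stage. In addition a
fraction `hourglass_strength` (default 0.5) of the conserved-early/late genes
has its profile peak forced to the mid stage (per-gene Gaussian bump, width
0.10–0.25 rank units, floor 0–0.2). The warp is what lets the
correlation-distance argmin land on the planted pair: it creates genes whose
values *agree exactly yet vary across genes* at the mid-stage pair, which is
the signal a correlation metric rewards; a bump alone saturates at 1 under
Max-1 scaling and is invisible to correlation.

`simulate_hit_tables` plants one true ortholog per query with
true ~ N(μ + offset_s, σ) and paralog ~ N(μ + offset_s − δ, σ)
(μ ~ U(150, 300), σ = 3, δ = 30); with probability `paralog_rate` the paralog
is forced above the true hit in a panel species. Panel species carry
decreasing score offsets (15 apart) in list order — one slowly evolving
bridge species dominates the cross-species maximum, which is the premise of
routing assignment through intermediates — and the direct two-species tables
used by the RBH baseline get twice the confusion probability, modelling the
poorer paralog discrimination of a distant direct comparison. Dropout
removes a query/species table pair wholesale; a configurable fraction of
queries is lineage-restricted (fallback hits only).

`simulate_peak_data` places fixed-length peaks (default 400 bp, grid-aligned)
on a non-overlapping slot lattice: a shared pool plus stage-specific peaks.
Conservation is planted bin-exactly: shared bins at the minimum requested
per-stage fraction, stage-specific bins topped up so each stage hits its
target to within one bin; conserved bins get hits scoring 45–90, other bins
sub-threshold hits (20–39) or none. Reads are Bernoulli-placed inside peaks
at the target FRiP, rejection-sampled outside otherwise.

What the generators do **not** emulate: raw reads, GC/library-prep biases,
count–noise mean–variance relationships, genuine paralog families or synteny,
correlated replicate structure, repeat content or real alignment scores.
Passing the planted-truth tests therefore demonstrates that the machinery
computes what it claims on data with the assumed structure — not that the
biological conclusions transfer to any particular real dataset.

## Problem sizes and determinism

Default test and acceptance runs use 2 000 genes × (6 + 4) stages × 3
replicates, 200 ortholog queries × 3 bridge species (20 seeds for
baseline comparisons), 100–300 peaks per stage on a 0.9–3.5 Mb toy genome,
10⁴ reads for FRiP and 10³ bins/vector pairs for calibration and identity
checks — sizes at which every planted signal is comfortably above noise.
All randomness flows through `numpy.random.default_rng` seeded from a single
integer; fixed seed ⇒ bit-identical generator output, and the pipeline
writers use stable row order and 6-significant-digit floats so whole result
directories hash identically across runs.

## Known limitations

* The species-wise confirmation contract is defined for bridge species only;
  a cross-species best hit landing directly in the partner species is not
  confirmable in this scheme (the synthetic panel therefore contains only
  third-party species plus the fallback lineage).
* `differential_bins` assumes equal-variance normal replicates (Student's t);
  with 2–3 replicates the test is fragile and the raw-p default is a
  visualization convention, not an inference procedure.
* The hourglass recovery guarantees hold under the generator's conditions
  (strength ≥ 0.5, CV ≤ 0.1); weaker planting or stronger noise can shift
  the correlation-distance argmin first, as that metric has the smallest
  margin.
* Entropy-based tissue specificity depends on the composition of the tissue
  panel; the packaged panel is synthetic and only exercises the computation.
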