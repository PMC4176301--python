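# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-study generator, and the design decisions taken
where the analysis recipe was genuinely open.

## Differential expression

**Probe filtering.** Two filters run before any statistics, in probe
order: (1) probe ids ending in a configurable suffix list (default
`_x_at`) are dropped as potentially cross-hybridising; (2) probes whose
linear-scale expression `2^x` is below `min_linear` (default 50) in
*every* sample are treated as absent. The absence threshold is applied on
the linear scale because array-summarised log2 values span roughly 2–14,
where a cutoff of 50 would be meaningless. Filtering errors out if nothing
survives.

**Moderated t.** For a contrast of conditions A and B the per-probe
pooled two-group variance `s²` (df `d = nA + nB − 2`) is shrunk toward a
global prior `(d0, s0²)`:

    s̃² = (d0·s0² + d·s²)/(d0 + d),  t̃ = log2FC / sqrt(s̃²(1/nA + 1/nB))

referred to t with `d + d0` df (standard normal when `d0 = ∞`). With
`d0 = 0` the statistic reduces exactly to the classical pooled t — the
oracle used in the tests.

**Prior estimation.** `(d0, s0²)` is moment-matched on `log s²` under the
scaled-F model: with `e = log s² − ψ(d/2) + log(d/2)`, the excess of
`Var(e)` over `ψ′(d/2)` equals `ψ′(d0/2)`, inverted by Newton iteration;
`s0²` follows from the mean of `e`. When the observed spread does not
exceed the trigamma floor the prior is reported infinite with
`s0² = exp(mean log s²)` (the geometric mean, which equals the common
value when all variances are identical). One *global* prior is estimated
from one-way residual variances across all conditions (df `N − k`) and
reused by every contrast; this uses all replication to stabilise the
prior rather than re-estimating it per pairwise contrast. Monte-Carlo
recovery at 10,000 probes (d0 = 4, s0² = 2) is part of the test suite.

**Significance.** Benjamini–Hochberg adjustment (via statsmodels) and the
call `p_adj ≤ 0.05 AND |linear fold| ≥ 1.5`, boundaries inclusive; a
`strict_bounds` flag switches both comparisons to strict for users who
read the thresholds exclusively. Significant probes collapse to genes by
taking, per gene, the significant probe of maximal |log2FC|; genes whose
significant probes disagree in sign are dropped and logged rather than
silently resolved. Gene symbols are matched case-insensitively and
displayed with their input casing.

## Gene-set enrichment

One-sided hypergeometric (equivalently Fisher exact) over-representation
of each signature in each GMT set, over the universe of genes actually
measured on the filtered, annotated array — not the union of set contents,
which would inflate enrichment of tissue-specific collections. Odds ratios
get a 0.5 continuity addition only when a 2×2 margin is zero, and the
result is flagged when they do. Depletion is not tested.

**Q-values.** Storey's estimator with π0(λ) = #{p > λ}/(m(1 − λ)) fit by
a cubic polynomial over λ ∈ {0.05, …, 0.95} and evaluated at λ = 0.95,
clipped to (0, 1]; `q = π0 · p · m / rank` with the usual step-up
monotonicity. With fewer than 10 p-values π0 is set to 1 (exactly BH; the
fallback is logged). π0 = 1 reproduces `bh_adjust` to machine precision —
a test invariant.

**Control subtraction.** Any set with q ≤ 0.05 in the control-shRNA vs
untransduced comparison is considered a transduction artifact and removed
from every treatment's table; removals are logged with the control q.

**Ranking across conditions.** Within a condition sets are ranked by q
(ties by p, then name); a `rank_by="odds"` option ranks by descending
odds ratio instead, since "odds ranking" is not a uniquely defined term.
A set is *present* in a condition when q ≤ 0.05 after control
subtraction; the cross-condition table sorts by number of conditions
present (descending), then average within-condition rank (ascending),
then name.

## Causal reasoning engine

Hypotheses are (node, direction) pairs over a signed multigraph of causal
statements `X increases/decreases Y`. Default propagation depth is 1 —
the knowledge base stores direct pairwise statements, and deeper
propagation multiplies noise; `max_depth ≥ 2` is available, in which case
a transcript reachable with conflicting sign products is marked ambiguous
and never silently dropped. The hypothesis node itself is excluded from
its own predictions.

Scoring: over transcripts both unambiguously predicted and present in the
signature, `score = n_correct − n_incorrect`;
`percent_correct = n_correct/(n_correct + n_incorrect)` (undefined when
there is no overlap). Ambiguous predictions count toward the hypothesis's
"possible transcripts" in the enrichment test (draw size) but are
excluded from the correctness tally and the enrichment overlap numerator,
since they carry no direction evidence.

**Enrichment p.** Hypergeometric upper tail for the overlap of the
hypothesis's possible transcripts with the signature, signs ignored.

**Correctness p.** Null model: each scored transcript is independently
observed up with probability q̂, the signature's empirical up-fraction,
else down. Knockdown signatures are heavily direction-imbalanced, and a
½ null would overstate significance for any down-predicting hypothesis;
q̂ = ½ remains available via the signature itself. Under this null the
number of correct calls is the sum of two binomials (transcripts
predicted up succeed with q̂, predicted down with 1 − q̂); the exact path
convolves them, used whenever n ≤ 1,000, and a seeded Monte-Carlo path
with the add-one estimator `p = (1 + #{null ≥ obs})/(1 + n_perm)`
(default n_perm = 10,000) covers larger n. Exhaustive 2^n sign
enumeration and exact-vs-permutation agreement are test invariants, as is
super-uniformity of the exact p under a randomised null. Other null
constructions (e.g. a quaternary scheme with an explicit ambiguous class)
are admissible readings of "correctness"; the binomial null is the one
implemented, with the permutation path as the model-free fallback.

**Ranking and filters.** Deterministic sort by score descending, then
enrichment p, correctness p, node name; rank is the 1-based position.
"Ranking score" is interpreted as this ordinal rank, the reading under
which a `rank < 100` cutoff is a top-N filter. The acceptance filters are
correctness p < 0.05, enrichment p < 0.05, n_correct ≥ 3,
percent_correct ≥ 0.60, rank < 100 — strict/inclusive exactly as written.
Evaluating the opposite direction of any hypothesis swaps n_correct and
n_incorrect exactly and negates the score (a test property).

## Conservation and clustering

An item (signed hypothesis label or pathway name) is conserved when
present in ≥ `min_conditions` (default 3) knockdown conditions and absent
from the control comparison. Hypothesis identity is the (node, direction)
pair: a node appearing with opposite directions in different conditions
is two distinct items. Only the knockdown conditions count toward
presence; the control comparison contributes exclusion only.

Direction summaries report n_down/(n_down + n_up) per condition and
pooled, alongside the exact rational and the rounded percentage as it
would conventionally be printed (230 of 268 prints as 86%).

Ward clustering of samples uses the dissimilarity `1 − r` (Pearson r over
probes), range [0, 2], so anti-correlated replicates land far apart —
`1 − |r|` would hide them. Agglomeration follows the Lance–Williams Ward
update (scipy's linkage on the precomputed condensed distances); an
independent O(n³) re-implementation verifies the merge sequence in the
tests. Zero-variance samples are rejected by name. The dendrogram exports
to Newick.

## Synthetic studies

The generator's defaults *are* the emulated study design, chosen once:

| parameter | default | rationale |
|---|---|---|
| conditions | 8 knockdowns + control shRNA + blank | the emulated design |
| efficiencies | Mecp2 .86, Mef2a .94, Mef2d .89, Fmr1 .86, Nlgn1 .89, Nlgn3 .89, Pten .95, Shank3 .90 | published per-gene values; config rejects ≤ 0.75 (the study inclusion rule) |
| replicates | 4, dropout p = 0.1, ≥ 3 kept | quadruplicates; 4 of 40 arrays failed QC |
| effect size | 1.0 log2 on downstream targets | a clear ~2-fold regulatory effect |
| noise | 0.25 log2, i.i.d. Gaussian | typical post-summarisation replicate SD; an optional t(5) mode probes robustness |
| artifact | −0.8 log2 on 120 genes, all transduced conditions | a transduction response distinct from, and smaller than, the planted effects |
| network | 8 regulators × 20 private targets + 15 shared targets, 30% negative edges | shared targets plant pathways that must be conserved across knockdowns |
| probes | 2,000, 1–2 per gene, 10% `_x_at` decoys | exercises filtering and gene collapse at desk scale |

Mean structure: blank = baseline; control shRNA = baseline + artifact;
knockdown k = control structure + `log2(1 − efficiency)` on the target
gene + `−sign(edge) × effect` on each network target (a down-regulated
regulator loses its activating or repressive influence, so the true
upstream explanation is the (target, −) hypothesis). Expected target
shift at 86% knockdown is log2(0.14) ≈ −2.84 — asserted against sample
means in the tests. Baselines are uniform on log2 4–12 with planted genes
floored at 7 so the absence filter removes only background.

What the generator does **not** emulate: probe-level (CEL) intensities,
batch or plate effects, correlated noise between genes, annotation errors,
and regulators regulating each other. Passing recovery tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not performance on real arrays with structured noise.

`evaluate_recovery` scores a pipeline run against the planted truth: the
rank of (perturbed node, −) among filtered hypotheses per condition, the
count of other survivors, conservation of the planted shared pathway at
min_conditions = 6, and removal of the planted artifact set by control
subtraction. Under the defaults across 50 seeds the planted hypothesis is
rank 1 in every condition-run, the shared pathway is always conserved,
and the artifact set is always subtracted (recomputed by
`scripts/acceptance.py`); with effect size 0 the planted hypothesis
essentially never survives the filters.

## Pipeline

Stage order: probe filter → global EB prior → per-condition contrasts
against the control shRNA plus the control-vs-blank contrast →
significance calls and gene collapse → enrichment with control
subtraction → CRE per condition with the blank comparison's surviving
hypotheses used for exclusion → conservation, direction summary, Ward
clustering → TSV outputs and a JSON manifest (seed, config, versions, row
counts). Contrasts between knockdowns and the blank are not run by
default — the control shRNA is the reference that cancels the shared
artifact. Any stage failure aborts with the stage name and removes
partial outputs. Re-running with the same config and seed yields
byte-identical outputs; a `--threads` option exists for interface
stability but results never depend on it.

## Numerical notes and limitations

- Trigamma inversion uses Newton iteration from the 1/x asymptote;
  convergence to 1e−10 relative in ≤ 50 steps.
- Probes with zero pooled variance and nonzero fold yield |t| = ∞ and
  p = 0 rather than NaN; zero fold yields t = 0, p = 1.
- Hypergeometric tails come from `scipy.stats.hypergeom.sf`, exact for
  the sizes used here.
- The moderated-t model is two-group with equal variances; multi-factor
  designs, paired layouts and surrogate-variable correction are out of
  scope, as are array normalisation (inputs are pre-normalised log2
  values; a `linear` read flag converts) and probe-annotation curation.
- The directional enrichment surface (Fisher + directional member counts)
  is a transparent surrogate for proprietary rank-based pathway engines;
  it reports over-representation only.
- Whether the moderated t should share one design across all ten groups
  or be fit pairwise is not determinable from the recipe emulated here;
  contrasts are pairwise with a single shared variance prior, which is
  the closer match to per-comparison linear models.
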