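# Methods

## Discovery model

The discovery input is a log2 expression matrix (RMA-style preprocessing is
assumed upstream; the package never transforms values) over a crossed design:
n strains × {control, CR} × replicates, one tissue at a time. Probe-level
matrices are first collapsed to gene level by keeping, per gene, the probe
set with the largest mean intensity over all supplied arrays; ties go to the
lexicographically smallest probe id so the collapse is order-independent.
Unannotated and ambiguous probes are dropped before collapsing.

Per strain, each gene is tested with a two-sided **pooled-variance** two-sample
t-test (df = n_a + n_b − 2). Pooled rather than Welch is the default because
the design is balanced and group variances are modelled as equal; Welch is
available via `welch=True`. Zero-variance genes return t = 0, p = 1 with a
warning instead of NaN. Signed fold changes use the magnitude-≥1 convention
(−4 means 4-fold down), stored next to the log2 difference.

A gene is selected when it passes p < α (strict, default α = 0.01, no
multiplicity correction) in at least k of n strains, **irrespective of
direction**; direction consistency across hit strains is reported as a
diagnostic only. Selection is monotone in k by construction.

## The chance-overlap null

Under strain independence a gene's hit count is Poisson–Binomial with
per-strain success probabilities p_s. The pmf is computed by iterative
convolution — exact, O(n²), numerically trivial at n ≤ 10ish strains — and
G·P(X ≥ k) is the expected consensus count. Two plug-ins for p_s are
provided:

* **observed list fractions** (default): p_s = |strain s's p<α list| / G.
  Real CR effects inflate the primary lists beyond α, and the chance-overlap
  question is about the lists actually in use, so this is the honest null
  for "how many of my consensus genes could be coincidence".
* **nominal α**: p_s = α for all strains, the idealised calibration case.

The null treats genes as exchangeable within a strain (a common p_s) and
independent across genes; both simplifications are inherited by the
simulation-based calibration tests, which satisfy them by construction.
Correlated genes in real data widen the null's variance but leave its mean
(the reported expectation) unchanged.

A pooled two-way fixed-effects ANOVA (strain + diet, additive; Type II sums
of squares so the unbalanced 8 v 7 case is handled) provides the
cross-check p-value for a diet main effect per gene, converted to q-values
with Storey's estimator: π0 from the λ-grid {0.05,…,0.95} smoothed with a
cubic spline and evaluated at λ = 0.95, clipped to (0, 1]; then
q_(i) = min_{j≥i} π0·m·p_(j)/j. With π0 = 1 this is exactly
Benjamini–Hochberg, which the tests assert. The additive model (no
interaction) is the default because the target is a main CR effect; an
interaction-inclusive residual is available via `interaction=True`.

The expression-level bias diagnostic compares the mean log2 expression of
the selected genes against the full transcriptome with a two-sided Wilcoxon
rank-sum test, since consensus selections tend to favour well-measured,
highly expressed transcripts.

## Enrichment

Gene scores are binary (membership in the consensus list); the random-set
z-score standardises a set's mean score against the exact mean/variance of a
uniformly random same-size set (sampling without replacement), which for
binary scores is the standardised hypergeometric overlap. Collections are
intersected with the measured universe, then size-filtered to [10, 1000]
genes inclusive. Significance is one-sided (over-representation only):
z above the upper-normal quantile at α/n_sets (4.34 at α = 0.05 for 7108
sets) *and* at least 5 selected genes in the set. Negative z is reported but
never significant. A continuous-score variant (pass per-gene scores instead
of the binary membership indicator; same moment formulas) is exposed but is
deliberately not the default: the object being enriched is a discrete gene
list.

The waterfall plan summarises significant sets by greedy sequential
coverage: claim the significant set with the most still-uncovered selected
genes, record newly covered vs previously covered members, repeat until no
significant set covers a new gene. Ties break by larger z, then
lexicographic set id. Newly-covered groups are pairwise disjoint and their
union plus the uncovered remainder reconstitutes the selection; per-step
coverage counts are non-increasing. This is a readability device, not a
topology-aware redundancy correction.

## qPCR mimicry screen

Plates are long-format CSV (sample_id, group, gene, ct, is_reference) with
the normaliser made explicit by the ``is_reference`` flag; one reference
gene per plate is the expected case, and when several are flagged their Ct
values are averaged per sample (the geometric-mean normaliser on the
expression scale). Technical
replicates are averaged within a biological sample before any testing, so
biological n drives degrees of freedom. Per gene: ΔCt per sample, ΔΔCt
between group means, relative expression 2^(−ΔΔCt) in the signed fold
convention. The classification of a compound's effect vs the CR reference
panel is *unchanged* when the two-sided pooled t on per-sample ΔCt has
p ≥ 0.05, otherwise *same*/*opposite* by sign agreement of the log2 folds.
ΔΔCt is invariant to uniform Ct shifts within a group (loading/efficiency
offsets common to target and reference), which the tests assert.
Amplification-efficiency correction is out of scope.

## Synthetic data

The generator reproduces the discovery design: defaults of 7 strains × 8 v 8
× 20,000 genes, per-gene baselines N(7, 1.5²) log2 units, per-strain offsets
N(0, 0.25²) (so the ANOVA has a genuine strain main effect), i.i.d. Gaussian
noise of sd 0.5 log2 units, 150 shared-effect genes and 350 strain-specific
genes of fixed effect size ±1 log2 (50/50 up/down), and one attenuated
strain (index 6, the BALB/cJ position) responding at factor 0.5 — emulating
a weak-responder strain. Effects are fixed constants per gene, not
per-sample draws. The noise sd and effect sizes are this package's choices
(variance components are not published for the motivating design); they were
picked so that per-strain power at α = 0.01 is ≈ 0.83, composing through the
5-of-7 binomial tail to ≈ 0.89 expected recovery — the regime the method is
meant for, strong-but-not-trivial single-strain evidence.

Everything derives from one `numpy.random.default_rng(seed)` stream, so a
seed pins the study byte-for-byte. Gene-set simulation samples member sets
uniformly; planted sets oversample a target selection with a configurable
weight factor. qPCR simulation writes Ct values as reference level + gene
offset − sign(fold)·log2|fold| for truly-moved genes, with biological
(sd 0.15 cycles) and technical (sd 0.05) noise at 3 + 3 replicates by
default.

What the simulations do **not** emulate: gene–gene correlation, array batch
effects, probe-level artefacts, heavy-tailed noise (available as an option,
off by default), or strain-by-diet interactions beyond the single attenuated
strain. Passing calibration/recovery tests therefore demonstrates
correctness of the statistics under the model's own assumptions, not
robustness to those violations.

## Numerical choices and edge cases

* Strict inequality p < α for list membership; strict z > threshold for
  enrichment; inclusive set-size bounds.
* Poisson–Binomial pmf via convolution is exact to ~1e-16 against 2^n
  enumeration (asserted to 1e-12 in tests).
* Zero-variance genes: t = 0/p = 1 (equal means) or p = 0 (separated means),
  with warnings.
* Sets of size 0 or N after universe intersection are skipped (zero
  sampling variance).
* Empty selections: enrichment/waterfall return empty results; the
  expression-bias diagnostic raises.
* All file I/O is UTF-8, tab-delimited for matrices/tables, case-sensitive
  gene symbols.

## Problem sizes in tests

The calibration and recovery tests run at 2000–5000 genes with 20 replicate
simulations — large enough that Poisson/binomial sampling bounds are tight
(4σ plus a small additive floor), small enough to keep the suite quick. The
acceptance script uses 20 × 5000-gene null replicates and a single
5000-gene recovery study; at these sizes the Monte-Carlo error on the
recovery rate is ~3 percentage points.

## Known limitations

* The chance-expectation null ignores gene–gene correlation; on real tissue
  data the observed/expected ratio remains interpretable but a formal
  p-value on the consensus count would need a permutation scheme.
* π0 spline smoothing can be unstable for very small m; q-values are
  intended for transcriptome-scale inputs.
* The screen's reference-gene handling assumes one stable normaliser per
  plate; normaliser instability propagates directly into ΔΔCt.
* Full-scale reproduction of the motivating dataset depends on the
  annotation version used for probe collapse and on GO release for set
  counts; consensus counts are annotation-sensitive.
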