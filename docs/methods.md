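# Methods

This note records the statistical models, rule conventions, defaults and
numerical choices behind `irgloss`, and what the synthetic-data tests do
and do not establish about real data.

## Classification rule ladder

Every protein is mapped to exactly one of 14 IRG classes or NONE by a
most-specific-first precedence ladder (see `irgloss.classify`). Three
conventions deserve note, because the underlying domain-rule literature
leaves them open:

- **"Upstream" for CTNL** means both TIR and CC occur before the *first*
  NBS in the ordered domain list; the relative order of TIR vs CC is
  immaterial. If TIR+CC+NBS+LRR are present but the upstream condition
  fails, the protein falls through to TNL.
- **NBS presence always routes to the NLR branch.** A protein with NBS
  plus PRR-style domains (e.g. NBS+TM+kinase) classifies as an NLR class
  (here N), never as a receptor-like kinase; likewise NBS disqualifies
  TIR-X (whose defining rule is "TIR plus any additional *non-NBS*
  domain"). Similarly, LysM rules precede the LRR receptor rules, so
  LysM+TM+LRR is LYP. These resolutions are deterministic and exercised
  by an exhaustive enumeration test (all architectures up to length 4
  over the 10-token vocabulary) against an independently coded rule
  table.
- **Unknown domain tokens** ingest as OTHER with a warning. OTHER counts
  toward TIR-X's "any additional domain", matching that rule's
  open-ended character; OTHER alone matches nothing.

## Repertoire difference testing

Differences use the **wild − crop** sign convention, so a uniformly
reduced crop produces an all-positive vector and the signed-rank
statistic attains its maximum V = m(m+1)/2. The normalizing denominator
is the sum of **absolute** differences (a signed sum could be zero or
negative and would not normalize). Identical repertoires yield the
all-zero vector, which is reported as a degenerate non-test (p = 1)
rather than being pushed through either branch.

The Shapiro–Wilk gate uses the Royston approximation (via scipy) at
threshold 0.05, strictly "> 0.05 ⇒ t-test". Shapiro–Wilk at n = 14 (or
9/5 in subscopes) has low power; this is accepted as-is, with no
fallback, because the gate is part of the procedure being implemented,
not a recommendation.

The Wilcoxon signed-rank test drops exact zeros, uses average ranks for
ties, and computes the **exact** two-sided p-value whenever the
remaining m ≤ 25 values are tie-free: the null distribution of the
positive rank sum over all 2^m equally likely sign assignments is built
by a counting recursion (O(m³) rather than O(2^m), but identical to
enumeration — a property the tests verify against a literal sign-vector
enumeration for m ≤ 12). With ties, zeros dropped to m > 25, or
otherwise, the normal approximation with tie-corrected variance and a
0.5 continuity correction is used, matching R's `wilcox.test`
conventions (half-integer V values arise naturally from average ranks).

BH correction is the step-up adjustment adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j,
capped at 1. The default family is **the crops within one scope** (m =
number of crops); pooling all scopes into one family is available via
`bh_family="joint"` in the pipeline. Per-scope families are the default
because each scope asks a distinct biological question (whole repertoire
vs NLR-only vs PRR-only).

## Gene-loss accounting

Presence means ≥ 1 gene of the species in the orthogroup; copy number is
ignored. Only outgroup-referenced orthogroups enter the analysis
universe. The loss rules are deliberately asymmetric to double absence:
an orthogroup absent from *both* ingroups is counted in denominators but
is not a loss event for either species, since each rule requires
presence in the other ingroup. Consequently simultaneous double losses
are invisible; the synthetic recovery tests condition on this (the
effective denominator for the crop-loss rate is the set of
wild-present orthogroups).

IRG orthogroups are a subset of the genome-wide universe, so the
genome-wide denominator includes them. The crop-vs-wild contrast is the
Welch (unequal-variance) two-sample t with Welch–Satterthwaite df — the
equal-variance form would give integer df and is not what the analysis
calls for. The paired IRG-vs-genome-wide contrast reuses the same
Shapiro-gated dispatch as the repertoire tests (t on the differences,
signed-rank fallback).

## PGLS

The residual covariance is pure Brownian motion: C[i,j] equals the
root-to-MRCA shared path length (diagonal = root-to-tip distance). No
signal-strength transformation (Pagel's λ, OU) is estimated: the model
is plain GLS with known correlation structure, fitted exactly by
Cholesky whitening. Wald t statistics use df = n − p. Crops not present
in the tree are handled by an explicit tip-rename map (proxy relative),
never by fuzzy matching. Predictors enter untransformed; the slope for a
predictor measured in years is therefore in percentage points per year,
which is why realistic effects are of order 10⁻³–10⁻⁴.

VIFs come from ordinary (non-phylogenetic) auxiliary regressions on the
raw design, as an initial linear model would compute them; perfect
collinearity reports `inf` rather than raising.

Numerical conventions: covariance must be positive definite (Cholesky
failure raises); rank-deficient designs raise; n = p + 1 fits are
produced with a warning (df = 1). GLS with C = I agrees with OLS to
better than 1e−10 on well-conditioned inputs, and the whole fit is
cross-checked against an independent GLS implementation in the tests.

## Synthetic-data generator

The generator's defaults describe a study of 15 crop/wild/outgroup
triplicates: proteomes of 5000 proteins with ~2.7% IRGs distributed over
the 14 classes at plant-realistic relative frequencies (NLRs and
LRR-kinases dominant, CTNL and RPW8-X rare), 20000 outgroup-referenced
orthogroups per triplicate, 3% background loss with a +2-point additive
IRG-specific excess in crops, and a Brownian trait model (σ² = 0.25,
slope 5×10⁻⁴ per year of domestication, domestication times uniform on
1–12 kyr). Where a parameter had no dictated value these were chosen
once as field-plausible magnitudes and are not tuned.

Architectures are drawn noise-free from fixed per-class templates, and
non-IRG decoys come from a fixed list verified to match no rule — so
classifier round-trips are exact by design. This validates the *rule
logic*, not robustness to annotation noise: real domain callers truncate,
split and mislabel domains, and none of that is modelled. Likewise
orthogroup losses are independent Bernoulli events with at most one gene
per species (multi-copy orthogroups are exercised by hand-written
fixtures), and the trait model has no measurement error. Passing tests
therefore demonstrate correctness of the computations on clean inputs,
not performance under real annotation error.

All randomness flows from one integer seed through named substreams
(`SeedSequence(seed, spawn_key=(purpose, index))`), so each table is
reproducible in isolation and the pipeline's output tree is
byte-identical across reruns of the same configuration.

## Pipeline

Stages write to their own subdirectories and never mutate another
stage's inputs; a manifest records the configuration hash (computed over
everything except the output location), the seed, and per-stage row
counts. P-values are serialized at full precision (`%.17g`); any
rounding is confined to human-readable display. Problem sizes in the
examples and tests (8–15 triplicates, 10³–2×10⁴ orthogroups, 10³ PGLS
replicates) were chosen to make every property measurable with
comfortable Monte-Carlo margins while keeping the whole suite fast.

## Known limitations

- The classifier is a rule engine over domain calls; it cannot rescue
  misannotated domains and has no confidence notion.
- Exact Wilcoxon p-values are unavailable in the presence of ties
  (average-rank ties make the 2^m enumeration non-uniform); the normal
  approximation is used there, as standard practice does.
- Gene gains, copy-number change and double losses are out of scope of
  the loss rules.
- PGLS assumes the supplied tree and branch lengths are correct and the
  Brownian structure adequate; no model comparison is offered.
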