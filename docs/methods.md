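# Methods

## Data model

All behavioral data live in a long-format trial table: one row per
response event, with observer id, task (`naming` | `rating` | `afc`),
the stimulus's true material and transformation, an exemplar index
(execution/viewpoint, treated as replication rather than a factor), a
block label, and exactly one populated response field (free text, a
[0, 1] rating, or a chosen category). CSV serialization is UTF-8,
comma-separated, header required, free text quoted; write→read
round-trips preserve every field.

The naming task asks two questions per stimulus (material name and
process name), so naming rows carry a `block_scale` of `material` or
`transformation` marking which question a row answers — the same column
that holds the scale label for rating rows. This keeps one schema for
all three tasks at the cost of overloading one column, which we prefer
to a task-specific schema.

Free-text responses are coded by normalization (case-folding, whitespace
collapse) and lexicon lookup. Strings without a mapping resolve to a
literal OTHER bucket that retains the original text; responses
containing the delimiter (default `;`) are split, each part counting as
one response event in all denominators. Coding is deliberately
mechanical — no stemming, no translation — because manual response
coding cannot be reproduced algorithmically; the lexicon is an editable
YAML mapping so users can extend it to their response corpus.

## Observer simulator

The simulator is a measurement model, not a perceptual theory. Each
(material, transformation) stimulus cell has a *confusion kernel*: a
probability vector over the task's response categories. Default kernels
place `accuracy` mass on the true category and spread the rest
uniformly; for transformation responses the bent↔folded off-diagonal
entry is replaced by `(base + confusability) · multiplier(material)`
before renormalization, so bent/folded confusions are elevated and can
be modulated per material (e.g. doubled for wire). `accuracy = 1/k`
recovers chance (uniform rows), `accuracy = 1` the identity.

On top of the kernels:

* **lapse rate** — probability of a uniform random response (default
  0.02 in the pipeline defaults; small but nonzero, as in standard
  psychophysical practice);
* **out-of-lexicon rate** (naming only) — probability of emitting a
  string outside the lexicon (default 0.1, matching the observation that
  a minority of free-naming responses fall outside the target
  categories);
* **rating noise** — additive Gaussian on the probability scale,
  truncated to [0, 1] (default SD 0.1); the rating for scale *s* is the
  kernel probability of *s* plus this noise, the simplest bounded model
  of a continuous "not true"–"true" bar;
* **observer jitter** — per-observer log-space Gaussian perturbation of
  kernel rows followed by renormalization (default SD 0.3), keeping rows
  valid probability vectors while producing realistic inter-observer
  spread.

Defaults were chosen once as plausible values for a task in which groups
perform well above chance with bent/folded as the dominant confusion;
none is estimated from data. Task designs follow the reference study's
arithmetic: 6 materials × 4 transformations × 30 exemplars = 720
stimuli; naming uses 24 stimuli per observer (one random exemplar per
cell, two questions each); rating uses 168 stimuli (the first 7
exemplars per cell, fixed across observers) rated once on each of the 6
material or 4 transformation scales; forced choice presents all 720.

What the simulator does *not* emulate: image-computable structure (no
shape features), execution/viewpoint effects (exemplars are i.i.d.
draws from the cell kernel), sequential effects, learning, or response
times. Passing tests therefore validate the *statistical pipeline* —
that known confusion structure is recovered and correctly summarized —
not any claim about human vision.

## Confusion matrices

Three semantics, one per task. Naming matrices are percentages of *all*
responses per actual category, with OTHER mass reported per row rather
than as a column — rows need not reach 100%, and the square matrix used
for perf/R² excludes OTHER. Rating matrices are mean ratings per actual
category × scale, averaged over exemplars and repetitions; the rating
bar maps linearly to [0, 1] and the mean normalized rating is taken as
the cell's accuracy. Forced-choice matrices are choice proportions (rows
sum to 1). Group matrices may pool trials or average per-observer
matrices; both are exposed and coincide under balance. Empty cells raise
errors rather than becoming silent zeros, since the designs are balanced
and an empty cell always indicates a data problem.

## perf, R², bootstrap and null

perf = 1 − mean(|R − P|) with both matrices on [0, 1] (percent matrices
divided by 100 so the chance level 0.5 is meaningful on all tasks);
P defaults to the identity. R² is the squared Pearson correlation of the
flattened matrices, reported for the group-average matrix.

The 95% CI on perf is a percentile bootstrap resampling **observers**
with replacement (default 10,000 replicates): observers are the
exchangeable units, and the statistic of interest is the group-mean
matrix's distance to the prediction. At 15 observers the percentile
bootstrap undercovers slightly (measured ≈ 0.92 at nominal 0.95 in the
test suite's reduced-replication study); we accept this known property
rather than switching to BCa, keeping the method transparent.

The null ensemble scores the group-mean response matrix against random
prediction matrices (default 100,000): i.i.d. uniform[0, 1] entries
(`uniform`, the default — it yields the analytic chance level
E[perf] = 0.5 for binary response matrices and realistic null CI
widths), or row-permuted identities (`permutation`, whose perf values
against an identity response are fully enumerable from permutation
fixed-point counts). The mean R² against uniform random predictions is
not exactly zero but 1/(cells − 1) in expectation (≈ 0.03 for a 6 × 6
matrix) — zero at the precision such values are conventionally printed.

Inter-observer consistency is the mean Pearson correlation over all
unordered pairs of flattened individual matrices; constant matrices are
excluded with a warning (their correlation is undefined).

## Repeated-measures ANOVA

Accuracy per observer × material × transformation cell: proportion
correct (forced choice), mean rating on the true-category scale
(rating; a composite penalizing false-scale ratings would be an
alternative, exposed through the cell-means accessor rather than
hard-coded), or proportion of correctly coded names (naming).

The two-way fully-within decomposition tests each effect against its
effect × subject interaction. Huynh–Feldt epsilon is computed per effect
from the covariance of the effect's orthonormal-contrast scores
(Kronecker products of one-factor contrast bases; the interaction uses
the Kronecker product of both factors' contrasts), with
ε_HF = (n·d·ε_GG − 2) / (d·(n − 1 − d·ε_GG)) capped at 1 — the same
construction as R's `car::Anova` univariate output, against which the
implementation is verified to 1e-6 (including the interaction term,
where pingouin's two-way epsilon differs and warns of inaccuracy).
Corrected p values come from the F distribution at (d₁ε, d₂ε) degrees of
freedom. A two-level factor has ε = 1 exactly; zero error SS yields
F = ∞ with p reported as 0. Under simulated non-spherical nulls the
corrected test holds its nominal .05 level (measured ≈ 0.05 at 2,000
simulations per effect).

Post-hoc comparisons are paired t tests over observers on level means
averaged across the other factor, reported with raw two-sided p values
flagged at .05 and .001 — no multiple-comparison correction, matching
how such tables are conventionally reported alongside an omnibus test.

## Scission PCA

Profiles are mean ratings per aggregate group × scale; the default
granularity is one row per material × transformation cell (24 rows),
with single-factor aggregation also exposed since the reported analyses
are ambiguous between the two. PCA centers columns but does not scale
them (all columns share the [0, 1] rating unit) and uses an
eigendecomposition of the covariance with a deterministic sign
convention (largest-magnitude loading positive); it matches
scikit-learn's PCA up to sign and is implemented directly so the sign
convention and centering policy are explicit. Separability is the mean
silhouette of rows in the first three components (three, matching the
dimensionality at which such embeddings are inspected visually) under a
given labeling; identical points score 0 by convention, a single label
is an error.

The scission property — material-driven rating kernels produce profiles
separable by material but not transformation, and conversely — is tested
as a sign test over 20 seeded simulations of both rating tasks and holds
in every run.

## Pipeline, determinism, problem sizes

`RunConfig` serializes every knob (task, input, simulator parameters,
seeds, resampling sizes) to YAML; `run_pipeline` executes
simulate/ingest → validation → confusion → performance statistics →
ANOVA → PCA, writes all artifacts plus a manifest, and is bit-identical
on rerun. All randomness flows from a single integer seed through
`numpy.random.default_rng`; derived sub-seeds stay below 2³¹.

The test suite and the acceptance script run at the study's native scale
(15 observers; 720 forced-choice stimuli; 168 × 6/4 rating trials) —
these sizes are small enough that no down-scaling is needed. Resampling
sizes default to 10,000 bootstrap replicates and 100,000 null draws,
both vectorized. The Monte-Carlo studies embedded in tests (bootstrap
coverage at 300 replications, type-I error at 2,000 simulations) use
reduced replication counts chosen to keep Monte-Carlo error well inside
the asserted bands.

## Known limitations

* The simulator's parameters are free; nothing here estimates them from
  data, and real observers' confusions need not follow an
  identity-plus-pair-confusion kernel.
* The lexicon approach cannot reproduce manual, context-sensitive
  response coding; naming statistics therefore depend on the lexicon
  supplied.
* The deposited-data adapter assumes a flat CSV with a user-supplied
  column mapping; it has been exercised only on constructed files.
* The null ensemble's construction (what "random prediction matrix"
  means, and what it is compared against) admits several readings; both
  implemented variants are explicit, and the default is documented
  above.
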