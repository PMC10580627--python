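# Methods

## Scope and model

`generank` operationalizes a seven-step, knowledge-driven gene
prioritization protocol for co-expression modules of a fixed blood
transcriptome repertoire. The statistical core is deliberately simple —
the contribution is the *workflow contract*: structured elicitation of
0–10 rubric scores from text-generation models, a fixed aggregation rule,
auditable parsing of a constrained record grammar, fact-check gating of
model-generated claims, and explicit context-budget handling when feeding
expression evidence back to a model.

The package never requires a live model. Scripted backends replay
recorded transcripts; the simulated scorer draws scores around a latent
relevance profile, which turns the pipeline into an instrument whose
recovery behavior can be measured against known ground truth.

## Scoring and aggregation

Each gene is scored once per prompt (models degrade when asked to score
several genes at once), in R replicates per model. Scores are integers in
[0, 10]; fractional score text is treated as a malformed record, not
rounded. The ranking statistic averages replicates within model first,
then models with equal weight, then sums the six per-criterion means.
With equal replicate counts this order coincides with pooling replicates
across models; the within-model-first order is kept because models are
distinct scorers whose replicate counts can diverge when malformed
responses are dropped. Criteria (and the three themes they instantiate)
are equally weighted by design; a weighted hook is intentionally not
provided. Ties in the cumulative score break by ascending gene symbol —
deterministic and audit-friendly.

Missing cells are NaN, never zero. A gene whose every cell for one
criterion is missing has that criterion contribute 0 with a logged
warning, mirroring tolerance of occasionally malformed replicates without
discarding the gene. A gene with no usable cell at all is a hard error.

Consistency matrices use Pearson correlation on the 0–10 interval scores
(configurable in principle; Spearman was considered and documented as the
road not taken since the scores are interval-scaled and the comparison
targets agreement in level, not just order). Vectors with zero variance
have undefined correlation and yield missing cells; pairs sharing fewer
than three genes are refused.

## Record grammar

A scoring response is one line of 21 pipe-delimited fields (3 header
fields + 6 × comment/references/score). The parser applies a bounded
repair pass before failing: internal newlines joined, a stray leading or
trailing delimiter stripped, literal doubled delimiters collapsed. After
repair the field count must be exactly 21 — weaker models deviate from
the format, and bounded repair with a hard failure keeps behavior
auditable where silent coercion would not be. Citations are
`"Author, Title, Year, Journal"` quoted groups; the title absorbs
interior commas, and a group that cannot be decomposed is kept leniently
with the raw text preserved and a note attached. Because the grammar has
no escape rule, the formatter replaces a raw `|` inside a field with `/`
(an artifact convention, documented here). A comment is mandatory only
for scores at or above 4; its absence below the threshold is legal.

## Selection extraction

Printed model answers name their pick in a preface sentence ("I would
suggest ALAS2 as the top candidate…"). Extraction strips parenthesized
spans — in the recorded transcripts these carry shortlist enumerations
and protein aliases, never the pick — then takes the first sentence
mentioning any candidate and requires exactly one distinct candidate
symbol there. Multiple distinct candidates in that sentence, or no
candidate anywhere, fail loudly; the extractor never guesses.

In the data-informed stages, a dataset whose textualized corpus exceeds
the model's single-context token budget is skipped with a warning and the
prior choice carried forward; partial context is never fed silently
(splitting a corpus across prompts makes models lose the conversation
thread, which is why budget violations skip rather than chunk-and-send).

## Fact-check gating

Every summary statement is sent to a backend with a fact-check prompt;
quoted citations in the reply are resolved by a pluggable resolver.
The packaged resolver is an **offline stub**: a lookup table keyed by
(first author, year, normalized title) with placeholder identifiers,
sufficient to exercise the verified/eliminated/unverified contract. A
statement verifies with ≥ 1 resolved reference (the threshold is config);
with zero it is eliminated and excluded downstream; with no resolver
everything is unverified — never silently verified. A live
literature-database resolver can be plugged in through the same callable
contract.

## Textualization and token accounting

The three sentence templates are fixed and invertible; counts and
intensities print as integers when integral, fold changes via the
shortest round-trip decimal representation (so `-0.3697682` survives a
render/parse cycle exactly). The token estimator is `ceil(chars / 4)` — a
stated heuristic rather than a vendor tokenizer, chosen so budgets are
deterministic and model-independent; per-model budget values (e.g. 8192
or 100 000 tokens) live in the workflow config. The sentence parser takes
the species as the first whitespace token after "In "; multi-word species
names would be split into the context label, a documented limitation.

Module activity is 100·(n_up − n_down)/n_total per patient, with a gene
counting as regulated only when **both** the fold-change and the
raw-difference gates pass in the same direction (the difference gate
suppresses large ratios of near-zero signals). The raw difference is
interpreted on the measurement scale as case value minus control mean,
sign-matched to direction; the cutoffs (1.5, 10) are arguments, not
constants. Cohort-level summaries are left to callers as per-patient
distributions; no single cohort scalar is imposed.

## Synthetic data

Two generators define the study conditions.

**Expression** (`synthetic_expression`): designated erythroid-restricted
genes are expressed `restriction_ratio` (default 50) times higher in the
restricted populations and in whole blood — whole blood contains the
restricted cells, isolated leukocyte fractions do not — over a baseline
of 50 units; cohorts shift module genes by configured mean log2 fold
changes (defaults span +2.5 for the strongest up-cohort to −2.0,
matching the direction structure of the reference cohorts: melanoma,
pregnancy, RSV, transplant up; influenza, MS down); multiplicative
log-normal noise with σ = 0.25 on the log2 scale, 10 patients and 10
controls per cohort. With zero noise the restriction ratio is exact.

**Studies** (`generate_synthetic_study`): latent per-criterion relevance
levels are uniform in [2, 8]; the planted top gene gets a flat profile
whose latent cumulative score exceeds the best competitor by exactly
`margin` (default 2), so only the runner-up sits at the stated gap.
Simulated scorers emit `clip(round(latent + ε), 0, 10)` with
ε ~ N(0, noise_sd) (default 0.5) from a stream addressed by
(seed, gene, criterion, replicate), making any single cell independently
replayable. Defaults: 10 genes, 2 models, 3 replicates.

What the generators do **not** emulate: correlated errors between
criteria or models, systematic per-model score offsets, format deviations
(the simulator always emits valid records; parser robustness is tested
separately), and hallucinated citations. Passing recovery tests therefore
show that the aggregation pipeline is a faithful instrument under
independent noise — not that any live model scores genes accurately.

## Packaged resources and their quirks

All worked-example material ships as plain-text resources under a sha256
manifest verified before load. The module table is reproduced verbatim,
including printed duplicate members (e.g. CHPT1 twice in M14.53's 17
printed entries; normalization dedups to 16). Two source-table rows are
internally inconsistent — M11.4 prints a size of 25 against 26 unique
listed symbols, M13.30 prints 32 against 29 — and are reproduced, not
repaired; size invariants are asserted for the nine self-consistent rows.
Likewise the theme table prints IFITL1 where the module table prints
IFIT1L; both spellings are kept where they appear. Symbol normalization
is lexical only (trim/uppercase/dedup); no alias or identifier-mapping
service is consulted.

## Problem sizes and numerics

Default test and acceptance sizes: 30-gene module × 2 models × 3
replicates for full-tensor runs; recovery Monte Carlo of 100 seeded runs
at 10 genes; exhaustive ranking-oracle sweep over all 3^8
2×2×2×1 tensors on the {0, 5, 10} alphabet plus seeded random tensors at
5×6×3×3. Score rounding is floor(x + 0.5) (half always up), avoiding
bankers'-rounding surprises at .5 offsets. All random streams derive from
user-visible integer seeds through independent, component-addressed
`numpy` generators; nothing reads global RNG state.

## Limitations

Live vendor adapters (and therefore sampling-parameter handling,
streaming, and real tokenizers) are out of scope; replicate-to-replicate
variability of real services is uncharacterized, so the simulator's
noise level is a free parameter, not an estimate. The fact-check stub
validates the pipeline contract, not real bibliographic truth. The CLI
exposes the per-artifact operations (`rank`, `consistency`, `textualize`,
`converge`, `consensus`) and one orchestrated `run`; the intermediate
scoring/summarize/factcheck/select steps are exercised through the
library API, which is the intended surface for backend-specific
composition.
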