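# Methods

## Model and task

Section identification is framed as instruction following: the model is
given a free-text description of every allowed section type and asked to
list, for each section it finds in the note, the section name plus
verbatim copies of the section's opening and closing text. Generative
models are unreliable at emitting character offsets directly but copy
text well, so offsets are recovered afterwards by locating the copied
anchors in the note. The approach assumes sections are contiguous and
non-overlapping, that a note is (conceptually) fully covered by the
predicted starts up to the next section, and that anchor texts of a few
dozen characters are specific enough to be located essentially uniquely.

## Prompt

Four components, in order: system message (clinician persona), task
description, one definition line per section type
(`<name>: <definition>, example section headings include '<h1>', …`),
then two exemplar output blocks, the note verbatim, and an `Output:`
cue. The exemplar blocks are synthetic, written in the exact required
shape, and validated against the same format check the backend applies
to model output. Rendering is byte-deterministic; prompt length is
affine in note length for a fixed schema.

## Retry on malformed output

A response is usable if it contains at least one block matching
`Section <int>: <text> Starts at: <text> Ends at: <text>` with
case-sensitive keywords and non-empty fields. Up to `max_retries`
(default 3, a package choice) additional generations are requested; if
all fail, the note contributes zero predicted sections — it penalizes
recall rather than aborting a corpus run. The parser is lenient beyond
the minimum check: well-formed blocks are extracted from amid free text,
and each block's trailing field runs until the next block header, so
commentary after a block folds into (and is stripped from) the last
field.

## Span resolution

Offsets are 0-based with inclusive endpoints; a span `[start, end]` has
length `end − start + 1`. The six resolution steps are described in the
README and `resolver`'s docstrings. Choices made where the procedure is
underdetermined:

- **Repeated start anchors.** Starts are located in emission order with
  a moving cursor (search from just past the previous start; on failure
  retry from the beginning of the note). This preserves note order for
  models that emit sections in order, while still recovering
  out-of-order emissions, and prevents two sections collapsing onto one
  occurrence. Identical resolved starts are deduplicated keeping the
  first, which also rules out zero-length sections.
- **End anchor position.** Within a section's window the *rightmost*
  qualifying match decides the end — an end marker later in the window
  dominates — and position outranks similarity score when fuzzy
  matching. A missing end match leaves the tentative end (next start −
  1; the last section tentatively ends at the last character of the
  note).
- **Name matching** is exact or case-folding only; no punctuation or
  whitespace normalization is applied to names.

### Fuzzy matching

Similarity is `100 · (1 − d/m)` with `d` the unit-cost Levenshtein
distance and `m = max(|a|, |b|)`; two empty strings score 100. The
normalization by the longer string is one reasonable reading of
"length-normalized"; the acceptance threshold (default 90) is compared
against scores computed as `100·(m−d)/m` so the boundary case (one
deletion against a length-10 query) lands on exactly 90.0 in floating
point.

The search considers candidate substrings with lengths within
[⌈0.8·|q|⌉, ⌊1.2·|q|⌋+1]. The window is sound with margin at threshold
90: similarity ≥ 90 forces the length difference below 10% of the longer
string. A brute-force all-substrings oracle guards this in the tests.
Ties break toward the smaller start offset, then the shorter candidate.
An exact occurrence short-circuits the scan (it always scores 100, which
nothing else can reach). The scan itself is a banded dynamic program
over the query, vectorized across all start positions, reading off the
distance for every candidate length from one pass; cost is
O(|note| · |q|²/…) in vectorized numpy operations and handles the
package's note sizes in milliseconds to tens of milliseconds per query.

## Evaluation

`Evaluate(L1, L2)` is directional: each S1 takes the maximum-overlap S2′
(ties: earliest start, then list order), contributes
`r = overlap/|S1|`, and counts as correct when overlap is strictly
positive *and* labels agree — the positivity guard keeps a vacuous
zero-overlap "counterpart" from counting. Degenerate conventions, chosen
to keep corpus aggregation total: empty L1 gives accuracy 0 and match
ratio 0 (flagged degenerate); empty L2 gives every r = 0;
precision + recall = 0 gives F1 = 0. Micro aggregation pools correct
counts and section counts across notes for precision/recall and pools
the per-section r lists for the match ratios. Per-type rows score the
label's own sections against the *full* opposite list (a prediction
matching a differently-labeled gold section is incorrect but still
contributes span coverage), and are sorted by F1 descending. When
several prediction files are evaluated together, the report carries each
run's scores and their mean and standard deviation.

## Synthetic data

The generator stands in for restricted clinical corpora. Defaults: 6–12
sections per note, drawn without replacement from the schema types that
have example headings; each section is a heading line (sampled from the
type's example headings, original casing, colon-terminated) plus
150–400 characters of seeded pseudo-clinical word salad; 50 notes per
corpus. This yields notes of a few kilobytes with roughly 450 gold
sections per corpus — sized so every study in the test suite and the
acceptance script completes quickly at one CPU while still exercising
corpus-level aggregation. Gold spans tile the note exactly, and sections
begin and end on non-whitespace so that whitespace-trimmed copied
anchors still pin the exact boundaries.

Simulated responses copy each section's first/last 30 characters as
anchors (30 keeps one or two injected edits comfortably above the
90-similarity threshold: one edit on a 30-character anchor scores
≈ 96.7). Error injection covers invalid names, case-mangled names,
anchor typos (each injected corruption is re-drawn until it genuinely
corrupts — differs from the original and occurs nowhere in the note
verbatim, making ablation directions deterministic), dropped sections,
block reordering, and malformed blocks; a manifest tallies every
corruption actually applied. Reproducibility comes from one
counter-derived random stream per note.

What the generator does *not* emulate: real clinical language, heading
ambiguity across types, nested or overlapping sections, annotation
idiosyncrasies (e.g. disagreement about boilerplate like dictation
lines), or notes whose sections do not tile the text. Passing round-trip
and ablation tests therefore demonstrates the correctness of the
pipeline's mechanics — format checking, anchor resolution, variant
matching, scoring — not performance on real notes, which depends on the
model queried and the corpus.

## Bundled schemas

The 27-type discharge and 15-type progress schemas are authored
reconstructions of conventional note structure; their definitions and
example headings are editable starting points (`load_schema` on a user
YAML overrides them) and carry no clinical validation. Both include an
`Unknown` catch-all; raw-label mapping falls back to `Unknown` only when
the schema defines it, otherwise unmappable labels are an error.

## Known limitations

- The HTTP backend is a thin generic chat-completion client; it is
  exercised only at the contract level in tests (no live endpoint).
- Fuzzy-threshold semantics depend on the max-length normalization
  above; implementations normalizing by alignment length or mean length
  would place the 90 boundary slightly differently.
- The resolver assumes one section per start offset and cannot represent
  nested sections.
- Match ratios for the last section depend on the tentative-end
  convention (end of note), which can overstate coverage for notes with
  trailing boilerplate.
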