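# Methods

## Problem and approach

Bone marrow reports are composed of named sections (specimen received,
clinical information, peripheral blood smear, bone marrow aspirate,
aspirate differential, iron content, bone marrow biopsy, comment,
diagnosis, disclaimer) whose headers make ground truth cheap to harvest:
splitting a report at its header lines and deleting the headers yields
labeled text blocks. `marrowsect` asks how well a lightweight, unsupervised
model can put the labels back — a useful primitive for report completeness
checking, storage organization, and bootstrapping labeled corpora for
heavier NLP models.

The model is a pipeline of classical pieces:

1. **Token replacement.** Accession identifiers, CD immunophenotyping
   markers, and numeric literals each carry section information, but every
   surface form is nearly unique. Each match is replaced by a fixed
   placeholder word (`ACCNUM`, `CDNUM`, `NUM`), collapsing the class to a
   single vocabulary entry. Precedence is accession > CD > number so
   `CD34` never loses its digits to the number rule. Replacement is
   idempotent (no placeholder contains a digit) and never touches
   whitespace, case, or punctuation.
2. **Featurization.** Text is tokenized by whitespace splitting only —
   case and attached punctuation are preserved because capitalization is
   itself a section cue (diagnosis lines tend to be fully capitalized).
   The V most frequent n-grams of the *training* text (default V = 200,
   total-occurrence counting, lexicographic tie-break at the cutoff) form
   the vocabulary; each block becomes a binary vector marking which
   vocabulary n-grams occur at least once in it.
3. **Clustering.** K-means (Lloyd's algorithm, squared Euclidean
   distance) with k = 10 centroids — one per section — is run 10 times
   from random initializations (k distinct data points each); the run with
   the lowest SSE wins. Every restart's SSE and the winner's per-iteration
   SSE trajectory are kept on the model object so the selection contract is
   checkable. Empty clusters during an iteration are reseeded with the
   globally worst-fit point. Iteration stops when assignments stop
   changing or after 300 iterations.
4. **Cluster → section map.** Each cluster is assigned the modal true
   section of the training blocks it captured (ties break to the smallest
   canonical section index; a cluster that captured nothing falls back to
   the global modal section). Prediction = featurize, nearest centroid,
   map lookup. Scored on the same labeled set that derived the map,
   accuracy is identically the size-weighted mean of cluster purities — a
   property the tests assert exactly.
5. **Ensemble.** One cluster typically ends up far less pure than the
   rest, mixing short or position-stereotyped sections. Blocks landing in
   the lowest-purity cluster are re-classified by a second 5-centroid
   K-means over three structural features: the number-token count, the
   median paragraph length in words (a paragraph is a non-blank line), and
   the block's relative location in its report
   (`block_index / (blocks − 1)`, 0 for a single-block report). The three
   features are standardized by the training mean and standard deviation
   before clustering, since raw counts would dominate a ratio in [0, 1].
   Blocks outside the target cluster keep their first-stage label
   bit-identically.

The train/test split is chronological (oldest 80% of reports train), so
evaluation always asks whether a model trained on older reports transfers
to newer ones.

## Choice of k and the elbow analysis

`sse_curve` fits every k in 1–19 (fresh derived seed per k) and
`elbow_point` takes the k maximizing the second forward difference of the
curve — the standard elbow criterion made mechanical. The harness reports
both the elbow-k accuracy and the k = 10 accuracy; k = 10 (one centroid
per section) is the default because matching centroids to sections
consistently scores higher than the elbow choice.

## Design choices where the design was open

- **Vocabulary provenance.** The vocabulary is built from training text
  only; the harness structurally cannot leak test text into it. An
  evaluation flag (`map_on_test`) exists to re-derive the cluster map on
  evaluation labels for protocol comparison, but it is off by default
  because it peeks at labels the model should not see.
- **Target-cluster selection.** The ensemble's target cluster is chosen by
  *training* purity, keeping the predictor label-free at test time. The
  alternative protocol — selecting the target and fitting the second
  stage on the labeled evaluation corpus itself — is available by passing
  that corpus to `fit_two_stage`, but it is not the default because it
  requires evaluation labels at fit time.
- **Header matching.** A header matches only when an entire line equals
  the header string (optional trailing colon, case-sensitive). Full-line
  matching prevents "Bone Marrow Aspirate" from also matching the
  differential's header. Header spellings are configurable per
  institution. Text before the first header is dropped with a warning;
  empty-bodied sections are kept as empty blocks so block positions stay
  faithful; a duplicated section yields two blocks with the same label.
- **Token spellings and patterns.** Placeholders are single words so they
  survive whitespace tokenization. Default patterns: accession =
  1–2 uppercase letters, 2 digits, hyphen, 3–6 digits; CD = `CD` followed
  by digits (case-sensitive); number = optional sign, digits, optional
  decimal part (a trailing `%` stays attached to the token as
  punctuation). An optional single-letter+digits rule and an end-of-report
  marker exist but are disabled by default. All patterns are configurable.
- **Tie-breaks.** Frequency ties in the vocabulary break
  lexicographically; cluster-map ties break to the smallest canonical
  section index; nearest-centroid ties break to the lowest cluster id;
  elbow ties break to the smallest k. Every tie rule exists to make fixed
  seeds produce byte-identical outputs.

## The synthetic corpus

Real marrow report corpora cannot leave hospital laboratory information
systems, so the package ships a seeded generator
(`marrowsect.synthetic`) that emulates the *structural* signals the
method exploits without imitating any institution's prose: ten sections in
canonical order behind header lines; templated section-specific word pools
mixed with a shared function-word pool; an accession id in specimen
received; a numeric-dense differential and blood smear; a one-line iron
content section; CD mentions concentrated in aspirate and biopsy sections.

Key conditions (defaults chosen once as realistic for templated pathology
reporting and not tuned):

| parameter | default | meaning |
|---|---|---|
| `n_reports` | 500 | corpus size; large enough for stable metrics at minute scale |
| `shared_vocab_overlap` | 0.3 | probability a content word comes from the shared pool; the difficulty dial |
| `section_dropout` | 0.1 | probability a non-mandatory section is omitted from a report |
| `seed` | 7 | root of all generator randomness |

`no_signal_config()` (overlap 1.0, structurally identical profiles, no
accession) is the negative control: with nothing distinguishing sections,
pipeline accuracy falls to the majority-section baseline, and the tests
assert that it does.

What the generator does *not* emulate: clinical phrase statistics, real
header spelling variation, cross-sectional correlations (a leukemic
differential co-occurring with a leukemic diagnosis), report length drift
over time, or transcription noise. Passing tests therefore demonstrate
that the implementation behaves as designed on data with the assumed
structure — not that any particular accuracy will be achieved on a given
institution's reports, which depends on how templated that institution's
reporting is.

## Problem sizes and numerics

The default experiment grid (tokens on/off × n 1–5 at k = 10, k sweeps
1–19 for n ∈ {1, 2}, ensembles for n ∈ {1, 2}) runs on the 500-report
corpus — about 4,700 blocks, 3,700 of them training — in roughly two
minutes on one core, and a rerun under the same root seed is
byte-identical. Property tests use 60–110-report corpora. Per-iteration
SSE monotonicity is asserted to 1e-9; the SSE-versus-k curve is checked
non-increasing to 1% slack because best-of-10 restarts do not guarantee
strict monotonicity. Standardization guards zero-variance features by
leaving their scale at 1. The chi-square uniformity test spreads a
cluster's expected counts over all ten sections regardless of which
sections the cluster actually contains, and empty clusters are excluded
from purity aggregation and from the pooled chi-square.

## Known limitations

- Binary presence features saturate: beyond ~200 vocabulary entries the
  extra n-grams are rare and mostly zero. High-n models (4-, 5-grams) are
  close to the majority baseline because few n-grams recur at all — the
  same direction the method shows on real reports.
- Accuracy is sensitive to K-means restart luck: a merged pair of
  sections costs roughly one section's worth of accuracy. Best-of-10
  restart selection mitigates but does not eliminate this; comparisons
  between conditions are therefore made on means over replicate seeds
  where the tests need stability.
- The ensemble's relative-location feature assumes the institution's
  canonical section order; reports ordered differently would need
  retraining.
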