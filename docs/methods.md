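# Methods

## The mapping task

Each echo-report sentence receives a triple of ontology terms: a Level-1
anatomic structure, a Level-2 attribute or functional element, and a
Level-3 descriptor. The ontology fixes three per-level vocabularies and
a set of licensed (L1, L2, L3) combinations; labels are unique within a
level but may recur across Levels 2 and 3 (negative terms such as
"none" do). All label matching in the package goes through one
normalization rule — casefold, punctuation to spaces, collapsed
whitespace — applied identically to ontology labels, gold labels and
reference-list entries, so that coverage audits and scoring are
deterministic rather than judgment calls.

## Text processing

Sentences are delimited at `. ! ? ;` followed by whitespace (or end of
text) and at newlines, with a guard that a period between digits never
splits, so decimal measurements ("EF 55.3%") survive. Normalization
casefolds, maps punctuation to spaces and collapses whitespace;
abbreviation expansion replaces whole tokens only ("LV" expands, "LVOT"
does not) using an explicit abbreviation table. Spell correction is
deliberately conservative: an out-of-vocabulary token is replaced only
by the *unique* vocabulary token within Damerau–Levenshtein distance 1
(optimal string alignment variant); ties and misses leave the token
unchanged, and in-vocabulary tokens are never touched. The distance
default of one edit corrects realistic typos without inventing words.
The train/validation splitter shuffles with a seeded RNG and takes
`round(n * fraction)` validation items (round-half-up); the default
fraction 0.24 reproduces a 723/228 split of a 951-sentence dictionary.

## Features

Four blocks per sentence, concatenated in a recorded layout:

1. **Negation flag** (1 value). Whole-token cue matching against a
   small cue list (multi-word cues match as token sequences). "Normal"
   and "non" are deliberately not cues; general-purpose negation
   detectors are known to over-flag them in echo text. The cue engine is
   swappable — any callable producing 0/1 can be configured.
2. **Entity embedding** (`entity_dim`, default 25). A recognizer maps
   the sentence to entity strings; the shipped default is a
   longest-match lexicon scan over ontology labels and synonyms, so the
   package runs with no model downloads, and any clinical-NER adapter
   with the same contract can be plugged in. Training sentences define
   an entity vocabulary; each sentence becomes a binary indicator
   vector, centered by the training mean, and projected onto the leading
   right-singular vectors of the centered matrix. Two conventions make
   the fit reproducible: each component's largest-magnitude loading is
   made positive, and components beyond the matrix rank are identically
   zero, so the embedding is always exactly `entity_dim` long even for
   small vocabularies. Binary indicators (not counts) were chosen
   because structured-report sentences rarely repeat an entity.
3. **Jaccard blocks**. Character trigrams (including single inter-word
   spaces) are compared by Jaccard index against every Level-1 term and
   against every distinct Level-2 ∪ Level-3 label, in ontology load
   order. Character rather than word granularity is used because many
   ontology terms are single words whose word-trigram set would be
   empty; strings shorter than the n-gram length contribute themselves
   as a single "gram" for the same reason. The L2∪L3 block size is
   computed from the loaded ontology, not hard-coded; at the reference
   scale of 27 L1 terms and 230 distinct L2∪L3 labels the assembled
   vectors are 53 / 284 / 285 long.
4. **Hierarchy features**. Levels 2 and 3 receive the previous level's
   class index as a single numeric feature (the +1 in 284 = 53 + 230
   + 1 forces this encoding rather than one-hot). The index is nominal;
   forests can still split on it, but the caveat stands that its
   ordering is arbitrary.

Ablation switches (`use_negation`, `use_hierarchy`, `use_entities`)
omit a block entirely; disabling negation shortens every vector by
exactly 1 and disabling hierarchy shortens Levels 2 and 3 by 1 each,
which the tests pin down.

## Cascade

Three scikit-learn random forests: (depth 25, 100 trees), (depth 40,
120 trees), (depth 25, 100 trees), all with `class_weight="balanced"`
(inverse-frequency weights) to counter class imbalance among ontology
terms. Training uses *teacher forcing*: the Level-2 and Level-3 forests
see gold upstream class indices, while inference feeds predicted
indices downstream. This is the simplest deterministic choice; the
exposure mismatch (training on gold, predicting on predictions) is a
known limitation and an alternative would be to train on
cross-validated predictions. One seed drives the splitter, the
projection and all three forests, making predictions a pure function of
(model, sentence). Labels unseen in training cannot be predicted even
if the ontology contains them — the classifier range is the training
label set.

Persistence writes a model directory (metadata JSON with configs, label
maps, vocabulary, training triples and an ontology content hash; the
ontology JSON; the projection JSON; one serialized forest per level).
Loading verifies the ontology hash and fails on any missing component,
and a round trip preserves predictions exactly.

## Evaluation

Correctness is cumulative by ontology level: percent of sentences with
L1 correct; with L1 and L2 correct; with all three correct (the
"overall" figure). Marginal per-level accuracy is deliberately not the
headline number because a correct L3 under a wrong L1 is clinically
meaningless. The extrapolation report counts gold triples that are
novel combinations relative to the *training-time* triple set — every
term known at its level, the combination unlicensed — and how many were
still mapped exactly.

Method comparison uses the Friedman rank test: scores are ranked within
each dataset row (mean ranks for ties), and the statistic
`12n/(k(k+1)) * Σ_j (R̄_j − (k+1)/2)²` is referred to χ²(k−1). No
tie-correction denominator is applied, so identical columns give
exactly 0; on tie-free matrices the statistic agrees with
`scipy.stats.friedmanchisquare`, which the tests verify. Nemenyi
post-hoc p-values come from the studentized-range approximation with
infinite degrees of freedom. The one-sample t-test compares a vector of
test-dataset scores against a fixed validation value; the degenerate
all-equal-to-mu case returns (0, 1) rather than erroring, while zero
variance away from mu is an error.

## Synthetic data generator

The generator replaces private institutional dictionaries. It emulates:
a three-level ontology of pronounceable CV-syllable nonsense terms with
negative terms at Levels 2 and 3 ("none" appears at both, mirroring
real L2/L3 label sharing); licensed triples sampled without replacement
so every term is licensed at least once; sentences realized from
paraphrase templates that always contain the gold terms' surface forms
("{l1} {l2} appears {l3}", "no {l2} of the {l1}" for negative
findings); whole-token abbreviations of Level-1 terms with the matching
abbreviation table emitted; and single-edit typos kept only when they
are uniquely recoverable by the spell corrector. Defaults: 8/12/16
terms per level, 60 triples, 800 sentences, 8% negation, 10%
abbreviation, 5% typo rate — the scale of a single institution's
dictionary with enough sentences per class to train a forest.

What it does *not* emulate, and therefore what passing tests do not
show: free-text syntax variation, compound sentences, context-dependent
abbreviations, label noise from human annotators, and institutional
drift in terminology. The synthetic task is separable by construction
(term surfaces appear in the sentence), so held-out accuracies near
100% demonstrate that the pipeline wiring is correct, not that the
method achieves any particular accuracy on real reports. The novel
combination sentences are compositional in the same way, which is why
extrapolation succeeds almost perfectly on synthetic data.

## Numerical choices and degenerate inputs

- Jaccard of two empty n-gram sets is 0 (an empty sentence matches
  nothing).
- Entity projection of a sentence with no recognized entities is the
  projection of the zero indicator (equivalently, minus the training
  mean through the components).
- Probability vectors from each forest sum to 1 within 1e-9.
- Empty training sets, unknown gold labels (reported with sentence and
  label), length-mismatched gold/prediction lists, incomplete score
  matrices, and infeasible generator configurations all raise early
  with specific messages.

## Problem sizes

The default test and acceptance runs train on 600 synthetic sentences
with 200 held out, with smaller 250-sentence trainings for ablation and
determinism contracts — sizes chosen to mirror the dictionary-scale
regime the method targets while keeping a full run in the order of
seconds.
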