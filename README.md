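# echomap

Map cardiac-ultrasound (transthoracic echocardiogram, TTE) report
sentences onto a three-level hierarchical ontology with a small,
interpretable statistical model.

Echo reports mix structured phrases and free text, and every institution
writes them differently; harmonizing them against a shared ontology is a
prerequisite for cross-institutional text mining and quality research.
The ontology here has three tiers — Level 1 anatomic structures (e.g.
*left ventricle*), Level 2 attributes/functional elements (*function*),
Level 3 descriptors (*hyperdynamic*) — plus a set of *licensed*
(L1, L2, L3) triples, the valid combinations. Negative findings are
explicit terms (*none*, *not seen*) rather than empty slots.

## Model

A sentence *s* is normalized (lowercased, punctuation stripped,
whole-token abbreviations expanded, conservative spell correction) and
encoded as:

- a negation flag from whole-token cue matching
  (*no, not, without, absent, denies, free of, neither, nor*);
- a 25-component linear embedding of recognized clinical entities:
  binary indicators over the training entity vocabulary, centered, and
  projected onto principal axes (zero-padded past the matrix rank);
- Jaccard indices J(A,B) = |A∩B| / |A∪B| between the sentence's
  character trigram set and each ontology term's, over the Level-1 terms
  and over the distinct Level-2 ∪ Level-3 terms.

Three random forests classify the three levels in cascade: Level 1
(depth 25, 100 trees), Level 2 (depth 40, 120 trees, plus the Level-1
predicted class index as a feature), Level 3 (depth 25, 100 trees, plus
the Level-2 index), all with inverse-frequency class weighting. At the
reference ontology scale (27 L1 terms, 230 distinct L2∪L3 terms) the
per-level input vectors are 53, 284 and 285 features.

Because real institutional dictionaries are private, the package ships a
synthetic-data generator that emulates structured-reporting sentences
built from ontology terms, with configurable negation rate (default 8%),
abbreviations, recoverable typos and deliberately novel term
combinations for extrapolation tests.

## Worked example

```python
import echomap as em

cfg = em.GeneratorConfig(seed=7)          # 800 sentences, 8% negated, typos on
o = em.generate_ontology(cfg)
sentences = em.generate_dictionary(o, cfg)
train, held_out = em.split_dictionary(sentences, 0.25, seed=7)

model = em.train_cascade(train, o, ccfg=em.CascadeConfig(seed=7))
preds = model.predict_batch([s.text for s in held_out])
report = em.cumulative_accuracy([s.gold for s in held_out],
                                [p.triple for p in preds])
print(f"n={report.n}  L1={report.acc_l1:.1f}%  "
      f"L1+2={report.acc_l12:.1f}%  L1+2+3={report.acc_l123:.1f}%")

novel = em.generate_novel_sentences(o, cfg)
view = em.Ontology(o.terms, model.training_triples)
ex = em.extrapolation_report(
    [s.gold for s in novel],
    [p.triple for p in model.predict_batch([s.text for s in novel])],
    view,
)
print(f"novel combinations mapped correctly: {ex.novel_correct}/{ex.novel_count}")
```

prints

```
n=200  L1=97.5%  L1+2=97.5%  L1+2+3=97.5%
novel combinations mapped correctly: 50/50
```

Accuracy is *cumulative*: the second figure counts sentences correct at
Levels 1 **and** 2, the third at all three levels, so
`acc_l123 <= acc_l12 <= acc_l1` always. The extrapolation lines show the
cascade mapping sentences whose gold triple was never licensed in
training — each term is known, only the three-way combination is new.

The same workflow is available from a shell:

```sh
echomap synth --seed 7 --out data/
echomap train --ontology data/ontology.json --dictionary data/dictionary.tsv \
              --abbreviations data/abbreviations.tsv --seed 7 --model-dir model/
echomap predict  --model-dir model/ --dictionary data/dictionary.tsv --out pred.tsv
echomap evaluate --model-dir model/ --dictionary data/dictionary.tsv --out eval.json
echomap coverage --ontology data/ontology.json --dictionary data/dictionary.tsv --out cov.json
```

The library also provides the coverage audits (`dictionary_coverage`,
`reference_coverage`) for measuring how much of an external data
dictionary the ontology represents and how many ontology terms appear in
a general reference vocabulary, and the method-comparison statistics
(`friedman_nemenyi`, `one_sample_t`) for comparing mapping methods
across datasets.

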