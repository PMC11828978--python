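"""The hierarchical random-forest cascade.

Three random-forest classifiers, one per ontology level.  The Level-1
forest sees [negation | entity embedding | L1 Jaccard block]; the Level-2
forest additionally sees the L2∪L3 Jaccard block and the Level-1 class
index; the Level-3 forest appends the Level-2 class index.  Training uses
teacher forcing (gold upstream labels); inference feeds each level's
*predicted* class index downstream.

Hyperparameters follow the reference configuration: (depth 25, 100
trees), (depth 40, 120 trees), (depth 25, 100 trees), with inverse
frequency class weighting to mitigate class imbalance among ontology
terms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import __version__ as _pkg_version
from .features import (
    EntityProjection,
    FeatureConfig,
    Recognizer,
    assemble_features,
    detect_negation,
    embed_entities,
    fit_entity_projection,
    jaccard_block,
    lexicon_recognizer,
)
from .ontology import (
    LabeledSentence,
    MappingTriple,
    Ontology,
    load_ontology,
    save_ontology,
)
from .textprep import (
    AbbreviationMap,
    Vocabulary,
    correct_spelling,
    corpus_vocabulary,
    normalize_sentence,
)

__all__ = [
    "CascadeConfig",
    "CascadeModel",
    "Prediction",
    "train_cascade",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class CascadeConfig:
    """Per-level forest hyperparameters and the global seed."""

    l1_max_depth: int = 25
    l1_n_trees: int = 100
    l2_max_depth: int = 40
    l2_n_trees: int = 120
    l3_max_depth: int = 25
    l3_n_trees: int = 100
    class_balancing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            self.l1_max_depth,
            self.l1_n_trees,
            self.l2_max_depth,
            self.l2_n_trees,
            self.l3_max_depth,
            self.l3_n_trees,
        ):
            if f <= 0:
                raise ValueError("forest depths and tree counts must be positive")

    def level_params(self, level: int) -> tuple[int, int]:
        return {
            1: (self.l1_max_depth, self.l1_n_trees),
            2: (self.l2_max_depth, self.l2_n_trees),
            3: (self.l3_max_depth, self.l3_n_trees),
        }[level]

    def to_json(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_json(cls, d: dict) -> "CascadeConfig":
        return cls(**d)


@dataclass(frozen=True)
class Prediction:
    """One sentence's predicted triple with per-level probabilities."""

    triple: MappingTriple
    labels: tuple[str, str, str]
    probabilities: tuple[np.ndarray, np.ndarray, np.ndarray]


class CascadeModel:
    """Fitted cascade: three forests, entity projection, frozen ontology
    snapshot, label-index maps and the training-triple set."""

    def __init__(
        self,
        forests: dict[int, RandomForestClassifier],
        projection: EntityProjection,
        fcfg: FeatureConfig,
        ccfg: CascadeConfig,
        ontology: Ontology,
        label_maps: dict[int, dict[str, int]],
        training_triples: frozenset[MappingTriple],
        abbrev: AbbreviationMap,
        vocab: Vocabulary,
    ):
        self.forests = forests
        self.projection = projection
        self.fcfg = fcfg
        self.ccfg = ccfg
        self.ontology = ontology
        self.label_maps = label_maps
        self.inverse_maps = {
            lv: {i: lab for lab, i in m.items()} for lv, m in label_maps.items()
        }
        self.training_triples = training_triples
        self.abbrev = abbrev
        self.vocab = vocab
        self.recognizer: Recognizer = lexicon_recognizer(ontology)
        self.version = f"echomap/{_pkg_version} fmt/{MODEL_FORMAT_VERSION}"
        # term orders frozen at fit time
        self._l1_terms = ontology.labels(1)
        self._l23_terms = ontology.l23_labels()

    # -- feature pipeline ------------------------------------------------
    def preprocess(self, sentence: str) -> str:
        s = normalize_sentence(sentence, self.abbrev)
        if self.vocab.tokens:
            s = correct_spelling(s, self.vocab)
        return s

    def sentence_blocks(self, s: str) -> dict:
        """Shared per-sentence feature blocks (input already normalized)."""
        return {
            "negation": detect_negation(s, self.fcfg.negation_cues),
            "entity_embedding": (
                embed_entities(s, self.projection, self.recognizer)
                if self.fcfg.use_entities
                else None
            ),
            "jaccard_l1": jaccard_block(s, self._l1_terms, self.fcfg.ngram_n),
            "jaccard_l23": jaccard_block(s, self._l23_terms, self.fcfg.ngram_n),
        }

    def feature_matrix(
        self,
        level: int,
        blocks: Sequence[dict],
        pred_l1: Sequence[float] | None = None,
        pred_l2: Sequence[float] | None = None,
    ) -> np.ndarray:
        rows = []
        for i, b in enumerate(blocks):
            fv = assemble_features(
                level,
                negation=b["negation"],
                entity_embedding=b["entity_embedding"],
                jaccard_l1=b["jaccard_l1"],
                jaccard_l23=b["jaccard_l23"] if level >= 2 else None,
                pred_l1=pred_l1[i] if pred_l1 is not None else None,
                pred_l2=pred_l2[i] if pred_l2 is not None else None,
                cfg=self.fcfg,
            )
            rows.append(fv.values)
        return np.stack(rows)

    # -- inference -------------------------------------------------------
    def predict_batch(self, sentences: Sequence[str]) -> list[Prediction]:
        """Predict triples for many raw sentences at once."""
        norm = [self.preprocess(s) for s in sentences]
        for s, raw in zip(norm, sentences):
            if not s:
                raise ValueError(f"sentence empty after normalization: {raw!r}")
        blocks = [self.sentence_blocks(s) for s in norm]

        X1 = self.feature_matrix(1, blocks)
        p1 = self.forests[1].predict_proba(X1)
        i1 = self.forests[1].classes_[np.argmax(p1, axis=1)]

        hier1 = i1.astype(float) if self.fcfg.use_hierarchy else None
        X2 = self.feature_matrix(2, blocks, pred_l1=hier1)
        p2 = self.forests[2].predict_proba(X2)
        i2 = self.forests[2].classes_[np.argmax(p2, axis=1)]

        hier2 = i2.astype(float) if self.fcfg.use_hierarchy else None
        X3 = self.feature_matrix(3, blocks, pred_l1=hier1, pred_l2=hier2)
        p3 = self.forests[3].predict_proba(X3)
        i3 = self.forests[3].classes_[np.argmax(p3, axis=1)]

        out = []
        for k in range(len(sentences)):
            labs = (
                self.inverse_maps[1][int(i1[k])],
                self.inverse_maps[2][int(i2[k])],
                self.inverse_maps[3][int(i3[k])],
            )
            out.append(
                Prediction(
                    triple=MappingTriple(*labs),
                    labels=labs,
                    probabilities=(p1[k], p2[k], p3[k]),
                )
            )
        return out

    def predict_triple(self, sentence: str) -> Prediction:
        """Map one raw report sentence onto the ontology."""
        return self.predict_batch([sentence])[0]


def train_cascade(
    train: Sequence[LabeledSentence],
    o: Ontology,
    fcfg: FeatureConfig | None = None,
    ccfg: CascadeConfig | None = None,
    abbrev: AbbreviationMap | None = None,
    recognizer: Recognizer | None = None,
) -> CascadeModel:
    """Fit the three-level cascade on a labeled dictionary.

    The entity projection and the spell-correction vocabulary are fitted
    on the training sentences only.  Downstream forests are trained with
    the *gold* upstream class index (teacher forcing); inference swaps in
    predicted indices.  Fully deterministic given ``ccfg.seed``.
    """
    if not train:
        raise ValueError("train_cascade: empty training set")
    fcfg = fcfg or FeatureConfig()
    ccfg = ccfg or CascadeConfig()
    abbrev = abbrev or AbbreviationMap()

    for s in train:
        for lv, lab in zip((1, 2, 3), s.gold.as_tuple()):
            if not o.has_label(lv, lab):
                raise ValueError(
                    f"gold label {lab!r} of sentence {s.text!r} is not a "
                    f"level-{lv} ontology term"
                )

    # label-index maps over the training label set, sorted for determinism
    label_maps = {
        lv: {
            lab: i
            for i, lab in enumerate(
                sorted({s.gold.as_tuple()[lv - 1] for s in train})
            )
        }
        for lv in (1, 2, 3)
    }

    norm = [normalize_sentence(s.text, abbrev) for s in train]
    vocab = corpus_vocabulary(norm)
    rec = recognizer or lexicon_recognizer(o)
    projection = fit_entity_projection(norm, rec, dim=fcfg.entity_dim)

    model = CascadeModel(
        forests={},
        projection=projection,
        fcfg=fcfg,
        ccfg=ccfg,
        ontology=o,
        label_maps=label_maps,
        training_triples=frozenset(s.gold for s in train),
        abbrev=abbrev,
        vocab=vocab,
    )
    if recognizer is not None:
        model.recognizer = recognizer

    blocks = [model.sentence_blocks(s) for s in norm]
    y = {
        lv: np.array([label_maps[lv][s.gold.as_tuple()[lv - 1]] for s in train])
        for lv in (1, 2, 3)
    }
    gold1 = y[1].astype(float) if fcfg.use_hierarchy else None
    gold2 = y[2].astype(float) if fcfg.use_hierarchy else None

    X = {
        1: model.feature_matrix(1, blocks),
        2: model.feature_matrix(2, blocks, pred_l1=gold1),
        3: model.feature_matrix(3, blocks, pred_l1=gold1, pred_l2=gold2),
    }
    for lv in (1, 2, 3):
        depth, trees = ccfg.level_params(lv)
        forest = RandomForestClassifier(
            n_estimators=trees,
            max_depth=depth,
            class_weight="balanced" if ccfg.class_balancing else None,
            random_state=ccfg.seed + lv,
            n_jobs=1,
        )
        forest.fit(X[lv], y[lv])
        model.forests[lv] = forest
    return model


# -- persistence ---------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_model(m: CascadeModel, dir_path: str | Path) -> None:
    """Persist the cascade: metadata JSON, ontology, projection, forests."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    save_ontology(m.ontology, d / "ontology.json")
    m.projection.save(d / "projection.json")
    for lv, forest in m.forests.items():
        joblib.dump(forest, d / f"forest_l{lv}.joblib")
    import sklearn

    meta = {
        "version": m.version,
        "feature_config": m.fcfg.to_json(),
        "cascade_config": m.ccfg.to_json(),
        "label_maps": {str(lv): mp for lv, mp in m.label_maps.items()},
        "training_triples": sorted(t.as_tuple() for t in m.training_triples),
        "abbreviations": dict(m.abbrev.entries),
        "vocabulary": sorted(m.vocab.tokens),
        "ontology_sha256": _sha256(d / "ontology.json"),
        "library_versions": {
            "sklearn": sklearn.__version__,
            "numpy": np.__version__,
        },
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_model(dir_path: str | Path) -> CascadeModel:
    """Load a saved cascade; predictions match the saved model exactly."""
    d = Path(dir_path)
    for fname in ("metadata.json", "ontology.json", "projection.json"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"model component missing: {d / fname}")
    meta = json.loads((d / "metadata.json").read_text(encoding="utf-8"))
    if _sha256(d / "ontology.json") != meta["ontology_sha256"]:
        raise ValueError(
            f"ontology.json hash mismatch in {d}: file does not match metadata"
        )
    forests = {}
    for lv in (1, 2, 3):
        f = d / f"forest_l{lv}.joblib"
        if not f.exists():
            raise FileNotFoundError(f"model component missing: {f}")
        forests[lv] = joblib.load(f)
    model = CascadeModel(
        forests=forests,
        projection=EntityProjection.load(d / "projection.json"),
        fcfg=FeatureConfig.from_json(meta["feature_config"]),
        ccfg=CascadeConfig.from_json(meta["cascade_config"]),
        ontology=load_ontology(d / "ontology.json"),
        label_maps={
            int(lv): {k: int(v) for k, v in mp.items()}
            for lv, mp in meta["label_maps"].items()
        },
        training_triples=frozenset(
            MappingTriple(*t) for t in meta["training_triples"]
        ),
        abbrev=AbbreviationMap(meta["abbreviations"]),
        vocab=Vocabulary(frozenset(meta["vocabulary"])),
    )
    model.version = meta["version"]
    return model
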