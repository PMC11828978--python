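"""Engineered sentence features for the hierarchical classifier.

Each sentence is encoded by four feature blocks:

1. a binary negation flag from a whole-token cue match;
2. a 25-component linear embedding of recognized clinical entities
   (binary indicators over the training entity vocabulary, centered and
   reduced by principal components with a fixed sign convention);
3. character-trigram Jaccard indices between the sentence and every
   ontology term — one block over Level-1 terms, a second over the
   distinct Level-2 ∪ Level-3 terms;
4. for Levels 2 and 3, the previous level's predicted class index.

With the reference configuration (27 Level-1 terms, 230 distinct
Level-2/3 terms, 25 entity components) the per-level input vectors are
53, 284 and 285 features long.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .ontology import Ontology, normalize_label

__all__ = [
    "DEFAULT_NEGATION_CUES",
    "FeatureConfig",
    "EntityProjection",
    "FeatureVector",
    "detect_negation",
    "char_ngrams",
    "jaccard",
    "jaccard_block",
    "lexicon_recognizer",
    "fit_entity_projection",
    "embed_entities",
    "assemble_features",
]

#: Default negation cues.  Deliberately excludes "normal" and "non",
#: which a published detector is known to over-flag in echo text.
DEFAULT_NEGATION_CUES: tuple[str, ...] = (
    "no",
    "not",
    "without",
    "absent",
    "denies",
    "free of",
    "neither",
    "nor",
)

Recognizer = Callable[[str], Sequence[str]]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-engineering switches and sizes.

    ``use_negation`` / ``use_hierarchy`` / ``use_entities`` support the
    ablation experiments; each disabled block is simply omitted from the
    assembled vector, with the layout recorded.
    """

    ngram_n: int = 3
    entity_dim: int = 25
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES
    use_negation: bool = True
    use_hierarchy: bool = True
    use_entities: bool = True

    def __post_init__(self) -> None:
        if self.ngram_n < 1:
            raise ValueError("ngram_n must be >= 1")
        if self.entity_dim < 1:
            raise ValueError("entity_dim must be >= 1")
        object.__setattr__(self, "negation_cues", tuple(self.negation_cues))

    def to_json(self) -> dict:
        return {
            "ngram_n": self.ngram_n,
            "entity_dim": self.entity_dim,
            "negation_cues": list(self.negation_cues),
            "use_negation": self.use_negation,
            "use_hierarchy": self.use_hierarchy,
            "use_entities": self.use_entities,
        }

    @classmethod
    def from_json(cls, d: dict) -> "FeatureConfig":
        return cls(
            ngram_n=d["ngram_n"],
            entity_dim=d["entity_dim"],
            negation_cues=tuple(d["negation_cues"]),
            use_negation=d["use_negation"],
            use_hierarchy=d["use_hierarchy"],
            use_entities=d["use_entities"],
        )


def detect_negation(s: str, cues: Sequence[str] = DEFAULT_NEGATION_CUES) -> int:
    """1 iff any cue matches whole tokens of the normalized sentence.

    Multi-word cues ("free of") match as contiguous token sequences.
    """
    toks = s.split()
    joined = " " + " ".join(toks) + " "
    for cue in cues:
        if f" {cue} " in joined:
            return 1
    return 0


def char_ngrams(s: str, n: int = 3) -> frozenset[str]:
    """All contiguous length-``n`` substrings of ``s`` (spaces included).

    Strings shorter than ``n`` yield the singleton of the whole string;
    the empty string yields the empty set — so a one-word ontology term
    always has a non-empty trigram set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not s:
        return frozenset()
    if len(s) < n:
        return frozenset({s})
    return frozenset(s[i : i + n] for i in range(len(s) - n + 1))


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|A∩B| / |A∪B|; defined as 0 when both sets are empty."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def jaccard_block(s: str, terms: Sequence[str], n: int = 3) -> np.ndarray:
    """Jaccard index between the sentence's character n-grams and each
    term's, in the fixed term order of the ontology."""
    sg = char_ngrams(s, n)
    return np.array([jaccard(sg, char_ngrams(t, n)) for t in terms])


def lexicon_recognizer(o: Ontology) -> Recognizer:
    """Longest-match entity recognizer over ontology labels and synonyms.

    A pragmatic stand-in for a clinical NER system: scans the normalized
    sentence for the longest token spans that are known term surfaces.
    Any callable mapping a sentence to entity strings can replace it.
    """
    surfaces: set[str] = set()
    for t in o.terms:
        surfaces.add(t.label)
        surfaces.update(t.synonyms)
    max_len = max((len(s.split()) for s in surfaces), default=1)

    def recognize(sentence: str) -> list[str]:
        toks = normalize_label(sentence).split()
        found: list[str] = []
        i = 0
        while i < len(toks):
            for span in range(min(max_len, len(toks) - i), 0, -1):
                cand = " ".join(toks[i : i + span])
                if cand in surfaces:
                    found.append(cand)
                    i += span
                    break
            else:
                i += 1
        return found

    return recognize


@dataclass(frozen=True)
class EntityProjection:
    """Fitted linear reduction of entity indicators to a fixed embedding.

    ``components`` is (entity_dim, |vocabulary|); rows beyond the rank of
    the centered training matrix are identically zero, so the output is
    always exactly ``entity_dim`` long.
    """

    entity_vocabulary: tuple[str, ...]
    mean_vector: np.ndarray
    components: np.ndarray

    @property
    def dim(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> dict:
        return {
            "entity_vocabulary": list(self.entity_vocabulary),
            "mean_vector": self.mean_vector.tolist(),
            "components": self.components.tolist(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "EntityProjection":
        return cls(
            entity_vocabulary=tuple(d["entity_vocabulary"]),
            mean_vector=np.asarray(d["mean_vector"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "EntityProjection":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


def _indicator(entities: Sequence[str], vocab_index: dict[str, int]) -> np.ndarray:
    v = np.zeros(len(vocab_index))
    for e in entities:
        j = vocab_index.get(e)
        if j is not None:
            v[j] = 1.0
    return v


def fit_entity_projection(
    train: Sequence[str], recognizer: Recognizer, dim: int = 25
) -> EntityProjection:
    """Fit the entity embedding on training sentences only.

    Builds the entity vocabulary from the recognizer's output over the
    corpus, encodes sentences as binary indicators, centers, and takes the
    leading right-singular vectors as components.  The sign of each
    component is fixed so its largest-magnitude loading is positive, which
    makes the fit deterministic.  When the matrix rank is below ``dim``
    the remaining components are zero.
    """
    if not train:
        raise ValueError("fit_entity_projection requires training sentences")
    per_sentence = [list(recognizer(s)) for s in train]
    vocab = sorted({e for ents in per_sentence for e in ents})
    if not vocab:
        raise ValueError("entity recognizer produced no entities on the corpus")
    index = {e: j for j, e in enumerate(vocab)}
    X = np.stack([_indicator(ents, index) for ents in per_sentence])
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD; right-singular vectors are the principal axes
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (svals[0] if svals.size else 0.0)
    rank = int((svals > tol).sum())
    k = min(dim, rank)
    comps = np.zeros((dim, len(vocab)))
    comps[:k] = vt[:k]
    for r in range(k):  # deterministic sign: largest |loading| positive
        j = int(np.argmax(np.abs(comps[r])))
        if comps[r, j] < 0:
            comps[r] = -comps[r]
    return EntityProjection(tuple(vocab), mean, comps)


def embed_entities(
    s: str, proj: EntityProjection, recognizer: Recognizer
) -> np.ndarray:
    """Project one sentence's entity indicators through the fitted reduction.

    Unknown entities are ignored; a sentence with no recognized entities
    embeds as the projection of the zero indicator vector.
    """
    index = {e: j for j, e in enumerate(proj.entity_vocabulary)}
    v = _indicator(list(recognizer(s)), index)
    return proj.components @ (v - proj.mean_vector)


@dataclass(frozen=True)
class FeatureVector:
    """An assembled per-level input vector with its named block layout."""

    level: int
    values: np.ndarray
    block_layout: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def assemble_features(
    level: int,
    *,
    negation: int,
    entity_embedding: np.ndarray | None,
    jaccard_l1: np.ndarray,
    jaccard_l23: np.ndarray | None = None,
    pred_l1: float | None = None,
    pred_l2: float | None = None,
    cfg: FeatureConfig,
) -> FeatureVector:
    """Concatenate feature blocks for one level.

    Level 1: [negation | entities | Jaccard over L1 terms].
    Level 2 appends [Jaccard over distinct L2∪L3 terms | L1 prediction].
    Level 3 appends the L2 prediction.  Blocks disabled by the ablation
    flags are omitted and the layout records what remains.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"invalid level {level}")
    blocks: list[tuple[str, np.ndarray]] = []
    if cfg.use_negation:
        blocks.append(("negation", np.array([float(negation)])))
    if cfg.use_entities:
        if entity_embedding is None:
            raise ValueError("entity embedding required when use_entities")
        blocks.append(("entities", np.asarray(entity_embedding, dtype=float)))
    blocks.append(("jaccard_l1", np.asarray(jaccard_l1, dtype=float)))
    if level >= 2:
        if jaccard_l23 is None:
            raise ValueError("jaccard_l23 required for levels 2 and 3")
        blocks.append(("jaccard_l23", np.asarray(jaccard_l23, dtype=float)))
        if cfg.use_hierarchy:
            if pred_l1 is None:
                raise ValueError("level-1 prediction required when use_hierarchy")
            blocks.append(("pred_l1", np.array([float(pred_l1)])))
    if level == 3 and cfg.use_hierarchy:
        if pred_l2 is None:
            raise ValueError("level-2 prediction required when use_hierarchy")
        blocks.append(("pred_l2", np.array([float(pred_l2)])))

    layout: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, arr in blocks:
        layout[name] = (pos, pos + len(arr))
        pos += len(arr)
    values = np.concatenate([arr for _, arr in blocks])
    return FeatureVector(level=level, values=values, block_layout=layout)
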