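"""Synthetic ontologies and structured-reporting dictionaries.

Real institutional data dictionaries and patient reports are private, so
this module generates stand-ins with the statistical structure the
pipeline assumes: a three-level ontology of pronounceable nonsense terms
with licensed triples, and labeled sentences realized from paraphrase
templates over those triples.  Templates guarantee that each gold term's
surface form (or its abbreviation) appears in the sentence, mirroring
structured-reporting phrasing, which makes the mapping learnable from
lexical-overlap features.  Negative findings are realized through
negation templates ("no <l2> of the <l1>") whose gold Level-3 term is an
explicit negative term ("none", "not seen"); by default 8% of sentences
carry negation.  Optional corruptions emulate real text: whole-token
abbreviations (with the matching abbreviation map emitted) and
single-edit typos that the spell corrector can recover.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ontology import (
    LabeledSentence,
    MappingTriple,
    Ontology,
    OntologyTerm,
    save_dictionary,
    save_ontology,
)
from .textprep import AbbreviationMap, save_abbreviations

__all__ = [
    "GeneratorConfig",
    "generate_ontology",
    "generate_dictionary",
    "generate_novel_sentences",
    "make_abbreviations",
    "write_outputs",
    "NEGATIVE_L3_TERMS",
]

NEGATIVE_L3_TERMS = ("none", "not seen")

_DEFAULT_TEMPLATES = (
    "{l1} {l2} appears {l3}",
    "the {l1} {l2} is {l3}",
    "{l2} of the {l1} is {l3}",
    "{l1} shows {l3} {l2}",
)
# negative realizations keyed on the gold negative term
_NEG_TEMPLATES = {
    "none": "no {l2} of the {l1}",
    "not seen": "{l1} {l2} not seen",
}
_L2_NONE_TEMPLATE = "no findings of the {l1}"

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the scale of a single institution's data dictionary
    (hundreds of sentences over a few dozen terms) with an 8% negation
    rate.
    """

    n_l1: int = 8
    n_l2: int = 12
    n_l3: int = 16
    n_triples: int = 60
    n_sentences: int = 800
    negation_rate: float = 0.08
    abbrev_rate: float = 0.10
    typo_rate: float = 0.05
    paraphrase_templates: tuple[str, ...] = _DEFAULT_TEMPLATES
    n_novel: int = 50
    dataset: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_l1, self.n_l2, self.n_l3, self.n_sentences) <= 0:
            raise ValueError("level sizes and n_sentences must be positive")
        for r in (self.negation_rate, self.abbrev_rate, self.typo_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.n_triples > self.n_l1 * self.n_l2 * self.n_l3:
            raise ValueError("n_triples exceeds the number of possible triples")
        object.__setattr__(
            self, "paraphrase_templates", tuple(self.paraphrase_templates)
        )

    def to_json(self) -> dict:
        d = dict(self.__dict__)
        d["paraphrase_templates"] = list(self.paraphrase_templates)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "paraphrase_templates" in d:
            d["paraphrase_templates"] = tuple(d["paraphrase_templates"])
        return cls(**d)


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _labels(rng: random.Random, count: int, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < count:
        w = _word(rng, rng.randint(2, 4))
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def generate_ontology(cfg: GeneratorConfig) -> Ontology:
    """Build a toy three-level ontology, deterministic given the seed.

    Level 2 includes the negative term "none"; Level 3 includes "none"
    and "not seen" (so one label is shared between Levels 2 and 3, as in
    real TTE ontologies).  Licensed triples are sampled without
    replacement such that every term appears in at least one triple.
    """
    if cfg.n_l2 < 2 or cfg.n_l3 < 3:
        raise ValueError("need n_l2 >= 2 and n_l3 >= 3 to host negative terms")
    rng = random.Random(cfg.seed)
    taken = set(NEGATIVE_L3_TERMS)
    l1 = _labels(rng, cfg.n_l1, taken)
    l2 = _labels(rng, cfg.n_l2 - 1, taken) + ["none"]
    l3 = _labels(rng, cfg.n_l3 - 2, taken) + list(NEGATIVE_L3_TERMS)

    regular_l2 = [t for t in l2 if t != "none"]
    o1, o2, o3 = list(l1), list(regular_l2), list(l3)
    rng.shuffle(o1), rng.shuffle(o2), rng.shuffle(o3)
    m = max(len(o1), len(o2), len(o3))
    base = {
        (o1[i % len(o1)], o2[i % len(o2)], o3[i % len(o3)]) for i in range(m)
    }
    base.add((o1[0], "none", "none"))  # licenses the Level-2 negative term
    if cfg.n_triples < len(base):
        raise ValueError(
            f"n_triples={cfg.n_triples} cannot cover every term "
            f"(needs >= {len(base)})"
        )
    pool = [
        (a, b, c)
        for a in l1
        for b in regular_l2
        for c in l3
        if (a, b, c) not in base
    ]
    extra = rng.sample(pool, cfg.n_triples - len(base))
    triples = [MappingTriple(*t) for t in sorted(base | set(extra))]

    terms = (
        [OntologyTerm(t, 1) for t in l1]
        + [OntologyTerm(t, 2) for t in l2]
        + [OntologyTerm(t, 3) for t in l3]
    )
    return Ontology(terms, triples)


def make_abbreviations(o: Ontology) -> AbbreviationMap:
    """Deterministic abbreviation map for Level-1 terms (e.g. "badu" -> "bd")."""
    entries: dict[str, str] = {}
    for lab in o.labels(1):
        base = "".join(c for c in lab if c in _CONSONANTS)[:2] or lab[:2]
        key = base
        k = 2
        while key in entries or key == lab:
            key = base + lab[min(k, len(lab) - 1)]
            k += 1
        entries[key] = lab
    return AbbreviationMap(entries)


def _is_negative(t: MappingTriple) -> bool:
    return t.l2 == "none" or t.l3 in NEGATIVE_L3_TERMS


def _realize(t: MappingTriple, rng: random.Random, templates: Sequence[str]) -> str:
    if t.l2 == "none":
        return _L2_NONE_TEMPLATE.format(l1=t.l1)
    if t.l3 in _NEG_TEMPLATES:
        return _NEG_TEMPLATES[t.l3].format(l1=t.l1, l2=t.l2)
    tpl = rng.choice(list(templates))
    return tpl.format(l1=t.l1, l2=t.l2, l3=t.l3)


def _vocabulary(o: Ontology, templates: Sequence[str]) -> set[str]:
    toks: set[str] = set()
    for t in o.terms:
        toks.update(t.label.split())
    for tpl in list(templates) + list(_NEG_TEMPLATES.values()) + [_L2_NONE_TEMPLATE]:
        toks.update(
            w for w in tpl.replace("{l1}", "").replace("{l2}", "").replace("{l3}", "").split()
        )
    return toks


def _typo(token: str, rng: random.Random, vocab: set[str]) -> str | None:
    """One random character edit, kept only if uniquely recoverable."""
    from .textprep import damerau_levenshtein

    letters = "abcdefghijklmnopqrstuvwxyz"
    i = rng.randrange(len(token))
    op = rng.choice(("sub", "del", "ins", "swap"))
    if op == "sub":
        bad = token[:i] + rng.choice(letters) + token[i + 1 :]
    elif op == "del":
        bad = token[:i] + token[i + 1 :]
    elif op == "ins":
        bad = token[:i] + rng.choice(letters) + token[i:]
    else:
        if i == len(token) - 1:
            i -= 1
        bad = token[:i] + token[i + 1] + token[i] + token[i + 2 :]
    if bad == token or bad in vocab:
        return None
    # unique candidate at distance <= 1 => correct_spelling restores it
    cands = [v for v in vocab if damerau_levenshtein(bad, v, cap=1) <= 1]
    return bad if cands == [token] else None


def _corrupt(
    sentence: str,
    gold_l1: str,
    abbrev: AbbreviationMap,
    rng: random.Random,
    cfg: GeneratorConfig,
    vocab: set[str],
) -> str:
    if cfg.abbrev_rate and rng.random() < cfg.abbrev_rate:
        inv = {v: k for k, v in abbrev.entries.items()}
        short = inv.get(gold_l1)
        if short:
            sentence = sentence.replace(gold_l1, short.upper(), 1)
    if cfg.typo_rate and rng.random() < cfg.typo_rate:
        toks = sentence.split()
        idx = [i for i, w in enumerate(toks) if len(w) >= 4 and w in vocab]
        if idx:
            i = rng.choice(idx)
            bad = _typo(toks[i], rng, vocab)
            if bad is not None:
                toks[i] = bad
                sentence = " ".join(toks)
    return sentence


def generate_dictionary(o: Ontology, cfg: GeneratorConfig) -> list[LabeledSentence]:
    """Realize ``cfg.n_sentences`` labeled sentences from licensed triples.

    Negated sentences (gold triple carrying a negative term) are drawn at
    ``cfg.negation_rate``; abbreviation substitution and recoverable
    single-edit typos are applied at their configured rates.
    """
    rng = random.Random(cfg.seed + 1)
    triples = sorted(o.triples, key=MappingTriple.as_tuple)
    neg = [t for t in triples if _is_negative(t)]
    pos = [t for t in triples if not _is_negative(t)]
    if not pos:
        raise ValueError("ontology has no positive triples")
    abbrev = make_abbreviations(o)
    vocab = _vocabulary(o, cfg.paraphrase_templates)
    out = []
    for _ in range(cfg.n_sentences):
        t = rng.choice(neg) if neg and rng.random() < cfg.negation_rate else rng.choice(pos)
        text = _realize(t, rng, cfg.paraphrase_templates)
        text = _corrupt(text, t.l1, abbrev, rng, cfg, vocab)
        out.append(LabeledSentence(text=text, gold=t, dataset=cfg.dataset))
    return out


def generate_novel_sentences(o: Ontology, cfg: GeneratorConfig) -> list[LabeledSentence]:
    """Sentences whose gold triples are novel combinations: every term
    exists in the ontology but the three-way combination is unlicensed."""
    rng = random.Random(cfg.seed + 2)
    licensed = {t.as_tuple() for t in o.triples}
    regular_l2 = [t for t in o.labels(2) if t != "none"]
    regular_l3 = [t for t in o.labels(3) if t not in NEGATIVE_L3_TERMS]
    pool = [
        (a, b, c)
        for a in o.labels(1)
        for b in regular_l2
        for c in regular_l3
        if (a, b, c) not in licensed
    ]
    if not pool:
        raise ValueError("no unlicensed rearrangement exists")
    if cfg.n_novel > len(pool):
        raise ValueError(
            f"requested {cfg.n_novel} novel triples but only {len(pool)} exist"
        )
    chosen = rng.sample(sorted(pool), cfg.n_novel)
    out = []
    for tup in chosen:
        t = MappingTriple(*tup)
        text = _realize(t, rng, cfg.paraphrase_templates)
        out.append(LabeledSentence(text=text, gold=t, dataset=cfg.dataset + "-novel"))
    return out


def write_outputs(
    outdir: str | Path,
    o: Ontology,
    sentences: Sequence[LabeledSentence],
    cfg: GeneratorConfig,
) -> dict[str, Path]:
    """Write ontology JSON, dictionary TSV, abbreviation TSV and manifest."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": d / "ontology.json",
        "dictionary": d / "dictionary.tsv",
        "abbreviations": d / "abbreviations.tsv",
        "manifest": d / "manifest.json",
    }
    save_ontology(o, paths["ontology"])
    save_dictionary(sentences, paths["dictionary"])
    save_abbreviations(make_abbreviations(o), paths["abbreviations"])
    paths["manifest"].write_text(
        json.dumps({"generator_config": cfg.to_json()}, indent=1), encoding="utf-8"
    )
    return paths
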