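"""Three-level transthoracic-echocardiogram (TTE) ontology.

The ontology has three tiers — Level 1 anatomic structures, Level 2
attributes/functional elements, Level 3 descriptors — plus a set of
*licensed* (L1, L2, L3) triples: the term combinations that constitute
valid report-sentence mappings.  A label may legitimately appear at both
Level 2 and Level 3 (e.g. negative findings such as "none"), but labels
are unique within a level.

This module also carries the labeled-sentence dictionary container and
the coverage audits: how much of an external institution's data
dictionary the ontology can represent, and how many ontology terms appear
in a general medical reference vocabulary (a local stand-in for UMLS or
RadLex membership).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "OntologyTerm",
    "MappingTriple",
    "Ontology",
    "LabeledSentence",
    "ReferenceTermList",
    "OntologyError",
    "normalize_label",
    "load_ontology",
    "save_ontology",
    "load_dictionary",
    "save_dictionary",
    "load_reference_list",
    "contains_triple",
    "is_novel_combination",
    "dictionary_coverage",
    "reference_coverage",
    "CoverageReport",
]

LEVELS = (1, 2, 3)

_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


class OntologyError(ValueError):
    """Raised for schema or invariant violations in ontology data."""


def normalize_label(label: str) -> str:
    """Normalize a term label: lowercase, punctuation to spaces, collapsed whitespace.

    The same rule is applied to ontology labels, gold labels and reference
    entries so that coverage audits are deterministic.
    """
    s = _PUNCT_RE.sub(" ", label.casefold())
    return _WS_RE.sub(" ", s).strip()


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term at one level.

    Parameters
    ----------
    label : normalized label (lowercase, single-spaced).
    level : 1, 2 or 3.
    synonyms : alternative normalized surface forms.
    reference_ids : mapping of reference-vocabulary name to an opaque
        identifier (e.g. a UMLS CUI), where licensed.
    """

    label: str
    level: int
    synonyms: tuple[str, ...] = ()
    reference_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label or self.label != normalize_label(self.label):
            raise OntologyError(f"term label not normalized: {self.label!r}")
        if self.level not in LEVELS:
            raise OntologyError(f"term {self.label!r}: level must be 1, 2 or 3")
        object.__setattr__(self, "synonyms", tuple(normalize_label(s) for s in self.synonyms))
        object.__setattr__(self, "reference_ids", dict(self.reference_ids))

    def __hash__(self) -> int:  # reference_ids is unhashable; identity is (label, level)
        return hash((self.label, self.level))


@dataclass(frozen=True)
class MappingTriple:
    """A licensed (Level 1, Level 2, Level 3) assignment of one sentence.

    Negative findings use explicit terms ("none", "not seen") rather than
    empty slots.
    """

    l1: str
    l2: str
    l3: str

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "l3"):
            v = getattr(self, name)
            if not v or not v.strip():
                raise OntologyError(f"triple component {name} is empty")
            object.__setattr__(self, name, normalize_label(v))

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.l1, self.l2, self.l3)


@dataclass(frozen=True)
class LabeledSentence:
    """A raw report sentence with its gold three-level mapping."""

    text: str
    gold: MappingTriple
    dataset: str = "default"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise OntologyError("sentence text is empty")


@dataclass(frozen=True)
class ReferenceTermList:
    """A local membership list standing in for a general medical vocabulary."""

    name: str
    entries: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", frozenset(normalize_label(e) for e in self.entries)
        )


class Ontology:
    """Terms at three levels plus the set of licensed triples."""

    def __init__(self, terms: Iterable[OntologyTerm], triples: Iterable[MappingTriple]):
        self.terms: tuple[OntologyTerm, ...] = tuple(terms)
        self.triples: frozenset[MappingTriple] = frozenset(triples)
        self._by_level: dict[int, dict[str, OntologyTerm]] = {lv: {} for lv in LEVELS}
        for t in self.terms:
            lvl = self._by_level[t.level]
            if t.label in lvl:
                raise OntologyError(
                    f"duplicate label {t.label!r} at level {t.level}"
                )
            lvl[t.label] = t
        for tr in self.triples:
            for lv, lab in zip(LEVELS, tr.as_tuple()):
                if lab not in self._by_level[lv]:
                    raise OntologyError(
                        f"triple {tr.as_tuple()} references unknown level-{lv} "
                        f"term {lab!r}"
                    )

    # -- queries ---------------------------------------------------------
    def labels(self, level: int) -> tuple[str, ...]:
        """Labels at one level, in load order (frozen for feature layout)."""
        if level not in LEVELS:
            raise OntologyError(f"invalid level {level}")
        return tuple(self._by_level[level])

    def has_label(self, level: int, label: str) -> bool:
        return normalize_label(label) in self._by_level[level]

    def term(self, level: int, label: str) -> OntologyTerm:
        return self._by_level[level][normalize_label(label)]

    def level_counts(self) -> dict[int, int]:
        return {lv: len(self._by_level[lv]) for lv in LEVELS}

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def distinct_labels(self) -> frozenset[str]:
        """Distinct labels across all three levels (shared labels counted once)."""
        return frozenset(t.label for t in self.terms)

    def l23_labels(self) -> tuple[str, ...]:
        """Distinct Level-2 ∪ Level-3 labels, load order, shared labels once.

        This ordering defines the Level-2/3 Jaccard feature block.
        """
        seen: dict[str, None] = {}
        for t in self.terms:
            if t.level in (2, 3) and t.label not in seen:
                seen[t.label] = None
        return tuple(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return set(self.terms) == set(other.terms) and self.triples == other.triples

    def __repr__(self) -> str:
        c = self.level_counts()
        return (
            f"Ontology(L1={c[1]}, L2={c[2]}, L3={c[3]}, "
            f"triples={self.n_triples})"
        )


# -- persistence ---------------------------------------------------------

def load_ontology(path: str | Path) -> Ontology:
    """Load an ontology from its JSON serialization, validating all invariants."""
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise OntologyError(f"malformed ontology JSON in {path}: {e}") from e
    try:
        terms = [
            OntologyTerm(
                label=normalize_label(t["label"]),
                level=int(t["level"]),
                synonyms=tuple(t.get("synonyms", ())),
                reference_ids=dict(t.get("reference_ids", {})),
            )
            for t in data["terms"]
        ]
        triples = [MappingTriple(*tr) for tr in data["triples"]]
    except (KeyError, TypeError) as e:
        raise OntologyError(f"ontology JSON schema violation in {path}: {e}") from e
    return Ontology(terms, triples)


def save_ontology(o: Ontology, path: str | Path) -> None:
    data = {
        "terms": [
            {
                "label": t.label,
                "level": t.level,
                "synonyms": list(t.synonyms),
                "reference_ids": dict(t.reference_ids),
            }
            for t in o.terms
        ],
        "triples": sorted(tr.as_tuple() for tr in o.triples),
    }
    Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")


_DICT_COLUMNS = ["sentence", "level1", "level2", "level3", "dataset"]


def load_dictionary(path: str | Path) -> list[LabeledSentence]:
    """Read a labeled dictionary TSV (sentence, level1, level2, level3, dataset)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DICT_COLUMNS if c not in df.columns]
    if missing:
        raise OntologyError(f"dictionary {path} missing columns: {missing}")
    return [
        LabeledSentence(
            text=row.sentence,
            gold=MappingTriple(row.level1, row.level2, row.level3),
            dataset=row.dataset,
        )
        for row in df.itertuples()
    ]


def save_dictionary(sentences: Sequence[LabeledSentence], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            (s.text, s.gold.l1, s.gold.l2, s.gold.l3, s.dataset)
            for s in sentences
        ],
        columns=_DICT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_reference_list(path: str | Path, name: str | None = None) -> ReferenceTermList:
    """Read a reference term list: one normalized term per line."""
    p = Path(path)
    entries = [ln.strip() for ln in p.read_text(encoding="utf-8").splitlines()]
    return ReferenceTermList(name or p.stem, frozenset(e for e in entries if e))


# -- triple queries ------------------------------------------------------

def contains_triple(o: Ontology, t: MappingTriple) -> bool:
    """True iff ``t`` is a licensed combination of the ontology."""
    return t in o.triples


def is_novel_combination(o: Ontology, t: MappingTriple) -> bool:
    """True iff every component of ``t`` exists at its level but the
    three-way combination is not licensed — the extrapolation regime."""
    return (
        o.has_label(1, t.l1)
        and o.has_label(2, t.l2)
        and o.has_label(3, t.l3)
        and not contains_triple(o, t)
    )


# -- coverage audits -----------------------------------------------------

@dataclass(frozen=True)
class CoverageReport:
    """Counts for one dataset (or one reference list / level)."""

    covered: int
    total: int

    @property
    def fraction(self) -> float:
        return self.covered / self.total if self.total else 0.0


def dictionary_coverage(
    o: Ontology,
    sentences: Sequence[LabeledSentence],
    synonyms: Mapping[str, str] | None = None,
) -> dict[str, CoverageReport]:
    """How many dictionary sentences the ontology can represent.

    A sentence is *represented* iff each of its three gold labels (after
    optional synonym mapping and normalization) exists at the matching
    ontology level.  Returns per-dataset reports plus an ``"all"`` total.
    """
    if not sentences:
        raise OntologyError("dictionary_coverage: empty sentence list")
    syn = {normalize_label(k): normalize_label(v) for k, v in (synonyms or {}).items()}

    def resolve(label: str) -> str:
        lab = normalize_label(label)
        return syn.get(lab, lab)

    per: dict[str, list[int]] = {}
    for s in sentences:
        ok = all(
            o.has_label(lv, resolve(lab))
            for lv, lab in zip(LEVELS, s.gold.as_tuple())
        )
        cnt = per.setdefault(s.dataset, [0, 0])
        cnt[0] += int(ok)
        cnt[1] += 1
    out = {ds: CoverageReport(c, n) for ds, (c, n) in sorted(per.items())}
    out["all"] = CoverageReport(
        sum(r.covered for r in out.values()), sum(r.total for r in out.values())
    )
    return out


def reference_coverage(
    o: Ontology, ref: ReferenceTermList, level: int | str = "all"
) -> CoverageReport:
    """How many ontology terms appear in a reference vocabulary.

    A term counts as covered when its label or any synonym is in
    ``ref.entries``.  ``level="all"`` counts distinct labels across levels
    once (a label shared by Levels 2 and 3 contributes a single count).
    """
    if not ref.entries:
        raise OntologyError("reference_coverage: empty reference list")

    def covered(term: OntologyTerm) -> bool:
        return term.label in ref.entries or any(s in ref.entries for s in term.synonyms)

    if level == "all":
        status: dict[str, bool] = {}
        for t in o.terms:
            status[t.label] = status.get(t.label, False) or covered(t)
        return CoverageReport(sum(status.values()), len(status))
    if level not in LEVELS:
        raise OntologyError(f"invalid level {level!r}")
    terms = [o.term(level, lab) for lab in o.labels(level)]
    return CoverageReport(sum(covered(t) for t in terms), len(terms))
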