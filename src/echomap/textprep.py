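"""Sentence delimitation and normalization for structured report text.

Report text is split into sentences, abbreviations are expanded on whole
tokens, everything is lowercased with punctuation mapped to spaces, and
out-of-vocabulary tokens are spell-corrected conservatively (unique
candidate within a small Damerau–Levenshtein distance, else left alone).
The module also owns the deterministic train/validation splitter.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TypeVar

from .ontology import LabeledSentence, normalize_label

__all__ = [
    "AbbreviationMap",
    "Vocabulary",
    "split_sentences",
    "normalize_sentence",
    "correct_spelling",
    "damerau_levenshtein",
    "split_dictionary",
    "load_abbreviations",
    "save_abbreviations",
    "load_vocabulary",
]

T = TypeVar("T")


@dataclass(frozen=True)
class AbbreviationMap:
    """Whole-token abbreviation → expansion map (both sides normalized)."""

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for k, v in self.entries.items():
            nk, nv = normalize_label(k), normalize_label(v)
            if nk == nv:
                raise ValueError(f"abbreviation {k!r} maps to itself")
            norm[nk] = nv
        object.__setattr__(self, "entries", norm)


@dataclass(frozen=True)
class Vocabulary:
    """Normalized tokens known to the corpus and ontology."""

    tokens: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", frozenset(self.tokens))

    def __contains__(self, token: str) -> bool:
        return token in self.tokens


# Sentence boundary: ".", "!", "?", ";" followed by whitespace or end of
# text; a period between digits (a decimal number) is protected.  Newlines
# always delimit — structured-report lines are short declaratives.
_BOUNDARY_RE = re.compile(r"(?<=[.!?;])(?<!\d.)\s+|(?<=[.!?;])(?<!\d.)$|\n+")


def split_sentences(text: str) -> list[str]:
    """Delimit raw text into sentences; decimals like ``55.3`` stay intact."""
    parts = _BOUNDARY_RE.split(text)
    return [p.strip() for p in parts if p and p.strip()]


def normalize_sentence(s: str, abbrev: AbbreviationMap | None = None) -> str:
    """Lowercase, map punctuation to spaces, collapse whitespace, and expand
    whole-token abbreviations.  Idempotent provided no expansion token is
    itself an abbreviation key."""
    base = normalize_label(s)
    if abbrev is None or not abbrev.entries:
        return base
    out = [abbrev.entries.get(tok, tok) for tok in base.split()]
    return " ".join(out)


def damerau_levenshtein(a: str, b: str, cap: int | None = None) -> int:
    """Damerau–Levenshtein distance (optimal string alignment variant).

    ``cap`` allows an early exit: any distance > cap is reported as cap+1.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if cap is not None and abs(la - lb) > cap:
        return cap + 1
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if cap is not None and min(cur) > cap:
            return cap + 1
        prev2, prev = prev, cur
    return prev[lb]


def correct_spelling(s: str, vocab: Vocabulary, max_edit: int = 1) -> str:
    """Replace each out-of-vocabulary token by the unique vocabulary token
    within ``max_edit`` edits; leave it unchanged on zero candidates or a
    tie at the minimal distance.  In-vocabulary tokens are never altered."""
    if not vocab.tokens:
        raise ValueError("correct_spelling requires a non-empty vocabulary")
    out = []
    for tok in s.split():
        if tok in vocab or tok.isdigit():
            out.append(tok)
            continue
        best_d, best = max_edit + 1, []
        for cand in vocab.tokens:
            d = damerau_levenshtein(tok, cand, cap=max_edit)
            if d < best_d:
                best_d, best = d, [cand]
            elif d == best_d:
                best.append(cand)
        out.append(best[0] if best_d <= max_edit and len(best) == 1 else tok)
    return " ".join(out)


def split_dictionary(
    sentences: Sequence[T], validation_fraction: float = 0.24, seed: int = 0
) -> tuple[list[T], list[T]]:
    """Deterministic disjoint train/validation partition.

    Validation size is ``round(n * fraction)`` with round-half-up, so a
    951-sentence dictionary at fraction 228/951 yields the 723/228 split.
    """
    if not 0.0 <= validation_fraction <= 1.0:
        raise ValueError(f"validation_fraction {validation_fraction} outside [0, 1]")
    items = list(sentences)
    n = len(items)
    n_val = int(n * validation_fraction + 0.5)
    idx = list(range(n))
    random.Random(seed).shuffle(idx)
    val_set = set(idx[:n_val])
    train = [items[i] for i in range(n) if i not in val_set]
    val = [items[i] for i in range(n) if i in val_set]
    return train, val


# -- file formats --------------------------------------------------------

def load_abbreviations(path: str | Path) -> AbbreviationMap:
    """Read a TSV of ``abbrev<TAB>expansion`` rows (no header)."""
    entries = {}
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        k, v = ln.split("\t", 1)
        entries[k] = v
    return AbbreviationMap(entries)


def save_abbreviations(abbrev: AbbreviationMap, path: str | Path) -> None:
    lines = [f"{k}\t{v}" for k, v in sorted(abbrev.entries.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Read a vocabulary file: one token per line."""
    toks = Path(path).read_text(encoding="utf-8").split()
    return Vocabulary(frozenset(toks))


def corpus_vocabulary(sentences: Sequence[LabeledSentence | str]) -> Vocabulary:
    """Vocabulary of all tokens in a normalized corpus."""
    toks: set[str] = set()
    for s in sentences:
        text = s if isinstance(s, str) else s.text
        toks.update(normalize_label(text).split())
    return Vocabulary(frozenset(toks))
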