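"""Rule-based clinical NLP: normalization, concept tagging, assertion detection.

The pipeline turns raw note or criteria text into a :data:`ConceptBag`:

1. sentence segmentation on ``. ! ?`` and newlines;
2. tokenization with character offsets, punctuation-only tokens dropped;
3. lower-casing and suffix-rule lemmatization (plural ``-s``/``-es``,
   ``-ies``→``y``) with a small exception table for irregulars;
4. duplicate-sentence removal by exact match on the lemma sequence
   (first occurrence kept) — clinical notes routinely repeat copied
   sentences, which would otherwise inflate term counts;
5. greedy longest-match dictionary tagging over lemmas;
6. NegEx-style trigger/scope assertion detection assigning NEG, HIST or
   FAM to tagged concepts within a bounded token window.

Everything is deterministic and dictionary-driven; no trained models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import Assertion, ConceptBag, ConceptTerm, FormatError, Lexicon

# Conjunctions that terminate an assertion trigger's scope.
ADVERSATIVES = {"but", "however", "although"}

_ASSERTION_PRECEDENCE = {Assertion.NEG: 0, Assertion.HIST: 1, Assertion.FAM: 2}

DEFAULT_SCOPE_LIMIT = 6


# ---------------------------------------------------------------------------
# Tokens and sentences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    surface: str  # original casing
    lemma: str
    start: int  # character offsets into the original text, half-open
    end: int


@dataclass(frozen=True)
class Sentence:
    tokens: tuple

    @property
    def lemmas(self) -> tuple:
        return tuple(t.lemma for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


_LEMMA_EXCEPTIONS = {
    # irregular verbs / common clinical participles the suffix rules miss
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "has": "have", "had": "have",
    "noted": "note", "ruled": "rule", "denied": "deny", "denies": "deny",
    # irregular plurals
    "children": "child", "feet": "foot", "teeth": "tooth",
    "men": "man", "women": "woman",
    # -s words that are not plurals
    "pertussis": "pertussis", "diabetes": "diabetes", "sepsis": "sepsis",
}


def lemmatize(word: str) -> str:
    """Suffix-stripping lemmatizer over lower-cased words."""
    w = word.lower()
    if w in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 4 and w.endswith(("ches", "shes", "sses", "xes", "zes")):
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")
_SENT_SPLIT_RE = re.compile(r"[.!?\n]")


def tokenize(text: str, offset: int = 0) -> list:
    """Word tokens with absolute character offsets; punctuation dropped."""
    return [
        Token(surface=m.group(), lemma=lemmatize(m.group()),
              start=offset + m.start(), end=offset + m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def segment_and_normalize(text: str) -> list:
    """Split text into normalized sentences with duplicates removed.

    Duplicate removal is exact match on the lemma sequence, keeping the
    first occurrence. Empty sentences (punctuation only) are dropped.
    """
    sentences = []
    seen = set()
    pos = 0
    for m in list(_SENT_SPLIT_RE.finditer(text)) + [None]:
        end = m.start() if m is not None else len(text)
        chunk = text[pos:end]
        tokens = tokenize(chunk, offset=pos)
        pos = m.end() if m is not None else len(text)
        if not tokens:
            continue
        key = tuple(t.lemma for t in tokens)
        if key in seen:
            continue
        seen.add(key)
        sentences.append(Sentence(tokens=tuple(tokens)))
    return sentences


# ---------------------------------------------------------------------------
# Concept tagging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConceptTag:
    """A tagged concept span, in token indices (half-open)."""

    start: int
    end: int
    concept_id: str


def _compile_lexicon(lexicon: Lexicon) -> dict:
    """first lemma -> [(lemma tuple, (concept ids,))], longest phrase first.

    Lexicon phrases run through the same lemmatizer as note text so that
    e.g. "skull fractures" matches the lemmas [skull, fracture]. Compiled
    once per Lexicon instance and cached on it.
    """
    cached = getattr(lexicon, "_trialscreen_index", None)
    if cached is not None:
        return cached
    grouped: dict = {}
    for entry in lexicon.entries:
        lemmas = tuple(t.lemma for t in tokenize(entry.phrase))
        if lemmas:
            grouped.setdefault(lemmas, set()).add(entry.concept_id)
    index: dict = {}
    for lemmas, cids in grouped.items():
        index.setdefault(lemmas[0], []).append((lemmas, tuple(sorted(cids))))
    for lst in index.values():
        lst.sort(key=lambda item: (-len(item[0]), item[0]))
    lexicon._trialscreen_index = index
    return index


def tag_concepts(sentence: Sentence, lexicon: Lexicon) -> list:
    """Greedy longest-match left-to-right dictionary tagging.

    Matched spans never overlap; a phrase mapping to several concept ids
    yields one tag per id on the same span.
    """
    index = _compile_lexicon(lexicon)
    lemmas = sentence.lemmas
    tags = []
    i = 0
    n = len(lemmas)
    while i < n:
        matched = False
        for phrase_lemmas, cids in index.get(lemmas[i], ()):
            L = len(phrase_lemmas)
            if i + L <= n and lemmas[i:i + L] == phrase_lemmas:
                for cid in cids:
                    tags.append(ConceptTag(start=i, end=i + L, concept_id=cid))
                i += L
                matched = True
                break
        if not matched:
            i += 1
    return tags


# ---------------------------------------------------------------------------
# Assertion detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssertionRule:
    """A trigger phrase assigning an assertion within a bounded scope.

    ``direction="forward"`` scopes over tokens after the trigger,
    ``"backward"`` over tokens before it. The scope covers at most
    ``scope_limit`` tokens and is cut short by adversative conjunctions
    (but/however/although) and the sentence boundary.
    """

    trigger: tuple  # lemmatized trigger tokens
    assertion: Assertion
    direction: str  # "forward" | "backward"
    scope_limit: int = DEFAULT_SCOPE_LIMIT

    def __post_init__(self) -> None:
        if not self.trigger:
            raise ValueError("empty trigger")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.scope_limit < 1:
            raise ValueError("scope_limit must be >= 1")


def make_rule(trigger: str, assertion: Union[Assertion, str], direction: str = "forward",
              scope_limit: int = DEFAULT_SCOPE_LIMIT) -> AssertionRule:
    """Build a rule from a surface trigger phrase (lemmatized on the way in)."""
    lemmas = tuple(t.lemma for t in tokenize(trigger))
    return AssertionRule(trigger=lemmas, assertion=Assertion(assertion),
                         direction=direction, scope_limit=scope_limit)


_DEFAULT_RULE_SPECS = [
    # negation
    ("no", "NEG", "forward"),
    ("not", "NEG", "forward"),
    ("denies", "NEG", "forward"),
    ("without", "NEG", "forward"),
    ("negative for", "NEG", "forward"),
    ("rule out", "NEG", "forward"),
    ("ruled out", "NEG", "backward"),
    # temporal past
    ("history of", "HIST", "forward"),
    ("past", "HIST", "forward"),
    ("previous", "HIST", "forward"),
    ("prior", "HIST", "forward"),
    # non-patient experiencer
    ("mother", "FAM", "forward"),
    ("father", "FAM", "forward"),
    ("sibling", "FAM", "forward"),
    ("family history of", "FAM", "forward"),
]


def default_rules() -> list:
    """The built-in NegEx-style trigger set (editable via a rules TSV)."""
    return [make_rule(t, a, d) for t, a, d in _DEFAULT_RULE_SPECS]


def load_rules(path: Union[str, Path]) -> list:
    """Load assertion rules from TSV: trigger, assertion, direction, scope_limit."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty rules file")
    rules = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise FormatError(f"{path}: line {lineno}: expected 4 columns, got {len(cols)}")
        trigger, assertion, direction, scope = (c.strip() for c in cols)
        try:
            rules.append(make_rule(trigger, assertion, direction, int(scope)))
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if not rules:
        raise FormatError(f"{path}: no rules after header")
    return rules


def write_rules(rules: Iterable[AssertionRule], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("trigger\tassertion\tdirection\tscope_limit\n")
        for r in rules:
            fh.write(f"{' '.join(r.trigger)}\t{r.assertion.value}\t{r.direction}\t{r.scope_limit}\n")


def _trigger_occurrences(lemmas: Sequence[str], rules: Sequence[AssertionRule]) -> list:
    """Greedy longest-match trigger occurrences: (start, end, [rules]).

    Occurrences never overlap, so a longer trigger ("family history of",
    FAM) shadows a shorter one embedded in it ("history of", HIST).
    """
    by_first: dict = {}
    grouped: dict = {}
    for r in rules:
        grouped.setdefault(r.trigger, []).append(r)
    for trig, rs in grouped.items():
        by_first.setdefault(trig[0], []).append((trig, rs))
    for lst in by_first.values():
        lst.sort(key=lambda item: (-len(item[0]), item[0]))
    occurrences = []
    i = 0
    n = len(lemmas)
    while i < n:
        matched = False
        for trig, rs in by_first.get(lemmas[i], ()):
            L = len(trig)
            if i + L <= n and tuple(lemmas[i:i + L]) == trig:
                occurrences.append((i, i + L, rs))
                i += L
                matched = True
                break
        if not matched:
            i += 1
    return occurrences


def detect_assertions(sentence: Sentence, tags: Sequence[ConceptTag],
                      rules: Sequence[AssertionRule]) -> list:
    """Assign an assertion to every tagged concept.

    For each tag the nearest in-scope trigger wins; the token gap between
    trigger and tag must be < scope_limit and must not contain an
    adversative conjunction. Ties on distance resolve NEG > HIST > FAM,
    then earlier trigger position. Untriggered tags are AFFIRMED.
    """
    lemmas = sentence.lemmas
    occurrences = _trigger_occurrences(lemmas, rules)
    terms = []
    for tag in tags:
        best = None  # (gap, precedence, trigger position, assertion)
        for start, end, rs in occurrences:
            for rule in rs:
                if rule.direction == "forward":
                    gap = tag.start - end
                    between = lemmas[end:tag.start]
                else:
                    gap = start - tag.end
                    between = lemmas[tag.end:start]
                if gap < 0 or gap >= rule.scope_limit:
                    continue
                if any(tok in ADVERSATIVES for tok in between):
                    continue
                key = (gap, _ASSERTION_PRECEDENCE[rule.assertion], start)
                if best is None or key < best[0]:
                    best = (key, rule.assertion)
        assertion = best[1] if best is not None else Assertion.AFFIRMED
        terms.append(ConceptTerm(concept_id=tag.concept_id, assertion=assertion))
    return terms


# ---------------------------------------------------------------------------
# End-to-end extraction
# ---------------------------------------------------------------------------


def extract_concepts(text: str, lexicon: Lexicon,
                     rules: Optional[Sequence[AssertionRule]] = None) -> ConceptBag:
    """Raw text -> bag of rendered assertion-qualified concept terms.

    Counts aggregate over the deduplicated sentences; an empty text yields
    an empty bag.
    """
    if rules is None:
        rules = default_rules()
    bag: ConceptBag = {}
    for sentence in segment_and_normalize(text):
        tags = tag_concepts(sentence, lexicon)
        for term in detect_assertions(sentence, tags, rules):
            rendered = term.render()
            bag[rendered] = bag.get(rendered, 0) + 1
    return dict(sorted(bag.items()))
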