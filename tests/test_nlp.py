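"""Normalization, concept tagging, assertion detection and extraction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import optimal_tiling_tokens

from trialscreen import Assertion, ConceptTerm, Lexicon, LexiconEntry, extract_concepts
from trialscreen.nlp import (
    default_rules,
    detect_assertions,
    lemmatize,
    load_rules,
    make_rule,
    segment_and_normalize,
    tag_concepts,
    write_rules,
)
from trialscreen.synth import fixture_trial_mappings


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("word, lemma", [
    ("fractures", "fracture"),
    ("noted", "note"),
    ("injuries", "injury"),
    ("denies", "deny"),
    ("boxes", "box"),
    ("fever", "fever"),
    ("sepsis", "sepsis"),   # -is words are not plurals
    ("children", "child"),
])
def test_lemmatizer_suffix_rules_and_exceptions(word, lemma):
    assert lemmatize(word) == lemma


def test_segment_empty_text():
    assert segment_and_normalize("") == []
    assert segment_and_normalize("...!!\n\n") == []


def test_duplicate_sentences_removed_keeping_first():
    sentences = segment_and_normalize("Fever and cough. Fever and cough.")
    assert len(sentences) == 1
    assert sentences[0].lemmas == ("fever", "and", "cough")


def test_lemmatized_tokens_example():
    (sentence,) = segment_and_normalize("Skull fractures noted.")
    assert sentence.lemmas == ("skull", "fracture", "note")


@given(st.text(alphabet="abc XY.\n!?', ", max_size=80))
def test_token_offsets_strictly_increasing_nonoverlapping(text):
    for sentence in segment_and_normalize(text):
        spans = [(t.start, t.end) for t in sentence.tokens]
        assert all(s < e for s, e in spans)
        assert all(prev_end <= start for (_, prev_end), (start, _) in zip(spans, spans[1:]))
        for token in sentence.tokens:
            assert text[token.start:token.end] == token.surface


# ---------------------------------------------------------------------------
# Concept tagging
# ---------------------------------------------------------------------------


def test_tag_concepts_simple(lexicon):
    (sentence,) = segment_and_normalize("to rule out pneumonia")
    tags = tag_concepts(sentence, lexicon)
    assert [(t.concept_id, sentence.lemmas[t.start:t.end]) for t in tags] == [
        ("C0032285", ("pneumonia",))]


def test_longest_match_wins():
    lex = Lexicon([
        LexiconEntry("head", "C9100001", "finding"),
        LexiconEntry("head injury", "C9000010", "finding"),
    ])
    (sentence,) = segment_and_normalize("head injury")
    tags = tag_concepts(sentence, lex)
    assert [t.concept_id for t in tags] == ["C9000010"]


def test_multi_concept_phrase_yields_tag_per_concept(lexicon):
    (sentence,) = segment_and_normalize("patient has a cold")
    tags = tag_concepts(sentence, lexicon)
    assert sorted(t.concept_id for t in tags) == ["C9000045", "C9000046"]
    assert len({(t.start, t.end) for t in tags}) == 1


def test_no_match_yields_empty(lexicon):
    (sentence,) = segment_and_normalize("parent at bedside")
    assert tag_concepts(sentence, lexicon) == []


def _fixture_sentences(lexicon):
    """Every templated sentence the generator can emit, plus criteria texts."""
    texts = []
    for mapping in fixture_trial_mappings():
        texts.extend([mapping["inclusion_text"], mapping["exclusion_text"]])
    for entry in lexicon.entries:
        texts.append(f"Patient presents with {entry.phrase} today.")
        texts.append(f"No {entry.phrase} noted.")
        texts.append(f"History of {entry.phrase}.")
        texts.append(f"Family history of {entry.phrase}.")
    sentences = []
    for text in texts:
        sentences.extend(segment_and_normalize(text))
    return [s for s in sentences if len(s) <= 12]


def test_greedy_tagging_matches_exhaustive_tiling_oracle(lexicon):
    """On every fixture sentence, greedy longest-match covers as many tokens
    as the best non-overlapping tiling found by exhaustive enumeration."""
    phrase_set = set()
    for entry in lexicon.entries:
        (s,) = segment_and_normalize(entry.phrase)
        phrase_set.add(s.lemmas)
    checked = 0
    for sentence in _fixture_sentences(lexicon):
        tags = tag_concepts(sentence, lexicon)
        spans = {(t.start, t.end) for t in tags}
        assert all(sentence.lemmas[a:b] in phrase_set for a, b in spans)
        ordered = sorted(spans)
        assert all(p[1] <= q[0] for p, q in zip(ordered, ordered[1:]))  # non-overlap
        greedy_tokens = sum(b - a for a, b in spans)
        assert greedy_tokens == optimal_tiling_tokens(sentence.lemmas, phrase_set)
        checked += 1
    assert checked > 100


# ---------------------------------------------------------------------------
# Assertion detection
# ---------------------------------------------------------------------------


def _terms(text, lexicon, rules):
    (sentence,) = segment_and_normalize(text)
    return detect_assertions(sentence, tag_concepts(sentence, lexicon), rules)


@pytest.mark.parametrize("text, rendered", [
    ("to rule out pneumonia", "NEG_C0032285"),
    ("pneumonia was ruled out", "NEG_C0032285"),
    ("history of asthma", "HIST_C9000003"),
    ("patient has asthma", "C9000003"),
    ("denies fever", "NEG_C9000001"),
    ("family history of asthma", "FAM_C9000003"),
    ("mother has asthma", "FAM_C9000003"),
])
def test_assertion_examples(lexicon, rules, text, rendered):
    assert [t.render() for t in _terms(text, lexicon, rules)] == [rendered]


def test_scope_limited_to_window(lexicon, rules):
    # six intervening tokens put the concept outside the default scope of 6
    text = "no aa bb cc dd ee ff fever"
    assert [t.render() for t in _terms(text, lexicon, rules)] == ["C9000001"]
    text = "no aa bb fever"
    assert [t.render() for t in _terms(text, lexicon, rules)] == ["NEG_C9000001"]


def test_adversative_terminates_scope(lexicon, rules):
    assert [t.render() for t in _terms("no rash but fever", lexicon, rules)] == [
        "NEG_C9000020", "C9000001"]


def test_precedence_negation_beats_temporal(lexicon, rules):
    # HIST trigger 'past' forward at gap 0 and NEG 'ruled out' backward at gap 0
    assert [t.render() for t in _terms("past asthma ruled out", lexicon, rules)] == [
        "NEG_C9000003"]


def test_every_default_rule_fires(lexicon, rules):
    """Rule-coverage: each shipped trigger flips 'fever' on a minimal sentence."""
    for rule in rules:
        trigger = " ".join(rule.trigger)
        text = f"{trigger} fever" if rule.direction == "forward" else f"fever {trigger}"
        terms = _terms(text, lexicon, rules)
        assert any(t.assertion is rule.assertion and t.concept_id == "C9000001"
                   for t in terms), f"rule {trigger!r} never fired"


def test_rules_tsv_roundtrip(tmp_path, rules):
    path = tmp_path / "rules.tsv"
    write_rules(rules, path)
    assert load_rules(path) == rules


def test_make_rule_validates():
    with pytest.raises(ValueError):
        make_rule("no", "NEG", "sideways")
    with pytest.raises(ValueError):
        make_rule("", "NEG")


# ---------------------------------------------------------------------------
# End-to-end extraction
# ---------------------------------------------------------------------------


def test_extract_worked_example(lexicon):
    assert extract_concepts("to rule out pneumonia", lexicon) == {"NEG_C0032285": 1}


def test_extract_empty(lexicon):
    assert extract_concepts("", lexicon) == {}


def test_extract_dedup_and_triggers(lexicon):
    bag = extract_concepts("Fever today. Fever today. History of asthma.", lexicon)
    assert bag == {"C9000001": 1, "HIST_C9000003": 1}


@given(st.lists(st.sampled_from([
    "Patient presents with fever today.",
    "No cough noted.",
    "History of asthma.",
    "Family history of seizure.",
    "Exam shows skull fractures.",
    "Parent at bedside.",
]), min_size=0, max_size=6))
def test_extraction_idempotent_under_text_duplication(lexicon, parts):
    text = " ".join(parts)
    assert extract_concepts(text, lexicon) == extract_concepts(text + "\n" + text, lexicon)


def test_appending_new_phrase_is_monotone(lexicon):
    base = "Patient presents with fever today. No cough noted."
    before = extract_concepts(base, lexicon)
    after = extract_concepts(base + " Exam shows rash.", lexicon)
    assert set(before) <= set(after)
    assert all(after[t] >= c for t, c in before.items())
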