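"""Turn a clinical note into a bag of assertion-qualified concept terms.

The note below mixes an affirmed finding, a negated work-up phrase, a
historical condition and a duplicated sentence. The pipeline lemmatizes,
drops the duplicate, tags lexicon phrases (longest match) and applies
NegEx-style trigger/scope assertion detection.
"""

from trialscreen import extract_concepts, fixture_lexicon

note = (
    "Patient presents with head injury today. Skull fractures noted. "
    "CXR to rule out pneumonia. History of asthma. "
    "Patient presents with head injury today."
)

lexicon = fixture_lexicon()
bag = extract_concepts(note, lexicon)

print("note:", note)
print("extracted bag:")
for term, count in bag.items():
    print(f"  {term}: {count}")
print()
print("Bare identifiers are affirmed mentions (matchable against inclusion "
      "criteria); NEG_/HIST_ prefixes mark negated and historical mentions, "
      "which match only criteria written in that same qualified form. The "
      "duplicated sentence contributes once.")
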