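"""Generate a planted-signal corpus and look at what the generator controls.

Builds the default synthetic study set: a lexicon of 8 word classes and
1,600 labeled posts (400 per triage category) in which class 1 is emitted
far more often in crisis posts than in green ones.
"""

from collections import Counter

from lexcnn import generate_corpus, generate_lexicon, planted_signal_spec

spec = planted_signal_spec()
lexicon = generate_lexicon(spec, seed=1)
corpus = generate_corpus(spec, lexicon, seed=1)

print(f"classes: {len(lexicon.classes)}, patterns: {len(lexicon.entries)}")
print(f"posts: {len(corpus)} ({Counter(p.label for p in corpus)})")
print("planted-class emission rate by category:",
      {c: spec.rates[c][0] for c in ("crisis", "red", "amber", "green")})
print("\nexample crisis post:")
print(" ", corpus[0].text[:120])
print("\nexample green post:")
print(" ", corpus[-1].text[:120])
# The crisis post mixes planted-class words (c01w..) with background tokens
# and negative emojis; the green post shows positive emojis instead.
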