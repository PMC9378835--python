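"""Rank word classes by discriminability and derive attention weights.

Counts each class's token frequency per triage category, max-normalizes the
rows, ranks classes by the spread delta of the normalized row, and converts
the top-k deltas into per-word attention weights in [1, 2).
"""

import numpy as np

from lexcnn import (compute_class_frequencies, discriminability,
                    generate_corpus, generate_lexicon, planted_signal_spec,
                    preprocess_corpus, word_weights)

spec = planted_signal_spec()
lexicon = generate_lexicon(spec, seed=1)
corpus = generate_corpus(spec, lexicon, seed=1)
tokenized, _ = preprocess_corpus(corpus, n=80)

freq = compute_class_frequencies(tokenized, lexicon)
disc = discriminability(freq, k=3)

print("class  delta    selected")
for i in np.argsort(-disc.sd):
    cid = disc.class_ids[i]
    print(f"{lexicon.classes[cid].name}  {disc.sd[i]:.4f}  "
          f"{'*' if cid in disc.selected else ''}")

wt = word_weights(lexicon, disc)
planted_word = sorted(p for p, ids in lexicon.entries.items() if 1 in ids)[0]
print(f"\nweight of planted-class word {planted_word!r}: "
      f"{wt.weight(planted_word.rstrip('*')):.4f}")
print(f"weight of an out-of-lexicon word: {wt.weight('whatever'):.4f}")
# The planted class dominates the ranking (delta ~0.7 vs ~0.05 noise for the
# uniform classes); its words get weight ~1.46 while everything else stays
# at the neutral weight 1, so the classifier's attention is steered toward
# exactly the tokens that separate the categories.
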