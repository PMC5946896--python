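"""Validate a translation-pair stimulus set for lexical overlap.

Cross-language decoding is only evidence of shared *semantics* if the two
word forms of a concept share no letters the classifier could exploit;
the criterion is a normalized Levenshtein distance of 1.0 per pair.
"""

import semdecode as sd
from semdecode.stimuli import TranslationPair

pairs = sd.generate_stimulus_set(10)
report = sd.validate_stimulus_set(pairs)
print(report.to_string(index=False))
print(f"mean distance: {report.attrs['mean']:.2f}  (SD {report.attrs['sd']:.2f})")

# a deliberately bad pair: 'kat' vs 'kate' share almost all letters
bad = sd.validate_stimulus_set([TranslationPair(1, "kat", "kate")])
print("\n'kat' / 'kate' flagged:", bool(bad["flagged"].iloc[0]),
      f"(distance {bad['normalized_distance'].iloc[0]:.2f})")
# Every built-in pair scores 1.00 (no exploitable overlap); pairs below
# the threshold are flagged for replacement.
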