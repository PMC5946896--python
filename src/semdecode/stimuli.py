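"""Stimulus-set validation for cross-language designs.

Cross-language decoding is only interpretable as *semantic* transfer if the
two languages' word forms for a concept share no letters or phonemes in
predictable positions; otherwise the classifier may exploit lexical overlap.
The constraint is operationalised as a normalized Levenshtein distance of
1.0 between translation equivalents (edit distance divided by the longer
word's length), e.g. Dutch *maan* vs French *lune*, *paard* vs *cheval*.

This module provides the edit-distance primitives and a validator that
reports per-pair distances and flags any pair below the required threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TranslationPair:
    """Words in two languages denoting the same concept."""

    concept_id: int
    word_l1: str
    word_l2: str

    def __post_init__(self) -> None:
        if not self.word_l1 or not self.word_l2:
            raise ValueError("both words must be non-empty")


#: The two translation pairs used as worked examples of the zero-overlap
#: constraint (Dutch / French): moon and horse.
PAPER_PAIRS: tuple[tuple[str, str], ...] = (("maan", "lune"), ("paard", "cheval"))

# Synthetic filler pairs: equal-length words built from disjoint letter sets,
# which guarantees normalized Levenshtein distance 1.0.
_FILLER_L1_LETTERS = "bdgkmnprst"
_FILLER_L2_LETTERS = "cfhjlvwxyz"


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b``.

    Computed by the standard dynamic program; symmetric and satisfies the
    metric axioms.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


def normalized_levenshtein(a: str, b: str) -> float:
    """Edit distance divided by the longer word's length, in [0, 1].

    1.0 means no exploitable lexical overlap (every alignment rewrites the
    whole word); 0.0 means identical strings.  Comparison is case-folded
    but accent-preserving.
    """
    if not a and not b:
        raise ValueError("at least one string must be non-empty")
    return levenshtein(a.casefold(), b.casefold()) / max(len(a), len(b))


def generate_stimulus_set(n_concepts: int) -> list[TranslationPair]:
    """Concept-labelled translation pairs with zero lexical overlap.

    The first two pairs are the printed worked examples (maan/lune,
    paard/cheval); further concepts get synthetic filler pairs built from
    disjoint letter inventories so that every pair has normalized
    Levenshtein distance exactly 1.0.
    """
    if n_concepts < 0:
        raise ValueError("n_concepts must be >= 0")
    pairs: list[TranslationPair] = []
    for cid in range(1, n_concepts + 1):
        if cid <= len(PAPER_PAIRS):
            w1, w2 = PAPER_PAIRS[cid - 1]
        else:
            # deterministic 5-letter words from disjoint alphabets
            idx = [(cid * 7 + p * 3) % 10 for p in range(5)]
            w1 = "".join(_FILLER_L1_LETTERS[i] for i in idx)
            w2 = "".join(_FILLER_L2_LETTERS[(i + cid) % 10] for i in idx)
        pairs.append(TranslationPair(concept_id=cid, word_l1=w1, word_l2=w2))
    return pairs


def validate_stimulus_set(
    pairs: list[TranslationPair], max_overlap: float = 0.0
) -> pd.DataFrame:
    """Per-pair lexical-overlap report.

    Returns a DataFrame with one row per pair (concept_id, word_l1, word_l2,
    normalized_distance, flagged) plus ``mean`` and ``sd`` of the distances
    in ``df.attrs``.  A pair is flagged when its normalized distance falls
    below ``1 - max_overlap``; the default demands distance 1.0 exactly.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    threshold = 1.0 - max_overlap
    rows = []
    for p in pairs:
        d = normalized_levenshtein(p.word_l1, p.word_l2)
        rows.append(
            {
                "concept_id": p.concept_id,
                "word_l1": p.word_l1,
                "word_l2": p.word_l2,
                "normalized_distance": d,
                "flagged": d < threshold - 1e-12,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["mean"] = float(report["normalized_distance"].mean())
    report.attrs["sd"] = float(report["normalized_distance"].std(ddof=0))
    return report


def read_pairs_tsv(path) -> list[TranslationPair]:
    """Read translation pairs from a two/three-column TSV (word_l1, word_l2
    and optionally concept_id)."""
    df = pd.read_csv(path, sep="\t")
    if "concept_id" not in df.columns:
        df = df.assign(concept_id=np.arange(1, len(df) + 1))
    return [
        TranslationPair(int(r.concept_id), str(r.word_l1), str(r.word_l2))
        for r in df.itertuples()
    ]


def write_report_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
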