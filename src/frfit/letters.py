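"""Compact letter displays for pairwise significance structure.

Groups that share no letter differ significantly; groups sharing a
letter do not.  Uses the insert-and-absorb algorithm, which is exact for
the small group counts (2–4) arising here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

LATIN = "abcdefghijklmnopqrstuvwxyz"
GREEK = "αβγδεζηθικλμνξοπρστυφχψω"


def compact_letters(
    labels: Sequence,
    pairwise_p: Mapping[tuple, float],
    alpha: float = 0.05,
    alphabet: str = LATIN,
) -> dict:
    """Assign letters so two groups share a letter iff their pairwise
    p-value is >= alpha.

    ``pairwise_p`` maps unordered label pairs (either order accepted) to
    p-values; missing pairs are treated as non-significant.
    """
    labels = list(labels)

    def pval(x, y) -> float:
        if (x, y) in pairwise_p:
            return pairwise_p[(x, y)]
        if (y, x) in pairwise_p:
            return pairwise_p[(y, x)]
        return 1.0

    # columns: maximal sets of mutually non-different labels
    columns: list[set] = [set(labels)]
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            if pval(gi, gj) >= alpha:
                continue
            split: list[set] = []
            for col in columns:
                if gi in col and gj in col:
                    split.append(col - {gj})
                    split.append(col - {gi})
                else:
                    split.append(col)
            # absorb: keep only maximal, non-duplicate, non-empty sets
            uniq: list[set] = []
            for c in split:
                if c and c not in uniq:
                    uniq.append(c)
            columns = [c for c in uniq if not any(c < o for o in uniq)]

    out = {g: "" for g in labels}
    for k, col in enumerate(columns):
        for g in labels:
            if g in col:
                out[g] += alphabet[k % len(alphabet)]
    return out
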