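"""Independent brute-force oracles used to cross-check the scanners.

These deliberately re-derive matching from first principles (their own
complement table, all-offsets loops) so they share no code path with the
implementation they verify.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_occurrences(sequence: str, variants: tuple[str, ...]):
    """All (start, strand_set) element matches by direct offset-by-offset
    comparison on both strands."""
    length = len(variants[0])
    out = {}
    for i in range(len(sequence) - length + 1):
        window = sequence[i : i + length]
        strands = set()
        for v in variants:
            if window == v:
                strands.add("plus")
            if window == oracle_revcomp(v):
                strands.add("minus")
        if strands:
            out[i] = frozenset(strands)
    return out


def oracle_composites(sequence, variants_a, variants_b, spacer_len, ordered=False):
    """All composite (up_start, down_start, up_is_a) triples by a double
    loop over every occurrence pair."""
    occ_a = oracle_occurrences(sequence, variants_a)
    occ_b = oracle_occurrences(sequence, variants_b)
    len_a, len_b = len(variants_a[0]), len(variants_b[0])
    pairs = set()
    for up_start in occ_a:
        for down_start in occ_b:
            if down_start - (up_start + len_a) == spacer_len:
                pairs.add((up_start, down_start, True))
    if not ordered and variants_a != variants_b:
        for up_start in occ_b:
            for down_start in occ_a:
                if down_start - (up_start + len_b) == spacer_len:
                    pairs.add((up_start, down_start, False))
    return pairs
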