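"""SMAD binding elements and the composite-motif orientation grammar.

SMAD MH1 domains recognise short GC-rich or GTCT-type DNA elements.  Two
MH1 domains can co-occupy a *composite motif* — two elements separated by
a short spacer — and the relative orientation of the two domains follows
from which strand carries each element's +1 guanine:

* the +1 Gua of an element on the **minus** strand of the upstream site
  and of an element on the **plus** strand of the downstream site both
  face the spacer, giving a **back-to-back** arrangement;
* the mirror case (plus upstream, minus downstream) is **face-to-face**;
* two elements on the same strand give **face-to-back**.

BMP-activated SMAD1/5/8 complexes productively engage only the
back-to-back arrangement on a 5-bp spacer; this module encodes that rule
as :func:`predict_responsiveness`.

All element sequences are written 5'→3' with the +1 guanine as the first
base.  Coordinates are 0-based half-open on the plus (reference) strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import FrozenSet, Iterable

from .errors import InputError

__all__ = [
    "Strand",
    "BindingMode",
    "Responsiveness",
    "BindingElement",
    "ElementInstance",
    "CompositeHit",
    "CANONICAL_ELEMENTS",
    "reverse_complement",
    "is_palindromic",
    "element_occurrences",
    "classify_binding_modes",
    "make_composite_hit",
    "predict_responsiveness",
    "load_element_table",
]

# --------------------------------------------------------------------------
# alphabet

IUPAC_CODES = "ACGTRYSWKMBDHVN"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _validate_iupac(seq: str) -> None:
    for i, base in enumerate(seq):
        if base.upper() not in _EXPAND:
            raise InputError(
                f"non-IUPAC character {base!r} at position {i} in sequence {seq!r}"
            )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an IUPAC DNA string.

    Degenerate codes map to their complements (R↔Y, K↔M, S/W/N fixed).
    An involution: ``reverse_complement(reverse_complement(s)) == s``.

    Raises
    ------
    InputError
        If the sequence contains a non-IUPAC character; the message names
        the offending position.
    """
    _validate_iupac(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def expand_degenerate(seq: str) -> tuple[str, ...]:
    """All explicit ACGT strings matching an IUPAC pattern, in product order."""
    _validate_iupac(seq)
    pools = [_EXPAND[b] for b in seq.upper()]
    return tuple("".join(p) for p in itertools.product(*pools))


# --------------------------------------------------------------------------
# enums

class Strand(str, Enum):
    PLUS = "plus"
    MINUS = "minus"


class BindingMode(str, Enum):
    FACE_TO_FACE = "face_to_face"
    FACE_TO_BACK = "face_to_back"
    BACK_TO_BACK = "back_to_back"


class Responsiveness(str, Enum):
    BMP = "BMP_responsive"
    BMP_WEAK = "BMP_responsive_weak"
    TGFB = "TGFB_responsive"
    NONE = "nonresponsive"


def _parse_strands(strands: Iterable) -> FrozenSet[Strand]:
    """Normalise a strand specification; ``"both"`` expands to plus+minus."""
    out: set[Strand] = set()
    for s in strands:
        if isinstance(s, Strand):
            out.add(s)
        elif s == "both":
            out.update({Strand.PLUS, Strand.MINUS})
        else:
            out.add(Strand(s))
    if not out:
        raise InputError("strand set must be nonempty")
    return frozenset(out)


def strands_label(strands: FrozenSet[Strand]) -> str:
    """Human-readable strand label: ``plus``, ``minus`` or ``both``."""
    if strands == frozenset({Strand.PLUS, Strand.MINUS}):
        return "both"
    (only,) = strands
    return only.value


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class BindingElement:
    """A named SMAD recognition sequence, 5'→3', +1 Gua first.

    ``sequence`` may contain IUPAC degenerate codes and/or several
    ``|``-separated alternatives (used for the 5GC family, GGCGC|GGCCG);
    matching always operates on the fully expanded explicit variants.
    """

    id: str
    sequence: str
    plus_one_offset: int = 0

    def __post_init__(self) -> None:
        variants: list[str] = []
        for alt in self.sequence.split("|"):
            variants.extend(expand_degenerate(alt))
        if not variants:
            raise InputError(f"element {self.id}: empty sequence")
        lengths = {len(v) for v in variants}
        if len(lengths) != 1:
            raise InputError(f"element {self.id}: variants differ in length")
        if lengths.pop() < 4:
            raise InputError(f"element {self.id}: sequence shorter than 4 bp")
        object.__setattr__(self, "_variants", tuple(dict.fromkeys(variants)))

    @property
    def variants(self) -> tuple[str, ...]:
        """Explicit ACGT strings this element matches."""
        return self._variants  # type: ignore[attr-defined]

    @property
    def length(self) -> int:
        return len(self.variants[0])


def is_palindromic(element: BindingElement) -> bool:
    """True iff the element equals its own reverse complement.

    For degenerate elements the comparison is between the expanded match
    sets.  Odd-length sequences can never be self-complementary.
    """
    fwd = set(element.variants)
    rev = {reverse_complement(v) for v in fwd}
    return fwd == rev


#: The built-in element table (versioned with the package).
CANONICAL_ELEMENTS: dict[str, BindingElement] = {
    "SBE": BindingElement("SBE", "GTCTG"),
    "pGC_SBE": BindingElement("pGC_SBE", "GGCGCC"),
    "npGC_SBE": BindingElement("npGC_SBE", "GGCTCC"),
    "pSBE": BindingElement("pSBE", "GTCTAGAC"),
    "FIVE_GC": BindingElement("FIVE_GC", "GGCGC|GGCCG"),
}

#: Elements the responsiveness predicate knows about.
_KNOWN_IDS = frozenset(CANONICAL_ELEMENTS)


def load_element_table(path) -> dict[str, BindingElement]:
    """Read user elements from a two-column TSV (id, sequence).

    Returned table contains the canonical elements plus the user entries;
    a user entry may override a canonical id.
    """
    table = dict(CANONICAL_ELEMENTS)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 'id<TAB>sequence'")
            table[parts[0]] = BindingElement(parts[0], parts[1].upper())
    return table


@dataclass(frozen=True)
class ElementInstance:
    """An element occurrence on a reference sequence.

    ``strands`` records on which strand(s) the element reads 5'→3';
    palindromic sites carry both strands in a single instance.
    """

    element_id: str
    start: int
    end: int
    strands: FrozenSet[Strand]

    def __post_init__(self) -> None:
        if not self.strands:
            raise InputError("ElementInstance requires a nonempty strand set")
        if self.end <= self.start:
            raise InputError("ElementInstance requires end > start")

    @property
    def strands_label(self) -> str:
        return strands_label(self.strands)


@dataclass(frozen=True)
class CompositeHit:
    """An ordered (upstream, downstream) pair of element instances.

    ``spacer_seq`` is read from the plus strand between the two elements;
    ``modes`` is the set of achievable MH1 binding arrangements and
    ``label`` the predicted transcriptional responsiveness.
    """

    upstream: ElementInstance
    downstream: ElementInstance
    spacer_seq: str
    spacer_len: int
    modes: FrozenSet[BindingMode]
    label: Responsiveness

    def __post_init__(self) -> None:
        if self.upstream.end > self.downstream.start:
            raise InputError(
                "composite elements overlap: upstream ends at "
                f"{self.upstream.end}, downstream starts at {self.downstream.start}"
            )
        if self.spacer_len != self.downstream.start - self.upstream.end:
            raise InputError("spacer_len inconsistent with element coordinates")
        if self.spacer_len != len(self.spacer_seq):
            raise InputError("spacer_seq length inconsistent with spacer_len")
        if not self.modes:
            raise InputError("CompositeHit requires a nonempty mode set")


# --------------------------------------------------------------------------
# operations

def element_occurrences(sequence: str, element: BindingElement) -> list[ElementInstance]:
    """Exact-match occurrences of an element on both strands.

    The input sequence is expected uppercase; lowercase (soft-masked) and
    non-ACGT bases never match.  A site whose plus-strand bases equal an
    element variant is a plus-strand occurrence; a site equal to the
    reverse complement of a variant is a minus-strand occurrence.
    Palindromic sites are emitted once with both strands set.  Sorted by
    start.
    """
    found: dict[int, set[Strand]] = {}
    for v in element.variants:
        for strand, pattern in ((Strand.PLUS, v), (Strand.MINUS, reverse_complement(v))):
            start = sequence.find(pattern)
            while start != -1:
                found.setdefault(start, set()).add(strand)
                start = sequence.find(pattern, start + 1)
    length = element.length
    return [
        ElementInstance(element.id, s, s + length, frozenset(strands))
        for s, strands in sorted(found.items())
    ]


_MODE_OF_ASSIGNMENT = {
    (Strand.MINUS, Strand.PLUS): BindingMode.BACK_TO_BACK,
    (Strand.PLUS, Strand.MINUS): BindingMode.FACE_TO_FACE,
    (Strand.PLUS, Strand.PLUS): BindingMode.FACE_TO_BACK,
    (Strand.MINUS, Strand.MINUS): BindingMode.FACE_TO_BACK,
}


def classify_binding_modes(
    upstream_strands: Iterable, downstream_strands: Iterable
) -> FrozenSet[BindingMode]:
    """Achievable MH1 binding arrangements for a composite.

    Each strand assignment (one strand per element) contributes one mode:
    upstream-minus with downstream-plus puts both +1 guanines adjacent to
    the spacer on opposing strands (back-to-back); the mirror assignment
    is face-to-face; same-strand assignments are face-to-back.  The
    result is the union over all assignments allowed by the two strand
    sets (``"both"`` expands to plus and minus).
    """
    up = _parse_strands(upstream_strands)
    down = _parse_strands(downstream_strands)
    return frozenset(_MODE_OF_ASSIGNMENT[(u, d)] for u in up for d in down)


def make_composite_hit(
    sequence: str,
    upstream: ElementInstance,
    downstream: ElementInstance,
    strict_labels: bool = False,
) -> CompositeHit:
    """Assemble a :class:`CompositeHit`, computing spacer, modes and label."""
    spacer = sequence[upstream.end : downstream.start]
    modes = classify_binding_modes(upstream.strands, downstream.strands)
    hit = CompositeHit(
        upstream=upstream,
        downstream=downstream,
        spacer_seq=spacer,
        spacer_len=downstream.start - upstream.end,
        modes=modes,
        label=Responsiveness.NONE,
    )
    label = predict_responsiveness(hit, strict=strict_labels)
    object.__setattr__(hit, "label", label)
    return hit


def predict_responsiveness(hit: CompositeHit, strict: bool = True) -> Responsiveness:
    """Predicted transcriptional responsiveness of a composite hit.

    BMP-responsive requires all of: a 5-bp spacer, an achievable
    back-to-back arrangement, and an element pair drawn from
    {pGC_SBE, SBE} containing at least one pGC_SBE.  When the only
    back-to-back route places the (non-palindromic) SBE upstream on the
    minus strand — the fully antisense composite — the call is downgraded
    to weak.  A 5-bp spaced pSBE pair is TGFβ-responsive.  Everything
    else, including npGC_SBE- and 5GC-containing pairs, is labelled
    nonresponsive.

    Parameters
    ----------
    strict
        If true (default) an element id outside the canonical table
        raises :class:`InputError`; if false such pairs are labelled
        nonresponsive (used when scanning user-defined elements).
    """
    up_id = hit.upstream.element_id
    down_id = hit.downstream.element_id
    if up_id not in _KNOWN_IDS or down_id not in _KNOWN_IDS:
        if strict:
            unknown = up_id if up_id not in _KNOWN_IDS else down_id
            raise InputError(f"unknown element id {unknown!r}")
        return Responsiveness.NONE

    pair = {up_id, down_id}
    if hit.spacer_len == 5 and BindingMode.BACK_TO_BACK in hit.modes:
        if pair <= {"pGC_SBE", "SBE"} and "pGC_SBE" in pair:
            # back-to-back needs the upstream element on the minus strand;
            # when that element is the SBE the whole composite is antisense
            if up_id == "SBE":
                return Responsiveness.BMP_WEAK
            return Responsiveness.BMP
    if hit.spacer_len == 5 and pair == {"pSBE"}:
        return Responsiveness.TGFB
    return Responsiveness.NONE
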