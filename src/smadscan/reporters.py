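"""Synthetic luciferase reporter insert design and responsiveness labelling.

Each construct places a cassette of SMAD motifs upstream of a minimal
adenoviral major late promoter (MLP).  The cassette is flanked by the
KpnI site used for cloning and joined to the MLP by a fixed 10-bp
junction carrying overlapping XhoI/BglII sites, so the MLP-proximal
motif always sits exactly 10 bp before the MLP — the geometry of the
reporter series that mapped the 5-bp spacer rule.

The library enumerator regenerates the design space of that series:
a spacing grid for three GC-palindrome motifs, homotypic orientation
sets for the non-palindromic elements, a copy-number ladder, natural
ID-locus linker variants, heterocomposite orientation variants and a
single-nucleotide permutation scan of the GC palindrome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .grammar import (
    CANONICAL_ELEMENTS,
    Responsiveness,
    reverse_complement,
)
from .scanner import canonical_classes, scan_classes

__all__ = [
    "MLP",
    "NAMED_LINKERS",
    "LibraryConfig",
    "ReporterConstruct",
    "gc_poor_spacer",
    "build_insert",
    "enumerate_library",
    "label_library",
    "load_expected_outcomes",
    "consistency_report",
]

#: minimal adenoviral major late promoter used in all constructs.
MLP = "GGGCTATAAAAGGGGGTGGGGGCGCGTTCGTCCTCACTCTCTTCC"

KPNI = "GGTACC"
XHOI = "CTCGAG"
BGLII = "AGATCT"
HINDIII = "AAGCTT"

#: 10-bp cassette->MLP junction: XhoI and BglII sites overlapping by 2 bp.
MLP_JUNCTION = "CTCGAGATCT"
assert XHOI in MLP_JUNCTION and BGLII in MLP_JUNCTION and len(MLP_JUNCTION) == 10

#: natural ID-locus linkers plus the GC-poor control linker.
NAMED_LINKERS = {"ID1": "TGGCT", "ID2": "AGAGA", "ID3": "AGGCT", "CTRL": "AACTT"}

_SPACING_GRID = (2, 3, 4, 5, 6, 10, 20)
_ORIENT_PAIRS = ("FF", "FR", "RF", "RR")


@dataclass(frozen=True)
class ReporterConstruct:
    """One reporter insert: motif cassette + junction + MLP."""

    construct_id: str
    series: str
    motifs: tuple[tuple[str, str], ...]  # (element id or raw sequence, "+"/"-")
    spacers: tuple[str, ...]  # resolved spacer sequences, len = n_motifs - 1
    insert: str
    spacer_to_mlp: int = 10

    @property
    def cassette(self) -> str:
        parts = [_motif_sequence(m, o) for m, o in self.motifs]
        out = [parts[0]]
        for spacer, motif in zip(self.spacers, parts[1:]):
            out.append(spacer)
            out.append(motif)
        return "".join(out)


def _motif_sequence(motif: str, orientation: str) -> str:
    """Resolve a motif spec (element id or raw ACGT) to plus-strand bases."""
    if motif in CANONICAL_ELEMENTS:
        variants = CANONICAL_ELEMENTS[motif].variants
        if len(variants) != 1:
            raise InputError(
                f"degenerate element {motif!r} cannot be placed in a construct; "
                "give an explicit variant"
            )
        seq = variants[0]
    else:
        if not set(motif) <= set("ACGT"):
            raise InputError(f"motif {motif!r} is neither an element id nor ACGT")
        seq = motif
    if orientation == "+":
        return seq
    if orientation == "-":
        return reverse_complement(seq)
    raise InputError(f"orientation must be '+' or '-', got {orientation!r}")


def gc_poor_spacer(length: int, rng: np.random.Generator) -> str:
    """A GC-poor spacer: A/T bases with at most one C, never any G.

    Guanine-free spacers cannot complete any SMAD element across a
    motif/spacer boundary, so spacer choice never changes a construct's
    label.
    """
    if length < 0:
        raise InputError("spacer length must be >= 0")
    bases = list(rng.choice(list("AT"), size=length))
    if length >= 2 and rng.random() < 0.5:
        bases[int(rng.integers(length))] = "C"
    return "".join(bases)


def _construct_rng(construct_id: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(construct_id.encode()) & 0x7FFFFFFF])


def _resolve_spacer(spec, rng: np.random.Generator) -> str:
    if isinstance(spec, (int, np.integer)):
        return gc_poor_spacer(int(spec), rng)
    if isinstance(spec, str):
        if spec in NAMED_LINKERS:
            return NAMED_LINKERS[spec]
        if set(spec) <= set("ACGT"):
            return spec
        raise InputError(f"unknown linker name {spec!r}")
    raise InputError(f"spacer spec must be an int length or a string, got {spec!r}")


def build_insert(
    construct_id: str,
    series: str,
    motifs: Sequence[tuple[str, str]],
    spacers: Sequence,
    seed: int = 0,
    max_len: int = 300,
) -> ReporterConstruct:
    """Deterministically assemble one reporter insert.

    ``motifs`` is an ordered list of (element id or raw sequence,
    orientation) pairs; ``spacers`` gives, between consecutive motifs,
    either a literal/named linker or an integer length for a seeded
    GC-poor spacer.  The insert is KpnI context + cassette + 10-bp
    XhoI/BglII junction + MLP; the MLP appears exactly once and the
    MLP-proximal motif ends exactly 10 bp before it.
    """
    motifs = tuple((str(m), str(o)) for m, o in motifs)
    if not motifs:
        raise InputError("a construct needs at least one motif")
    if len(spacers) != len(motifs) - 1:
        raise InputError("need exactly one spacer between consecutive motifs")
    rng = _construct_rng(construct_id, seed)
    resolved = tuple(_resolve_spacer(s, rng) for s in spacers)
    construct = ReporterConstruct(construct_id, series, motifs, resolved, insert="")
    insert = KPNI + construct.cassette + MLP_JUNCTION + MLP
    if len(insert) > max_len:
        raise InputError(
            f"construct {construct_id}: insert length {len(insert)} exceeds "
            f"synthesis limit {max_len}"
        )
    if insert.count(MLP) != 1:
        raise InputError(f"construct {construct_id}: MLP must occur exactly once")
    return replace(construct, insert=insert)


@dataclass
class LibraryConfig:
    """Which design series to enumerate (all on by default)."""

    spacing_grid: tuple[int, ...] = _SPACING_GRID
    orientation_elements: tuple[str, ...] = ("npGC_SBE", "SBE", "pSBE")
    copy_numbers: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    id_linkers: tuple[str, ...] = ("ID1", "ID2", "ID3", "CTRL")
    hetero_orientations: tuple[str, ...] = ("sense", "sbe_antisense", "full_antisense")
    permutation_positions: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    @classmethod
    def empty(cls) -> "LibraryConfig":
        return cls(
            spacing_grid=(), orientation_elements=(), copy_numbers=(),
            id_linkers=(), hetero_orientations=(), permutation_positions=(),
        )


def enumerate_library(
    config: LibraryConfig | None = None, seed: int = 0
) -> list[ReporterConstruct]:
    """Enumerate the reporter design space; all constructs distinct.

    Series
    ------
    spacing
        Three GC-palindrome motifs with linker a (motif 1-2) and linker
        b (motif 2-3) over the spacing grid.
    orientation
        5-bp spaced homotypic pairs of each non-GC-palindrome element in
        every orientation combination (palindromic elements once).
    copy_number
        One to six GC-palindrome motifs with 5-bp GC-poor spacers.
    id_linker
        GC-palindrome + SBE heterocomposite with each natural ID-locus
        linker and the GC-poor control.
    hetero_orientation
        The heterocomposite in sense, SBE-antisense and full-antisense
        arrangements.
    permutation
        Every single-nucleotide substitution of the GC palindrome within
        the control heterocomposite.
    """
    if config is None:
        config = LibraryConfig()
    out: list[ReporterConstruct] = []
    seen_ids: set[str] = set()
    pgc = "pGC_SBE"

    def add(construct: ReporterConstruct) -> None:
        if construct.construct_id in seen_ids:
            raise InputError(f"duplicate construct id {construct.construct_id}")
        seen_ids.add(construct.construct_id)
        out.append(construct)

    for a in config.spacing_grid:
        for b in config.spacing_grid:
            cid = f"spacing_a{a}_b{b}"
            add(build_insert(cid, "spacing", [(pgc, "+")] * 3, [a, b], seed))

    for el in config.orientation_elements:
        from .grammar import is_palindromic

        pairs = ("FF",) if is_palindromic(CANONICAL_ELEMENTS[el]) else _ORIENT_PAIRS
        for pair in pairs:
            orients = ["+" if c == "F" else "-" for c in pair]
            cid = f"orient_{el}_{pair}"
            add(build_insert(cid, "orientation", list(zip([el, el], orients)), [5], seed))

    for n in config.copy_numbers:
        cid = f"copy_pGC_x{n}"
        add(build_insert(cid, "copy_number", [(pgc, "+")] * n, [5] * (n - 1), seed))

    for name in config.id_linkers:
        cid = f"idlinker_{name}"
        add(build_insert(cid, "id_linker", [(pgc, "+"), ("SBE", "+")], [name], seed))

    hetero_motifs = {
        "sense": [(pgc, "+"), ("SBE", "+")],
        "sbe_antisense": [(pgc, "+"), ("SBE", "-")],
        "full_antisense": [("SBE", "-"), (pgc, "+")],
    }
    # fixed GC-free 5-mer keeps this series distinct from the id_linker
    # series (which already covers the AACTT control in sense orientation)
    for orient in config.hetero_orientations:
        cid = f"hetero_{orient}"
        add(build_insert(cid, "hetero_orientation", hetero_motifs[orient], ["ATTTA"], seed))

    pgc_seq = CANONICAL_ELEMENTS[pgc].variants[0]
    for pos in config.permutation_positions:
        original = pgc_seq[pos - 1]
        for base in "ACGT":
            if base == original:
                continue
            variant = pgc_seq[: pos - 1] + base + pgc_seq[pos:]
            cid = f"perm_p{pos}{base}"
            add(
                build_insert(
                    cid, "permutation", [(variant, "+"), ("SBE", "+")], ["CTRL"], seed
                )
            )

    inserts = [c.insert for c in out]
    if len(set(inserts)) != len(inserts):
        raise InputError("library contains byte-identical inserts")
    return out


_BMP_RANK = {
    Responsiveness.NONE: 0,
    Responsiveness.TGFB: 0,
    Responsiveness.BMP_WEAK: 1,
    Responsiveness.BMP: 2,
}


def label_library(library: Sequence[ReporterConstruct]) -> pd.DataFrame:
    """Predicted BMP and TGFβ labels per construct.

    Each insert is scanned for all canonical 5-bp composite classes; a
    construct is BMP-responsive iff at least one hit is (weak if only a
    weak hit is present), and TGFβ-responsive iff a 5-bp pSBE pair is
    present.
    """
    classes = canonical_classes(spacer_len=5)
    rows = []
    for c in library:
        hits = [h for hit_list in scan_classes(c.insert, classes).values() for h in hit_list]
        best = Responsiveness.NONE
        for h in hits:
            if _BMP_RANK[h.label] > _BMP_RANK[best]:
                best = h.label
        bmp = best if best in (Responsiveness.BMP, Responsiveness.BMP_WEAK) else Responsiveness.NONE
        tgfb = (
            Responsiveness.TGFB
            if any(h.label is Responsiveness.TGFB for h in hits)
            else Responsiveness.NONE
        )
        rows.append(
            {
                "construct_id": c.construct_id,
                "series": c.series,
                "bmp_label": bmp.value,
                "tgfb_label": tgfb.value,
            }
        )
    return pd.DataFrame(rows, columns=["construct_id", "series", "bmp_label", "tgfb_label"])


def load_expected_outcomes() -> pd.DataFrame:
    """The bundled qualitative outcome table for the default library."""
    path = resources.files("smadscan").joinpath("data/reporter_expectations.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def consistency_report(
    labels: pd.DataFrame, expected: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge predicted labels with the expected-outcome fixture.

    Adds boolean ``bmp_match`` / ``tgfb_match`` columns; constructs
    absent from the fixture are dropped from the report.
    """
    if expected is None:
        expected = load_expected_outcomes()
    merged = labels.merge(
        expected[["construct_id", "expected_bmp", "expected_tgfb"]],
        on="construct_id",
        how="inner",
    )
    merged["bmp_match"] = merged["bmp_label"] == merged["expected_bmp"]
    merged["tgfb_match"] = merged["tgfb_label"] == merged["expected_tgfb"]
    return merged
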