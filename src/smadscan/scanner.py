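"""Composite-motif scanning and peak-region screening.

A *composite class* is an element pair plus a fixed spacer length
(e.g. pGC_SBE + SBE with a 5-bp spacer, the "ID-like" heterocomposite).
:func:`scan_composites` enumerates every occurrence of a class in one
sequence; :func:`screen_regions` applies a set of classes to a peak-region
collection and reports, per class, how many regions carry at least one
occurrence — the screening used to ask how common composite motifs are
among transcription-factor-bound regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError
from .grammar import (
    CANONICAL_ELEMENTS,
    BindingElement,
    CompositeHit,
    element_occurrences,
    make_composite_hit,
)

__all__ = [
    "CompositeClass",
    "RegionRecord",
    "ScreenSummary",
    "canonical_classes",
    "scan_composites",
    "scan_classes",
    "screen_regions",
    "summarize_screen",
    "hits_table",
]

#: element ids used in the default genome screening (the four
#: non-degenerate canonical elements).
SCREEN_ELEMENT_IDS = ("SBE", "pGC_SBE", "npGC_SBE", "pSBE")


@dataclass(frozen=True)
class CompositeClass:
    """An element pair at a fixed spacer length.

    ``ordered=False`` (default) counts both A-spacer-B and B-spacer-A
    arrangements, matching detection of e.g. CAGAC-N5-GGCGCC loci.
    """

    element_a: BindingElement
    element_b: BindingElement
    spacer_len: int = 5
    ordered: bool = False

    def __post_init__(self) -> None:
        if self.spacer_len < 0:
            raise InputError("spacer_len must be >= 0")

    @property
    def class_id(self) -> str:
        ids = [self.element_a.id, self.element_b.id]
        if not self.ordered:
            ids = sorted(ids)
        return f"{ids[0]}+{ids[1]}/{self.spacer_len}"


def canonical_classes(spacer_len: int = 5, ordered: bool = False) -> list[CompositeClass]:
    """All homo- and heterocomposite classes over the four core elements."""
    out = []
    ids = SCREEN_ELEMENT_IDS
    for i, a in enumerate(ids):
        for b in ids[i:]:
            out.append(
                CompositeClass(
                    CANONICAL_ELEMENTS[a], CANONICAL_ELEMENTS[b], spacer_len, ordered
                )
            )
    return out


def scan_composites(
    sequence: str,
    element_a: BindingElement,
    element_b: BindingElement,
    spacer_len: int,
    ordered: bool = False,
) -> list[CompositeHit]:
    """All composite occurrences of an element pair at an exact spacer.

    Every upstream instance of one element paired with a downstream
    instance of the other (or the same, for homocomposites) whose gap on
    the plus strand equals ``spacer_len``.  Unordered scanning considers
    both element orders.  Hits are deduplicated by (upstream start,
    downstream start, element pair) and sorted by upstream start.
    """
    if spacer_len < 0:
        raise InputError("spacer_len must be >= 0")
    occ_a = element_occurrences(sequence, element_a)
    occ_b = occ_a if element_b.id == element_a.id else element_occurrences(sequence, element_b)

    orders = [(occ_a, occ_b)]
    if not ordered and element_b.id != element_a.id:
        orders.append((occ_b, occ_a))

    seen: set[tuple[int, int, str, str]] = set()
    hits: list[CompositeHit] = []
    for ups, downs in orders:
        by_start = {inst.start: inst for inst in downs}
        for up in ups:
            down = by_start.get(up.end + spacer_len)
            if down is None:
                continue
            key = (up.start, down.start, up.element_id, down.element_id)
            if key in seen:
                continue
            seen.add(key)
            hits.append(make_composite_hit(sequence, up, down, strict_labels=False))
    hits.sort(key=lambda h: (h.upstream.start, h.downstream.start))
    return hits


def scan_classes(
    sequence: str, classes: Sequence[CompositeClass]
) -> dict[str, list[CompositeHit]]:
    """Scan one sequence for every class; mapping class_id -> hits."""
    return {
        c.class_id: scan_composites(
            sequence, c.element_a, c.element_b, c.spacer_len, c.ordered
        )
        for c in classes
    }


@dataclass
class RegionRecord:
    """One screened peak region with its per-class composite hits."""

    region_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    hits: dict[str, list[CompositeHit]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(f"region {self.region_id}: end must exceed start")

    @property
    def positive_classes(self) -> set[str]:
        return {cid for cid, hits in self.hits.items() if hits}


@dataclass
class ScreenSummary:
    """Aggregate composite positivity over one region set.

    ``class_counts`` has one row per composite class (class_id,
    n_positive_regions, n_total_regions, fraction_positive); fractions
    are NA when the region set is empty.  ``per_region`` is the long
    table (region_id, class_id, n_hits, positive).  ``excluded`` lists
    (region_id, reason) pairs for regions that could not be screened.
    """

    class_counts: pd.DataFrame
    per_region: pd.DataFrame
    regions: list[RegionRecord]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_total_regions(self) -> int:
        return len(self.regions)


def _resolve_sequence(region, sequences: Mapping[str, str]) -> str:
    """Region sequence from a genome (chrom slice) or per-region FASTA."""
    name = getattr(region, "name", None) or f"{region.chrom}:{region.start}-{region.end}"
    if region.chrom in sequences:
        chrom_seq = sequences[region.chrom]
        if region.end > len(chrom_seq) or region.start < 0:
            raise InputError(
                f"region {name} outside bounds of {region.chrom} "
                f"(length {len(chrom_seq)})"
            )
        return chrom_seq[region.start : region.end]
    if name in sequences:
        return sequences[name]
    raise InputError(f"no sequence for region {name} (chromosome {region.chrom})")


def _apply_mask_policy(seq: str, mask_policy: str) -> str:
    """``upper``: match soft-masked bases; ``exclude``: never match them."""
    if mask_policy == "upper":
        return seq.upper()
    if mask_policy == "exclude":
        return "".join(b if b.isupper() else "n" for b in seq)
    raise InputError(f"unknown mask policy {mask_policy!r}")


def screen_regions(
    regions: Sequence,
    sequences: Mapping[str, str],
    classes: Sequence[CompositeClass] | None = None,
    mask_policy: str = "upper",
) -> ScreenSummary:
    """Screen a peak-region set for composite positivity per class.

    A region is positive for a class iff it carries at least one hit of
    that class.  Regions whose coordinates fall outside the supplied
    sequences are excluded and listed in ``ScreenSummary.excluded``.
    Deterministic given inputs.

    Parameters
    ----------
    regions
        Objects with ``chrom``, ``start``, ``end`` and optional ``name``
        attributes (e.g. from :func:`smadscan.io.read_bed`).
    sequences
        Either chromosome sequences keyed by chrom, or per-region
        sequences keyed by region name.
    classes
        Composite classes to screen; defaults to the ten canonical
        5-bp spaced homo-/heterocomposite classes.
    """
    if classes is None:
        classes = canonical_classes()
    class_ids = [c.class_id for c in classes]
    if len(set(class_ids)) != len(class_ids):
        raise InputError("duplicate composite class ids")

    records: list[RegionRecord] = []
    excluded: list[tuple[str, str]] = []
    for region in regions:
        name = getattr(region, "name", None) or f"{region.chrom}:{region.start}-{region.end}"
        try:
            seq = _apply_mask_policy(_resolve_sequence(region, sequences), mask_policy)
        except InputError as exc:
            excluded.append((name, str(exc)))
            continue
        rec = RegionRecord(name, region.chrom, region.start, region.end, seq)
        rec.hits = scan_classes(seq, classes)
        records.append(rec)

    long_rows = [
        {
            "region_id": rec.region_id,
            "class_id": cid,
            "n_hits": len(rec.hits.get(cid, [])),
            "positive": bool(rec.hits.get(cid)),
        }
        for rec in records
        for cid in class_ids
    ]
    per_region = pd.DataFrame(
        long_rows, columns=["region_id", "class_id", "n_hits", "positive"]
    )

    n_total = len(records)
    count_rows = []
    for cid in class_ids:
        n_pos = sum(1 for rec in records if rec.hits.get(cid))
        count_rows.append(
            {
                "class_id": cid,
                "n_positive_regions": n_pos,
                "n_total_regions": n_total,
                "fraction_positive": (n_pos / n_total) if n_total else float("nan"),
            }
        )
    class_counts = pd.DataFrame(
        count_rows,
        columns=[
            "class_id",
            "n_positive_regions",
            "n_total_regions",
            "fraction_positive",
        ],
    )
    return ScreenSummary(class_counts, per_region, records, excluded)


def summarize_screen(summaries: Mapping[str, ScreenSummary]) -> pd.DataFrame:
    """Tidy multi-dataset table (dataset, class_id, n_positive, n_total,
    fraction) with one ``total`` row per dataset summing over classes."""
    if not summaries:
        raise InputError("at least one summary required")
    if len(set(summaries)) != len(list(summaries)):  # pragma: no cover - dict keys unique
        raise InputError("duplicate dataset ids")
    rows = []
    for dataset, summary in summaries.items():
        for _, r in summary.class_counts.iterrows():
            rows.append(
                {
                    "dataset": dataset,
                    "class_id": r["class_id"],
                    "n_positive": int(r["n_positive_regions"]),
                    "n_total": int(r["n_total_regions"]),
                    "fraction": r["fraction_positive"],
                }
            )
        n_total = summary.n_total_regions
        n_pos_sum = int(summary.class_counts["n_positive_regions"].sum())
        rows.append(
            {
                "dataset": dataset,
                "class_id": "total",
                "n_positive": n_pos_sum,
                "n_total": n_total,
                "fraction": (n_pos_sum / n_total) if n_total else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["dataset", "class_id", "n_positive", "n_total", "fraction"])


def hits_table(summary: ScreenSummary) -> pd.DataFrame:
    """Flat per-hit table with region-relative and absolute coordinates."""
    rows = []
    for rec in summary.regions:
        for cid, hits in rec.hits.items():
            for h in hits:
                rows.append(
                    {
                        "region_id": rec.region_id,
                        "class_id": cid,
                        "up_element": h.upstream.element_id,
                        "up_start": h.upstream.start,
                        "up_end": h.upstream.end,
                        "up_abs_start": rec.start + h.upstream.start,
                        "down_element": h.downstream.element_id,
                        "down_start": h.downstream.start,
                        "down_end": h.downstream.end,
                        "down_abs_start": rec.start + h.downstream.start,
                        "strand_assignments": (
                            f"{h.upstream.strands_label}/{h.downstream.strands_label}"
                        ),
                        "spacer_seq": h.spacer_seq,
                        "modes": ",".join(sorted(m.value for m in h.modes)),
                        "label": h.label.value,
                    }
                )
    columns = [
        "region_id", "class_id", "up_element", "up_start", "up_end",
        "up_abs_start", "down_element", "down_start", "down_end",
        "down_abs_start", "strand_assignments", "spacer_seq", "modes", "label",
    ]
    return pd.DataFrame(rows, columns=columns)
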