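"""Functional genomic classification of regions and abundance-normalised
class distributions.

Composite-positive peak regions are assigned to promoter / UTR / exon /
intron / intergenic classes by their midpoint, and the per-class share
of positives is divided by each class's genomic abundance so that a
class covering half the genome is not trivially "enriched".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import InputError

__all__ = [
    "AnnotationModel",
    "DEFAULT_PRECEDENCE",
    "classify_region",
    "normalized_distribution",
    "annotation_from_gff",
]

#: tie-break order for overlapping annotation classes.
DEFAULT_PRECEDENCE = ("promoter", "utr", "exon", "intron", "intergenic")

#: HOMER-like promoter window around the TSS (upstream, downstream), bp.
DEFAULT_PROMOTER_WINDOW = (-1000, 100)


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


@dataclass
class AnnotationModel:
    """Interval sets per functional class plus their genomic shares.

    Built from a BED-with-class file (chrom, start, end, class) and an
    optional TSS BED from which strand-aware promoter windows are
    derived.  ``class_genomic_share`` is the fraction of the genome
    covered by each class after applying precedence (a base counts for
    its highest-precedence class only); the remainder is intergenic.
    """

    trees: dict[str, dict[str, IntervalTree]]
    class_genomic_share: dict[str, float]
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int, str]],
        chrom_sizes: Mapping[str, int],
        tss: Iterable[tuple[str, int, str]] = (),
        promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
        precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    ) -> "AnnotationModel":
        """Build a model from class intervals and optional TSS positions.

        Parameters
        ----------
        intervals
            (chrom, start, end, class) records; class names must appear
            in ``precedence``.
        tss
            (chrom, position, strand) records; each contributes a
            promoter interval ``position + window`` oriented by strand.
        """
        precedence = tuple(precedence)
        if "intergenic" not in precedence:
            precedence = precedence + ("intergenic",)
        trees: dict[str, dict[str, IntervalTree]] = {c: {} for c in precedence}

        def _add(cls_name: str, chrom: str, start: int, end: int) -> None:
            if cls_name not in trees:
                raise InputError(
                    f"annotation class {cls_name!r} not in precedence {precedence}"
                )
            if end <= start:
                raise InputError(
                    f"empty annotation interval {chrom}:{start}-{end} ({cls_name})"
                )
            trees[cls_name].setdefault(chrom, IntervalTree()).addi(start, end)

        up, down = promoter_window
        for chrom, pos, strand in tss:
            if strand == "-":
                start, end = pos - down, pos - up
            else:
                start, end = pos + up, pos + down
            size = chrom_sizes.get(chrom)
            start = max(0, start)
            if size is not None:
                end = min(size, end)
            if end > start:
                _add("promoter", chrom, start, end)

        for chrom, start, end, cls_name in intervals:
            _add(cls_name, chrom, start, end)

        shares = _genomic_shares(trees, dict(chrom_sizes), precedence)
        return cls(trees, shares, precedence, dict(chrom_sizes))


def _genomic_shares(
    trees: dict[str, dict[str, IntervalTree]],
    chrom_sizes: dict[str, int],
    precedence: tuple[str, ...],
) -> dict[str, float]:
    """Per-class genome fraction with precedence masking.

    A base covered by several classes is attributed to the highest-
    precedence one; bases covered by nothing are intergenic.
    """
    genome = sum(chrom_sizes.values())
    if genome <= 0:
        raise InputError("chromosome sizes must sum to a positive genome length")
    shares = {c: 0.0 for c in precedence}
    for chrom, size in chrom_sizes.items():
        claimed: list[tuple[int, int]] = []
        for cls_name in precedence:
            if cls_name == "intergenic":
                continue
            tree = trees.get(cls_name, {}).get(chrom)
            if tree is None:
                continue
            own = [(max(0, iv.begin), min(size, iv.end)) for iv in tree]
            own = [(s, e) for s, e in own if e > s]
            # bp newly claimed by this class = its coverage not already taken
            newly = _merged_length(claimed + own) - _merged_length(claimed)
            shares[cls_name] += newly
            claimed = claimed + own
    assigned = sum(v for c, v in shares.items() if c != "intergenic")
    shares = {c: v / genome for c, v in shares.items()}
    shares["intergenic"] = max(0.0, (genome - assigned) / genome)
    return shares


def annotation_from_gff(
    path,
) -> tuple[list[tuple[str, int, int, str]], list[tuple[str, int, str]]]:
    """Convenience converter: GFF3 genes -> class intervals + TSS list.

    Exons and UTRs map to their classes; gaps between a gene's merged
    exons become introns.  Returns (intervals, tss) suitable for
    :meth:`AnnotationModel.from_intervals`.  GFF coordinates (1-based
    closed) are converted to BED conventions.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    intervals: list[tuple[str, int, int, str]] = []
    tss: list[tuple[str, int, str]] = []
    utr_types = ("five_prime_UTR", "three_prime_UTR", "UTR")
    for ft in utr_types:
        for f in db.features_of_type(ft):
            intervals.append((f.seqid, f.start - 1, f.end, "utr"))
    for gene in db.features_of_type("gene"):
        strand = gene.strand if gene.strand in ("+", "-") else "+"
        tss_pos = (gene.start - 1) if strand == "+" else gene.end
        tss.append((gene.seqid, tss_pos, strand))
        exons = []
        for ex in db.children(gene, featuretype="exon"):
            exons.append((ex.start - 1, ex.end))
            intervals.append((ex.seqid, ex.start - 1, ex.end, "exon"))
        # introns = gene body between consecutive merged exons
        merged: list[tuple[int, int]] = []
        for s, e in sorted(exons):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for (_, left_end), (right_start, _) in zip(merged, merged[1:]):
            if right_start > left_end:
                intervals.append((gene.seqid, left_end, right_start, "intron"))
        if not merged:
            intervals.append((gene.seqid, gene.start - 1, gene.end, "intron"))
    return intervals, tss


def classify_region(region, model: AnnotationModel, by: str = "midpoint") -> str:
    """Functional class of a region.

    Default HOMER-like convention: the class of the interval containing
    the region midpoint, ties broken by precedence
    (promoter > utr > exon > intron > intergenic).  ``by="overlap"``
    instead returns the highest-precedence class overlapping any part of
    the region.
    """
    chrom = region.chrom
    known = chrom in model.chrom_sizes or any(
        chrom in per_chrom for per_chrom in model.trees.values()
    )
    if not known:
        raise InputError(f"unknown chromosome {chrom!r}")
    if by == "midpoint":
        point = (region.start + region.end) // 2
        for cls_name in model.precedence:
            tree = model.trees.get(cls_name, {}).get(chrom)
            if tree is not None and tree.overlaps_point(point):
                return cls_name
        return "intergenic"
    if by == "overlap":
        for cls_name in model.precedence:
            tree = model.trees.get(cls_name, {}).get(chrom)
            if tree is not None and tree.overlap(region.start, region.end):
                return cls_name
        return "intergenic"
    raise InputError(f"unknown classification policy {by!r}")


def normalized_distribution(
    positive_regions: Sequence, model: AnnotationModel, by: str = "midpoint"
) -> pd.DataFrame:
    """Class distribution of positive regions, normalised by genomic share.

    Columns: class, n, raw_pct (share of positives, sums to 100),
    genomic_share (fraction of genome), enrichment (raw fraction divided
    by genomic share; 1.0 means proportional representation) and
    normalized_pct (enrichments rescaled to sum to 100 for plotting).
    """
    if not positive_regions:
        raise InputError("at least one positive region required")
    counts: dict[str, int] = {}
    for region in positive_regions:
        cls_name = classify_region(region, model, by=by)
        counts[cls_name] = counts.get(cls_name, 0) + 1
    n_total = sum(counts.values())

    rows = []
    for cls_name in model.precedence:
        n = counts.get(cls_name, 0)
        if n == 0:
            continue
        share = model.class_genomic_share.get(cls_name, 0.0)
        if share <= 0:
            raise InputError(
                f"class {cls_name!r} has positive regions but zero genomic share"
            )
        raw_frac = n / n_total
        rows.append(
            {
                "class": cls_name,
                "n": n,
                "raw_pct": 100.0 * raw_frac,
                "genomic_share": share,
                "enrichment": raw_frac / share,
            }
        )
    df = pd.DataFrame(rows)
    df["normalized_pct"] = 100.0 * df["enrichment"] / df["enrichment"].sum()
    return df
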