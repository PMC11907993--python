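"""Synthetic fixtures: peak sets with planted composites, linker samples
and noisy binding curves.

The generators emulate the statistical regime the screening analysis
assumes: peak regions of ChIP-seq-like length (default 300 bp) at
human-like GC content (default 0.41) in which exact composite motifs are
rare, with composites planted at a controlled per-region rate and a
truth table recording every plant.  Backgrounds are rejection-sampled to
contain no composite of any screened class, so scanner positivity on a
planted set must equal the truth table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, StageError
from .grammar import reverse_complement
from .hill import BindingCurve, hill_model
from .scanner import CompositeClass, canonical_classes, scan_classes

__all__ = [
    "SyntheticPeakSet",
    "generate_background",
    "plant_composites",
    "sample_linkers",
    "simulate_binding_curve",
]

_BASES = np.array(list("ACGT"))


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    name: str


@dataclass
class SyntheticPeakSet:
    """A synthetic genome + peak set with a plant truth table.

    Each region occupies its own synthetic chromosome (named after the
    region), so BED coordinates are region-relative and trivially valid.
    ``truth`` has one row per planted composite: region_id, class_id,
    offset (plus-strand start of the upstream element), spacer_seq and
    strand ('+' for a sense plant, '-' for a reverse-complemented one).
    """

    sequences: dict[str, str]
    peaks: list[Region]
    truth: pd.DataFrame
    params: dict = field(default_factory=dict)

    def copy(self) -> "SyntheticPeakSet":
        return SyntheticPeakSet(
            dict(self.sequences),
            [replace(r) for r in self.peaks],
            self.truth.copy(),
            dict(self.params),
        )


_TRUTH_COLUMNS = ["region_id", "class_id", "offset", "spacer_seq", "strand"]


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=_TRUTH_COLUMNS)


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def generate_background(
    n_regions: int,
    length: int | tuple[int, int] = 300,
    gc_content: float = 0.41,
    seed: int = 0,
    classes: Sequence[CompositeClass] | None = None,
    max_attempts: int = 10_000,
) -> SyntheticPeakSet:
    """Composite-free background peak set.

    Region sequences are i.i.d. bases with P(G)=P(C)=gc/2, rejection-
    sampled until they contain no occurrence of any screened composite
    class; planting truth on top of such a background is therefore
    exact.  Byte-identical output for identical parameters and seed.

    Parameters
    ----------
    length
        Fixed region length or an inclusive (min, max) range sampled
        uniformly per region.  Must be >= 50 bp.
    """
    if not 0 < gc_content < 1:
        raise InputError("gc_content must be in (0, 1)")
    lo, hi = (length, length) if isinstance(length, int) else length
    if lo < 50:
        raise InputError("region length must be >= 50 bp")
    if classes is None:
        classes = canonical_classes()
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    peaks: list[Region] = []
    for i in range(n_regions):
        region_id = f"region_{i:05d}"
        L = int(rng.integers(lo, hi + 1))
        for attempt in range(max_attempts):
            seq = _random_sequence(L, gc_content, rng)
            if not any(hits for hits in scan_classes(seq, classes).values()):
                break
        else:
            raise StageError(
                f"background: no composite-free sequence found for {region_id} "
                f"after {max_attempts} attempts (gc={gc_content})"
            )
        sequences[region_id] = seq
        peaks.append(Region(region_id, 0, L, region_id))
    params = {
        "n_regions": n_regions,
        "length": (lo, hi),
        "gc_content": gc_content,
        "seed": seed,
        "classes": [c.class_id for c in classes],
    }
    return SyntheticPeakSet(sequences, peaks, _empty_truth(), params)


def plant_composites(
    peakset: SyntheticPeakSet,
    composite_class: CompositeClass,
    rate: float | None = None,
    count: int | None = None,
    linker_sampler: Callable[[np.random.Generator], str] | None = None,
    minus_strand_fraction: float = 0.0,
    seed: int = 0,
    classes: Sequence[CompositeClass] | None = None,
    max_attempts: int = 100,
) -> SyntheticPeakSet:
    """Plant one composite into a deterministic number of regions.

    ``count = round(rate * n_regions)`` regions are chosen without
    replacement; each receives one composite (element A + linker +
    element B) written over its sequence at a uniform-random valid
    offset, optionally as the reverse complement of the whole cassette.
    After writing, the region is re-scanned: the plant must be the only
    composite occurrence of any screened class, otherwise a new offset
    and linker are drawn.  The truth table gains one row per plant.
    Regions too short for the composite are skipped with a note.
    """
    if (rate is None) == (count is None):
        raise InputError("give exactly one of rate or count")
    n = len(peakset.peaks)
    if rate is not None:
        if not 0 <= rate <= 1:
            raise InputError("rate must be in [0, 1]")
        count = int(round(rate * n))
    assert count is not None
    if count > n:
        raise InputError(f"cannot plant into {count} of {n} regions")
    if classes is None:
        classes = canonical_classes(composite_class.spacer_len)
    if composite_class.class_id not in {c.class_id for c in classes}:
        classes = list(classes) + [composite_class]

    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(n, size=count, replace=False).tolist())
    out = peakset.copy()
    seq_a = composite_class.element_a.variants[0]
    seq_b = composite_class.element_b.variants[0]
    spacer_len = composite_class.spacer_len
    cassette_len = len(seq_a) + spacer_len + len(seq_b)

    new_rows = []
    skipped: list[str] = []
    for idx in chosen:
        region = out.peaks[idx]
        seq = out.sequences[region.name]
        L = len(seq)
        if L < cassette_len:
            skipped.append(region.name)
            continue
        minus = bool(rng.random() < minus_strand_fraction)
        prior = set(
            out.truth.loc[out.truth["region_id"] == region.name, "class_id"]
        )
        allowed = prior | {composite_class.class_id}
        planted = None
        for attempt in range(max_attempts):
            if linker_sampler is not None:
                linker = linker_sampler(rng)
            else:
                linker = "".join(rng.choice(_BASES, size=spacer_len))
            if len(linker) != spacer_len:
                raise InputError(
                    f"linker sampler returned length {len(linker)}, "
                    f"expected {spacer_len}"
                )
            cassette = seq_a + linker + seq_b
            if minus:
                cassette = reverse_complement(cassette)
            offset = int(rng.integers(0, L - cassette_len + 1))
            candidate = seq[:offset] + cassette + seq[offset + cassette_len :]
            hits_by_class = scan_classes(candidate, classes)
            present = {cid for cid, hits in hits_by_class.items() if hits}
            own = hits_by_class.get(composite_class.class_id, [])
            # exactness: the plant is detected at its offset, every prior
            # plant in this region survives, and no other class appears
            if present == allowed and any(h.upstream.start == offset for h in own):
                planted = (candidate, offset, linker)
                break
        if planted is None:
            raise StageError(
                f"planting failed in {region.name} after {max_attempts} attempts"
            )
        candidate, offset, linker = planted
        out.sequences[region.name] = candidate
        new_rows.append(
            {
                "region_id": region.name,
                "class_id": composite_class.class_id,
                "offset": offset,
                "spacer_seq": linker,
                "strand": "-" if minus else "+",
            }
        )
    out.truth = pd.concat(
        [out.truth, pd.DataFrame(new_rows, columns=_TRUTH_COLUMNS)],
        ignore_index=True,
    )
    plants = list(out.params.get("plants", []))
    plants.append(
        {
            "class": composite_class.class_id,
            "count": count,
            "seed": seed,
            "skipped_too_short": skipped,
        }
    )
    out.params["plants"] = plants
    return out


def sample_linkers(
    n: int,
    g_boost_positions: Sequence[int] = (2, 3),
    g_prob: float = 0.6,
    length: int = 5,
    seed: int = 0,
) -> list[str]:
    """Random linkers with elevated guanine at chosen 1-based positions.

    Non-boosted positions are uniform over ACGT; at boosted positions
    P(G)=``g_prob`` and the other bases share the remainder equally.
    """
    if not set(g_boost_positions) <= set(range(1, length + 1)):
        raise InputError(f"boost positions must lie in 1..{length}")
    if not 0.25 < g_prob <= 1.0:
        raise InputError("g_prob must be in (0.25, 1]")
    rng = np.random.default_rng(seed)
    boosted = set(g_boost_positions)
    uniform = np.full(4, 0.25)
    boosted_p = np.array([(1 - g_prob) / 3] * 4)
    boosted_p[2] = g_prob  # index 2 = G in ACGT order
    out = []
    for _ in range(n):
        bases = [
            rng.choice(_BASES, p=boosted_p if (pos + 1) in boosted else uniform)
            for pos in range(length)
        ]
        out.append("".join(bases))
    return out


def simulate_binding_curve(
    bmax: float,
    kd: float,
    h: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    units: str = "nM",
) -> BindingCurve:
    """Hill-model responses with Gaussian noise, clipped to [0, 1]."""
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(concentrations, dtype=float)
    xs, ys, reps = [], [], []
    for r in range(replicates):
        y = hill_model(X, bmax, kd, h)
        if noise_sd > 0:
            y = np.clip(y + rng.normal(0.0, noise_sd, size=len(X)), 0.0, 1.0)
        xs.append(X)
        ys.append(y)
        reps.append(np.full(len(X), r))
    return BindingCurve(
        np.concatenate(xs), np.concatenate(ys), units=units,
        replicate=np.concatenate(reps),
    )
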