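"""Standard-format readers/writers, run manifests and the umbrella pipeline.

All tabular outputs are TSV with a header row and trailing newline;
configs and manifests are JSON.  Coordinates follow BED conventions
(0-based half-open) throughout.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import InputError, StageError
from .grammar import IUPAC_CODES, load_element_table
from .linkers import build_frequency_matrix, extract_linkers, profile_table
from .scanner import (
    CompositeClass,
    canonical_classes,
    hits_table,
    screen_regions,
)

__all__ = [
    "Region",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_tsv",
    "run_manifest",
    "run_pipeline",
]

_IUPAC_SET = set(IUPAC_CODES)


@dataclass(frozen=True)
class Region:
    """A BED interval; ``name`` doubles as the region id."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(
                f"region {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if not self.name:
            object.__setattr__(self, "name", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path) -> dict[str, str]:
    """FASTA -> uppercase sequences keyed by the first header token.

    Rejects empty files, duplicate ids and non-IUPAC characters (the
    error names the record and in-record position).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise InputError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        for i, base in enumerate(seq):
            if base not in _IUPAC_SET:
                raise InputError(
                    f"{path}: record {record.id!r}: non-IUPAC character "
                    f"{base!r} at position {i}"
                )
        sequences[record.id] = seq
    if not sequences:
        raise InputError(f"{path}: empty or malformed FASTA")
    return sequences


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path) -> list[Region]:
    """BED3+ -> validated, sorted region list.

    The 4th column, when present, becomes the region id; otherwise
    ``chrom:start-end``.  Malformed coordinates are reported with their
    line number.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: non-integer coordinates {parts[1]!r}/{parts[2]!r}"
                ) from None
            if end <= start:
                raise InputError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            if start < 0:
                raise InputError(f"{path}:{lineno}: negative start {start}")
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else ""
            regions.append(Region(chrom, start, end, name))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def write_bed(path, regions: Sequence[Region]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    """TSV with header, stable column order, trailing newline."""
    df.to_csv(path, sep="\t", index=False)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_manifest(
    command: str, params: Mapping, inputs: Sequence, seed: int | None = None
) -> dict:
    """Reproducibility manifest: command, parameters, input checksums."""
    return {
        "command": command,
        "version": __version__,
        "seed": seed,
        "parameters": dict(params),
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_classes(config: Mapping) -> list[CompositeClass]:
    spacer = int(config.get("spacer", 5))
    ordered = bool(config.get("ordered", False))
    table = (
        load_element_table(config["elements"])
        if config.get("elements")
        else None
    )
    if "classes" in config and config["classes"]:
        from .grammar import CANONICAL_ELEMENTS

        registry = table or CANONICAL_ELEMENTS
        out = []
        for pair in config["classes"]:
            a, b = pair.split("+")
            if a not in registry or b not in registry:
                raise InputError(f"unknown element in class {pair!r}")
            out.append(CompositeClass(registry[a], registry[b], spacer, ordered))
        return out
    return canonical_classes(spacer, ordered)


def run_pipeline(config: Mapping, out_dir, seed: int = 0) -> dict[str, str]:
    """screen -> linker profile -> annotation, with a run manifest.

    ``config`` keys: ``genome_fasta`` (genome or per-region FASTA),
    ``peaks_bed``; optional ``spacer``, ``classes`` (list of "A+B"
    pairs), ``elements`` (user element TSV), ``mask_policy``,
    ``annotation`` (dict with class_bed, tss_bed, chrom_sizes).
    Returns a mapping of output names to written paths; any stage
    failure raises :class:`StageError` tagged with the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    try:
        sequences = read_fasta(config["genome_fasta"])
        regions = read_bed(config["peaks_bed"])
        classes = _load_classes(config)
    except (KeyError, OSError, InputError) as exc:
        raise StageError(f"[inputs] {exc}") from exc

    try:
        summary = screen_regions(
            regions, sequences, classes, config.get("mask_policy", "upper")
        )
        hits = hits_table(summary)
        write_tsv(summary.class_counts, out_dir / "screen_summary.tsv")
        write_tsv(summary.per_region, out_dir / "screen_per_region.tsv")
        write_tsv(hits, out_dir / "hits.tsv")
        outputs["screen_summary"] = str(out_dir / "screen_summary.tsv")
        outputs["screen_per_region"] = str(out_dir / "screen_per_region.tsv")
        outputs["hits"] = str(out_dir / "hits.tsv")
    except (InputError, StageError) as exc:
        raise StageError(f"[screen] {exc}") from exc

    try:
        all_hits = [
            h
            for rec in summary.regions
            for hit_list in rec.hits.values()
            for h in hit_list
        ]
        if all_hits:
            linkers = extract_linkers(all_hits)
            profile = build_frequency_matrix(linkers)
            write_tsv(profile_table(profile), out_dir / "linker_profile.tsv")
            outputs["linker_profile"] = str(out_dir / "linker_profile.tsv")
    except InputError as exc:
        raise StageError(f"[linker_profile] {exc}") from exc

    ann_cfg = config.get("annotation")
    if ann_cfg:
        try:
            from .annotate import AnnotationModel, normalized_distribution

            class_rows = []
            for r in read_bed(ann_cfg["class_bed"]):
                class_rows.append((r.chrom, r.start, r.end, r.name))
            tss_rows = []
            if ann_cfg.get("tss_bed"):
                for r in read_bed(ann_cfg["tss_bed"]):
                    tss_rows.append((r.chrom, r.start, "+"))
            chrom_sizes = {}
            with open(ann_cfg["chrom_sizes"]) as fh:
                for line in fh:
                    if line.strip():
                        chrom, size = line.split("\t")[:2]
                        chrom_sizes[chrom] = int(size)
            model = AnnotationModel.from_intervals(class_rows, chrom_sizes, tss_rows)
            positives = [
                rec for rec in summary.regions if rec.positive_classes
            ]
            if positives:
                dist = normalized_distribution(positives, model)
                write_tsv(dist, out_dir / "annotation_distribution.tsv")
                outputs["annotation_distribution"] = str(
                    out_dir / "annotation_distribution.tsv"
                )
        except (KeyError, OSError, InputError) as exc:
            raise StageError(f"[annotation] {exc}") from exc

    manifest = run_manifest(
        "pipeline",
        {k: v for k, v in config.items() if k != "annotation"},
        [config.get("genome_fasta", ""), config.get("peaks_bed", "")],
        seed=seed,
    )
    write_json(manifest, out_dir / "manifest.json")
    outputs["manifest"] = str(out_dir / "manifest.json")
    return outputs
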