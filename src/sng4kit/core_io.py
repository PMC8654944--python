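"""Data model and plain-text readers/writers.

All coordinates are 0-based half-open (BED convention). Fragment files follow
the 10X ``fragments.tsv`` layout: five tab-separated columns —
chrom, start, end, barcode, read_support — with ``#`` comment lines allowed.
Gzip input is accepted transparently on read; output is always uncompressed.

Fragment collections are carried as :class:`pandas.DataFrame` objects with
columns ``chrom, start, end, barcode, read_support`` (one row per deduplicated
fragment); the :class:`Fragment` dataclass exists for record-level
construction and validation. Sorting is lexicographic by chromosome name, then
numeric by start, end, barcode — no karyotype ordering.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "OrderError",
    "GenomicInterval",
    "Fragment",
    "Peak",
    "TSSRecord",
    "CopyNumberRecord",
    "FRAGMENT_COLUMNS",
    "read_fragment_file",
    "write_fragment_file",
    "fragments_to_frame",
    "frame_to_fragments",
    "read_bed",
    "write_bed",
    "peaks_to_frame",
    "read_tss_table",
    "write_tss_table",
    "read_copy_number",
    "write_copy_number",
    "write_bedgraph",
]


class ParseError(ValueError):
    """A line could not be parsed into the expected fields."""


class ValidationError(ValueError):
    """Parsed values violate a record invariant."""


class OrderError(ValueError):
    """Records are not in the required sort order."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Fragment:
    """One barcoded, deduplicated sequencing fragment.

    ``(chrom, start, end, barcode)`` is the deduplication key: no two
    fragments in one library may share it.
    """

    interval: GenomicInterval
    barcode: str
    read_support: int = 1

    def __post_init__(self) -> None:
        if self.read_support < 1:
            raise ValidationError(
                f"read_support must be >= 1, got {self.read_support}"
            )


@dataclass(frozen=True)
class Peak:
    """A called or reference peak; ``score`` is typically a -log10 q-value."""

    interval: GenomicInterval
    name: str | None = None
    score: float | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class CopyNumberRecord:
    """Gene-level copy number on the log2(relative to ploidy + 1) scale."""

    gene_id: str
    cn_value: float


FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "read_support"]

_FRAGMENT_SORT = ["chrom", "start", "end", "barcode"]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragment_file(
    path,
    require_sorted: bool = False,
    dedup: str = "error",
) -> pd.DataFrame:
    """Read a fragments TSV into a validated DataFrame.

    Parameters
    ----------
    path
        Fragments file (optionally gzip-compressed).
    require_sorted
        Verify (chrom lexicographic, start, end) order and raise
        :class:`OrderError` otherwise.
    dedup
        ``"error"`` (default) rejects duplicate ``(chrom, start, end,
        barcode)`` rows; ``"collapse"`` merges them, summing ``read_support``.
        The explicit mode keeps the dedup state of a library unambiguous.
    """
    if dedup not in ("error", "collapse"):
        raise ValueError(f"dedup must be 'error' or 'collapse', got {dedup!r}")
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ParseError(
                    f"{path}: line {ln}: expected >=5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                start, end, support = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
            if start < 0:
                raise ValidationError(f"{path}: line {ln}: negative start {start}")
            if end <= start:
                raise ValidationError(
                    f"{path}: line {ln}: start >= end ([{start}, {end}))"
                )
            if support < 1:
                raise ValidationError(
                    f"{path}: line {ln}: read_support must be >= 1, got {support}"
                )
            rows.append((parts[0], start, end, parts[3], support))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if df.empty:
        return df.astype(
            {"chrom": str, "start": "int64", "end": "int64",
             "barcode": str, "read_support": "int64"}
        )
    if require_sorted:
        key = df[["chrom", "start", "end"]]
        if not key.equals(
            key.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        ):
            raise OrderError(f"{path}: records not sorted by (chrom, start, end)")
    dup = df.duplicated(_FRAGMENT_SORT, keep=False)
    if dup.any():
        if dedup == "error":
            first = df[dup].iloc[0]
            raise ValidationError(
                f"{path}: duplicate fragment "
                f"{first.chrom}:{first.start}-{first.end}/{first.barcode}; "
                "re-read with dedup='collapse' to merge"
            )
        df = (
            df.groupby(_FRAGMENT_SORT, as_index=False, sort=True)["read_support"]
            .sum()[FRAGMENT_COLUMNS]
        )
    return df.reset_index(drop=True)


def fragments_to_frame(fragments: Iterable[Fragment]) -> pd.DataFrame:
    """Convert an iterable of :class:`Fragment` records to the frame layout."""
    rows = [
        (f.interval.chrom, f.interval.start, f.interval.end, f.barcode,
         f.read_support)
        for f in fragments
    ]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def frame_to_fragments(df: pd.DataFrame) -> list[Fragment]:
    return [
        Fragment(GenomicInterval(r.chrom, int(r.start), int(r.end)),
                 r.barcode, int(r.read_support))
        for r in df.itertuples(index=False)
    ]


def write_fragment_file(fragments, path) -> None:
    """Write fragments sorted by (chrom, start, end, barcode).

    Output is deterministic: identical input produces byte-identical files.
    """
    if not isinstance(fragments, pd.DataFrame):
        fragments = fragments_to_frame(fragments)
    df = fragments.sort_values(_FRAGMENT_SORT, kind="mergesort")
    with open(path, "wt", newline="") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")


def read_bed(path) -> list[Peak]:
    """Read a BED3/BED4/BED5 file into Peak records (coordinates preserved)."""
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: expected >=3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
            name = parts[3] if len(parts) > 3 else None
            score = None
            if len(parts) > 4:
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {ln}: {exc}") from None
            try:
                peaks.append(Peak(GenomicInterval(parts[0], start, end), name, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {ln}: {exc}") from None
    return peaks


def _fmt_score(score: float) -> str:
    if score == int(score) and abs(score) < 1e15:
        return str(int(score))
    return repr(float(score))


def write_bed(peaks: Sequence[Peak], path) -> None:
    """Write peaks as BED, sorted; emits 3, 4 or 5 columns as populated."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "wt", newline="") as fh:
        for p in rows:
            fields = [p.chrom, str(p.start), str(p.end)]
            if p.name is not None or p.score is not None:
                fields.append(p.name if p.name is not None else ".")
            if p.score is not None:
                fields.append(_fmt_score(p.score))
            fh.write("\t".join(fields) + "\n")


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [p.name for p in peaks],
            "score": [p.score for p in peaks],
        }
    )


def read_tss_table(path) -> list[TSSRecord]:
    """Read a TSS table TSV with header gene_id/chrom/tss/strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(TSSRecord(r.gene_id, r.chrom, int(r.tss), str(r.strand)))
    return out


def write_tss_table(records: Sequence[TSSRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in records],
            "chrom": [t.chrom for t in records],
            "tss": [t.tss for t in records],
            "strand": [t.strand for t in records],
        }
    )
    with open(path, "wt", newline="") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_copy_number(path) -> list[CopyNumberRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    out = []
    for r in df.itertuples(index=False):
        cn = float(r.cn_value)
        if not math.isfinite(cn):
            raise ValidationError(f"non-finite cn_value for {r.gene_id}")
        out.append(CopyNumberRecord(r.gene_id, cn))
    return out


def write_copy_number(records: Sequence[CopyNumberRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in records],
            "cn_value": [c.cn_value for c in records],
        }
    )
    with open(path, "wt", newline="") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a (chrom, start, end, value) frame as bedGraph."""
    with open(path, "wt", newline="") as fh:
        track.to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")
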