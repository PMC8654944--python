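"""Count/RPM matrices over region sets, FRiP, pseudobulk aggregation and
depth-scaled coverage tracks.

Counting conventions (all half-open):

* ``fragments`` mode — a fragment contributes 1 to a region if they share at
  least one base; a fragment overlapping two disjoint regions counts once in
  each (no unique assignment).
* ``cut_sites`` mode — the two Tn5 insertion positions of a fragment are its
  ``start`` and ``end - 1``; each position falling inside a region counts
  separately. No ATAC-style +4/-5 shift is applied.
* RPM — raw count x 1e6 / library total, where the total is *all*
  deduplicated fragments of the library genome-wide, not only those inside
  the region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import Peak, peaks_to_frame
from .peaks_diff import merge_intervals
from ._regions import RegionIndex

__all__ = [
    "CellRegionMatrix",
    "LibrarySignalMatrix",
    "build_cell_region_matrix",
    "count_region_overlaps",
    "compute_rpm_matrix",
    "compute_frip",
    "aggregate_pseudobulk",
    "make_coverage_track",
]


@dataclass
class CellRegionMatrix:
    """Cells x regions sparse count matrix."""

    barcodes: list[str]
    regions: list[Peak]
    counts: sp.csr_matrix
    count_mode: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{p.chrom}:{p.start}-{p.end}" for p in self.regions]
        return pd.DataFrame(
            self.counts.toarray(), index=self.barcodes, columns=cols
        )


@dataclass
class LibrarySignalMatrix:
    """Regions x libraries RPM matrix plus the totals used to normalize."""

    rpm: pd.DataFrame
    library_totals: dict[str, int]

    @property
    def regions(self) -> list[str]:
        return list(self.rpm.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.rpm.columns)


def _cut_site_pairs(index: RegionIndex, frags: pd.DataFrame):
    chroms = frags["chrom"].to_numpy()
    starts = frags["start"].to_numpy(dtype=np.int64)
    ends = frags["end"].to_numpy(dtype=np.int64) - 1
    f1, r1 = index.site_pairs(chroms, starts)
    f2, r2 = index.site_pairs(chroms, ends)
    return np.concatenate([f1, f2]), np.concatenate([r1, r2])


def build_cell_region_matrix(
    fragments: pd.DataFrame,
    regions: Sequence[Peak],
    count_mode: str = "fragments",
) -> CellRegionMatrix:
    """Per-cell counts over a disjoint region set.

    fragments mode: distinct fragments of the barcode overlapping the region
    by >= 1 bp. cut_sites mode: fragment end positions (start and end-1,
    each counted separately) inside the region.
    """
    if count_mode not in ("fragments", "cut_sites"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    index = RegionIndex(regions)  # raises OverlapError on overlapping input
    barcodes, bc_codes = np.unique(fragments["barcode"].to_numpy(), return_inverse=True)
    if count_mode == "fragments":
        f_idx, r_idx = index.overlap_pairs(fragments)
    else:
        f_idx, r_idx = _cut_site_pairs(index, fragments)
    mat = sp.coo_matrix(
        (np.ones(len(f_idx), dtype=np.int64), (bc_codes[f_idx], r_idx)),
        shape=(len(barcodes), index.n),
    ).tocsr()
    return CellRegionMatrix(list(barcodes), list(regions), mat, count_mode)


def count_region_overlaps(
    fragments: pd.DataFrame,
    regions: Sequence[Peak],
    count_mode: str = "fragments",
) -> np.ndarray:
    """Aggregate (library-level) counts per region, in region input order."""
    index = RegionIndex(regions)
    if count_mode == "fragments":
        return index.count_overlaps(fragments)
    if count_mode == "cut_sites":
        _, r_idx = _cut_site_pairs(index, fragments)
        return np.bincount(r_idx, minlength=index.n).astype(np.int64)
    raise ValueError(f"unknown count_mode {count_mode!r}")


def compute_rpm_matrix(
    libraries: Mapping[str, pd.DataFrame],
    regions: Sequence[Peak],
) -> LibrarySignalMatrix:
    """RPM matrix (regions x libraries) over a disjoint reference set."""
    index = RegionIndex(regions)
    region_ids = [f"{p.chrom}:{p.start}-{p.end}" for p in regions]
    cols = {}
    totals = {}
    for name, frags in libraries.items():
        if len(frags) == 0:
            raise ValueError(f"library {name!r} is empty: RPM undefined")
        raw = index.count_overlaps(frags)
        totals[name] = int(len(frags))
        cols[name] = raw * 1e6 / totals[name]
    rpm = pd.DataFrame(cols, index=region_ids)
    return LibrarySignalMatrix(rpm, totals)


def compute_frip(fragments: pd.DataFrame, peaks: Sequence[Peak]) -> float:
    """Fraction of distinct fragments overlapping >= 1 peak by >= 1 bp.

    Peaks are merged to a disjoint set internally.
    """
    if len(fragments) == 0:
        raise ValueError("FRiP undefined for an empty library")
    index = RegionIndex(merge_intervals(peaks))
    return float(index.any_overlap_mask(fragments).mean())


def aggregate_pseudobulk(
    fragments: pd.DataFrame,
    cluster_map: Mapping[str, object],
) -> tuple[dict, pd.DataFrame, dict]:
    """Partition fragments by the cluster of their barcode.

    Returns (cluster -> fragment frame, unassigned fragment frame, report).
    Barcodes absent from the map are dropped into the unassigned frame and
    tallied in the report; empty clusters are allowed and reported.
    """
    assigned = fragments["barcode"].map(dict(cluster_map))
    out: dict = {}
    for cluster in sorted(set(cluster_map.values()), key=str):
        out[cluster] = fragments[assigned == cluster].reset_index(drop=True)
    unassigned = fragments[assigned.isna()].reset_index(drop=True)
    report = {
        "n_input": int(len(fragments)),
        "n_unassigned": int(len(unassigned)),
        "cluster_sizes": {str(k): int(len(v)) for k, v in out.items()},
    }
    return out, unassigned, report


def make_coverage_track(
    fragments: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 50,
    scale: str = "raw",
) -> pd.DataFrame:
    """Binned coverage as bedGraph rows (chrom, start, end, value).

    Per-bin value is the number of fragments overlapping the bin, scaled to
    RPM when requested. Adjacent equal-value bins are merged; zero-valued
    runs are omitted (bedGraph convention). Output is sorted.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if scale not in ("raw", "rpm"):
        raise ValueError(f"unknown scale {scale!r}")
    factor = 1e6 / len(fragments) if scale == "rpm" and len(fragments) else 1.0
    rows = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        n_bins = (length + bin_size - 1) // bin_size
        sub = fragments[fragments["chrom"] == chrom]
        if len(sub) == 0:
            continue
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        lo = s // bin_size
        hi = (e - 1) // bin_size
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi + 1, -1)
        cov = np.cumsum(diff[:-1])
        # run-length encode, skipping zero runs
        change = np.flatnonzero(np.diff(cov) != 0) + 1
        bounds = np.concatenate([[0], change, [n_bins]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            v = cov[a]
            if v == 0:
                continue
            rows.append(
                (chrom, int(a * bin_size), int(min(b * bin_size, length)),
                 float(v * factor) if scale == "rpm" else int(v))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
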