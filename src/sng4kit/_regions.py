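"""Overlap queries against a disjoint, sorted region set.

Every counting operation in the package requires its region set to be
pairwise disjoint (overlapping inputs must be merged first), which reduces
interval joins to binary search on per-chromosome start/end arrays.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Peak


class OverlapError(ValueError):
    """Region set violates the disjointness precondition."""


class RegionIndex:
    """Index over a disjoint set of regions, preserving input order."""

    def __init__(self, regions: Sequence[Peak]):
        self.regions = list(regions)
        self.n = len(self.regions)
        # per-chrom sorted views; _perm maps sorted position -> input index
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[int]] = {}
        for i, p in enumerate(self.regions):
            chroms.setdefault(p.chrom, []).append(i)
        for chrom, idx in chroms.items():
            idx_arr = np.asarray(idx, dtype=np.int64)
            starts = np.asarray([self.regions[i].start for i in idx], dtype=np.int64)
            ends = np.asarray([self.regions[i].end for i in idx], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends, idx_arr = starts[order], ends[order], idx_arr[order]
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                j = int(bad[0])
                a, b = self.regions[idx_arr[j]], self.regions[idx_arr[j + 1]]
                raise OverlapError(
                    f"regions overlap: {a.chrom}:{a.start}-{a.end} and "
                    f"{b.chrom}:{b.start}-{b.end}"
                )
            self._by_chrom[chrom] = (starts, ends, idx_arr)

    def overlap_pairs(self, frags: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """All (fragment row position, region input index) overlap pairs.

        Overlap means >= 1 shared base under half-open semantics. A fragment
        spanning several disjoint regions yields one pair per region.
        """
        f_idx_out: list[np.ndarray] = []
        r_idx_out: list[np.ndarray] = []
        if len(frags) == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        chrom_arr = frags["chrom"].to_numpy()
        s_all = frags["start"].to_numpy(dtype=np.int64)
        e_all = frags["end"].to_numpy(dtype=np.int64)
        for chrom, (starts, ends, idx_arr) in self._by_chrom.items():
            fpos = np.flatnonzero(chrom_arr == chrom)
            if fpos.size == 0:
                continue
            s, e = s_all[fpos], e_all[fpos]
            # first candidate: leftmost region whose end > fragment start;
            # subsequent candidates handle fragments spanning several regions
            first = np.searchsorted(ends, s, side="right")
            offset = 0
            while True:
                cand = first + offset
                valid = cand < len(starts)
                if not valid.any():
                    break
                hit = valid & (starts[np.where(valid, cand, 0)] < e)
                if not hit.any():
                    break
                f_idx_out.append(fpos[hit])
                r_idx_out.append(idx_arr[cand[hit]])
                offset += 1
        if not f_idx_out:
            return (np.empty(0, dtype=np.int64),) * 2
        return np.concatenate(f_idx_out), np.concatenate(r_idx_out)

    def count_overlaps(self, frags: pd.DataFrame) -> np.ndarray:
        """Number of fragments overlapping each region (input order)."""
        _, r_idx = self.overlap_pairs(frags)
        return np.bincount(r_idx, minlength=self.n).astype(np.int64)

    def any_overlap_mask(self, frags: pd.DataFrame) -> np.ndarray:
        """Boolean per fragment row: overlaps >= 1 region."""
        mask = np.zeros(len(frags), dtype=bool)
        f_idx, _ = self.overlap_pairs(frags)
        mask[f_idx] = True
        return mask

    def site_pairs(self, chroms: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(site row position, region index) pairs for point positions."""
        p_out: list[np.ndarray] = []
        r_out: list[np.ndarray] = []
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        for chrom, entry in self._by_chrom.items():
            starts, ends, idx_arr = entry
            sel = np.flatnonzero(chroms == chrom)
            if sel.size == 0:
                continue
            pos = positions[sel]
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.maximum(j, 0)])
            p_out.append(sel[ok])
            r_out.append(idx_arr[j[ok]])
        if not p_out:
            return (np.empty(0, dtype=np.int64),) * 2
        return np.concatenate(p_out), np.concatenate(r_out)
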