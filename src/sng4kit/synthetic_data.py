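"""Synthetic barcoded-fragment simulator.

Generates fragment files, bulk replicate libraries, TSS / copy-number tables
and full ground truth with the statistical shape of a two-cell-type
single-nuclei G4 profiling experiment: a few hundred to a couple of thousand
cells per type, a median of several hundred unique fragments per cell,
roughly 45% of fragments falling in peaks, and peak repertoires that are
partly shared between the cell types and partly type-specific.

The generator states a world; its defaults are fixed and are not tuning
knobs. Shared peaks receive a strength boost (``shared_strength_factor``)
because loci detected in both cell types are, in the data this emulates,
systematically the stronger ones — the downstream common-versus-specific
support comparison is only meaningful if the world encodes that.

Everything is deterministic given ``(config, seed)``; each stage draws from
its own ``default_rng([seed, stage_offset])`` stream so stages are
individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CopyNumberRecord,
    GenomicInterval,
    Peak,
    TSSRecord,
    write_bed,
    write_copy_number,
    write_fragment_file,
    write_tss_table,
)
from .peaks_diff import PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM, define_promoters

__all__ = ["SimConfig", "SimTruth", "SimulatedDataset",
           "simulate_peak_repertoire", "simulate_cells",
           "simulate_bulk_replicates", "simulate_annotation",
           "simulate_dataset", "write_dataset"]

# margin keeping peaks (and hence peak fragments) clear of chromosome edges
_EDGE_MARGIN = 1200
# stage offsets for per-stage rng streams
_STAGE_REPERTOIRE, _STAGE_ANNOTATION, _STAGE_CELLS, _STAGE_BULK = 1, 2, 3, 4


@dataclass
class SimConfig:
    """World parameters; defaults are the stated experimental regime."""

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000,
                                 "chr3": 2_000_000}
    )
    n_peaks: int = 600
    peak_width_mean: int = 300
    shared_fraction: float = 0.5
    shared_strength_factor: float = 2.0
    n_cells_a: int = 300
    n_cells_b: int = 300
    median_frags_per_cell: int = 800
    frag_count_dispersion: float = 10.0   # negative-binomial size parameter
    frip: float = 0.45
    fragment_length_log_mean: float = 5.2  # exp(5.2) ~ 180 bp
    fragment_length_log_sd: float = 0.45
    n_bulk_replicates: int = 2
    bulk_depth: int = 200_000
    n_genes: int = 200
    n_diff_promoters: int = 20
    diff_rate_ratio: float = 4.0
    cn_high_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_peaks", "peak_width_mean", "n_cells_a", "n_cells_b",
                     "median_frags_per_cell", "n_bulk_replicates",
                     "bulk_depth", "n_genes", "n_diff_promoters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("shared_fraction", "frip", "cn_high_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated data."""

    cell_labels: dict           # barcode -> "A" | "B"
    peak_classes: dict          # peak name -> shared | A_specific | B_specific
    peak_strengths: dict        # peak name -> positive float
    diff_promoter_genes: set
    cn_table: list              # CopyNumberRecord

    def to_json_dict(self) -> dict:
        return {
            "cell_labels": self.cell_labels,
            "peak_classes": self.peak_classes,
            "peak_strengths": self.peak_strengths,
            "diff_promoter_genes": sorted(self.diff_promoter_genes),
            "cn_table": {r.gene_id: r.cn_value for r in self.cn_table},
        }


@dataclass
class SimulatedDataset:
    config: SimConfig
    peaks: list                         # list[Peak], coordinate-sorted
    sc_fragments: pd.DataFrame
    bulk_libraries: dict                # name -> fragment frame
    tss_table: list                     # list[TSSRecord]
    truth: SimTruth


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


def simulate_peak_repertoire(
    config: SimConfig, seed: int | None = None
) -> tuple[list[Peak], dict, dict]:
    """Place non-overlapping peaks and assign classes and strengths.

    Exactly round(n_peaks * shared_fraction) peaks are shared; the remainder
    splits as evenly as possible between A-specific and B-specific (A gets
    the odd one). Strengths are gamma(shape 2, scale 1) draws; shared peaks
    are multiplied by shared_strength_factor.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, _STAGE_REPERTOIRE)
    chroms = sorted(config.chrom_sizes)
    usable = np.array(
        [config.chrom_sizes[c] - 2 * _EDGE_MARGIN for c in chroms], dtype=float
    )
    if (usable <= 0).any():
        raise ValueError("chromosomes too short for peak placement margin")
    widths = np.clip(
        np.round(rng.gamma(4.0, config.peak_width_mean / 4.0, config.n_peaks)),
        50, 900,
    ).astype(np.int64)
    if config.n_peaks * (widths.mean() + 1) > usable.sum() / 2:
        raise ValueError("peak budget exceeds half the usable genome")
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    ivals: list[tuple[str, int, int]] = []
    attempts = 0
    max_attempts = 50 * config.n_peaks
    for w in widths:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "could not place non-overlapping peaks within retry budget"
                )
            ci = rng.choice(len(chroms), p=usable / usable.sum())
            chrom = chroms[ci]
            start = int(
                rng.integers(_EDGE_MARGIN,
                             config.chrom_sizes[chrom] - _EDGE_MARGIN - w)
            )
            end = start + int(w)
            if all(e <= start or s >= end for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                ivals.append((chrom, start, end))
                break
    ivals.sort()
    peaks = [
        Peak(GenomicInterval(c, s, e), name=f"peak_{i + 1:04d}")
        for i, (c, s, e) in enumerate(ivals)
    ]
    n_shared = int(round(config.n_peaks * config.shared_fraction))
    n_spec = config.n_peaks - n_shared
    n_a = (n_spec + 1) // 2
    perm = rng.permutation(config.n_peaks)
    classes: dict[str, str] = {}
    for pos, idx in enumerate(perm):
        name = peaks[idx].name
        if pos < n_shared:
            classes[name] = "shared"
        elif pos < n_shared + n_a:
            classes[name] = "A_specific"
        else:
            classes[name] = "B_specific"
    strengths = {
        p.name: float(s * (config.shared_strength_factor
                           if classes[p.name] == "shared" else 1.0))
        for p, s in zip(peaks, rng.gamma(2.0, 1.0, config.n_peaks))
    }
    return peaks, classes, strengths


def _draw_fragments(
    rng: np.random.Generator,
    config: SimConfig,
    peaks: Sequence[Peak],
    classes: Mapping[str, str],
    strengths: Mapping[str, float],
    cell_type: str,
    n_fragments: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fragment model for one cell type.

    With probability frip the fragment is centred uniformly inside a peak of
    the type's repertoire (shared + own-specific, chosen proportionally to
    strength); otherwise its midpoint is uniform on the genome. Lengths are
    lognormal clipped to [30, 1000] bp.
    """
    chroms = sorted(config.chrom_sizes)
    chrom_len = np.array([config.chrom_sizes[c] for c in chroms], dtype=np.int64)
    own = f"{cell_type}_specific"
    rep = [p for p in peaks if classes[p.name] in ("shared", own)]
    w = np.array([strengths[p.name] for p in rep], dtype=float)
    w = w / w.sum()
    n = n_fragments
    lengths = np.clip(
        np.round(rng.lognormal(config.fragment_length_log_mean,
                               config.fragment_length_log_sd, n)),
        30, 1000,
    ).astype(np.int64)
    is_peak = rng.random(n) < config.frip
    chrom_idx = np.empty(n, dtype=np.int64)
    mids = np.empty(n, dtype=np.int64)
    npk = int(is_peak.sum())
    if npk and len(rep):
        pk = rng.choice(len(rep), size=npk, p=w)
        pk_start = np.array([p.start for p in rep])[pk]
        pk_width = np.array([p.end - p.start for p in rep])[pk]
        pk_chrom = np.array([chroms.index(p.chrom) for p in rep])[pk]
        mids[is_peak] = pk_start + (rng.random(npk) * pk_width).astype(np.int64)
        chrom_idx[is_peak] = pk_chrom
    else:
        is_peak[:] = False
    nbg = int((~is_peak).sum())
    if nbg:
        bg_chrom = rng.choice(len(chroms), size=nbg,
                              p=chrom_len / chrom_len.sum())
        chrom_idx[~is_peak] = bg_chrom
        mids[~is_peak] = (rng.random(nbg) * chrom_len[bg_chrom]).astype(np.int64)
    starts = mids - lengths // 2
    starts = np.clip(starts, 0, chrom_len[chrom_idx] - lengths)
    ends = starts + lengths
    return chrom_idx, starts, ends


def _frame(chroms, chrom_idx, starts, ends, barcodes, supports) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms)[chrom_idx],
            "start": starts,
            "end": ends,
            "barcode": barcodes,
            "read_support": supports,
        }
    )
    df = (
        df.groupby(["chrom", "start", "end", "barcode"], as_index=False,
                   sort=True)["read_support"].sum()
    )
    return df[["chrom", "start", "end", "barcode", "read_support"]].sort_values(
        ["chrom", "start", "end", "barcode"], kind="mergesort"
    ).reset_index(drop=True)


def simulate_cells(
    config: SimConfig,
    peaks: Sequence[Peak],
    classes: Mapping[str, str],
    strengths: Mapping[str, float],
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate barcoded single-cell fragments for both cell types.

    Per-cell fragment counts are negative-binomial with mean
    median_frags_per_cell and size frag_count_dispersion (single-cell depth
    is overdispersed relative to Poisson). Output is deduplicated per
    barcode (duplicate positions collapse, summing read_support) and sorted.
    Returns (fragment frame, barcode -> type labels).
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, _STAGE_CELLS)
    chroms = sorted(config.chrom_sizes)
    frames = []
    labels: dict[str, str] = {}
    for cell_type, n_cells in (("A", config.n_cells_a), ("B", config.n_cells_b)):
        r = config.frag_count_dispersion
        m = config.median_frags_per_cell
        counts = rng.negative_binomial(r, r / (r + m), n_cells)
        counts = np.maximum(counts, 1)
        bcs = [f"{cell_type}{i:05d}-1" for i in range(n_cells)]
        labels.update({b: cell_type for b in bcs})
        total = int(counts.sum())
        chrom_idx, starts, ends = _draw_fragments(
            rng, config, peaks, classes, strengths, cell_type, total
        )
        barcode_col = np.repeat(np.asarray(bcs, dtype=object), counts)
        supports = 1 + rng.poisson(0.3, total)
        frames.append(
            _frame(chroms, chrom_idx, starts, ends, barcode_col, supports)
        )
    df = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end", "barcode"], kind="mergesort"
    ).reset_index(drop=True)
    return df, labels


def simulate_bulk_replicates(
    config: SimConfig,
    peaks: Sequence[Peak],
    classes: Mapping[str, str],
    strengths: Mapping[str, float],
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Bulk replicate libraries per type, one pooled barcode per library.

    Replicates of a type differ only by sampling noise.
    """
    if seed is None:
        seed = config.seed
    if config.bulk_depth < 1:
        raise ValueError("bulk_depth must be positive for bulk libraries")
    rng = _rng(seed, _STAGE_BULK)
    chroms = sorted(config.chrom_sizes)
    out: dict[str, pd.DataFrame] = {}
    for cell_type in ("A", "B"):
        for rep in range(1, config.n_bulk_replicates + 1):
            name = f"bulk_{cell_type}_rep{rep}"
            chrom_idx, starts, ends = _draw_fragments(
                rng, config, peaks, classes, strengths, cell_type,
                config.bulk_depth,
            )
            supports = 1 + rng.poisson(0.3, config.bulk_depth)
            barcode_col = np.full(config.bulk_depth, name, dtype=object)
            out[name] = _frame(chroms, chrom_idx, starts, ends, barcode_col,
                               supports)
    return out


def simulate_annotation(
    config: SimConfig,
    peaks: Sequence[Peak],
    classes: Mapping[str, str],
    strengths: Mapping[str, float],
    seed: int | None = None,
) -> tuple[list[TSSRecord], list[CopyNumberRecord], set, dict]:
    """Place gene TSSs and build the copy-number table.

    n_diff_promoters A-specific peaks are chosen as differential promoter
    peaks: each gets a TSS whose promoter window (strand-aware) fully
    contains the peak, and its strength is boosted to diff_rate_ratio times
    the mean strength so the type-A cluster carries a clear excess of signal
    there. Remaining genes are placed with promoter windows that avoid all
    type-specific peaks and one another. The copy-number table marks
    round(cn_high_fraction * n_diff) differential genes as amplified
    (cn_value in (1.6, 2.5), i.e. > 1.5) and draws Normal(1.0, 0.1) for all
    other genes.

    Returns (tss_table, cn_table, diff_gene_ids, updated_strengths).
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, _STAGE_ANNOTATION)
    a_specific = [p for p in peaks
                  if classes[p.name] == "A_specific"
                  and (p.end - p.start) <= PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM]
    if config.n_diff_promoters > len(a_specific):
        raise ValueError(
            f"n_diff_promoters={config.n_diff_promoters} exceeds the "
            f"{len(a_specific)} available A-specific peaks"
        )
    if config.n_diff_promoters > config.n_genes:
        raise ValueError("n_diff_promoters exceeds n_genes")
    candidates = list(rng.permutation(len(a_specific)))
    strengths = dict(strengths)
    base_mean = float(np.mean(list(strengths.values())))
    tss_records: list[TSSRecord] = []
    diff_genes: set[str] = set()
    gene_i = 0
    specific_peaks = [p for p in peaks if classes[p.name] != "shared"]

    def _promoter(chrom: str, tss: int, strand: str) -> GenomicInterval:
        rec = TSSRecord("tmp", chrom, tss, strand)
        return define_promoters([rec], config.chrom_sizes)["tmp"]

    taken: list[GenomicInterval] = []
    # each differential gene gets a promoter window fully containing its
    # peak, disjoint from other promoters and other type-specific peaks
    for ci in candidates:
        if len(diff_genes) == config.n_diff_promoters:
            break
        pk = a_specific[ci]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            lo, hi = pk.end - PROMOTER_DOWNSTREAM, pk.start + PROMOTER_UPSTREAM
        else:
            lo, hi = pk.end - PROMOTER_UPSTREAM, pk.start + PROMOTER_DOWNSTREAM
        lo = max(lo, 0)
        placed_win = None
        for _ in range(10):
            tss = int(rng.integers(lo, hi + 1))
            win = _promoter(pk.chrom, tss, strand)
            others = [p for p in specific_peaks if p.name != pk.name]
            if any(win.overlaps(t) for t in taken):
                continue
            if any(win.overlaps(p.interval) for p in others):
                continue
            placed_win = (tss, win)
            break
        if placed_win is None:
            continue  # crowded neighbourhood; use another candidate peak
        tss, win = placed_win
        strengths[pk.name] = config.diff_rate_ratio * base_mean
        gene_i += 1
        gid = f"gene_{gene_i:04d}"
        tss_records.append(TSSRecord(gid, pk.chrom, tss, strand))
        diff_genes.add(gid)
        taken.append(win)
    if len(diff_genes) < config.n_diff_promoters:
        raise RuntimeError(
            "could not place the requested number of differential promoters"
        )
    chroms = sorted(config.chrom_sizes)
    chrom_len = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    tries = 0
    while gene_i < config.n_genes:
        tries += 1
        if tries > 200 * config.n_genes:
            raise RuntimeError("could not place non-overlapping gene promoters")
        ci = int(rng.choice(len(chroms), p=chrom_len / chrom_len.sum()))
        chrom = chroms[ci]
        tss = int(rng.integers(_EDGE_MARGIN,
                               config.chrom_sizes[chrom] - _EDGE_MARGIN))
        strand = "+" if rng.random() < 0.5 else "-"
        win = _promoter(chrom, tss, strand)
        if any(win.overlaps(t) for t in taken):
            continue
        if any(win.overlaps(p.interval) for p in specific_peaks):
            continue
        gene_i += 1
        gid = f"gene_{gene_i:04d}"
        tss_records.append(TSSRecord(gid, chrom, tss, strand))
        taken.append(win)
    diff_sorted = sorted(diff_genes)
    n_high = int(round(config.cn_high_fraction * len(diff_sorted)))
    high = set(
        np.asarray(diff_sorted, dtype=object)[
            rng.choice(len(diff_sorted), size=n_high, replace=False)
        ]
    ) if n_high else set()
    cn_table = []
    for rec in tss_records:
        if rec.gene_id in high:
            cn = float(rng.uniform(1.6, 2.5))
        else:
            cn = float(rng.normal(1.0, 0.1))
        cn_table.append(CopyNumberRecord(rec.gene_id, cn))
    return tss_records, cn_table, diff_genes, strengths


def simulate_dataset(config: SimConfig, seed: int | None = None
                     ) -> SimulatedDataset:
    """Run all simulator stages in order; fully deterministic given seed."""
    if seed is None:
        seed = config.seed
    peaks, classes, strengths = simulate_peak_repertoire(config, seed)
    tss, cn_table, diff_genes, strengths = simulate_annotation(
        config, peaks, classes, strengths, seed
    )
    sc_frags, cell_labels = simulate_cells(config, peaks, classes, strengths,
                                           seed)
    bulk = simulate_bulk_replicates(config, peaks, classes, strengths, seed)
    truth = SimTruth(cell_labels, classes, strengths, diff_genes, cn_table)
    return SimulatedDataset(config, peaks, sc_frags, bulk, tss, truth)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write every artifact of a simulated dataset as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fragments_sc"] = outdir / "fragments_sc.tsv"
    write_fragment_file(ds.sc_fragments, paths["fragments_sc"])
    for name, frame in ds.bulk_libraries.items():
        p = outdir / f"fragments_{name}.tsv"
        paths[f"fragments_{name}"] = p
        write_fragment_file(frame, p)
    paths["peaks_truth"] = outdir / "peaks_truth.bed"
    scored = [
        Peak(p.interval, p.name, ds.truth.peak_strengths[p.name])
        for p in ds.peaks
    ]
    write_bed(scored, paths["peaks_truth"])
    paths["cell_labels"] = outdir / "cell_labels.tsv"
    with open(paths["cell_labels"], "wt", newline="") as fh:
        fh.write("barcode\tcell_type\n")
        for bc in sorted(ds.truth.cell_labels):
            fh.write(f"{bc}\t{ds.truth.cell_labels[bc]}\n")
    paths["tss"] = outdir / "tss.tsv"
    write_tss_table(ds.tss_table, paths["tss"])
    paths["copy_number"] = outdir / "copy_number.tsv"
    write_copy_number(ds.truth.cn_table, paths["copy_number"])
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "wt") as fh:
        json.dump(ds.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
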