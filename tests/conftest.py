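import pytest

from sng4kit import RunConfig, SimConfig
from sng4kit.pipeline import run_mixed_population_workflow
from sng4kit.synthetic_data import simulate_dataset


def small_config(**overrides) -> SimConfig:
    """Desk-scale world for unit tests: same structure, ~25x fewer fragments."""
    base = dict(
        chrom_sizes={"chr1": 400_000, "chr2": 400_000},
        n_peaks=80,
        peak_width_mean=250,
        n_cells_a=40,
        n_cells_b=40,
        median_frags_per_cell=150,
        bulk_depth=30_000,
        n_genes=40,
        n_diff_promoters=8,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(), seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """The full stated world: 300+300 cells, 600 peaks, FRiP 0.45, seed 7."""
    return simulate_dataset(SimConfig(), seed=7)


@pytest.fixture(scope="session")
def workflow_run(tmp_path_factory):
    """One full mixed-population workflow run at defaults (seed 7)."""
    outdir = tmp_path_factory.mktemp("workflow")
    cfg = RunConfig(outdir=str(outdir), seed=7)
    report = run_mixed_population_workflow(cfg)
    return cfg, report, outdir
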