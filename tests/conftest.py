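import numpy as np
import pytest

from chromscore.features import CellInputs, assemble_features, drop_edge_loci, fit_feature_transform
from chromscore.synthetic_fixtures import (
    FixtureConfig,
    make_blacklist,
    simulate_all_cells,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Mini-genome small enough for seconds-scale tests of every stage."""
    return FixtureConfig(
        seed=11, n_chroms=2, chrom_length=200_000, n_cell_types=3,
        n_elements=25, n_repressive=8,
    )


@pytest.fixture(scope="session")
def small_cells(small_cfg):
    return simulate_all_cells(small_cfg)


@pytest.fixture(scope="session")
def small_blacklist(small_cfg):
    return make_blacklist(small_cfg)


@pytest.fixture(scope="session")
def small_cell_inputs(small_cfg, small_cells):
    return {
        c.cell_type: CellInputs(c.cell_type, small_cfg.layout, c.signals, c.peaks, c.states)
        for c in small_cells
    }


@pytest.fixture(scope="session")
def trained_expert(small_cfg, small_cells, small_cell_inputs):
    """One expert trained on the first cell's tiling-MPRA labels, with its transform."""
    from chromscore import labels as lb
    from chromscore.experts import ExpertConfig, train_expert
    from chromscore.synthetic_fixtures import simulate_assay_readouts

    cell = small_cells[0]
    ci = small_cell_inputs[cell.cell_type]
    readout = simulate_assay_readouts(cell.truth, "sharpr", seed=7)
    ds = lb.build_dataset(
        "sharpr/CT1", cell.cell_type, "plasmid_mpra", lb.label_sharpr(readout),
        layout=small_cfg.layout,
    )
    chroms = ds.records["chrom"].to_numpy()
    refs = ds.records["ref_pos"].to_numpy(dtype=np.int64)
    tc, trefs, keep = drop_edge_loci(chroms, refs, small_cfg.layout)
    tf = fit_feature_transform(tc, trefs, ci)
    X = assemble_features(tc, trefs, ci, tf)
    ens = train_expert(
        X, ds.y()[keep], ExpertConfig(n_members=15, seed=3),
        name="sharpr/CT1", cell_type=cell.cell_type, assay_class="plasmid_mpra",
        feature_names=tuple(tf.feature_names),
    )
    return ens, tf, ds
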