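import numpy as np
import pytest

import scregseg as sg


@pytest.fixture(scope="session")
def small_sim():
    """Small three-state simulation: fragments, counts, ground truth."""
    cfg = sg.SimConfig(
        n_chroms=2,
        chrom_length=150_000,
        n_cells=60,
        n_clusters=3,
        state_clusters=((0, 1), None, (2,)),
        seed=11,
    )
    frags, chrom_sizes, labels, truth = sg.simulate_dataset(cfg)
    bins = sg.make_bins(chrom_sizes, cfg.binsize)
    cm = sg.count_matrix(frags, bins, cap=4)
    return {
        "cfg": cfg,
        "frags": frags,
        "chrom_sizes": chrom_sizes,
        "labels": labels,
        "truth": truth,
        "cm": cm,
    }


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Fitted model on the small simulation (reduced schedule)."""
    model = sg.DirichletMultinomialHMM(small_sim["cm"], n_states=3)
    res = model.fit(n_iter=60, n_restarts=2, seed=5)
    return res


@pytest.fixture(scope="session")
def small_seg(small_fit):
    return small_fit.decode()
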