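import numpy as np
import pandas as pd
import pytest

from csnnorm import (
    ExpressionMatrix,
    GroupDesign,
    SimConfig,
    pair_by_orthologs,
    simulate_pair,
)
from csnnorm.deg import DEGConfig


def make_matrix(values, gene_ids=None, conditions=None, study="s1",
                species="spA"):
    """Small ExpressionMatrix from a 2-D array for unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    if conditions is None:
        conditions = [""] * n_samples
    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                         columns=sample_ids)
    samples = pd.DataFrame(
        {"study": study, "species": species, "condition": list(conditions)},
        index=frame.columns,
    )
    return ExpressionMatrix(frame, samples)


@pytest.fixture
def design():
    return GroupDesign("C1", "C2")


@pytest.fixture
def floor_config():
    return DEGConfig(zero_variance="floor")


@pytest.fixture(scope="session")
def small_pair():
    """Ortholog-paired synthetic pair with default-strength batch effects."""
    cfg = SimConfig(n_genes=400, seed=7)
    X, Y, truth = simulate_pair(cfg)
    Xp, Yp = pair_by_orthologs(X, Y, truth.ortholog_map)
    return Xp, Yp, truth


def no_batch_config(**kw):
    """SimConfig with all per-study distortions switched off."""
    defaults = dict(
        batch_offset_sd=0.0,
        batch_scale_range=(1.0, 1.0),
        batch_shift_range=(0.0, 0.0),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def truth_pair_keys(truth, which):
    """Map a truth direction dict onto the paired 'a|b' gene namespace."""
    lookup = {a: f"{a}|{b}" for a, b in truth.ortholog_map.pairs}
    lookup.update({b: f"{a}|{b}" for a, b in truth.ortholog_map.pairs})
    return {lookup[g]: d for g, d in which.items()}
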