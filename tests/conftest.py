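import numpy as np
import pandas as pd
import pytest

from phosnet.ingest import SITE_INDEX, PhosphoTable


def make_design(n_conditions=2, n_times=3, n_replicates=4, step=6.0):
    """Balanced sample design with one sample per (condition, time, rep)."""
    conds = (
        ["control", "cold"][:n_conditions]
        if n_conditions <= 2
        else [f"cond{i}" for i in range(n_conditions)]
    )
    rows = []
    for c in conds:
        for t in range(n_times):
            for r in range(1, n_replicates + 1):
                rows.append((f"Intensity {c}_{int(t * step):02d}_r{r}", c, t * step, f"r{r}"))
    return pd.DataFrame(
        [(c, t, r) for _, c, t, r in rows],
        index=[x[0] for x in rows],
        columns=["condition", "time_min", "replicate"],
    )


def make_table(values, design, proteins=None, loc_prob=1.0):
    """PhosphoTable from a (sites x samples) array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    proteins = proteins or [f"P{i + 1:03d}" for i in range(n)]
    idx = pd.MultiIndex.from_tuples(
        [(p, 101, "S", 1) for p in proteins], names=SITE_INDEX
    )
    inten = pd.DataFrame(values, index=idx, columns=design.index)
    meta = pd.DataFrame(
        {"localization_prob": loc_prob, "is_contaminant": False, "is_reverse": False},
        index=idx,
    )
    return PhosphoTable(inten, design, meta)


@pytest.fixture
def design_2x3x4():
    return make_design(2, 3, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
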