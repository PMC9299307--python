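import numpy as np
import pandas as pd
import pytest

from interactkit import FactorialDataset, build_design, fit_ols, generate_example1


def dataset_from_cells(cells: dict, factor_names=("A", "B"), response="y") -> FactorialDataset:
    """Build a dataset from {cell levels: iterable of response values}."""
    rows = []
    for cell, values in cells.items():
        cell = (cell,) if isinstance(cell, str) else tuple(cell)
        for v in values:
            rows.append(dict(zip(factor_names, cell)) | {response: float(v)})
    return FactorialDataset.from_frame(pd.DataFrame(rows), list(factor_names), response)


def exact_cell_data(means: dict, n: int, sd: float) -> dict:
    """Cell samples with *exactly* the requested mean and sample sd (ddof=1)."""
    z = np.arange(n, dtype=float)
    z -= z.mean()
    z /= z.std(ddof=1)
    return {cell: mu + sd * z for cell, mu in means.items()}


@pytest.fixture(scope="session")
def example1():
    return generate_example1(seed=7)


@pytest.fixture(scope="session")
def example1_fit(example1):
    return fit_ols(build_design(example1), example1)
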