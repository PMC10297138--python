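"""Shared fixtures: small simulated fields and plate tables."""

import numpy as np
import pandas as pd
import pytest

from rush_screen.synthetic import (
    FieldLayout,
    NoiseModel,
    WellCondition,
    simulate_field,
)


@pytest.fixture(scope="session")
def default_field():
    """One default-noise 50-cell field with its ground truth."""
    return simulate_field(WellCondition(n_cells=50), seed=11)


@pytest.fixture(scope="session")
def noiseless_field():
    """A noiseless 50-cell field (exact rendering, no illumination falloff)."""
    return simulate_field(WellCondition(n_cells=50), noise=NoiseModel.noiseless(), seed=11)


@pytest.fixture()
def small_layout():
    return FieldLayout(shape=(64, 64), n_cells=5)


def make_wells(values, n_cells=50, plate="P1", prefix="W"):
    """Wells table from a list of (well_id, role, gfp) or (well_id, role, gfp, n_cells)."""
    rows = []
    for entry in values:
        wid, role, gfp = entry[:3]
        n = entry[3] if len(entry) > 3 else n_cells
        rows.append((wid, role, gfp, n))
    wells = pd.DataFrame(
        dict(
            plate_id=plate,
            well_id=[r[0] for r in rows],
            n_cells=[r[3] for r in rows],
            well_gfp=[float(r[2]) for r in rows],
            qc_flags="",
        )
    )
    platemap = pd.DataFrame(
        dict(
            plate_id=plate,
            well_id=[r[0] for r in rows],
            role=[r[1] for r in rows],
            compound_id=[
                f"{prefix}{i}" if r[1] == "compound" else "" for i, r in enumerate(rows)
            ],
            dose_tier=["low" if r[1] == "compound" else "" for r in rows],
            biotin="yes",
        )
    )
    return wells, platemap


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
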