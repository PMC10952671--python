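import numpy as np
import pandas as pd
import pytest

from treedom import io as tdio
from treedom import synthetic as syn


@pytest.fixture
def toy_plots() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": ["p1", "p2", "p3", "p4"],
            "habitat": ["terra_firme", "terra_firme", "terra_firme", "terra_firme"],
            "lat": [-4.0, -4.1, -4.2, -4.3],
            "lon": [-73.0, -73.1, -73.2, -73.3],
            "area_ha": [0.1, 0.1, 0.1, 0.05],
        }
    ).set_index("plot_id")


@pytest.fixture
def toy_table(toy_plots) -> tdio.InventoryTable:
    records = pd.DataFrame(
        {
            "plot_id": ["p1", "p1", "p2", "p2", "p3", "p4"],
            "species": ["A", "B", "A", "C", "B", "A"],
            "id_status": ["species"] * 6,
            "count": [3, 1, 2, 2, 5, 4],
        }
    )
    return tdio.InventoryTable(plots=toy_plots, records=records)


@pytest.fixture(scope="session")
def community():
    """One default synthetic community, identification-filtered."""
    cfg = syn.SyntheticConfig(seed=20260901)
    table, truth, landscape = syn.generate(cfg)
    filtered, _ = tdio.filter_identifications(table)
    return {"config": cfg, "raw": table, "table": filtered, "truth": truth, "landscape": landscape}


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)
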