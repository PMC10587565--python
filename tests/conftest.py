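import hypothesis
import numpy as np
import pandas as pd
import pytest

from smtzkit.io import ASVTable, DepthProfile, TaxonomyTable, TAXONOMY_RANKS

hypothesis.settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def simple_profile() -> DepthProfile:
    """A clean 6-section core: linear methane rise below 30 cmbsf."""
    depth = np.array([25.0, 27, 29, 31, 33, 35])
    ch4 = np.where(depth >= 30, 0.1 + 0.2 * (depth - 30), 0.0)
    return DepthProfile(
        pd.DataFrame(
            {
                "core_id": "c1",
                "depth_cmbsf": depth,
                "ch4_mM": ch4,
                "so4_mM": np.linspace(10, 5, 6),
                "h2s_uM": np.linspace(100, 900, 6),
                "porosity": np.linspace(0.85, 0.78, 6),
            }
        )
    )


@pytest.fixture
def tiny_asv_table() -> tuple[ASVTable, TaxonomyTable]:
    counts = pd.DataFrame(
        [[5, 0, 10, 1], [2, 3, 0, 1]],
        index=["s1", "s2"],
        columns=["a1", "a2", "a3", "a4"],
    )
    tax = pd.DataFrame(
        {
            "domain": ["Archaea", "Archaea", "Bacteria", "Bacteria"],
            "phylum": ["Halobacterota", "Halobacterota", "Desulfobacterota", None],
            "class": ["Methanosarcinia", "Methanosarcinia", "Desulfobacteria", None],
            "order": ["ANME-1", "Methanosarciniales", "Desulfobacterales", None],
            "family": ["ANME-1b", "Methanosaetaceae", "Desulfosarcinaceae", None],
            "genus": ["ANME-1b", "Methanosaeta", "SEEP-SRB1", None],
        },
        index=["a1", "a2", "a3", "a4"],
    )[TAXONOMY_RANKS]
    return ASVTable(counts), TaxonomyTable(tax)
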