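import pandas as pd
import pytest

from phosphokin.simulate import SimulationDesign, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact two-ligand study with three planted active kinases."""
    design = SimulationDesign(seed=7, n_proteins=30)
    return simulate_study(design, n_kinases=8, substrates_per_kinase=4, n_active=3, delta=1.5)


@pytest.fixture()
def toy_measurements():
    """Two peptides sharing a site set plus one distinct group, two runs."""
    rows = [
        # peptide_id, protein, sites, run, condition, timepoint, replicate, intensity
        ("p1", "PROTA", "S15", "US_1h_r1", "US", "1h", 1, 10.0),
        ("p2", "PROTA", "S15", "US_1h_r1", "US", "1h", 1, 11.0),
        ("p3", "PROTA", "S15;T20", "US_1h_r1", "US", "1h", 1, 9.0),
        ("p1", "PROTA", "S15", "fibrin_1h_r1", "fibrin", "1h", 1, 12.0),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_id",
            "protein",
            "site_positions",
            "run",
            "condition",
            "timepoint",
            "replicate",
            "intensity",
        ],
    )
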