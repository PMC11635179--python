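import numpy as np
import pandas as pd
import pytest

from tempbeta.assemblage import IncidenceSeries, ReplicateTable


def make_incidence(rows, species="ABCDEFGH"):
    """IncidenceSeries from a list of species-letter sets."""
    species = tuple(species)
    presence = np.array([[s in r for s in species] for r in rows])
    return IncidenceSeries(meadow="m", times=tuple(range(1, len(rows) + 1)),
                           species=species, presence=presence)


def make_table(rows, times=None):
    """ReplicateTable from (region, meadow, time, replicate, species, count) tuples."""
    df = pd.DataFrame(rows, columns=["region", "meadow", "time", "replicate",
                                     "species", "count"])
    return ReplicateTable(df, times=tuple(times) if times else ())


@pytest.fixture
def toy_csv(tmp_path):
    """1 meadow, 2 times, 1 replicate, 3 species — 6 rows."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "region,meadow,time,replicate,species,count\n"
        "R1,M1,1,1,spA,2\n"
        "R1,M1,1,1,spB,1\n"
        "R1,M1,1,1,spC,0\n"
        "R1,M1,2,1,spA,0\n"
        "R1,M1,2,1,spB,3\n"
        "R1,M1,2,1,spC,4\n"
    )
    return path


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by pipeline-level tests."""
    from tempbeta.simulate import ScenarioConfig, generate_study
    return generate_study(ScenarioConfig(seed=42, pool_size=40,
                                         richness_per_time=12, n_times=6))
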