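import numpy as np
import pytest

import equiprev as eq
from equiprev import synthetic as syn


@pytest.fixture(scope="session")
def specs():
    return eq.mics_dimensions()


@pytest.fixture(scope="session")
def table1_groups(specs):
    """The packaged Ghana ITN disaggregated-estimate table, grouped."""
    return eq.read_disaggregated_table(eq.table1_fixture_path(), specs)


@pytest.fixture(scope="session")
def default_frame():
    """The default ten-region MICS-like frame (built once per session)."""
    return syn.build_frame(syn.default_config())


@pytest.fixture(scope="session")
def two_stratum_frame():
    """A single-region frame whose samples have 2 strata and 30 PSUs at the
    take used in the resampling-oracle tests."""
    cfg = syn.PopulationConfig(
        regions=(
            syn.RegionConfig(
                label="Ashanti",
                baseline_prevalence=50.0,
                urban_share=0.5,
                eas_per_stratum=60,
                households_per_ea=80,
            ),
        ),
        seed=42,
    )
    return syn.build_frame(cfg)


@pytest.fixture
def design():
    return eq.DesignSpec()


def make_records(weights, outcomes, clusters=None, strata=None, **dims):
    """Hand-build SurveyRecord lists for small worked examples."""
    n = len(weights)
    clusters = clusters or [f"c{i}" for i in range(n)]
    strata = strata or ["s1"] * n
    records = []
    for i in range(n):
        values = {dim: vals[i] for dim, vals in dims.items()}
        records.append(
            eq.SurveyRecord(
                stratum_id=strata[i],
                cluster_id=clusters[i],
                weight=float(weights[i]),
                outcome=int(outcomes[i]),
                values=values,
            )
        )
    return records


@pytest.fixture
def make_records_factory():
    return make_records
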