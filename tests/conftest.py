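import datetime as dt

import pytest

from trossa.records import FleetDataset, TrossaRecord
from trossa.reference import reference_rate_table
from trossa.synthetic import FleetConfig, generate_fleet


def make_record(
    trip="T1",
    boat="B1",
    depth=25.0,
    soak=1,
    net_length=50.0,
    n_nets=20,
    net_height=2.0,
    has_leb=False,
    birds=None,
    mammals=None,
    lumpfish=0,
    **kw,
):
    """A valid record with 2000 m² area and one soak day unless overridden."""
    set_date = dt.date(2022, 4, 1)
    return TrossaRecord(
        trip_id=trip,
        boat_id=boat,
        date_set=set_date,
        date_hauled=set_date + dt.timedelta(days=soak),
        mean_depth=depth,
        net_length=net_length,
        n_nets=n_nets,
        net_height=net_height,
        has_leb=has_leb,
        bird_counts=dict(birds or {}),
        mammal_counts=dict(mammals or {}),
        lumpfish_count=lumpfish,
        **kw,
    )


@pytest.fixture
def tiny_dataset():
    """Three trips, one with a deterrent trossa, hand-computable counts."""
    records = [
        make_record("T1", depth=20, birds={"common_eider": 2}, lumpfish=30),
        make_record("T1", depth=25, has_leb=True, birds={"common_eider": 1}, lumpfish=25),
        make_record("T1", depth=40, lumpfish=40),
        make_record("T2", boat="B2", depth=15, soak=2, birds={"black_guillemot": 1}, lumpfish=60),
        make_record("T2", boat="B2", depth=18, soak=2, lumpfish=55),
        make_record("T3", boat="B3", depth=55, mammals={"harbour_seal": 1}, lumpfish=20),
    ]
    return FleetDataset(records=records)


@pytest.fixture(scope="session")
def study_fleet():
    """A study-scale synthetic fleet (84 trips, 61 deterrent trossas)."""
    dataset, truth = generate_fleet(FleetConfig(seed=11))
    return dataset, truth


@pytest.fixture
def ref_table():
    return reference_rate_table()
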