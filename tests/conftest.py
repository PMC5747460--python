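import numpy as np
import pytest

from invasiontrace.records import OccurrenceRecord, RecordSet


def make_record(record_id="r1", tu="TU1", lon=10.0, lat=40.0, year=1850, status="wild"):
    return OccurrenceRecord(
        record_id=record_id, tu_id=tu, tu_name=f"unit {tu}", lon=lon, lat=lat, year=year, status=status
    )


@pytest.fixture
def small_recordset():
    """TU 'X' with wild 1850/1820 and cultivated 1830; TU 'Y' wild 1900."""
    return RecordSet(
        [
            make_record("a", "X", 10.0, 40.0, 1850, "wild"),
            make_record("b", "X", 10.1, 40.1, 1820, "wild"),
            make_record("c", "X", 10.2, 40.2, 1830, "cultivated"),
            make_record("d", "Y", 12.0, 41.0, 1900, "wild"),
        ]
    )


@pytest.fixture
def four_points():
    """Two tight pairs 10 apart: the classic hand-checkable 2-cluster set."""
    return np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])


@pytest.fixture
def occurrence_csv(tmp_path):
    path = tmp_path / "records.csv"
    path.write_text(
        "record_id,tu_id,tu_name,lon,lat,year,status,source\n"
        "r1,TU1,Alpha,10.5,40.25,1850,wild,herbarium\n"
        "r2,TU2,Beta,11.0,41.0,1830,cultivated,catalogue\n"
        "r3,TU3,Gamma,12.5,39.5,1900,wild,flora\n",
        encoding="utf-8",
    )
    return path
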