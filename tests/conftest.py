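import pytest

from stroketriage import (
    GeoPoint,
    PointRole,
    Scenario,
    generate_case_fixture,
)
from stroketriage.config import Geography


@pytest.fixture
def case_params():
    params, _, _ = generate_case_fixture()
    return params


@pytest.fixture
def case_table():
    return generate_case_fixture()[1]


@pytest.fixture
def case_geography(case_table):
    """The reference case as geography: synthetic coordinates, measured legs.

    Coordinates are synthetic placeholders (the case publishes travel times
    and distances, not facility coordinates); every leg the model needs is
    carried by the override table, so the coordinates never enter a timeline.
    """
    _, table, labels = generate_case_fixture()
    points = [
        GeoPoint(48.10, 8.20, PointRole.SCENE, labels["scene"]),
        GeoPoint(48.15, 8.25, PointRole.EMS_BASE, labels["ems_base"]),
        GeoPoint(48.00, 8.40, PointRole.HEMS_BASE, labels["hems_base"]),
        GeoPoint(48.25, 8.35, PointRole.PSC, labels["psc"]),
        GeoPoint(48.05, 8.75, PointRole.CSC, labels["csc"]),
    ]
    return Geography(points=points, overrides=table)
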