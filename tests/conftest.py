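import warnings

import pytest

from strawpoly import datamodel as dm


@pytest.fixture(scope="session")
def class_map():
    return dm.load_class_map()


@pytest.fixture(scope="session")
def measurements(class_map):
    out = []
    for name in ("table2_guariba.csv", "table3_valparaiso.csv"):
        out.extend(dm.load_compound_table(dm.fixture_path(name), class_map))
    return out


@pytest.fixture(scope="session")
def conditions_and_ic50():
    return dm.load_conditions()


@pytest.fixture(scope="session")
def conditions(conditions_and_ic50):
    return conditions_and_ic50[0]


@pytest.fixture(scope="session")
def response_table(measurements, class_map, conditions_and_ic50):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dm.aggregate_classes(
            measurements, class_map, ic50=conditions_and_ic50[1]
        )
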