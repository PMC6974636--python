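"""Shared fixtures: packaged structures and the published reference table."""

from collections import namedtuple

import pytest
from hypothesis import HealthCheck, settings

from lanthimass import load_structure

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Published reference values for the seven lantibiotic species:
#: printed elemental formula, printed calculated and observed [M+2H]2+ m/z,
#: and the printed signed ppm error.
Table2Row = namedtuple(
    "Table2Row", "species formula calc_mz observed_mz error_ppm"
)

TABLE2 = [
    Table2Row("kyamicin", "C76H108N20O25S3", 899.3551, 899.3553, 0.22),
    Table2Row("deoxykyamicin", "C76H108N20O24S3", 891.3576, 891.3557, -2.13),
    Table2Row("partially reduced kyamicin (k=1)", "C76H110N20O25S2", 884.3768, 884.3767, -0.11),
    Table2Row("partially reduced kyamicin (k=2)", "C76H112N20O25S", 869.3987, 869.3990, 0.35),
    Table2Row("reduced kyamicin", "C76H114N20O25", 854.4204, 854.4202, -0.23),
    Table2Row("duramycin", "C89H125N23O25S3", 1006.9262, 1006.9232, -2.98),
    Table2Row("deoxyduramycin", "C89H125N23O24S3", 998.9287, 998.9253, -3.40),
]


@pytest.fixture(scope="session")
def kyamicin():
    return load_structure("kyamicin")


@pytest.fixture(scope="session")
def duramycin():
    return load_structure("duramycin")


@pytest.fixture(scope="session")
def cinnamycin():
    return load_structure("cinnamycin")


@pytest.fixture(scope="session")
def table2():
    return TABLE2


@pytest.fixture(scope="session")
def table2_variants(kyamicin, duramycin):
    """The seven reference species as SpeciesVariant objects, table order."""
    return [
        kyamicin.variant(),
        kyamicin.variant(hydroxylated=False),
        kyamicin.variant(reduced_bridges=1),
        kyamicin.variant(reduced_bridges=2),
        kyamicin.variant(reduced_bridges=3),
        duramycin.variant(),
        duramycin.variant(hydroxylated=False),
    ]
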