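"""Shared fixtures: default parameter sets and cached reference simulations."""

import numpy as np
import pytest

import mabsim as ms


@pytest.fixture(scope="session")
def phys():
    return ms.PhysiologyParameters()


@pytest.fixture(scope="session")
def drug():
    return ms.DrugParameters()


@pytest.fixture(scope="session")
def tmdd_p():
    return ms.TMDDParameters()


@pytest.fixture(scope="session")
def disease_p():
    return ms.DiseaseParameters()


@pytest.fixture(scope="session")
def escalating_truth(phys, drug, tmdd_p, disease_p):
    """Reference PK/PD simulation of the escalating weekly regimen, 8 weeks."""
    doses = ms.make_regimen("gottlieb_escalating")
    return ms.simulate(phys, drug, tmdd_p, disease_p, doses, 8 * 168.0,
                       output_step=1.0)


@pytest.fixture(scope="session")
def escalating_drive(escalating_truth):
    return ms.DriveProfile(escalating_truth.time_h,
                           escalating_truth.occupancy_drive)


@pytest.fixture(scope="session")
def single_1_tmdd(phys, drug, tmdd_p):
    doses = ms.make_regimen("single_1")
    return ms.simulate(phys, drug, tmdd_p, None, doses, 6000.0,
                       output_step=4.0)


@pytest.fixture(scope="session")
def single_1_no_tmdd(phys, drug):
    doses = ms.make_regimen("single_1")
    return ms.simulate(phys, drug, None, None, doses, 6000.0,
                       output_step=4.0)


@pytest.fixture(scope="session")
def dose_1_amount(drug):
    return ms.make_regimen("single_1")[0].amount_umol(
        ms.REFERENCE_WEIGHT_KG, drug.mw)
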