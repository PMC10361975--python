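import dataclasses

import pytest

from datacollab import preprocessing as pp
from datacollab import synthetic


def small_profiles(n_checkup=160, n_hospital=170, prev_checkup=0.15,
                   prev_hospital=0.2):
    """Down-scaled institution profiles keeping the default structure
    (missing rates, visit models, class-conditional distributions)."""
    checkup, hospital = synthetic.default_profiles()
    checkup = dataclasses.replace(checkup, n_samples=n_checkup,
                                  prevalence=prev_checkup)
    hospital = dataclasses.replace(hospital, n_samples=n_hospital,
                                   prevalence=prev_hospital)
    return checkup, hospital


@pytest.fixture(scope="session")
def default_cohorts():
    checkup, hospital = synthetic.default_profiles()
    return (synthetic.generate_institution(checkup, seed=20140),
            synthetic.generate_institution(hospital, seed=20150))


@pytest.fixture(scope="session")
def prepared_default(default_cohorts):
    """Both institutions cleaned and encoded on the common feature set,
    with missing cells retained for replicate-level imputation."""
    chk, hos = default_cohorts
    rc = pp.clean_institution(chk.visits)
    rh = pp.clean_institution(hos.visits)
    common = pp.common_feature_set(rc, rh)
    pc = pp.prepare_institution(chk.visits, features=common, impute=False,
                                institution="checkup")
    ph = pp.prepare_institution(hos.visits, features=common, impute=False,
                                institution="hospital")
    return pc, ph


@pytest.fixture(scope="session")
def small_cohorts():
    checkup, hospital = small_profiles()
    return (synthetic.generate_institution(checkup, seed=11),
            synthetic.generate_institution(hospital, seed=12))


@pytest.fixture(scope="session")
def prepared_small(small_cohorts):
    chk, hos = small_cohorts
    rc = pp.clean_institution(chk.visits)
    rh = pp.clean_institution(hos.visits)
    common = pp.common_feature_set(rc, rh)
    pc = pp.prepare_institution(chk.visits, features=common, impute=False,
                                institution="checkup")
    ph = pp.prepare_institution(hos.visits, features=common, impute=False,
                                institution="hospital")
    return pc, ph
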