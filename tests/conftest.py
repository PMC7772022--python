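import numpy as np
import pytest

import femfall
from femfall import cohort as C
from femfall import pipeline as P


@pytest.fixture(scope="session")
def default_spec():
    return femfall.default_spec(seed=0)


@pytest.fixture(scope="session")
def one_subject(default_spec):
    """One fractured subject: (record, shape, rendered scan)."""
    rec = C.sample_clinical(default_spec, "fractured", 1, 101)[0]
    shp = C.sample_shape(default_spec, "fractured", 202, bmd_total=rec.bmd_total)
    scan = C.render_scan(shp, rec, 303)
    return rec, shp, scan


@pytest.fixture(scope="session")
def small_cohort():
    """Seven fractured + five control subjects with rendered scans."""
    spec = C.CohortSpec(n_fractured=7, n_control=5, seed=11)
    return C.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_config():
    cfg = P.PipelineConfig(seed=11, n_fractured=7, n_control=5,
                           target_elements=1500, n_runs=3,
                           models=["lr", "rf"])
    return cfg


@pytest.fixture(scope="session")
def small_attribute_table(small_cohort, small_config):
    """Full 39-attribute table for the 12-subject cohort (desk meshes)."""
    return P.compute_attribute_table(small_cohort, small_config)
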