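import numpy as np
import pytest

import riskscale as rs

SPAN = 3.5
OFFSETS = np.array([-SPAN, -SPAN / 3, SPAN / 3, SPAN])


def make_thresholds(locations, span=SPAN):
    offs = np.array([-span, -span / 3, span / 3, span])
    return [float(l) + offs for l in np.atleast_1d(locations)]


@pytest.fixture(scope="session")
def small_survey():
    """Default-structure synthetic survey at a reduced sample size."""
    cfg = rs.GeneratorConfig(n_per_group=40, seed=11)
    ds, truth = rs.generate_survey(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def health_calibration():
    """Calibrated 18-item health scale on a simulated stacked sample."""
    rng = np.random.default_rng(2101)
    from riskscale.simulate import HEALTH_LOCATIONS
    taus = make_thresholds(list(HEALTH_LOCATIONS.values()))
    theta = rng.normal(0.5, 2.9, 1200)
    data = rs.sample_pcm_matrix(theta, taus, rng)
    cals, rep = rs.calibrate_items(data, item_ids=list(HEALTH_LOCATIONS))
    persons = rs.estimate_persons(data, cals)
    return {"data": data, "cals": cals, "report": rep, "persons": persons,
            "theta_true": theta, "taus_true": taus}
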