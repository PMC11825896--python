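import numpy as np
import pandas as pd
import pytest

from edlatent import cohort as ch
from edlatent import model as md


@pytest.fixture(scope="session")
def small_cohort():
    """Default-scenario cohort, n=1200, plus its ground truth."""
    cfg = ch.default_config(1200, 42)
    table, gt = ch.generate_cohort(cfg)
    return cfg, table, gt


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    cfg, table, _ = small_cohort
    return md.frame_from_generated(table, cfg)


@pytest.fixture(scope="session")
def toy_frame():
    """Five hand-sized visits in model-frame format (30-day outcomes)."""
    rng = np.random.default_rng(7)
    n = 5
    data = {}
    for c in ch.BASELINE_COLUMNS:
        data[c] = rng.standard_normal(n).round(2)
    for c in ("female", "ins_medicaid", "ins_commercial", "ins_self_pay",
              "diabetes", "chf", "hypertension"):
        data[c] = rng.integers(0, 2, n).astype(float)
    data["acuity2"] = np.array([1.0, 0.0, 0.0, 1.0, 0.0])
    for c in ("temperature_z", "blood_pressure_z", "respiration_rate_z",
              "heart_rate_z"):
        data[c] = rng.standard_normal(n).round(2)
    data["admitted"] = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
    data["treatment_time"] = np.array([0.8, 1.5, 0.3, 2.2, 0.9])
    data["revisit_30d"] = np.array([0.0, 1.0, 0.0, 0.0, 1.0])
    data["readmission_30d"] = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def toy_params(toy_frame):
    """Hand-chosen valid parameters for the toy frame."""
    nB = len(ch.BASELINE_COLUMNS)
    rng = np.random.default_rng(3)
    proxies = {
        nm: md.ProxyParameters(alpha=0.1 * i, lam=0.4 + 0.1 * i,
                               kappa=rng.standard_normal(nB).round(2) * 0.1,
                               sigma=0.9 + 0.05 * i)
        for i, nm in enumerate(ch.CONTINUOUS_PROXIES)}
    eta = np.concatenate([[-0.4], rng.standard_normal(nB).round(2) * 0.3])
    acuity = np.concatenate([[-1.0, 0.8],
                             rng.standard_normal(nB).round(2) * 0.2])
    threshold = md.ThresholdParameters(
        boundary_a=2.0, start_w0=0.4, delta0=-0.3, delta_h=1.0,
        delta_x=rng.standard_normal(nB).round(2) * 0.1,
        delta_w=rng.standard_normal(len(ch.PROXY_COLUMNS)).round(2) * 0.1)
    outcomes = {
        "revisit_30d": md.OutcomeParameters(b0=0.2, bh=0.1, ba=-0.05,
                                            bha=0.02),
        "readmission_30d": md.OutcomeParameters(b0=0.05, bh=0.1, ba=0.06,
                                                bha=0.0),
    }
    return md.ModelParameters(eta=eta, proxies=proxies, acuity=acuity,
                              threshold=threshold, outcomes=outcomes)
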