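import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template_maps():
    from somnostate.synth import make_template_maps

    return make_template_maps(19, 4, seed=7)


@pytest.fixture(scope="session")
def clean_epoch(template_maps):
    """A preprocessed noise-free-ish epoch plus its generating sequence."""
    from somnostate.preprocess import preprocess_epoch
    from somnostate.synth import SimulationConfig, simulate_epoch

    cfg = SimulationConfig(seed=1, snr=50.0)
    rng = np.random.default_rng(11)
    epoch, seq = simulate_epoch(cfg, template_maps, suppression=False, rng=rng)
    return preprocess_epoch(epoch), seq


def make_meta_frame(n_patients, n_pod, rng):
    """Synthetic covariate table for stats-layer tests."""
    import pandas as pd

    rows = []
    for i in range(n_patients):
        rows.append(
            dict(
                patient_id=f"P{i:03d}",
                age=float(rng.normal(70.7, 6.5)),
                sex=str(rng.choice(["female", "male"])),
                mmse_band=str(rng.choice(["24-27", "28-29", "30"])),
                asa_band=str(rng.choice(["I-II", "III-IV"])),
                surgical_site=str(rng.choice(["abdomen/thorax", "other"])),
                anaesthetic=str(rng.choice(["TIVA", "inhalation"])),
                randomization=str(rng.choice(["open", "blinded"])),
                pod=bool(i < n_pod),
            )
        )
    return pd.DataFrame(rows)


def simulate_descriptor_table(
    n_patients,
    n_intervals,
    rng,
    slopes=None,
    sd_between=1.0,
    sd_within=1.0,
    intercept=10.0,
    response="sigma",
):
    """Response records drawn directly from the random-intercept trend model.

    ``slopes`` maps (pod, suppression) cells to duration slopes; used for
    null calibration and for CI-coverage checks of the contrast machinery.
    """
    import pandas as pd

    from somnostate.stats import prepare_table

    slopes = slopes or {}
    meta = make_meta_frame(n_patients, max(2, n_patients // 3), rng)
    rows = []
    for i in range(n_patients):
        pod = bool(meta.loc[i, "pod"])
        b = rng.normal(0.0, sd_between)
        for j in range(n_intervals):
            t = 15.0 + 30.0 * j + rng.uniform(-3, 3)
            supp = bool(j % 2) if rng.random() < 0.5 else not bool(j % 2)
            y = intercept + b + slopes.get((pod, supp), 0.0) * t + rng.normal(0.0, sd_within)
            rows.append(
                dict(patient_id=f"P{i:03d}", mean_time=t, suppression=supp, **{response: y})
            )
    return prepare_table(pd.DataFrame(rows), meta)
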