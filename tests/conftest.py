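import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import comigrate as cm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def long_csv(tmp_path):
    """3 species x 5 days, one year, fully observed."""
    path = tmp_path / "counts.csv"
    rows = ["year,date,species,count"]
    vals = {
        "Sylvia borin": [5, 9, 14, 9, 4],
        "Sylvia communis": [2, 4, 8, 5, 1],
        "Erithacus rubecula": [11, 7, 3, 1, 0],
    }
    for sp, series in vals.items():
        for d, v in enumerate(series):
            rows.append(f"2010,2010-04-{d + 1:02d},{sp},{v}")
    path.write_text("\n".join(rows) + "\n")
    return path, vals


def two_group_scenario(
    seed=0, n_species=8, sep_sigmas=5.0, noise="none", jitter=0.0, year_noise=0.0,
    years=(2015,), amplitude=30.0, wave_sd=5.0, season_length=60,
):
    """Small planted two-group scenario used across network/community tests."""
    half = n_species // 2
    groups = np.array([0] * half + [1] * (n_species - half))
    mid = season_length / 2
    sep = sep_sigmas * wave_sd
    return cm.SimScenario(
        n_species=n_species,
        n_groups=2,
        group_assignment=groups,
        years=years,
        peak_day0=np.array([mid - sep / 2, mid + sep / 2]),
        peak_trend=np.zeros(2),
        wave_sd=np.full(n_species, wave_sd),
        amplitude=np.full(n_species, amplitude),
        season_length=season_length,
        year_noise_sd=year_noise,
        peak_jitter_sd=jitter,
        noise=noise,
        seed=seed,
    )


@pytest.fixture()
def planted_two_groups():
    return two_group_scenario
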