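"""Shared fixtures: small synthetic datasets and peak-list files."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dispfit.data import DispersionDataset, ExperimentPoint, RateValue, SpinSystem
from dispfit.simulate import SimDesign, default_cpmg_design, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def cr72_dataset() -> DispersionDataset:
    """One spin, two fields, 15 CPMG frequencies, CR72 truth, sigma=0.5."""
    return simulate_dataset(default_cpmg_design(seed=1))


@pytest.fixture()
def flat_dataset() -> DispersionDataset:
    """No-exchange data: flat dispersion with Gaussian noise."""
    d = default_cpmg_design(seed=2, model="NoRex")
    d.true_params = {"R2:N": {"r20": {600.0: 10.0, 800.0: 10.0}}}
    return simulate_dataset(d)


@pytest.fixture()
def r1rho_design() -> SimDesign:
    return SimDesign(
        model="TP02",
        true_params={
            "R5:N": {"r20": {600.0: 10.0}, "pA": 0.95, "kex": 2000.0, "dw": 2.0}
        },
        fields_mhz=[600.0],
        seed=4,
        omega1=[400.0, 700.0, 1000.0, 1500.0, 2200.0],
        offsets_ppm=[-2.0, 0.0, 2.0],
        r1=1.5,
        sigma=0.2,
    )


@pytest.fixture()
def tiny_dataset() -> DispersionDataset:
    """Hand-built two-point dataset for exact chi2 arithmetic."""
    spins = [SpinSystem("R2:N")]
    points = [
        ExperimentPoint("CPMG_SQ", 600.0, nu_cpmg=50.0, relax_time_T=0.04),
        ExperimentPoint("CPMG_SQ", 600.0, nu_cpmg=500.0, relax_time_T=0.04),
    ]
    values = {
        ("R2:N", 0): RateValue(12.0, 0.5),
        ("R2:N", 1): RateValue(10.0, 0.5),
    }
    return DispersionDataset(spins, points, values)


@pytest.fixture()
def sparky_file(tmp_path):
    text = (
        "     Assignment         w1         w2   Data Height\n"
        "\n"
        "        R2N-HN    120.123      8.234      1000000\n"
        "        R3N-HN    118.500      8.010       912345\n"
        "        garbage line without numbers\n"
        "        R4N-HN    121.111      7.950       500000\n"
        "        R4N-HN    121.111      7.950       480000\n"
    )
    p = tmp_path / "peaks.list"
    p.write_text(text)
    return p
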