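"""Shared fixtures: representative transients and small cohorts."""

import numpy as np
import pytest

from lvtransient import synthetic


def representative_params(n_frames: int = 28,
                          noise_sd_ml: float = 0.0) -> synthetic.TransientParams:
    """Median-parameter plateau patient of the No-MACE class."""
    cls = synthetic.default_no_mace_params()
    rr = cls.rr_median_ms
    edv = cls.edv_median_ml
    esv = edv * (1 - cls.ef_median_pct / 100)
    sv = edv - esv
    ts = cls.systolic_frac_median * rr
    ta = 0.16 * rr
    td = cls.diastasis_median_ms
    tp = rr - ts - td - ta
    return synthetic.TransientParams(
        rr_ms=rr, edv_ml=edv, esv_ml=esv, systole_ms=ts,
        passive_ms=tp, diastasis_ms=td, active_ms=ta,
        passive_ml=cls.passive_frac_median * sv,
        active_ml=(1 - cls.passive_frac_median) * sv,
        n_frames=n_frames, noise_sd_ml=noise_sd_ml)


def make_params(rr=800.0, edv=160.0, esv=80.0, ts=280.0, tp=300.0,
                td=120.0, ta=100.0, p_frac=0.65, n_frames=28,
                noise_sd_ml=0.0, merged=False) -> synthetic.TransientParams:
    sv = edv - esv
    return synthetic.TransientParams(
        rr_ms=rr, edv_ml=edv, esv_ml=esv, systole_ms=ts, passive_ms=tp,
        diastasis_ms=td, active_ms=ta, passive_ml=p_frac * sv,
        active_ml=(1 - p_frac) * sv, n_frames=n_frames,
        noise_sd_ml=noise_sd_ml, merged_filling=merged)


@pytest.fixture
def rep_params():
    return representative_params()


@pytest.fixture
def rep_transient(rep_params):
    return synthetic.generate_transient(rep_params)


@pytest.fixture(scope="session")
def small_cohort():
    spec = synthetic.CohortSpec(n_patients=60, seed=3)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
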