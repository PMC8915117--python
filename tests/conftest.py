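"""Shared fixtures: synthetic records and cohorts, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ecgid.denoise import wt_ukf_denoise
from ecgid.fiducials import detect_p_t_waves, detect_r_peaks
from ecgid.synthetic import NoiseSpec, draw_template, generate_cohort, generate_record


@pytest.fixture(scope="session")
def template():
    return draw_template(np.random.default_rng(42))


@pytest.fixture(scope="session")
def clean_record(template):
    return generate_record(template, 30, noise=NoiseSpec.none(), seed=7)


@pytest.fixture(scope="session")
def noisy_record(template):
    return generate_record(template, 30, noise=NoiseSpec(), seed=7)


@pytest.fixture(scope="session")
def detection_cohort():
    """10 subjects x 20 beats with the default (moderate) noise, denoised and
    delineated; used by every detector-accuracy check."""
    records = generate_cohort(10, 20, noise=NoiseSpec(), seed=11)
    out = []
    for rec in records:
        den = wt_ukf_denoise(rec.samples, rec.fs).denoised
        r_peaks = detect_r_peaks(den, rec.fs)
        fids = detect_p_t_waves(den, rec.fs, r_peaks)
        out.append((rec, den, r_peaks, fids))
    return out
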