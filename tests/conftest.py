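"""Shared fixtures: coefficient tables, fast phantoms, and one full
clinical-scale pipeline run reused by the vessel, inpainting and
acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from rhodomap import (OpticalCoefficients, PhantomSpec, SpectralBand,
                      generate_movie, generate_mp_set, run_pipeline)

MP_BANDS = [SpectralBand(460, 600), SpectralBand(480, 600),
            SpectralBand(510, 600), SpectralBand(530, 600)]
MP_WEIGHTS = (1.0, 1.0, -1.0, -1.0)


@pytest.fixture(scope="session")
def coeffs():
    return OpticalCoefficients.default()


def small_spec(**overrides) -> PhantomSpec:
    """A fast phantom: 96 x 96 over a 24-degree field, 30 s at 8 fps."""
    defaults = dict(shape=(96, 96), field_of_view_deg=24.0, duration=30.0,
                    n_vessels=3, seed=0)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Noise- and vessel-free float64 phantom (model-exact curves)."""
    spec = small_spec(noise_sigma=0.0, n_vessels=0, dtype="float64")
    movie, truth = generate_movie(spec)
    return spec, movie, truth


@pytest.fixture(scope="session")
def pipeline_run(coeffs):
    """One full run at the clinical study conditions.

    256 x 256 over 30 degrees, 60 s at 8 fps, bleaching rate 0.04/frame,
    2% sensor noise, a vessel tree, and a four-band macular pigment set;
    the complete five-step pipeline on top.
    """
    spec = PhantomSpec(seed=1)
    movie, truth = generate_movie(spec)
    mpset, d_truth = generate_mp_set(spec, MP_BANDS, MP_WEIGHTS, coeffs,
                                     noise_sigma=0.5)
    result = run_pipeline(movie, mp_set=mpset, coeffs=coeffs)
    return {"spec": spec, "movie": movie, "truth": truth, "mpset": mpset,
            "d_truth": d_truth, "result": result}
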