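"""Shared fixtures: worked-example curve and small simulated batches."""

import numpy as np
import pytest

from pomoforce.curve_io import CurveMeta, preprocess_contact
from pomoforce.synthetic_data import generate_curve, worked_example_spec


@pytest.fixture(scope="session")
def b32_s9():
    """Noiseless worked-example curve (elastic line 38x - 3.1), preprocessed."""
    raw, gt = generate_curve(worked_example_spec(), sample_id="b32-s9",
                             genotype="B32")
    curve = preprocess_contact(raw.deformation, raw.force,
                               raw.meta.contact_threshold_n, raw.meta)
    return curve, gt


def make_curve(deformation, force, sample_id="test", **meta_kwargs):
    """Build a preprocessed Curve from plain arrays (helper, not a fixture)."""
    meta = CurveMeta(sample_id=sample_id, **meta_kwargs)
    return preprocess_contact(np.asarray(deformation, float),
                              np.asarray(force, float),
                              meta.contact_threshold_n, meta)
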