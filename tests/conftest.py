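import numpy as np
import pytest
from hypothesis import settings

from ctcenter import CohortSpec, CTVolume, PatientModel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

PITCH = 354.0 / 512.0


def make_patient(
    chest=104.0,
    ruler=None,
    width=152.0,
    scan_length=60.0,
    pad_nominal=75.0,
    pad_dent=3.4,
    offset=0.0,
    ctdivol=0.72,
    group="calculated",
):
    return PatientModel(
        true_chest_thickness=chest,
        ruler_chest_thickness=chest if ruler is None else ruler,
        body_width=width,
        scan_length=scan_length,
        pad_nominal=pad_nominal,
        pad_dent=pad_dent,
        true_offset=offset,
        ctdivol=ctdivol,
        group_label=group,
    )


@pytest.fixture
def noise_free_spec():
    return CohortSpec(noise_sd=0.0, seed=0)


@pytest.fixture
def default_patient():
    # short scan (12 slices) keeps rendering cheap in unit tests
    return make_patient()


def make_box_volume(n_slices=3, rows=64, cols=64, body_rows=None, body_cols=None, hu_body=0.0):
    """A rectangular 'body' in air, for analytic centering checks."""
    hu = np.full((n_slices, rows, cols), -1000.0, dtype=np.float32)
    if body_rows is not None:
        r0, r1 = body_rows
        c0, c1 = body_cols
        hu[:, r0 : r1 + 1, c0 : c1 + 1] = hu_body
    return CTVolume(hu=hu, dfov=cols * PITCH, slice_spacing=5.0)
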