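"""Shared fixtures: small phantom datasets and slice pipelines."""

import numpy as np
import pytest

from mmunet import brats_io, phantom


def cases_to_slices(cases, normalization="zscore_nonzero"):
    """Turn 2-D phantom cases directly into normalized SlicePairs."""
    return [
        brats_io.SlicePair(
            images=brats_io.normalize(c.images, normalization),
            labels=c.labels,
            case_id=c.case_id,
            slice_index=0,
        )
        for c in cases
    ]


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(
        image_size=32, region_radii=(10.0, 6.0, 3.0), noise_sd=3.0, seed=11
    )


@pytest.fixture(scope="session")
def small_jitter():
    return phantom.JitterSpec(center_px=3.0, radius_frac=0.15)


@pytest.fixture(scope="session")
def small_cases(small_spec, small_jitter):
    return phantom.generate_dataset(8, small_spec, small_jitter, 0.25, seed=11)


@pytest.fixture(scope="session")
def small_slices(small_cases):
    return cases_to_slices(small_cases)
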