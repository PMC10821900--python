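import numpy as np
import pytest

from skinquant import FieldParams, generate_wholemount


@pytest.fixture(scope="session")
def small_params() -> FieldParams:
    """512x512 field with 20 follicles: the same areal follicle density,
    intensities and noise as the default whole-mount geometry, at desk
    scale."""
    return FieldParams(width_px=512, height_px=512, n_follicles=20, seed=0)


@pytest.fixture(scope="session")
def small_field(small_params):
    return generate_wholemount(small_params)


@pytest.fixture(scope="session")
def noisefree_field(small_params):
    import dataclasses
    p = dataclasses.replace(small_params, noise_sd=0.0, seed=2)
    return generate_wholemount(p)


def match_points(detected, truth, gate_px: float = 3.0):
    """Hungarian one-to-one matching of detected to truth points.

    Returns (n_matched, rms_error) counting only pairs within ``gate_px``.
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    det = np.asarray(detected, float).reshape(-1, 2)
    tru = np.asarray(truth, float).reshape(-1, 2)
    if len(det) == 0 or len(tru) == 0:
        return 0, float("nan")
    d = cdist(det, tru)
    ri, ci = linear_sum_assignment(d)
    matched = d[ri, ci] <= gate_px
    errs = d[ri, ci][matched]
    return int(matched.sum()), float(np.sqrt(np.mean(errs**2))) if matched.any() else float("nan")
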