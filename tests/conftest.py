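"""Shared fixtures and independent oracle helpers.

The planted-tile generator here is the oracle for the stain estimator: it
builds OD images directly as ``S @ C`` with pure-dye pixel clusters whose
concentrations are scaled so every cluster passes the all-channel OD
foreground threshold.  It deliberately never calls the estimation code.
"""

import numpy as np
import pytest

from stainpipe import StainMatrix
from stainpipe.synthetic import SlideParams, default_profile, generate_slide

BASE_H = (0.65, 0.70, 0.29)
BASE_E = (0.07, 0.99, 0.11)


@pytest.fixture
def base_matrix() -> StainMatrix:
    return StainMatrix.from_columns(BASE_H, BASE_E, normalize=True)


def planted_od_tile(
    S: StainMatrix,
    rng: np.random.Generator,
    n: int = 64,
    beta: float = 0.15,
    pure_lo: float = 1.1,
    pure_hi: float = 1.6,
):
    """OD tile composed of pure-H, pure-E and mixed pixel groups.

    Pure-cluster concentrations are scaled by ``beta / min(column)`` so
    those pixels clear the foreground threshold in every channel, putting
    the exact planted directions at the angular extremes of the cloud.
    Returns ``(od, concentrations)``.
    """
    groups = rng.integers(0, 3, size=(n, n))
    scale_h = beta / S.matrix[:, 0].min()
    scale_e = beta / S.matrix[:, 1].min()
    c = np.zeros((n, n, 2))
    ch = rng.uniform(pure_lo, pure_hi, (n, n)) * scale_h
    ce = rng.uniform(pure_lo, pure_hi, (n, n)) * scale_e
    cm = rng.uniform(0.2, 1.2, (n, n, 2))
    c[..., 0] = np.where(groups == 0, ch, np.where(groups == 2, cm[..., 0], 0.0))
    c[..., 1] = np.where(groups == 1, ce, np.where(groups == 2, cm[..., 1], 0.0))
    return c @ S.matrix.T, c


def random_planted_matrix(rng: np.random.Generator) -> StainMatrix:
    """Random perturbation of the classic H&E columns, kept strictly
    positive so pure clusters remain representable."""
    while True:
        h = np.asarray(BASE_H) + rng.normal(0.0, 0.08, 3)
        e = np.asarray(BASE_E) + rng.normal(0.0, 0.04, 3)
        if (h > 0.05).all() and (e > 0.02).all():
            return StainMatrix.from_columns(h, e, normalize=True)


@pytest.fixture(scope="session")
def small_slide():
    """One deterministic positive synthetic slide shared across tests."""
    params = SlideParams(height=672, width=672, label="positive", seed=11)
    return generate_slide(params, default_profile(), slide_id="fixture-slide")


@pytest.fixture(scope="session")
def tissue_tile(small_slide):
    """A dense-tissue 224px uint8 tile cut from the fixture slide."""
    mask = small_slide.truth_mask
    best, best_frac = None, -1.0
    for r in range(0, 672 - 224, 112):
        for c in range(0, 672 - 224, 112):
            frac = mask[r : r + 224, c : c + 224].mean()
            if frac > best_frac:
                best, best_frac = (r, c), frac
    r, c = best
    return small_slide.image[r : r + 224, c : c + 224]
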