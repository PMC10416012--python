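"""Beer-Lambert optical-density transforms and stain-vector operations.

An H&E pixel is modelled as transmitted light through two absorbing dyes:
``I = I0 * 10**(-S @ c)`` where ``S`` is a 3x2 matrix whose columns are the
per-RGB-channel optical-density directions of hematoxylin and eosin and
``c`` holds the two non-negative dye concentrations.  This module provides

* RGB <-> optical density conversion,
* stain-matrix estimation from a single tile (angular-percentile method on
  the top-2 principal plane of the OD pixel cloud),
* reconstruction of a tile against a fixed target matrix ("normalization"),
* random element-wise perturbation of the estimated matrix ("jittering").
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import (
    DegenerateStains,
    InsufficientTissue,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StainMatrix",
    "MacenkoParams",
    "JitterParams",
    "DEFAULT_TARGET_MATRIX",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "compute_concentrations",
    "normalize_stains",
    "jitter_stains",
]

#: Minimum angle (degrees) between the two stain columns before the matrix
#: is considered rank deficient.
MIN_COLUMN_ANGLE_DEG = 1.0


def _as_float_image(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected an HxWx3 image, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise InvalidInputError("image contains non-finite values")
    return arr


@dataclass(frozen=True)
class StainMatrix:
    """3x2 matrix of stain absorption vectors.

    Column 0 is the hematoxylin OD direction, column 1 the eosin OD
    direction.  Estimated matrices have unit-norm columns; jittered
    matrices are deliberately exempt from that constraint.
    """

    matrix: np.ndarray
    min_angle_deg: float = MIN_COLUMN_ANGLE_DEG

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 2):
            raise InvalidInputError(f"stain matrix must be 3x2, got {m.shape}")
        if not np.isfinite(m).all():
            raise InvalidInputError("stain matrix contains non-finite values")
        if (m < 0).any():
            raise InvalidInputError("stain matrix elements must be >= 0")
        norms = np.linalg.norm(m, axis=0)
        if (norms == 0).any():
            raise DegenerateStains("stain matrix has a zero column")
        cosang = float(np.clip((m[:, 0] @ m[:, 1]) / (norms[0] * norms[1]), -1, 1))
        angle = np.degrees(np.arccos(cosang))
        if angle <= self.min_angle_deg:
            raise DegenerateStains(
                f"stain columns are {angle:.3f} deg apart "
                f"(minimum {self.min_angle_deg} deg)"
            )
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_columns(
        cls, hematoxylin, eosin, normalize: bool = False
    ) -> "StainMatrix":
        m = np.stack(
            [np.asarray(hematoxylin, float), np.asarray(eosin, float)], axis=1
        )
        if normalize:
            m = m / np.linalg.norm(m, axis=0, keepdims=True)
        return cls(m)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.matrix[:, 1]

    def column_angles_deg(self, other: "StainMatrix") -> np.ndarray:
        """Per-column angle (degrees) between this matrix and ``other``."""
        a = self.matrix / np.linalg.norm(self.matrix, axis=0, keepdims=True)
        b = other.matrix / np.linalg.norm(other.matrix, axis=0, keepdims=True)
        cos = np.clip(np.sum(a * b, axis=0), -1.0, 1.0)
        return np.degrees(np.arccos(cos))

    def to_dict(self) -> dict:
        return {
            "columns": ["hematoxylin", "eosin"],
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainMatrix":
        return cls(np.asarray(d["matrix"], dtype=np.float64))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StainMatrix":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Packaged default target matrix (classic H&E absorption directions,
#: unit-normalized).  The original target patch behind published results is
#: not public; this is a documented stand-in.
DEFAULT_TARGET_MATRIX = StainMatrix.from_columns(
    (0.65, 0.70, 0.29), (0.07, 0.99, 0.11), normalize=True
)


@dataclass(frozen=True)
class MacenkoParams:
    """Parameters of the angular-percentile stain estimator."""

    alpha: float = 1.0  # angle percentile in (0, 50)
    beta: float = 0.15  # OD foreground threshold
    min_foreground_pixels: int = 100
    i0: float = 255.0

    def __post_init__(self):
        if not (0 < self.alpha < 50):
            raise InvalidInputError("alpha must lie in (0, 50)")
        if self.beta <= 0:
            raise InvalidInputError("beta must be > 0")
        if self.min_foreground_pixels < 3:
            raise InvalidInputError("min_foreground_pixels must be >= 3")


@dataclass(frozen=True)
class JitterParams:
    """Uniform multiplicative perturbation range for stain elements."""

    low: float = 0.75
    high: float = 1.25
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.low <= self.high):
            raise InvalidInputError("need 0 < low <= high")


def rgb_to_od(
    pixels: np.ndarray, i0: float = 255.0, min_intensity: float = 1.0
) -> np.ndarray:
    """Convert intensities to base-10 optical densities.

    Intensities are clipped to ``[min_intensity, i0]`` before the log so
    the output is finite and bounded; the white point maps to OD 0.
    """
    arr = _as_float_image(pixels)
    clipped = np.clip(arr, min_intensity, i0)
    return -np.log10(clipped / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`: ``I = i0 * 10**(-od)``."""
    arr = np.asarray(od, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise InvalidInputError("OD image contains non-finite values")
    if (arr < 0).any():
        raise InvalidInputError("OD values must be >= 0")
    return np.clip(i0 * np.power(10.0, -arr), 0.0, i0)


def _foreground_od(od: np.ndarray, params: MacenkoParams) -> np.ndarray:
    pix = od.reshape(-1, 3)
    keep = (pix > params.beta).all(axis=1)
    return pix[keep]


def estimate_stain_matrix(
    od: np.ndarray, params: MacenkoParams = MacenkoParams()
) -> StainMatrix:
    """Estimate the 3x2 stain matrix from an OD image.

    Foreground pixels (every channel above ``beta``) are projected onto the
    top-2 principal plane of the *uncentred* OD cloud; the alpha-th and
    (100-alpha)-th percentiles of the polar angle give the two extreme
    directions, which are mapped back to 3-space, oriented non-negative,
    unit-normalized, and ordered so hematoxylin (largest red component)
    comes first.

    Raises
    ------
    InsufficientTissue
        Fewer than ``min_foreground_pixels`` foreground pixels.
    DegenerateStains
        The OD cloud is effectively one-dimensional (single stain).
    """
    fg = _foreground_od(np.asarray(od, dtype=np.float64), params)
    if fg.shape[0] < params.min_foreground_pixels:
        raise InsufficientTissue(
            f"{fg.shape[0]} foreground pixels "
            f"(need {params.min_foreground_pixels})"
        )

    # Principal directions of the raw (uncentred) OD cloud via the 3x3
    # Gram matrix -- equivalent to the right singular vectors of fg.
    gram = fg.T @ fg / fg.shape[0]
    evals, evecs = np.linalg.eigh(gram)  # ascending order
    if evals[2] <= 0 or evals[1] <= 1e-6 * evals[2]:
        raise DegenerateStains("OD cloud is rank deficient (single stain?)")
    basis = evecs[:, [2, 1]]  # 3x2, leading plane
    # Deterministic sign: each basis vector points into the positive octant.
    for j in range(2):
        if basis[:, j].sum() < 0:
            basis[:, j] = -basis[:, j]

    proj = fg @ basis  # N x 2
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [params.alpha, 100.0 - params.alpha])

    cols = []
    for ang in (lo, hi):
        v = basis @ np.array([np.cos(ang), np.sin(ang)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise DegenerateStains("extreme direction collapsed to zero")
        cols.append(v / nrm)

    # Hematoxylin absorbs red most strongly: larger first component wins;
    # tie-break on the green component.
    a, b = cols
    if (a[0], a[1]) >= (b[0], b[1]):
        h, e = a, b
    else:
        h, e = b, a
    return StainMatrix.from_columns(h, e)


def compute_concentrations(od: np.ndarray, S: StainMatrix) -> np.ndarray:
    """Per-pixel least-squares dye concentrations, clipped at zero.

    Solves ``od ~= S @ c`` for every pixel; returns an HxWx2 array.
    """
    arr = np.asarray(od, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected HxWx3 OD image, got {arr.shape}")
    pinv = np.linalg.pinv(S.matrix)  # 2x3
    conc = arr.reshape(-1, 3) @ pinv.T
    return np.clip(conc, 0.0, None).reshape(arr.shape[0], arr.shape[1], 2)


def _restore_dtype(out: np.ndarray, like: np.ndarray, i0: float) -> np.ndarray:
    if np.issubdtype(np.asarray(like).dtype, np.integer):
        return np.clip(np.rint(out), 0, i0).astype(np.asarray(like).dtype)
    return out


def normalize_stains(
    tile: np.ndarray,
    target: StainMatrix = DEFAULT_TARGET_MATRIX,
    params: MacenkoParams = MacenkoParams(),
    return_details: bool = False,
):
    """Re-express a tile's dye concentrations against a target stain matrix.

    The tile's own matrix is estimated, concentrations are solved against
    it, and the image is rebuilt as ``OD' = target @ C`` -- concentrations
    are not rescaled.  If estimation fails (too little tissue, or a single
    stain) the tile is returned unchanged and a warning is logged.
    """
    details = {"fallback": False, "source_matrix": None, "concentrations": None}
    try:
        od = rgb_to_od(tile, i0=params.i0)
        src = estimate_stain_matrix(od, params)
    except (InsufficientTissue, DegenerateStains) as exc:
        logger.warning("stain normalization skipped: %s", exc)
        warnings.warn(f"stain normalization skipped: {exc}", stacklevel=2)
        out = np.array(tile, copy=True)
        details["fallback"] = True
        return (out, details) if return_details else out

    conc = compute_concentrations(od, src)
    od_new = conc @ target.matrix.T
    out = _restore_dtype(od_to_rgb(od_new, i0=params.i0), tile, params.i0)
    details.update(source_matrix=src, concentrations=conc)
    return (out, details) if return_details else out


def jitter_stains(
    tile: np.ndarray,
    params: JitterParams = JitterParams(),
    rng: Optional[np.random.Generator] = None,
    macenko: MacenkoParams = MacenkoParams(),
    return_details: bool = False,
):
    """Perturb each element of the tile's estimated stain matrix by an
    independent ``Uniform(low, high)`` factor and rebuild the tile.

    The perturbed matrix is used as drawn -- columns are *not* re-normalized,
    so the jitter also scales effective stain intensity.  Deterministic
    under a fixed ``params.seed`` (or caller-provided ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    details = {"fallback": False, "source_matrix": None, "jittered_matrix": None,
               "factors": None}
    try:
        od = rgb_to_od(tile, i0=macenko.i0)
        src = estimate_stain_matrix(od, macenko)
    except (InsufficientTissue, DegenerateStains) as exc:
        logger.warning("stain jitter skipped: %s", exc)
        warnings.warn(f"stain jitter skipped: {exc}", stacklevel=2)
        out = np.array(tile, copy=True)
        details["fallback"] = True
        return (out, details) if return_details else out

    conc = compute_concentrations(od, src)
    factors = rng.uniform(params.low, params.high, size=(3, 2))
    jittered = src.matrix * factors
    od_new = conc @ jittered.T
    out = _restore_dtype(od_to_rgb(od_new, i0=macenko.i0), tile, macenko.i0)
    details.update(source_matrix=src, jittered_matrix=jittered, factors=factors)
    return (out, details) if return_details else out
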