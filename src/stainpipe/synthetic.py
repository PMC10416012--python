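"""Synthetic H&E-like slide generator with planted ground truth.

Slides are rendered through the same Beer-Lambert model the estimation
code assumes: a planted 3x2 stain matrix, two non-negative concentration
fields (nuclei spots for hematoxylin, diffuse blobs for eosin), additive
OD noise, a near-white background tint, and a global gamma.  Each slide
carries its truth mask, truth matrix, and label, so every downstream
stage can be checked against the generator.

Geometry (mask, nuclei, blobs) and rendering (noise) use two independent
seeded streams derived from the slide seed, so the same virtual biopsy
can be "rescanned" under a different scanner profile: identical geometry,
different pixel statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .stain import StainMatrix

__all__ = [
    "ScannerProfile",
    "SlideParams",
    "SyntheticSlide",
    "default_profile",
    "generate_slide",
    "generate_dataset",
    "shift_profile",
]

#: Classic H&E absorption directions used as the default planted matrix.
_BASE_H = (0.65, 0.70, 0.29)
_BASE_E = (0.07, 0.99, 0.11)


def default_profile(name: str = "scanner-a") -> "ScannerProfile":
    return ScannerProfile(
        name=name,
        stain_matrix=StainMatrix.from_columns(_BASE_H, _BASE_E, normalize=True),
        background_rgb=(255.0, 255.0, 255.0),
        noise_sd=0.0,
        gamma=1.0,
    )


@dataclass(frozen=True)
class ScannerProfile:
    """A virtual scanner: planted stain matrix, background tint, additive
    OD noise level, and a global intensity exponent."""

    name: str
    stain_matrix: StainMatrix
    background_rgb: Tuple[float, float, float] = (255.0, 255.0, 255.0)
    noise_sd: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        bg = np.asarray(self.background_rgb, dtype=float)
        if bg.shape != (3,) or (bg < 200).any() or (bg > 255).any():
            raise ConfigurationError(
                "background_rgb must be a near-white triple in [200, 255]"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be > 0")


@dataclass(frozen=True)
class SlideParams:
    """Size, label, tissue coverage and class-dependent texture controls."""

    height: int = 1024
    width: int = 1024
    label: str = "negative"  # "positive" | "negative"
    tissue_fraction_range: Tuple[float, float] = (0.25, 0.50)
    nuclei_density_by_class: Dict[str, float] = field(
        default_factory=lambda: {"negative": 0.002, "positive": 0.010}
    )
    blob_scale_by_class: Dict[str, float] = field(
        default_factory=lambda: {"negative": 28.0, "positive": 12.0}
    )
    min_side_tiles: int = 2  # dimensions must fit this many training tiles
    training_tile_side: int = 316
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tissue_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("tissue_fraction_range must satisfy 0 < lo <= hi <= 1")
        min_dim = self.min_side_tiles * self.training_tile_side
        if self.height < min_dim or self.width < min_dim:
            raise ConfigurationError(
                f"slide dimensions must be >= {min_dim} px per side"
            )
        if self.label not in ("positive", "negative"):
            raise ConfigurationError("label must be 'positive' or 'negative'")


@dataclass
class SyntheticSlide:
    image: np.ndarray  # HxWx3 uint8
    truth_mask: np.ndarray  # HxW bool
    truth_stain: StainMatrix
    label: str
    seed: int
    slide_id: str = ""


def _geometry_fields(params: SlideParams):
    """Mask + concentration fields from the geometry stream only."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    h, w = params.height, params.width

    field_ = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 16.0)
    lo, hi = params.tissue_fraction_range
    target_frac = rng.uniform(lo, hi)
    thr = np.quantile(field_, 1.0 - target_frac)
    mask = field_ > thr

    # Hematoxylin: sparse nuclei bumps (density is the class signal);
    # eosin is strongly suppressed inside nuclei and heavy in stroma, so
    # the OD cloud contains near-pure populations of both dyes.
    density = params.nuclei_density_by_class[params.label]
    impulses = (rng.random((h, w)) < density).astype(np.float64)
    bumps = 35.0 * gaussian_filter(impulses, sigma=2.0)
    h_conc = 0.02 + bumps

    blob_scale = params.blob_scale_by_class[params.label]
    blobs = gaussian_filter(rng.standard_normal((h, w)), sigma=blob_scale)
    sd = blobs.std() or 1.0
    e_amp = 1.8 + 0.6 * np.clip(blobs / sd, -1.0, 1.0)
    e_conc = e_amp * np.exp(-4.0 * bumps)

    conc = np.stack([h_conc, e_conc], axis=-1) * mask[..., None]
    return mask, conc, target_frac


def generate_slide(
    params: SlideParams,
    profile: ScannerProfile,
    slide_id: str = "",
) -> SyntheticSlide:
    """Render one slide.  Deterministic under ``params.seed``; the truth
    mask and concentrations depend only on the seed, never on the
    profile, so rescans share geometry."""
    mask, conc, _ = _geometry_fields(params)
    render_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    od = conc @ profile.stain_matrix.matrix.T
    if profile.noise_sd > 0:
        od = od + render_rng.normal(0.0, profile.noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)

    bg = np.asarray(profile.background_rgb, dtype=np.float64)
    rgb = bg * np.power(10.0, -od)
    rgb = 255.0 * np.power(np.clip(rgb / 255.0, 0.0, 1.0), profile.gamma)
    image = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    return SyntheticSlide(
        image=image,
        truth_mask=mask,
        truth_stain=profile.stain_matrix,
        label=params.label,
        seed=params.seed,
        slide_id=slide_id,
    )


def generate_dataset(
    n_pos: int,
    n_neg: int,
    params: SlideParams,
    profile: ScannerProfile,
    seed: int = 0,
    out_dir: Optional[Path] = None,
):
    """Generate a labelled slide set plus manifest.

    Per-slide seeds are derived deterministically from the master seed
    and do not depend on the profile, so two calls with the same seed and
    different profiles produce rescans of the same virtual biopsies.

    Returns ``(slides, manifest)``; when ``out_dir`` is given, slides are
    written as PNG + truth JSON + mask PNG and the manifest gains a
    ``path`` column and is saved as ``manifest.csv``.
    """
    if n_pos + n_neg < 2:
        raise ConfigurationError("need at least 2 slides")
    slide_seeds = np.random.SeedSequence(seed).generate_state(n_pos + n_neg)
    labels = ["positive"] * n_pos + ["negative"] * n_neg

    slides, rows = [], []
    for i, label in enumerate(labels):
        sid = f"{profile.name}-s{i:03d}"
        p = replace(params, label=label, seed=int(slide_seeds[i]))
        slide = generate_slide(p, profile, slide_id=sid)
        slides.append(slide)
        row = {
            "slide_id": sid,
            "label": label,
            "profile": profile.name,
            "seed": int(slide_seeds[i]),
        }
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            img_path = out_dir / f"{sid}.png"
            _write_png(img_path, slide.image)
            _write_png(out_dir / f"{sid}.mask.png",
                       (slide.truth_mask * 255).astype(np.uint8))
            (out_dir / f"{sid}.truth.json").write_text(
                json.dumps(
                    {
                        "slide_id": sid,
                        "label": label,
                        "seed": int(slide_seeds[i]),
                        "stain_matrix": slide.truth_stain.to_dict(),
                    },
                    indent=2,
                )
            )
            row["path"] = str(img_path)
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return slides, manifest


def _write_png(path: Path, arr: np.ndarray) -> None:
    from PIL import Image

    Image.fromarray(arr).save(path)


def shift_profile(
    base: ScannerProfile,
    column_rotation_degrees: float = 0.0,
    background_delta: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    gamma_delta: float = 0.0,
    name: Optional[str] = None,
    reference_axis: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ScannerProfile:
    """Derive a shifted scanner from ``base``.

    Each stain column is rotated by the stated angle within the plane it
    spans with ``reference_axis`` (towards the axis) and re-normalized;
    the background tint and gamma are offset.  Raises a configuration
    error if any resulting stain element would be negative or the
    background leaves the near-white band.
    """
    theta = np.radians(column_rotation_degrees)
    ref = np.asarray(reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)

    cols = []
    for j in range(2):
        v = base.stain_matrix.matrix[:, j]
        v = v / np.linalg.norm(v)
        u = ref - (ref @ v) * v
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise ConfigurationError("reference axis parallel to a stain column")
        u = u / nu
        v_new = np.cos(theta) * v + np.sin(theta) * u
        if (v_new < -1e-12).any():
            raise ConfigurationError(
                "rotation produced a negative stain element"
            )
        cols.append(np.clip(v_new, 0.0, None))

    bg = tuple(
        float(b + d)
        for b, d in zip(base.background_rgb, background_delta)
    )
    return ScannerProfile(
        name=name or f"{base.name}-shifted",
        stain_matrix=StainMatrix.from_columns(cols[0], cols[1], normalize=True),
        background_rgb=bg,
        noise_sd=base.noise_sd,
        gamma=base.gamma + gamma_delta,
    )
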