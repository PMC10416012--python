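"""Three-arm experiment harness (no processing / stain normalization /
stain jittering) plus dataset splitting and QA utilities.

The harness runs the full pipeline on a manifest of slide images:
tissue segmentation -> tiling -> geometric augmentation -> arm-specific
stain processing -> classifier training -> tile scoring -> slide-level
aggregation -> threshold selection, metrics, ROC and bootstrap intervals
per validation set.  Arm semantics are enforced structurally:

* ``NP``  - no stain processing anywhere;
* ``SN``  - training AND validation tiles normalized to the target matrix;
* ``SJ``  - training tiles jittered, validation tiles untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    TilePrediction,
    TrainConfig,
    bootstrap_ci,
    compute_metrics,
    roc_and_auc,
    select_threshold,
    slide_score,
    train_tile_classifier,
)
from .errors import ConfigurationError, InvalidInputError
from .stain import (
    DEFAULT_TARGET_MATRIX,
    JitterParams,
    MacenkoParams,
    StainMatrix,
    jitter_stains,
    normalize_stains,
)
from .tiling import (
    Tile,
    TileSpec,
    extract_tiles,
    maybe_reflect,
    rescale_to_magnification,
    rotate_and_crop,
    segment_tissue,
)

logger = logging.getLogger(__name__)

ARMS = ("NP", "SN", "SJ")

__all__ = [
    "ExperimentConfig",
    "ArmReport",
    "split_dataset",
    "run_arm",
    "export_qa_grid",
    "load_slide_image",
]


def load_slide_image(path: Union[str, Path]) -> np.ndarray:
    """Read a flat PNG/TIFF slide as an HxWx3 uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr


def split_dataset(
    manifest: pd.DataFrame,
    ratio: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random slide-level split; ``round(n * ratio)`` slides go to
    training, the remainder to validation."""
    if len(manifest) < 2:
        raise InvalidInputError("need at least 2 slides to split")
    rng = np.random.default_rng(seed)

    def _split_idx(idx: np.ndarray, r: float) -> Tuple[np.ndarray, np.ndarray]:
        perm = rng.permutation(idx)
        n_train = int(math.floor(len(idx) * r + 0.5))
        return perm[:n_train], perm[n_train:]

    if stratify:
        tr_parts, va_parts = [], []
        for _, grp in manifest.groupby("label", sort=True):
            tr, va = _split_idx(grp.index.to_numpy(), ratio)
            tr_parts.append(tr)
            va_parts.append(va)
        tr_idx = np.concatenate(tr_parts)
        va_idx = np.concatenate(va_parts)
    else:
        tr_idx, va_idx = _split_idx(manifest.index.to_numpy(), ratio)
    return (
        manifest.loc[np.sort(tr_idx)].reset_index(drop=True),
        manifest.loc[np.sort(va_idx)].reset_index(drop=True),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run one arm reproducibly."""

    arm: str
    train_manifest: Union[str, Path]
    validation_manifests: Dict[str, Union[str, Path]] = field(default_factory=dict)
    tile_spec: TileSpec = TileSpec()
    macenko: MacenkoParams = MacenkoParams()
    jitter: JitterParams = JitterParams()
    target_matrix: Optional[StainMatrix] = None
    train_config: TrainConfig = TrainConfig()
    split_ratio: float = 0.8
    stratify_split: bool = False
    seed: int = 0
    native_magnification: int = 10
    n_augment: int = 1  # augmented copies materialized per training tile
    tile_cutoff: float = 0.5
    n_boot: int = 200
    out_dir: Optional[Union[str, Path]] = None

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ConfigurationError(f"arm must be one of {ARMS}")
        if self.arm == "SN" and self.target_matrix is None:
            object.__setattr__(self, "target_matrix", DEFAULT_TARGET_MATRIX)
        if not (0.0 < self.split_ratio < 1.0):
            raise ConfigurationError("split_ratio must be in (0, 1)")
        if self.n_augment < 1:
            raise ConfigurationError("n_augment must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "arm": self.arm,
                "train_manifest": str(self.train_manifest),
                "validation_manifests": {
                    k: str(v) for k, v in self.validation_manifests.items()
                },
                "tile_spec": self.tile_spec.__dict__,
                "macenko": self.macenko.__dict__,
                "jitter": {"low": self.jitter.low, "high": self.jitter.high},
                "target": None
                if self.target_matrix is None
                else self.target_matrix.matrix.tolist(),
                "train_config": {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in self.train_config.__dict__.items()
                },
                "split_ratio": self.split_ratio,
                "stratify_split": self.stratify_split,
                "seed": self.seed,
                "native_magnification": self.native_magnification,
                "n_augment": self.n_augment,
                "tile_cutoff": self.tile_cutoff,
                "n_boot": self.n_boot,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ArmReport:
    arm: str
    config_hash: str
    seed: int
    version: str
    tile_metrics: Dict[str, dict]
    slide_metrics: Dict[str, dict]
    roc: Dict[str, dict]
    bootstrap: Dict[str, dict]
    n_training_tiles: int = 0

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "n_training_tiles": self.n_training_tiles,
            "tile_metrics": self.tile_metrics,
            "slide_metrics": self.slide_metrics,
            "roc": self.roc,
            "bootstrap": self.bootstrap,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"manifest not found: {path}")
    mf = pd.read_csv(path)
    required = {"slide_id", "label", "path"}
    if not required.issubset(mf.columns):
        raise InvalidInputError(
            f"manifest {path} missing columns {required - set(mf.columns)}"
        )
    return mf


def _label_to_int(label) -> int:
    if isinstance(label, str):
        return 1 if label.lower() in ("positive", "1", "true", "cd") else 0
    return int(label)


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return np.random.SeedSequence(list(digest[:8]))


def _prepare_slide(path, config: ExperimentConfig):
    img = load_slide_image(path)
    img = rescale_to_magnification(img, config.native_magnification, config.tile_spec)
    mask = segment_tissue(img)
    return img, mask


def _training_tiles_for_slide(
    row, config: ExperimentConfig, aug_rng, jit_rng
) -> List[np.ndarray]:
    img, mask = _prepare_slide(row["path"], config)
    tiles = extract_tiles(
        img, mask, config.tile_spec, mode="training", slide_id=row["slide_id"]
    )
    out = []
    for tile in tiles:
        for _ in range(config.n_augment):
            t = rotate_and_crop(
                tile, aug_rng.uniform(0.0, 360.0), crop_size=config.tile_spec.tile_size
            )
            t = maybe_reflect(t, 0.5, aug_rng)
            px = t.pixels
            if config.arm == "SN":
                px = normalize_stains(px, config.target_matrix, config.macenko)
            elif config.arm == "SJ":
                px = jitter_stains(px, config.jitter, rng=jit_rng,
                                   macenko=config.macenko)
            out.append(px)
    return out


def _score_validation_set(
    manifest: pd.DataFrame, clf, config: ExperimentConfig
):
    """Tile + slide scores for one validation manifest."""
    slide_fracs, slide_labels = [], []
    tile_scores_all, tile_labels_all = [], []
    for _, row in manifest.iterrows():
        img, mask = _prepare_slide(row["path"], config)
        tiles = extract_tiles(
            img, mask, config.tile_spec, mode="inference", slide_id=row["slide_id"]
        )
        if not tiles:
            logger.warning("slide %s produced no tiles; skipped", row["slide_id"])
            continue
        images = []
        for t in tiles:
            px = t.pixels
            if config.arm == "SN":
                # validation tiles are normalized only in the SN arm;
                # jitter is never applied at validation time
                px = normalize_stains(px, config.target_matrix, config.macenko)
            images.append(px)
        scores = clf.score(images)
        preds = [
            TilePrediction(t.slide_id, t.row, t.col, float(s))
            for t, s in zip(tiles, scores)
        ]
        ss = slide_score(preds, config.tile_cutoff)
        slide_fracs.append(ss.fraction_positive)
        y = _label_to_int(row["label"])
        slide_labels.append(y)
        tile_scores_all.extend(scores.tolist())
        tile_labels_all.extend([y] * len(scores))
    return (
        np.array(slide_fracs),
        np.array(slide_labels),
        np.array(tile_scores_all),
        np.array(tile_labels_all),
    )


def run_arm(config: ExperimentConfig) -> ArmReport:
    """Execute one arm end to end; fully reproducible under the master
    seed.  The decision threshold gamma is re-selected independently on
    each validation set (accuracy-maximizing), as in the reference
    protocol."""
    train_mf = _read_manifest(config.train_manifest)
    for p in train_mf["path"]:
        if not Path(p).exists():
            raise InvalidInputError(f"missing slide image: {p}")

    split_seed = int(_stage_seed(config.seed, "split").generate_state(1)[0])
    train_part, val_part = split_dataset(
        train_mf, config.split_ratio, seed=split_seed, stratify=config.stratify_split
    )

    aug_rng = np.random.default_rng(_stage_seed(config.seed, "augment"))
    jit_rng = np.random.default_rng(_stage_seed(config.seed, "jitter"))

    images, labels = [], []
    for _, row in train_part.iterrows():
        tile_imgs = _training_tiles_for_slide(row, config, aug_rng, jit_rng)
        images.extend(tile_imgs)
        labels.extend([_label_to_int(row["label"])] * len(tile_imgs))
    logger.info("arm %s: %d training tiles from %d slides",
                config.arm, len(images), len(train_part))

    train_seed = int(_stage_seed(config.seed, "train").generate_state(1)[0] % (2**31))
    tc = TrainConfig(**{**config.train_config.__dict__, "seed": train_seed})
    clf = train_tile_classifier(images, labels, tc)

    validation_sets: Dict[str, pd.DataFrame] = {"validation": val_part}
    for name, path in config.validation_manifests.items():
        validation_sets[name] = _read_manifest(path)

    tile_metrics, slide_metrics, roc_out, boot_out = {}, {}, {}, {}
    boot_seed = int(_stage_seed(config.seed, "bootstrap").generate_state(1)[0])
    for name, mf in validation_sets.items():
        fracs, ys, tile_scores, tile_ys = _score_validation_set(mf, clf, config)
        if fracs.size == 0:
            logger.warning("validation set %s empty; skipped", name)
            continue
        gamma = select_threshold(fracs, ys)
        slide_metrics[name] = compute_metrics(fracs, ys, gamma, "slide").to_dict()
        tile_metrics[name] = compute_metrics(
            tile_scores, tile_ys, config.tile_cutoff, "tile"
        ).to_dict()
        try:
            roc = roc_and_auc(fracs, ys)
            roc_out[name] = {
                "auc": roc.auc,
                "fpr": roc.fpr.tolist(),
                "tpr": roc.tpr.tolist(),
                "thresholds": [float(t) for t in roc.thresholds],
            }
        except Exception as exc:  # single-class validation set
            logger.warning("ROC unavailable for %s: %s", name, exc)
        if fracs.size >= 2:
            def _f1(f, y, g=gamma):
                return compute_metrics(f, y, g, "slide").f1

            def _acc(f, y, g=gamma):
                return compute_metrics(f, y, g, "slide").accuracy

            boot_out[name] = {
                "f1_ci": list(bootstrap_ci(_f1, fracs, ys, config.n_boot,
                                           seed=boot_seed)),
                "accuracy_ci": list(bootstrap_ci(_acc, fracs, ys, config.n_boot,
                                                 seed=boot_seed)),
            }

    report = ArmReport(
        arm=config.arm,
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        tile_metrics=tile_metrics,
        slide_metrics=slide_metrics,
        roc=roc_out,
        bootstrap=boot_out,
        n_training_tiles=len(images),
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"report_{config.arm}.json").write_text(report.to_json())
        for name, roc in roc_out.items():
            pd.DataFrame(
                {"threshold": roc["thresholds"], "fpr": roc["fpr"],
                 "tpr": roc["tpr"]}
            ).to_csv(out / f"roc_{config.arm}_{name}.csv", index=False)
    return report


def export_qa_grid(
    tiles: Sequence[np.ndarray], path: Union[str, Path], n: int = 100
) -> np.ndarray:
    """Arrange the first ``n`` tiles in a near-square grid (ceil(sqrt)
    columns, blank white cells at the end) and write it as a JPEG."""
    if len(tiles) == 0:
        raise InvalidInputError("no tiles to export")
    chosen = [np.asarray(t.pixels if isinstance(t, Tile) else t) for t in tiles[:n]]
    side = chosen[0].shape[0]
    k = len(chosen)
    ncols = int(math.ceil(math.sqrt(k)))
    nrows = int(math.ceil(k / ncols))
    grid = np.full((nrows * side, ncols * side, 3), 255, dtype=np.uint8)
    for i, t in enumerate(chosen):
        r, c = divmod(i, ncols)
        grid[r * side : (r + 1) * side, c * side : (c + 1) * side] = t
    from PIL import Image

    Image.fromarray(grid).save(Path(path), format="JPEG")
    return grid
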