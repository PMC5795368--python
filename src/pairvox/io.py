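"""Image sequence I/O, CIELAB conversion and label-map serialization.

Frames are read from a directory (or explicit file list) in
lexicographic filename order, which is taken as temporal order.  Label
maps are written as 16-bit single-channel PNGs (supervoxel counts can
exceed 255) alongside a JSON manifest recording the grid geometry and
hyperparameters, so the labels are interpretable standalone and
round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from skimage.color import lab2rgb, rgb2lab

from .segmentation import PairSegmentation, VideoSegmentation
from .synthetic import SyntheticVideo

__all__ = [
    "RunConfig",
    "read_frames",
    "rgb_to_cielab",
    "cielab_to_rgb",
    "write_labels",
    "read_labels",
    "write_synthetic",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class RunConfig:
    """A run's full parameterization, persisted in the output manifest.

    Defaults mirror :class:`pairvox.vrgmm.Hyperparams` and the default
    candidate window ``eta_x = eta_y = 2``.
    """

    vx: int
    vy: int
    eta_x: int = 2
    eta_y: int = 2
    lambda_s: float = 2.0
    lambda_c: float = 8.0
    sigma_c: float = 10.0
    n_iter: int = 20

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})


def _to_unit_rgb(img: np.ndarray, path: str) -> np.ndarray:
    """Scale an 8/16-bit (or float) image to RGB in [0, 1], HxWx3."""
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{path}: expected a grayscale or RGB image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    img = img.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def read_frames(path: str | Path | Sequence[str | Path]) -> list[np.ndarray]:
    """Read an ordered frame sequence as RGB arrays in [0, 1].

    ``path`` may be a directory (image files sorted lexicographically),
    a single file, or an explicit list of files.  All frames must share
    one size; mismatches raise with the offending files listed.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if p.is_dir():
            files = sorted(f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES)
            if not files:
                raise FileNotFoundError(f"no image files found in {p}")
        else:
            if not p.exists():
                raise FileNotFoundError(str(p))
            files = [p]
    else:
        files = [Path(f) for f in path]
        if not files:
            raise FileNotFoundError("empty frame list")
    frames = [_to_unit_rgb(iio.imread(f), str(f)) for f in files]
    shapes = [f.shape[:2] for f in frames]
    if len(set(shapes)) > 1:
        bad = ", ".join(f"{f.name}: {s[1]}x{s[0]}" for f, s in zip(files, shapes))
        raise ValueError(f"frames differ in size ({bad})")
    return frames


def rgb_to_cielab(frame: np.ndarray) -> np.ndarray:
    """sRGB in [0, 1] -> CIELAB (D65 white point, L in [0, 100])."""
    return rgb2lab(np.asarray(frame, dtype=float))


def cielab_to_rgb(frame: np.ndarray) -> np.ndarray:
    """CIELAB -> sRGB in [0, 1], clipped to gamut."""
    return np.clip(lab2rgb(np.asarray(frame, dtype=float)), 0.0, 1.0)


def _label_path(outdir: Path, pair: int, frame: int) -> Path:
    return outdir / f"pair{pair:04d}_frame{frame}.png"


def write_labels(
    seg: VideoSegmentation,
    outdir: str | Path,
    config: RunConfig | None = None,
    extra_manifest: dict | None = None,
) -> list[Path]:
    """Write per-pair 16-bit PNG label maps plus a JSON manifest.

    Pair ``t`` yields ``pair{t:04d}_frame{t}.png`` and
    ``pair{t:04d}_frame{t+1}.png``.  Round-trips losslessly through
    :func:`read_labels` for up to 65536 labels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for pair in seg:
        t = pair.frame_index
        if pair.K > 65536:
            raise ValueError(f"K={pair.K} exceeds 16-bit label range")
        for frame, labels in ((t, pair.labels_t), (t + 1, pair.labels_t1)):
            f = _label_path(outdir, t, frame)
            iio.imwrite(f, labels.astype(np.uint16))
            written.append(f)
    manifest = {
        "format": "pairvox-labels-v1",
        "n_pairs": len(seg),
        "K": seg.pairs[0].K if len(seg) else None,
        "config": config.to_dict() if config is not None else None,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    mf = outdir / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=2))
    written.append(mf)
    return written


def read_labels(outdir: str | Path) -> VideoSegmentation:
    """Read a label directory written by :func:`write_labels`."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    video = VideoSegmentation()
    for t in range(manifest["n_pairs"]):
        lab_t = iio.imread(_label_path(outdir, t, t)).astype(np.int32)
        lab_t1 = iio.imread(_label_path(outdir, t, t + 1)).astype(np.int32)
        video.pairs.append(
            PairSegmentation(
                labels_t=lab_t, labels_t1=lab_t1, frame_index=t, K=manifest["K"]
            )
        )
    return video


def write_synthetic(video: SyntheticVideo, outdir: str | Path) -> tuple[Path, Path]:
    """Emit a synthetic scenario as PNG frames plus ground-truth PNGs.

    Frames go to ``<outdir>/frames/f{t:04d}.png`` (8-bit sRGB, converted
    from CIELAB); ground-truth label maps to ``<outdir>/gt/f{t:04d}.png``
    (16-bit).  Returns the two directories.
    """
    outdir = Path(outdir)
    frames_dir = outdir / "frames"
    gt_dir = outdir / "gt"
    frames_dir.mkdir(parents=True, exist_ok=True)
    gt_dir.mkdir(parents=True, exist_ok=True)
    for t, (frame, gt) in enumerate(zip(video.frames, video.gt_labels)):
        rgb8 = np.round(cielab_to_rgb(frame) * 255.0).astype(np.uint8)
        iio.imwrite(frames_dir / f"f{t:04d}.png", rgb8)
        iio.imwrite(gt_dir / f"f{t:04d}.png", gt.astype(np.uint16))
    meta = {"scenario": video.scenario, "params": video.params, "n_frames": video.n_frames}
    (outdir / "scenario.json").write_text(json.dumps(meta, indent=2, default=str))
    return frames_dir, gt_dir
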