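"""Synthetic test videos with exact per-voxel ground truth.

Three scenarios exercise the pairwise supervoxel model end to end
without any external data: a constant-color frame pair (the degenerate
case where only the spatial prior acts), a square object translating
over a uniform background (moving-object temporal consistency), and a
background-only sequence in which an object appears partway through
(new-object handling).

Colors are specified directly in CIELAB so the EM core sees exact
values; conversion to and from sRGB lives in :mod:`pairvox.io` and only
applies to real images.  Optional noise is i.i.d. Gaussian on the color
channels (spatial structure stays exact) and requires an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import InvalidParameterError

__all__ = [
    "SyntheticVideo",
    "make_constant_pair",
    "make_moving_object_video",
    "make_new_object_video",
    "DEFAULT_BG",
    "DEFAULT_FG",
]

#: Default background: a mid-dark, slightly green-ish gray.
DEFAULT_BG = (40.0, -5.0, 5.0)
#: Default object color: clearly brighter and warmer than the background
#: (CIELAB distance ~48), so object/background are unambiguous.
DEFAULT_FG = (75.0, 25.0, -15.0)


@dataclass
class SyntheticVideo:
    """Frames plus congruent ground-truth label maps.

    ``frames[t]`` is an ``(H, W, 3)`` CIELAB array; ``gt_labels[t]`` an
    ``(H, W)`` int map (0 = background; objects get 1, 2, ...).
    """

    frames: list
    gt_labels: list
    scenario: str
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _constant_frame(W: int, H: int, color) -> np.ndarray:
    return np.broadcast_to(np.asarray(color, dtype=float), (H, W, 3)).copy()


def _noise(rng: np.ndarray, frames: list, noise_sd: float) -> list:
    return [f + rng.normal(0.0, noise_sd, size=f.shape) for f in frames]


def _validate_geometry(W: int, H: int) -> None:
    if W <= 0 or H <= 0:
        raise InvalidParameterError(f"frame size must be positive, got {W}x{H}")


def _as_displacement(d) -> tuple[int, int]:
    """Scalar displacement means horizontal motion; a pair is (dx, dy)."""
    if np.isscalar(d):
        return int(d), 0
    dx, dy = d
    return int(dx), int(dy)


def make_constant_pair(W: int, H: int, color=(50.0, 0.0, 0.0)) -> SyntheticVideo:
    """Two identical constant-color frames; ground truth is one region.

    Segmenting this pair must reproduce the pure spatial prior: with
    ``vx = vy`` the exact square anchor tiling, with unequal sizes a
    rectangular tiling with the same supervoxel count.
    """
    _validate_geometry(W, H)
    frame = _constant_frame(W, H, color)
    gt = np.zeros((H, W), dtype=np.int32)
    return SyntheticVideo(
        frames=[frame, frame.copy()],
        gt_labels=[gt, gt.copy()],
        scenario="constant",
        params={"W": W, "H": H, "color": tuple(float(c) for c in np.ravel(color))},
    )


def make_moving_object_video(
    W: int,
    H: int,
    n_frames: int,
    object_size: int,
    displacement_per_frame,
    fg_color=DEFAULT_FG,
    bg_color=DEFAULT_BG,
    noise_sd: float = 0.0,
    seed: int | None = None,
    start: tuple[int, int] = (4, 4),
) -> SyntheticVideo:
    """A square object translating over a uniform background.

    The object's top-left corner starts at ``start = (x0, y0)`` and
    moves by ``displacement_per_frame`` each frame (scalar: horizontal;
    pair: ``(dx, dy)``), so the object centers form an arithmetic
    sequence.  Ground truth per frame is {0: background, 1: object}.

    Raises
    ------
    InvalidParameterError
        If the object would leave the frame on any frame, or noise is
        requested without a seed.
    """
    _validate_geometry(W, H)
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if object_size < 1 or object_size > min(W, H):
        raise InvalidParameterError(f"object_size {object_size} does not fit in {W}x{H}")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise InvalidParameterError("a seed is required for a noisy scenario")
    dx, dy = _as_displacement(displacement_per_frame)
    x0, y0 = start

    frames, gts = [], []
    for t in range(n_frames):
        x = x0 + t * dx
        y = y0 + t * dy
        if x < 0 or y < 0 or x + object_size > W or y + object_size > H:
            raise InvalidParameterError(
                f"object leaves the {W}x{H} frame at frame {t} "
                f"(top-left ({x}, {y}), size {object_size})"
            )
        frame = _constant_frame(W, H, bg_color)
        frame[y : y + object_size, x : x + object_size] = np.asarray(fg_color, dtype=float)
        gt = np.zeros((H, W), dtype=np.int32)
        gt[y : y + object_size, x : x + object_size] = 1
        frames.append(frame)
        gts.append(gt)
    if noise_sd > 0:
        frames = _noise(np.random.default_rng(seed), frames, noise_sd)
    return SyntheticVideo(
        frames=frames,
        gt_labels=gts,
        scenario="moving_object",
        params={
            "W": W,
            "H": H,
            "n_frames": n_frames,
            "object_size": object_size,
            "displacement": (dx, dy),
            "start": (int(x0), int(y0)),
            "noise_sd": float(noise_sd),
            "seed": seed,
        },
    )


def make_new_object_video(
    W: int,
    H: int,
    n_frames: int,
    appear_at_frame: int,
    object_size: int = 12,
    position: tuple[int, int] | None = None,
    fg_color=DEFAULT_FG,
    bg_color=DEFAULT_BG,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SyntheticVideo:
    """Uniform background, then a square object from ``appear_at_frame`` on.

    Ground truth has one region before the object appears and two after,
    so the pair straddling ``appear_at_frame`` exercises the new-object
    case: the supervoxels claiming the object in the later frame had
    background-only extents in the earlier one.
    """
    _validate_geometry(W, H)
    if not (0 < appear_at_frame < n_frames):
        raise InvalidParameterError(
            f"appear_at_frame must lie in (0, n_frames), got {appear_at_frame} of {n_frames}"
        )
    if object_size < 1 or object_size > min(W, H):
        raise InvalidParameterError(f"object_size {object_size} does not fit in {W}x{H}")
    if noise_sd > 0 and seed is None:
        raise InvalidParameterError("a seed is required for a noisy scenario")
    if position is None:
        position = ((W - object_size) // 2, (H - object_size) // 2)
    x0, y0 = position
    if x0 < 0 or y0 < 0 or x0 + object_size > W or y0 + object_size > H:
        raise InvalidParameterError(f"object at {position} leaves the {W}x{H} frame")

    frames, gts = [], []
    for t in range(n_frames):
        frame = _constant_frame(W, H, bg_color)
        gt = np.zeros((H, W), dtype=np.int32)
        if t >= appear_at_frame:
            frame[y0 : y0 + object_size, x0 : x0 + object_size] = np.asarray(
                fg_color, dtype=float
            )
            gt[y0 : y0 + object_size, x0 : x0 + object_size] = 1
        frames.append(frame)
        gts.append(gt)
    if noise_sd > 0:
        frames = _noise(np.random.default_rng(seed), frames, noise_sd)
    return SyntheticVideo(
        frames=frames,
        gt_labels=gts,
        scenario="new_object",
        params={
            "W": W,
            "H": H,
            "n_frames": n_frames,
            "appear_at_frame": appear_at_frame,
            "object_size": object_size,
            "position": (int(x0), int(y0)),
            "noise_sd": float(noise_sd),
            "seed": seed,
        },
    )
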