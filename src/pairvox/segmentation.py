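"""Label assignment and the pairwise sliding scheme over a video.

A video of ``|T|`` frames is segmented as ``|T| - 1`` independent frame
pairs: pair ``t`` covers frames ``t`` and ``t+1``, so every internal
frame receives two valid superpixel segmentations (one with its
predecessor, one with its successor).  Pairs share no state — results
are identical whatever order, or concurrency, they are processed in —
which is the coarse-grained parallelism of the scheme; any cross-pair
label linking is deliberately left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import AnchorMap, GridSpec, build_grid
from .vrgmm import (
    Hyperparams,
    PairFeatures,
    ParamSet,
    candidate_logdensities,
    features_from_frames,
    run_em,
)

__all__ = ["PairSegmentation", "VideoSegmentation", "assign_labels", "segment_pair", "segment_video"]


@dataclass
class PairSegmentation:
    """Supervoxel labels for one frame pair.

    ``labels_t[y, x]`` and ``labels_t1[y, x]`` are the supervoxel
    indices of voxel ``(x, y)`` in frames ``t`` and ``t+1``; both always
    lie in the voxel's candidate set, so no superpixel strays outside
    its overlap region.
    """

    labels_t: np.ndarray  # (H, W) int32
    labels_t1: np.ndarray  # (H, W) int32
    frame_index: int
    K: int


@dataclass
class VideoSegmentation:
    """One :class:`PairSegmentation` per consecutive pair, ``t = 0..|T|-2``."""

    pairs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, t: int) -> PairSegmentation:
        return self.pairs[t]


def assign_labels(
    features: PairFeatures,
    params: ParamSet,
    anchors: AnchorMap,
    frame_index: int = 0,
) -> PairSegmentation:
    """Maximum-posterior labels over each voxel's candidate set.

    With constant mixture weights the posterior argmax reduces to the
    density argmax, ``l_i = argmax_{k in Ki} g(z_i; theta_k)`` (and the
    hatted analogue for frame ``t+1``).  Candidate slots are ordered by
    ascending supervoxel index, so exact ties resolve to the smallest
    index.
    """
    logp, logp_hat = candidate_logdensities(features, params, anchors)
    grid = anchors.grid
    idx = np.arange(anchors.n_voxels)
    lab_t = anchors.voxel_candidates[idx, np.argmax(logp, axis=1)]
    lab_t1 = anchors.voxel_candidates[idx, np.argmax(logp_hat, axis=1)]
    return PairSegmentation(
        labels_t=lab_t.reshape(grid.H, grid.W).astype(np.int32),
        labels_t1=lab_t1.reshape(grid.H, grid.W).astype(np.int32),
        frame_index=frame_index,
        K=grid.K,
    )


def segment_pair(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    vx: int,
    vy: int,
    hp: Hyperparams = Hyperparams(),
    eta_x: int = 2,
    eta_y: int = 2,
    frame_index: int = 0,
    grid: GridSpec | None = None,
    anchors: AnchorMap | None = None,
) -> PairSegmentation:
    """Segment one CIELAB frame pair: grid, EM fit, then label assignment.

    ``grid``/``anchors`` may be passed in to share geometry across the
    pairs of a video; they must match the frame size.
    """
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frame pair must have identical shapes")
    if grid is None:
        H, W = frame_t.shape[:2]
        grid = build_grid(W, H, vx, vy, eta_x, eta_y)
    if anchors is None:
        anchors = AnchorMap(grid)
    params = run_em(frame_t, frame_t1, grid, hp, anchors=anchors)
    features = features_from_frames(frame_t, frame_t1)
    return assign_labels(features, params, anchors, frame_index=frame_index)


def segment_video(
    frames: Sequence[np.ndarray],
    vx: int,
    vy: int,
    hp: Hyperparams = Hyperparams(),
    eta_x: int = 2,
    eta_y: int = 2,
) -> VideoSegmentation:
    """Segment every consecutive pair of a CIELAB frame sequence.

    Pairs are mutually independent by contract: the result is identical
    regardless of processing order, so callers may parallelize at pair
    granularity.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError(f"need >= 2 frames, got {len(frames)}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"all frames must share one shape, got {sorted(map(str, shapes))}")
    H, W = frames[0].shape[:2]
    grid = build_grid(W, H, vx, vy, eta_x, eta_y)
    anchors = AnchorMap(grid)
    video = VideoSegmentation()
    for t in range(len(frames) - 1):
        video.pairs.append(
            segment_pair(
                frames[t],
                frames[t + 1],
                vx,
                vy,
                hp,
                eta_x,
                eta_y,
                frame_index=t,
                grid=grid,
                anchors=anchors,
            )
        )
    return video
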