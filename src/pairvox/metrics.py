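"""Segmentation quality metrics: boundary recall, under-segmentation
error and achievable segmentation accuracy, in 2D (per frame) and 3D
(per consecutive frame pair).

The 3D variants apply the 2D formulas to the concatenated voxel sets of
a frame pair, so a supervoxel that drifts onto a different object in the
second frame is penalized even if each frame looks fine in isolation —
they are the temporal-consistency measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter

from .segmentation import PairSegmentation, VideoSegmentation

__all__ = [
    "MetricsReport",
    "boundary_recall_2d",
    "under_segmentation_error_2d",
    "asa_2d",
    "ue_3d",
    "asa_3d",
    "evaluate_pair",
    "evaluate_video",
]

#: Fraction of a superpixel's own area it must leak into a ground-truth
#: region before counting toward that region's cover (under-segmentation).
UE_OVERLAP_FRACTION = 0.05


@dataclass
class MetricsReport:
    """Metric values for one segmented frame pair against ground truth.

    2D values are averaged over the pair's two frames; 3D values are
    computed on the concatenated pair.  ``n_superpixels`` is the average
    number of distinct labels per frame.
    """

    br_2d: float
    ue_2d: float
    asa_2d: float
    ue_3d: float
    asa_3d: float
    n_superpixels: float


def _check_shapes(seg: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: segmentation {seg.shape} vs ground truth {gt.shape}")
    return seg, gt


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels with a 4-neighbor of different label."""
    b = np.zeros(labels.shape, dtype=bool)
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    b[1:, :] |= labels[1:, :] != labels[:-1, :]
    return b


def boundary_recall_2d(seg: np.ndarray, gt: np.ndarray, tol: int = 2) -> float:
    """Fraction of ground-truth boundary pixels within ``tol`` pixels
    (Chebyshev distance) of a segmentation boundary pixel.

    A ground truth with no boundary at all (a single region) is
    vacuously recalled: returns 1.0.
    """
    seg, gt = _check_shapes(seg, gt)
    gt_b = _boundary_mask(gt)
    n_gt = int(gt_b.sum())
    if n_gt == 0:
        return 1.0
    seg_near = maximum_filter(_boundary_mask(seg).astype(np.uint8), size=2 * tol + 1)
    return float(seg_near[gt_b].sum()) / n_gt


def _contingency(seg: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Overlap table ``n[k, j] = |s_k intersect g_j|`` over relabelled ids."""
    _, seg_i = np.unique(seg.ravel(), return_inverse=True)
    _, gt_i = np.unique(gt.ravel(), return_inverse=True)
    n_s, n_g = seg_i.max() + 1, gt_i.max() + 1
    return np.bincount(seg_i * n_g + gt_i, minlength=n_s * n_g).reshape(n_s, n_g)


def _ue(seg: np.ndarray, gt: np.ndarray) -> float:
    tab = _contingency(seg, gt)
    sizes = tab.sum(axis=1)  # |s_k|
    N = int(sizes.sum())
    # s_k counts toward g_j's cover iff its overlap strictly exceeds 5% of |s_k|
    counted = tab > UE_OVERLAP_FRACTION * sizes[:, None]
    total = float((counted * sizes[:, None]).sum())
    return (total - N) / N


def _asa(seg: np.ndarray, gt: np.ndarray) -> float:
    tab = _contingency(seg, gt)
    return float(tab.max(axis=1).sum()) / tab.sum()


def under_segmentation_error_2d(seg: np.ndarray, gt: np.ndarray) -> float:
    """Leakage of superpixels across ground-truth boundaries.

    ``UE = (sum_{g_j} sum_{k : |s_k ∩ g_j| > 0.05 |s_k|} |s_k| - |I|) / |I|``:
    each ground-truth region is covered by the superpixels overlapping
    it by more than 5 % of their own area, and UE charges the pixels the
    cover adds beyond the frame itself.  Zero when every superpixel sits
    inside one region.
    """
    seg, gt = _check_shapes(seg, gt)
    return _ue(seg, gt)


def asa_2d(seg: np.ndarray, gt: np.ndarray) -> float:
    """Achievable segmentation accuracy: fraction of pixels correct when
    every superpixel takes the label of its best-overlapping ground-truth
    region, ``ASA = (1/|I|) sum_k max_j |s_k ∩ g_j|``."""
    seg, gt = _check_shapes(seg, gt)
    return _asa(seg, gt)


def _pair_arrays(
    pair_seg: PairSegmentation | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pair_seg, PairSegmentation):
        return pair_seg.labels_t, pair_seg.labels_t1
    a, b = pair_seg
    return np.asarray(a), np.asarray(b)


def ue_3d(
    pair_seg: PairSegmentation | tuple[np.ndarray, np.ndarray],
    gt_pair: tuple[np.ndarray, np.ndarray],
) -> float:
    """Under-segmentation error on the concatenated voxels of a frame
    pair: supervoxels and ground-truth regions each pool both frames, and
    ``|I|`` becomes the two-frame voxel count."""
    seg_t, seg_t1 = _pair_arrays(pair_seg)
    gt_t, gt_t1 = np.asarray(gt_pair[0]), np.asarray(gt_pair[1])
    _check_shapes(seg_t, gt_t)
    _check_shapes(seg_t1, gt_t1)
    return _ue(np.stack([seg_t, seg_t1]), np.stack([gt_t, gt_t1]))


def asa_3d(
    pair_seg: PairSegmentation | tuple[np.ndarray, np.ndarray],
    gt_pair: tuple[np.ndarray, np.ndarray],
) -> float:
    """Achievable segmentation accuracy on the concatenated frame pair."""
    seg_t, seg_t1 = _pair_arrays(pair_seg)
    gt_t, gt_t1 = np.asarray(gt_pair[0]), np.asarray(gt_pair[1])
    _check_shapes(seg_t, gt_t)
    _check_shapes(seg_t1, gt_t1)
    return _asa(np.stack([seg_t, seg_t1]), np.stack([gt_t, gt_t1]))


def evaluate_pair(
    pair_seg: PairSegmentation | tuple[np.ndarray, np.ndarray],
    gt_pair: tuple[np.ndarray, np.ndarray],
    tol: int = 2,
) -> MetricsReport:
    """All metrics for one segmented pair; 2D values average both frames."""
    seg_t, seg_t1 = _pair_arrays(pair_seg)
    gt_t, gt_t1 = np.asarray(gt_pair[0]), np.asarray(gt_pair[1])
    return MetricsReport(
        br_2d=0.5 * (boundary_recall_2d(seg_t, gt_t, tol) + boundary_recall_2d(seg_t1, gt_t1, tol)),
        ue_2d=0.5
        * (under_segmentation_error_2d(seg_t, gt_t) + under_segmentation_error_2d(seg_t1, gt_t1)),
        asa_2d=0.5 * (asa_2d(seg_t, gt_t) + asa_2d(seg_t1, gt_t1)),
        ue_3d=ue_3d(pair_seg, gt_pair),
        asa_3d=asa_3d(pair_seg, gt_pair),
        n_superpixels=0.5 * (len(np.unique(seg_t)) + len(np.unique(seg_t1))),
    )


def evaluate_video(
    video_seg: VideoSegmentation, gt_frames: Sequence[np.ndarray], tol: int = 2
) -> list[MetricsReport]:
    """Per-pair metric reports for a whole video.

    ``gt_frames`` holds one ground-truth label map per frame; pair ``t``
    is evaluated against frames ``t`` and ``t+1``.  Video-level numbers
    are the plain means over these per-pair reports.
    """
    if len(gt_frames) != len(video_seg) + 1:
        raise ValueError(
            f"need one ground-truth map per frame: {len(video_seg) + 1} expected, "
            f"got {len(gt_frames)}"
        )
    return [
        evaluate_pair(pair, (gt_frames[t], gt_frames[t + 1]), tol)
        for t, pair in enumerate(video_seg)
    ]
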