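"""Independent brute-force references used by the test suite.

Everything here is written with plain Python loops, explicit matrix
inverses/determinants and dense per-voxel tables — deliberately naive and
structurally unrelated to the vectorized implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

from pairvox.grid import GridSpec, anchor_label, candidate_set, overlap_region


def dense_gaussian(z, mu, Sigma):
    """Multivariate normal density via explicit inverse and determinant."""
    z = np.asarray(z, float)
    mu = np.asarray(mu, float)
    Sigma = np.asarray(Sigma, float)
    D = len(mu)
    diff = z - mu
    quad = float(diff @ np.linalg.inv(Sigma) @ diff)
    norm = 1.0 / math.sqrt((2.0 * math.pi) ** D * np.linalg.det(Sigma))
    return norm * math.exp(-0.5 * quad)


def voxel_features(frame_t, frame_t1):
    """Per-voxel (spatial, color_t, color_t1) lists in row-major order."""
    H, W = frame_t.shape[:2]
    feats = []
    for y in range(H):
        for x in range(W):
            feats.append(
                (
                    np.array([x, y], float),
                    np.asarray(frame_t[y, x], float),
                    np.asarray(frame_t1[y, x], float),
                )
            )
    return feats


def density_tables(frame_t, frame_t1, params, grid: GridSpec):
    """Dense per-voxel candidate density tables for both frames."""
    feats = voxel_features(frame_t, frame_t1)
    tables = []
    for i, (zs, zc, zch) in enumerate(feats):
        x, y = int(zs[0]), int(zs[1])
        Ki = list(candidate_set(anchor_label(x, y, grid), grid))
        row, row_hat = {}, {}
        for k in Ki:
            row[k] = dense_gaussian(zs, params.mu_s[k], params.Sigma_s[k]) * dense_gaussian(
                zc, params.mu_c[k], params.Sigma_c[k]
            )
            row_hat[k] = dense_gaussian(
                zs, params.mu_s_hat[k], params.Sigma_s_hat[k]
            ) * dense_gaussian(zch, params.mu_c[k], params.Sigma_c[k])
        tables.append((Ki, row, row_hat))
    return tables


def brute_e_step(frame_t, frame_t1, params, grid: GridSpec):
    """Responsibilities by direct normalization of dense density tables.

    Returns two lists of dicts ``k -> R`` (frame t, frame t+1), one per voxel.
    """
    R, R_hat = [], []
    for Ki, row, row_hat in density_tables(frame_t, frame_t1, params, grid):
        s = sum(row.values())
        sh = sum(row_hat.values())
        R.append({k: row[k] / s for k in Ki})
        R_hat.append({k: row_hat[k] / sh for k in Ki})
    return R, R_hat


def brute_log_likelihood(frame_t, frame_t1, params, grid: GridSpec):
    total = 0.0
    for _, row, row_hat in density_tables(frame_t, frame_t1, params, grid):
        total += math.log(sum(row.values())) + math.log(sum(row_hat.values()))
    return total


def floor_eigenvalues(Sigma, floor):
    """Eigenvalue flooring by explicit eigendecomposition of one matrix."""
    sym = 0.5 * (Sigma + Sigma.T)
    w, V = np.linalg.eigh(sym)
    w = np.maximum(w, floor)
    return V @ np.diag(w) @ V.T


def brute_m_step(frame_t, frame_t1, R, R_hat, grid: GridSpec, hp):
    """Weighted-moment parameter update with centered covariances.

    ``R``/``R_hat`` are per-voxel dicts as returned by brute_e_step.
    Returns dict of parameter arrays keyed like ParamSet fields.
    """
    feats = voxel_features(frame_t, frame_t1)
    K = grid.K
    out = {
        "mu_s": np.zeros((K, 2)),
        "Sigma_s": np.zeros((K, 2, 2)),
        "mu_s_hat": np.zeros((K, 2)),
        "Sigma_s_hat": np.zeros((K, 2, 2)),
        "mu_c": np.zeros((K, 3)),
        "Sigma_c": np.zeros((K, 3, 3)),
    }
    for k in range(K):
        Ik = list(overlap_region(k, grid))
        w = np.array([R[i].get(k, 0.0) for i in Ik])
        wh = np.array([R_hat[i].get(k, 0.0) for i in Ik])
        zs = np.array([feats[i][0] for i in Ik])
        zc = np.array([feats[i][1] for i in Ik])
        zch = np.array([feats[i][2] for i in Ik])

        mu_s = (w[:, None] * zs).sum(0) / w.sum()
        d = zs - mu_s
        Sig_s = sum(w[j] * np.outer(d[j], d[j]) for j in range(len(Ik))) / w.sum()
        mu_sh = (wh[:, None] * zs).sum(0) / wh.sum()
        dh = zs - mu_sh
        Sig_sh = sum(wh[j] * np.outer(dh[j], dh[j]) for j in range(len(Ik))) / wh.sum()

        wc = w.sum() + wh.sum()
        mu_c = ((w[:, None] * zc).sum(0) + (wh[:, None] * zch).sum(0)) / wc
        dc = zc - mu_c
        dch = zch - mu_c
        Sig_c = (
            sum(w[j] * np.outer(dc[j], dc[j]) for j in range(len(Ik)))
            + sum(wh[j] * np.outer(dch[j], dch[j]) for j in range(len(Ik)))
        ) / wc

        out["mu_s"][k] = mu_s
        out["Sigma_s"][k] = floor_eigenvalues(Sig_s, hp.lambda_s)
        out["mu_s_hat"][k] = mu_sh
        out["Sigma_s_hat"][k] = floor_eigenvalues(Sig_sh, hp.lambda_s)
        out["mu_c"][k] = mu_c
        out["Sigma_c"][k] = floor_eigenvalues(Sig_c, hp.lambda_c)
    return out


def brute_assign(frame_t, frame_t1, params, grid: GridSpec):
    """Per-voxel density argmax with smallest-index tie-break."""
    H, W = frame_t.shape[:2]
    lab = np.zeros((H, W), int)
    lab_hat = np.zeros((H, W), int)
    for (Ki, row, row_hat), i in zip(
        density_tables(frame_t, frame_t1, params, grid), range(H * W)
    ):
        y, x = divmod(i, W)
        lab[y, x] = max(Ki, key=lambda k: (row[k], -k))
        lab_hat[y, x] = max(Ki, key=lambda k: (row_hat[k], -k))
    return lab, lab_hat


# ---------------------------------------------------------------- metrics


def overlap_table(seg, gt):
    """Dict table ``(s_label, g_label) -> count`` by per-pixel loops."""
    tab = {}
    for s, g in zip(np.ravel(seg), np.ravel(gt)):
        tab[(int(s), int(g))] = tab.get((int(s), int(g)), 0) + 1
    return tab


def brute_ue(seg, gt):
    tab = overlap_table(seg, gt)
    sizes = {}
    for (s, _), n in tab.items():
        sizes[s] = sizes.get(s, 0) + n
    N = sum(sizes.values())
    total = 0
    gt_labels = {g for (_, g) in tab}
    for g in gt_labels:
        for s, size in sizes.items():
            if tab.get((s, g), 0) > 0.05 * size:
                total += size
    return (total - N) / N


def brute_asa(seg, gt):
    tab = overlap_table(seg, gt)
    best = {}
    for (s, _), n in tab.items():
        best[s] = max(best.get(s, 0), n)
    N = sum(tab.values())
    return sum(best.values()) / N


def brute_boundary_recall(seg, gt, tol=2):
    H, W = np.asarray(gt).shape
    seg = np.asarray(seg)
    gt = np.asarray(gt)

    def boundary(lbl):
        pts = []
        for y in range(H):
            for x in range(W):
                for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W and lbl[yy, xx] != lbl[y, x]:
                        pts.append((y, x))
                        break
        return pts

    gt_b = boundary(gt)
    if not gt_b:
        return 1.0
    seg_b = boundary(seg)
    hit = 0
    for y, x in gt_b:
        if any(max(abs(y - yy), abs(x - xx)) <= tol for yy, xx in seg_b):
            hit += 1
    return hit / len(gt_b)
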