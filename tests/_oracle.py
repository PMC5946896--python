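"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: explicit loops over centres, offsets, folds and
training exemplars, no shared code with the package's vectorized paths.
"""

import numpy as np


def brute_sphere_offsets(radius):
    out = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    out.append((dx, dy, dz))
    return out


def brute_nearest_neighbour(train_X, train_y, test_X):
    """1-NN with Euclidean distance; ties go to the earliest training row."""
    preds = []
    for t in test_X:
        best_j, best_d = 0, None
        for j, r in enumerate(train_X):
            d = float(np.sqrt(((t - r) ** 2).sum()))
            if best_d is None or d < best_d - 0.0:
                best_j, best_d = j, d
        preds.append(train_y[best_j])
    return np.array(preds)


def brute_searchlight(dataset, subject, scheme, radius, min_voxels, zscore=True):
    """Per-centre pooled fold accuracy, direction-averaged; NaN where the
    sphere holds fewer than min_voxels in-mask voxels."""
    mask = dataset.mask
    shape = mask.shape
    offsets = brute_sphere_offsets(radius)
    acc = np.full(shape, np.nan)
    for cx in range(shape[0]):
        for cy in range(shape[1]):
            for cz in range(shape[2]):
                if not mask[cx, cy, cz]:
                    continue
                vox = []
                for dx, dy, dz in offsets:
                    x, y, z = cx + dx, cy + dy, cz + dz
                    if 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]:
                        if mask[x, y, z]:
                            vox.append((x, y, z))
                if len(vox) < min_voxels:
                    continue
                flat = np.flatnonzero(mask.reshape(-1))
                lookup = {tuple(np.unravel_index(f, shape)): i for i, f in enumerate(flat)}
                idx = [lookup[v] for v in vox]
                direction_accs = []
                for direction in scheme.directions():
                    correct = total = 0
                    for train_runs, test_runs in direction.folds:
                        Xtr, ytr, _ = dataset.patterns(
                            subject, direction.train_task, direction.train_language, train_runs
                        )
                        Xte, yte, _ = dataset.patterns(
                            subject, direction.test_task, direction.test_language, test_runs
                        )
                        Xtr, Xte = Xtr[:, idx], Xte[:, idx]
                        if zscore:
                            mu, sdv = Xtr.mean(0), Xtr.std(0)
                            sdv = np.where(sdv < 1e-12, 1.0, sdv)
                            Xtr, Xte = (Xtr - mu) / sdv, (Xte - mu) / sdv
                        pred = brute_nearest_neighbour(Xtr, ytr, Xte)
                        correct += int((pred == yte).sum())
                        total += len(yte)
                    direction_accs.append(correct / total)
                acc[cx, cy, cz] = float(np.mean(direction_accs))
    return acc
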