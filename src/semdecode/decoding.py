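"""Searchlight and ROI pattern classification with cross-language /
cross-modality train-test schemes.

A classifier is trained on the per-concept activation patterns of one
condition cell (task, language, training runs) and tested on another
(typically the other language, held-out run), fold by fold; above-chance
transfer indicates representational structure shared across the two
cells.  The searchlight slides a radius-3-voxel sphere over the grid and
performs this classification on each sphere's voxels, producing one
accuracy map per subject and scheme.  Each scheme carries a mirrored
direction (e.g. train L1 -> test L2 and train L2 -> test L1) whose maps
are averaged.

The classifier is k-nearest-neighbours (default k=1, Euclidean distance
on per-voxel z-scored patterns; scaling statistics come from the training
folds only).  Ties are deterministic: distance ties resolve by training
order, vote ties by the smallest concept label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .dataset import BetaPatternDataset
from .geometry import VolumeGeometry

__all__ = [
    "sphere_offsets",
    "Searchlight",
    "KNNSettings",
    "knn_classify",
    "DecodingScheme",
    "make_cross_language_scheme",
    "make_cross_modality_scheme",
    "make_within_language_scheme",
    "AccuracyMap",
    "run_searchlight",
    "smooth_map",
]


def sphere_offsets(radius_vox: int) -> np.ndarray:
    """All integer offsets (dx, dy, dz) with dx²+dy²+dz² <= radius²,
    ordered lexicographically.  Radius 0 gives just the centre; radius 3
    gives 123 offsets."""
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius_vox)
    axis = np.arange(-r, r + 1)
    grid = np.array(list(itertools.product(axis, axis, axis)))
    return grid[(grid**2).sum(axis=1) <= r * r]


@dataclass(frozen=True)
class Searchlight:
    """Spherical neighbourhood definition: radius in voxels (default 3)
    and the minimum number of in-mask voxels a sphere needs for its centre
    to be evaluated (centres below that are undefined, not zero)."""

    radius_vox: int = 3
    min_voxels: int = 10

    @property
    def offsets(self) -> np.ndarray:
        return sphere_offsets(self.radius_vox)

    def kernel(self) -> np.ndarray:
        """0/1 indicator kernel of the sphere, shape (2r+1,)*3."""
        r = self.radius_vox
        k = np.zeros((2 * r + 1,) * 3)
        off = self.offsets
        k[off[:, 0] + r, off[:, 1] + r, off[:, 2] + r] = 1.0
        return k


@dataclass(frozen=True)
class KNNSettings:
    """k-NN classifier settings: neighbour count, distance metric and
    whether to z-score each feature using training-fold statistics."""

    k: int = 1
    metric: str = "euclidean"
    zscore: bool = True


def knn_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int = 1,
    metric: str = "euclidean",
) -> np.ndarray:
    """Majority vote of the k nearest training exemplars.

    Deterministic tie handling: neighbours at equal distance are taken in
    training order (stable sort); tied votes go to the smallest label.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.size == 0 or len(train_X) == 0:
        raise ValueError("empty training set")
    if len(train_X) < k:
        raise ValueError(f"need at least k={k} training exemplars, have {len(train_X)}")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    D = cdist(test_X, train_X, metric=metric)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    neigh = train_y[order]  # (n_test, k)
    classes = np.unique(train_y)
    votes = (neigh[:, :, None] == classes[None, None, :]).sum(axis=1)
    return classes[np.argmax(votes, axis=1)]


# ---------------------------------------------------------------------------
# train/test schemes


@dataclass(frozen=True)
class DecodingScheme:
    """Declarative train/test fold specification.

    ``folds`` is a tuple of ``(train_runs, test_runs)`` pairs; training
    patterns come from cell (train_task, train_language) restricted to
    train_runs, test patterns from (test_task, test_language, test_runs).
    ``direction_pair`` is the mirrored scheme whose accuracy map is
    averaged with this one.  Chance level is 1 / n_concepts.
    """

    train_task: str
    train_language: str
    test_task: str
    test_language: str
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    direction_pair: "DecodingScheme | None" = None
    name: str = ""
    lexically_confounded: bool = False

    def __post_init__(self) -> None:
        if not self.folds:
            raise ValueError("scheme needs at least one fold")
        same_cell = (self.train_task == self.test_task
                     and self.train_language == self.test_language)
        for train_runs, test_runs in self.folds:
            if same_cell and set(train_runs) & set(test_runs):
                raise ValueError(
                    "train and test share a (task, language, run) cell within a fold"
                )

    def directions(self) -> tuple["DecodingScheme", ...]:
        return (self,) if self.direction_pair is None else (self, self.direction_pair)


def _loro_folds(n_runs: int) -> tuple:
    """Leave-one-run-out: train on n-1 runs, test on the held-out run."""
    runs = tuple(range(n_runs))
    return tuple(
        (tuple(x for x in runs if x != r), (r,)) for r in runs
    )


def make_cross_language_scheme(task: str, n_runs: int = 5) -> DecodingScheme:
    """Within-task, cross-language transfer: train on 4 of the 5 runs in
    one language, test on the held-out run of the *other* language; 5
    folds per direction, both directions averaged."""
    folds = _loro_folds(n_runs)
    back = DecodingScheme(
        train_task=task, train_language="L2", test_task=task, test_language="L1",
        folds=folds, name=f"cross_language:{task}:L2->L1",
    )
    return DecodingScheme(
        train_task=task, train_language="L1", test_task=task, test_language="L2",
        folds=folds, direction_pair=back, name=f"cross_language:{task}",
    )


def make_cross_modality_scheme(
    task_a: str, task_b: str, n_runs: int = 5, all_runs: bool = False
) -> DecodingScheme:
    """Cross-task *and* cross-language transfer: train on task A in L1,
    test on task B in L2 (and the mirrored direction).  By default run-wise
    folds are kept (train 4 runs of A, test the held-out run of B) for
    comparability with the within-task scheme; ``all_runs=True`` trains on
    all runs and tests on all runs, which is valid because the cells differ
    in both task and language."""
    if task_a == task_b:
        raise ValueError(
            "cross-modality scheme needs two different tasks; use "
            "make_cross_language_scheme for within-task transfer"
        )
    if all_runs:
        folds = ((tuple(range(n_runs)), tuple(range(n_runs))),)
    else:
        folds = _loro_folds(n_runs)
    back = DecodingScheme(
        train_task=task_b, train_language="L2", test_task=task_a, test_language="L1",
        folds=folds, name=f"cross_modality:{task_b}.L2->{task_a}.L1",
    )
    return DecodingScheme(
        train_task=task_a, train_language="L1", test_task=task_b, test_language="L2",
        folds=folds, direction_pair=back, name=f"cross_modality:{task_a}->{task_b}",
    )


def make_within_language_scheme(task: str, language: str = "L1", n_runs: int = 5) -> DecodingScheme:
    """Within-task, within-language decoding.  Flagged lexically
    confounded: within one language, semantic overlap cannot be told apart
    from lexical overlap, so reports must carry the caveat."""
    return DecodingScheme(
        train_task=task, train_language=language, test_task=task, test_language=language,
        folds=_loro_folds(n_runs), name=f"within_language:{task}:{language}",
        lexically_confounded=True,
    )


# ---------------------------------------------------------------------------
# accuracy maps


@dataclass
class AccuracyMap:
    """Per-voxel mean cross-validated decoding accuracy for one subject
    and scheme.  ``data`` is a 3-D float array in [0, 1], NaN where
    undefined (outside the mask or sphere below min_voxels)."""

    geometry: VolumeGeometry
    mask: np.ndarray
    data: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("accuracies must lie in [0, 1]")

    def mean(self) -> float:
        return float(np.nanmean(self.data[self.mask]))

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.geometry.affine), path)

    @classmethod
    def from_nifti(cls, path, provenance: dict | None = None) -> "AccuracyMap":
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        geom = VolumeGeometry(shape=data.shape, affine=img.affine)
        return cls(geometry=geom, mask=np.isfinite(data), data=data,
                   provenance=provenance or {})


def _zscore_from_train(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _fold_patterns(dataset: BetaPatternDataset, subject: int, scheme: DecodingScheme, fold):
    train_runs, test_runs = fold
    Xtr, ytr, _ = dataset.patterns(subject, scheme.train_task, scheme.train_language, train_runs)
    Xte, yte, _ = dataset.patterns(subject, scheme.test_task, scheme.test_language, test_runs)
    return Xtr, ytr, Xte, yte


def _sphere_runs(radius_vox: int) -> list[tuple[int, int, int]]:
    """Decompose the sphere into contiguous x-runs: for every (dy, dz)
    with dy²+dz² <= r², the run spans dx in [-lx, lx] with
    lx = floor(sqrt(r² - dy² - dz²))."""
    r = int(radius_vox)
    runs = []
    for dy in range(-r, r + 1):
        for dz in range(-r, r + 1):
            rem = r * r - dy * dy - dz * dz
            if rem >= 0:
                runs.append((dy, dz, int(np.floor(np.sqrt(rem)))))
    return runs


def _sphere_sums(vols: np.ndarray, radius_vox: int) -> np.ndarray:
    """Sum of each volume over the sphere around every voxel (volume edges
    behave as zeros).  Batched cumulative sums along x turn each x-run of
    the sphere into a two-slice difference, which is much cheaper than an
    explicit 3-D convolution."""
    r = int(radius_vox)
    B = vols.shape[0]
    nx, ny, nz = vols.shape[1:]
    pad = np.zeros((B, nx + 2 * r + 1, ny + 2 * r, nz + 2 * r), dtype=vols.dtype)
    pad[:, r + 1 : r + 1 + nx, r : r + ny, r : r + nz] = vols
    C = np.cumsum(pad, axis=1)
    out = np.zeros_like(vols)
    for dy, dz, lx in _sphere_runs(r):
        ys, zs = slice(r + dy, r + dy + ny), slice(r + dz, r + dz + nz)
        out += C[:, r + 1 + lx : r + 1 + lx + nx, ys, zs]
        out -= C[:, r - lx : r - lx + nx, ys, zs]
    return out


def _searchlight_fold_euclidean(
    Xtr, ytr, Xte, yte, mask, radius_vox: int, settings: KNNSettings
):
    """Per-centre correct counts for one fold, vectorized over centres.

    Squared Euclidean distances over each sphere are assembled from
    sphere-summed squares and cross products:
    ``D = sum(t²) + sum(r²) - 2 sum(t·r)``.
    Sums are accumulated in single precision; only the argmin over
    training patterns matters, so this does not move predictions except
    on exact distance ties, which the stable ordering resolves.
    Returns (correct_counts (n_centres,), n_test).
    """
    shape = mask.shape
    if settings.zscore:
        Xtr, Xte = _zscore_from_train(Xtr, Xte)
    Xtr = np.asarray(Xtr, dtype=np.float32)
    Xte = np.asarray(Xte, dtype=np.float32)
    n_tr, n_te = len(Xtr), len(Xte)
    trv = np.zeros((n_tr,) + shape, dtype=np.float32)
    tev = np.zeros((n_te,) + shape, dtype=np.float32)
    trv[:, mask] = Xtr
    tev[:, mask] = Xte
    cross = (tev[:, None] * trv[None, :]).reshape((n_te * n_tr,) + shape)
    batch = np.concatenate([cross, tev**2, trv**2], axis=0)
    sums = _sphere_sums(batch, radius_vox)
    s_cross = sums[: n_te * n_tr].reshape((n_te, n_tr) + shape)
    s_t2 = sums[n_te * n_tr : n_te * n_tr + n_te]
    s_r2 = sums[n_te * n_tr + n_te :]
    D = s_t2[:, None] + s_r2[None, :] - 2.0 * s_cross  # (n_te, n_tr, nx, ny, nz)
    D = np.moveaxis(D[:, :, mask], 2, 0)  # (n_centres, n_te, n_tr)
    classes = np.unique(ytr)
    if settings.k == 1:
        pred = ytr[np.argmin(D, axis=2)]  # (n_centres, n_te)
    else:
        order = np.argsort(D, axis=2, kind="stable")[:, :, : settings.k]
        neigh = ytr[order]
        votes = (neigh[..., None] == classes[None, None, None, :]).sum(axis=2)
        pred = classes[np.argmax(votes, axis=2)]
    correct = (pred == yte[None, :]).sum(axis=1)
    return correct, n_te


def run_searchlight(
    dataset: BetaPatternDataset,
    subject: int,
    scheme: DecodingScheme,
    searchlight: Searchlight | None = None,
    settings: KNNSettings | None = None,
) -> AccuracyMap:
    """Whole-volume searchlight cross-classification for one subject.

    For each in-mask centre whose sphere holds at least ``min_voxels``
    in-mask voxels, the accuracy is the pooled fraction of correct test
    predictions over the scheme's folds; if the scheme has a mirrored
    direction the two directions' maps are averaged.  Centres with too few
    voxels are NaN (undefined), never zero.
    """
    searchlight = searchlight or Searchlight()
    settings = settings or KNNSettings()
    mask = dataset.mask
    n_in_sphere = _sphere_sums(mask[None].astype(float), searchlight.radius_vox)[0]
    valid = mask & (np.round(n_in_sphere) >= searchlight.min_voxels)
    valid_flat = valid[mask]

    direction_maps = []
    for direction in scheme.directions():
        correct = np.zeros(int(mask.sum()))
        total = 0
        for fold in direction.folds:
            Xtr, ytr, Xte, yte = _fold_patterns(dataset, subject, direction, fold)
            if settings.metric == "euclidean":
                c, n_te = _searchlight_fold_euclidean(
                    Xtr, ytr, Xte, yte, mask, searchlight.radius_vox, settings
                )
            else:
                c, n_te = _searchlight_fold_generic(
                    Xtr, ytr, Xte, yte, mask, searchlight, settings
                )
            correct += c
            total += n_te
        direction_maps.append(correct / total)

    acc_flat = np.mean(direction_maps, axis=0)
    data = np.full(dataset.geometry.shape, np.nan)
    data[mask] = np.where(valid_flat, acc_flat, np.nan)
    return AccuracyMap(
        geometry=dataset.geometry, mask=valid, data=data,
        provenance={
            "subject": subject, "scheme": scheme.name,
            "radius_vox": searchlight.radius_vox, "min_voxels": searchlight.min_voxels,
            "k": settings.k, "metric": settings.metric, "zscore": settings.zscore,
            "lexically_confounded": scheme.lexically_confounded,
        },
    )


def _searchlight_fold_generic(Xtr, ytr, Xte, yte, mask, searchlight, settings):
    """Reference path for non-Euclidean metrics: loop over centres."""
    shape = mask.shape
    if settings.zscore:
        Xtr, Xte = _zscore_from_train(Xtr, Xte)
    flat_index = -np.ones(shape, dtype=int)
    flat_index[mask] = np.arange(int(mask.sum()))
    offsets = searchlight.offsets
    centres = np.argwhere(mask)
    correct = np.zeros(int(mask.sum()))
    for ci, centre in enumerate(centres):
        pos = centre[None, :] + offsets
        ok = (pos >= 0).all(axis=1) & (pos < np.asarray(shape)[None, :]).all(axis=1)
        pos = pos[ok]
        idx = flat_index[pos[:, 0], pos[:, 1], pos[:, 2]]
        idx = idx[idx >= 0]
        if idx.size == 0:
            continue
        pred = knn_classify(Xtr[:, idx], ytr, Xte[:, idx], k=settings.k, metric=settings.metric)
        correct[ci] = (pred == yte).sum()
    return correct, len(Xte)


def smooth_map(amap: AccuracyMap, fwhm_mm: float) -> AccuracyMap:
    """Gaussian-smooth an accuracy map (sigma = fwhm / (2 sqrt(2 ln 2)) per
    axis, in mm), with mask-aware renormalization so values near mask edges
    and undefined voxels do not bleed in.  fwhm = 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return amap
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / amap.geometry.voxel_size
    defined = amap.mask & np.isfinite(amap.data)
    num = np.where(defined, np.nan_to_num(amap.data), 0.0)
    num = gaussian_filter(num, sigma=sigma_vox, mode="constant", truncate=6.0)
    den = gaussian_filter(defined.astype(float), sigma=sigma_vox, mode="constant", truncate=6.0)
    out = np.full(amap.geometry.shape, np.nan)
    out[defined] = num[defined] / den[defined]
    prov = dict(amap.provenance)
    prov["smoothed_fwhm_mm"] = fwhm_mm
    return AccuracyMap(geometry=amap.geometry, mask=defined, data=out, provenance=prov)
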