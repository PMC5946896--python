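"""Region-of-interest decoding with a permutation + bootstrap group null.

Each ROI (a sphere around a world-mm coordinate, or an explicit mask) is
decoded as a single pooled feature vector — no searchlight — with the
same cross-validated scheme and classifier as the whole-brain analysis.
Group-level significance follows the Stelzer-style recipe: concept labels
are permuted within each run to obtain P chance accuracies per subject
(default P = 100); drawing one chance accuracy per subject and averaging,
B times (default B = 10000), builds the group-level null distribution;
``p = (1 + #{null >= observed}) / (1 + B)``.  Across ROIs, p-values are
FDR-corrected (Benjamini-Hochberg, q = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataset import BetaPatternDataset
from .decoding import DecodingScheme, KNNSettings, knn_classify
from .geometry import VolumeGeometry

__all__ = [
    "ROISpec",
    "builtin_rois",
    "roi_accuracy",
    "NullDistribution",
    "PermutationResult",
    "permutation_bootstrap_p",
    "fdr_correct",
    "roi_table",
]


@dataclass(frozen=True)
class ROISpec:
    """A named region: sphere of ``radius_mm`` around ``center_mm`` (world
    coordinates), or an explicit boolean mask volume."""

    name: str
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float = 8.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            if self.center_mm is None:
                raise ValueError("give either a center or an explicit mask")
            if self.radius_mm <= 0:
                raise ValueError("radius must be > 0")
        elif not np.asarray(self.mask).any():
            raise ValueError("explicit ROI mask is empty")

    def resolve_mask(self, geometry: VolumeGeometry) -> np.ndarray:
        """Boolean voxel mask of the ROI on the given grid."""
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != geometry.shape:
                raise ValueError("explicit ROI mask shape mismatch")
            return mask
        coords = geometry.world_coordinates()
        d2 = ((coords - np.asarray(self.center_mm)) ** 2).sum(axis=-1)
        mask = d2 <= self.radius_mm**2
        if not mask.any():
            raise ValueError(f"ROI {self.name!r} resolves to no voxels on this grid")
        return mask

    def to_nifti(self, geometry: VolumeGeometry, path) -> None:
        nib.save(
            nib.Nifti1Image(self.resolve_mask(geometry).astype(np.uint8), geometry.affine),
            path,
        )

    @classmethod
    def from_nifti(cls, path, name: str | None = None) -> "ROISpec":
        img = nib.load(path)
        return cls(name=name or str(path), mask=np.asarray(img.dataobj).astype(bool))


#: Five regions previously associated with first-language semantic
#: processing of written words (MNI mm): left inferior frontal gyrus,
#: left middle temporal gyrus, cerebellum, left superior motor area,
#: left middle frontal gyrus.
_BUILTIN = (
    ("left_inferior_frontal_gyrus", (-45.0, 23.0, 12.0)),
    ("left_middle_temporal_gyrus", (-56.0, -44.0, 4.0)),
    ("cerebellum", (20.0, -78.0, -35.0)),
    ("left_superior_motor_area", (-3.0, 16.0, 53.0)),
    ("left_middle_frontal_gyrus", (-27.0, 13.0, 52.0)),
)


def builtin_rois(radius_mm: float = 8.0) -> list[ROISpec]:
    """The five semantic-network ROIs with their standard-space centres.

    The originating study supplies only peak coordinates, so the default
    extent is a transparent stand-in: an 8 mm radius sphere.
    """
    return [ROISpec(name=n, center_mm=c, radius_mm=radius_mm) for n, c in _BUILTIN]


# ---------------------------------------------------------------------------


class _RoiPatterns:
    """Cached per-cell ROI pattern matrices for one subject.

    Holds a (n_concepts, n_roi_voxels) matrix per (task, language, run)
    cell touched by the scheme, so label permutations and cross-validation
    folds reuse the same extracted data.
    """

    def __init__(self, dataset: BetaPatternDataset, subject: int,
                 roi: ROISpec, scheme: DecodingScheme):
        roi_mask = roi.resolve_mask(dataset.geometry)
        inter = roi_mask & dataset.mask
        if not inter.any():
            raise ValueError(f"ROI {roi.name!r} does not intersect the data mask")
        self.feature_index = inter[dataset.mask]
        self.n_concepts = dataset.n_concepts
        self.cells: dict = {}
        for direction in scheme.directions():
            for cell in ((direction.train_task, direction.train_language),
                         (direction.test_task, direction.test_language)):
                if cell in self.cells:
                    continue
                ti = dataset.task_index(cell[0])
                li = dataset.language_index(cell[1])
                self.cells[cell] = dataset.betas[subject, ti, li][:, :, self.feature_index]

    def cell_patterns(self, task: str, language: str, runs, perm: dict | None):
        """Stacked (patterns, labels) for the cell restricted to runs;
        ``perm`` maps (task, language, run) -> a label permutation."""
        arr = self.cells[(task, language)]  # (R, C, V)
        X, y = [], []
        labels = np.arange(1, self.n_concepts + 1)
        for r in runs:
            lab = labels if perm is None else labels[perm[(task, language, r)]]
            X.append(arr[r])
            y.append(lab)
        return np.concatenate(X), np.concatenate(y)

    def accuracy(self, scheme: DecodingScheme, settings: KNNSettings,
                 perm: dict | None = None) -> float:
        from .decoding import _zscore_from_train

        direction_accs = []
        for direction in scheme.directions():
            correct = total = 0
            for train_runs, test_runs in direction.folds:
                Xtr, ytr = self.cell_patterns(
                    direction.train_task, direction.train_language, train_runs, perm)
                Xte, yte = self.cell_patterns(
                    direction.test_task, direction.test_language, test_runs, perm)
                if settings.zscore:
                    Xtr, Xte = _zscore_from_train(Xtr, Xte)
                pred = knn_classify(Xtr, ytr, Xte, k=settings.k, metric=settings.metric)
                correct += int((pred == yte).sum())
                total += len(yte)
            direction_accs.append(correct / total)
        return float(np.mean(direction_accs))

    def random_perm(self, scheme: DecodingScheme, rng) -> dict:
        """Independent concept-label permutation for every run of every
        cell the scheme touches."""
        perm = {}
        for (task, language), arr in self.cells.items():
            for r in range(arr.shape[0]):
                perm[(task, language, r)] = rng.permutation(self.n_concepts)
        return perm


def roi_accuracy(
    dataset: BetaPatternDataset,
    subject: int,
    roi: ROISpec,
    scheme: DecodingScheme,
    settings: KNNSettings | None = None,
) -> float:
    """Pooled cross-validated decoding accuracy over all ROI voxels taken
    as one feature vector (direction-averaged, like the searchlight)."""
    settings = settings or KNNSettings()
    return _RoiPatterns(dataset, subject, roi, scheme).accuracy(scheme, settings)


@dataclass
class NullDistribution:
    """Group-level chance distribution: the per-subject permutation
    accuracies (S x P) and the bootstrap group means (B,)."""

    subject_chance: np.ndarray = field(repr=False)
    group_means: np.ndarray = field(repr=False)
    seed: int | None

    def __post_init__(self) -> None:
        for arr in (self.subject_chance, self.group_means):
            a = np.asarray(arr)
            if a.size and (a.min() < 0 or a.max() > 1):
                raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    null: NullDistribution
    subject_accuracies: np.ndarray


def permutation_bootstrap_p(
    dataset: BetaPatternDataset,
    roi: ROISpec,
    scheme: DecodingScheme,
    P: int = 100,
    B: int = 10000,
    seed: int | None = None,
    settings: KNNSettings | None = None,
) -> PermutationResult:
    """Group-level p-value for an ROI's mean decoding accuracy.

    Within each run, concept labels are permuted and the cross-validated
    accuracy recomputed, P times per subject; B bootstrap draws of one
    chance accuracy per subject, averaged, form the group null.
    ``p = (1 + #{null >= observed}) / (1 + B)``; identical seeds give
    identical results.
    """
    if P < 1 or B < 1:
        raise ValueError("P and B must be >= 1")
    settings = settings or KNNSettings()
    rng = np.random.default_rng(seed)
    S = dataset.n_subjects
    observed = np.empty(S)
    chance = np.empty((S, P))
    for s in range(S):
        pats = _RoiPatterns(dataset, s, roi, scheme)
        observed[s] = pats.accuracy(scheme, settings)
        for p_i in range(P):
            perm = pats.random_perm(scheme, rng)
            chance[s, p_i] = pats.accuracy(scheme, settings, perm=perm)
    draw = rng.integers(0, P, size=(B, S))
    group_means = chance[np.arange(S)[None, :], draw].mean(axis=1)
    obs_mean = float(observed.mean())
    p = float((1 + (group_means >= obs_mean - 1e-12).sum()) / (1 + B))
    return PermutationResult(
        observed=obs_mean,
        p_value=p,
        null=NullDistribution(subject_chance=chance, group_means=group_means, seed=seed),
        subject_accuracies=observed,
    )


def fdr_correct(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return flags


def roi_table(
    rois: list[ROISpec], results: dict[str, list[PermutationResult]], q: float = 0.05
) -> pd.DataFrame:
    """Result table across ROIs and schemes with FDR flags per scheme
    column (correction over the ROIs within each scheme)."""
    rows = []
    for scheme_name, res_list in results.items():
        flags = fdr_correct([r.p_value for r in res_list], q=q)
        for roi, res, flag in zip(rois, res_list, flags):
            rows.append(
                {
                    "region": roi.name,
                    "x_mm": roi.center_mm[0] if roi.center_mm else np.nan,
                    "y_mm": roi.center_mm[1] if roi.center_mm else np.nan,
                    "z_mm": roi.center_mm[2] if roi.center_mm else np.nan,
                    "scheme": scheme_name,
                    "observed_accuracy": res.observed,
                    "p": res.p_value,
                    "significant_fdr": bool(flag),
                }
            )
    return pd.DataFrame(rows)
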