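"""Whole-brain second-level inference on accuracy maps.

Per voxel, a one-sample t-test compares the subjects' (smoothed) decoding
accuracies against chance (1 / n_concepts).  Suprathreshold voxels are
grouped into 26-connected clusters, and cluster extents are assessed
against a sign-flip permutation null: each subject's deviation from
chance is randomly sign-flipped, the t-map is recomputed, and the maximal
cluster extent per permutation forms the null distribution (a
distribution-free replacement for parametric random-field cluster
correction, with the same family-wise error contract).  The test is
one-sided: only above-chance decoding is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .decoding import AccuracyMap
from .geometry import VolumeGeometry

__all__ = [
    "GroupMap",
    "ClusterRecord",
    "one_sample_t",
    "extract_clusters",
    "cluster_correct",
    "report_table",
    "read_table",
]

# z-equivalents are capped at the z for p = 1e-16 to avoid infinities
_Z_CAP = float(stats.norm.isf(1e-16))

_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    18: ndimage.generate_binary_structure(3, 2),
    6: ndimage.generate_binary_structure(3, 1),
}


@dataclass
class GroupMap:
    """Group t-map versus chance: per-voxel t, probability-matched
    z-equivalent, nominal degrees of freedom (n_subjects - 1), validity
    mask and the chance level used."""

    t: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    df: int
    mask: np.ndarray = field(repr=False)
    chance: float
    geometry: VolumeGeometry


def _t_to_z(t: np.ndarray, df) -> np.ndarray:
    """Map t to the standard-normal deviate with the same upper-tail
    probability, capped to avoid infinities."""
    p = stats.t.sf(t, df)
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0))
    return np.clip(z, -_Z_CAP, _Z_CAP)


def _stack(maps: list[AccuracyMap]):
    geom = maps[0].geometry
    for m in maps[1:]:
        if m.geometry.shape != geom.shape or not np.allclose(m.geometry.affine, geom.affine):
            raise ValueError("accuracy maps have mismatched geometry")
    return geom, np.stack([m.data for m in maps])


def one_sample_t(maps: list[AccuracyMap], chance: float) -> GroupMap:
    """Per-voxel one-sample t-test of mean accuracy against chance.

    Voxels need at least 2 subjects with defined values; zero-variance
    voxels are flagged undefined (NaN), not infinite.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subject maps")
    geom, data = _stack(maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n = np.isfinite(data).sum(axis=0)
        mean = np.nanmean(data, axis=0)
        sd = np.nanstd(data, axis=0, ddof=1)
    valid = (n >= 2) & (sd > 1e-12)
    t = np.full(geom.shape, np.nan)
    z = np.full(geom.shape, np.nan)
    t[valid] = (mean[valid] - chance) / (sd[valid] / np.sqrt(n[valid]))
    z[valid] = _t_to_z(t[valid], n[valid] - 1)
    return GroupMap(t=t, z=z, df=len(maps) - 1, mask=valid, chance=chance, geometry=geom)


@dataclass
class ClusterRecord:
    """One suprathreshold cluster: peak location in world mm, peak t and
    z, extent in voxels, and (after correction) the corrected p-value."""

    peak_xyz_mm: tuple[float, float, float]
    peak_t: float
    peak_z: float
    extent: int
    p_corrected: float | None = None


def _label_clusters(t: np.ndarray, threshold: float, connectivity: int):
    supra = np.nan_to_num(t, nan=-np.inf) > threshold
    labels, n = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    return labels, n


def extract_clusters(
    group: GroupMap, voxel_p: float = 0.001, connectivity: int = 26
) -> list[ClusterRecord]:
    """Partition voxels with one-sided p < voxel_p into connected clusters
    (26-connectivity by default) and report each cluster's peak and extent,
    sorted by extent descending."""
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    t_crit = float(stats.t.isf(voxel_p, group.df))
    labels, n = _label_clusters(group.t, t_crit, connectivity)
    records = []
    for lab in range(1, n + 1):
        sel = labels == lab
        extent = int(sel.sum())
        idx = np.argwhere(sel)
        t_vals = group.t[sel]
        peak_i = int(np.argmax(t_vals))
        peak_vox = idx[peak_i]
        xyz = group.geometry.voxel_to_world(peak_vox)[0]
        records.append(
            ClusterRecord(
                peak_xyz_mm=tuple(float(v) for v in xyz),
                peak_t=float(t_vals[peak_i]),
                peak_z=float(group.z[sel][peak_i]),
                extent=extent,
            )
        )
    records.sort(key=lambda r: r.extent, reverse=True)
    return records


def cluster_correct(
    maps: list[AccuracyMap],
    chance: float,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int | None = None,
    connectivity: int = 26,
) -> list[ClusterRecord]:
    """Cluster-extent correction by sign-flip permutation.

    The null hypothesis is symmetry of the per-subject accuracy deviations
    around chance; each permutation flips the sign of every subject's
    deviation map independently, recomputes the one-sided t-map, and takes
    the maximal cluster extent.  ``corrected p = (1 + #{null >= extent}) /
    (1 + n_perm)``.

    Only voxels where every subject has a defined accuracy enter the
    permutation (complete-case analysis).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    geom, data = _stack(maps)
    n_subj = data.shape[0]
    if n_subj < 5:
        warnings.warn(
            f"only {n_subj} subjects: the sign-flip permutation space has "
            f"just 2^{n_subj} elements", stacklevel=2,
        )
    complete = np.isfinite(data).all(axis=0)
    X = data[:, complete] - chance  # (S, V)
    df = n_subj - 1
    t_crit = float(stats.t.isf(voxel_p, df))
    sum_sq = (X**2).sum(axis=0)  # invariant under sign flips

    def t_from_mean(m):
        var = (sum_sq - n_subj * m**2) / df
        sd = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n_subj))
        t[sd <= 1e-12] = np.nan
        return t

    # observed clusters
    obs_t = np.full(geom.shape, np.nan)
    obs_t[complete] = t_from_mean(X.mean(axis=0))
    obs_z = np.full(geom.shape, np.nan)
    ok = np.isfinite(obs_t)
    obs_z[ok] = _t_to_z(obs_t[ok], df)
    group = GroupMap(t=obs_t, z=obs_z, df=df, mask=ok, chance=chance, geometry=geom)
    records = extract_clusters(group, voxel_p, connectivity)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.zeros(n_perm, dtype=int)
    vol = np.zeros(geom.shape)
    struct = _STRUCTURES[connectivity]
    for i in range(n_perm):
        t_p = t_from_mean((signs[i] @ X) / n_subj)
        vol[:] = 0.0
        vol[complete] = np.nan_to_num(t_p, nan=-np.inf)
        labels, n_lab = ndimage.label(vol > t_crit, structure=struct)
        if n_lab:
            null_max[i] = int(np.bincount(labels.ravel())[1:].max())

    for rec in records:
        rec.p_corrected = float((1 + (null_max >= rec.extent).sum()) / (1 + n_perm))
    return records


def report_table(records: list[ClusterRecord]) -> pd.DataFrame:
    """Cluster table in the conventional report layout: peak world
    coordinates, peak z, cluster size, corrected p; sorted by extent
    descending.  (Anatomical labelling is out of scope — coordinates
    only.)"""
    rows = [
        {
            "x_mm": r.peak_xyz_mm[0],
            "y_mm": r.peak_xyz_mm[1],
            "z_mm": r.peak_xyz_mm[2],
            "peak_t": r.peak_t,
            "peak_z": r.peak_z,
            "cluster_size": r.extent,
            "p_corrected": r.p_corrected,
        }
        for r in sorted(records, key=lambda r: r.extent, reverse=True)
    ]
    cols = ["x_mm", "y_mm", "z_mm", "peak_t", "peak_z", "cluster_size", "p_corrected"]
    return pd.DataFrame(rows, columns=cols)


def write_table(records: list[ClusterRecord], path) -> None:
    report_table(records).to_csv(path, sep="\t", index=False)


def read_table(path) -> list[ClusterRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ClusterRecord(
            peak_xyz_mm=(r.x_mm, r.y_mm, r.z_mm), peak_t=r.peak_t, peak_z=r.peak_z,
            extent=int(r.cluster_size),
            p_corrected=None if pd.isna(r.p_corrected) else float(r.p_corrected),
        )
        for r in df.itertuples()
    ]
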