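"""First-level GLM: from run time series + events to per-concept beta volumes.

Each run is modelled with one HRF-convolved regressor per concept (built
from that concept's correctly answered trials only), the temporal
derivatives of those regressors, optional motion regressors, a discrete
cosine high-pass set with a 128 s cutoff, and an intercept.  Ordinary
least squares per voxel yields the concept betas; derivative, motion and
drift columns are nuisance and discarded.

High-pass filtering is implemented as DCT regressors *inside* the design
rather than by pre-filtering the data; for OLS the two are equivalent and
the in-design form keeps the contract simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "canonical_hrf",
    "DesignMatrix",
    "build_design",
    "fit_glm",
    "fit_dataset",
    "dct_highpass_basis",
    "n_dct_regressors",
]

# Canonical double-gamma parameters (peak delay 6 s, undershoot delay 16 s,
# unit dispersions, undershoot ratio 1/6, 32 s window): the de-facto
# standard in the major fMRI analysis packages.
HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_PEAK_DISP_S = 1.0
HRF_UNDERSHOOT_DISP_S = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_WINDOW_S = 32.0

_DEFAULT_CUTOFF_S = 128.0
_OVERSAMPLE = 16  # design built on a TR/16 grid, then sampled at scan times


def _hrf_peak_value() -> float:
    t = np.linspace(0.0, HRF_WINDOW_S, 4096)
    h = gamma_dist.pdf(t, HRF_PEAK_DELAY_S / HRF_PEAK_DISP_S, scale=HRF_PEAK_DISP_S)
    h -= HRF_UNDERSHOOT_RATIO * gamma_dist.pdf(
        t, HRF_UNDERSHOOT_DELAY_S / HRF_UNDERSHOOT_DISP_S, scale=HRF_UNDERSHOOT_DISP_S
    )
    return float(h.max())


_HRF_PEAK = None


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Difference of two gamma densities (positive lobe peaking near 5 s,
    undershoot near 15 s, ratio 1/6), rescaled so the maximum response is
    1.  ``t`` is a grid of non-negative seconds; the response is 0 at
    ``t = 0`` and (by convention) beyond the 32 s window.
    """
    global _HRF_PEAK
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is only defined for t >= 0")
    if _HRF_PEAK is None:
        _HRF_PEAK = _hrf_peak_value()
    h = gamma_dist.pdf(t, HRF_PEAK_DELAY_S / HRF_PEAK_DISP_S, scale=HRF_PEAK_DISP_S)
    h -= HRF_UNDERSHOOT_RATIO * gamma_dist.pdf(
        t, HRF_UNDERSHOOT_DELAY_S / HRF_UNDERSHOOT_DISP_S, scale=HRF_UNDERSHOOT_DISP_S
    )
    h[t > HRF_WINDOW_S] = 0.0
    return h / _HRF_PEAK


def convolve_events(
    onsets, durations, n_scans: int, tr_s: float, oversample: int = _OVERSAMPLE
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at scan times.

    Events are laid out as unit-height boxcars on a ``tr_s / oversample``
    grid, convolved with the canonical HRF on that grid, and sampled at
    ``t = i * tr_s``.  Shared by the GLM and the time-series simulator so
    that noise-free simulation and estimation agree exactly.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    dt = tr_s / oversample
    n_fine = n_scans * oversample + int(np.ceil(HRF_WINDOW_S / dt))
    stick = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.round(onset / dt))
        i1 = max(i0 + 1, int(np.round((onset + dur) / dt)))
        stick[i0:i1] += 1.0
    hrf = canonical_hrf(np.arange(0, HRF_WINDOW_S + dt, dt)) * dt
    conv = np.convolve(stick, hrf)[:n_fine]
    return conv[: n_scans * oversample : oversample].copy()


def n_dct_regressors(duration_s: float, cutoff_s: float = _DEFAULT_CUTOFF_S) -> int:
    """Number of cosine regressors (excluding the constant) whose frequency
    ``k / (2 T)`` lies strictly below ``1 / cutoff``."""
    x = 2.0 * duration_s / cutoff_s
    n = int(np.floor(x))
    if np.isclose(n, x):
        n -= 1
    return max(n, 0)


def dct_highpass_basis(
    n_scans: int, tr_s: float, cutoff_s: float = _DEFAULT_CUTOFF_S
) -> np.ndarray:
    """Discrete-cosine drift basis, shape ``(n_scans, K)``, constant excluded.

    Column k (1-based) is ``cos(pi * k * (2 i + 1) / (2 N))``, the standard
    DCT-II basis; K is chosen so every column's frequency is below the
    high-pass cutoff (default 128 s).
    """
    K = n_dct_regressors(n_scans * tr_s, cutoff_s)
    i = np.arange(n_scans)
    basis = np.empty((n_scans, K))
    for k in range(1, K + 1):
        basis[:, k - 1] = np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans))
    return basis


@dataclass
class DesignMatrix:
    """A first-level design: ``matrix`` (scans x columns) plus bookkeeping.

    ``concept_columns`` indexes the canonical-HRF concept regressors, in
    concept order; ``unestimable`` lists concepts whose regressor is all
    zeros (every trial excluded) — those columns are kept in place but
    skipped during estimation, and their betas are returned as NaN.
    """

    matrix: np.ndarray = field(repr=False)
    names: list[str]
    concept_columns: list[int]
    concept_ids: list[int]
    unestimable: list[int]
    tr_s: float

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]


def build_design(
    events,
    n_scans: int,
    tr_s: float,
    n_concepts: int | None = None,
    motion: np.ndarray | None = None,
    cutoff_s: float = _DEFAULT_CUTOFF_S,
    include_derivatives: bool = True,
    oversample: int = _OVERSAMPLE,
) -> DesignMatrix:
    """Build the run design matrix from an event table.

    Parameters
    ----------
    events : EventTable or DataFrame
        Rows with ``onset_s``, ``duration_s``, ``concept_id``,
        ``correct`` (bool).  Trials with ``correct == False`` are excluded
        from the concept regressors.
    n_scans, tr_s :
        Run length in scans and repetition time in seconds.
    n_concepts :
        Total number of concepts (defaults to the max id present); concepts
        with no surviving trials yield an all-zero, unestimable column.
    motion : (n_scans, 6) array, optional
        Rigid-body motion parameter regressors.
    """
    frame = getattr(events, "frame", events)
    onset = np.asarray(frame["onset_s"], dtype=float)
    duration = np.asarray(frame["duration_s"], dtype=float)
    concept = np.asarray(frame["concept_id"], dtype=int)
    correct = (
        np.asarray(frame["correct"], dtype=bool)
        if "correct" in frame
        else np.ones(len(frame), dtype=bool)
    )
    run_end = n_scans * tr_s
    if np.any(onset < 0) or np.any(onset >= run_end):
        raise ValueError("event onsets must fall within the run")
    if n_concepts is None:
        n_concepts = int(concept.max())

    cols, names = [], []
    concept_columns, unestimable = [], []
    regs = np.zeros((n_scans, n_concepts))
    for c in range(1, n_concepts + 1):
        sel = (concept == c) & correct
        if sel.any():
            regs[:, c - 1] = convolve_events(onset[sel], duration[sel], n_scans, tr_s, oversample)
        else:
            unestimable.append(c)
    for c in range(1, n_concepts + 1):
        concept_columns.append(len(cols))
        cols.append(regs[:, c - 1])
        names.append(f"concept_{c:02d}")
    if include_derivatives:
        for c in range(1, n_concepts + 1):
            cols.append(np.gradient(regs[:, c - 1], tr_s))
            names.append(f"concept_{c:02d}_derivative")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_scans, 6):
            raise ValueError("motion must have shape (n_scans, 6)")
        for j in range(6):
            cols.append(motion[:, j])
            names.append(f"motion_{j}")
    dct = dct_highpass_basis(n_scans, tr_s, cutoff_s)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"drift_dct_{k + 1}")
    cols.append(np.ones(n_scans))
    names.append("intercept")
    return DesignMatrix(
        matrix=np.column_stack(cols),
        names=names,
        concept_columns=concept_columns,
        concept_ids=list(range(1, n_concepts + 1)),
        unestimable=unestimable,
        tr_s=tr_s,
    )


def fit_glm(
    series: np.ndarray, design: DesignMatrix, mask: np.ndarray | None = None
) -> np.ndarray:
    """Ordinary least squares per voxel; returns the concept betas only.

    ``series`` is either a 4-D run (``nx, ny, nz, n_scans``) or a 2-D
    ``(n_scans, n_voxels)`` matrix.  With a 4-D input and a mask, betas
    come back as ``(n_concepts, nx, ny, nz)`` with NaN outside the mask;
    otherwise as ``(n_concepts, n_voxels)``.  Unestimable concepts (all
    trials excluded) get NaN betas.

    Raises
    ------
    ValueError
        If the design is rank deficient on its estimable columns; the
        offending column names are included in the message.
    """
    series = np.asarray(series, dtype=float)
    volumetric = series.ndim == 4
    if volumetric:
        if series.shape[3] != design.n_scans:
            raise ValueError("time axis must match design rows")
        if mask is None:
            mask = np.ones(series.shape[:3], dtype=bool)
        Y = series[mask].T  # (n_scans, V)
    else:
        if series.shape[0] != design.n_scans:
            raise ValueError("series rows must match design rows")
        Y = series

    X = design.matrix
    dead_cols = [design.concept_columns[c - 1] for c in design.unestimable]
    keep = np.setdiff1d(np.arange(X.shape[1]), dead_cols)
    Xk = X[:, keep]
    # rank check with named offenders via pivoted QR
    r_diag = np.abs(np.diag(np.linalg.qr(Xk, mode="r")))
    tol = max(Xk.shape) * np.finfo(float).eps * (r_diag.max() if r_diag.size else 1.0)
    if np.any(r_diag < tol):
        bad = [design.names[keep[j]] for j in np.nonzero(r_diag < tol)[0]]
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")

    beta_k, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    betas_full = np.full((X.shape[1], Y.shape[1]), np.nan)
    betas_full[keep] = beta_k
    concept_betas = betas_full[design.concept_columns]

    if volumetric:
        out = np.full((len(design.concept_columns),) + series.shape[:3], np.nan)
        out[:, mask] = concept_betas
        return out
    return concept_betas


def fit_dataset(ts, include_derivatives: bool = True):
    """Fit the GLM run by run on a simulated time-series dataset and
    assemble the concept betas into a :class:`~semdecode.dataset.BetaPatternDataset`.

    Runs where a concept is unestimable keep NaN betas replaced by zeros
    and are recorded in ``dataset_notes`` (conservative: the run still
    participates, chance level keeps the full concept count).
    """
    from .dataset import BetaPatternDataset

    cfg, geom = ts.config, ts.geometry
    mask = ts.mask
    V = int(mask.sum())
    betas = np.zeros(
        (cfg.n_subjects, len(cfg.tasks), cfg.n_languages, cfg.n_runs, cfg.n_concepts, V)
    )
    notes = []
    for key, series in ts.series.items():
        s, task, lang, r = key
        events = ts.events[key]
        design = build_design(
            events, n_scans=series.shape[3], tr_s=cfg.tr_s,
            n_concepts=cfg.n_concepts, include_derivatives=include_derivatives,
        )
        b = fit_glm(series, design, mask=mask)  # (C, nx, ny, nz)
        bm = b[:, mask]
        if design.unestimable:
            notes.append({"key": key, "unestimable_concepts": design.unestimable})
            bm = np.nan_to_num(bm)
        ti = cfg.tasks.index(task)
        li = 0 if lang == "L1" else 1
        betas[s, ti, li, r] = bm
    ds = BetaPatternDataset(
        geometry=geom, mask=mask, betas=betas, tasks=tuple(cfg.tasks)
    )
    ds.notes = notes
    return ds
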