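"""Synthetic multi-subject datasets with controllable signal topography.

The generator emulates a within-subject bilingual design: three tasks
(picture naming, word reading, word listening) x two languages (L1, L2)
x five runs per task-language cell, with ten concepts presented six times
per run.  Ground-truth "representations" are planted in user-chosen
effect regions:

* ``shared_semantic`` — one random concept pattern per subject, reused
  across both languages and the region's listed tasks.  Cross-language
  and cross-modality decoders can transfer on it.
* ``language_specific`` — an independent pattern per language (shared
  across listed tasks).  Supports within-language transfer across tasks,
  but not cross-language decoding.
* ``modality_specific`` — an independent pattern per task (shared across
  languages).  Supports cross-language decoding within a task, but not
  transfer across tasks.
* ``none`` — no concept-dependent signal.

Concept patterns are i.i.d. standard normal per voxel, scaled by the
region amplitude; run-level i.i.d. Gaussian noise (optionally spatially
smoothed) is added everywhere.  Every draw is tied to the config seed, so
identical configs give bit-identical datasets, and the same patterns
underlie both the directly generated beta datasets and the simulated raw
time series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from . import glm
from .dataset import DEFAULT_TASKS, LANGUAGES, BetaPatternDataset
from .geometry import VolumeGeometry
from .stimuli import generate_stimulus_set  # re-exported: stimulus sets belong to the design

__all__ = [
    "EffectRegion",
    "SimulationConfig",
    "EventTable",
    "SimulatedTimeseries",
    "generate_beta_dataset",
    "generate_timeseries",
    "generate_stimulus_set",
    "cuboid_region",
]

SHARINGS = ("shared_semantic", "language_specific", "modality_specific", "none")


@dataclass(frozen=True)
class EffectRegion:
    """A set of voxels carrying concept information with a given sharing mode.

    ``tasks=None`` means all tasks in the config.  ``amplitude`` scales the
    unit-variance concept patterns (so amplitude / noise_sd is the per-voxel
    contrast-to-noise ratio).
    """

    mask: np.ndarray
    sharing: str
    amplitude: float = 1.0
    tasks: tuple[str, ...] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.sharing not in SHARINGS:
            raise ValueError(f"sharing must be one of {SHARINGS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError("effect region mask is empty")
        object.__setattr__(self, "mask", mask)


def cuboid_region(
    geometry: VolumeGeometry,
    lo: tuple[int, int, int],
    hi: tuple[int, int, int],
    sharing: str,
    amplitude: float = 1.0,
    tasks: tuple[str, ...] | None = None,
    name: str = "",
) -> EffectRegion:
    """Convenience: an axis-aligned box region ``lo`` (inclusive) to ``hi``
    (exclusive) in voxel indices."""
    mask = np.zeros(geometry.shape, dtype=bool)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    mask[sl] = True
    return EffectRegion(mask=mask, sharing=sharing, amplitude=amplitude, tasks=tasks, name=name)


# inter-trial intervals: 1.0-5.2 s in 300 ms steps, pseudologarithmic
# density tuned to a 2.6 s mean
_ITI_VALUES = np.round(np.arange(1.0, 5.2 + 1e-9, 0.3), 10)
_ITI_MEAN_S = 2.6


def _iti_weights() -> np.ndarray:
    def mean_at(lam):
        w = np.exp(-lam * _ITI_VALUES)
        return float((w * _ITI_VALUES).sum() / w.sum()) - _ITI_MEAN_S

    lam = brentq(mean_at, 1e-9, 10.0)
    w = np.exp(-lam * _ITI_VALUES)
    return w / w.sum()


_ITI_W = None


@dataclass(frozen=True)
class SimulationConfig:
    """Design parameters of the simulated study.

    Defaults mirror the emulated design: 22 subjects, 3 tasks x 2
    languages x 5 runs, 10 concepts shown 6 times per run, TR 2 s, 1 s
    stimulus duration, jittered ITIs (mean 2.6 s, 1.0-5.2 s in 0.3 s
    steps), 143 analyzed scans per run.
    """

    n_subjects: int = 22
    tasks: tuple[str, ...] = DEFAULT_TASKS
    n_languages: int = 2
    n_runs: int = 5
    n_concepts: int = 10
    presentations_per_run: int = 6
    effect_regions: tuple[EffectRegion, ...] = ()
    noise_sd: float = 1.0
    tr_s: float = 2.0
    seed: int = 0
    accuracy: float = 1.0
    stimulus_duration_s: float = 1.0
    n_scans_per_run: int = 143
    drift_sd: float = 1.0
    timeseries_noise_sd: float | None = None
    noise_smooth_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.n_concepts < 2:
            raise ValueError("n_concepts must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.n_subjects, self.n_languages, self.presentations_per_run) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")
        if self.n_languages != 2:
            raise ValueError("the design has exactly 2 languages (L1, L2)")

    @property
    def languages(self) -> tuple[str, ...]:
        return LANGUAGES

    def to_json(self, path=None) -> str:
        """Serialize the config (effect-region masks as flat voxel indices
        plus the grid shape, so any mask round-trips)."""
        import json

        d = dataclasses.asdict(self)
        d["effect_regions"] = [
            {
                "shape": list(reg.mask.shape),
                "voxels": np.flatnonzero(reg.mask).tolist(),
                "sharing": reg.sharing,
                "amplitude": reg.amplitude,
                "tasks": list(reg.tasks) if reg.tasks is not None else None,
                "name": reg.name,
            }
            for reg in self.effect_regions
        ]
        text = json.dumps(d, indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        import json
        from pathlib import Path

        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            source = Path(source).read_text()
        elif isinstance(source, Path):
            source = source.read_text()
        d = json.loads(source)
        regions = []
        for r in d.pop("effect_regions", []):
            mask = np.zeros(int(np.prod(r["shape"])), dtype=bool)
            mask[r["voxels"]] = True
            regions.append(
                EffectRegion(
                    mask=mask.reshape(r["shape"]), sharing=r["sharing"],
                    amplitude=r["amplitude"],
                    tasks=tuple(r["tasks"]) if r["tasks"] is not None else None,
                    name=r.get("name", ""),
                )
            )
        d["tasks"] = tuple(d["tasks"])
        return cls(effect_regions=tuple(regions), **d)

    @property
    def trials_per_run(self) -> int:
        return self.n_concepts * self.presentations_per_run

    def validate_regions(self, geometry: VolumeGeometry) -> None:
        for reg in self.effect_regions:
            if reg.mask.shape != geometry.shape:
                raise ValueError("effect region mask outside geometry (shape mismatch)")
            if reg.tasks is not None and not set(reg.tasks) <= set(self.tasks):
                raise ValueError(f"region tasks {reg.tasks} not in config tasks {self.tasks}")
        for i, a in enumerate(self.effect_regions):
            for b in self.effect_regions[i + 1 :]:
                if a.sharing != b.sharing and np.any(a.mask & b.mask):
                    raise ValueError(
                        "overlapping effect regions with conflicting sharing: "
                        f"{a.sharing!r} vs {b.sharing!r}"
                    )


@dataclass
class EventTable:
    """Trial events of one run: onset, duration, concept, language, run,
    correctness; BIDS-style TSV round trip."""

    frame: pd.DataFrame
    tr_s: float

    def __post_init__(self) -> None:
        f = self.frame
        onsets = np.asarray(f["onset_s"], dtype=float)
        if np.any(onsets < 0):
            raise ValueError("onsets must be non-negative")
        for _, grp in f.groupby("run"):
            o = np.asarray(grp["onset_s"], dtype=float)
            if np.any(np.diff(o) <= 0):
                raise ValueError("onsets must be strictly increasing within a run")
        if np.any(np.asarray(f["concept_id"], dtype=int) < 1):
            raise ValueError("concept ids are 1-based")

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        out = self.frame.rename(columns={"onset_s": "onset", "duration_s": "duration",
                                         "concept_id": "trial_type"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr_s: float) -> "EventTable":
        f = pd.read_csv(path, sep="\t")
        f = f.rename(columns={"onset": "onset_s", "duration": "duration_s",
                              "trial_type": "concept_id"})
        return cls(frame=f, tr_s=tr_s)


@dataclass
class SimulatedTimeseries:
    """Raw-series counterpart of a beta dataset.

    ``series`` maps (subject, task, language, run) to a 4-D array
    ``(nx, ny, nz, n_scans)``; ``events`` maps the same keys to
    :class:`EventTable` rows for that run.
    """

    config: SimulationConfig
    geometry: VolumeGeometry
    mask: np.ndarray
    series: dict
    events: dict


# ---------------------------------------------------------------------------


def _pattern_streams(config: SimulationConfig):
    """Independent RNG streams so betas and time series share patterns."""
    root = np.random.SeedSequence(config.seed)
    pat, beta_noise, ev = root.spawn(3)
    return (
        np.random.default_rng(pat),
        np.random.default_rng(beta_noise),
        np.random.default_rng(ev),
    )


def _signal_maps(config: SimulationConfig, geometry: VolumeGeometry, rng) -> np.ndarray:
    """Noise-free concept amplitude maps, shape (S, T, L, C, n_voxels)."""
    S, T, L, C = (config.n_subjects, len(config.tasks), config.n_languages, config.n_concepts)
    V = geometry.n_voxels
    signal = np.zeros((S, T, L, C, V))
    flat_masks = [reg.mask.reshape(-1) for reg in config.effect_regions]
    for s in range(S):
        for reg, fmask in zip(config.effect_regions, flat_masks):
            nv = int(fmask.sum())
            reg_tasks = reg.tasks if reg.tasks is not None else config.tasks
            t_idx = [config.tasks.index(t) for t in reg_tasks]
            if reg.sharing == "shared_semantic":
                pat = rng.standard_normal((C, nv)) * reg.amplitude
                for ti in t_idx:
                    for li in range(L):
                        signal[s, ti, li][:, fmask] += pat
            elif reg.sharing == "language_specific":
                pat = rng.standard_normal((L, C, nv)) * reg.amplitude
                for ti in t_idx:
                    for li in range(L):
                        signal[s, ti, li][:, fmask] += pat[li]
            elif reg.sharing == "modality_specific":
                pat = rng.standard_normal((len(t_idx), C, nv)) * reg.amplitude
                for k, ti in enumerate(t_idx):
                    for li in range(L):
                        signal[s, ti, li][:, fmask] += pat[k]
            # sharing == "none": no concept-dependent signal
    return signal


def _noise_volume(rng, config: SimulationConfig, geometry: VolumeGeometry, shape_extra) -> np.ndarray:
    """White (or optionally smoothed-and-rescaled) Gaussian noise volumes."""
    full = shape_extra + geometry.shape
    noise = rng.standard_normal(full)
    if config.noise_smooth_fwhm_mm > 0:
        sigma_vox = (
            config.noise_smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        ) / geometry.voxel_size
        impulse = np.zeros(geometry.shape)
        impulse[tuple(s // 2 for s in geometry.shape)] = 1.0
        kern = gaussian_filter(impulse, sigma=sigma_vox)
        scale = np.sqrt((kern**2).sum())
        flat = noise.reshape((-1,) + geometry.shape)
        for i in range(flat.shape[0]):
            flat[i] = gaussian_filter(flat[i], sigma=sigma_vox) / scale
    return noise * config.noise_sd


def generate_beta_dataset(
    config: SimulationConfig, geometry: VolumeGeometry | None = None
) -> BetaPatternDataset:
    """Draw a full multi-subject beta dataset.

    One beta volume per (subject, task, language, run, concept): the
    subject's noise-free concept signal plus run-level Gaussian noise.
    Identical config (including seed) gives bit-identical output.
    """
    if geometry is None:
        geometry = VolumeGeometry.isotropic()
    config.validate_regions(geometry)
    rng_pat, rng_noise, _ = _pattern_streams(config)
    S, T, L = config.n_subjects, len(config.tasks), config.n_languages
    R, C, V = config.n_runs, config.n_concepts, geometry.n_voxels
    signal = _signal_maps(config, geometry, rng_pat)  # (S,T,L,C,V)
    betas = np.empty((S, T, L, R, C, V))
    for s in range(S):
        for ti in range(T):
            for li in range(L):
                noise = _noise_volume(rng_noise, config, geometry, (R, C)).reshape(R, C, V)
                betas[s, ti, li] = signal[s, ti, li][None] + noise
    mask = np.ones(geometry.shape, dtype=bool)
    ds = BetaPatternDataset(
        geometry=geometry, mask=mask, betas=betas.reshape(S, T, L, R, C, V),
        tasks=config.tasks,
    )
    ds.config = config
    return ds


def _make_run_events(config: SimulationConfig, rng, language: str, run: int) -> EventTable:
    global _ITI_W
    if _ITI_W is None:
        _ITI_W = _iti_weights()
    order = rng.permutation(np.repeat(np.arange(1, config.n_concepts + 1),
                                      config.presentations_per_run))
    itis = rng.choice(_ITI_VALUES, size=len(order), p=_ITI_W)
    onsets = np.empty(len(order))
    t = 2.0  # initial fixation
    for i in range(len(order)):
        onsets[i] = t
        t += config.stimulus_duration_s + itis[i]
    run_end = config.n_scans_per_run * config.tr_s
    if onsets[-1] + config.stimulus_duration_s + glm.HRF_WINDOW_S / 2 > run_end:
        raise ValueError(
            f"run too short: last event ends at {onsets[-1] + config.stimulus_duration_s:.1f}s "
            f"but the run has only {run_end:.1f}s"
        )
    correct = rng.random(len(order)) < config.accuracy
    frame = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": config.stimulus_duration_s,
            "concept_id": order,
            "language": language,
            "run": run,
            "correct": correct,
        }
    )
    return EventTable(frame=frame, tr_s=config.tr_s)


def generate_timeseries(
    config: SimulationConfig,
    geometry: VolumeGeometry | None = None,
    subjects=None,
    memory_limit_gb: float = 4.0,
) -> SimulatedTimeseries:
    """Simulate raw 4-D runs: HRF-convolved event responses with the same
    generative concept patterns as :func:`generate_beta_dataset`, plus
    low-frequency drift (inside the 128 s DCT span) and white noise.

    ``subjects`` restricts generation to a subset (raw series are big;
    the full default design would not fit in memory, and the estimated
    footprint is checked against ``memory_limit_gb``).
    """
    if geometry is None:
        geometry = VolumeGeometry.isotropic()
    config.validate_regions(geometry)
    subjects = list(range(config.n_subjects)) if subjects is None else list(subjects)
    n_bytes = (
        len(subjects) * len(config.tasks) * config.n_languages * config.n_runs
        * geometry.n_voxels * config.n_scans_per_run * 8
    )
    if n_bytes > memory_limit_gb * 1e9:
        raise MemoryError(
            f"requested time series would take ~{n_bytes / 1e9:.1f} GB; "
            "restrict `subjects` or shrink the config/geometry"
        )
    rng_pat, _, rng_ev = _pattern_streams(config)
    signal = _signal_maps(config, geometry, rng_pat)  # (S,T,L,C,V)
    ts_noise_sd = (
        config.noise_sd if config.timeseries_noise_sd is None else config.timeseries_noise_sd
    )
    n_scans = config.n_scans_per_run
    dct = glm.dct_highpass_basis(n_scans, config.tr_s)
    series, events = {}, {}
    for s in subjects:
        for ti, task in enumerate(config.tasks):
            for li, lang in enumerate(LANGUAGES):
                for r in range(config.n_runs):
                    ev = _make_run_events(config, rng_ev, lang, r)
                    f = ev.frame
                    X = np.zeros((n_scans, config.n_concepts))
                    for c in range(1, config.n_concepts + 1):
                        sel = np.asarray(f["concept_id"]) == c
                        if sel.any():
                            X[:, c - 1] = glm.convolve_events(
                                np.asarray(f["onset_s"])[sel],
                                np.asarray(f["duration_s"])[sel],
                                n_scans, config.tr_s,
                            )
                    data = X @ signal[s, ti, li]  # (n_scans, V)
                    if config.drift_sd > 0 and dct.shape[1] > 0:
                        raw = dct @ rng_ev.standard_normal((dct.shape[1], geometry.n_voxels))
                        rms = np.sqrt((raw**2).mean(axis=0, keepdims=True))
                        rms[rms == 0] = 1.0
                        data = data + raw / rms * config.drift_sd
                    if ts_noise_sd > 0:
                        data = data + ts_noise_sd * rng_ev.standard_normal(data.shape)
                    vol = np.moveaxis(data.reshape((n_scans,) + geometry.shape), 0, -1)
                    series[(s, task, lang, r)] = np.ascontiguousarray(vol)
                    events[(s, task, lang, r)] = ev
    mask = np.ones(geometry.shape, dtype=bool)
    return SimulatedTimeseries(
        config=config, geometry=geometry, mask=mask, series=series, events=events
    )
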