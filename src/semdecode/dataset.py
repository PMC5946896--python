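"""Container for per-condition activation patterns.

The unit of analysis for all decoders is a :class:`BetaPatternDataset`:
one activation (beta) volume per (subject, task, language, run, concept),
restricted to a common in-brain mask on a shared voxel grid.  Datasets are
produced either by the simulator (:mod:`semdecode.simulate`) or by the
first-level GLM (:mod:`semdecode.glm`), or loaded from a directory of
NIfTI files with a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import VolumeGeometry

LANGUAGES = ("L1", "L2")
DEFAULT_TASKS = ("naming", "reading", "listening")


@dataclass
class BetaPatternDataset:
    """Per-condition beta patterns on a common grid.

    Attributes
    ----------
    geometry : VolumeGeometry
        The shared voxel grid.
    mask : (nx, ny, nz) bool ndarray
        In-analysis voxels; patterns are stored only for these.
    betas : ndarray, shape (S, T, L, R, C, V)
        Beta values indexed (subject, task, language, run, concept,
        mask voxel), with V = ``mask.sum()``.
    tasks, languages : tuple of str
        Condition labels for the task and language axes.
    """

    geometry: VolumeGeometry
    mask: np.ndarray
    betas: np.ndarray = field(repr=False)
    tasks: tuple[str, ...] = DEFAULT_TASKS
    languages: tuple[str, ...] = LANGUAGES

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape must match geometry")
        self.betas = np.asarray(self.betas)
        if self.betas.ndim != 6:
            raise ValueError("betas must be 6-D (subject, task, language, run, concept, voxel)")
        S, T, L, R, C, V = self.betas.shape
        if V != int(self.mask.sum()):
            raise ValueError("last beta axis must equal number of in-mask voxels")
        if T != len(self.tasks) or L != len(self.languages):
            raise ValueError("task/language axes must match labels")
        if R < 2 or C < 2:
            raise ValueError("need at least 2 runs and 2 concepts")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")

    # -- basic accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.betas.shape[0]

    @property
    def n_runs(self) -> int:
        return self.betas.shape[3]

    @property
    def n_concepts(self) -> int:
        return self.betas.shape[4]

    @property
    def concepts(self) -> np.ndarray:
        """Concept labels (1-based)."""
        return np.arange(1, self.n_concepts + 1)

    def task_index(self, task: str) -> int:
        try:
            return self.tasks.index(task)
        except ValueError:
            raise KeyError(f"unknown task {task!r}; have {self.tasks}") from None

    def language_index(self, language: str) -> int:
        try:
            return self.languages.index(language)
        except ValueError:
            raise KeyError(f"unknown language {language!r}; have {self.languages}") from None

    def patterns(
        self, subject: int, task: str, language: str, runs
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked patterns for the given cell.

        Returns ``(X, labels, run_ids)`` with X of shape
        ``(len(runs) * n_concepts, V)``, concept labels 1-based.
        """
        ti, li = self.task_index(task), self.language_index(language)
        runs = list(runs)
        X = self.betas[subject, ti, li, runs]  # (r, C, V)
        n_r, C, V = X.shape
        labels = np.tile(np.arange(1, C + 1), n_r)
        run_ids = np.repeat(np.asarray(runs), C)
        return X.reshape(n_r * C, V), labels, run_ids

    def volume(self, subject: int, task: str, language: str, run: int, concept: int) -> np.ndarray:
        """Full 3-D beta volume for one condition (NaN outside the mask)."""
        ti, li = self.task_index(task), self.language_index(language)
        vol = np.full(self.geometry.shape, np.nan)
        vol[self.mask] = self.betas[subject, ti, li, run, concept - 1]
        return vol

    # -- NIfTI round trip ------------------------------------------------

    def to_dir(self, path, per_run_4d: bool = False) -> None:
        """Write beta NIfTIs plus ``manifest.json`` and the mask.

        By default one 3-D file per (subject, task, language, run, concept);
        with ``per_run_4d`` one 4-D file per run whose last axis indexes the
        concepts in order.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        affine = self.geometry.affine
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), path / "mask.nii.gz")
        entries = []
        for s in range(self.n_subjects):
            for ti, task in enumerate(self.tasks):
                for li, lang in enumerate(self.languages):
                    for r in range(self.n_runs):
                        stem = f"sub-{s:02d}_task-{task}_lang-{lang}_run-{r}"
                        if per_run_4d:
                            vol = np.zeros(
                                self.geometry.shape + (self.n_concepts,), dtype=np.float32
                            )
                            vol[self.mask] = self.betas[s, ti, li, r].T
                            fname = f"{stem}_betas.nii.gz"
                            nib.save(nib.Nifti1Image(vol, affine), path / fname)
                            entries.append(
                                {"file": fname, "subject": s, "task": task,
                                 "language": lang, "run": r, "concept": None}
                            )
                            continue
                        for c in range(1, self.n_concepts + 1):
                            fname = f"{stem}_concept-{c:02d}_beta.nii.gz"
                            vol = np.zeros(self.geometry.shape, dtype=np.float32)
                            vol[self.mask] = self.betas[s, ti, li, r, c - 1]
                            nib.save(nib.Nifti1Image(vol, affine), path / fname)
                            entries.append(
                                {"file": fname, "subject": s, "task": task,
                                 "language": lang, "run": r, "concept": c}
                            )
        manifest = {
            "tasks": list(self.tasks),
            "languages": list(self.languages),
            "n_subjects": self.n_subjects,
            "n_runs": self.n_runs,
            "n_concepts": self.n_concepts,
            "mask": "mask.nii.gz",
            "volumes": entries,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, path) -> "BetaPatternDataset":
        """Load a dataset written by :meth:`to_dir` (or laid out the same way)."""
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        mask_img = nib.load(path / manifest["mask"])
        mask = np.asarray(mask_img.dataobj).astype(bool)
        geometry = VolumeGeometry(shape=mask.shape, affine=mask_img.affine)
        tasks = tuple(manifest["tasks"])
        languages = tuple(manifest["languages"])
        S, R, C = manifest["n_subjects"], manifest["n_runs"], manifest["n_concepts"]
        betas = np.zeros((S, len(tasks), len(languages), R, C, int(mask.sum())))
        for e in manifest["volumes"]:
            vol = np.asarray(nib.load(path / e["file"]).dataobj, dtype=float)
            loc = (e["subject"], tasks.index(e["task"]), languages.index(e["language"]),
                   e["run"])
            if e.get("concept") is None:  # 4-D per-run file, last axis = concepts
                betas[loc] = vol[mask].T
            else:
                betas[loc + (e["concept"] - 1,)] = vol[mask]
        return cls(geometry=geometry, mask=mask, betas=betas, tasks=tasks, languages=languages)
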