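"""Generator contracts: sharing semantics, seeding, event structure."""

import numpy as np
import pandas as pd
import pytest

import semdecode as sd
from semdecode import glm
from semdecode.simulate import EventTable, _make_run_events


@pytest.fixture(scope="module")
def geom():
    return sd.VolumeGeometry.isotropic((8, 8, 8), 3.0)


def _cfg(geom, sharing, **kw):
    region = sd.cuboid_region(geom, (1, 1, 1), (6, 6, 6), sharing, amplitude=1.0)
    defaults = dict(
        n_subjects=2, tasks=("naming", "reading"), n_runs=2, n_concepts=3,
        presentations_per_run=2, effect_regions=(region,), noise_sd=0.0, seed=42,
    )
    defaults.update(kw)
    return sd.SimulationConfig(**defaults), region


def test_shared_semantic_patterns_equal_across_languages_and_tasks(geom):
    cfg, region = _cfg(geom, "shared_semantic")
    ds = sd.generate_beta_dataset(cfg, geom)
    rv = region.mask[ds.mask]
    for c in (1, 2, 3):
        l1 = ds.betas[0, 0, 0, 0, c - 1][rv]
        l2 = ds.betas[0, 0, 1, 0, c - 1][rv]
        other_task = ds.betas[0, 1, 0, 1, c - 1][rv]
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(l1, other_task)


def test_language_specific_patterns_differ_across_languages(geom):
    cfg, region = _cfg(geom, "language_specific")
    ds = sd.generate_beta_dataset(cfg, geom)
    rv = region.mask[ds.mask]
    l1 = ds.betas[0, 0, 0, 0, 0][rv]
    l2 = ds.betas[0, 0, 1, 0, 0][rv]
    assert not np.allclose(l1, l2)
    assert abs(np.corrcoef(l1, l2)[0, 1]) < 0.5  # independent draws
    # but shared across tasks within a language
    np.testing.assert_array_equal(l1, ds.betas[0, 1, 0, 0, 0][rv])


def test_modality_specific_patterns_differ_across_tasks_not_languages(geom):
    cfg, region = _cfg(geom, "modality_specific")
    ds = sd.generate_beta_dataset(cfg, geom)
    rv = region.mask[ds.mask]
    naming = ds.betas[0, 0, 0, 0, 0][rv]
    reading = ds.betas[0, 1, 0, 0, 0][rv]
    np.testing.assert_array_equal(naming, ds.betas[0, 0, 1, 0, 0][rv])
    assert not np.allclose(naming, reading)


def test_cross_language_correlation_inside_regions(geom):
    """Noise-free: correlation 1 in shared regions, ~0 in language-specific."""
    shared = sd.cuboid_region(geom, (0, 0, 0), (4, 8, 8), "shared_semantic")
    langspec = sd.cuboid_region(geom, (4, 0, 0), (8, 8, 8), "language_specific")
    cfg = sd.SimulationConfig(
        n_subjects=4, tasks=("reading",), n_runs=2, n_concepts=4,
        presentations_per_run=2, effect_regions=(shared, langspec),
        noise_sd=0.0, seed=7,
    )
    ds = sd.generate_beta_dataset(cfg, geom)
    corr_shared, corr_lang = [], []
    for s in range(4):
        for c in range(4):
            a = ds.betas[s, 0, 0, 0, c]
            b = ds.betas[s, 0, 1, 0, c]
            sv, lv = shared.mask[ds.mask], langspec.mask[ds.mask]
            corr_shared.append(np.corrcoef(a[sv], b[sv])[0, 1])
            corr_lang.append(np.corrcoef(a[lv], b[lv])[0, 1])
    assert np.allclose(corr_shared, 1.0)
    assert abs(np.mean(corr_lang)) < 0.15


def test_seed_determinism_and_divergence(geom):
    cfg, _ = _cfg(geom, "shared_semantic", noise_sd=1.0)
    a = sd.generate_beta_dataset(cfg, geom)
    b = sd.generate_beta_dataset(cfg, geom)
    np.testing.assert_array_equal(a.betas, b.betas)
    cfg2, _ = _cfg(geom, "shared_semantic", noise_sd=1.0, seed=43)
    c = sd.generate_beta_dataset(cfg2, geom)
    assert not np.array_equal(a.betas, c.betas)


def test_conflicting_overlapping_regions_rejected(geom):
    a = sd.cuboid_region(geom, (0, 0, 0), (4, 4, 4), "shared_semantic")
    b = sd.cuboid_region(geom, (2, 2, 2), (6, 6, 6), "language_specific")
    cfg = sd.SimulationConfig(
        n_subjects=1, tasks=("reading",), effect_regions=(a, b), seed=0
    )
    with pytest.raises(ValueError, match="conflicting sharing"):
        sd.generate_beta_dataset(cfg, geom)


def test_region_outside_geometry_rejected(geom):
    other = sd.VolumeGeometry.isotropic((12, 12, 12), 3.0)
    region = sd.cuboid_region(other, (0, 0, 0), (3, 3, 3), "shared_semantic")
    cfg = sd.SimulationConfig(n_subjects=1, tasks=("reading",), effect_regions=(region,))
    with pytest.raises(ValueError, match="outside geometry"):
        sd.generate_beta_dataset(cfg, geom)


def test_config_invariants():
    with pytest.raises(ValueError):
        sd.SimulationConfig(n_runs=1)
    with pytest.raises(ValueError):
        sd.SimulationConfig(n_concepts=1)
    with pytest.raises(ValueError):
        sd.SimulationConfig(noise_sd=-0.1)


def test_event_table_design_counts():
    """10 concepts x 6 presentations -> 60 rows per run, onsets increasing."""
    cfg = sd.SimulationConfig(n_subjects=1, tasks=("reading",), seed=3)
    rng = np.random.default_rng(0)
    ev = _make_run_events(cfg, rng, "L1", 0)
    f = ev.frame
    assert len(f) == 60
    assert (f["concept_id"].value_counts() == 6).all()
    assert (np.diff(f["onset_s"]) > 0).all()
    itis = np.diff(f["onset_s"]) - cfg.stimulus_duration_s
    assert itis.min() >= 1.0 - 1e-9 and itis.max() <= 5.2 + 1e-9
    # jitter values on the 300 ms lattice starting at 1.0 s
    steps = (itis - 1.0) / 0.3
    assert np.allclose(np.round(steps), steps, atol=1e-6)


def test_event_table_validation_rejects_bad_onsets():
    frame = pd.DataFrame(
        {"onset_s": [3.0, 2.0], "duration_s": 1.0, "concept_id": [1, 2],
         "language": "L1", "run": 0, "correct": True}
    )
    with pytest.raises(ValueError, match="strictly increasing"):
        EventTable(frame=frame, tr_s=2.0)


def test_event_table_tsv_round_trip(tmp_path):
    cfg = sd.SimulationConfig(n_subjects=1, tasks=("reading",), seed=3)
    ev = _make_run_events(cfg, np.random.default_rng(1), "L2", 2)
    path = tmp_path / "events.tsv"
    ev.to_tsv(path)
    back = EventTable.from_tsv(path, tr_s=2.0)
    pd.testing.assert_frame_equal(
        ev.frame.reset_index(drop=True), back.frame[ev.frame.columns], check_dtype=False
    )


def test_incorrect_trial_rate_follows_accuracy():
    cfg = sd.SimulationConfig(n_subjects=1, tasks=("reading",), accuracy=0.7, seed=5)
    rng = np.random.default_rng(2)
    rates = [
        _make_run_events(cfg, rng, "L1", r).frame["correct"].mean() for r in range(20)
    ]
    assert abs(np.mean(rates) - 0.7) < 0.05


def test_single_event_timeseries_is_scaled_hrf(geom):
    """Zero noise and drift: one event's voxel trace equals amplitude x HRF."""
    region = sd.cuboid_region(geom, (0, 0, 0), (8, 8, 8), "shared_semantic", amplitude=1.0)
    cfg = sd.SimulationConfig(
        n_subjects=1, tasks=("reading",), n_runs=2, n_concepts=2,
        presentations_per_run=1, effect_regions=(region,), noise_sd=0.0,
        drift_sd=0.0, n_scans_per_run=60, seed=9,
    )
    ts = sd.generate_timeseries(cfg, geom, subjects=[0])
    key = (0, "reading", "L1", 0)
    series, events = ts.series[key], ts.events[key]
    f = events.frame
    sig = sd.generate_beta_dataset(cfg, geom)
    vox = (4, 4, 4)
    trace = series[vox]
    # reconstruct expected trace from the generative amplitudes + regressors
    expected = np.zeros_like(trace)
    for c in (1, 2):
        sel = np.asarray(f["concept_id"]) == c
        reg = glm.convolve_events(
            np.asarray(f["onset_s"])[sel], np.asarray(f["duration_s"])[sel],
            cfg.n_scans_per_run, cfg.tr_s,
        )
        amp = sig.volume(0, "reading", "L1", 0, c)[vox]
        expected += amp * reg
    np.testing.assert_allclose(trace, expected, atol=1e-10)


def test_run_too_short_rejected(geom):
    cfg = sd.SimulationConfig(
        n_subjects=1, tasks=("reading",), n_scans_per_run=40, seed=1
    )
    with pytest.raises(ValueError, match="run too short"):
        sd.generate_timeseries(cfg, geom, subjects=[0])


def test_config_json_round_trip(geom, tmp_path):
    region = sd.cuboid_region(geom, (1, 1, 1), (4, 4, 4), "shared_semantic",
                              amplitude=1.5, tasks=("reading",), name="roi")
    cfg = sd.SimulationConfig(
        n_subjects=3, tasks=("naming", "reading"), effect_regions=(region,),
        noise_sd=0.7, seed=99,
    )
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    back = sd.SimulationConfig.from_json(path)
    assert (back.n_subjects, back.tasks, back.noise_sd, back.seed) == (3, ("naming", "reading"), 0.7, 99)
    r = back.effect_regions[0]
    assert (r.sharing, r.amplitude, r.tasks, r.name) == ("shared_semantic", 1.5, ("reading",), "roi")
    np.testing.assert_array_equal(r.mask, region.mask)
    a = sd.generate_beta_dataset(cfg, geom)
    b = sd.generate_beta_dataset(back, geom)
    np.testing.assert_array_equal(a.betas, b.betas)


def test_memory_guard(geom):
    cfg = sd.SimulationConfig(seed=1)  # full default design
    big = sd.VolumeGeometry.isotropic((64, 64, 34), 3.0)
    with pytest.raises(MemoryError):
        sd.generate_timeseries(cfg, big)
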