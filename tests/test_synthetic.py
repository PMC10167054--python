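import json

import numpy as np
import pytest

from corticoflow.emg import FapenParams, compute_fapen, preprocess_offline, select_steady_segment
from corticoflow.fnirs import REGIONS, mbll_convert
from corticoflow.protocol import DOMINANT, build_timeline
from corticoflow.synthetic import (
    Cohort,
    CortexModel,
    EffectConfig,
    MotorUnitPool,
    PhysioNoise,
    generate_cohort,
    simulate_emg,
    simulate_fnirs,
)


# ---------------------------------------------------------------------------
# motor-unit pools and EMG


def test_recruitment_is_nested_and_monotone():
    pool = MotorUnitPool.default_agonist()
    assert pool.n_units == 120
    assert np.all(np.diff(pool.recruitment_thresholds) >= 0)
    assert 0 < pool.n_active(0.2) < pool.n_active(0.8) == 120
    # antagonist recruits at the weakest co-activation drive
    ant = MotorUnitPool.default_antagonist()
    assert ant.n_active(0.15 * 0.2 * 0.6) > 0


def test_empty_pool_rejected():
    with pytest.raises(ValueError, match="empty"):
        MotorUnitPool(
            recruitment_thresholds=np.array([]),
            amplitudes_mv=np.array([]),
            durations_ms=np.array([]),
        )


def test_silent_muscle_warns(task_only_timeline):
    pool = MotorUnitPool.default_agonist()
    quiet = MotorUnitPool.exponential(threshold_range=(0.5, 0.75))
    with pytest.warns(UserWarning, match="silent"):
        simulate_emg(quiet, pool, excitation=0.3, coactivation=0.0,
                     timeline=task_only_timeline, seed=0)


def test_same_seed_bit_identical(task_only_timeline):
    pool_a = MotorUnitPool.default_agonist()
    pool_t = MotorUnitPool.default_antagonist()
    r1 = simulate_emg(pool_a, pool_t, 0.5, 0.2, task_only_timeline, seed=42)
    r2 = simulate_emg(pool_a, pool_t, 0.5, 0.2, task_only_timeline, seed=42)
    for m in ("BIC", "TRI"):
        np.testing.assert_array_equal(r1.samples[m], r2.samples[m])
    r3 = simulate_emg(pool_a, pool_t, 0.5, 0.2, task_only_timeline, seed=43)
    assert not np.array_equal(r1.samples["BIC"], r3.samples["BIC"])


def test_rest_contains_only_noise(short_protocol):
    tl = build_timeline(short_protocol)
    rec = simulate_emg(
        MotorUnitPool.default_agonist(), MotorUnitPool.default_antagonist(),
        0.8, 0.25, tl, seed=3, noise_sd_mv=0.003,
    )
    rest = rec.samples["BIC"][tl.mask("rest", 1000.0)]
    task = rec.samples["BIC"][tl.mask("task", 1000.0)]
    assert np.sqrt(np.mean(rest**2)) < 0.01
    assert np.sqrt(np.mean(task**2)) > 0.1


def test_task_rms_increases_with_excitation(task_only_timeline):
    """Energy monotonicity over seed averages."""
    pool_a = MotorUnitPool.default_agonist()
    pool_t = MotorUnitPool.default_antagonist()
    levels = [0.2, 0.4, 0.6, 0.8]
    means = []
    for exc in levels:
        vals = [
            np.sqrt(np.mean(simulate_emg(pool_a, pool_t, exc, 0.0,
                                         task_only_timeline, seed=s).samples["BIC"] ** 2))
            for s in range(4)
        ]
        means.append(np.mean(vals))
    assert all(a < b for a, b in zip(means[:-1], means[1:]))


def test_fapen_increases_with_recruitment(task_only_timeline):
    """The programmed complexity effect: the full 120-unit pool at 80%
    drive yields higher fApEn than the sparse recruitment at 20%,
    averaged over seeds, per the entropy oracle's own statistic."""
    pool_a = MotorUnitPool.default_agonist()
    pool_t = MotorUnitPool.default_antagonist()
    p = FapenParams()
    lo, hi = [], []
    for s in range(6):
        for exc, sink in [(0.2, lo), (0.8, hi)]:
            rec = simulate_emg(pool_a, pool_t, exc, 0.0, task_only_timeline, seed=s)
            filt = preprocess_offline(rec)
            seg = select_steady_segment(filt, "BIC", duration_s=5.0)
            sink.append(compute_fapen(seg, p))
    assert np.mean(hi) > np.mean(lo)


def test_invalid_drives_rejected(task_only_timeline):
    pool = MotorUnitPool.default_agonist()
    with pytest.raises(ValueError):
        simulate_emg(pool, pool, 0.0, 0.1, task_only_timeline, seed=0)
    with pytest.raises(ValueError):
        simulate_emg(pool, pool, 0.5, 1.5, task_only_timeline, seed=0)


# ---------------------------------------------------------------------------
# cortical hemodynamics


def test_null_cortex_flat_zero_od(short_protocol):
    tl = build_timeline(short_protocol)
    opt = simulate_fnirs(CortexModel.null(), tl, drive=1.0, seed=0)
    assert np.all(opt.od == 0)


def test_programmed_hbo2_recovered_through_mbll(short_protocol):
    """Noise-free generator output fed to the forward MBLL recovers the
    programmed hemodynamics to 1e-9 uM."""
    tl = build_timeline(short_protocol)
    cortex = CortexModel(
        gains={r: 1.0 for r in REGIONS},
        coupling=np.zeros((6, 6)),
        coupling_amp=0.0,
        directed_amp=0.0,
        channel_noise_sd=0.0,
        physio=PhysioNoise.silent(),
    )
    opt = simulate_fnirs(cortex, tl, drive=2.0, seed=0)
    hemo = mbll_convert(opt)
    from corticoflow.fnirs import task_regressor

    programmed = 2.0 * task_regressor(tl, 11.0)
    for ch in range(30):
        np.testing.assert_allclose(hemo.hbo2[:, ch], programmed, atol=1e-9)
        np.testing.assert_allclose(hemo.hbr[:, ch], -0.3 * programmed, atol=1e-9)


def test_unstable_directed_system_rejected():
    with pytest.raises(ValueError, match="unstable"):
        CortexModel(
            gains={r: 0.0 for r in REGIONS},
            coupling=np.zeros((6, 6)),
            directed={("LMC", "RMC"): 1.2, ("RMC", "LMC"): 1.1},
        )


def test_asymmetric_coupling_rejected():
    C = np.zeros((6, 6))
    C[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        CortexModel(gains={}, coupling=C)


def test_programmed_coupling_dominates_fc():
    """Latent coupling 0.8 between LMC and RMC only: the estimated
    region-pair correlation is highest there, near the closed-form value
    w a^2 / (a^2 + sigma_ch^2 / n_ch). The full session length keeps the
    effective dof of the band-limited series high enough for the
    closed-form comparison."""
    from corticoflow.connectivity import functional_connectivity
    from corticoflow.fnirs import bandpass_hemo, mark_invalid_channels
    from corticoflow.protocol import ProtocolSpec

    tl = build_timeline(ProtocolSpec())
    C = np.zeros((6, 6))
    i, j = REGIONS.index("LMC"), REGIONS.index("RMC")
    C[i, j] = C[j, i] = 0.8
    cortex = CortexModel(
        gains={r: 0.0 for r in REGIONS},
        coupling=C,
        coupling_amp=0.4,
        directed_amp=0.0,
        channel_noise_sd=0.05,
        physio=PhysioNoise.silent(),
    )
    mats = []
    for s in range(20):
        opt = simulate_fnirs(cortex, tl, drive=0.0, seed=s)
        hemo = mbll_convert(opt)
        hemo.valid = mark_invalid_channels(opt)
        hemo = bandpass_hemo(hemo)
        mats.append(functional_connectivity(hemo, scope="region", window="session").values)
    mean_fc = np.tanh(np.mean(np.arctanh(np.clip(mats, -0.999999, 0.999999)), axis=0))
    off = mean_fc.copy()
    np.fill_diagonal(off, -np.inf)
    assert np.unravel_index(np.argmax(off), off.shape) in {(i, j), (j, i)}
    # closed form: corr = w a^2 / (a^2 + sigma^2/5) with a=0.4, sigma=0.05
    expect = 0.8 * 0.4**2 / (0.4**2 + 0.05**2 / 5)
    assert mean_fc[i, j] == pytest.approx(expect, abs=0.05)


# ---------------------------------------------------------------------------
# cohort


def test_cohort_size_and_determinism(short_protocol):
    c1 = Cohort(n_subjects=3, protocol=short_protocol, seed=11)
    c2 = Cohort(n_subjects=3, protocol=short_protocol, seed=11)
    keys = [ds.key for ds in c1.datasets()]
    assert len(keys) == 3 * 4
    ds1 = c1.dataset(2, DOMINANT, 0.8)
    ds2 = c2.dataset(2, DOMINANT, 0.8)
    np.testing.assert_array_equal(ds1.emg.samples["BIC"], ds2.emg.samples["BIC"])
    np.testing.assert_array_equal(ds1.optical.od, ds2.optical.od)
    assert ds1.truth == ds2.truth


def test_default_cohort_has_84_datasets(default_cohort):
    truth = default_cohort.ground_truth()
    assert len(truth["datasets"]) == 21 * 4
    assert len(truth["drives"]) == 21


def test_null_effects_have_no_cross_modal_drive():
    c = Cohort(n_subjects=4, effects=EffectConfig.null(), seed=0)
    assert np.all(c.drives == 1.0)
    truth = c.ground_truth()
    assert all(not d["directed_edges"] and not d["coupling"] for d in truth["datasets"])


def test_cohort_written_files_round_trip(tmp_path, short_protocol):
    from corticoflow.io import read_dataset, read_manifest, read_mvc_trials

    out = tmp_path / "cohort"
    cohort = generate_cohort(2, short_protocol, seed=5, out_dir=out)
    manifest = read_manifest(out)
    assert len(manifest) == 8
    truth = json.loads((out / "ground_truth.json").read_text())
    assert len(truth["datasets"]) == 8

    entry = manifest.iloc[0]
    emg, optical = read_dataset(out / entry["path"])
    ds = cohort.dataset(int(entry["subject"]), entry["side"], float(entry["force"]))
    # CSV float formatting bounds the round-trip error
    np.testing.assert_allclose(emg.samples["BIC"], ds.emg.samples["BIC"], atol=1e-4)
    np.testing.assert_allclose(optical.od, ds.optical.od, rtol=1e-4, atol=1e-9)
    assert emg.timeline == ds.emg.timeline
    assert len(read_mvc_trials(out, 1, "BIC")) == 3

    with pytest.raises(FileExistsError):
        generate_cohort(2, short_protocol, seed=5, out_dir=out)
    generate_cohort(2, short_protocol, seed=5, out_dir=out, overwrite=True)


def test_cohort_rejects_single_subject():
    with pytest.raises(ValueError):
        Cohort(n_subjects=1)
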