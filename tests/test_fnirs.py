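import numpy as np
import pytest

from corticoflow.fnirs import (
    HemoSignal,
    OpticalRecording,
    bandpass_hemo,
    default_layout,
    glm_activation,
    mark_invalid_channels,
    mbll_convert,
    mbll_forward,
    remove_motion_artifacts,
    task_regressor,
)
from corticoflow.protocol import ProtocolSpec, build_timeline


@pytest.fixture
def timeline(short_protocol):
    return build_timeline(short_protocol)


def _optical(od, timeline, rate=11.0):
    return OpticalRecording(od=od, rate=rate, layout=default_layout(), timeline=timeline)


def _hemo(hbo2, timeline, rate=11.0, valid=None):
    n_ch = hbo2.shape[1]
    return HemoSignal(
        hbo2=hbo2,
        hbr=-0.3 * hbo2,
        rate=rate,
        layout=default_layout()[:n_ch],
        timeline=timeline,
        valid=np.ones(n_ch, bool) if valid is None else valid,
    )


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


# ---------------------------------------------------------------------------
# MBLL


def test_zero_od_gives_zero_concentration(timeline):
    n = timeline.n_samples(11.0)
    hemo = mbll_convert(_optical(np.zeros((n, 30, 2)), timeline))
    assert np.all(hemo.hbo2 == 0) and np.all(hemo.hbr == 0)


def test_forward_inverse_round_trip(timeline, rng):
    n = timeline.n_samples(11.0)
    hbo2 = rng.normal(0, 1, (n, 30))
    hbr = rng.normal(0, 0.5, (n, 30))
    od = mbll_forward(hbo2, hbr)
    back = mbll_convert(_optical(od, timeline))
    np.testing.assert_allclose(back.hbo2, hbo2, atol=1e-9)
    np.testing.assert_allclose(back.hbr, hbr, atol=1e-9)


def test_doubling_dpf_halves_concentrations(timeline, rng):
    n = timeline.n_samples(11.0)
    od = rng.normal(0, 0.01, (n, 30, 2))
    c1 = mbll_convert(_optical(od, timeline), dpf=6.0)
    c2 = mbll_convert(_optical(od, timeline), dpf=12.0)
    np.testing.assert_allclose(c2.hbo2, c1.hbo2 / 2, rtol=1e-12)


def test_mbll_linearity(timeline, rng):
    n = timeline.n_samples(11.0)
    od_a = rng.normal(0, 0.01, (n, 30, 2))
    od_b = rng.normal(0, 0.01, (n, 30, 2))
    ca = mbll_convert(_optical(od_a, timeline)).hbo2
    cb = mbll_convert(_optical(od_b, timeline)).hbo2
    mixed = mbll_convert(_optical(2 * od_a + od_b, timeline)).hbo2
    np.testing.assert_allclose(mixed, 2 * ca + cb, atol=1e-12)


def test_singular_extinction_rejected(timeline):
    n = timeline.n_samples(11.0)
    bad = {730.0: (1.0, 1.0), 850.0: (2.0, 2.0)}
    with pytest.raises(ValueError, match="singular"):
        mbll_convert(_optical(np.zeros((n, 30, 2)), timeline), extinction_table=bad)


# ---------------------------------------------------------------------------
# channel quality and artifacts


def test_channel_quality_flags(timeline, rng):
    n = timeline.n_samples(11.0)
    od = rng.normal(0.01, 0.001, (n, 30, 2))
    od[:, 3, :] = 0.25  # flatlined
    od[:, 7, 0] = rng.normal(0.0, 0.5, n)  # unstable intensity
    valid = mark_invalid_channels(_optical(od, timeline))
    assert not valid[3] and not valid[7]
    assert valid.sum() == 28


def test_artifact_removal_idempotent_on_clean_signal(timeline, rng):
    n = timeline.n_samples(11.0)
    hemo = _hemo(rng.normal(0, 0.1, (n, 5)), timeline)
    out = remove_motion_artifacts(hemo)
    np.testing.assert_allclose(out.hbo2, hemo.hbo2)
    assert out.valid.all()


def test_spike_injected_and_recovered(timeline, rng):
    """A spike at 10x the signal's peak amplitude is detected and the
    local deviation from the pre-spike signal stays under 3 SD."""
    n = timeline.n_samples(11.0)
    clean = rng.normal(0, 0.1, (n, 1))
    spiked = clean.copy()
    spiked[n // 2, 0] += 10 * np.abs(clean).max()
    out = remove_motion_artifacts(_hemo(spiked, timeline))
    resid = out.hbo2[:, 0] - clean[:, 0]
    lo, hi = n // 2 - 15, n // 2 + 15
    assert np.abs(resid[lo:hi]).max() < 3 * clean.std()
    assert not np.allclose(out.hbo2, spiked)  # spike actually touched


def test_pervasive_artifact_span_invalidates_channel(timeline, rng):
    """A contiguous high-amplitude span covering 30% of the record
    exceeds the 20% artifact budget: channel is invalidated, not patched."""
    n = timeline.n_samples(11.0)
    x = rng.normal(0, 0.05, (n, 1))
    span = slice(int(0.3 * n), int(0.6 * n))
    x[span, 0] += rng.normal(0, 3.0, span.stop - span.start)
    out = remove_motion_artifacts(_hemo(x, timeline))
    assert not out.valid[0]


# ---------------------------------------------------------------------------
# functional band-pass


def test_cardiac_band_removed():
    """1.1 Hz suppressed >= 99% in steady state (edge ring-in of the slow
    0.01 Hz high-pass poles excluded), matching the designed response."""
    from scipy import signal as sp_signal

    tl = build_timeline(ProtocolSpec())
    n = tl.n_samples(11.0)
    t = np.arange(n) / 11.0
    x = np.sin(2 * np.pi * 1.1 * t)[:, None]
    y = bandpass_hemo(_hemo(x, tl)).hbo2[:, 0]
    mid = slice(n // 3, 2 * n // 3)
    assert rms(y[mid]) < 0.01 * rms(x)
    sos = sp_signal.butter(4, [0.01, 0.2], btype="bandpass", fs=11.0, output="sos")
    _, h = sp_signal.sosfreqz(sos, worN=[2 * np.pi * 1.1 / 11.0])
    assert np.abs(h[0]) ** 2 < 0.01  # double (zero-phase) pass


def test_functional_band_passed(timeline):
    n = timeline.n_samples(11.0)
    t = np.arange(n) / 11.0
    x = np.sin(2 * np.pi * 0.05 * t)[:, None]
    y = bandpass_hemo(_hemo(x, timeline)).hbo2[:, 0]
    # within 3 dB in the middle of the record (away from edge transients)
    mid = slice(n // 4, 3 * n // 4)
    assert rms(y[mid]) > 10 ** (-3 / 20) * rms(x[mid])


def test_dc_offset_removed(timeline):
    n = timeline.n_samples(11.0)
    x = np.full((n, 1), 5.0)
    y = bandpass_hemo(_hemo(x, timeline)).hbo2[:, 0]
    assert np.abs(y).max() < 0.05


# ---------------------------------------------------------------------------
# GLM activation


def test_exact_regressor_recovers_unit_beta(timeline):
    reg = task_regressor(timeline, 11.0)
    hemo = _hemo(np.tile(reg[:, None], (1, 30)), timeline)
    act = glm_activation(hemo)
    np.testing.assert_allclose(act.beta, 1.0, atol=1e-10)
    assert set(act.region_integral) == {"LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL"}


def test_pure_noise_beta_centered_at_zero(timeline, rng):
    """Monte-Carlo null: mean beta within 2 SE of zero."""
    n = timeline.n_samples(11.0)
    betas = []
    for _ in range(100):
        hemo = _hemo(rng.standard_normal((n, 1)), timeline)
        betas.append(glm_activation(hemo).beta[0])
    betas = np.asarray(betas)
    assert abs(betas.mean()) < 2 * betas.std(ddof=1) / np.sqrt(len(betas))


def test_invalid_channels_never_enter_region_means(timeline, rng):
    n = timeline.n_samples(11.0)
    reg = task_regressor(timeline, 11.0)
    hbo2 = np.tile(reg[:, None], (1, 30))
    hbo2[:, 0] += 1e3  # wild channel, masked below
    valid = np.ones(30, bool)
    valid[0] = False
    act = glm_activation(_hemo(hbo2, timeline, valid=valid))
    # LPFC mean over channels 1..4 only: identical to the clean response
    clean = glm_activation(_hemo(np.tile(reg[:, None], (1, 30)), timeline))
    assert act.region_integral["LPFC"] == pytest.approx(clean.region_integral["LPFC"])


def test_no_task_block_rejected(rng):
    from corticoflow.protocol import Timeline

    tl = Timeline.from_records([{"label": "rest", "start_s": 0, "end_s": 60}])
    hemo = _hemo(rng.standard_normal((660, 2)), tl)
    with pytest.raises(ValueError):
        glm_activation(hemo)


def test_pipeline_integral_proportional_to_gain(timeline):
    """Noise-free synthetic recordings: the recovered activation integral
    is proportional to the programmed region gain (r > 0.99)."""
    from corticoflow.synthetic import CortexModel, simulate_fnirs
    from corticoflow.fnirs import REGIONS

    gains = [0.2, 0.5, 1.0, 1.5, 2.0]
    integrals = []
    for g in gains:
        cortex = CortexModel(
            gains={r: (g if r == "LMC" else 0.0) for r in REGIONS},
            coupling=np.zeros((6, 6)),
            coupling_amp=0.0,
            directed_amp=0.0,
            channel_noise_sd=0.0,
            physio=__import__("corticoflow.synthetic", fromlist=["PhysioNoise"]).PhysioNoise.silent(),
        )
        opt = simulate_fnirs(cortex, timeline, drive=1.0, seed=0)
        hemo = bandpass_hemo(mbll_convert(opt))
        act = glm_activation(hemo)
        integrals.append(act.region_integral["LMC"])
    r = np.corrcoef(gains, integrals)[0, 1]
    assert r > 0.99
    assert integrals[-1] > integrals[0] > 0
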