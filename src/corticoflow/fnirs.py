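"""fNIRS hemodynamic pipeline.

Dual-wavelength (730/850 nm) optical-density changes from a 30-channel,
30-mm source-detector montage covering six cortical regions (LPFC, RPFC,
LMC, RMC, LOL, ROL) are converted to oxy-/deoxy-hemoglobin concentration
changes with the modified Beer-Lambert law (MBLL), cleaned of invalid
channels and motion artifacts, band-pass filtered to the functional band
(0.01-0.2 Hz), and summarized per channel as a GLM task beta and a
baseline-corrected task-block HbO2 integral.

MBLL, per channel and wavelength pair:

    dOD(lambda) = [eps_HbO2(lambda) * dHbO2 + eps_HbR(lambda) * dHbR] * d * DPF

with source-detector distance d (cm) and differential pathlength factor
DPF; the 2x2 extinction system is inverted to recover concentrations in
micromolar. HbO2 is the downstream activation marker; HbR is retained in
containers but unused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .protocol import Timeline

logger = logging.getLogger(__name__)

REGIONS = ("LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL")
CHANNELS_PER_REGION = 5
N_CHANNELS = len(REGIONS) * CHANNELS_PER_REGION
WAVELENGTHS_NM = (730.0, 850.0)

#: Molar extinction coefficients, cm^-1 / M (hemoglobin compilation of
#: W. B. Gratzer / S. Prahl), rows = wavelength, cols = (HbO2, HbR).
EXTINCTION_CM_M = {
    730.0: (390.0, 1102.2),
    850.0: (1058.0, 691.32),
}

DEFAULT_DPF = 6.0
DEFAULT_DISTANCE_CM = 3.0  # 30-mm separation


def default_layout() -> list[dict]:
    """Channel -> (source, detector, region) map: 5 channels per region."""
    layout = []
    for ci in range(N_CHANNELS):
        region = REGIONS[ci // CHANNELS_PER_REGION]
        layout.append(
            {
                "channel": ci,
                "name": f"ch{ci + 1:02d}",
                "source": ci,
                "detector": ci,
                "region": region,
            }
        )
    return layout


@dataclass
class OpticalRecording:
    """Per-channel, per-wavelength optical-density change series."""

    od: np.ndarray  # (n_samples, n_channels, 2) for (730, 850) nm
    rate: float
    layout: list[dict]
    timeline: Timeline
    distance_cm: float = DEFAULT_DISTANCE_CM
    force: float | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        if self.od.ndim != 3 or self.od.shape[2] != 2:
            raise ValueError("od must have shape (samples, channels, 2 wavelengths)")
        if self.od.shape[1] != len(self.layout):
            raise ValueError("layout does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]

    def regions(self) -> list[str]:
        return [entry["region"] for entry in self.layout]


@dataclass
class HemoSignal:
    """Hemoglobin concentration changes (micromolar) with validity mask."""

    hbo2: np.ndarray  # (n_samples, n_channels)
    hbr: np.ndarray
    rate: float
    layout: list[dict]
    timeline: Timeline
    valid: np.ndarray  # (n_channels,) bool
    force: float | None = None
    side: str | None = None

    @property
    def n_channels(self) -> int:
        return self.hbo2.shape[1]

    def regions(self) -> list[str]:
        return [entry["region"] for entry in self.layout]

    def region_means(self) -> tuple[np.ndarray, list[str]]:
        """HbO2 averaged over each region's valid channels; regions with no
        valid channel are dropped."""
        regions = np.array(self.regions())
        series, names = [], []
        for r in REGIONS:
            sel = (regions == r) & self.valid
            if sel.any():
                series.append(self.hbo2[:, sel].mean(axis=1))
                names.append(r)
        if not names:
            raise ValueError("no valid channels in any region")
        return np.column_stack(series), names


@dataclass
class ActivationResult:
    """Per-channel GLM beta and baseline-corrected task HbO2 integral."""

    beta: np.ndarray  # (n_channels,)
    integral_um_s: np.ndarray  # (n_channels,)
    valid: np.ndarray
    layout: list[dict]
    region_integral: dict[str, float]
    region_beta: dict[str, float]


# ---------------------------------------------------------------------------
# MBLL


def extinction_matrix(extinction_table: dict[float, tuple[float, float]] | None = None) -> np.ndarray:
    table = extinction_table or EXTINCTION_CM_M
    try:
        rows = [table[w] for w in WAVELENGTHS_NM]
    except KeyError as exc:  # pragma: no cover
        raise ValueError(f"extinction table missing wavelength {exc}") from exc
    E = np.asarray(rows, dtype=float) * 1e-6  # cm^-1 / uM
    if abs(np.linalg.det(E)) < 1e-18:
        raise ValueError("extinction matrix is singular")
    return E


def mbll_forward(
    hbo2: np.ndarray,
    hbr: np.ndarray,
    distance_cm: float = DEFAULT_DISTANCE_CM,
    dpf: float = DEFAULT_DPF,
    extinction_table: dict | None = None,
) -> np.ndarray:
    """Synthesize optical-density changes from known concentration changes.

    Inverse of :func:`mbll_convert`; used by the synthetic generator so the
    pipeline's forward conversion is exercised end to end.
    """
    E = extinction_matrix(extinction_table)
    conc = np.stack([hbo2, hbr], axis=-1)  # (..., 2)
    return conc @ E.T * (distance_cm * dpf)


def mbll_convert(
    optical: OpticalRecording,
    dpf: float = DEFAULT_DPF,
    extinction_table: dict | None = None,
) -> HemoSignal:
    """Modified Beer-Lambert conversion of dOD to (dHbO2, dHbR) in uM."""
    if optical.distance_cm <= 0:
        raise ValueError("source-detector distance must be positive")
    E = extinction_matrix(extinction_table)
    Einv = np.linalg.inv(E)
    conc = optical.od @ Einv.T / (optical.distance_cm * dpf)
    return HemoSignal(
        hbo2=conc[:, :, 0],
        hbr=conc[:, :, 1],
        rate=optical.rate,
        layout=optical.layout,
        timeline=optical.timeline,
        valid=np.ones(optical.n_channels, dtype=bool),
        force=optical.force,
        side=optical.side,
    )


# ---------------------------------------------------------------------------
# channel quality and motion artifacts


def mark_invalid_channels(
    optical: OpticalRecording,
    flat_var: float = 1e-12,
    intensity_cv_max: float = 0.15,
) -> np.ndarray:
    """Flag flat or unstable channels.

    A channel is invalid if its OD variance is below ``flat_var`` at either
    wavelength, or the coefficient of variation of the implied raw
    intensity (10^-OD) exceeds ``intensity_cv_max``.
    """
    if optical.od.shape[0] < optical.rate:
        raise ValueError("need at least 1 s of data")
    valid = np.ones(optical.n_channels, dtype=bool)
    for ci in range(optical.n_channels):
        for wi in range(2):
            od = optical.od[:, ci, wi]
            if od.var() < flat_var:
                valid[ci] = False
                break
            intensity = np.power(10.0, -od)
            if intensity.std() / intensity.mean() > intensity_cv_max:
                valid[ci] = False
                break
    if not valid.all():
        logger.info("invalid channels: %s", np.flatnonzero(~valid).tolist())
    return valid


def remove_motion_artifacts(
    hemo: HemoSignal,
    sd_window_s: float = 1.0,
    sd_factor: float = 5.0,
    max_artifact_fraction: float = 0.2,
) -> HemoSignal:
    """Spike suppression by moving-SD thresholding + cubic interpolation.

    Samples where the 1-s moving SD exceeds ``sd_factor`` times its median
    are replaced by cubic interpolation from flanking clean samples. If the
    artifact span exceeds ``max_artifact_fraction`` of the record the
    channel is marked invalid instead.
    """
    w = max(3, int(round(sd_window_s * hemo.rate)))
    kernel = np.ones(w) / w
    hbo2 = hemo.hbo2.copy()
    hbr = hemo.hbr.copy()
    valid = hemo.valid.copy()
    n = hbo2.shape[0]
    t = np.arange(n)
    for ci in range(hemo.n_channels):
        if not valid[ci]:
            continue
        x = hbo2[:, ci]
        m1 = np.convolve(x, kernel, mode="same")
        m2 = np.convolve(x**2, kernel, mode="same")
        msd = np.sqrt(np.maximum(m2 - m1**2, 0.0))
        med = np.median(msd)
        if med <= 0:
            continue
        bad = msd > sd_factor * med
        n_bad = int(bad.sum())
        if n_bad == 0:
            continue
        if n_bad > max_artifact_fraction * n:
            valid[ci] = False
            logger.info("channel %d invalidated: %.0f%% artifact", ci, 100 * n_bad / n)
            continue
        good = ~bad
        for arr in (hbo2, hbr):
            # shape-preserving cubic: an ordinary cubic spline overshoots
            # badly across gaps anchored in noise
            f = interpolate.PchipInterpolator(t[good], arr[good, ci])
            arr[bad, ci] = f(t[bad])
        logger.info("channel %d: interpolated %d artifact samples", ci, n_bad)
    return HemoSignal(
        hbo2=hbo2, hbr=hbr, rate=hemo.rate, layout=hemo.layout,
        timeline=hemo.timeline, valid=valid, force=hemo.force, side=hemo.side,
    )


def bandpass_hemo(hemo: HemoSignal, low_hz: float = 0.01, high_hz: float = 0.2) -> HemoSignal:
    """Zero-phase 0.01-0.2 Hz Butterworth band-pass of the hemoglobin series.

    Removes cardiac and respiratory interference and slow drift.
    """
    tau = 1.0 / (2 * np.pi * low_hz)
    if hemo.hbo2.shape[0] < 3 * tau * hemo.rate:
        logger.warning("record shorter than 3 high-pass time constants; edge effects likely")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=hemo.rate, output="sos")
    # generous reflection padding keeps the slow high-pass ring-in out of
    # the record
    pad = min(hemo.hbo2.shape[0] - 1, int(round(3 * tau * hemo.rate)))
    return HemoSignal(
        hbo2=signal.sosfiltfilt(sos, hemo.hbo2, axis=0, padlen=pad),
        hbr=signal.sosfiltfilt(sos, hemo.hbr, axis=0, padlen=pad),
        rate=hemo.rate,
        layout=hemo.layout,
        timeline=hemo.timeline,
        valid=hemo.valid.copy(),
        force=hemo.force,
        side=hemo.side,
    )


# ---------------------------------------------------------------------------
# hemodynamic response and activation


def double_gamma_hrf(rate: float, duration_s: float = 30.0,
                     peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration_s, 1.0 / rate)
    h = gamma_dist.pdf(t, peak_s) - gamma_dist.pdf(t, undershoot_s) / ratio
    return h / h.max()


def task_regressor(timeline: Timeline, rate: float, hrf: np.ndarray | None = None) -> np.ndarray:
    """Task boxcar convolved with the HRF, peak-normalized."""
    n = timeline.n_samples(rate)
    boxcar = timeline.mask("task", rate).astype(float)
    if hrf is None:
        hrf = double_gamma_hrf(rate)
    reg = np.convolve(boxcar, hrf)[:n]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def glm_activation(
    hemo: HemoSignal,
    baseline_s: float = 2.0,
    hrf: np.ndarray | None = None,
) -> ActivationResult:
    """Per-channel GLM beta and baseline-corrected task HbO2 integral.

    Design matrix: [boxcar (x) HRF, constant, linear drift]. The integral is
    the trapezoid of the task-block-averaged HbO2, corrected by the mean of
    the ``baseline_s`` seconds preceding each task block, over the task
    window (uM*s). Region values average the region's valid channels.
    """
    timeline, rate = hemo.timeline, hemo.rate
    task_ranges = timeline.sample_ranges("task", rate)
    if not task_ranges:
        raise ValueError("timeline contains no task block")
    if not hemo.valid.any():
        raise ValueError("no valid channels")
    n = hemo.hbo2.shape[0]
    X = np.column_stack(
        [task_regressor(timeline, rate, hrf), np.ones(n), np.linspace(-1, 1, n)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design")
    beta_all, *_ = np.linalg.lstsq(X, hemo.hbo2, rcond=None)
    beta = beta_all[0]

    # block-averaged, baseline-corrected task epoch
    n_base = int(round(baseline_s * rate))
    block_len = min(hi - lo for lo, hi in task_ranges)
    epochs = []
    for lo, hi in task_ranges:
        if lo - n_base < 0 or lo + block_len > n:
            continue
        base = hemo.hbo2[lo - n_base : lo].mean(axis=0)
        epochs.append(hemo.hbo2[lo : lo + block_len] - base)
    if not epochs:
        raise ValueError("no task block with a full pre-task baseline window")
    mean_epoch = np.mean(epochs, axis=0)
    integral = np.trapezoid(mean_epoch, dx=1.0 / rate, axis=0)

    regions = np.array(hemo.regions())
    region_integral, region_beta = {}, {}
    for r in REGIONS:
        sel = (regions == r) & hemo.valid
        if sel.any():
            region_integral[r] = float(integral[sel].mean())
            region_beta[r] = float(beta[sel].mean())
    return ActivationResult(
        beta=beta,
        integral_um_s=integral,
        valid=hemo.valid.copy(),
        layout=hemo.layout,
        region_integral=region_integral,
        region_beta=region_beta,
    )
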