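"""Synthetic paired sEMG + fNIRS cohort generator.

Emulates an isometric elbow-contraction protocol: per subject, one session
per condition (20%/80% MVC x dominant/non-dominant arm), each a 3-min
relaxation followed by five 15-s task / 30-s rest cycles, with biceps
(BIC, agonist) and triceps (TRI, antagonist) EMG at 1 kHz and a
30-channel dual-wavelength optical recording over six cortical regions at
11 Hz.

EMG is an interference pattern: motor units with exponentially spaced
recruitment thresholds fire as jittered point processes once the drive
exceeds their threshold, each convolved with a Ricker-shaped action
potential whose amplitude and duration grow with recruitment index.
Higher force recruits more units at higher rates, producing a denser,
more complex signal (higher fApEn) - the programmed effect downstream
analyses must recover.

Cortical hemodynamics per region: a task boxcar convolved with the
canonical double-gamma HRF scaled by a region gain, plus
correlation-structured latent noise (programmed functional connectivity),
a stable lagged cross-region recursion on slow innovations (programmed
directed influence), physiological sinusoids (cardiac 1.1 Hz,
respiration 0.25 Hz, Mayer 0.1 Hz), drift and white noise. Channels add
white sensor noise to their region signal; HbR is -0.3 x HbO2, and the
pair is pushed through the inverse modified Beer-Lambert law so the
analysis pipeline's forward conversion is exercised.

A per-subject latent drive scales both motor-unit excitation and task
gains, inducing the programmed positive fApEn <-> HbO2 coupling across
the cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .emg import EmgRecording, MUSCLES
from .fnirs import (
    CHANNELS_PER_REGION,
    DEFAULT_DISTANCE_CM,
    DEFAULT_DPF,
    OpticalRecording,
    REGIONS,
    default_layout,
    mbll_forward,
    task_regressor,
)
from .protocol import DOMINANT, NON_DOMINANT, Block, ProtocolSpec, Timeline, build_timeline

__all__ = [
    "MotorUnitPool",
    "PhysioNoise",
    "CortexModel",
    "EffectConfig",
    "Dataset",
    "Cohort",
    "simulate_emg",
    "simulate_fnirs",
    "simulate_mvc_trials",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# motor-unit pool and EMG


@dataclass(frozen=True)
class MotorUnitPool:
    """Recruitment-ordered motor-unit pool for one muscle."""

    recruitment_thresholds: np.ndarray  # fraction of MVC, nondecreasing
    amplitudes_mv: np.ndarray
    durations_ms: np.ndarray
    base_rate_hz: float = 8.0
    rate_gain_hz: float = 40.0  # extra Hz per unit of supra-threshold drive
    isi_cv: float = 0.2

    def __post_init__(self) -> None:
        thr = np.sort(np.asarray(self.recruitment_thresholds, dtype=float))
        object.__setattr__(self, "recruitment_thresholds", thr)
        if thr.size == 0:
            raise ValueError("empty motor-unit pool")
        if (thr < 0).any() or (thr >= 1).any():
            raise ValueError("recruitment thresholds must lie in [0, 1)")
        if self.base_rate_hz <= 0:
            raise ValueError("base_rate_hz must be positive")
        if self.isi_cv < 0:
            raise ValueError("isi_cv must be non-negative")

    @property
    def n_units(self) -> int:
        return self.recruitment_thresholds.size

    def n_active(self, excitation: float) -> int:
        return int(np.sum(self.recruitment_thresholds < excitation))

    @classmethod
    def exponential(
        cls,
        n_units: int = 120,
        threshold_range: tuple[float, float] = (0.1, 0.75),
        amplitude_range_mv: tuple[float, float] = (0.08, 0.6),
        duration_range_ms: tuple[float, float] = (15.0, 8.0),
        **kwargs,
    ) -> "MotorUnitPool":
        """Exponentially spaced thresholds and amplitudes over the given spans."""
        u = np.linspace(0.0, 1.0, n_units)
        t0, t1 = threshold_range
        a0, a1 = amplitude_range_mv
        d0, d1 = duration_range_ms
        return cls(
            recruitment_thresholds=t0 * (t1 / t0) ** u,
            amplitudes_mv=a0 * (a1 / a0) ** u,
            durations_ms=d0 + (d1 - d0) * u,
            **kwargs,
        )

    @classmethod
    def linear(
        cls,
        n_units: int = 120,
        threshold_range: tuple[float, float] = (0.015, 0.3),
        amplitude_range_mv: tuple[float, float] = (0.08, 0.6),
        duration_range_ms: tuple[float, float] = (15.0, 8.0),
        **kwargs,
    ) -> "MotorUnitPool":
        """Linearly spaced thresholds; amplitudes still exponential."""
        u = np.linspace(0.0, 1.0, n_units)
        a0, a1 = amplitude_range_mv
        d0, d1 = duration_range_ms
        return cls(
            recruitment_thresholds=np.linspace(*threshold_range, n_units),
            amplitudes_mv=a0 * (a1 / a0) ** u,
            durations_ms=d0 + (d1 - d0) * u,
            **kwargs,
        )

    @classmethod
    def default_agonist(cls) -> "MotorUnitPool":
        # exponential thresholds over [0.1, 0.75): ~41 of 120 units at 20%
        # MVC, all at 80%; recruitment stays nonempty down to the weakest
        # per-subject drive (0.6 x 20% = 12% MVC)
        return cls.exponential(threshold_range=(0.1, 0.75))

    @classmethod
    def default_antagonist(cls) -> "MotorUnitPool":
        # linear low-threshold span so co-activation drives (1.8-25% of its
        # own MVC) recruit a nonempty, nested set that grows steeply with
        # force, programming the co-contraction increase at 80% MVC
        return cls.linear(threshold_range=(0.015, 0.3))


def _ricker_template(amp_mv: float, duration_ms: float, rate: float) -> np.ndarray:
    """Second derivative of a Gaussian (Ricker wavelet) action potential."""
    half = duration_ms / 2000.0  # s
    t = np.arange(-half, half, 1.0 / rate)
    sigma = half / 3.5
    w = (1 - (t / sigma) ** 2) * np.exp(-(t**2) / (2 * sigma**2))
    return amp_mv * w


def _unit_spike_train(
    rng: np.random.Generator,
    rate_hz: float,
    t_start: float,
    t_end: float,
    isi_cv: float,
) -> np.ndarray:
    """Jittered point-process firing times within [t_start, t_end)."""
    mean_isi = 1.0 / rate_hz
    times = []
    t = t_start + rng.uniform(0.0, mean_isi)
    while t < t_end:
        times.append(t)
        isi = rng.normal(mean_isi, isi_cv * mean_isi)
        t += max(isi, 0.2 * mean_isi)
    return np.asarray(times)


def _interference(
    pool: MotorUnitPool,
    excitation: float,
    timeline: Timeline,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = timeline.n_samples(rate)
    out = np.zeros(n)
    if excitation <= 0:
        return out
    active = np.flatnonzero(pool.recruitment_thresholds < excitation)
    if active.size == 0:
        warnings.warn(
            f"excitation {excitation:.3f} below all recruitment thresholds: silent muscle"
        )
        return out
    task_blocks = timeline.blocks_of("task")
    for ui in active:
        template = _ricker_template(pool.amplitudes_mv[ui], pool.durations_ms[ui], rate)
        fr = pool.base_rate_hz + pool.rate_gain_hz * (
            excitation - pool.recruitment_thresholds[ui]
        )
        for blk in task_blocks:
            times = _unit_spike_train(rng, fr, blk.start_s, blk.end_s, pool.isi_cv)
            if times.size == 0:
                continue
            starts = np.round(times * rate).astype(int)
            idx = starts[:, None] + np.arange(template.size)[None, :]
            keep = (idx >= 0) & (idx < n)
            np.add.at(out, idx[keep], np.broadcast_to(template, idx.shape)[keep])
    return out


def simulate_emg(
    pool_agonist: MotorUnitPool,
    pool_antagonist: MotorUnitPool,
    excitation: float,
    coactivation: float,
    timeline: Timeline,
    seed: int | np.random.SeedSequence,
    rate: float = 1000.0,
    noise_sd_mv: float = 0.003,
    force: float | None = None,
    side: str | None = None,
) -> EmgRecording:
    """Two-muscle interference EMG for one session.

    During task blocks, units with threshold below the drive fire as
    jittered point processes (rate = base + gain x supra-threshold drive)
    convolved with their action-potential template; the antagonist is
    driven at ``coactivation x excitation``. Rest/relaxation contain
    measurement noise only. Same seed, same output.
    """
    if not (0 < excitation <= 1):
        raise ValueError("excitation must lie in (0, 1]")
    if not (0 <= coactivation <= 1):
        raise ValueError("coactivation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bic = _interference(pool_agonist, excitation, timeline, rate, rng)
    tri = _interference(pool_antagonist, coactivation * excitation, timeline, rate, rng)
    n = timeline.n_samples(rate)
    bic = bic + rng.normal(0.0, noise_sd_mv, n)
    tri = tri + rng.normal(0.0, noise_sd_mv, n)
    return EmgRecording(
        samples={"BIC": bic, "TRI": tri},
        rate=rate,
        timeline=timeline,
        force=force if force is not None else excitation,
        side=side,
    )


def simulate_mvc_trials(
    pool: MotorUnitPool,
    seed: int | np.random.SeedSequence,
    n_trials: int = 3,
    duration_s: float = 5.0,
    rate: float = 1000.0,
    noise_sd_mv: float = 0.003,
) -> list[np.ndarray]:
    """Maximal-effort recordings (excitation 1.0) for MVC referencing."""
    rng = np.random.default_rng(seed)
    tl = Timeline((Block("task", 0.0, duration_s),))
    out = []
    for _ in range(n_trials):
        x = _interference(pool, 1.0, tl, rate, rng)
        out.append(x + rng.normal(0.0, noise_sd_mv, x.size))
    return out


# ---------------------------------------------------------------------------
# cortical hemodynamics


@dataclass(frozen=True)
class PhysioNoise:
    """Physiological confound amplitudes (uM) and frequencies (Hz)."""

    cardiac_hz: float = 1.1  # below the 5.5 Hz Nyquist at 11 Hz sampling
    cardiac_amp: float = 0.2
    resp_hz: float = 0.25
    resp_amp: float = 0.1
    mayer_hz: float = 0.1
    mayer_amp: float = 0.08
    drift_amp: float = 0.3
    white_sd: float = 0.0  # region-level white; channel noise is separate

    @classmethod
    def silent(cls) -> "PhysioNoise":
        return cls(cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0, drift_amp=0.0, white_sd=0.0)


@dataclass(frozen=True)
class CortexModel:
    """Six-region hemodynamic forward model.

    ``coupling`` is a symmetric matrix of extra latent correlation between
    region pairs; ``directed`` holds lagged cross-region coefficients
    (source, target) -> coefficient applied at ``directed_lag_s``. The
    lagged system is validated as stable (companion spectral radius < 1)
    at construction.
    """

    gains: dict[str, float]  # uM task-response amplitude per region
    coupling: np.ndarray  # (6, 6) symmetric, zero diagonal
    directed: dict[tuple[str, str], float] = field(default_factory=dict)
    directed_lag_s: float = 2.0
    coupling_amp: float = 0.4  # uM, latent component scale
    directed_amp: float = 0.35  # uM, directed component scale
    channel_noise_sd: float = 0.05  # uM per-channel white noise
    physio: PhysioNoise = field(default_factory=PhysioNoise)
    channels_per_region: int = CHANNELS_PER_REGION
    nominal_rate: float = 11.0

    def __post_init__(self) -> None:
        C = np.asarray(self.coupling, dtype=float)
        if C.shape != (len(REGIONS), len(REGIONS)):
            raise ValueError("coupling must be 6x6")
        if not np.allclose(C, C.T):
            raise ValueError("coupling must be symmetric")
        object.__setattr__(self, "coupling", C)
        if np.linalg.eigvalsh(np.eye(len(REGIONS)) + C).min() <= 0:
            raise ValueError("I + coupling must be positive definite")
        for r, g in self.gains.items():
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}")
            if g < 0:
                raise ValueError("gains must be non-negative")
        for amp in (self.coupling_amp, self.directed_amp, self.channel_noise_sd):
            if amp < 0:
                raise ValueError("amplitudes must be non-negative")
        if self._companion_radius() >= 1.0:
            raise ValueError("directed lag system is unstable (spectral radius >= 1)")

    def _lag_samples(self) -> int:
        return max(1, int(round(self.directed_lag_s * self.nominal_rate)))

    def _lag_matrix(self) -> np.ndarray:
        A = np.zeros((len(REGIONS), len(REGIONS)))
        for (src, dst), c in self.directed.items():
            A[REGIONS.index(dst), REGIONS.index(src)] = c
        return A

    def _companion_radius(self) -> float:
        k = len(REGIONS)
        L = self._lag_samples()
        comp = np.zeros((k * L, k * L))
        comp[:k, (L - 1) * k :] = self._lag_matrix()  # only the L-th lag is nonzero
        if L > 1:
            comp[k:, :-k] = np.eye(k * (L - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    def gain_vector(self) -> np.ndarray:
        return np.array([self.gains.get(r, 0.0) for r in REGIONS])

    @classmethod
    def null(cls) -> "CortexModel":
        """All gains, couplings, directed edges and physiology zero;
        channel white noise only."""
        return cls(
            gains={r: 0.0 for r in REGIONS},
            coupling=np.zeros((len(REGIONS), len(REGIONS))),
            coupling_amp=0.0,
            directed_amp=0.0,
            channel_noise_sd=0.0,
            physio=PhysioNoise.silent(),
        )


def simulate_fnirs(
    cortex: CortexModel,
    timeline: Timeline,
    drive: float,
    seed: int | np.random.SeedSequence,
    rate: float = 11.0,
    dpf: float = DEFAULT_DPF,
    distance_cm: float = DEFAULT_DISTANCE_CM,
    force: float | None = None,
    side: str | None = None,
) -> OpticalRecording:
    """Dual-wavelength optical-density recording for one session.

    Region HbO2 = drive x gain x (task boxcar (x) HRF) + coupling-mixed
    latents + lagged directed component + physiological sinusoids + drift
    (+ white). Channels add sensor noise; HbR = -0.3 x HbO2; the pair is
    mapped through the inverse MBLL to optical densities.
    """
    if drive < 0:
        raise ValueError("drive must be non-negative")
    rng = np.random.default_rng(seed)
    k = len(REGIONS)
    n = timeline.n_samples(rate)
    t = np.arange(n) / rate

    response = task_regressor(timeline, rate)
    region_sig = drive * cortex.gain_vector()[:, None] * response[None, :]

    # correlation-structured latents: Sigma = I + coupling
    if cortex.coupling_amp > 0:
        Lc = np.linalg.cholesky(np.eye(k) + cortex.coupling)
        region_sig = region_sig + cortex.coupling_amp * (Lc @ rng.standard_normal((k, n)))

    # directed influence: stable lagged recursion on slow innovations
    if cortex.directed_amp > 0:
        white = rng.standard_normal((k, n))
        if n > 24:
            sos = sp_signal.butter(2, 0.15, btype="lowpass", fs=rate, output="sos")
            innov = sp_signal.sosfiltfilt(sos, white, axis=1)
            innov = innov / np.maximum(innov.std(axis=1, keepdims=True), 1e-12)
        else:
            innov = white
        A = cortex._lag_matrix()
        lag = cortex._lag_samples()
        w = innov.copy()
        if np.any(A):
            for ti in range(lag, n):
                w[:, ti] += A @ w[:, ti - lag]
        region_sig = region_sig + cortex.directed_amp * w

    # physiological oscillations as quasi-periodic narrowband noise,
    # independent per region: pure shared-frequency sinusoids would be
    # cross-predictable between regions and forge directed influence
    ph = cortex.physio
    for comp_amp, comp_hz in (
        (ph.cardiac_amp, ph.cardiac_hz),
        (ph.resp_amp, ph.resp_hz),
        (ph.mayer_amp, ph.mayer_hz),
    ):
        if comp_amp > 0 and comp_hz < 0.45 * rate and n > 30:
            band = [0.85 * comp_hz, min(1.15 * comp_hz, 0.49 * rate)]
            sos_c = sp_signal.butter(2, band, btype="bandpass", fs=rate, output="sos")
            osc = sp_signal.sosfiltfilt(sos_c, rng.standard_normal((k, n)), axis=1)
            osc = osc / np.maximum(osc.std(axis=1, keepdims=True), 1e-12)
            region_sig = region_sig + comp_amp * osc
    if ph.drift_amp > 0 and n > 1:
        slopes = rng.normal(0.0, ph.drift_amp, k)
        region_sig = region_sig + slopes[:, None] * (t[None, :] / t[-1])
    if ph.white_sd > 0:
        region_sig = region_sig + rng.normal(0.0, ph.white_sd, (k, n))

    # channels: region signal + sensor noise
    n_ch = k * cortex.channels_per_region
    hbo2 = np.repeat(region_sig, cortex.channels_per_region, axis=0).T  # (n, n_ch)
    if cortex.channel_noise_sd > 0:
        hbo2 = hbo2 + rng.normal(0.0, cortex.channel_noise_sd, (n, n_ch))
        hbr = -0.3 * hbo2 + rng.normal(0.0, 0.3 * cortex.channel_noise_sd, (n, n_ch))
    else:
        hbr = -0.3 * hbo2
    od = mbll_forward(hbo2, hbr, distance_cm, dpf)
    return OpticalRecording(
        od=od,
        rate=rate,
        layout=default_layout(),
        timeline=timeline,
        distance_cm=distance_cm,
        force=force,
        side=side,
    )


# ---------------------------------------------------------------------------
# cohort-level effect structure


def _contralateral(side: str, kind: str) -> str:
    # all subjects right-hand dominant: dominant arm -> left hemisphere
    hemi = "L" if side == DOMINANT else "R"
    return f"{hemi}{kind}"


def _ipsilateral(side: str, kind: str) -> str:
    hemi = "R" if side == DOMINANT else "L"
    return f"{hemi}{kind}"


@dataclass(frozen=True)
class EffectConfig:
    """Programmed ground-truth effect sizes for the cohort.

    Defaults program every direction the downstream analyses are expected
    to recover: more recruitment and co-activation at 80% vs 20% MVC,
    stronger contralateral motor-cortex gain scaling with a shared
    per-subject drive (cross-modal coupling), condition-dependent latent
    coupling (functional connectivity), and dominant-side-only directed
    edges (effective connectivity).
    """

    drive_sd: float = 0.2
    drive_clip: tuple[float, float] = (0.6, 1.4)
    coactivation: dict[float, float] = field(
        default_factory=lambda: {0.2: 0.15, 0.8: 0.25}
    )
    emg_noise_sd_mv: float = 0.003
    # task-response amplitude (uM) per (region role, force); roles are
    # resolved per side via contralateral/ipsilateral mapping
    gain_contra_mc: dict[float, float] = field(default_factory=lambda: {0.2: 0.5, 0.8: 1.0})
    gain_ipsi_mc: dict[float, float] = field(default_factory=lambda: {0.2: 0.25, 0.8: 0.5})
    gain_contra_pfc: dict[float, float] = field(default_factory=lambda: {0.2: 0.3, 0.8: 0.6})
    gain_ipsi_pfc: dict[float, float] = field(default_factory=lambda: {0.2: 0.2, 0.8: 0.4})
    gain_contra_ol: dict[float, float] = field(default_factory=lambda: {0.2: 0.15, 0.8: 0.35})
    gain_ipsi_ol: dict[float, float] = field(default_factory=lambda: {0.2: 0.1, 0.8: 0.2})
    # latent-correlation coupling per force: (regionA, regionB, weight)
    coupling: dict[float, tuple[tuple[str, str, float], ...]] = field(
        default_factory=lambda: {
            0.2: (("LMC", "RMC", 0.45),),
            0.8: (
                ("LMC", "RMC", 0.5),
                ("LPFC", "RPFC", 0.6),
                ("LPFC", "LMC", 0.45),
                ("RPFC", "LMC", 0.4),
            ),
        }
    )
    # directed edges per side: (source, target, coefficient)
    directed: dict[str, tuple[tuple[str, str, float], ...]] = field(
        default_factory=lambda: {
            DOMINANT: (("LMC", "RMC", 0.5), ("LMC", "LOL", 0.4)),
            NON_DOMINANT: (),
        }
    )

    def gains_for(self, force: float, side: str) -> dict[str, float]:
        return {
            _contralateral(side, "MC"): self.gain_contra_mc[force],
            _ipsilateral(side, "MC"): self.gain_ipsi_mc[force],
            _contralateral(side, "PFC"): self.gain_contra_pfc[force],
            _ipsilateral(side, "PFC"): self.gain_ipsi_pfc[force],
            _contralateral(side, "OL"): self.gain_contra_ol[force],
            _ipsilateral(side, "OL"): self.gain_ipsi_ol[force],
        }

    def coupling_matrix(self, force: float) -> np.ndarray:
        C = np.zeros((len(REGIONS), len(REGIONS)))
        for a, b, w in self.coupling.get(force, ()):
            i, j = REGIONS.index(a), REGIONS.index(b)
            C[i, j] = C[j, i] = w
        return C

    def cortex_for(self, force: float, side: str) -> CortexModel:
        return CortexModel(
            gains=self.gains_for(force, side),
            coupling=self.coupling_matrix(force),
            directed={(s, d): c for s, d, c in self.directed.get(side, ())},
        )

    @classmethod
    def null(cls) -> "EffectConfig":
        """No cross-modal drive variance, no coupling, no directed edges,
        force-independent co-activation."""
        return cls(
            drive_sd=0.0,
            coactivation={0.2: 0.2, 0.8: 0.2},
            coupling={0.2: (), 0.8: ()},
            directed={DOMINANT: (), NON_DOMINANT: ()},
        )


@dataclass
class Dataset:
    """One subject x condition paired recording with its ground truth."""

    subject: int
    side: str
    force: float
    emg: EmgRecording
    optical: OpticalRecording
    truth: dict

    @property
    def key(self) -> tuple[int, str, float]:
        return (self.subject, self.side, self.force)

    @property
    def label(self) -> str:
        side = "dom" if self.side == DOMINANT else "nondom"
        return f"sub-{self.subject:02d}_{side}_f{int(round(self.force * 100))}"


class Cohort:
    """Lazy, deterministic cohort: datasets are generated on iteration."""

    def __init__(
        self,
        n_subjects: int = 21,
        protocol: ProtocolSpec | None = None,
        effects: EffectConfig | None = None,
        seed: int = 0,
        pool_agonist: MotorUnitPool | None = None,
        pool_antagonist: MotorUnitPool | None = None,
    ) -> None:
        if n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        self.n_subjects = n_subjects
        self.protocol = protocol or ProtocolSpec()
        self.effects = effects or EffectConfig()
        self.seed = int(seed)
        self.pool_agonist = pool_agonist or MotorUnitPool.default_agonist()
        self.pool_antagonist = pool_antagonist or MotorUnitPool.default_antagonist()
        self.timeline = build_timeline(self.protocol)
        self.drives = self._draw_drives()

    def _draw_drives(self) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
        lo, hi = self.effects.drive_clip
        return np.clip(
            1.0 + self.effects.drive_sd * rng.standard_normal(self.n_subjects), lo, hi
        )

    @property
    def subjects(self) -> range:
        return range(1, self.n_subjects + 1)

    def excitation(self, subject: int, force: float) -> float:
        return float(min(force * self.drives[subject - 1], 1.0))

    def mvc_trials(self, subject: int, muscle: str) -> list[np.ndarray]:
        pool = self.pool_agonist if muscle == "BIC" else self.pool_antagonist
        ss = np.random.SeedSequence([self.seed, subject, 900 + MUSCLES.index(muscle)])
        return simulate_mvc_trials(pool, ss, noise_sd_mv=self.effects.emg_noise_sd_mv)

    def dataset(self, subject: int, side: str, force: float) -> Dataset:
        eff = self.effects
        drive = float(self.drives[subject - 1])
        excitation = self.excitation(subject, force)
        coact = eff.coactivation[force]
        cond_idx = list(self.protocol.conditions).index((force, side))
        emg = simulate_emg(
            self.pool_agonist,
            self.pool_antagonist,
            excitation,
            coact,
            self.timeline,
            np.random.SeedSequence([self.seed, subject, cond_idx, 1]),
            rate=self.protocol.emg_rate,
            noise_sd_mv=eff.emg_noise_sd_mv,
            force=force,
            side=side,
        )
        cortex = eff.cortex_for(force, side)
        optical = simulate_fnirs(
            cortex,
            self.timeline,
            drive,
            np.random.SeedSequence([self.seed, subject, cond_idx, 2]),
            rate=self.protocol.nirs_rate,
            force=force,
            side=side,
        )
        truth = {
            "subject": subject,
            "side": side,
            "force": force,
            "drive": drive,
            "excitation": excitation,
            "coactivation": coact,
            "active_units_bic": self.pool_agonist.n_active(excitation),
            "active_units_tri": self.pool_antagonist.n_active(coact * excitation),
            "region_gains": {r: drive * g for r, g in eff.gains_for(force, side).items()},
            "coupling": [list(e) for e in eff.coupling.get(force, ())],
            "directed_edges": [list(e) for e in eff.directed.get(side, ())],
        }
        return Dataset(subject, side, force, emg, optical, truth)

    def datasets(self):
        for subject in self.subjects:
            for force, side in self.protocol.conditions:
                yield self.dataset(subject, side, force)

    def ground_truth(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "protocol": {
                "relaxation_s": self.protocol.relaxation_s,
                "task_s": self.protocol.task_s,
                "rest_s": self.protocol.rest_s,
                "repetitions": self.protocol.repetitions,
                "conditions": [list(c) for c in self.protocol.conditions],
                "emg_rate": self.protocol.emg_rate,
                "nirs_rate": self.protocol.nirs_rate,
            },
            "drives": self.drives.tolist(),
            "drive_sd": self.effects.drive_sd,
            "datasets": [
                self.dataset_truth(subject, side, force)
                for subject in self.subjects
                for force, side in self.protocol.conditions
            ],
        }

    def dataset_truth(self, subject: int, side: str, force: float) -> dict:
        """Ground truth without generating the signals."""
        eff = self.effects
        drive = float(self.drives[subject - 1])
        excitation = self.excitation(subject, force)
        coact = eff.coactivation[force]
        return {
            "subject": subject,
            "side": side,
            "force": force,
            "drive": drive,
            "excitation": excitation,
            "coactivation": coact,
            "active_units_bic": self.pool_agonist.n_active(excitation),
            "active_units_tri": self.pool_antagonist.n_active(coact * excitation),
            "region_gains": {r: drive * g for r, g in eff.gains_for(force, side).items()},
            "coupling": [list(e) for e in eff.coupling.get(force, ())],
            "directed_edges": [list(e) for e in eff.directed.get(side, ())],
        }


def generate_cohort(
    n_subjects: int = 21,
    protocol: ProtocolSpec | None = None,
    effects: EffectConfig | None = None,
    seed: int = 0,
    out_dir=None,
    overwrite: bool = False,
) -> Cohort:
    """Build a cohort; if ``out_dir`` is given, write it to disk.

    On disk: one directory per subject x condition with EMG CSV + JSON
    sidecar and fNIRS OD CSV + channel-map JSON, per-subject MVC trials,
    plus ``ground_truth.json`` and ``manifest.tsv`` at the root.
    """
    cohort = Cohort(n_subjects, protocol, effects, seed)
    if out_dir is not None:
        from .io import write_cohort

        write_cohort(cohort, out_dir, overwrite=overwrite)
    return cohort
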