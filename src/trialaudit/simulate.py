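"""Synthetic yes/no fNIRS trial generator.

Emulates the statistical structure that the reanalysis tooling assumes:
20 highly correlated channels, day/session/trial grouping, optionally
imbalanced per-condition trial counts, a condition-locked hemodynamic
response in the "yes" trials, and a pre-stimulus baseline window.

Per trial, channel ``c`` and epoch time ``tau`` the signal is

    x(tau, c) = beta * h(tau) * g_c * [condition == yes]
                + sigma_shared * z(tau)        (shared across channels, white)
                + eps_c(tau)                   (per-channel white, sd sigma_chan)
                + d_c(tau)                     (per-channel AR(1) drift)

with everything freshly drawn per trial.  The implied inter-channel
correlation of the white noise is rho = sigma_shared^2 / (sigma_shared^2 +
sigma_chan^2).  ``h`` is a canonical double-gamma hemodynamic response
normalised to unit peak.

The generative model is jointly Gaussian, so the Bayes-optimal single-trial
yes/no accuracy has a closed form (see :func:`bayes_accuracy`); the
"effect-strong" preset uses it to place the effect amplitude at a target
Bayes accuracy of 0.9.

Sampling rate and epoch window defaults are stand-ins chosen for this
simulator; the source experiments' acquisition parameters are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.linalg import solve, toeplitz
from scipy.signal import lfilter

from .data import CONDITIONS, DayRecord, SessionRecord, TrialDataset


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def validate(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("HRF delays must be positive")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("HRF undershoot ratio must be >= 0")


def hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical double-gamma HRF, zero for t <= 0, unit peak on the grid.

    The response is the difference of two gamma densities (peak minus
    scaled undershoot); if the evaluated grid reaches past the peak the
    curve is rescaled so its maximum is exactly 1.
    """
    params.validate()
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    g1 = stats.gamma.pdf(tp, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion)
    g2 = stats.gamma.pdf(
        tp, params.undershoot_delay / params.undershoot_dispersion, scale=params.undershoot_dispersion
    )
    h[pos] = g1 - params.undershoot_ratio * g2
    peak = h.max() if h.size else 0.0
    if peak > 0:
        h = h / peak
    return h


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification for one synthetic patient recording.

    ``trials_per_condition`` may be an int (balanced) or a mapping like
    ``{"yes": 7, "no": 3}`` to create class imbalance.
    """

    n_days: int = 1
    sessions_per_day: int = 10
    trials_per_condition: int | Mapping[str, int] = 10
    n_channels: int = 20
    epoch_window_s: tuple[float, float] = (-5.0, 20.0)
    sampling_rate_hz: float = 2.0
    effect_amplitude: float = 0.0
    channel_loadings: np.ndarray | None = None
    shared_noise_sd: float = np.sqrt(0.95)
    channel_noise_sd: float = np.sqrt(0.05)
    drift_ar_coefficient: float = 0.0
    drift_innovation_sd: float = 0.0
    hrf_params: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_days, self.sessions_per_day, self.n_channels) <= 0:
            raise ValueError("n_days, sessions_per_day and n_channels must be positive")
        for cond in CONDITIONS:
            if self.n_trials(cond) < 0:
                raise ValueError(f"negative trial count for condition {cond!r}")
        start, end = self.epoch_window_s
        if not (start < 0.0 < end):
            raise ValueError("epoch window must contain a pre-stimulus baseline: start < 0 < end")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.effect_amplitude < 0:
            raise ValueError("effect_amplitude must be >= 0")
        if self.shared_noise_sd < 0 or self.channel_noise_sd < 0 or self.drift_innovation_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.drift_ar_coefficient < 1.0:
            raise ValueError("drift_ar_coefficient must lie in [0, 1)")
        if self.channel_loadings is not None and len(self.channel_loadings) != self.n_channels:
            raise ValueError("channel_loadings length must equal n_channels")
        self.hrf_params.validate()

    def n_trials(self, condition: str) -> int:
        if isinstance(self.trials_per_condition, Mapping):
            return int(self.trials_per_condition[condition])
        return int(self.trials_per_condition)

    @property
    def loadings(self) -> np.ndarray:
        if self.channel_loadings is None:
            return np.ones(self.n_channels)
        return np.asarray(self.channel_loadings, dtype=float)

    @property
    def channel_correlation(self) -> float:
        """Implied white-noise inter-channel correlation rho."""
        s2, c2 = self.shared_noise_sd**2, self.channel_noise_sd**2
        tot = s2 + c2
        return s2 / tot if tot > 0 else 0.0

    @property
    def time_axis(self) -> np.ndarray:
        start, end = self.epoch_window_s
        fs = self.sampling_rate_hz
        n = int(round((end - start) * fs))
        return start + np.arange(n) / fs


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) sample along the last axis."""
    if sd == 0.0:
        return np.zeros(shape)
    innov = rng.standard_normal(shape) * sd
    if phi == 0.0:
        return innov
    # stationary start: scale the first innovation to the marginal sd
    innov[..., 0] /= np.sqrt(1.0 - phi**2)
    return lfilter([1.0], [1.0, -phi], innov, axis=-1)


def generate_dataset(config: SyntheticConfig) -> TrialDataset:
    """Draw one dataset from the generative model; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = config.time_axis
    h = hrf(t, config.hrf_params)
    g = config.loadings
    beta, s_sd, c_sd = config.effect_amplitude, config.shared_noise_sd, config.channel_noise_sd
    phi, d_sd = config.drift_ar_coefficient, config.drift_innovation_sd
    C, T = config.n_channels, t.shape[0]

    def draw(n_trials: int, is_yes: bool) -> np.ndarray:
        x = np.zeros((n_trials, C, T))
        if is_yes and beta > 0:
            x += beta * g[None, :, None] * h[None, None, :]
        if s_sd > 0:
            x += s_sd * rng.standard_normal((n_trials, 1, T))
        if c_sd > 0:
            x += c_sd * rng.standard_normal((n_trials, C, T))
        x += _ar1(rng, (n_trials, C, T), phi, d_sd)
        return x

    days = []
    for d in range(config.n_days):
        sessions = []
        for s in range(config.sessions_per_day):
            sessions.append(
                SessionRecord(
                    session_id=f"session-{s:02d}",
                    trials_yes=draw(config.n_trials("yes"), True),
                    trials_no=draw(config.n_trials("no"), False),
                )
            )
        days.append(DayRecord(day_id=f"day-{d:02d}", sessions=sessions))
    return TrialDataset(
        patient_id=f"synthetic-{config.seed}",
        days=days,
        n_channels=C,
        time_axis=t,
        sampling_rate=config.sampling_rate_hz,
    ).check()


# ---------------------------------------------------------------------------
# Bayes-optimal discriminability of the generative model
# ---------------------------------------------------------------------------


def _temporal_block(config: SyntheticConfig, aggregated_white: float) -> np.ndarray:
    """T x T noise covariance in one channel-eigendirection."""
    t = config.time_axis
    T = t.shape[0]
    B = aggregated_white * np.eye(T)
    if config.drift_innovation_sd > 0:
        phi = config.drift_ar_coefficient
        marg = config.drift_innovation_sd**2 / (1.0 - phi**2)
        B = B + marg * toeplitz(phi ** np.arange(T))
    return B


def bayes_discriminability(config: SyntheticConfig) -> float:
    """Mahalanobis separation d of the yes/no class means under the model.

    The trial covariance is sigma_s^2 (J x I) + sigma_c^2 I + sigma_d^2
    (I x R) over (channel, time); in the channel eigenbasis it block-
    diagonalises, so d^2 reduces to at most two T x T solves.  Bayes
    accuracy with equal priors is Phi(d / 2).
    """
    config.validate()
    h = hrf(config.time_axis, config.hrf_params) * config.effect_amplitude
    g = config.loadings
    C = config.n_channels
    s2, c2 = config.shared_noise_sd**2, config.channel_noise_sd**2
    g_par = float(g.sum()) / np.sqrt(C)  # component of g along the all-ones direction
    g_perp2 = float(g @ g) - g_par**2
    d2 = 0.0
    if g_par != 0.0:
        B1 = _temporal_block(config, C * s2 + c2)
        d2 += g_par**2 * float(h @ solve(B1, h, assume_a="pos"))
    if g_perp2 > 1e-12:
        B2 = _temporal_block(config, c2)
        d2 += g_perp2 * float(h @ solve(B2, h, assume_a="pos"))
    return float(np.sqrt(d2))


def bayes_accuracy(config: SyntheticConfig) -> float:
    """Closed-form Bayes-optimal single-trial accuracy, Phi(d/2)."""
    return float(stats.norm.cdf(bayes_discriminability(config) / 2.0))


def effect_amplitude_for_bayes_accuracy(config: SyntheticConfig, target: float) -> float:
    """Effect amplitude beta placing the model's Bayes accuracy at ``target``.

    d scales linearly in beta, so beta = d_target / d(beta=1).
    """
    if not 0.5 < target < 1.0:
        raise ValueError("target Bayes accuracy must lie in (0.5, 1)")
    d_unit = bayes_discriminability(replace(config, effect_amplitude=1.0))
    if d_unit == 0.0:
        raise ValueError("model has no discriminative signal at beta = 1")
    return float(2.0 * stats.norm.ppf(target) / d_unit)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("null-highcorr", "effect-strong", "imbalanced")

#: base of the effect-strong preset, before the calibrated effect is applied:
#: 2 Hz, (-5, 15) s epochs, rho = 0.95 white noise of unit total variance,
#: slow AR(1) drift (marginal sd 2.0, phi = 0.95 -> innovation sd 0.6245).
_EFFECT_BASE = SyntheticConfig(
    n_days=1,
    sessions_per_day=10,
    trials_per_condition=20,
    n_channels=20,
    epoch_window_s=(-5.0, 15.0),
    sampling_rate_hz=2.0,
    effect_amplitude=0.0,
    drift_ar_coefficient=0.95,
    drift_innovation_sd=2.0 * np.sqrt(1.0 - 0.95**2),
)


def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Documented generator presets.

    - ``"null-highcorr"``: no effect, inter-channel correlation 0.95,
      20 channels, 10 sessions x 10 trials/condition, 200 timepoints
      ((-5, 20) s at 8 Hz).  The regime in which an averaging order that
      retains only across-channel variance grossly inflates false positives.
    - ``"effect-strong"``: a condition-locked response whose amplitude
      (beta ~= 1.343) is calibrated so the Bayes-optimal single-trial
      accuracy of the generative model is 0.9.
    - ``"imbalanced"``: null data with 7 yes / 3 no trials per session,
      exercising class-balancing logic.
    """
    if name == "null-highcorr":
        return SyntheticConfig(
            n_days=1,
            sessions_per_day=10,
            trials_per_condition=10,
            n_channels=20,
            epoch_window_s=(-5.0, 20.0),
            sampling_rate_hz=8.0,
            effect_amplitude=0.0,
            seed=seed,
        )
    if name == "effect-strong":
        base = replace(_EFFECT_BASE, seed=seed)
        beta = effect_amplitude_for_bayes_accuracy(base, 0.9)
        return replace(base, effect_amplitude=beta)
    if name == "imbalanced":
        return SyntheticConfig(
            n_days=1,
            sessions_per_day=10,
            trials_per_condition={"yes": 7, "no": 3},
            n_channels=20,
            effect_amplitude=0.0,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}")


def null_config(name: str = "null-highcorr", seed: int = 0) -> SyntheticConfig:
    """Null (no-effect) presets; rejects presets with an effect."""
    cfg = preset(name, seed)
    if cfg.effect_amplitude != 0.0:
        raise ValueError(f"preset {name!r} is not a null preset")
    return cfg


def effect_config(name: str = "effect-strong", seed: int = 0) -> SyntheticConfig:
    """Effect presets; rejects null presets."""
    cfg = preset(name, seed)
    if cfg.effect_amplitude == 0.0:
        raise ValueError(f"preset {name!r} has no effect")
    return cfg
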