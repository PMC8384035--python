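"""Raw sEMG to muscle activation a(t).

The pipeline follows the classic activation-dynamics model used in
EMG-driven musculoskeletal modelling (Lloyd & Besier style):

1. preprocessing — band-pass, mains notch, full-wave rectification,
   normalisation by the peak rectified value, low-pass envelope extraction;
2. neural activation — a stable second-order recursive filter with a pure
   electromechanical delay d:

       u(i) = alpha * e(i - d) - beta1 * u(i-1) - beta2 * u(i-2)

   with beta1 = gamma1 + gamma2, beta2 = gamma1 * gamma2, |gamma_j| < 1 for
   stability, and alpha - beta1 - beta2 = 1 so a constant envelope maps to the
   same constant (unity DC gain);
3. muscle activation — a nonlinear map with shape factor A in [-3, 0]:

       a(t) = (exp(A * u(t)) - 1) / (exp(A) - 1)

   A = -3 is strongly exponential, A -> 0 is the linear limit a = u.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import signal as _sig


@dataclass(frozen=True)
class ActivationParams:
    """Parameters of the activation-dynamics model.

    gamma1/gamma2 are the poles of the recursive filter; the recursive
    coefficients and gain follow from them (beta1 = g1+g2, beta2 = g1*g2,
    alpha = 1 + beta1 + beta2) so stability and unity gain hold by
    construction. ``d_ms`` is the electromechanical delay, rounded to whole
    samples of the envelope clock ``fs``.
    """

    gamma1: float = -0.5
    gamma2: float = -0.5
    d_ms: float = 40.0
    fs: float = 1111.11
    A: float = -2.0
    lowpass_hz: float = 4.0
    bandpass_hz: tuple[float, float] = (20.0, 450.0)
    notch_hz: float = 50.0

    def __post_init__(self) -> None:
        if not (abs(self.gamma1) < 1.0 and abs(self.gamma2) < 1.0):
            raise ValueError("stability requires |gamma1| < 1 and |gamma2| < 1")
        if not (-3.0 <= self.A <= 0.0):
            raise ValueError("shape factor A must lie in [-3, 0]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def beta1(self) -> float:
        return self.gamma1 + self.gamma2

    @property
    def beta2(self) -> float:
        return self.gamma1 * self.gamma2

    @property
    def alpha(self) -> float:
        # unity-gain constraint alpha - beta1 - beta2 = 1
        return 1.0 + self.beta1 + self.beta2

    @property
    def d_samples(self) -> int:
        return int(round(self.d_ms * self.fs / 1000.0))


@dataclass
class ActivationTrace:
    """Envelope, neural activation and muscle activation for one channel."""

    e: np.ndarray
    u: np.ndarray
    a: np.ndarray
    fs: float
    params: ActivationParams = field(default_factory=ActivationParams)


def preprocess_emg(raw: np.ndarray, params: ActivationParams | None = None) -> np.ndarray:
    """Raw sEMG channel -> normalised low-pass envelope e(i) in [0, ~1].

    Band-pass + notch filtering, full-wave rectification, division by the peak
    rectified value, then zero-phase low-pass envelope extraction. Small
    filter undershoot is clipped at zero; overshoot above 1 is retained.
    """
    if params is None:
        params = ActivationParams()
    x = np.asarray(raw, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("input signal must be nonempty and finite")
    nyq = params.fs / 2.0
    lo, hi = params.bandpass_hz
    hi = min(hi, 0.99 * nyq)
    if x.size > 30:  # too-short signals skip band filtering (filtfilt padding)
        sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=params.fs, output="sos")
        x = _sig.sosfiltfilt(sos, x)
        if params.notch_hz and params.notch_hz < nyq:
            b, a = _sig.iirnotch(params.notch_hz, Q=30.0, fs=params.fs)
            x = _sig.filtfilt(b, a, x)
    r = np.abs(x)
    peak = r.max()
    if peak == 0:
        raise ValueError("peak is zero: cannot normalise an all-zero signal")
    r = r / peak
    if r.size > 30:
        sos = _sig.butter(4, params.lowpass_hz, btype="lowpass", fs=params.fs, output="sos")
        r = _sig.sosfiltfilt(sos, r)
    return np.clip(r, 0.0, None)


def neural_activation(e: np.ndarray, params: ActivationParams) -> np.ndarray:
    """Apply the delayed second-order recursion to an envelope.

    Zero initial conditions; e(k) = 0 for k < 0 (the delay shifts zeros in).
    For a constant envelope the output converges to the same constant.
    """
    e = np.asarray(e, dtype=float)
    d = params.d_samples
    delayed = np.concatenate([np.zeros(d), e])[: len(e)] if d > 0 else e
    # u(i) + beta1 u(i-1) + beta2 u(i-2) = alpha e(i-d): an IIR filter
    u = _sig.lfilter([params.alpha], [1.0, params.beta1, params.beta2], delayed)
    return u


def muscle_activation(u: np.ndarray, A: float = -2.0) -> np.ndarray:
    """Nonlinear neural-to-muscle activation map with shape factor A.

    a = (exp(A u) - 1) / (exp(A) - 1); strictly increasing, a(0) = 0,
    a(1) = 1. A = 0 uses the analytic limit a = u.
    """
    if A > 0 or A < -3.0:
        raise ValueError("shape factor A must lie in [-3, 0]")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("u must be finite")
    if A == 0.0:
        return u.copy()
    return np.expm1(A * u) / np.expm1(A)


def activation_trace(raw: np.ndarray, params: ActivationParams | None = None) -> ActivationTrace:
    """Full channel pipeline: raw sEMG -> (e, u, a)."""
    if params is None:
        params = ActivationParams()
    e = preprocess_emg(raw, params)
    u = neural_activation(e, params)
    a = muscle_activation(u, params.A)
    return ActivationTrace(e=e, u=u, a=a, fs=params.fs, params=params)


def fit_activation_params(
    e: np.ndarray,
    reference: np.ndarray,
    fs: float = 1111.11,
    A: float = -2.0,
    d_grid_ms: tuple[float, float, float] = (0.0, 80.0, 5.0),
) -> ActivationParams:
    """Fit (gamma1, gamma2, d) by least squares against a reference activation.

    Coarse grid over the stability region and candidate delays, then a
    Nelder-Mead refinement of the poles at the best delay. Returns parameters
    whose MSE is no worse than the defaults'. A constant reference carries no
    information: a warning is issued and the defaults returned.
    """
    e = np.asarray(e, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if e.shape != reference.shape:
        raise ValueError("envelope and reference must have the same length")
    defaults = ActivationParams(fs=fs, A=A)
    if np.ptp(reference) < 1e-12:
        warnings.warn("constant reference trace: returning default parameters")
        return defaults

    def mse(g1: float, g2: float, d_ms: float) -> float:
        p = ActivationParams(gamma1=g1, gamma2=g2, d_ms=d_ms, fs=fs, A=A)
        a = muscle_activation(neural_activation(e, p), A)
        return float(np.mean((a - reference) ** 2))

    lo, hi, step = d_grid_ms
    d_candidates = np.arange(lo, hi + step / 2, step)
    g_grid = np.linspace(-0.9, 0.9, 7)
    best = (defaults.gamma1, defaults.gamma2, defaults.d_ms)
    best_mse = mse(*best)
    for d in d_candidates:
        for g1 in g_grid:
            for g2 in g_grid:
                m = mse(g1, g2, d)
                if m < best_mse:
                    best, best_mse = (g1, g2, d), m

    g1, g2, d = best

    def objective(x):
        y1, y2 = np.clip(x, -0.97, 0.97)
        return mse(y1, y2, d)

    res = optimize.minimize(objective, [g1, g2], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 400})
    y1, y2 = np.clip(res.x, -0.97, 0.97)
    if mse(y1, y2, d) < best_mse:
        g1, g2 = float(y1), float(y2)
    fitted = ActivationParams(gamma1=g1, gamma2=g2, d_ms=float(d), fs=fs, A=A)
    # guarantee: never worse than the defaults
    if mse(fitted.gamma1, fitted.gamma2, fitted.d_ms) > mse(
        defaults.gamma1, defaults.gamma2, defaults.d_ms
    ):
        return defaults
    return fitted
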