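"""Linear predictive coding of EEG channels.

An order-``K`` LPC model approximates each sample from its ``K``
predecessors::

    x(n) = eps(n) - sum_{i=1..K} a_i x(n - i)

so the prediction-error (whitening) polynomial is
``A(z) = 1 + sum a_i z^{-i}`` and the coefficient vector
``a = [a_1 .. a_K]`` is the point that represents the whole channel in
LPC-coefficient space. The coefficients compress the channel's power
spectrum: the implied model spectrum is ``sigma^2 / |A(e^{j w})|^2``,
and the roots of ``A(z)`` are oscillatory modes (resonances) whose
angles give frequencies and whose radii give sharpness.

Estimation uses the autocorrelation method solved by the
Levinson-Durbin recursion — the canonical LPC estimator, which
guarantees a stable (minimum-phase) model from biased sample
autocorrelations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LPCModel",
    "OscillatoryMode",
    "fit_lpc",
    "fit_lpc_orders",
    "levinson_durbin",
    "lpc_spectrum",
    "oscillatory_modes",
]


@dataclass
class LPCModel:
    """Order-K AR coefficients plus residual variance, with fs context."""

    order: int
    coefficients: np.ndarray = field(repr=False)
    residual_variance: float
    fs: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.coefficients.shape != (self.order,):
            raise ValueError("coefficient count must equal the order")
        if self.residual_variance < 0:
            raise ValueError("residual variance must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coefficients": self.coefficients.tolist(),
            "residual_variance": self.residual_variance,
            "fs": self.fs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LPCModel":
        return cls(d["order"], np.asarray(d["coefficients"], dtype=float),
                   d["residual_variance"], d["fs"])


@dataclass(frozen=True)
class OscillatoryMode:
    """A resonance of the fitted AR polynomial.

    ``frequency`` is the pole angle mapped to Hz, ``pole_magnitude`` the
    pole radius (sharpness; 1 = undamped), and ``amplitude`` the model
    spectral density evaluated at the pole frequency (a.u.) — a summary
    that grows with both residue size and pole sharpness.
    """

    frequency: float
    amplitude: float
    pole_magnitude: float


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation r(0..max_lag) via FFT."""
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    return acf / n


def levinson_durbin(r: np.ndarray, order: int):
    """Solve the Yule-Walker normal equations by Levinson-Durbin.

    Parameters
    ----------
    r
        Autocorrelation sequence ``r(0..order)``.
    order
        Maximum model order.

    Returns
    -------
    coeffs : list of ndarray
        ``coeffs[k]`` (k = 1..order) is the length-k coefficient vector
        for the order-k model in the ``A(z) = 1 + sum a_i z^{-i}``
        convention; ``coeffs[0]`` is an empty array.
    errors : ndarray
        Prediction-error powers for orders 0..order.

    The whole recursion costs O(order^2) and yields every lower-order
    model for free, which the training grid search exploits.
    """
    r = np.asarray(r, dtype=float)
    if r.size < order + 1:
        raise ValueError("need r(0..order)")
    if r[0] <= 0:
        raise ValueError("zero-variance (degenerate) signal")
    coeffs: list[np.ndarray] = [np.empty(0)]
    errors = np.empty(order + 1)
    errors[0] = r[0]
    a = np.empty(0)
    for m in range(1, order + 1):
        acc = r[m] + (a @ r[m - 1:0:-1] if m > 1 else 0.0)
        k = -acc / errors[m - 1]
        a_new = np.empty(m)
        if m > 1:
            a_new[: m - 1] = a + k * a[::-1]
        a_new[m - 1] = k
        errors[m] = errors[m - 1] * (1.0 - k * k)
        a = a_new
        coeffs.append(a.copy())
    return coeffs, errors


def fit_lpc(x: np.ndarray, order: int, fs: float) -> LPCModel:
    """Fit an order-K LPC model to a signal (autocorrelation method)."""
    x = np.asarray(x, dtype=float)
    if x.size < 10 * order:
        raise ValueError(
            f"signal length {x.size} too short for order {order} "
            f"(need >= {10 * order})"
        )
    r = _autocorrelation(x, order)
    coeffs, errors = levinson_durbin(r, order)
    return LPCModel(order, coeffs[order], float(errors[order]), fs)


def fit_lpc_orders(x: np.ndarray, max_order: int, fs: float) -> list[LPCModel]:
    """Fit all orders 1..max_order in a single Levinson-Durbin pass."""
    x = np.asarray(x, dtype=float)
    if x.size < 10 * max_order:
        raise ValueError("signal too short for the requested maximum order")
    r = _autocorrelation(x, max_order)
    coeffs, errors = levinson_durbin(r, max_order)
    return [LPCModel(k, coeffs[k], float(errors[k]), fs)
            for k in range(1, max_order + 1)]


def lpc_spectrum(model: LPCModel, freqs: np.ndarray) -> np.ndarray:
    """Model power spectral density sigma^2 / |A(e^{j 2 pi f / fs})|^2."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if (freqs < 0).any() or (freqs > model.fs / 2).any():
        raise ValueError("frequencies must lie in [0, fs/2]")
    i = np.arange(1, model.order + 1)
    # A evaluated on the unit circle at each grid frequency
    phases = np.exp(-2j * np.pi * np.outer(freqs, i) / model.fs)
    a_vals = 1.0 + phases @ model.coefficients.astype(complex)
    return model.residual_variance / np.abs(a_vals) ** 2


def oscillatory_modes(model: LPCModel) -> list[OscillatoryMode]:
    """Extract resonances from the roots of A(z), sorted by amplitude.

    Complex-conjugate pole pairs are reported once (the positive-angle
    member); real poles map to modes at 0 Hz (positive pole) or fs/2
    (negative pole).
    """
    poly = np.concatenate(([1.0], model.coefficients))
    roots = np.roots(poly)
    modes = []
    for root in roots:
        if root.imag < -1e-12:
            continue  # conjugate partner of a reported pole
        if abs(root.imag) <= 1e-12:
            freq = 0.0 if root.real >= 0 else model.fs / 2.0
        else:
            freq = float(np.angle(root)) * model.fs / (2.0 * np.pi)
        amp = float(lpc_spectrum(model, np.array([freq]))[0])
        modes.append(OscillatoryMode(freq, amp, min(float(abs(root)), 1.0)))
    modes.sort(key=lambda m: m.amplitude, reverse=True)
    return modes
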