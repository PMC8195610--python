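"""Species-tuning functions and their sigmoid fits.

The fitted discriminant surfaces are collapsed onto the species axis by
marginalizing, over the expression coordinate e, the two classes belonging to
one species:

    D_M(s) = ∫₀¹ [P_monkey-threat + P_monkey-fear](e, s) de
    D_H(s) = ∫₀¹ [P_human-angry + P_human-fear](e, 1−s) de

The human curve is evaluated at 1−s so that both category centers appear at
s = 0 and the curves are directly comparable. Each tuning curve is fitted
with the sigmoid D(s) = (tanh(ω·(s−θ)) + 1)/2, whose threshold θ is the 50%
crossing and whose slope at threshold is ω/2; a narrower tuning corresponds
to a larger |ω|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import curve_fit

from .discriminant import DiscriminantModel, predict_probabilities

__all__ = ["TuningFit", "marginal_tuning", "fit_sigmoid"]

# class indices (0-based) per species: 1 human-angry, 2 human-fear,
# 3 monkey-threat, 4 monkey-fear
_SPECIES_CLASSES = {"monkey": (2, 3), "human": (0, 1)}


@dataclass(frozen=True)
class TuningFit:
    """A species-tuning curve with its fitted sigmoid parameters."""

    species: str
    s_grid: np.ndarray
    samples: np.ndarray
    theta: float | None
    omega: float | None
    residual_rms: float
    degenerate: bool = False

    @property
    def steepness_at_threshold(self) -> float | None:
        return None if self.omega is None else self.omega / 2.0

    def __call__(self, s):
        if self.degenerate:
            raise ValueError("degenerate tuning fit has no sigmoid")
        return _sigmoid(np.asarray(s, dtype=float), self.omega, self.theta)


def _sigmoid(s, omega, theta):
    return 0.5 * (np.tanh(omega * (s - theta)) + 1.0)


def marginal_tuning(
    model: DiscriminantModel, n_nodes: int = 101
) -> tuple[TuningFit, TuningFit]:
    """Marginalize a fitted model into (monkey, human) tuning fits.

    Integrals over e use composite Simpson quadrature on ``n_nodes``
    equidistant nodes; both curves are sampled on the same s-grid.
    """
    if n_nodes < 3 or n_nodes % 2 == 0:
        raise ValueError("n_nodes must be an odd number >= 3 for Simpson quadrature")
    axis = np.linspace(0.0, 1.0, n_nodes)
    ee, ss = np.meshgrid(axis, axis)
    p = predict_probabilities(model, ee.ravel(), ss.ravel())
    P = p.T.reshape(4, n_nodes, n_nodes)  # [class, i_s, i_e]
    fits = []
    for species in ("monkey", "human"):
        j1, j2 = _SPECIES_CLASSES[species]
        integrand = P[j1] + P[j2]
        d = simpson(integrand, x=axis, axis=1)  # integrate over e → D(s)
        if species == "human":
            d = d[::-1].copy()  # flip the s-axis so the category center is at s=0
        fits.append(fit_sigmoid(axis, d, species))
    return fits[0], fits[1]


def fit_sigmoid(s_grid: np.ndarray, samples: np.ndarray, species: str = "") -> TuningFit:
    """Nonlinear least-squares fit of the tanh sigmoid to tuning samples.

    θ is initialized from the linearly interpolated 0.5 crossing, ω from
    twice the local finite-difference slope there. Samples that never cross
    0.5 are flagged degenerate (θ undefined).
    """
    s = np.asarray(s_grid, dtype=float)
    d = np.asarray(samples, dtype=float)
    if s.shape != d.shape or s.ndim != 1 or len(s) < 4:
        raise ValueError("need matching 1D s and D arrays with at least 4 samples")
    if d.min() < -1e-9 or d.max() > 1.0 + 1e-9:
        raise ValueError("tuning samples must lie in [0, 1]")
    centered = d - 0.5
    sign_change = np.nonzero(np.diff(np.sign(centered)) != 0)[0]
    exact = np.nonzero(np.abs(centered) < 1e-12)[0]
    if len(sign_change) == 0 and len(exact) == 0:
        return TuningFit(species, s, d, None, None, float("nan"), degenerate=True)
    if np.ptp(d) < 1e-9:  # constant at 0.5: crossing everywhere, slope zero
        return TuningFit(species, s, d, None, None, float("nan"), degenerate=True)
    if len(sign_change):
        i = sign_change[0]
        f = centered[i] / (centered[i] - centered[i + 1])
        theta0 = s[i] + f * (s[i + 1] - s[i])
        slope0 = (d[i + 1] - d[i]) / (s[i + 1] - s[i])
    else:
        i = exact[0]
        theta0 = s[i]
        j = min(i + 1, len(s) - 1)
        slope0 = (d[j] - d[max(i - 1, 0)]) / (s[j] - s[max(i - 1, 0)])
    omega0 = 2.0 * slope0 if slope0 != 0 else 1.0
    popt, _ = curve_fit(
        lambda x, om, th: _sigmoid(x, om, th), s, d, p0=[omega0, theta0], maxfev=10000
    )
    omega, theta = float(popt[0]), float(popt[1])
    rms = float(np.sqrt(np.mean((_sigmoid(s, omega, theta) - d) ** 2)))
    return TuningFit(species, s, d, theta, omega, rms)
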