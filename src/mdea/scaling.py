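"""Scaling-index fits and theoretical predictions.

The entropy curve is fitted to S(l) = A + delta ln l by ordinary least
squares; delta is compared against the three theoretical scalings:

* crucial events (IPL renewal, one-sided unit steps):
  delta = mu - 1 for 1 < mu <= 2 and delta = 1/(mu - 1) for 2 < mu < 3;
* pure fBm: delta = H;
* fractional diffusion with a time-dependent coefficient (Caputo order
  alpha combined with Hurst exponent H): delta = (2H - 1 + alpha) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dea import EntropyCurve

__all__ = [
    "ScalingFit",
    "fit_delta",
    "predict_delta_crucial",
    "predict_delta_fde",
    "predict_delta_fbm",
]


@dataclass(frozen=True)
class ScalingFit:
    """Result of the OLS fit S(l) = A + delta ln l."""

    delta: float
    A: float
    stderr: float
    fit_range: tuple[float, float]
    n_points: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"delta = {self.delta:.4f} +/- {self.stderr:.4f} "
                f"(A = {self.A:.3f}, l in [{self.fit_range[0]:g}, "
                f"{self.fit_range[1]:g}], {self.n_points} points)")


def fit_delta(curve: EntropyCurve, l_min: float | None = None,
              l_max: float | None = None) -> ScalingFit:
    """Unweighted OLS of S against ln l restricted to [l_min, l_max]."""
    if l_min is None:
        l_min = float(curve.ls[0])
    if l_max is None:
        l_max = float(curve.ls[-1])
    if not l_min < l_max:
        raise ValueError(f"need l_min < l_max (got {l_min}, {l_max})")
    mask = (curve.ls >= l_min) & (curve.ls <= l_max)
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 curve points in [{l_min}, {l_max}], "
            f"got {int(mask.sum())}")
    res = stats.linregress(np.log(curve.ls[mask]), curve.Ss[mask])
    return ScalingFit(delta=float(res.slope), A=float(res.intercept),
                      stderr=float(res.stderr),
                      fit_range=(float(l_min), float(l_max)),
                      n_points=int(mask.sum()))


def predict_delta_crucial(mu: float, allow_ordinary: bool = False) -> float:
    """Scaling index of the one-sided crucial-event walker.

    delta = mu - 1 on 1 < mu <= 2 and delta = 1/(mu - 1) on 2 < mu < 3
    (both branches give 1 at mu = 2).  Outside (1, 3) the events are no
    longer "crucial"; mu >= 3 yields ordinary scaling 0.5, returned only
    when ``allow_ordinary`` is set.
    """
    if mu >= 3:
        if allow_ordinary:
            return 0.5
        raise ValueError(f"mu must lie in (1, 3) (got {mu}); "
                         "mu >= 3 is ordinary scaling")
    if mu <= 1:
        raise ValueError(f"mu must lie in (1, 3) (got {mu})")
    return mu - 1.0 if mu <= 2 else 1.0 / (mu - 1.0)


def predict_delta_fde(H: float, alpha: float) -> float:
    """Second-moment scaling of the fractional diffusion equation with a
    time-dependent diffusion coefficient: delta = (2H - 1 + alpha) / 2."""
    if not 0 < H < 1:
        raise ValueError(f"H must lie in (0, 1) (got {H})")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1] (got {alpha})")
    return (2.0 * H - 1.0 + alpha) / 2.0


def predict_delta_fbm(H: float) -> float:
    """Pure fBm: DEA without stripes yields delta = H."""
    if not 0 < H < 1:
        raise ValueError(f"H must lie in (0, 1) (got {H})")
    return float(H)
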