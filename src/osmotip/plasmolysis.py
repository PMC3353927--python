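"""Tip plasmolysis: forward retraction model, fitting, and synthesis.

Under a hypertonic step the protoplast pulls away from the apical
wall.  Only the apical osmotic zone (length ``l``) is water-permeable;
as the membrane retracts by ``x`` it loses contact with the permeable
wall, and wall already passed is covered by an unstirred layer whose
osmotic permeability is effectively zero.  The efflux balance

    pi r^2 dx/dt = P_os * dPi * 2 pi r * (l - x)

then gives a saturating exponential retraction

    x(t) = l * (1 - exp(-k t)),    k = 2 * P_os * dPi / r

with plateau equal to the zone length: the rate constant carries the
permeability, the plateau carries the zone geometry, so a single
retraction time course identifies both.

``fit_retraction`` recovers (P_os, l) from a measured curve by
nonlinear least squares; ``synth_retraction`` generates seeded noisy
curves from known truth for validation and power analysis.  Curves are
exchanged as 2-column CSV (time_s, retraction_um) with a JSON sidecar
for the known radius and osmotic step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .constants import pressure_form_to_pos_cm

__all__ = [
    "RetractionCurve",
    "retraction_forward",
    "RetractionFit",
    "fit_retraction",
    "synth_retraction",
]


@dataclass(frozen=True)
class RetractionCurve:
    """A plasmolytic retraction time course.

    ``times`` in s, ``x`` (retraction) in um, with the known tube
    radius ``r`` (um) and applied osmotic step ``dPi`` (MPa).  For
    synthetic curves the generating truth ``(P_os_bar, l)`` and the
    seed are carried along.
    """

    times: np.ndarray
    x: np.ndarray
    r: float
    dPi: float
    truth: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)
        if t.ndim != 1 or t.shape != x.shape:
            raise ValueError("times and x must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.r <= 0 or self.dPi <= 0:
            raise ValueError("r and dPi must be strictly positive")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        path = Path(path)
        arr = np.column_stack([self.times, self.x])
        np.savetxt(path, arr, delimiter=",", comments="",
                   header="time_s,retraction_um", fmt="%.10g")
        sidecar = {"r_um": self.r, "dPi_MPa": self.dPi,
                   "truth_P_os_bar": self.truth[0] if self.truth else None,
                   "truth_l_um": self.truth[1] if self.truth else None,
                   "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "RetractionCurve":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        truth = None
        if sidecar.get("truth_P_os_bar") is not None:
            truth = (sidecar["truth_P_os_bar"], sidecar["truth_l_um"])
        return cls(times=arr[:, 0], x=arr[:, 1], r=sidecar["r_um"],
                   dPi=sidecar["dPi_MPa"], truth=truth,
                   seed=sidecar.get("seed"))


def retraction_forward(P_os_bar: float, dPi: float, r: float, l: float,
                       t) -> np.ndarray:
    """Retraction x(t) = l*(1 - exp(-k t)), k = 2*P_os*dPi/r (um).

    ``P_os_bar`` is the pressure-form permeability (um.MPa^-1.s^-1),
    ``dPi`` the applied hypertonic step (MPa), ``r`` the tube radius
    (um), ``l`` the permeable-zone length (um).  ``t`` may be scalar
    or array, in s.
    """
    if min(P_os_bar, dPi, r, l) <= 0:
        raise ValueError("P_os_bar, dPi, r and l must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    k = 2.0 * P_os_bar * dPi / r
    return l * (1.0 - np.exp(-k * t))


@dataclass(frozen=True)
class RetractionFit:
    """Least-squares estimates from a retraction curve.

    ``P_os_bar`` in um.MPa^-1.s^-1 (``P_os_cm`` gives the familiar
    cm/s concentration form at the given temperature), ``l`` in um.
    ``l_identified`` is False when the curve was truncated well before
    its plateau (observed span under ~63% of the fitted plateau, i.e.
    shorter than one rate-constant time), leaving the plateau poorly
    constrained.
    """

    P_os_bar: float
    l: float
    P_os_bar_se: float
    l_se: float
    residual_norm: float
    converged: bool
    l_identified: bool
    temperature: float = 298.15

    @property
    def P_os_cm(self) -> float:
        return pressure_form_to_pos_cm(self.P_os_bar, self.temperature)


def fit_retraction(curve: RetractionCurve,
                   temperature: float = 298.15) -> RetractionFit:
    """Fit (P_os, l) to a retraction curve by nonlinear least squares.

    The radius and the osmotic step are known inputs; the two free
    parameters are the permeability (through the rate constant) and
    the zone length (the plateau).  Initialisation: l0 from the
    largest observed retraction plus 10%, k0 from the initial slope
    over the first fifth of the curve.  Non-convergence is flagged,
    never silently replaced.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 time points to fit")
    t, x = curve.times, curve.x
    l0 = max(float(np.max(x)), 1e-6) * 1.1
    n0 = max(2, len(t) // 5)
    with np.errstate(all="ignore"):
        slope = np.polyfit(t[:n0], x[:n0], 1)[0]
    k0 = max(slope / l0, 1e-4)
    p0 = [k0 * curve.r / (2.0 * curve.dPi), l0]

    def model(tt, p_os_bar, l):
        k = 2.0 * p_os_bar * curve.dPi / curve.r
        return l * (1.0 - np.exp(-k * tt))

    try:
        popt, pcov = curve_fit(model, t, x, p0=p0,
                               bounds=([0.0, 0.0], [np.inf, np.inf]),
                               maxfev=10000)
        converged = bool(np.all(np.isfinite(popt))
                         and np.all(np.isfinite(np.diag(pcov))))
    except RuntimeError:
        popt = np.array([np.nan, np.nan])
        pcov = np.full((2, 2), np.nan)
        converged = False

    resid = (x - model(t, *popt)) if converged else x * np.nan
    se = np.sqrt(np.diag(pcov))
    k_hat = 2.0 * popt[0] * curve.dPi / curve.r if converged else np.nan
    # identifiability: the plateau is only pinned down if the curve has
    # approached it; require the record to span at least one 1/k time
    l_identified = bool(converged and np.isfinite(k_hat)
                        and t[-1] * k_hat >= 1.0)
    return RetractionFit(
        P_os_bar=float(popt[0]), l=float(popt[1]),
        P_os_bar_se=float(se[0]), l_se=float(se[1]),
        residual_norm=float(np.sqrt(np.nansum(resid**2))),
        converged=converged, l_identified=l_identified,
        temperature=temperature)


def synth_retraction(P_os_bar: float, l: float, r: float, dPi: float,
                     times, noise_sd: float = 0.0,
                     seed: int | None = None) -> RetractionCurve:
    """Synthetic retraction curve: forward model plus seeded Gaussian
    measurement noise of standard deviation ``noise_sd`` um.

    Emulates a hand-digitised plasmolysis video time course: a
    saturating retraction towards the zone-length plateau with
    additive position-reading noise.  Reproducible per seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(times, dtype=float)
    x = retraction_forward(P_os_bar, dPi, r, l, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=times.shape)
    return RetractionCurve(times=times, x=x, r=r, dPi=dPi,
                           truth=(P_os_bar, l), seed=seed)
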