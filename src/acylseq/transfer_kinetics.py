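"""First-order kinetics of interstrand aminoacyl-transfer with competing
donor hydrolysis.

Model
-----
The acyl donor strand carries an activated aminoacyl group at its
5'-phosphate.  While annealed to the acceptor (duplex occupancy ``theta``),
the aminoacyl group transfers to the acceptor's 2',3'-diol with rate
constant ``k_T`` (h^-1); in parallel the activated donor hydrolyzes with
rate constant ``k_H`` (h^-1) regardless of annealing state.  With donor in
one equivalent the acceptor aminoacylation yield follows

    Y(t) = Y_max * (1 - exp(-k_obs * t)),
    k_obs = theta*k_T + k_H,      Y_max = theta*k_T / (theta*k_T + k_H),

i.e. a single-exponential rise to a plateau below 1 set by the competition
between transfer and hydrolysis.  With n sequential equivalents of donor the
plateau compounds as Y_n = 1 - (1 - Y_1)**n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class TimeCourse:
    """An aminoacylation time course: times in hours, yields as fractions."""

    times: np.ndarray
    yields: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.times.shape != self.yields.shape:
            raise ValueError("times and yields must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time_h": self.times, "yield_fraction": self.yields}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "TimeCourse":
        df = pd.read_csv(path, sep="\t")
        return cls(times=df["time_h"].to_numpy(),
                   yields=df["yield_fraction"].to_numpy(),
                   label=label or Path(path).stem)


@dataclass
class TransferKinetics:
    """Fitted (or specified) kinetic parameters of one transfer reaction.

    k_T and k_H are in h^-1; theta is the duplex-bound fraction of the donor
    at the reaction temperature, supplied from the melting model rather than
    co-fitted (transfer only happens in the duplex, and theta*k_T is not
    separable from theta without it).
    """

    k_T: float
    k_H: float
    theta: float = 1.0
    rss: float | None = None
    stderr: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k_T < 0 or self.k_H < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0, 1]")

    @property
    def k_obs(self) -> float:
        return self.theta * self.k_T + self.k_H

    @property
    def y_max(self) -> float:
        num = self.theta * self.k_T
        denom = num + self.k_H
        return num / denom if denom > 0 else 0.0

    def to_dict(self) -> dict:
        return {"k_T_per_h": self.k_T, "k_H_per_h": self.k_H,
                "theta": self.theta, "k_obs_per_h": self.k_obs,
                "Y_max": self.y_max, "rss": self.rss,
                "stderr": self.stderr, "flags": self.flags}


def yield_model(t, kin: TransferKinetics):
    """Closed-form aminoacylation yield Y(t) = Y_max*(1 - exp(-k_obs*t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    y = kin.y_max * (1.0 - np.exp(-kin.k_obs * t))
    return float(y) if y.ndim == 0 else y


def _curve(params: np.ndarray, t: np.ndarray, theta: float) -> np.ndarray:
    k_t, k_h = params
    k_obs = theta * k_t + k_h
    with np.errstate(over="ignore"):
        y_max = theta * k_t / k_obs if k_obs > 0 else 0.0
        return y_max * (1.0 - np.exp(-k_obs * t))


def fit_time_course(tc: TimeCourse, theta: float | Literal["free"] = 1.0,
                    bounds: tuple[float, float] = (1e-3, 1e2),
                    n_starts: int = 20, seed: int = 0) -> TransferKinetics:
    """Least-squares fit of (k_T, k_H) to a time course.

    Multistart trust-region least squares: ``n_starts`` starting points
    drawn log-uniformly over ``bounds`` (h^-1), best of starts returned,
    deterministic given ``seed``.  ``theta`` is either a known fraction or
    "free" to co-fit it (requires at least 4 points; rarely identifiable in
    practice, see the package docs).  Standard errors come from the Jacobian
    at the optimum; flat-at-zero data return k_T = 0 with a flag rather
    than an error.
    """
    t, y = tc.times, tc.yields
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if len(np.unique(t[t > 0])) < 2:
        raise ValueError("need at least 2 distinct positive times")
    fit_theta = theta == "free"
    if fit_theta and len(t) < 4:
        raise ValueError("theta cannot be fit with fewer than 4 points")
    if np.allclose(y, 0.0):
        kin = TransferKinetics(k_T=0.0, k_H=float(np.mean(bounds)),
                               theta=1.0 if fit_theta else float(theta),
                               rss=float(np.sum(y ** 2)))
        kin.flags.append("all_zero_yields")
        return kin

    rng = np.random.default_rng(seed)
    lo, hi = bounds
    nparams = 3 if fit_theta else 2

    def residuals(params):
        if fit_theta:
            k_t, k_h, th = params
        else:
            k_t, k_h = params
            th = float(theta)
        return _curve(np.array([k_t, k_h]), t, th) - y

    lb = [lo, lo] + ([0.0] if fit_theta else [])
    ub = [hi, hi] + ([1.0] if fit_theta else [])
    best = None
    for _ in range(n_starts):
        x0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=2))
        if fit_theta:
            x0 = np.append(x0, rng.uniform(0.1, 1.0))
        try:
            res = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    rss = float(2 * best.cost)
    dof = max(len(t) - nparams, 1)
    # covariance from the Gauss-Newton approximation J^T J
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(nparams, np.nan)

    if fit_theta:
        k_t, k_h, th = best.x
        stderr = {"k_T": se[0], "k_H": se[1], "theta": se[2]}
    else:
        k_t, k_h = best.x
        th = float(theta)
        stderr = {"k_T": se[0], "k_H": se[1]}
    g = np.zeros(nparams)
    g[0], g[1] = th, 1.0  # d k_obs / d(k_T, k_H)
    if fit_theta:
        g[2] = k_t
    try:
        quad = max(float(g @ np.linalg.inv(jtj) @ g), 0.0)
        stderr["k_obs"] = float(np.sqrt(quad * rss / dof))
    except np.linalg.LinAlgError:
        stderr["k_obs"] = float("nan")
    return TransferKinetics(k_T=float(k_t), k_H=float(k_h), theta=float(th),
                            rss=rss, stderr={k: float(v) for k, v in stderr.items()})


def stereoselectivity_factor(fit_L: TransferKinetics, fit_D: TransferKinetics,
                             mode: Literal["rate", "yield"] = "rate",
                             ) -> tuple[float, list[str]]:
    """L-over-D preference in the same sequence context.

    ``mode="rate"`` (default) is the ratio of effective initial transfer
    rates (theta*k_T)_L / (theta*k_T)_D; ``mode="yield"`` compares plateau
    yields Y_max instead.  Returns (factor, flags); a zero D-rate gives
    ``inf`` with a flag rather than an exception.
    """
    if mode == "rate":
        num = fit_L.theta * fit_L.k_T
        den = fit_D.theta * fit_D.k_T
    elif mode == "yield":
        num, den = fit_L.y_max, fit_D.y_max
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0:
        return float("inf"), ["zero_D_rate"]
    return num / den, []


def multi_equivalent_plateau(y1: float, n: int) -> float:
    """Plateau after ``n`` sequential equivalents of donor: 1 - (1-y1)**n.

    Each fresh donor equivalent converts the same fraction ``y1`` of the
    still-unreacted acceptor before hydrolysis exhausts it.
    """
    if not 0 <= y1 <= 1:
        raise ValueError("y1 must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - y1) ** n
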