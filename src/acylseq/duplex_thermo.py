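"""Two-state duplex hybridization: fraction bound, melting temperature,
and melting-curve fitting.

For a bimolecular, non-self-complementary duplex A + B <=> AB with total
strand concentrations a0 and b0 (mol/L) and van't Hoff parameters dH
(kcal/mol) and dS (kcal/mol/K), the association constant at absolute
temperature T is K(T) = exp(-(dH - T*dS)/(R*T)).  The duplex concentration
x solves K = x/((a0-x)(b0-x)); the bound fraction of the limiting strand is
theta = x/min(a0, b0).  T_M is the temperature where theta = 0.5, which for
equimolar strands reduces to the standard closed form
T_M = dH / (dS + R*ln(C_T/4)) with C_T = a0 + b0.  No heat-capacity term
(dCp = 0), the usual assumption for short oligonucleotide duplexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1
_T0 = 273.15


@dataclass
class DuplexThermo:
    """Duplex thermodynamics and strand concentrations.

    dH in kcal/mol (negative for a binding duplex), dS in kcal/mol/K,
    concentrations in mol/L.
    """

    dH: float
    dS: float
    conc_donor: float
    conc_acceptor: float

    def __post_init__(self) -> None:
        if self.conc_donor <= 0 or self.conc_acceptor <= 0:
            raise ValueError("strand concentrations must be positive")
        if self.dH >= 0:
            raise ValueError("a binding duplex requires dH < 0")

    @property
    def tm(self) -> float:
        return melting_temperature(self)

    def to_dict(self) -> dict:
        return {"dH_kcal_mol": self.dH, "dS_kcal_mol_K": self.dS,
                "conc_donor_M": self.conc_donor,
                "conc_acceptor_M": self.conc_acceptor, "Tm_C": self.tm}


def association_constant(thermo: DuplexThermo, temp_c: float) -> float:
    t_k = temp_c + _T0
    return float(np.exp(-(thermo.dH - t_k * thermo.dS) / (R_KCAL * t_k)))


def fraction_bound(thermo: DuplexThermo, temp_c) -> float | np.ndarray:
    """Bound fraction theta of the limiting strand at temperature(s) in C.

    Solves the bimolecular mass-action quadratic
    K*x**2 - (K*(a0+b0) + 1)*x + K*a0*b0 = 0 and takes the physical root in
    [0, min(a0, b0)] (the smaller root of the downward-opening pair).
    """
    temp_arr = np.atleast_1d(np.asarray(temp_c, dtype=float))
    if np.any(temp_arr < -20) or np.any(temp_arr > 120):
        raise ValueError("temperature outside the physical range [-20, 120] C")
    a0, b0 = thermo.conc_donor, thermo.conc_acceptor
    t_k = temp_arr + _T0
    # exponent capped at 300: K = 1e130 already pins theta at 1 to within
    # float precision, and the cap keeps K**2 finite inside the quadratic
    exponent = np.clip(-(thermo.dH - t_k * thermo.dS) / (R_KCAL * t_k), None, 300.0)
    k_assoc = np.exp(exponent)
    b = k_assoc * (a0 + b0) + 1.0
    # smaller root of K x^2 - b x + K a0 b0 = 0; the discriminant is expanded
    # to K^2 (a0-b0)^2 + 2 K (a0+b0) + 1 (exact algebra, all terms positive)
    # because the naive b^2 - 4 K^2 a0 b0 cancels catastrophically at large K
    disc = np.sqrt((k_assoc * (a0 - b0)) ** 2 + 2.0 * k_assoc * (a0 + b0) + 1.0)
    x = 2.0 * k_assoc * a0 * b0 / (b + disc)
    theta = np.clip(x / min(a0, b0), 0.0, 1.0)
    return float(theta[0]) if np.isscalar(temp_c) or np.ndim(temp_c) == 0 else theta


def melting_temperature(thermo: DuplexThermo, method: str = "auto") -> float:
    """Temperature (C) at which half the limiting strand is duplexed.

    For equimolar strands the closed form dH/(dS + R*ln(C_T/4)) - 273.15 is
    used; otherwise (or with ``method="bisect"``) the root of
    theta(T) - 0.5 is bracketed and solved numerically.
    """
    a0, b0 = thermo.conc_donor, thermo.conc_acceptor
    equimolar = np.isclose(a0, b0, rtol=1e-12)
    if method == "auto" and equimolar:
        c_t = a0 + b0
        denom = thermo.dS + R_KCAL * np.log(c_t / 4.0)
        t_k = thermo.dH / denom
        if t_k <= 0:
            raise ValueError("no physical melting temperature for these parameters")
        return float(t_k - _T0)
    f = lambda t: fraction_bound(thermo, t) - 0.5
    lo, hi = -20.0, 120.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("theta = 0.5 has no root in the physical range")
    return float(brentq(f, lo, hi, xtol=1e-9))


def thermo_from_tm(tm_c: float, dH: float, conc_donor: float,
                   conc_acceptor: float | None = None) -> DuplexThermo:
    """Construct equimolar-calibrated thermodynamics with a prescribed T_M.

    Given the enthalpy and the per-strand concentration, the entropy is
    chosen so that the equimolar closed form returns exactly ``tm_c``.
    Useful for building simulation scenarios around a measured T_M.
    """
    if conc_acceptor is None:
        conc_acceptor = conc_donor
    c_t = conc_donor + conc_acceptor
    dS = dH / (tm_c + _T0) - R_KCAL * np.log(c_t / 4.0)
    return DuplexThermo(dH=dH, dS=float(dS), conc_donor=conc_donor,
                        conc_acceptor=conc_acceptor)


@dataclass
class MeltingCurve:
    """A melting curve: temperatures (C, ascending) and raw signal."""

    temps: np.ndarray
    signals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.temps.shape != self.signals.shape:
            raise ValueError("temps and signals must have equal length")
        if np.any(np.diff(self.temps) <= 0):
            raise ValueError("temps must be strictly ascending")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"temp_C": self.temps, "signal": self.signals}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "MeltingCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(temps=df["temp_C"].to_numpy(), signals=df["signal"].to_numpy(),
                   label=label or Path(path).stem)


@dataclass
class MeltingFit:
    """Result of a two-state melting-curve fit: thermodynamics + baselines."""

    thermo: DuplexThermo
    baselines: dict[str, float]
    rss: float

    @property
    def tm(self) -> float:
        return self.thermo.tm

    def to_json(self, path: str | Path) -> None:
        payload = self.thermo.to_dict() | {"baselines": self.baselines,
                                           "rss": self.rss}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def melting_signal(thermo: DuplexThermo, temps, baselines) -> np.ndarray:
    """Observed signal under sloping single- and double-strand baselines:
    (1-theta)*(m_ss*T + c_ss) + theta*(m_ds*T + c_ds)."""
    temps = np.asarray(temps, dtype=float)
    m_ss, c_ss, m_ds, c_ds = baselines
    theta = fraction_bound(thermo, temps)
    return (1.0 - theta) * (m_ss * temps + c_ss) + theta * (m_ds * temps + c_ds)


def fit_melting_curve(curve: MeltingCurve, conc_donor: float,
                      conc_acceptor: float, n_starts: int = 12,
                      seed: int = 0) -> MeltingFit:
    """Fit (dH, dS, four baseline parameters) to a melting curve.

    Multistart seeded least squares; dH is parameterized together with the
    midpoint temperature (dS derived from it) so starting points can be
    spread across the observed temperature window.  A curve with no visible
    transition inside its window fails with a non-convergence error.
    """
    if len(curve.temps) < 8:
        raise ValueError("need at least 8 points spanning the transition")
    t, y = curve.temps, curve.signals
    span = float(np.ptp(y))
    if span == 0:
        raise RuntimeError("flat curve: no melting transition to fit")
    c_t = conc_donor + conc_acceptor
    log_term = R_KCAL * np.log(c_t / 4.0)

    def unpack(params):
        dh, tm_k, m_ss, c_ss, m_ds, c_ds = params
        ds = dh / tm_k - log_term
        thermo = DuplexThermo(dH=dh, dS=ds, conc_donor=conc_donor,
                              conc_acceptor=conc_acceptor)
        return thermo, (m_ss, c_ss, m_ds, c_ds)

    def residuals(params):
        thermo, baselines = unpack(params)
        return melting_signal(thermo, t, baselines) - y

    rng = np.random.default_rng(seed)
    lb = [-300.0, t[0] - 30 + _T0, -np.inf, -np.inf, -np.inf, -np.inf]
    ub = [-5.0, t[-1] + 30 + _T0, np.inf, np.inf, np.inf, np.inf]
    y_lo, y_hi = float(y[0]), float(y[-1])
    best = None
    for _ in range(n_starts):
        x0 = np.array([
            rng.uniform(-120.0, -20.0),
            rng.uniform(t[0], t[-1]) + _T0,
            0.0, y_hi, 0.0, y_lo,
        ])
        try:
            res = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        except (ValueError, RuntimeError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("melting-curve fit did not converge from any start")
    rss = float(2 * best.cost)
    # model comparison against a plain straight line: when the transition lies
    # outside the window the curve is just (noisy) baseline, a line explains
    # it almost as well, and the thermodynamic parameters are unconstrained
    line_resid = y - np.polyval(np.polyfit(t, y, 1), t)
    rss_line = float(np.sum(line_resid ** 2))
    if rss > 0.2 * rss_line:
        raise RuntimeError("melting-curve fit did not converge: "
                           "no transition evident inside the temperature window")
    thermo, (m_ss, c_ss, m_ds, c_ds) = unpack(best.x)
    # a transition outside the window leaves theta nearly constant across it,
    # so the thermodynamic parameters are not actually constrained by the data
    theta_span = fraction_bound(thermo, float(t[0])) - fraction_bound(thermo, float(t[-1]))
    if theta_span < 0.2:
        raise RuntimeError("melting transition outside the temperature window: "
                           "fitted duplex fraction barely changes across it")
    return MeltingFit(thermo=thermo,
                      baselines={"m_ss": float(m_ss), "c_ss": float(c_ss),
                                 "m_ds": float(m_ds), "c_ds": float(c_ds)},
                      rss=rss)
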