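"""FvCB photosynthesis model: forward simulation and A/Ci curve fitting.

Net assimilation is the minimum of the Rubisco-limited and the
RuBP-regeneration-limited rate::

    Ac = Vcmax * (Cc - Gamma*) / (Cc + Kc * (1 + O/Ko)) - Rd
    Aj = J    * (Cc - Gamma*) / (4*Cc + 8*Gamma*)       - Rd

with ``J = Jmax`` under saturating chamber light (1800 umol m-2 s-1).
Chloroplastic CO2 follows from mesophyll conductance, ``Cc = Ci - A/gm``,
where gm carries a linear temperature dependence anchored at 25 C.

Kinetic constants default to the widely used tobacco-derived 25 C set with
Arrhenius temperature scaling; every value is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "KineticConstants",
    "ACiCurve",
    "FvCBParams",
    "FitResult",
    "GmConfig",
    "FitError",
    "RUBISCO",
    "RUBP",
    "PAPER_CI_SETPOINTS",
    "gm_at_temperature",
    "ci_to_cc",
    "fvcb_assimilation",
    "solve_assimilation_at_ci",
    "fit_aci",
    "plot_average",
]

RUBISCO = "Rubisco"
RUBP = "RuBP"

#: The 12 chamber Ci setpoints, umol mol^-1 (400 appears twice by design).
PAPER_CI_SETPOINTS = (400.0, 200.0, 50.0, 100.0, 300.0, 400.0,
                      600.0, 900.0, 1200.0, 1500.0, 1800.0, 2000.0)

#: Saturating chamber PAR, umol m^-2 s^-1.
CHAMBER_PAR = 1800.0

_R_GAS = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics at 25 C plus Arrhenius activation energies (J mol^-1)."""

    gamma_star: float = 42.75   # umol mol^-1
    Kc: float = 404.9           # umol mol^-1
    Ko: float = 278.4           # mmol mol^-1
    O: float = 210.0            # mmol mol^-1
    Ha_gamma_star: float = 37830.0
    Ha_Kc: float = 79430.0
    Ha_Ko: float = 36380.0

    def __post_init__(self) -> None:
        for name in ("gamma_star", "Kc", "Ko", "O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def Km(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), umol mol^-1."""
        return self.Kc * (1.0 + self.O / self.Ko)

    def at_leaf_temperature(self, t_leaf_c: float) -> "KineticConstants":
        """Arrhenius-scaled constants at ``t_leaf_c`` (O is conserved)."""
        if t_leaf_c == 25.0:
            return self
        tk = t_leaf_c + 273.15
        ref = 298.15

        def arr(k25: float, ha: float) -> float:
            return k25 * math.exp(ha * (tk - ref) / (ref * _R_GAS * tk))

        return replace(
            self,
            gamma_star=arr(self.gamma_star, self.Ha_gamma_star),
            Kc=arr(self.Kc, self.Ha_Kc),
            Ko=arr(self.Ko, self.Ha_Ko),
        )


@dataclass(frozen=True)
class GmConfig:
    """Mesophyll conductance at 25 C and its linear temperature slope."""

    gm25: float = 0.3       # mol m^-2 s^-1 bar^-1
    slope_per_c: float = 0.0

    def at(self, t_leaf_c: float) -> float:
        return gm_at_temperature(self.gm25, self.slope_per_c, t_leaf_c)


@dataclass
class ACiCurve:
    """One leaf's assimilation response to stepped intercellular CO2."""

    plot_id: str
    leaf_id: str
    ci: np.ndarray             # umol mol^-1
    a: np.ndarray              # umol m^-2 s^-1
    leaf_temperature: float = 25.0
    par_chamber: float = CHAMBER_PAR

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.ci.shape != self.a.shape:
            raise ValueError("Ci and A must have equal length")
        if np.any(self.ci <= 0):
            raise ValueError("Ci setpoints must be positive")


@dataclass(frozen=True)
class FvCBParams:
    """Fitted (or true) FvCB parameters; ``jmax`` is None when unidentifiable."""

    vcmax: float
    jmax: float | None
    rd: float
    gm: float = GmConfig().gm25
    limitation_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.vcmax <= 0 or self.rd <= 0 or self.gm <= 0:
            raise ValueError("rates must be positive")
        if self.jmax is not None and self.jmax <= 0:
            raise ValueError("jmax must be positive or None")


@dataclass(frozen=True)
class FitResult:
    params: FvCBParams
    sse: float
    n_used: int
    excluded_points: tuple[int, ...]
    converged: bool
    message: str
    jmax_available: bool


class FitError(RuntimeError):
    """Raised when the optimiser fails; carries the best candidate found."""

    def __init__(self, message: str, best: FitResult | None = None):
        super().__init__(message)
        self.best = best


def gm_at_temperature(gm25: float, slope: float, t_leaf_c: float) -> float:
    """Linear temperature response: gm25 * (1 + slope * (T - 25))."""
    gm = gm25 * (1.0 + slope * (t_leaf_c - 25.0))
    if gm <= 0:
        raise ValueError(
            f"gm is nonpositive ({gm:g}) at T={t_leaf_c:g} C with "
            f"gm25={gm25:g}, slope={slope:g}"
        )
    return gm


def ci_to_cc(ci, a, gm: float):
    """Cc = Ci - A/gm. Nonpositive results are the caller's cue to exclude."""
    if gm <= 0:
        raise ValueError("gm must be positive")
    return np.asarray(ci, dtype=float) - np.asarray(a, dtype=float) / gm


def fvcb_assimilation(cc, vcmax: float, jmax: float, rd: float,
                      k: KineticConstants = KineticConstants()):
    """Net assimilation and limitation labels at chloroplastic CO2 ``cc``.

    Returns ``(a, labels)`` where ``labels`` marks each point Rubisco- or
    RuBP-limited by the min rule.
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(cc <= 0):
        raise ValueError("Cc must be positive")
    ac = vcmax * (cc - k.gamma_star) / (cc + k.Km) - rd
    aj = jmax * (cc - k.gamma_star) / (4.0 * cc + 8.0 * k.gamma_star) - rd
    a = np.minimum(ac, aj)
    labels = np.where(ac <= aj, RUBISCO, RUBP)
    return a, labels


def solve_assimilation_at_ci(ci: float, vcmax: float, jmax: float, rd: float,
                             gm: float, k: KineticConstants = KineticConstants()) -> float:
    """Solve the implicit A = model(Ci - A/gm) for one chamber setpoint."""
    if ci <= 0:
        raise ValueError("Ci must be positive")

    def g(a: float) -> float:
        cc = ci - a / gm
        return fvcb_assimilation(cc, vcmax, jmax, rd, k)[0] - a

    lo = -rd - 1.0
    hi = min(vcmax + 10.0, gm * (ci - 1e-9) + 0.0)
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-14))


def _model_on_cc(cc: np.ndarray, theta: np.ndarray, k: KineticConstants) -> np.ndarray:
    vcmax, jmax, rd = theta
    ac = vcmax * (cc - k.gamma_star) / (cc + k.Km)
    aj = jmax * (cc - k.gamma_star) / (4.0 * cc + 8.0 * k.gamma_star)
    return np.minimum(ac, aj) - rd


def _model_jac(cc: np.ndarray, theta: np.ndarray, k: KineticConstants) -> np.ndarray:
    vcmax, jmax, rd = theta
    dc = (cc - k.gamma_star) / (cc + k.Km)
    dj = (cc - k.gamma_star) / (4.0 * cc + 8.0 * k.gamma_star)
    rubisco = vcmax * dc <= jmax * dj
    jac = np.empty((cc.size, 3))
    jac[:, 0] = np.where(rubisco, dc, 0.0)
    jac[:, 1] = np.where(rubisco, 0.0, dj)
    jac[:, 2] = -1.0
    return jac


_START_GRID = [(v, j) for v in (40.0, 90.0, 160.0, 280.0)
               for j in (120.0, 200.0, 320.0)]


def fit_aci(curve: ACiCurve, k: KineticConstants = KineticConstants(),
            gm_config: GmConfig = GmConfig(), min_points: int = 6,
            min_rubp_points: int = 2) -> FitResult:
    """Nonlinear least squares for (Vcmax, Jmax, Rd) on one A/Ci curve.

    Cc is recomputed from the observed A and gm; points with Cc <= 0 are
    excluded. If fewer than ``min_rubp_points`` points are RuBP-limited at
    the optimum, Jmax is reported unavailable and (Vcmax, Rd) are refit with
    the Rubisco-limited model alone.
    """
    kt = k.at_leaf_temperature(curve.leaf_temperature)
    gm = gm_config.at(curve.leaf_temperature)
    cc_all = ci_to_cc(curve.ci, curve.a, gm)
    usable = cc_all > kt.gamma_star * 1e-6
    excluded = tuple(int(i) for i in np.nonzero(~usable)[0])
    cc, a_obs = cc_all[usable], curve.a[usable]
    if cc.size < min_points:
        raise FitError(
            f"only {cc.size} usable points (need >= {min_points}) on "
            f"{curve.plot_id}/{curve.leaf_id}"
        )
    lo_ci, hi_ci = float(np.min(curve.ci)), float(np.max(curve.ci))
    if hi_ci / max(lo_ci, 1e-9) < 3.0:
        raise FitError("Ci setpoints do not span low and high CO2")

    def resid(theta: np.ndarray) -> np.ndarray:
        return _model_on_cc(cc, theta, kt) - a_obs

    def jac(theta: np.ndarray) -> np.ndarray:
        return _model_jac(cc, theta, kt)

    starts = sorted(_START_GRID,
                    key=lambda s: float(np.sum(resid(np.array([s[0], s[1], 1.5])) ** 2)))
    best = None
    any_converged = False
    for v0, j0 in starts[:3]:
        res = least_squares(resid, x0=np.array([v0, j0, 1.5]), jac=jac,
                            bounds=([1e-3, 1e-3, 1e-4], [2000.0, 2000.0, 50.0]),
                            method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10)
        any_converged = any_converged or bool(res.success)
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not any_converged:
        candidate = None
        if best is not None:
            candidate = _result_from_theta(best.x, cc, a_obs, kt, gm, excluded,
                                           False, "optimizer did not converge",
                                           min_rubp_points)
        raise FitError("A/Ci fit did not converge", best=candidate)
    return _result_from_theta(best.x, cc, a_obs, kt, gm, excluded, True,
                              "converged", min_rubp_points)


def _result_from_theta(theta, cc, a_obs, kt, gm, excluded, converged, message,
                       min_rubp_points) -> FitResult:
    vcmax, jmax, rd = (float(t) for t in theta)
    _, labels = fvcb_assimilation(cc, vcmax, jmax, rd, kt)
    n_rubp = int(np.sum(labels == RUBP))
    jmax_available = n_rubp >= min_rubp_points
    if not jmax_available:
        # Jmax never binds: refit the Rubisco branch only for a stable answer.
        def resid2(th):
            return th[0] * (cc - kt.gamma_star) / (cc + kt.Km) - th[1] - a_obs

        res2 = least_squares(resid2, x0=np.array([vcmax, rd]),
                             bounds=([1e-3, 1e-4], [2000.0, 50.0]),
                             method="trf", xtol=1e-12, ftol=1e-12)
        vcmax, rd = (float(t) for t in res2.x)
        labels = np.full(cc.shape, RUBISCO)
        sse = float(2.0 * res2.cost)
        message = f"{message}; no RuBP-limited points -> Jmax unavailable"
        params = FvCBParams(vcmax, None, rd, gm, tuple(labels))
    else:
        sse = float(np.sum((_model_on_cc(cc, np.array([vcmax, jmax, rd]), kt) - a_obs) ** 2))
        params = FvCBParams(vcmax, jmax, rd, gm, tuple(labels))
    return FitResult(params, sse, int(cc.size), excluded, converged, message,
                     jmax_available)


def plot_average(params_per_leaf: list[FvCBParams]) -> dict:
    """Leaf-to-plot averaging; Jmax averages only identifiable leaves."""
    if not params_per_leaf:
        raise ValueError("no leaves to average")
    vcmax = float(np.mean([p.vcmax for p in params_per_leaf]))
    jvals = [p.jmax for p in params_per_leaf if p.jmax is not None]
    jmax = float(np.mean(jvals)) if jvals else None
    return {
        "vcmax": vcmax,
        "jmax": jmax,
        "n_leaves": len(params_per_leaf),
        "n_jmax_leaves": len(jvals),
    }
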