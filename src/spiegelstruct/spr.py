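"""1:1 Langmuir SPR kinetics with mass-transport limitation.

Model
-----
Binding of an analyte at bulk concentration ``C`` to an immobilised
ligand surface follows

    dR/dt = ka * Cs * (Rmax - R) - kd * R

where ``R`` is the response (RU), ``Rmax`` the surface capacity and
``Cs`` the analyte concentration in the surface compartment. Transport
of analyte between bulk and surface at rate ``kt`` (RU M^-1 s^-1) is
treated in the standard two-compartment quasi-steady-state form

    Cs = (kt * C + kd * R) / (kt + ka * (Rmax - R))

which reduces to the plain Langmuir model as kt -> infinity. The
dissociation phase uses C = 0. The equilibrium dissociation constant is
Kd = kd / ka and is independent of kt.

The default protocol mirrors a direct-binding Biacore format: 240 s
association, 240 s dissociation, and a two-fold analyte dilution series
starting at 500 nM, with the transport coefficient fixed at 1e7
RU M^-1 s^-1 unless explicitly floated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "KineticModel",
    "Sensorgram",
    "FitResult",
    "CompetitionCurve",
    "DEFAULT_KT",
    "DEFAULT_T_ASSOC",
    "DEFAULT_T_DISSOC",
    "default_concentration_series",
    "closed_form_langmuir",
    "simulate_sensorgram",
    "fit_kinetics",
    "free_ligand_concentration",
    "simulate_competition",
    "scale_ka",
]

DEFAULT_KT = 1.0e7  # RU M^-1 s^-1, transport coefficient
DEFAULT_T_ASSOC = 240.0  # s
DEFAULT_T_DISSOC = 240.0  # s


def default_concentration_series(top: float = 500e-9, n: int = 15) -> np.ndarray:
    """Two-fold dilution series from ``top`` with a final zero, in M."""
    series = top / 2.0 ** np.arange(n - 1)
    return np.append(series, 0.0)


@dataclass
class KineticModel:
    """1:1 binding parameters: ka (1/M/s), kd (1/s), Rmax (RU), kt (RU/M/s)."""

    ka: float
    kd: float
    rmax: float
    kt: float = DEFAULT_KT

    def __post_init__(self) -> None:
        for name in ("ka", "kd", "rmax", "kt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def Kd(self) -> float:
        return self.kd / self.ka

    def req(self, conc: float) -> float:
        """Equilibrium response at analyte concentration ``conc``."""
        return self.rmax * conc / (conc + self.Kd)


@dataclass
class Sensorgram:
    times: np.ndarray  # s, uniform grid starting at 0
    response: np.ndarray  # RU
    analyte_concentration: float  # M
    t_assoc: float  # association phase end, s
    t_end: float  # dissociation phase end, s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.response = np.asarray(self.response, float)
        if self.times.size != self.response.size:
            raise ValueError("times and response must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def phase(self) -> np.ndarray:
        """'association' / 'dissociation' label per time point."""
        return np.where(self.times <= self.t_assoc, "association", "dissociation")


@dataclass
class FitResult:
    estimates: KineticModel
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = False

    @property
    def Kd(self) -> float:
        return self.estimates.Kd


def _rate(t: float, r: np.ndarray, model: KineticModel, conc: float) -> np.ndarray:
    free = model.rmax - r[0]
    cs = (model.kt * conc + model.kd * r[0]) / (model.kt + model.ka * free)
    return np.array([model.ka * cs * free - model.kd * r[0]])


def simulate_sensorgram(
    model: KineticModel,
    conc: float,
    t_assoc: float = DEFAULT_T_ASSOC,
    t_dissoc: float = DEFAULT_T_DISSOC,
    dt: float = 0.5,
) -> Sensorgram:
    """Integrate the transport-coupled 1:1 model over both phases.

    Uses a stiff-capable adaptive integrator (LSODA) with absolute
    tolerance 1e-6 RU; the returned grid is uniform with step ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if conc < 0:
        raise ValueError("analyte concentration must be non-negative")
    t_a = np.arange(0.0, t_assoc + dt / 2, dt)
    sol_a = solve_ivp(
        _rate, (0.0, t_a[-1]), [0.0], t_eval=t_a, args=(model, conc),
        method="LSODA", rtol=1e-8, atol=1e-6,
    )
    r_a = sol_a.y[0]
    t_d = np.arange(t_a[-1], t_a[-1] + t_dissoc + dt / 2, dt)
    if len(t_d) > 1:
        sol_d = solve_ivp(
            _rate, (t_d[0], t_d[-1]), [r_a[-1]], t_eval=t_d, args=(model, 0.0),
            method="LSODA", rtol=1e-8, atol=1e-6,
        )
        times = np.concatenate([t_a, t_d[1:]])
        response = np.concatenate([r_a, sol_d.y[0][1:]])
    else:
        times, response = t_a, r_a
    response = np.clip(response, 0.0, model.rmax)
    return Sensorgram(times, response, conc, t_assoc=t_a[-1], t_end=times[-1])


def closed_form_langmuir(
    model: KineticModel, conc: float, times: np.ndarray, t_assoc: float
) -> np.ndarray:
    """Transport-free 1:1 Langmuir response, exact closed form."""
    times = np.asarray(times, float)
    req = model.req(conc) if conc > 0 else 0.0
    kobs = model.ka * conc + model.kd
    r = np.where(times <= t_assoc, req * (1.0 - np.exp(-kobs * times)), np.nan)
    r_at = req * (1.0 - np.exp(-kobs * t_assoc))
    mask = times > t_assoc
    r[mask] = r_at * np.exp(-model.kd * (times[mask] - t_assoc))
    return r


def fit_kinetics(
    sensorgrams: list[Sensorgram],
    kt: float | None = DEFAULT_KT,
    init: KineticModel | None = None,
) -> FitResult:
    """Global nonlinear least squares over a concentration series.

    ka, kd and Rmax are shared across all curves; ``kt`` is fixed at the
    given value (pass ``None`` to float it). Parameters are fitted on a
    log10 scale. Non-convergence is flagged on the result, never raised.
    """
    if not sensorgrams:
        raise ValueError("need at least one sensorgram")
    float_kt = kt is None
    rmax0 = max(float(np.max(s.response)) for s in sensorgrams) * 1.5 + 1e-6
    if init is None:
        init = KineticModel(1e5, 1e-2, rmax0, DEFAULT_KT if float_kt else kt)
    x0 = [np.log10(init.ka), np.log10(init.kd), np.log10(init.rmax)]
    if float_kt:
        x0.append(np.log10(init.kt))

    grids = [(s.times, s.analyte_concentration, s.t_assoc, s.response) for s in sensorgrams]

    def unpack(x) -> KineticModel:
        ka, kd, rmax = 10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2]
        ktv = 10.0 ** x[3] if float_kt else kt
        return KineticModel(ka, kd, rmax, ktv)

    def residuals(x):
        m = unpack(x)
        res = []
        for times, conc, t_assoc, data in grids:
            dt = times[1] - times[0]
            sim = simulate_sensorgram(m, conc, t_assoc, times[-1] - t_assoc, dt)
            res.append(sim.response[: len(data)] - data)
        return np.concatenate(res)

    try:
        sol = least_squares(residuals, x0, method="trf", xtol=1e-12, ftol=1e-12)
        converged = bool(sol.success)
        x, rss = sol.x, float(np.sum(sol.fun**2))
        # asymptotic standard errors from the Jacobian
        stderr = {}
        try:
            dof = max(sol.fun.size - sol.x.size, 1)
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * rss / dof
            names = ["ka", "kd", "rmax"] + (["kt"] if float_kt else [])
            vals = 10.0 ** sol.x
            for i, name in enumerate(names):
                # delta method for the log10 parameterisation
                stderr[name] = float(np.sqrt(max(cov[i, i], 0.0)) * vals[i] * np.log(10.0))
        except np.linalg.LinAlgError:
            pass
    except Exception:  # pathological residuals: report the initial point, flagged
        x, rss, converged, stderr = np.asarray(x0), np.nan, False, {}
    return FitResult(estimates=unpack(x), stderr=stderr, rss=rss, converged=converged)


def free_ligand_concentration(total_a: float, total_b: float, kd: float) -> float:
    """Free A in a 1:1 A+B equilibrium with ligand depletion.

    Root of A_free^2 + (B - A + Kd) A_free - Kd A = 0:
    A_free = ((A - B - Kd) + sqrt((A - B - Kd)^2 + 4 Kd A)) / 2.
    """
    if total_a < 0 or total_b < 0 or kd < 0:
        raise ValueError("concentrations and Kd must be non-negative")
    h = total_a - total_b - kd
    s = np.sqrt(h * h + 4.0 * kd * total_a)
    # numerically stable branch: avoid h + s cancellation when h < 0
    if h >= 0:
        return 0.5 * (h + s)
    denom = s - h
    return (2.0 * kd * total_a / denom) if denom > 0 else 0.0


@dataclass
class CompetitionCurve:
    competitor_concentrations: np.ndarray  # M
    signal_fraction: np.ndarray  # report-point signal / no-competitor signal
    solution_kd: float  # M

    def __post_init__(self) -> None:
        self.competitor_concentrations = np.asarray(self.competitor_concentrations, float)
        self.signal_fraction = np.asarray(self.signal_fraction, float)


def simulate_competition(
    chip_model: KineticModel,
    solution_kd: float,
    aptamer_conc: float,
    competitor_series,
    t_assoc: float = DEFAULT_T_ASSOC,
    t_dissoc: float = DEFAULT_T_DISSOC,
    dt: float = 1.0,
) -> CompetitionCurve:
    """Competitive format: analyte pre-equilibrated with a solution competitor.

    The free analyte fraction follows the 1:1 depletion equilibrium; the
    report point is the response at the end of the dissociation phase,
    normalised to the no-competitor signal.
    """
    competitor_series = np.asarray(competitor_series, float)
    if np.any(competitor_series < 0):
        raise ValueError("competitor concentrations must be non-negative")

    def report_point(conc: float) -> float:
        s = simulate_sensorgram(chip_model, conc, t_assoc, t_dissoc, dt)
        return float(s.response[-1])

    ref = report_point(aptamer_conc)
    if ref <= 0:
        raise ValueError("no-competitor signal is zero; cannot normalise")
    fractions = np.array(
        [
            report_point(free_ligand_concentration(aptamer_conc, b, solution_kd)) / ref
            for b in competitor_series
        ]
    )
    return CompetitionCurve(competitor_series, np.clip(fractions, 0.0, 1.0), solution_kd)


def scale_ka(model: KineticModel, factor: float) -> KineticModel:
    """Scenario helper: divalent-cation titrations act on the association
    rate constant, so an ion condition is represented as a multiplicative
    ka factor (no mechanistic ion-binding model is implied)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return KineticModel(model.ka * factor, model.kd, model.rmax, model.kt)
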