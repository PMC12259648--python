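"""1:1 Langmuir SPR kinetics: simulation, global fitting, and summaries.

For a 1:1 interaction with association rate ka (1/(M s)), dissociation
rate kd (1/s) and analyte concentration C, the sensor response follows

    association:  R(t) = Req (1 - exp(-(ka C + kd) t)),  Req = Rmax C/(C + KD)
    dissociation: R(t) = R(t_assoc) exp(-kd (t - t_assoc))

with KD = kd/ka.  Fitting is a global nonlinear least-squares sharing
(ka, kd, Rmax) across the whole concentration series, the standard Biacore
practice for this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "KineticFit",
    "KineticFitError",
    "simulate_sensorgram",
    "langmuir_response",
    "fit_1to1",
    "fold_change",
    "summarize_kinetics",
]


class KineticFitError(RuntimeError):
    """Global fit failed to converge from any start."""


@dataclass
class Sensorgram:
    """One SPR curve: response (RU) vs time for a single analyte concentration."""

    concentration_M: float
    times_s: np.ndarray
    response_RU: np.ndarray
    t_assoc_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.response_RU = np.asarray(self.response_RU, dtype=float)
        if self.times_s.shape != self.response_RU.shape:
            raise ValueError("times and response must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.response_RU)):
            raise ValueError("response must be finite")
        if self.t_assoc_s <= 0:
            raise ValueError("association window must have positive length")

    @property
    def is_blank(self) -> bool:
        return self.concentration_M == 0.0


def langmuir_response(
    t: np.ndarray, conc_M: float, ka: float, kd: float, rmax: float, t_assoc: float
) -> np.ndarray:
    """Noise-free 1:1 Langmuir response at times ``t`` (closed form)."""
    t = np.asarray(t, dtype=float)
    kobs = ka * conc_M + kd
    req = rmax * conc_M / (conc_M + kd / ka) if conc_M > 0 else 0.0
    # np.where evaluates both branches; clip the dissociation exponent so
    # the unused branch cannot overflow during optimizer line searches
    r = np.where(
        t <= t_assoc,
        req * (1.0 - np.exp(-kobs * t)),
        req
        * (1.0 - np.exp(-kobs * t_assoc))
        * np.exp(np.clip(-kd * (t - t_assoc), -700.0, 0.0)),
    )
    return r


def simulate_sensorgram(
    ka: float,
    kd: float,
    rmax: float,
    conc_series_M,
    t_assoc_s: float = 120.0,
    t_dissoc_s: float = 1360.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt_s: float = 1.0,
) -> list[Sensorgram]:
    """Simulate a concentration series of 1:1 Langmuir sensorgrams.

    The default timing mirrors a 120 s association / 1360 s dissociation
    injection cycle.  A 0 M entry produces a blank (pure-noise) curve.
    """
    if ka <= 0 or kd <= 0 or rmax <= 0:
        raise ValueError("ka, kd and Rmax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_assoc_s + t_dissoc_s + dt_s / 2, dt_s)
    curves = []
    for conc in conc_series_M:
        clean = langmuir_response(times, conc, ka, kd, rmax, t_assoc_s)
        noise = rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else 0.0
        curves.append(
            Sensorgram(
                concentration_M=float(conc),
                times_s=times,
                response_RU=clean + noise,
                t_assoc_s=t_assoc_s,
            )
        )
    return curves


@dataclass
class KineticFit:
    """Result of a global 1:1 fit.  KD is stored as kd/ka exactly."""

    ka: float
    kd: float
    rmax: float
    KD: float
    rms_RU: float
    n_points: int
    flags: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.ka, self.kd, self.rmax) <= 0:
            raise ValueError("rate constants and Rmax must be positive")
        if self.KD != self.kd / self.ka:
            raise ValueError("KD must equal kd/ka exactly as stored")


# Log-spaced multi-start grid, fixed order, over (ka, kd).
_KA_STARTS = (1e3, 1e5, 1e7)
_KD_STARTS = (1e-5, 1e-3, 1e-1)


def fit_1to1(
    curves: list[Sensorgram],
    subtract_blank: bool = True,
    per_curve_rmax: bool = False,
) -> KineticFit:
    """Globally fit a 1:1 Langmuir model to a sensorgram series.

    (ka, kd, Rmax) are shared across all non-blank curves; when a 0 M blank
    is present it is subtracted first.  Optimization runs in log-parameter
    space from a fixed 3x3 grid of (ka, kd) starts.  The dissociation rate
    is flagged as poorly constrained when its approximate 95% confidence
    half-width exceeds 50% of the estimate.
    """
    blanks = [c for c in curves if c.is_blank]
    active = [c for c in curves if not c.is_blank]
    if len(active) < 2:
        raise ValueError("need at least two non-blank concentrations")
    blank = blanks[0].response_RU if (subtract_blank and blanks) else None

    responses, times, concs, t_assoc = [], [], [], active[0].t_assoc_s
    for c in active:
        r = c.response_RU
        if blank is not None and blank.shape == r.shape:
            r = r - blank
        responses.append(r)
        times.append(c.times_s)
        concs.append(c.concentration_M)

    n_curves = len(active)

    def unpack(p):
        q = np.clip(p, -60.0, 60.0)  # keep exp() finite during line searches
        ka, kd = np.exp(q[0]), np.exp(q[1])
        rmaxes = np.exp(q[2:]) if per_curve_rmax else [np.exp(q[2])] * n_curves
        return ka, kd, rmaxes

    def resid(p):
        ka, kd, rmaxes = unpack(p)
        out = [
            responses[i]
            - langmuir_response(times[i], concs[i], ka, kd, rmaxes[i], t_assoc)
            for i in range(n_curves)
        ]
        return np.concatenate(out)

    rmax0 = max(float(np.max(r)) for r in responses)
    rmax0 = max(rmax0, 1e-3)
    best = None
    for ka0 in _KA_STARTS:
        for kd0 in _KD_STARTS:
            p0 = [np.log(ka0), np.log(kd0)]
            p0 += [np.log(rmax0)] * (n_curves if per_curve_rmax else 1)
            try:
                sol = least_squares(resid, p0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise KineticFitError("1:1 global fit failed to converge from every start")

    ka, kd, rmaxes = unpack(best.x)
    res = best.fun
    n_pts = res.size
    dof = max(n_pts - best.x.size, 1)
    s2 = float(res @ res) / dof
    stderr: dict = {}
    flags: dict = {}
    try:
        jtj = best.jac.T @ best.jac
        cov = s2 * np.linalg.inv(jtj)
        # parameters are logs, so sqrt(var) is a relative (fractional) error
        rel = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        stderr = {"ka_rel": float(rel[0]), "kd_rel": float(rel[1])}
        flags["kd_poorly_constrained"] = bool(1.96 * rel[1] > 0.5)
        flags["ka_poorly_constrained"] = bool(1.96 * rel[0] > 0.5)
    except np.linalg.LinAlgError:
        flags["covariance_singular"] = True
    return KineticFit(
        ka=float(ka),
        kd=float(kd),
        rmax=float(np.mean(rmaxes)),
        KD=float(kd) / float(ka),
        rms_RU=float(np.sqrt(np.mean(res**2))),
        n_points=n_pts,
        flags=flags,
        stderr=stderr,
    )


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported ratios)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Ratio of two positive quantities with half-away-from-zero rounding."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(numerator / denominator, ndigits)


def write_sensorgram_csv(curves: list[Sensorgram], path) -> None:
    """Write a concentration series as a tidy CSV (time_s, response_RU,
    concentration_M, phase)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": c.times_s,
                    "response_RU": c.response_RU,
                    "concentration_M": c.concentration_M,
                    "phase": np.where(c.times_s <= c.t_assoc_s, "association", "dissociation"),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgram_csv(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    curves = []
    for conc, grp in df.groupby("concentration_M", sort=True):
        assoc = grp.loc[grp["phase"] == "association", "time_s"]
        t_assoc = float(assoc.max()) if len(assoc) else float(grp["time_s"].max())
        curves.append(
            Sensorgram(
                concentration_M=float(conc),
                times_s=grp["time_s"].to_numpy(),
                response_RU=grp["response_RU"].to_numpy(),
                t_assoc_s=t_assoc,
            )
        )
    return curves


def summarize_kinetics(fits: dict[str, KineticFit | dict]) -> pd.DataFrame:
    """Build a rate-constant summary table (ka x1e5, kd x1e-4, KD x1e-9).

    Accepts fitted :class:`KineticFit` objects or externally supplied rows
    (dicts with the same scaled columns, e.g. published values).  An
    internal-consistency column |KD - kd/ka|/KD is computed for every row
    and rows off by more than 5% are flagged.
    """
    rows = []
    for name, fit in fits.items():
        if isinstance(fit, KineticFit):
            ka5, kd4, kd_nM = fit.ka / 1e5, fit.kd / 1e-4, fit.KD / 1e-9
        else:
            ka5, kd4, kd_nM = fit["ka_1e5"], fit["kd_1e-4"], fit["KD_nM"]
        implied_nM = (kd4 * 1e-4) / (ka5 * 1e5) / 1e-9
        inconsistency = abs(kd_nM - implied_nM) / kd_nM if kd_nM > 0 else np.nan
        rows.append(
            {
                "variant": name,
                "ka_1e5": ka5,
                "kd_1e-4": kd4,
                "KD_nM": kd_nM,
                "KD_from_rates_nM": implied_nM,
                "kd_over_ka_inconsistency": inconsistency,
                "consistency_flag": bool(inconsistency > 0.05),
            }
        )
    return pd.DataFrame(rows).set_index("variant")
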