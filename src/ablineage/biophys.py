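"""Thermostability and hydrodynamic-radius analytics.

Melting temperatures are extracted nanoDSF-style: the intrinsic-fluorescence
ratio F350/F330 is smoothed, differentiated, and Tm taken as the location
of the first-derivative maximum (quadratic interpolation around the grid
peak).  Hydrodynamic radii come from Taylor dispersion: a Gaussian fit of
the taylorgram gives the residence time t_R and temporal variance sigma^2,
the diffusion coefficient follows from the Taylor-Aris relation
D = r_c^2 t_R / (24 sigma^2), and the Stokes-Einstein equation converts D
to R_h = k_B T / (6 pi eta D).  Group comparisons use an exact
Mann-Whitney U test (full enumeration of labelings, midrank tie handling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.stats import rankdata

__all__ = [
    "MeltCurve",
    "TmResult",
    "Taylorgram",
    "RhResult",
    "ExtractionError",
    "simulate_melt_curve",
    "tm_from_first_derivative",
    "simulate_taylorgram",
    "rh_from_taylorgram",
    "mann_whitney_exact",
    "group_summary",
    "WATER_VISCOSITY_PA_S",
]

KB = 1.380649e-23  # J/K
GAS_R = 8.314462618  # J/(mol K)

#: Viscosity of water (Pa s) at the two measurement temperatures.
WATER_VISCOSITY_PA_S = {25.0: 0.00089, 37.0: 0.000692}


class ExtractionError(RuntimeError):
    """A transition or peak could not be extracted from the trace."""


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------


@dataclass
class MeltCurve:
    """A thermal unfolding trace: two fluorescence channels vs temperature."""

    temperatures_C: np.ndarray
    f330: np.ndarray
    f350: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        if not (len(self.temperatures_C) == len(self.f330) == len(self.f350)):
            raise ValueError("channel lengths must match the temperature grid")
        if np.any(np.diff(self.temperatures_C) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperatures_C[0] < 20 or self.temperatures_C[-1] > 100:
            raise ValueError("temperatures outside the 20-100 degC window")

    @property
    def ratio(self) -> np.ndarray:
        return self.f350 / self.f330


@dataclass
class TmResult:
    """Per-replicate melting temperatures with summary statistics."""

    tms_C: list[float]
    mean_tm_C: float
    sd_tm_C: float


# Two-state default baselines: (intercept at 60 degC, slope per degC).
_DEFAULT_BASELINES = {
    "f330_native": (1.00, -0.0008),
    "f330_unfolded": (0.97, -0.0008),
    "f350_native": (0.60, -0.0004),
    "f350_unfolded": (0.95, -0.0004),
}


def unfolded_fraction(t_C: np.ndarray, tm_C: float, dH_kJ_mol: float) -> np.ndarray:
    """Two-state van't Hoff unfolded fraction; exactly 0.5 at Tm."""
    t_K = np.asarray(t_C, dtype=float) + 273.15
    tm_K = tm_C + 273.15
    return 1.0 / (1.0 + np.exp(dH_kJ_mol * 1e3 / GAS_R * (1.0 / t_K - 1.0 / tm_K)))


def simulate_melt_curve(
    tm_C: float,
    dH_kJ_mol: float = 400.0,
    baselines: dict | None = None,
    t_min_C: float = 25.0,
    t_max_C: float = 95.0,
    step_C: float = 0.1,
    noise_frac: float = 0.0,
    seed: int | None = None,
    replicate: int = 0,
) -> MeltCurve:
    """Simulate a two-state nanoDSF melt curve (25-95 degC ramp).

    Each fluorescence channel mixes linear native/unfolded baselines with
    the van't Hoff unfolded fraction; ``noise_frac`` is the relative SD of
    multiplicative Gaussian noise per point.
    """
    if not t_min_C < tm_C < t_max_C:
        raise ValueError("Tm must lie inside the temperature ramp")
    b = dict(_DEFAULT_BASELINES)
    if baselines:
        b.update(baselines)
    temps = np.arange(t_min_C, t_max_C + step_C / 2, step_C)
    fu = unfolded_fraction(temps, tm_C, dH_kJ_mol)

    def channel(native_key, unfolded_key):
        an, bn = b[native_key]
        au, bu = b[unfolded_key]
        native = an + bn * (temps - 60.0)
        unf = au + bu * (temps - 60.0)
        return native * (1 - fu) + unf * fu

    f330 = channel("f330_native", "f330_unfolded")
    f350 = channel("f350_native", "f350_unfolded")
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        f330 = f330 * (1 + rng.normal(0, noise_frac, temps.shape))
        f350 = f350 * (1 + rng.normal(0, noise_frac, temps.shape))
    return MeltCurve(temps, f330, f350, replicate=replicate)


def _tm_single(
    curve: MeltCurve,
    smoothing_window: int,
    polyorder: int = 2,
    peak_smooth_C: float = 7.0,
    fit_halfwidth_C: float = 1.5,
) -> float:
    temps = curve.temperatures_C
    if len(temps) < 50:
        raise ExtractionError("melt curve too short (<50 points)")
    ratio = curve.ratio
    step = float(np.median(np.diff(temps)))
    window = min(smoothing_window, len(ratio) // 2 * 2 - 1)
    # moving-polynomial derivative, then a wider temperature-scaled
    # smoothing pass so the peak location is set by the transition, not by
    # point noise
    deriv = savgol_filter(ratio, window_length=window, polyorder=polyorder,
                          deriv=1, delta=step)
    w2 = int(peak_smooth_C / step) // 2 * 2 + 1
    if 3 <= w2 < len(deriv):
        deriv = savgol_filter(deriv, window_length=w2, polyorder=polyorder)
    i = int(np.argmax(deriv))
    if i == 0 or i == len(deriv) - 1:
        raise ExtractionError("no interior first-derivative maximum")
    peak = deriv[i]
    floor = float(np.median(deriv))
    span = float(np.max(ratio) - np.min(ratio))
    if span < 1e-6 or peak - floor < 0.02 * span:
        raise ExtractionError("no unfolding transition detected")
    # quadratic interpolation around the grid maximum
    mask = (temps >= temps[i] - fit_halfwidth_C) & (temps <= temps[i] + fit_halfwidth_C)
    if int(mask.sum()) >= 5:
        a, b, _c = np.polyfit(temps[mask], deriv[mask], 2)
        if a < 0:
            tm = -b / (2 * a)
            if temps[i] - fit_halfwidth_C <= tm <= temps[i] + fit_halfwidth_C:
                return float(tm)
    y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
    return float(temps[i] + shift * step)


def tm_from_first_derivative(
    curves: MeltCurve | Sequence[MeltCurve], smoothing_window: int = 11
) -> TmResult:
    """Extract Tm(s) as the maximum of d(F350/F330)/dT.

    Accepts a single curve or a replicate set; the summary SD uses the
    sample (n-1) convention and is 0.0 for a single curve.
    """
    if isinstance(curves, MeltCurve):
        curves = [curves]
    tms = [_tm_single(c, smoothing_window) for c in curves]
    mean = float(np.mean(tms))
    sd = float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0
    return TmResult(tms_C=tms, mean_tm_C=mean, sd_tm_C=sd)


# ---------------------------------------------------------------------------
# Taylor dispersion
# ---------------------------------------------------------------------------


@dataclass
class Taylorgram:
    """A Taylor-dispersion elution trace plus its run conditions."""

    times_s: np.ndarray
    signal: np.ndarray
    capillary_radius_m: float = 37.5e-6
    temperature_C: float = 25.0
    viscosity_Pa_s: float = 0.00089
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times_s.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if self.capillary_radius_m <= 0 or self.viscosity_Pa_s <= 0:
            raise ValueError("capillary radius and viscosity must be positive")


@dataclass
class RhResult:
    """Hydrodynamic radius estimate from one taylorgram."""

    rh_nm: float
    n_species: int
    dispersity_flag: bool
    residence_time_s: float
    sigma_s: float
    diffusion_m2_s: float
    species: list = field(default_factory=list)  # (rh_nm, amplitude) per species


def _rh_to_sigma2(rh_nm: float, tg_T_C: float, eta: float, rc: float, t_r: float) -> float:
    d = KB * (tg_T_C + 273.15) / (6 * math.pi * eta * rh_nm * 1e-9)
    return rc**2 * t_r / (24 * d)


def simulate_taylorgram(
    rh_nm: float | Sequence[tuple[float, float]],
    temperature_C: float = 25.0,
    viscosity_Pa_s: float | None = None,
    capillary_radius_m: float = 37.5e-6,
    residence_time_s: float = 240.0,
    amplitude: float = 1.0,
    baseline: float = 0.05,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt_s: float = 0.25,
    replicate: int = 0,
) -> Taylorgram:
    """Simulate a Gaussian taylorgram for one species or a mixture.

    ``rh_nm`` may be a single radius or a list of ``(radius_nm, fraction)``
    pairs sharing the same residence time.
    """
    if viscosity_Pa_s is None:
        viscosity_Pa_s = WATER_VISCOSITY_PA_S.get(temperature_C, 0.00089)
    species = rh_nm if not isinstance(rh_nm, (int, float)) else [(float(rh_nm), 1.0)]
    times = np.arange(0.0, 2 * residence_time_s + dt_s / 2, dt_s)
    signal = np.full_like(times, baseline)
    for rh, frac in species:
        s2 = _rh_to_sigma2(rh, temperature_C, viscosity_Pa_s, capillary_radius_m, residence_time_s)
        signal = signal + amplitude * frac * np.exp(
            -((times - residence_time_s) ** 2) / (2 * s2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0, noise_sd, times.shape)
    return Taylorgram(
        times_s=times,
        signal=signal,
        capillary_radius_m=capillary_radius_m,
        temperature_C=temperature_C,
        viscosity_Pa_s=viscosity_Pa_s,
        replicate=replicate,
    )


def _sigma_to_rh(sigma: float, tg: Taylorgram, t_r: float) -> tuple[float, float]:
    d = tg.capillary_radius_m**2 * t_r / (24 * sigma**2)
    rh = KB * (tg.temperature_C + 273.15) / (6 * math.pi * tg.viscosity_Pa_s * d)
    return rh * 1e9, d


def rh_from_taylorgram(
    tg: Taylorgram, dual_ratio: float = 1.5, min_structure: float = 5e-4
) -> RhResult:
    """Estimate R_h from a taylorgram via Taylor dispersion + Stokes-Einstein.

    A single Gaussian (plus constant baseline) is fitted first.  The fit
    residual is compared against the high-frequency noise level estimated
    from its first differences: a residual RMS exceeding ``dual_ratio``
    times the noise estimate (and ``min_structure`` of the peak amplitude)
    indicates structured misfit, so a dual-species model (two Gaussians
    sharing the residence time) is fitted and the dispersity flag raised.
    The reported radius is that of the dominant-amplitude species.
    """
    t, y = tg.times_s, tg.signal
    c0 = float(np.median(np.concatenate([y[: len(y) // 20], y[-len(y) // 20 :]])))
    a0 = float(np.max(y) - c0)
    if a0 <= 0:
        raise ExtractionError("no peak above baseline")
    tr0 = float(t[np.argmax(y)])
    weights = np.clip(y - c0, 0, None)
    s0 = math.sqrt(float(np.sum(weights * (t - tr0) ** 2) / max(np.sum(weights), 1e-12)))
    s0 = max(s0, (t[1] - t[0]) * 2)

    def single(p):
        a, tr, s, c = p
        return a * np.exp(-((t - tr) ** 2) / (2 * s**2)) + c - y

    sol = least_squares(single, [a0, tr0, s0, c0], max_nfev=4000)
    if not sol.success and sol.status <= 0:
        raise ExtractionError("single-species peak fit did not converge")
    a, tr, s, c = sol.x
    s = abs(float(s))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    noise_est = float(np.std(np.diff(sol.fun)) / np.sqrt(2.0))
    structured = rms > max(dual_ratio * noise_est, min_structure * abs(a))
    rh, d = _sigma_to_rh(s, tg, float(tr))
    if not structured:
        return RhResult(
            rh_nm=rh,
            n_species=1,
            dispersity_flag=False,
            residence_time_s=float(tr),
            sigma_s=s,
            diffusion_m2_s=d,
            species=[(rh, float(a))],
        )

    def dual(p):
        a1, a2, tr_, s1, s2, c_ = p
        g1 = a1 * np.exp(-((t - tr_) ** 2) / (2 * s1**2))
        g2 = a2 * np.exp(-((t - tr_) ** 2) / (2 * s2**2))
        return g1 + g2 + c_ - y

    sol2 = least_squares(
        dual, [a * 0.7, a * 0.3, tr, s * 0.8, s * 1.6, c], max_nfev=8000
    )
    if not sol2.success and sol2.status <= 0:
        raise ExtractionError("dual-species peak fit did not converge")
    a1, a2, tr2, s1, s2, _c2 = sol2.x
    pairs = sorted(
        [(abs(float(a1)), abs(float(s1))), (abs(float(a2)), abs(float(s2)))],
        reverse=True,
    )
    species = []
    for amp, sig in pairs:
        rh_i, _ = _sigma_to_rh(sig, tg, float(tr2))
        species.append((rh_i, amp))
    rh_main, d_main = _sigma_to_rh(pairs[0][1], tg, float(tr2))
    return RhResult(
        rh_nm=rh_main,
        n_species=2,
        dispersity_flag=True,
        residence_time_s=float(tr2),
        sigma_s=pairs[0][1],
        diffusion_m2_s=d_main,
        species=species,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_melt_csv(curves: Sequence[MeltCurve], path) -> None:
    import pandas as pd

    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "temperature_C": c.temperatures_C,
                    "f330": c.f330,
                    "f350": c.f350,
                    "replicate": c.replicate,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_melt_csv(path) -> list[MeltCurve]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        MeltCurve(
            grp["temperature_C"].to_numpy(),
            grp["f330"].to_numpy(),
            grp["f350"].to_numpy(),
            replicate=int(rep),
        )
        for rep, grp in df.groupby("replicate", sort=True)
    ]


def write_taylorgram_csv(tg: Taylorgram, path) -> None:
    """Taylorgram CSV with a commented run-condition header block."""
    import pandas as pd

    with open(path, "w") as fh:
        fh.write(f"# capillary_radius_m={tg.capillary_radius_m!r}\n")
        fh.write(f"# temperature_C={tg.temperature_C!r}\n")
        fh.write(f"# viscosity_Pa_s={tg.viscosity_Pa_s!r}\n")
        fh.write(f"# replicate={tg.replicate}\n")
        pd.DataFrame({"time_s": tg.times_s, "signal": tg.signal}).to_csv(fh, index=False)


def read_taylorgram_csv(path) -> Taylorgram:
    import pandas as pd

    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].strip().split("=", 1)
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return Taylorgram(
        times_s=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        capillary_radius_m=meta.get("capillary_radius_m", 37.5e-6),
        temperature_C=meta.get("temperature_C", 25.0),
        viscosity_Pa_s=meta.get("viscosity_Pa_s", 0.00089),
        replicate=int(meta.get("replicate", 0)),
    )


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U and group summaries
# ---------------------------------------------------------------------------


def mann_whitney_exact(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test for small samples.

    U counts pairs where an observation of ``group_a`` exceeds one of
    ``group_b``, with half credit for ties.  The two-sided p-value is
    computed from the exact permutation distribution over all
    C(n_a + n_b, n_a) group labelings as
    p = min(1, 2 min(P(U <= u), P(U >= u))).
    """
    a = list(map(float, group_a))
    b = list(map(float, group_b))
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if len(a) > 12 or len(b) > 12:
        raise ValueError("exact enumeration supports group sizes up to 12")
    na, nb = len(a), len(b)
    pooled = np.array(a + b)
    # doubled midranks are integers, so the whole computation is exact
    ranks2 = np.rint(2 * rankdata(pooled)).astype(int)
    r2_obs = int(ranks2[:na].sum())

    # distribution of the doubled rank-sum of a size-na subset (0/1 counting
    # DP; equivalent to enumerating all C(na+nb, na) labelings exactly)
    max_sum = int(ranks2.sum())
    ways = [[0] * (max_sum + 1) for _ in range(na + 1)]
    ways[0][0] = 1
    for r2 in ranks2:
        for k in range(na, 0, -1):
            row_prev, row = ways[k - 1], ways[k]
            for s in range(max_sum - int(r2), -1, -1):
                if row_prev[s]:
                    row[s + int(r2)] += row_prev[s]
    dist = ways[na]
    total = sum(dist)
    le = sum(dist[: r2_obs + 1])
    ge = sum(dist[r2_obs:])
    u = (r2_obs - na * (na + 1)) / 2.0  # U_a from the rank-sum, ties included
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u, p


def group_summary(
    values: dict[str, float], predicate: Callable[[str], bool], ndigits: int = 2
) -> dict[bool, tuple[float, float]]:
    """Arithmetic mean and sample SD (n-1) per predicate group, rounded.

    Raises for singleton groups, where the sample SD is undefined.
    """
    groups: dict[bool, list[float]] = {True: [], False: []}
    for name, v in values.items():
        groups[bool(predicate(name))].append(float(v))
    out = {}
    for key, vals in groups.items():
        if not vals:
            continue
        if len(vals) < 2:
            raise ValueError(f"group {key} has a single member; SD undefined")
        out[key] = (
            round(float(np.mean(vals)), ndigits),
            round(float(np.std(vals, ddof=1)), ndigits),
        )
    return out
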