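"""Backbone ¹⁵N relaxation analysis: R1/R2 exponential fits, hetNOE,
flexibility flags, and rotational correlation time.

Longitudinal (R1) and transverse (R2) rates are obtained per residue by
fitting peak-height decays ``I(t) = I0 * exp(-R t)`` from pseudo-3D
experiments.  The heteronuclear NOE is the ratio of peak heights with and
without proton presaturation.  Residues whose R1 or R2 fall more than two
standard deviations from the profile mean, or whose hetNOE is below 0.6,
are flagged as flexible.  The overall tumbling time is estimated from the
R2/R1 ratio:

    tau_c = 1 / (4 pi nu_N) * sqrt(6 R2/R1 - 7)

with nu_N the ¹⁵N resonance frequency in Hz.  The estimate is only defined
where the radicand is positive (R2/R1 > 7/6).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "R1_DELAYS_S",
    "R2_DELAYS_S",
    "NU_N_600MHZ",
    "DecaySeries",
    "RateFit",
    "RelaxationProfile",
    "TumblingEstimate",
    "fit_exponential",
    "compute_hetnoe",
    "summarize_profile",
    "estimate_tau_c",
    "profile_tau_c",
]

#: Relaxation-delay presets (seconds) for the R1 and R2 pseudo-3D schedules.
R1_DELAYS_S = (0.020, 0.060, 0.100, 0.200, 0.400, 0.600, 0.800, 1.000, 1.200, 1.600)
R2_DELAYS_S = (0.01696, 0.03392, 0.06784, 0.10176, 0.13568,
               0.20352, 0.27136, 0.33920, 0.40704, 0.54772)

#: ¹⁵N resonance frequency on a 600 MHz (¹H) spectrometer, in Hz.
NU_N_600MHZ = 60.81e6

_RATE_CLIP = (1e-3, 1e3)  # Hz; sane range for initial-guess clipping
_MC_SEED = 1234
_MC_RESAMPLES = 200


@dataclass
class DecaySeries:
    """Peak heights of one residue versus relaxation delay."""

    residue_id: int
    delays: np.ndarray  # seconds, strictly increasing
    heights: np.ndarray  # arbitrary units
    residue_code: str = "X"
    height_errors: np.ndarray | None = None
    overlapped: bool = False

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, float)
        self.heights = np.asarray(self.heights, float)
        if self.delays.size < 3:
            raise ValueError("a decay series needs at least 3 delay points")
        if not np.all(np.diff(self.delays) > 0):
            raise ValueError("delays must be strictly increasing")
        if self.delays.shape != self.heights.shape:
            raise ValueError("delays and heights must have the same length")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.height_errors is not None:
            self.height_errors = np.asarray(self.height_errors, float)
            if self.height_errors.shape != self.heights.shape:
                raise ValueError("height_errors length mismatch")


@dataclass
class RateFit:
    """Single-exponential decay-rate fit for one residue."""

    rate: float  # Hz
    amplitude: float  # I0, same units as heights
    rate_error: float  # Hz, Monte-Carlo estimate
    converged: bool
    residue_id: int = -1

    def __post_init__(self) -> None:
        if self.converged and not self.rate > 0:
            raise ValueError("converged fits must have a positive rate")
        if self.rate_error < 0:
            raise ValueError("rate_error must be >= 0")


@dataclass
class TumblingEstimate:
    """Rotational correlation time from the R2/R1 ratio."""

    tau_c: float | None  # seconds; None when the radicand is non-positive
    nu_n: float  # Hz
    method: str  # 'from_mean_rates' | 'per_residue_mean' | 'single'
    defined: bool = True
    n_residues: int | None = None
    n_excluded: int = 0

    @property
    def tau_c_ns(self) -> float | None:
        return None if self.tau_c is None else self.tau_c * 1e9


@dataclass
class RelaxationProfile:
    """Per-residue relaxation summary with ensemble statistics and flags.

    ``table`` columns: residue_id, r1, r1_err, r2, r2_err, r2_over_r1,
    hetnoe, hetnoe_err, overlapped, usable, low_r1, low_r2, low_hetnoe.
    Means and SDs are computed over usable residues only (non-overlapped,
    converged fits).
    """

    table: pd.DataFrame
    stats: dict = field(default_factory=dict)
    hetnoe_threshold: float = 0.6
    sd_multiple: float = 2.0

    @property
    def flagged_residues(self) -> set[int]:
        t = self.table
        mask = t["low_r1"] | t["low_r2"] | t["low_hetnoe"]
        return set(t.loc[mask, "residue_id"].astype(int))


def _exp_model(t, i0, r):
    return i0 * np.exp(-r * t)


def fit_exponential(series: DecaySeries,
                    n_resamples: int = _MC_RESAMPLES,
                    mc_seed: int = _MC_SEED) -> RateFit:
    """Nonlinear least-squares fit of ``I(t) = I0 exp(-R t)``.

    Initial guesses: I0 = max height; R from the log-ratio of the first and
    last points, clipped to (1e-3, 1e3) Hz.  The rate error is the standard
    deviation of rates refit on ``n_resamples`` synthetic series with
    Gaussian noise scaled to the fit residuals (or supplied height errors),
    using a fixed seed so profiles are reproducible.  Optimizer failure
    yields ``converged=False`` rather than an exception.
    """
    t, y = series.delays, series.heights
    if np.allclose(y, y[0]):
        warnings.warn(f"residue {series.residue_id}: all heights equal; "
                      "rate pinned at the lower clip", stacklevel=2)
        return RateFit(rate=_RATE_CLIP[0], amplitude=float(y[0]), rate_error=0.0,
                       converged=True, residue_id=series.residue_id)

    i0_guess = float(np.max(y))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = y[0] / y[-1]
        r_guess = math.log(ratio) / (t[-1] - t[0]) if ratio > 0 else 1.0
    r_guess = float(np.clip(r_guess, *_RATE_CLIP))

    sigma = None
    if series.height_errors is not None and np.all(series.height_errors > 0):
        sigma = series.height_errors

    def _fit(yy):
        popt, _ = curve_fit(_exp_model, t, yy, p0=(i0_guess, r_guess),
                            sigma=sigma, maxfev=5000)
        return popt

    try:
        i0, r = _fit(y)
    except (RuntimeError, ValueError):
        return RateFit(rate=0.0, amplitude=0.0, rate_error=0.0,
                       converged=False, residue_id=series.residue_id)
    if not (np.isfinite(r) and r > 0 and np.isfinite(i0)):
        return RateFit(rate=0.0, amplitude=0.0, rate_error=0.0,
                       converged=False, residue_id=series.residue_id)

    # Monte-Carlo rate error from residual-scaled resampling
    rate_error = 0.0
    if n_resamples > 0:
        resid = y - _exp_model(t, i0, r)
        noise_sd = (np.sqrt(np.mean(series.height_errors ** 2))
                    if sigma is not None else float(np.sqrt(np.mean(resid ** 2))))
        if noise_sd > 0:
            rng = np.random.default_rng(np.random.SeedSequence(
                [_canon_seed(mc_seed), abs(series.residue_id)]))
            best = _exp_model(t, i0, r)
            rates = []
            for _ in range(n_resamples):
                try:
                    _, r_k = _fit(best + rng.normal(0.0, noise_sd, size=t.shape))
                except (RuntimeError, ValueError):
                    continue
                if np.isfinite(r_k):
                    rates.append(r_k)
            if len(rates) > 1:
                rate_error = float(np.std(rates, ddof=1))

    return RateFit(rate=float(r), amplitude=float(i0), rate_error=rate_error,
                   converged=True, residue_id=series.residue_id)


def _canon_seed(seed: int) -> int:
    return int(seed) % (2 ** 31)


def compute_hetnoe(sat_heights: Mapping[int, float] | pd.Series,
                   unsat_heights: Mapping[int, float] | pd.Series,
                   sat_errors: Mapping[int, float] | pd.Series | None = None,
                   unsat_errors: Mapping[int, float] | pd.Series | None = None
                   ) -> pd.DataFrame:
    """hetNOE = I_sat / I_unsat per residue, with quadrature error propagation.

    Inputs are keyed by residue id and must cover the same residue set.
    Residues with a zero unsaturated height are marked invalid (``valid``
    column) and should be excluded from profile averages.
    """
    sat = pd.Series(sat_heights, dtype=float)
    unsat = pd.Series(unsat_heights, dtype=float)
    if set(sat.index) != set(unsat.index):
        raise ValueError("saturated and unsaturated tables cover different residues")
    unsat = unsat.reindex(sat.index)
    valid = unsat != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        noe = sat / unsat
    noe[~valid] = np.nan

    err = pd.Series(np.nan, index=sat.index)
    if sat_errors is not None and unsat_errors is not None:
        es = pd.Series(sat_errors, dtype=float).reindex(sat.index)
        eu = pd.Series(unsat_errors, dtype=float).reindex(sat.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            err = np.abs(noe) * np.sqrt((es / sat) ** 2 + (eu / unsat) ** 2)
        err[~valid] = np.nan

    return pd.DataFrame({
        "residue_id": sat.index.astype(int),
        "hetnoe": noe.values,
        "hetnoe_err": err.values,
        "valid": valid.values,
    }).reset_index(drop=True)


def summarize_profile(r1_fits: Sequence[RateFit],
                      r2_fits: Sequence[RateFit],
                      hetnoe: pd.DataFrame,
                      overlapped: set[int] | None = None,
                      hetnoe_threshold: float = 0.6,
                      sd_multiple: float = 2.0,
                      min_usable: int = 5) -> RelaxationProfile:
    """Assemble the per-residue relaxation profile with flexibility flags.

    Means and SDs are computed over usable residues — converged fits that
    are not overlapped.  ``low_r1`` / ``low_r2`` flag residues more than
    ``sd_multiple`` standard deviations *below* the profile mean (deviations
    are detected two-sided; only the low direction is flagged as flexible);
    ``low_hetnoe`` flags hetNOE below ``hetnoe_threshold``.
    """
    overlapped = overlapped or set()

    def fits_frame(fits, name):
        return pd.DataFrame({
            "residue_id": [f.residue_id for f in fits],
            name: [f.rate if f.converged else np.nan for f in fits],
            f"{name}_err": [f.rate_error if f.converged else np.nan for f in fits],
            f"{name}_converged": [f.converged for f in fits],
        })

    df = fits_frame(r1_fits, "r1").merge(fits_frame(r2_fits, "r2"),
                                         on="residue_id", how="outer")
    noe = hetnoe.rename(columns={"valid": "hetnoe_valid"})
    df = df.merge(noe, on="residue_id", how="outer").sort_values("residue_id")
    df["overlapped"] = df["residue_id"].isin(overlapped)
    for col, default in (("r1_converged", False), ("r2_converged", False),
                         ("hetnoe_valid", False)):
        df[col] = df[col].fillna(default).astype(bool)

    df["usable"] = (~df["overlapped"]) & df["r1_converged"] & df["r2_converged"]
    both = df["r1_converged"] & df["r2_converged"]
    df["r2_over_r1"] = np.where(both, df["r2"] / df["r1"], np.nan)

    usable = df[df["usable"]]
    if len(usable) < min_usable:
        raise ValueError(f"only {len(usable)} usable residues; "
                         f"need at least {min_usable} for profile statistics")

    stats = {}
    for col in ("r1", "r2", "r2_over_r1", "hetnoe"):
        vals = usable[col].dropna()
        stats[f"{col}_mean"] = float(vals.mean())
        stats[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    for col in ("r1", "r2"):
        mean, sd = stats[f"{col}_mean"], stats[f"{col}_sd"]
        dev = df[col] - mean
        outlier = df["usable"] & (np.abs(dev) > sd_multiple * sd) & (sd > 0)
        df[f"low_{col}"] = outlier & (dev < 0)
        df[f"high_{col}"] = outlier & (dev > 0)
    df["low_hetnoe"] = (df["usable"] & df["hetnoe_valid"]
                        & (df["hetnoe"] < hetnoe_threshold))

    stats["n_usable"] = int(df["usable"].sum())
    stats["n_overlapped"] = int(df["overlapped"].sum())
    return RelaxationProfile(table=df.reset_index(drop=True), stats=stats,
                             hetnoe_threshold=hetnoe_threshold,
                             sd_multiple=sd_multiple)


def estimate_tau_c(r1: float, r2: float, nu_n: float = NU_N_600MHZ,
                   method: str = "single") -> TumblingEstimate:
    """tau_c = sqrt(6 R2/R1 - 7) / (4 pi nu_N), in seconds.

    Undefined (``defined=False``, ``tau_c=None``) when 6 R2/R1 - 7 <= 0;
    never silently NaN.
    """
    if not (r1 > 0 and r2 > 0):
        raise ValueError("R1 and R2 must be positive")
    if not nu_n > 0:
        raise ValueError("nu_N must be positive")
    radicand = 6.0 * r2 / r1 - 7.0
    if radicand < 0:
        return TumblingEstimate(tau_c=None, nu_n=nu_n, method=method, defined=False)
    tau = math.sqrt(radicand) / (4.0 * math.pi * nu_n)
    return TumblingEstimate(tau_c=tau, nu_n=nu_n, method=method, defined=True)


def profile_tau_c(profile: RelaxationProfile, nu_n: float = NU_N_600MHZ,
                  trim: float = 0.0) -> tuple[TumblingEstimate, TumblingEstimate]:
    """Tumbling time by both conventions: per-residue mean and mean-rate.

    ``per_residue_mean`` averages tau_c over usable, unflagged residues with
    a positive radicand, after symmetric trimming of a ``trim`` fraction
    from each tail.  ``from_mean_rates`` evaluates the tau_c expression on
    the profile-mean R1 and R2.  Residues with R2/R1 <= 7/6 are excluded
    and counted in ``n_excluded``.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    t = profile.table
    ok = t["usable"] & ~(t["low_r1"] | t["low_r2"] | t["low_hetnoe"])
    rows = t[ok]
    taus = []
    n_excluded = 0
    for _, row in rows.iterrows():
        est = estimate_tau_c(row["r1"], row["r2"], nu_n)
        if est.defined and est.tau_c is not None and est.tau_c > 0:
            taus.append(est.tau_c)
        else:
            n_excluded += 1
    if not taus:
        raise ValueError("no residue has R2/R1 above 7/6; tau_c is undefined")
    taus = np.sort(np.array(taus))
    k = int(trim * len(taus))
    trimmed = taus[k:len(taus) - k] if k > 0 else taus
    per_res = TumblingEstimate(tau_c=float(trimmed.mean()), nu_n=nu_n,
                               method="per_residue_mean", defined=True,
                               n_residues=len(trimmed), n_excluded=n_excluded)
    mean_est = estimate_tau_c(profile.stats["r1_mean"], profile.stats["r2_mean"],
                              nu_n, method="from_mean_rates")
    mean_est.n_residues = profile.stats["n_usable"]
    return per_res, mean_est
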