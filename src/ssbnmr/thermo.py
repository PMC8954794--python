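"""Thermodynamic model fitting: two-state DSC, independent-site ITC, and
CD molar-ellipticity / thermal-melt analysis.

DSC.  The excess heat capacity of a two-state (folded <-> unfolded)
transition with van 't Hoff enthalpy dH (kcal/mol) and midpoint T_m (K) is

    Cp_xs(T) = A * dH^2 / (R T^2) * K / (1 + K)^2,
    K(T)     = exp(-(dH / R) (1/T - 1/T_m)),

with R = 1.98720425e-3 kcal mol^-1 K^-1 and a dimensionless scale factor A
that absorbs the calorimetric/van 't Hoff discrepancy.  A polynomial
baseline is fitted jointly.

ITC.  Injection heats follow the single-class independent-site (Wiseman)
model: after injection k with cumulative injected volume dV_k the cell
concentrations follow the exponential-dilution convention
M_k = M0 exp(-dV_k/V0), X_k = X_syr (1 - exp(-dV_k/V0)); the complex
concentration is the closed-form mass-action root

    [PX]_k = 0.5 [ (n M_k + X_k + K_d) - sqrt((n M_k + X_k + K_d)^2
                                               - 4 n M_k X_k) ],

the cumulative heat is Q_k = dH * V0 * [PX]_k, and the measured heat of
injection k corrects for displaced volume:
q_k = Q_k - Q_{k-1} + (v_k / V0)(Q_k + Q_{k-1}) / 2 + offset.

CD.  Molar ellipticity [theta] = theta_mdeg / (10 * c * l) in
deg cm^2 dmol^-1 (c in mol/L, l in cm); melts are summarized by endpoint
change, a two-state sigmoid midpoint, and a reversibility score from the
cooling trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_GAS_KCAL",
    "Thermogram",
    "MeltFit",
    "ITCIsotherm",
    "BindingFit",
    "CDSpectrum",
    "CDMelt",
    "dsc_excess_cp",
    "fit_dsc_two_state",
    "itc_heats",
    "fit_itc_independent",
    "cd_molar_ellipticity",
    "melt_analysis",
]

#: Gas constant in kcal mol^-1 K^-1, used by every thermodynamic model here.
R_GAS_KCAL = 1.98720425e-3


class ConvergenceError(RuntimeError):
    """A thermodynamic fit failed to converge on the supplied data."""


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------

@dataclass
class Thermogram:
    """DSC scan: heat capacity versus temperature."""

    T: np.ndarray  # K, strictly increasing
    cp: np.ndarray  # kcal mol^-1 K^-1
    scan_rate_K_min: float = 1.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, float)
        self.cp = np.asarray(self.cp, float)
        if self.T.shape != self.cp.shape:
            raise ValueError("T and cp must have the same length")
        if not np.all(np.diff(self.T) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.T.size < 20 or (self.T[-1] - self.T[0]) <= 20.0:
            raise ValueError("thermogram must have >= 20 points spanning > 20 K")


@dataclass
class MeltFit:
    """Two-state DSC fit result."""

    tm_K: float
    dh_kcal_mol: float  # van 't Hoff enthalpy
    scale: float
    baseline_coefs: np.ndarray  # polynomial in (T - T_mid), ascending order
    rms: float  # kcal mol^-1 K^-1
    t_mid_K: float = 0.0  # centering used for the baseline polynomial

    def __post_init__(self) -> None:
        if not self.dh_kcal_mol > 0:
            raise ValueError("van 't Hoff enthalpy must be positive")

    @property
    def tm_C(self) -> float:
        return self.tm_K - 273.15

    def baseline(self, T: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(T, float) - self.t_mid_K,
                                                self.baseline_coefs)


def dsc_excess_cp(T, tm_K: float, dh_kcal_mol: float, scale: float = 1.0) -> np.ndarray:
    """Two-state excess heat capacity (kcal mol^-1 K^-1) on a Kelvin grid."""
    T = np.asarray(T, float)
    K = np.exp(-(dh_kcal_mol / R_GAS_KCAL) * (1.0 / T - 1.0 / tm_K))
    return scale * dh_kcal_mol ** 2 / (R_GAS_KCAL * T ** 2) * K / (1.0 + K) ** 2


def fit_dsc_two_state(thermogram: Thermogram, baseline_degree: int = 2) -> MeltFit:
    """Fit baseline polynomial + two-state excess heat capacity.

    The midpoint is initialized at the grid maximum of the edge-detrended
    signal; the scale from the detrended peak height.  A monotone signal
    (no interior peak) raises :class:`ConvergenceError`.
    """
    if not 0 <= baseline_degree <= 3:
        raise ValueError("baseline_degree must be in 0..3")
    T, cp = thermogram.T, thermogram.cp
    t_mid = float(T.mean())
    x = T - t_mid

    # rough baseline through the outer 15% of points on each side
    k = max(3, len(T) * 15 // 100)
    edge = np.r_[np.arange(k), np.arange(len(T) - k, len(T))]
    edge_coefs = np.polynomial.polynomial.polyfit(x[edge], cp[edge],
                                                  min(baseline_degree, 1))
    detrended = cp - np.polynomial.polynomial.polyval(x, edge_coefs)
    ipk = int(np.argmax(detrended))
    edge_rms = float(np.sqrt(np.mean(detrended[edge] ** 2)))
    if (ipk <= 0 or ipk >= len(T) - 1
            or detrended[ipk] <= max(1e-9, 5.0 * edge_rms)):
        raise ConvergenceError("no interior endotherm peak found; "
                               "cannot fit a two-state transition")
    tm0 = float(T[ipk])
    dh0 = 100.0  # kcal/mol, generic protein-unfolding magnitude
    peak = float(detrended[ipk])
    scale0 = max(peak * 4.0 * R_GAS_KCAL * tm0 ** 2 / dh0 ** 2, 1e-6)
    base0 = np.zeros(baseline_degree + 1)
    base0[: len(edge_coefs)] = edge_coefs

    def unpack(p):
        return p[0], p[1], p[2], p[3:]

    def resid(p):
        tm, dh, scale, coefs = unpack(p)
        model = (np.polynomial.polynomial.polyval(x, coefs)
                 + dsc_excess_cp(T, tm, dh, scale))
        return model - cp

    p0 = np.r_[tm0, dh0, scale0, base0]
    lower = np.r_[T[0], 1.0, 1e-9, -np.inf * np.ones(baseline_degree + 1)]
    upper = np.r_[T[-1], 5000.0, 1e6, np.inf * np.ones(baseline_degree + 1)]
    sol = least_squares(resid, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise ConvergenceError(f"DSC fit did not converge: {sol.message}")
    tm, dh, scale, coefs = unpack(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return MeltFit(tm_K=float(tm), dh_kcal_mol=float(dh), scale=float(scale),
                   baseline_coefs=np.asarray(coefs), rms=rms, t_mid_K=t_mid)


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass
class ITCIsotherm:
    """Injection-heat series from a titration of ligand into a cell."""

    v0_ml: float  # active cell volume
    cell_conc_M: float  # macromolecule concentration at the start
    syringe_conc_M: float  # titrant (ligand) concentration
    inj_vol_ul: np.ndarray  # per-injection volumes, microliters
    heats_ucal: np.ndarray  # measured heats, microcalories
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        self.inj_vol_ul = np.asarray(self.inj_vol_ul, float)
        self.heats_ucal = np.asarray(self.heats_ucal, float)
        if self.v0_ml <= 0 or self.cell_conc_M <= 0 or self.syringe_conc_M <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if np.any(self.inj_vol_ul <= 0):
            raise ValueError("injection volumes must be positive")
        if self.inj_vol_ul.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats must have equal length")
        if not np.all(np.isfinite(self.heats_ucal)):
            raise ValueError("heats must be finite")

    def molar_ratio(self) -> np.ndarray:
        """Cumulative ligand : macromolecule molar ratio after each injection."""
        x, m = _cell_concentrations(self)
        return x / m


@dataclass
class BindingFit:
    """Independent-site ITC fit result."""

    kd_M: float
    n: float
    dh_kcal_mol: float
    offset_ucal: float  # constant dilution heat per injection
    rms_ucal: float

    def __post_init__(self) -> None:
        if not self.kd_M > 0:
            raise ValueError("K_d must be positive")
        if not self.n > 0:
            raise ValueError("stoichiometry must be positive")

    @property
    def kd_uM(self) -> float:
        return self.kd_M * 1e6

    @property
    def ka_per_M(self) -> float:
        return 1.0 / self.kd_M


def _cell_concentrations(iso: ITCIsotherm) -> tuple[np.ndarray, np.ndarray]:
    """Total ligand X_k and macromolecule M_k in the cell after each injection.

    Exponential-dilution convention for a perfusion (overflow) cell: each
    injected volume displaces an equal volume of the current cell content.
    """
    v0_l = iso.v0_ml * 1e-3
    cum_l = np.cumsum(iso.inj_vol_ul) * 1e-6
    dil = np.exp(-cum_l / v0_l)
    m = iso.cell_conc_M * dil
    x = iso.syringe_conc_M * (1.0 - dil)
    return x, m


def complex_concentration(x: np.ndarray, m: np.ndarray,
                          kd: float, n: float) -> np.ndarray:
    """Closed-form mass-action complex concentration for independent sites.

    Smaller root of the binding quadratic; always satisfies
    0 <= [PX] <= min(n*M, X).
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    b = n * m + x + kd
    disc = b ** 2 - 4.0 * n * m * x
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def itc_heats(iso: ITCIsotherm, kd: float, n: float, dh_kcal_mol: float,
              offset_ucal: float = 0.0) -> np.ndarray:
    """Forward model: predicted heat (ucal) of each injection."""
    x, m = _cell_concentrations(iso)
    v0_l = iso.v0_ml * 1e-3
    px = complex_concentration(x, m, kd, n)
    q = dh_kcal_mol * v0_l * px * 1e9  # kcal -> ucal
    q_prev = np.r_[0.0, q[:-1]]
    v_l = iso.inj_vol_ul * 1e-6
    return q - q_prev + (v_l / v0_l) * (q + q_prev) / 2.0 + offset_ucal


def fit_itc_independent(iso: ITCIsotherm, discard_first: bool = False,
                        fit_offset: bool = True) -> BindingFit:
    """Nonlinear least-squares fit of the independent-site model.

    Free parameters: K_d (fitted in log space), stoichiometry n, molar
    enthalpy dH and, optionally, a constant per-injection dilution offset.
    ``discard_first`` drops the first injection (syringe-tip dilution
    artifact) from the residuals while keeping its volume bookkeeping.
    """
    if iso.inj_vol_ul.size < 6:
        raise ValueError("need at least 6 injections for a stable fit")
    if iso.syringe_conc_M <= iso.cell_conc_M:
        warnings.warn("syringe concentration does not exceed cell concentration; "
                      "the isotherm may never saturate", stacklevel=2)

    weight = np.ones_like(iso.heats_ucal)
    if discard_first:
        weight[0] = 0.0

    total_q = float(np.sum(iso.heats_ucal))
    v0_l = iso.v0_ml * 1e-3
    dh0 = total_q / (v0_l * iso.cell_conc_M * 1e9)  # assumes full saturation, n=1
    if abs(dh0) < 0.1:
        dh0 = -1.0 if total_q <= 0 else 1.0

    def resid(p):
        log_kd, n, dh, off = p
        model = itc_heats(iso, 10.0 ** log_kd, n, dh, off if fit_offset else 0.0)
        return (model - iso.heats_ucal) * weight

    p0 = np.array([np.log10(iso.cell_conc_M / 10.0), 1.0, dh0, 0.0])
    lower = np.array([-12.0, 1e-3, -1e4, -np.inf])
    upper = np.array([0.0, 1e3, 1e4, np.inf])
    sol = least_squares(resid, p0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15,
                        gtol=1e-15)
    if not sol.success:
        raise ConvergenceError(f"ITC fit did not converge: {sol.message}")
    log_kd, n, dh, off = sol.x
    used = weight > 0
    rms = float(np.sqrt(np.mean(sol.fun[used] ** 2)))
    return BindingFit(kd_M=float(10.0 ** log_kd), n=float(n),
                      dh_kcal_mol=float(dh),
                      offset_ucal=float(off) if fit_offset else 0.0,
                      rms_ucal=rms)


# ---------------------------------------------------------------------------
# CD
# ---------------------------------------------------------------------------

@dataclass
class CDSpectrum:
    """Far-UV CD spectrum in observed millidegrees."""

    wavelength_nm: np.ndarray
    theta_mdeg: np.ndarray
    path_cm: float
    conc_M: float
    temperature_C: float | None = None
    molar_ellipticity: np.ndarray | None = None  # deg cm^2 dmol^-1

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.theta_mdeg = np.asarray(self.theta_mdeg, float)
        if self.path_cm <= 0 or self.conc_M <= 0:
            raise ValueError("path length and concentration must be positive")
        if self.wavelength_nm.shape != self.theta_mdeg.shape:
            raise ValueError("wavelength and ellipticity must have equal length")


@dataclass
class CDMelt:
    """Ellipticity at fixed wavelength(s) over a heating (and optional
    cooling) temperature series."""

    wavelength_nm: np.ndarray  # (n_wl,)
    heating_T_C: np.ndarray  # (n_heat,)
    heating_mdeg: np.ndarray  # (n_heat, n_wl)
    path_cm: float = 0.1
    conc_M: float = 50e-6
    cooling_T_C: np.ndarray | None = None
    cooling_mdeg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.atleast_1d(np.asarray(self.wavelength_nm, float))
        self.heating_T_C = np.asarray(self.heating_T_C, float)
        self.heating_mdeg = np.atleast_2d(np.asarray(self.heating_mdeg, float))
        if self.heating_mdeg.shape != (self.heating_T_C.size, self.wavelength_nm.size):
            raise ValueError("heating_mdeg must be (n_temperatures, n_wavelengths)")
        if self.path_cm <= 0 or self.conc_M <= 0:
            raise ValueError("path length and concentration must be positive")
        if (self.cooling_T_C is None) != (self.cooling_mdeg is None):
            raise ValueError("cooling temperatures and ellipticities go together")
        if self.cooling_mdeg is not None:
            self.cooling_T_C = np.asarray(self.cooling_T_C, float)
            self.cooling_mdeg = np.atleast_2d(np.asarray(self.cooling_mdeg, float))


def cd_molar_ellipticity(spectrum: CDSpectrum) -> CDSpectrum:
    """Convert observed mdeg to molar ellipticity (deg cm^2 dmol^-1).

    [theta] = theta_mdeg / (10 * c * l), c in mol/L, l in cm.  Per-protein
    molar ellipticity (not mean-residue): divide by the residue count
    separately if MRE is wanted.
    """
    me = spectrum.theta_mdeg / (10.0 * spectrum.conc_M * spectrum.path_cm)
    spectrum.molar_ellipticity = me
    return spectrum


@dataclass
class MeltAnalysis:
    """Summary of a fixed-wavelength CD melt."""

    wavelength_nm: float
    heating_T_C: np.ndarray
    heating_molar: np.ndarray  # [theta](T), heating
    total_change: float  # [theta] at final T minus initial T (heating)
    midpoint_C: float | None  # two-state sigmoid midpoint; None if fit failed
    vant_hoff_dh: float | None  # kcal/mol from the sigmoid steepness
    cooling_T_C: np.ndarray | None = None
    cooling_molar: np.ndarray | None = None
    reversibility: float | None = None


def melt_analysis(melt: CDMelt, wavelength_nm: float) -> MeltAnalysis:
    """Analyze the melt at one wavelength: change, midpoint, reversibility.

    ``reversibility = 1 - |[theta]_cooled,final - [theta]_initial| /
    |total change|`` compares the signal recovered after cooling with the
    pre-heating signal; 1 means fully reversible, 0 means the cooled sample
    stayed at the hot-endpoint signal.  The midpoint comes from a two-state
    van 't Hoff sigmoid with constant folded/unfolded baselines.
    """
    iw = np.where(np.isclose(melt.wavelength_nm, wavelength_nm))[0]
    if len(iw) == 0:
        raise ValueError(f"wavelength {wavelength_nm} nm not in the melt grid "
                         f"{melt.wavelength_nm.tolist()}")
    iw = int(iw[0])
    scale = 10.0 * melt.conc_M * melt.path_cm
    heat = melt.heating_mdeg[:, iw] / scale
    total_change = float(heat[-1] - heat[0])

    midpoint, dh = _fit_sigmoid(melt.heating_T_C, heat)

    cooling = rev = cool_T = None
    if melt.cooling_mdeg is not None:
        cooling = melt.cooling_mdeg[:, iw] / scale
        cool_T = melt.cooling_T_C
        final_cooled = cooling[int(np.argmin(cool_T))]
        if total_change != 0:
            rev = 1.0 - abs(final_cooled - heat[0]) / abs(total_change)

    return MeltAnalysis(wavelength_nm=float(wavelength_nm),
                        heating_T_C=melt.heating_T_C, heating_molar=heat,
                        total_change=total_change, midpoint_C=midpoint,
                        vant_hoff_dh=dh, cooling_T_C=cool_T,
                        cooling_molar=cooling, reversibility=rev)


def _fit_sigmoid(T_C: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    """Two-state van 't Hoff sigmoid with constant baselines."""
    T = T_C + 273.15

    def model(p):
        tm, dh, yf, yu = p
        K = np.exp(-(dh / R_GAS_KCAL) * (1.0 / T - 1.0 / tm))
        f_unfolded = K / (1.0 + K)
        return yf + (yu - yf) * f_unfolded

    p0 = np.array([float(T[len(T) // 2]), 50.0, float(y[0]), float(y[-1])])
    try:
        sol = least_squares(lambda p: model(p) - y, p0,
                            bounds=([T[0] - 50, 1.0, -np.inf, -np.inf],
                                    [T[-1] + 50, 2000.0, np.inf, np.inf]))
        if not sol.success:
            return None, None
        tm, dh = sol.x[0], sol.x[1]
        if not (T[0] - 20 < tm < T[-1] + 20):
            return None, None
        return float(tm - 273.15), float(dh)
    except Exception:
        return None, None
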