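"""Readers and writers for the plain-text table schemas used by the pipeline.

All tables are TSV/CSV with a one-line header; files that need scalar
metadata (ITC cell volume and concentrations, CD path/concentration) carry
it in ``# key: value`` comment lines above the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .csp import ShiftTable
from .relax import DecaySeries
from .thermo import CDMelt, ITCIsotherm, Thermogram

__all__ = [
    "read_decay_tsv", "write_decay_tsv",
    "read_hetnoe_tsv", "write_hetnoe_tsv",
    "read_shift_tsv", "write_shift_tsv",
    "read_thermogram_csv", "write_thermogram_csv",
    "read_isotherm_csv", "write_isotherm_csv",
    "read_cd_melt_csv", "write_cd_melt_csv",
    "write_json",
]

_FLOAT_FMT = "%.8g"


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            if value:
                meta[key.strip()] = value.strip()
    return meta


def _write_table(df: pd.DataFrame, path, sep: str, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FMT)


# --- relaxation decays ------------------------------------------------------

def write_decay_tsv(series_list: list[DecaySeries], path) -> None:
    """Schema: residue_id, residue_name, delay_s, height, height_error, overlapped."""
    rows = []
    for s in series_list:
        err = s.height_errors if s.height_errors is not None else np.full_like(s.heights, np.nan)
        for t, h, e in zip(s.delays, s.heights, err):
            rows.append((s.residue_id, s.residue_code, t, h, e, int(s.overlapped)))
    df = pd.DataFrame(rows, columns=["residue_id", "residue_name", "delay_s",
                                     "height", "height_error", "overlapped"])
    _write_table(df, path, "\t")


def read_decay_tsv(path) -> list[DecaySeries]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_id", "delay_s", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; expected schema "
                         "residue_id, residue_name, delay_s, height[, height_error, overlapped]")
    out = []
    for rid, grp in df.groupby("residue_id"):
        grp = grp.sort_values("delay_s")
        errs = None
        if "height_error" in grp and grp["height_error"].notna().all():
            errs = grp["height_error"].to_numpy()
        out.append(DecaySeries(
            residue_id=int(rid),
            residue_code=str(grp["residue_name"].iloc[0]) if "residue_name" in grp else "X",
            delays=grp["delay_s"].to_numpy(),
            heights=grp["height"].to_numpy(),
            height_errors=errs,
            overlapped=bool(grp["overlapped"].iloc[0]) if "overlapped" in grp else False,
        ))
    return out


# --- hetNOE -----------------------------------------------------------------

def write_hetnoe_tsv(df: pd.DataFrame, path) -> None:
    """Schema: residue_id, sat_height, unsat_height, sat_err, unsat_err."""
    _write_table(df, path, "\t")


def read_hetnoe_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_id", "sat_height", "unsat_height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; expected schema "
                         "residue_id, sat_height, unsat_height[, sat_err, unsat_err]")
    return df


# --- shift tables -----------------------------------------------------------

def write_shift_tsv(table: ShiftTable, path) -> None:
    """Schema: residue_id, residue_name, site, delta_H_ppm, delta_N_ppm, ratio."""
    df = table.data.copy()
    df["ratio"] = table.ratio
    meta = {"ratio": table.ratio}
    if table.temperature_C is not None:
        meta["temperature_C"] = table.temperature_C
    _write_table(df, path, "\t", meta)


def read_shift_tsv(path) -> ShiftTable:
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_id", "site", "delta_H_ppm", "delta_N_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; expected schema "
                         "residue_id, residue_name, site, delta_H_ppm, delta_N_ppm[, ratio]")
    ratio = float(meta.get("ratio", df["ratio"].iloc[0] if "ratio" in df else 0.0))
    temp = float(meta["temperature_C"]) if "temperature_C" in meta else None
    return ShiftTable(data=df.drop(columns=[c for c in ("ratio",) if c in df]),
                      ratio=ratio, temperature_C=temp)


# --- DSC --------------------------------------------------------------------

def write_thermogram_csv(tg: Thermogram, path) -> None:
    """Schema: T_C, Cp_kcal_mol_K (temperatures written in Celsius)."""
    df = pd.DataFrame({"T_C": tg.T - 273.15, "Cp_kcal_mol_K": tg.cp})
    _write_table(df, path, ",", {"scan_rate_K_min": tg.scan_rate_K_min})


def read_thermogram_csv(path) -> Thermogram:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = {"T_C", "Cp_kcal_mol_K"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; "
                         "expected schema T_C, Cp_kcal_mol_K")
    return Thermogram(T=df["T_C"].to_numpy() + 273.15,
                      cp=df["Cp_kcal_mol_K"].to_numpy(),
                      scan_rate_K_min=float(meta.get("scan_rate_K_min", 1.0)))


# --- ITC --------------------------------------------------------------------

def write_isotherm_csv(iso: ITCIsotherm, path) -> None:
    """Schema: inj_vol_uL, heat_ucal, with cell metadata in # comments."""
    df = pd.DataFrame({"inj_vol_uL": iso.inj_vol_ul, "heat_ucal": iso.heats_ucal})
    _write_table(df, path, ",", {
        "v0_ml": iso.v0_ml,
        "cell_conc_M": iso.cell_conc_M,
        "syringe_conc_M": iso.syringe_conc_M,
        "temperature_K": iso.temperature_K,
    })


def read_isotherm_csv(path) -> ITCIsotherm:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = {"inj_vol_uL", "heat_ucal"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; "
                         "expected schema inj_vol_uL, heat_ucal")
    for key in ("v0_ml", "cell_conc_M", "syringe_conc_M"):
        if key not in meta:
            raise ValueError(f"{path}: missing '# {key}:' metadata line")
    return ITCIsotherm(
        v0_ml=float(meta["v0_ml"]),
        cell_conc_M=float(meta["cell_conc_M"]),
        syringe_conc_M=float(meta["syringe_conc_M"]),
        inj_vol_ul=df["inj_vol_uL"].to_numpy(),
        heats_ucal=df["heat_ucal"].to_numpy(),
        temperature_K=float(meta.get("temperature_K", 298.15)),
    )


# --- CD melt ----------------------------------------------------------------

def write_cd_melt_csv(melt: CDMelt, path) -> None:
    """Long schema: direction, T_C, wavelength_nm, theta_mdeg."""
    rows = []
    for ti, T in enumerate(melt.heating_T_C):
        for wi, wl in enumerate(melt.wavelength_nm):
            rows.append(("heating", T, wl, melt.heating_mdeg[ti, wi]))
    if melt.cooling_mdeg is not None:
        for ti, T in enumerate(melt.cooling_T_C):
            for wi, wl in enumerate(melt.wavelength_nm):
                rows.append(("cooling", T, wl, melt.cooling_mdeg[ti, wi]))
    df = pd.DataFrame(rows, columns=["direction", "T_C", "wavelength_nm", "theta_mdeg"])
    _write_table(df, path, ",", {"path_cm": melt.path_cm, "conc_M": melt.conc_M})


def read_cd_melt_csv(path) -> CDMelt:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = {"direction", "T_C", "wavelength_nm", "theta_mdeg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; "
                         "expected schema direction, T_C, wavelength_nm, theta_mdeg")
    wl = np.sort(df["wavelength_nm"].unique())

    def pivot(sub):
        piv = sub.pivot_table(index="T_C", columns="wavelength_nm",
                              values="theta_mdeg", sort=True)
        return piv.index.to_numpy(), piv.reindex(columns=wl).to_numpy()

    heat_T, heat = pivot(df[df["direction"] == "heating"])
    cool_T = cool = None
    cooling = df[df["direction"] == "cooling"]
    if len(cooling):
        cool_T, cool = pivot(cooling)
    return CDMelt(wavelength_nm=wl, heating_T_C=heat_T, heating_mdeg=heat,
                  path_cm=float(meta.get("path_cm", 0.1)),
                  conc_M=float(meta.get("conc_M", 50e-6)),
                  cooling_T_C=cool_T, cooling_mdeg=cool)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
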