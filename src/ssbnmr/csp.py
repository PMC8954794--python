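"""Chemical-shift-perturbation (CSP) mapping of a ligand-binding surface.

For each assigned amide site the combined ¹H/¹⁵N perturbation between an
apo and a ligand-containing spectrum is

    dd_avg = sqrt((ddN / 5.88)**2 + ddH**2)        [ppm]

where the 5.88 factor rescales the ¹⁵N shift range onto the ¹H range.
Sites are classified against the profile mean and standard deviation:
``gt2sd`` above mean + 2 SD, ``gt1sd`` above mean + 1 SD, else ``below``.
Tryptophan side-chain Nε-H entries are treated as first-class sites and by
default pooled with backbone amides in the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .struct import StructureEnsemble, write_ensemble

__all__ = [
    "N_SHIFT_SCALE",
    "ShiftTable",
    "CSPProfile",
    "compute_csp",
    "classify_profile",
    "titration_trajectory",
    "map_to_structure",
]

#: ¹⁵N-to-¹H shift-range scaling used in the combined perturbation.
N_SHIFT_SCALE = 5.88

_SITES = ("backbone_NH", "trp_sidechain_NeH")


@dataclass
class ShiftTable:
    """Assigned amide shifts at one titration condition.

    ``data`` columns: residue_id, residue_name, site, delta_H_ppm,
    delta_N_ppm.  ``site`` is ``backbone_NH`` or ``trp_sidechain_NeH``;
    the (residue_id, site) pair must be unique.
    """

    data: pd.DataFrame
    ratio: float = 0.0  # ligand : protein molar ratio
    temperature_C: float | None = None

    def __post_init__(self) -> None:
        required = {"residue_id", "site", "delta_H_ppm", "delta_N_ppm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        bad = set(self.data["site"]) - set(_SITES)
        if bad:
            raise ValueError(f"unknown site labels: {sorted(bad)}")
        keys = list(zip(self.data["residue_id"], self.data["site"]))
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (residue_id, site) entries")
        for col in ("delta_H_ppm", "delta_N_ppm"):
            if not np.all(np.isfinite(self.data[col])):
                raise ValueError(f"non-finite shifts in {col}")

    def keyed(self) -> pd.DataFrame:
        return self.data.set_index(["residue_id", "site"])


@dataclass
class CSPProfile:
    """Classified per-site perturbations at one titration point.

    ``table`` columns: residue_id, site, csp_ppm, csp_class; classes are
    {'below', 'gt1sd', 'gt2sd'} relative to mean + k*SD of the pooled
    profile.  ``unmatched`` lists (residue_id, site) keys present in only
    one of the two compared tables (e.g. broadened beyond detection).
    """

    table: pd.DataFrame
    mean: float
    sd: float
    k_low: float = 1.0
    k_high: float = 2.0
    unmatched: list = field(default_factory=list)

    @property
    def perturbed_sites(self) -> set[tuple[int, str]]:
        mask = self.table["csp_class"] != "below"
        return {(int(r), s) for r, s in
                zip(self.table.loc[mask, "residue_id"], self.table.loc[mask, "site"])}

    @property
    def perturbed_residues(self) -> set[int]:
        return {r for r, _s in self.perturbed_sites}


def csp_value(delta_h: float, delta_n: float) -> float:
    """Combined amide perturbation in ppm for one site."""
    return float(np.hypot(np.asarray(delta_n) / N_SHIFT_SCALE, delta_h))


def compute_csp(apo: ShiftTable, bound: ShiftTable) -> tuple[pd.DataFrame, list]:
    """Per-site combined perturbation between two shift tables.

    Returns ``(frame, unmatched)`` where ``frame`` has columns residue_id,
    site, csp_ppm over the shared (residue_id, site) keys and ``unmatched``
    lists keys present in exactly one table (never dropped silently).
    """
    a = apo.keyed()
    b = bound.keyed()
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("the two shift tables share no (residue_id, site) keys")
    unmatched = sorted(a.index.symmetric_difference(b.index))
    dh = b.loc[shared, "delta_H_ppm"] - a.loc[shared, "delta_H_ppm"]
    dn = b.loc[shared, "delta_N_ppm"] - a.loc[shared, "delta_N_ppm"]
    csp = np.hypot(dn / N_SHIFT_SCALE, dh)
    frame = pd.DataFrame({
        "residue_id": [k[0] for k in shared],
        "site": [k[1] for k in shared],
        "csp_ppm": csp.values,
    }).sort_values(["residue_id", "site"]).reset_index(drop=True)
    return frame, unmatched


def classify_profile(csp: pd.DataFrame, k_low: float = 1.0, k_high: float = 2.0,
                     include_sidechains: bool = True,
                     unmatched: list | None = None,
                     min_sites: int = 5) -> CSPProfile:
    """Classify sites against the pooled mean/SD of the perturbation profile.

    Backbone and Trp side-chain sites are pooled by default
    (``include_sidechains=False`` restricts the statistics — and the
    classified rows — to backbone amides).  Classification is one-sided:
    perturbations are non-negative by construction, so only the high tail
    is meaningful.
    """
    if k_high < k_low:
        raise ValueError("k_high must be >= k_low")
    work = csp if include_sidechains else csp[csp["site"] == "backbone_NH"]
    if len(work) < min_sites:
        raise ValueError(f"only {len(work)} sites; need at least {min_sites}")
    values = work["csp_ppm"].to_numpy(float)
    if np.any(values < 0):
        raise ValueError("perturbations must be non-negative")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0

    def classify(v):
        if sd > 0 and v > mean + k_high * sd:
            return "gt2sd"
        if sd > 0 and v > mean + k_low * sd:
            return "gt1sd"
        return "below"

    out = work.copy().reset_index(drop=True)
    out["csp_class"] = [classify(v) for v in out["csp_ppm"]]
    return CSPProfile(table=out, mean=mean, sd=sd, k_low=k_low, k_high=k_high,
                      unmatched=list(unmatched or []))


def titration_trajectory(tables: list[ShiftTable],
                         noise_floor: float = 0.005) -> pd.DataFrame:
    """Per-site CSP versus molar ratio, referenced to the apo table.

    The first table must be the apo reference (ratio 0) and ratios must be
    strictly increasing.  Returns a long-format frame with columns
    residue_id, site, ratio, csp_ppm, plus a per-site ``monotonic`` flag
    that is False where the CSP decreases by more than ``noise_floor`` ppm
    between consecutive ratios (fast exchange predicts a monotone rise).
    """
    if len(tables) < 2:
        raise ValueError("need the apo reference plus at least one titration point")
    ratios = [t.ratio for t in tables]
    if ratios[0] != 0:
        raise ValueError("first table must be the apo reference at ratio 0")
    if not all(b > a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("tables must be ordered by strictly increasing ratio")

    apo = tables[0]
    frames = []
    for tab in tables[1:]:
        frame, _ = compute_csp(apo, tab)
        frame["ratio"] = tab.ratio
        frames.append(frame)
    traj = pd.concat(frames, ignore_index=True)

    flags = {}
    for (rid, site), grp in traj.groupby(["residue_id", "site"]):
        vals = grp.sort_values("ratio")["csp_ppm"].to_numpy()
        flags[(rid, site)] = bool(np.all(np.diff(vals) > -noise_floor))
    traj["monotonic"] = [flags[(r, s)] for r, s in
                         zip(traj["residue_id"], traj["site"])]
    return traj


def map_to_structure(profile: CSPProfile, ensemble: StructureEnsemble,
                     pdb_out, table_out=None, scale: float = 100.0) -> pd.DataFrame:
    """Paint per-residue CSPs onto model 1 via the B-factor column.

    Every atom of a residue gets B = CSP (ppm) * ``scale`` (default x100 so
    typical perturbations land in a readable 0-100 range); residues without
    a CSP get 0.  The class labels go to a sidecar TSV when ``table_out``
    is given.  Side-chain sites are reported in the sidecar but the painted
    value per residue is the largest CSP over its sites.
    """
    if len(profile.table) == 0:
        raise ValueError("empty CSP profile")
    per_residue = profile.table.groupby("residue_id")["csp_ppm"].max()
    overlap = set(per_residue.index) & set(int(r) for r in ensemble.residue_ids)
    if not overlap:
        raise ValueError("no residue overlap between profile and structure")
    bf = np.array([per_residue.get(int(r), 0.0) * scale
                   for r in ensemble.residue_ids])
    write_ensemble(ensemble, pdb_out, bfactors=bf, models=[0])
    sidecar = profile.table.copy()
    if table_out is not None:
        sidecar.to_csv(table_out, sep="\t", index=False, float_format="%.6f")
    return sidecar
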