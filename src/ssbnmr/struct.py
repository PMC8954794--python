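"""Multi-model structure ensembles, distance-restraint statistics and
rigid-body superposition.

The module handles three related jobs that come up when characterizing an
NMR structure bundle:

* ingesting multi-model PDB files into an atom-aligned
  :class:`StructureEnsemble`;
* parsing XPLOR-dialect ``assign`` distance-restraint files and binning the
  restraints by residue separation (intra / sequential / medium / long /
  hydrogen bond);
* least-squares (Kabsch) superposition, pairwise ensemble RMSD over a
  residue/atom selection, and per-residue displacement between two
  superposed ensembles.

Conventions: "backbone" means N, CA, C (carbonyl O excluded); "heavy" means
all non-hydrogen atoms.  Both are configurable through
:class:`ResidueSelection`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructureEnsemble",
    "ResidueSelection",
    "RestraintRecord",
    "RestraintStats",
    "SuperpositionResult",
    "read_ensemble",
    "write_ensemble",
    "read_restraints_xplor",
    "classify_restraints",
    "superpose",
    "ensemble_pairwise_rmsd",
    "residue_displacement",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C"})


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StructureEnsemble:
    """Atom-aligned coordinate ensemble.

    Attributes
    ----------
    residue_ids, residue_names, atom_names, elements
        Per-atom annotation shared by every model (length ``n_atoms``).
    coords
        Array of shape ``(n_models, n_atoms, 3)`` in Å.
    chain_id, source
        Metadata carried through from the input file.
    """

    residue_ids: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n_atoms = self.coords.shape[1]
        for name in ("residue_ids", "residue_names", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have length n_atoms={n_atoms}")
            setattr(self, name, arr)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model(self, i: int) -> np.ndarray:
        """Coordinates of model ``i`` (0-based), shape (n_atoms, 3)."""
        return self.coords[i]

    def subset(self, mask: np.ndarray) -> "StructureEnsemble":
        return StructureEnsemble(
            residue_ids=self.residue_ids[mask],
            residue_names=self.residue_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            coords=self.coords[:, mask],
            chain_id=self.chain_id,
            source=self.source,
        )


@dataclass
class ResidueSelection:
    """Residue ranges plus an atom class, e.g. ``3-97,104-113:backbone``.

    ``ranges`` are inclusive 1-based ``(start, stop)`` pairs; an empty list
    selects every residue.  ``atom_class`` is one of ``backbone`` (N, CA, C),
    ``heavy`` (non-hydrogen), ``calpha`` or ``all``.
    """

    ranges: list[tuple[int, int]] = field(default_factory=list)
    atom_class: str = "backbone"

    _CLASSES = ("backbone", "heavy", "calpha", "all")

    def __post_init__(self) -> None:
        if self.atom_class not in self._CLASSES:
            raise ValueError(f"atom_class must be one of {self._CLASSES}")
        spans = sorted(self.ranges)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError(f"overlapping residue ranges {(a0, a1)} and {(b0, b1)}")
        for a0, a1 in spans:
            if a1 < a0:
                raise ValueError(f"range {(a0, a1)} has stop < start")

    @classmethod
    def parse(cls, text: str) -> "ResidueSelection":
        """Parse ``"3-97,104-113:backbone"``; ranges part may be ``all``."""
        part, _, klass = text.partition(":")
        klass = klass or "backbone"
        part = part.strip()
        ranges: list[tuple[int, int]] = []
        if part and part.lower() != "all":
            for chunk in part.split(","):
                lo, _, hi = chunk.partition("-")
                ranges.append((int(lo), int(hi) if hi else int(lo)))
        return cls(ranges=ranges, atom_class=klass)

    def atom_mask(self, ens: StructureEnsemble) -> np.ndarray:
        mask = np.ones(ens.n_atoms, dtype=bool)
        if self.ranges:
            in_range = np.zeros(ens.n_atoms, dtype=bool)
            for lo, hi in self.ranges:
                in_range |= (ens.residue_ids >= lo) & (ens.residue_ids <= hi)
            mask &= in_range
        if self.atom_class == "backbone":
            mask &= np.isin(ens.atom_names, sorted(BACKBONE_ATOMS))
        elif self.atom_class == "calpha":
            mask &= ens.atom_names == "CA"
        elif self.atom_class == "heavy":
            mask &= ens.elements != "H"
        return mask


@dataclass(frozen=True)
class RestraintRecord:
    """One distance restraint: ``d - d_minus .. d + d_plus`` between two atoms."""

    residue_i: int
    residue_j: int
    atom_i: str
    atom_j: str
    d: float
    d_minus: float
    d_plus: float
    source: str = "noe"  # noe | hbond
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.residue_i < 1 or self.residue_j < 1:
            raise ValueError("residue ids must be >= 1")
        if self.d - self.d_minus < 0:
            raise ValueError("lower bound d - d_minus must be >= 0")

    @property
    def separation(self) -> int:
        return abs(self.residue_i - self.residue_j)


@dataclass
class RestraintStats:
    """Category counts for a restraint set.

    NOE-derived restraints partition into intra (|i-j| = 0), sequential
    (|i-j| = 1), medium (1 < |i-j| <= 5) and long (|i-j| > 5) range;
    hydrogen-bond restraints are counted separately.  ``medium_share`` is
    the medium-range percentage of the NOE-derived distance restraints.
    """

    intra: int
    sequential: int
    medium: int
    long: int
    hbond: int

    @property
    def noe_total(self) -> int:
        return self.intra + self.sequential + self.medium + self.long

    @property
    def total(self) -> int:
        return self.noe_total + self.hbond

    @property
    def medium_share(self) -> float:
        if self.noe_total == 0:
            return 0.0
        return 100.0 * self.medium / self.noe_total

    def as_dict(self) -> dict:
        return {
            "intra": self.intra,
            "sequential": self.sequential,
            "medium": self.medium,
            "long": self.long,
            "hbond": self.hbond,
            "noe_total": self.noe_total,
            "total": self.total,
            "medium_share_pct": self.medium_share,
        }


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_ensemble(path, chain: str | None = None) -> StructureEnsemble:
    """Read a (multi-model) PDB file into an atom-aligned ensemble.

    Alternate locations are collapsed to the highest-occupancy conformer.
    Models must share the same atom set; a mismatch is a hard error that
    names the first offending atom.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"{path}: no models found")

    def model_atoms(model):
        chains = list(model.get_chains())
        if chain is not None:
            chains = [c for c in chains if c.id == chain]
            if not chains:
                raise ValueError(f"{path}: chain {chain!r} not found")
        picked = chains[:1]  # single-chain analyses; first chain by default
        out = []
        for ch in picked:
            for res in ch:
                if res.id[0] != " ":  # skip waters / heteroatoms
                    continue
                for atom in res:
                    if atom.is_disordered():
                        atom = max(atom.disordered_get_list(),
                                   key=lambda a: a.get_occupancy() or 0.0)
                    out.append((res.id[1], res.get_resname(), atom.get_name(),
                                (atom.element or "").strip() or _guess_element(atom.get_name()),
                                atom.get_coord()))
        return out, picked[0].id

    first, chain_id = model_atoms(models[0])
    keys = [(r, a) for r, _rn, a, _e, _c in first]
    index = {k: i for i, k in enumerate(keys)}
    if len(index) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"{path}: duplicate atom {dup} in model 1")

    coords = np.empty((len(models), len(keys), 3), dtype=float)
    coords[0] = np.array([c for *_ignored, c in first])
    for m, model in enumerate(models[1:], start=1):
        atoms, _ = model_atoms(model)
        if len(atoms) != len(keys):
            raise ValueError(
                f"{path}: model {m + 1} has {len(atoms)} atoms, model 1 has {len(keys)}")
        row = np.empty((len(keys), 3))
        seen = np.zeros(len(keys), dtype=bool)
        for r, _rn, a, _e, c in atoms:
            i = index.get((r, a))
            if i is None:
                raise ValueError(
                    f"{path}: model {m + 1} atom (residue {r}, {a}) absent from model 1")
            row[i] = c
            seen[i] = True
        if not seen.all():
            r, a = keys[int(np.argmin(seen))]
            raise ValueError(
                f"{path}: model {m + 1} is missing atom (residue {r}, {a})")
        coords[m] = row

    return StructureEnsemble(
        residue_ids=np.array([k[0] for k in keys], dtype=int),
        residue_names=np.array([rn for _r, rn, *_rest in first]),
        atom_names=np.array([k[1] for k in keys]),
        elements=np.array([e for *_ignored, e, _c in first]),
        coords=coords,
        chain_id=chain_id,
        source=str(path),
    )


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    return name[:1].upper() if name else "X"


def _format_atom_name(name: str) -> str:
    # one/two-letter elements start in column 14; 4-char names fill col 13-16
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_ensemble(ens: StructureEnsemble, path,
                   bfactors: np.ndarray | None = None,
                   models: Sequence[int] | None = None) -> None:
    """Write the ensemble as fixed-column PDB (MODEL/ENDMDL for > 1 model)."""
    which = range(ens.n_models) if models is None else models
    b = np.zeros(ens.n_atoms) if bfactors is None else np.asarray(bfactors, float)
    if b.shape != (ens.n_atoms,):
        raise ValueError("bfactors must have length n_atoms")
    lines: list[str] = []
    multi = len(list(which)) > 1
    which = range(ens.n_models) if models is None else models
    for mi, m in enumerate(which, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        for i in range(ens.n_atoms):
            x, y, z = ens.coords[m, i]
            lines.append(
                "ATOM  {serial:5d} {name}{alt}{res:>3s} {ch}{resid:4d}{icode}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {el:>2s}".format(
                    serial=i + 1,
                    name=_format_atom_name(str(ens.atom_names[i])),
                    alt=" ",
                    res=str(ens.residue_names[i])[:3],
                    ch=(ens.chain_id or "A")[:1],
                    resid=int(ens.residue_ids[i]),
                    icode=" ",
                    x=x, y=y, z=z, occ=1.0, bf=b[i],
                    el=str(ens.elements[i])[:2],
                ))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

class RestraintParseError(ValueError):
    pass


_SEL_RE = re.compile(r"resid\s+(\d+)\s+and\s+name\s+([^\s)]+)", re.IGNORECASE)
_HB_DONOR = {"N", "H", "HN"}


class RestraintList(list):
    """List of :class:`RestraintRecord` with a ``parse_errors`` report.

    ``parse_errors`` holds ``(line_number, message)`` tuples for statements
    that could not be parsed; parsing never aborts on them.
    """

    def __init__(self, records: Iterable[RestraintRecord] = (),
                 parse_errors: list[tuple[int, str]] | None = None):
        super().__init__(records)
        self.parse_errors: list[tuple[int, str]] = parse_errors or []


def read_restraints_xplor(path) -> RestraintList:
    """Parse XPLOR-dialect distance restraints.

    Grammar handled per statement (possibly spanning lines)::

        assign (resid I and name A)(resid J and name B) d d_minus d_plus

    OR-group (ambiguous) selections take the first ``(resid .. name ..)``
    pair of each side and are flagged ``ambiguous``.  A comment line
    mentioning hydrogen bonds opens a block in which amide-donor to
    oxygen-acceptor pairs are labelled ``source='hbond'``; any other comment
    closes it.  Unparseable statements are collected into
    ``result.parse_errors`` with their line numbers.
    """
    with open(path) as fh:
        raw_lines = fh.readlines()

    records: list[RestraintRecord] = []
    errors: list[tuple[int, str]] = []
    hbond_block = False

    # split into statements: each starts at a line whose first token is 'assign'
    statements: list[tuple[int, str, bool]] = []
    current: list[str] = []
    current_line = 0
    current_hb = False
    for lineno, raw in enumerate(raw_lines, start=1):
        comment = None
        if "!" in raw:
            raw, comment = raw.split("!", 1)
        if comment is not None and comment.strip():
            hbond_block = bool(re.search(r"h[\s-]*bond|hydrogen\s*bond",
                                         comment, re.IGNORECASE))
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.lower().startswith("assign"):
            if current:
                statements.append((current_line, " ".join(current), current_hb))
            current = [stripped]
            current_line = lineno
            current_hb = hbond_block
        elif current:
            current.append(stripped)
        else:
            errors.append((lineno, f"text outside assign statement: {stripped[:40]!r}"))
    if current:
        statements.append((current_line, " ".join(current), current_hb))

    for lineno, text, in_hb in statements:
        try:
            records.append(_parse_assign(text, in_hb))
        except RestraintParseError as exc:
            errors.append((lineno, str(exc)))

    return RestraintList(records, errors)


def _parse_assign(text: str, hbond_block: bool) -> RestraintRecord:
    body = text[len("assign"):].strip()
    groups = _split_paren_groups(body)
    if len(groups) < 2:
        raise RestraintParseError("expected two parenthesized selections")
    tail = groups[-1][1]
    nums = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", tail)
    if len(nums) < 3:
        raise RestraintParseError(f"expected 'd d_minus d_plus', got {tail!r}")
    d, dm, dp = (float(v) for v in nums[:3])

    sels = []
    ambiguous = False
    for grp, _after in groups[:2]:
        matches = _SEL_RE.findall(grp)
        if not matches:
            raise RestraintParseError(f"no 'resid .. name ..' in selection {grp[:40]!r}")
        if len(matches) > 1 or re.search(r"\bor\b", grp, re.IGNORECASE):
            ambiguous = True
        sels.append(matches[0])

    (ri, ai), (rj, aj) = sels
    ai, aj = ai.upper(), aj.upper()
    source = "noe"
    if hbond_block:
        pair = {ai, aj}
        if (pair & _HB_DONOR) and any(a.startswith("O") for a in pair):
            source = "hbond"
    return RestraintRecord(residue_i=int(ri), residue_j=int(rj),
                           atom_i=ai, atom_j=aj, d=d, d_minus=dm, d_plus=dp,
                           source=source, ambiguous=ambiguous)


def _split_paren_groups(body: str) -> list[tuple[str, str]]:
    """Split leading balanced ``(...)`` groups; returns (content, text_after)."""
    groups = []
    i = 0
    n = len(body)
    while i < n:
        while i < n and body[i].isspace():
            i += 1
        if i >= n or body[i] != "(":
            break
        depth = 0
        start = i
        while i < n:
            if body[i] == "(":
                depth += 1
            elif body[i] == ")":
                depth -= 1
                if depth == 0:
                    break
            i += 1
        if depth != 0:
            raise RestraintParseError("unbalanced parentheses")
        groups.append([body[start + 1:i], ""])
        i += 1
    if groups:
        groups[-1][1] = body[i:]
    return [tuple(g) for g in groups]


def classify_restraints(records: Sequence[RestraintRecord]) -> RestraintStats:
    """Bin restraints by residue separation; hydrogen bonds counted apart."""
    if not records:
        raise ValueError("no restraints to classify")
    counts = {"intra": 0, "sequential": 0, "medium": 0, "long": 0, "hbond": 0}
    for rec in records:
        if rec.source == "hbond":
            counts["hbond"] += 1
            continue
        s = rec.separation
        if s == 0:
            counts["intra"] += 1
        elif s == 1:
            counts["sequential"] += 1
        elif s <= 5:
            counts["medium"] += 1
        else:
            counts["long"] += 1
    return RestraintStats(**counts)


# ---------------------------------------------------------------------------
# superposition & RMSD
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    P = mobile - mob_c
    Q = reference - ref_c
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    t = ref_c - R @ mob_c
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection_mask: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal least-squares (Kabsch) superposition of paired coordinates.

    ``mobile`` and ``reference`` are ``(n_atoms, 3)`` arrays with matched
    rows.  With ``selection_mask`` the transform is computed (and the RMSD
    reported) over the selected atoms only.  Reflections are corrected so
    the rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if selection_mask is not None:
        mobile = mobile[selection_mask]
        reference = reference[selection_mask]
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    centered = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; superposition is degenerate")
    return _kabsch(mobile, reference)


def ensemble_pairwise_rmsd(ens: StructureEnsemble,
                           selection: ResidueSelection) -> tuple[float, float, np.ndarray]:
    """Mean ± SD of the RMSD over all unordered model pairs.

    Each of the C(n, 2) pairs is superposed independently on the selection
    before its RMSD is recorded.  Returns ``(mean, sd, rmsds)``; the SD is
    the sample standard deviation over pairs (0 for a single pair).
    """
    if ens.n_models < 2:
        raise ValueError("ensemble must contain at least 2 models")
    mask = selection.atom_mask(ens)
    if not mask.any():
        raise ValueError("selection matches no atoms in the ensemble")
    rmsds = []
    for i in range(ens.n_models):
        for j in range(i + 1, ens.n_models):
            res = superpose(ens.coords[j][mask], ens.coords[i][mask])
            rmsds.append(res.rmsd)
    rmsds = np.array(rmsds)
    sd = float(rmsds.std(ddof=1)) if len(rmsds) > 1 else 0.0
    return float(rmsds.mean()), sd, rmsds


@dataclass
class DisplacementResult:
    """Probe-atom distance between two superposed ensembles."""

    mean: float
    sd: float
    designated: float  # model 1 of each ensemble
    distances: np.ndarray  # (n_models_a, n_models_b)


def residue_displacement(ens_a: StructureEnsemble, ens_b: StructureEnsemble,
                         selection: ResidueSelection,
                         probe_residue: int, probe_atom: str = "CA") -> DisplacementResult:
    """Distance of a probe atom between two ensembles after superposition.

    Every model of ``ens_b`` is superposed onto every model of ``ens_a``
    using the common atoms of ``selection``; the probe-atom distance is
    recorded for each combination.  Residue numbering must agree between the
    ensembles — atoms are paired by (residue id, atom name), and a missing
    counterpart is an error rather than a silent renumbering.
    """
    def probe_index(ens):
        hits = np.where((ens.residue_ids == probe_residue)
                        & (ens.atom_names == probe_atom))[0]
        if len(hits) == 0:
            raise ValueError(f"probe atom {probe_atom} of residue {probe_residue} "
                             f"not found in {ens.source or 'ensemble'}")
        return int(hits[0])

    pa, pb = probe_index(ens_a), probe_index(ens_b)

    key_a = {(int(r), str(a)): i
             for i, (r, a) in enumerate(zip(ens_a.residue_ids, ens_a.atom_names))}
    mask_b = selection.atom_mask(ens_b)
    pairs = [(key_a[(int(r), str(a))], i)
             for i, (r, a) in enumerate(zip(ens_b.residue_ids, ens_b.atom_names))
             if mask_b[i] and (int(r), str(a)) in key_a]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 common atoms in the superposition frame")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])

    dist = np.empty((ens_a.n_models, ens_b.n_models))
    for ma in range(ens_a.n_models):
        ref = ens_a.coords[ma]
        for mb in range(ens_b.n_models):
            mob = ens_b.coords[mb]
            sup = superpose(mob[ib], ref[ia])
            probe_moved = sup.apply(mob[pb][None, :])[0]
            dist[ma, mb] = np.linalg.norm(probe_moved - ref[pa])
    sd = float(dist.std(ddof=1)) if dist.size > 1 else 0.0
    return DisplacementResult(mean=float(dist.mean()), sd=sd,
                              designated=float(dist[0, 0]), distances=dist)
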