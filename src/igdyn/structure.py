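"""Ensemble geometry: superposition, RMSD, dihedrals, NOE restraints, H-bonds,
buried surface.

Coordinates come from multi-model PDB files (NMR ensembles) read with gemmi
into a light :class:`StructureEnsemble` (one shared atom table, one coordinate
block per model).  Model numbers are 1-based throughout, matching PDB files;
"best structure" of a deposited NMR ensemble is model 1 by convention.

NOE restraints use upper-bound distances between protons or pseudo-atom
groups ('#' wildcard: methyls, methylenes, degenerate aromatic pairs) with
r^-6 sum averaging, d_eff = (sum_pairs d^-6)^(-1/6).  A restraint is
*compatible* with a conformer when its violation max(0, d - upper) does not
exceed the tolerance (default 0.3 A), which partitions a conformer-specific
restraint list into IN-specific / OUT-specific / both / neither.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .io import read_table, write_table

BACKBONE_ATOMS = ("N", "CA", "C")

# ---------------------------------------------------------------------------
# ensemble container and PDB I/O


class StructureEnsemble:
    """Multi-model coordinates with a shared atom table.

    Attributes
    ----------
    atoms:
        dict of numpy arrays ``chain``, ``resnum``, ``resname``, ``name``,
        ``element`` of length n_atoms.
    xyz:
        float array of shape (n_models, n_atoms, 3), Angstrom.
    source_id:
        free-text provenance tag (file name, generator call, ...).
    """

    def __init__(self, atoms: dict, xyz: np.ndarray, source_id: str = ""):
        self.atoms = {k: np.asarray(v) for k, v in atoms.items()}
        self.xyz = np.asarray(xyz, dtype=float)
        self.source_id = source_id
        n = len(self.atoms["name"])
        if self.xyz.ndim != 3 or self.xyz.shape[1:] != (n, 3):
            raise ValueError("xyz must have shape (n_models, n_atoms, 3)")
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def coords(self, model_number: int = 1) -> np.ndarray:
        """Coordinates of one model (1-based model number)."""
        if not 1 <= model_number <= self.n_models:
            raise IndexError(f"model {model_number} not in 1..{self.n_models}")
        return self.xyz[model_number - 1]

    def mask(
        self,
        selection: str = "all",
        residues: tuple[int, int] | Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Boolean atom mask.

        *selection* is ``backbone`` (N, CA, C), ``heavy`` (no hydrogens) or
        ``all``; *residues* an inclusive (first, last) pair or an explicit
        set of residue numbers.
        """
        m = np.ones(self.n_atoms, dtype=bool)
        if selection == "backbone":
            m &= np.isin(self.atoms["name"], BACKBONE_ATOMS)
        elif selection == "heavy":
            m &= np.char.upper(self.atoms["element"].astype(str)) != "H"
        elif selection != "all":
            raise ValueError(f"unknown selection {selection!r}")
        if residues is not None:
            if isinstance(residues, tuple) and len(residues) == 2:
                lo, hi = residues
                m &= (self.atoms["resnum"] >= lo) & (self.atoms["resnum"] <= hi)
            else:
                m &= np.isin(self.atoms["resnum"], list(residues))
        if atom_names is not None:
            m &= np.isin(self.atoms["name"], list(atom_names))
        return m

    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.atoms["resnum"])

    def residue_name(self, resnum: int) -> str:
        idx = np.nonzero(self.atoms["resnum"] == resnum)[0]
        if len(idx) == 0:
            raise KeyError(f"residue {resnum} not present")
        return str(self.atoms["resname"][idx[0]])

    def to_pdb(self, path: str | Path) -> None:
        """Write the ensemble as a multi-model PDB file (via gemmi)."""
        st = gemmi.Structure()
        st.name = self.source_id or "igdyn"
        for imodel in range(self.n_models):
            model = gemmi.Model(imodel + 1)
            chain_names = np.unique(self.atoms["chain"])
            for ch in chain_names:
                chain = gemmi.Chain(str(ch))
                sel = np.nonzero(self.atoms["chain"] == ch)[0]
                current = None
                residue = None
                for i in sel:
                    key = int(self.atoms["resnum"][i])
                    if key != current:
                        residue = gemmi.Residue()
                        residue.name = str(self.atoms["resname"][i])
                        residue.seqid = gemmi.SeqId(key, " ")
                        chain.add_residue(residue)
                        current = key
                    atom = gemmi.Atom()
                    atom.name = str(self.atoms["name"][i])
                    atom.element = gemmi.Element(str(self.atoms["element"][i]))
                    x, y, z = self.xyz[imodel, i]
                    atom.pos = gemmi.Position(x, y, z)
                    chain[-1].add_atom(atom)
                model.add_chain(chain)
            st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


class PDBParseError(ValueError):
    pass


def _check_model_records(path: Path) -> None:
    open_line = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tag = line[:6].strip()
        if tag == "MODEL":
            if open_line is not None:
                raise PDBParseError(
                    f"{path}: MODEL at line {open_line} not closed by ENDMDL "
                    f"before MODEL at line {lineno}"
                )
            open_line = lineno
        elif tag == "ENDMDL":
            open_line = None
    if open_line is not None:
        raise PDBParseError(f"{path}: MODEL at line {open_line} has no ENDMDL")


def read_pdb_ensemble(path: str | Path, include_het: bool = False) -> StructureEnsemble:
    """Read a (multi-model) PDB file; waters/heteroatoms excluded by default.

    All models must share the same atom list; the first mismatch is reported.
    """
    path = Path(path)
    _check_model_records(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    if not include_het:
        st.remove_ligands_and_waters()

    def atom_rows(model):
        rows, coords = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append((chain.name, res.seqid.num, res.name,
                                 atom.name, atom.element.name))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        return rows, np.array(coords)

    ref_rows, first = atom_rows(st[0])
    xyz = [first]
    for k in range(1, len(st)):
        rows, coords = atom_rows(st[k])
        if rows != ref_rows:
            for i, (a, b) in enumerate(zip(rows, ref_rows)):
                if a != b:
                    raise PDBParseError(
                        f"{path}: model {k + 1} atom {i} is {a}, model 1 has {b}"
                    )
            raise PDBParseError(
                f"{path}: model {k + 1} has {len(rows)} atoms, model 1 has {len(ref_rows)}"
            )
        xyz.append(coords)

    atoms = {
        "chain": np.array([r[0] for r in ref_rows]),
        "resnum": np.array([r[1] for r in ref_rows], dtype=int),
        "resname": np.array([r[2] for r in ref_rows]),
        "name": np.array([r[3] for r in ref_rows]),
        "element": np.array([r[4] for r in ref_rows]),
    }
    return StructureEnsemble(atoms, np.stack(xyz), source_id=path.name)


# ---------------------------------------------------------------------------
# superposition and RMSD


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # applied after rotation
    rmsd: float               # A, over the fitted atoms

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Kabsch least-squares rigid-body fit of *mobile* onto *reference*.

    Both arrays are (n, 3) with matched rows, n >= 3 and not collinear.  The
    returned rotation is proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matched (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("superposition atoms are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _fit_mask(ens: StructureEnsemble, fit_residues) -> np.ndarray:
    return ens.mask("backbone", residues=fit_residues)


def per_residue_rmsd(
    ensA: StructureEnsemble,
    ensB: StructureEnsemble | None = None,
    selection: str = "backbone",
    fit_residues: tuple[int, int] | Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-residue RMSD profile after one global backbone superposition.

    With two ensembles: best model of A vs best model of B (matched residues;
    unmatched ones are skipped with a warning).  With one ensemble: spread of
    the family, mean RMSD of models 2..N to model 1, each globally fitted to
    model 1 first.  Returns columns residue_id, rmsd.
    """
    if ensB is not None:
        common = np.intersect1d(ensA.residue_numbers(), ensB.residue_numbers())
        skipped = (set(ensA.residue_numbers()) | set(ensB.residue_numbers())) - set(common)
        if skipped:
            warnings.warn(f"residues absent in one ensemble skipped: {sorted(skipped)}")
        if fit_residues is None:
            fit_set = set(int(r) for r in common)
        elif isinstance(fit_residues, tuple) and len(fit_residues) == 2:
            fit_set = set(range(fit_residues[0], fit_residues[1] + 1))
        else:
            fit_set = set(int(r) for r in fit_residues)

        def matched(sel_residues, sel):
            idxA, idxB = [], []
            for r in sel_residues:
                mA = ensA.mask(sel, residues=[r])
                namesA = ensA.atoms["name"][mA]
                mB = ensB.mask(sel, residues=[r])
                namesB = list(ensB.atoms["name"][mB])
                for i, nm in zip(np.nonzero(mA)[0], namesA):
                    if nm in namesB:
                        idxA.append(i)
                        j = np.nonzero(mB)[0][namesB.index(nm)]
                        idxB.append(j)
            return np.array(idxA, dtype=int), np.array(idxB, dtype=int)

        fit_common = [r for r in common if int(r) in fit_set]
        fa, fb = matched(fit_common, "backbone")
        sup = superpose(ensA.coords(1)[fa], ensB.coords(1)[fb])
        movedA = sup.apply(ensA.coords(1))
        rows = []
        for r in common:
            ia, ib = matched([r], selection)
            if len(ia) == 0:
                continue
            diff = movedA[ia] - ensB.coords(1)[ib]
            rows.append({"residue_id": int(r),
                         "rmsd": float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))})
        return pd.DataFrame(rows)

    fit_res = fit_residues if fit_residues is not None else (
        int(ensA.residue_numbers().min()), int(ensA.residue_numbers().max()))
    fmask = _fit_mask(ensA, fit_res)
    sel_mask = ensA.mask(selection)
    ref = ensA.coords(1)
    moved = [ref]
    for k in range(2, ensA.n_models + 1):
        sup = superpose(ensA.coords(k)[fmask], ref[fmask])
        moved.append(sup.apply(ensA.coords(k)))
    moved = np.stack(moved)
    rows = []
    for r in ensA.residue_numbers():
        idx = np.nonzero(sel_mask & (ensA.atoms["resnum"] == r))[0]
        if len(idx) == 0:
            continue
        diff = moved[1:, idx] - ref[idx]
        per_model = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
        rows.append({"residue_id": int(r), "rmsd": float(per_model.mean())})
    return pd.DataFrame(rows)


def global_rmsd(
    ensA: StructureEnsemble,
    ensB: StructureEnsemble,
    selection: str = "backbone",
    residues: tuple[int, int] | None = None,
) -> float:
    """RMSD between best models over *residues* after fitting on that selection."""
    common = np.intersect1d(ensA.residue_numbers(), ensB.residue_numbers())
    if residues is not None:
        common = common[(common >= residues[0]) & (common <= residues[1])]
    idxA, idxB = [], []
    for r in common:
        mA = np.nonzero(ensA.mask(selection, residues=[r]))[0]
        namesB = list(ensB.atoms["name"][ensB.mask(selection, residues=[r])])
        posB = np.nonzero(ensB.mask(selection, residues=[r]))[0]
        for i in mA:
            nm = ensA.atoms["name"][i]
            if nm in namesB:
                idxA.append(i)
                idxB.append(posB[namesB.index(nm)])
    sup = superpose(ensA.coords(1)[idxA], ensB.coords(1)[idxB])
    return sup.rmsd


# ---------------------------------------------------------------------------
# dihedrals


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC sign convention, range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def phi_psi(ens: StructureEnsemble, model_number: int = 1) -> pd.DataFrame:
    """Backbone phi/psi per residue of one model.

    phi = C(i-1)-N-CA-C, psi = N-CA-C-N(i+1); undefined at chain breaks /
    termini (NaN).
    """
    xyz = ens.coords(model_number)

    def atom(resnum, name):
        idx = np.nonzero((ens.atoms["resnum"] == resnum) & (ens.atoms["name"] == name))[0]
        return xyz[idx[0]] if len(idx) else None

    rows = []
    resnums = ens.residue_numbers()
    for r in resnums:
        n, ca, c = atom(r, "N"), atom(r, "CA"), atom(r, "C")
        c_prev = atom(r - 1, "C") if (r - 1) in resnums else None
        n_next = atom(r + 1, "N") if (r + 1) in resnums else None
        phi = dihedral(c_prev, n, ca, c) if all(
            p is not None for p in (c_prev, n, ca, c)) else math.nan
        psi = dihedral(n, ca, c, n_next) if all(
            p is not None for p in (n, ca, c, n_next)) else math.nan
        rows.append({"residue_id": int(r), "phi": phi, "psi": psi})
    return pd.DataFrame(rows)


def circular_difference(a: float, b: float) -> float:
    """Minimal absolute angular separation of two angles, in [0, 180] degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# NOE restraints


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper-bound proton(-group) distance restraint.

    Atom names may end in '#', the pseudo-atom wildcard covering all protons
    whose name starts with the stem (HB# -> HB1/HB2/HB3, HG2# -> HG21...).
    ``conformer_tag`` marks restraints compatible with only one conformer.
    """

    res1: int
    atom1: str
    res2: int
    atom2: str
    upper: float            # A
    conformer_tag: str = "shared"   # IN | OUT | shared

    def __post_init__(self) -> None:
        if self.upper <= 0:
            raise ValueError("upper bound must be positive")


@dataclass(frozen=True)
class RestraintEvaluation:
    restraint: DistanceRestraint
    distance_IN: float
    distance_OUT: float
    violation_IN: float
    violation_OUT: float
    classification: str     # IN-specific | OUT-specific | both | neither


_NAME_ALIASES = {"HN": "H"}


def expand_selection(ens: StructureEnsemble, resnum: int, atom_name: str) -> np.ndarray:
    """Atom indices matched by a (possibly pseudo-atom) selection."""
    name = _NAME_ALIASES.get(atom_name, atom_name)
    res_mask = ens.atoms["resnum"] == resnum
    names = ens.atoms["name"]
    if name.endswith("#"):
        stem = name[:-1]
        hit = res_mask & np.char.startswith(names.astype(str), stem)
    else:
        hit = res_mask & (names == name)
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        raise KeyError(f"selection {atom_name!r} of residue {resnum} matches no atom")
    return idx


def evaluate_restraint(
    restraint: DistanceRestraint, ens: StructureEnsemble, model_number: int = 1
) -> float:
    """Effective distance (A) of the restraint in one model.

    Pseudo-atom groups are r^-6 sum averaged over all proton pairs:
    d_eff = (sum d^-6)^(-1/6); a single pair reduces to the plain distance.
    """
    i1 = expand_selection(ens, restraint.res1, restraint.atom1)
    i2 = expand_selection(ens, restraint.res2, restraint.atom2)
    xyz = ens.coords(model_number)
    d = np.linalg.norm(xyz[i1][:, None, :] - xyz[i2][None, :, :], axis=2)
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


def classify_distances(
    d_in: float, d_out: float, upper: float, tolerance: float = 0.3
) -> tuple[float, float, str]:
    """Violations against both conformers and the resulting class."""
    v_in = max(0.0, d_in - upper)
    v_out = max(0.0, d_out - upper)
    ok_in, ok_out = v_in <= tolerance, v_out <= tolerance
    if ok_in and ok_out:
        cls = "both"
    elif ok_in:
        cls = "IN-specific"
    elif ok_out:
        cls = "OUT-specific"
    else:
        cls = "neither"
    return v_in, v_out, cls


def classify_conformer_specific(
    restraints: Sequence[DistanceRestraint],
    ensIN: StructureEnsemble,
    ensOUT: StructureEnsemble,
    tolerance: float = 0.3,
) -> list[RestraintEvaluation]:
    """Evaluate every restraint against the best model of each conformer."""
    out = []
    for rst in restraints:
        d_in = evaluate_restraint(rst, ensIN)
        d_out = evaluate_restraint(rst, ensOUT)
        v_in, v_out, cls = classify_distances(d_in, d_out, rst.upper, tolerance)
        out.append(RestraintEvaluation(rst, d_in, d_out, v_in, v_out, cls))
    return out


def read_restraint_table(path: str | Path) -> list[DistanceRestraint]:
    """Restraint tables: columns res1, atom1, res2, atom2, upper_A, tag."""
    df = read_table(path, line_comments_only=True)
    return [
        DistanceRestraint(
            res1=int(r.res1), atom1=str(r.atom1),
            res2=int(r.res2), atom2=str(r.atom2),
            upper=float(r.upper_A),
            conformer_tag=str(getattr(r, "tag", "shared")),
        )
        for r in df.itertuples()
    ]


def write_restraint_table(restraints, path, **kwargs) -> None:
    df = pd.DataFrame(
        [
            {"res1": r.res1, "atom1": r.atom1, "res2": r.res2, "atom2": r.atom2,
             "upper_A": r.upper, "tag": r.conformer_tag}
            for r in restraints
        ]
    )
    write_table(df, path, **kwargs)


def evaluations_to_frame(evals: Sequence[RestraintEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "res1": e.restraint.res1, "atom1": e.restraint.atom1,
                "res2": e.restraint.res2, "atom2": e.restraint.atom2,
                "upper_A": e.restraint.upper, "tag": e.restraint.conformer_tag,
                "distance_IN": e.distance_IN, "distance_OUT": e.distance_OUT,
                "difference": abs(e.distance_IN - e.distance_OUT),
                "classification": e.classification,
            }
            for e in evals
        ]
    )


# ---------------------------------------------------------------------------
# hydrogen bonds


def detect_hbonds(
    ens: StructureEnsemble,
    presence_fraction: float = 15.0 / 20.0,
    h_acceptor_max: float = 2.5,
    angle_min: float = 120.0,
) -> list[tuple[int, int]]:
    """Backbone N-H...O hydrogen bonds present in a fraction of the family.

    Geometric criterion per model: H...acceptor < 2.5 A and donor-H...acceptor
    angle > 120 deg, with backbone amide N-H donors and any oxygen acceptor.
    Returns (donor residue, acceptor residue) pairs found in at least
    ``presence_fraction`` of the models (e.g. 15 of 20).
    """
    names = ens.atoms["name"].astype(str)
    elements = np.char.upper(ens.atoms["element"].astype(str))
    resnums = ens.atoms["resnum"]
    h_idx = np.nonzero(names == "H")[0]
    o_idx = np.nonzero(elements == "O")[0]
    counts: dict[tuple[int, int], int] = {}
    for k in range(1, ens.n_models + 1):
        xyz = ens.coords(k)
        for ih in h_idx:
            rid = int(resnums[ih])
            in_idx = np.nonzero((resnums == rid) & (names == "N"))[0]
            if len(in_idx) == 0:
                continue
            hpos, npos = xyz[ih], xyz[in_idx[0]]
            dist = np.linalg.norm(xyz[o_idx] - hpos, axis=1)
            for io, d in zip(o_idx[dist < h_acceptor_max], dist[dist < h_acceptor_max]):
                if int(resnums[io]) == rid:
                    continue
                v1 = npos - hpos
                v2 = xyz[io] - hpos
                cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if ang > angle_min:
                    key = (rid, int(resnums[io]))
                    counts[key] = counts.get(key, 0) + 1
    needed = presence_fraction * ens.n_models
    return sorted(k for k, c in counts.items() if c >= needed)


# ---------------------------------------------------------------------------
# buried surface (Shrake-Rupley)

_SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


def _sphere_points(n: int) -> np.ndarray:
    # golden-spiral quasi-uniform points on the unit sphere
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_UNIT_SPHERE = _sphere_points(N_SPHERE_POINTS)


def sasa(xyz: np.ndarray, elements: Sequence[str], probe: float = PROBE_RADIUS) -> np.ndarray:
    """Per-atom solvent-accessible surface (A^2), heavy atoms only.

    Shrake-Rupley sphere sampling with 960 points per atom and standard
    heavy-atom radii; hydrogens must be filtered out by the caller.
    """
    xyz = np.asarray(xyz, dtype=float)
    radii = np.array([_SASA_RADII.get(str(e).upper(), 1.70) for e in elements]) + probe
    n = len(xyz)
    areas = np.zeros(n)
    for i in range(n):
        pts = xyz[i] + radii[i] * _UNIT_SPHERE
        accessible = np.ones(len(pts), dtype=bool)
        d2 = np.sum((xyz - xyz[i]) ** 2, axis=1)
        neigh = np.nonzero((d2 < (radii + radii[i]) ** 2) & (d2 > 0))[0]
        for j in neigh:
            accessible &= np.sum((pts - xyz[j]) ** 2, axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return areas


def buried_surface(
    ens: StructureEnsemble,
    groupA: np.ndarray,
    groupB: np.ndarray,
    model_number: int = 1,
) -> float:
    """Buried interface area (A^2) between two disjoint atom groups.

    (SASA_A + SASA_B - SASA_AB)/2, each term from a Shrake-Rupley calculation
    of that group in isolation (hydrogens ignored).
    """
    groupA = np.asarray(groupA, dtype=bool)
    groupB = np.asarray(groupB, dtype=bool)
    if (groupA & groupB).any():
        raise ValueError("groups must be disjoint")
    heavy = ens.mask("heavy")
    a = groupA & heavy
    b = groupB & heavy
    xyz = ens.coords(model_number)
    el = ens.atoms["element"]

    def total(mask):
        return float(sasa(xyz[mask], el[mask]).sum())

    return (total(a) + total(b) - total(a | b)) / 2.0
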