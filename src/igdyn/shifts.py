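"""Chemical-shift classification rules and assignment-completeness statistics.

Two empirical classifiers and one bookkeeping tool:

* proline cis/trans from the Cbeta-Cgamma shift difference, using the
  published population statistics (trans: 4.51 +/- 1.37 ppm, cis:
  9.64 +/- 1.62 ppm) and a nearest-distribution (smallest z) call;
* cysteine redox state from the Cbeta shift (reduced < 32 ppm,
  oxidised > 35 ppm, ambiguous between);
* assignment completeness per nucleus against a documented atom inventory
  (fast-exchanging OH/SH and Lys NH3+ protons excluded; each Arg guanidinium
  NH2 group counts as one observable entity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import read_table

TRANS_MEAN, TRANS_SD = 4.51, 1.37
CIS_MEAN, CIS_SD = 9.64, 1.62
AMBIGUITY_Z = 3.0

CYS_REDUCED_MAX = 32.0   # ppm Cbeta
CYS_OXIDIZED_MIN = 35.0


@dataclass(frozen=True)
class ShiftRecord:
    residue_number: int
    residue_name: str    # 3-letter
    atom_name: str
    shift: float         # ppm

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift):
            raise ValueError("shift must be finite")


def proline_isomer(cb: float, cg: float) -> tuple[float, str]:
    """Classify a proline as cis or trans from its Cbeta/Cgamma shifts.

    Returns (delta, call) with delta = cb - cg in ppm; the call is the class
    whose population mean is nearest in units of its own standard deviation,
    or 'ambiguous' when delta is more than 3 sd from both.
    """
    delta = cb - cg
    z_trans = abs(delta - TRANS_MEAN) / TRANS_SD
    z_cis = abs(delta - CIS_MEAN) / CIS_SD
    if z_trans > AMBIGUITY_Z and z_cis > AMBIGUITY_Z:
        return delta, "ambiguous"
    return delta, ("trans" if z_trans <= z_cis else "cis")


def cysteine_redox(cb: float) -> str:
    """Reduced/oxidised call from the cysteine Cbeta shift."""
    if cb < CYS_REDUCED_MAX:
        return "reduced"
    if cb > CYS_OXIDIZED_MIN:
        return "oxidized"
    return "ambiguous"


# ---------------------------------------------------------------------------
# assignment completeness
#
# Observable-atom inventory per residue type.  Entities are what gets counted:
# most map to a single atom; degenerate groups that carry one observable shift
# value (Arg NH2 pairs) map several atom names onto one entity.  Excluded
# entirely: OH (Ser/Thr/Tyr), SH (Cys), Lys NH3+ protons and NZ.

def _atoms(h: str, c: str, n: str) -> dict:
    inv: dict[str, tuple[str, tuple[str, ...]]] = {}
    for nucleus, spec in (("H", h), ("C", c), ("N", n)):
        for token in spec.split():
            if "/" in token:   # grouped names -> one entity, e.g. HH11/HH12
                members = tuple(token.split("/"))
                inv[members[0] + "#"] = (nucleus, members)
            else:
                inv[token] = (nucleus, (token,))
    return inv


ATOM_INVENTORY: dict[str, dict] = {
    "ALA": _atoms("H HA HB1 HB2 HB3", "C CA CB", "N"),
    "ARG": _atoms("H HA HB2 HB3 HG2 HG3 HD2 HD3 HE HH11/HH12 HH21/HH22",
                  "C CA CB CG CD CZ", "N NE NH1 NH2"),
    "ASN": _atoms("H HA HB2 HB3 HD21 HD22", "C CA CB CG", "N ND2"),
    "ASP": _atoms("H HA HB2 HB3", "C CA CB CG", "N"),
    "CYS": _atoms("H HA HB2 HB3", "C CA CB", "N"),
    "GLN": _atoms("H HA HB2 HB3 HG2 HG3 HE21 HE22", "C CA CB CG CD", "N NE2"),
    "GLU": _atoms("H HA HB2 HB3 HG2 HG3", "C CA CB CG CD", "N"),
    "GLY": _atoms("H HA2 HA3", "C CA", "N"),
    "HIS": _atoms("H HA HB2 HB3 HD2 HE1", "C CA CB CG CD2 CE1", "N ND1 NE2"),
    "ILE": _atoms("H HA HB HG12 HG13 HG21 HG22 HG23 HD11 HD12 HD13",
                  "C CA CB CG1 CG2 CD1", "N"),
    "LEU": _atoms("H HA HB2 HB3 HG HD11 HD12 HD13 HD21 HD22 HD23",
                  "C CA CB CG CD1 CD2", "N"),
    "LYS": _atoms("H HA HB2 HB3 HG2 HG3 HD2 HD3 HE2 HE3",
                  "C CA CB CG CD CE", "N"),
    "MET": _atoms("H HA HB2 HB3 HG2 HG3 HE1 HE2 HE3", "C CA CB CG CE", "N"),
    "PHE": _atoms("H HA HB2 HB3 HD1 HD2 HE1 HE2 HZ",
                  "C CA CB CG CD1 CD2 CE1 CE2 CZ", "N"),
    "PRO": _atoms("HA HB2 HB3 HG2 HG3 HD2 HD3", "C CA CB CG CD", "N"),
    "SER": _atoms("H HA HB2 HB3", "C CA CB", "N"),
    "THR": _atoms("H HA HB HG21 HG22 HG23", "C CA CB CG2", "N"),
    "TRP": _atoms("H HA HB2 HB3 HD1 HE1 HE3 HZ2 HZ3 HH2",
                  "C CA CB CG CD1 CD2 CE2 CE3 CZ2 CZ3 CH2", "N NE1"),
    "TYR": _atoms("H HA HB2 HB3 HD1 HD2 HE1 HE2",
                  "C CA CB CG CD1 CD2 CE1 CE2 CZ", "N"),
    "VAL": _atoms("H HA HB HG11 HG12 HG13 HG21 HG22 HG23",
                  "C CA CB CG1 CG2", "N"),
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _entity_for(resname: str, atom_name: str) -> str | None:
    inv = ATOM_INVENTORY[resname]
    if atom_name in inv:
        return atom_name
    for entity, (_, members) in inv.items():
        if atom_name in members:
            return entity
    return None


def completeness(shifts: list[ShiftRecord], sequence: str) -> dict:
    """Percent of observable atoms assigned, per nucleus and overall.

    *sequence* is a one-letter string; residue numbers in *shifts* are 1-based
    positions in it.  Shifts for atoms outside the inventory (exchangeable
    protons, unknown names) are excluded with a warning.
    """
    theoretical = {"H": 0, "C": 0, "N": 0}
    for letter in sequence:
        resname = ONE_TO_THREE[letter.upper()]
        for nucleus, _ in ATOM_INVENTORY[resname].values():
            theoretical[nucleus] += 1

    assigned: dict[str, set] = {"H": set(), "C": set(), "N": set()}
    for rec in shifts:
        if not 1 <= rec.residue_number <= len(sequence):
            raise ValueError(f"residue {rec.residue_number} outside the sequence")
        resname = ONE_TO_THREE[sequence[rec.residue_number - 1].upper()]
        entity = _entity_for(resname, rec.atom_name)
        if entity is None:
            warnings.warn(
                f"shift for {resname}{rec.residue_number} {rec.atom_name} "
                "is not in the atom inventory; excluded"
            )
            continue
        nucleus = ATOM_INVENTORY[resname][entity][0]
        assigned[nucleus].add((rec.residue_number, entity))

    result = {}
    for nucleus in ("H", "C", "N"):
        total = theoretical[nucleus]
        result[nucleus] = 100.0 * len(assigned[nucleus]) / total if total else 0.0
    grand_total = sum(theoretical.values())
    grand_assigned = sum(len(v) for v in assigned.values())
    result["overall"] = 100.0 * grand_assigned / grand_total if grand_total else 0.0
    return result


def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Shift tables: columns residue_number, residue_name, atom_name, ppm."""
    df = read_table(path)
    return [
        ShiftRecord(int(r.residue_number), str(r.residue_name),
                    str(r.atom_name), float(r.ppm))
        for r in df.itertuples()
    ]


def classify_prolines(shifts: list[ShiftRecord]) -> pd.DataFrame:
    """Apply proline_isomer to every proline with both CB and CG assigned."""
    by_res: dict[int, dict[str, float]] = {}
    for rec in shifts:
        if rec.residue_name.upper() == "PRO" and rec.atom_name in ("CB", "CG"):
            by_res.setdefault(rec.residue_number, {})[rec.atom_name] = rec.shift
    rows = []
    for resnum in sorted(by_res):
        pair = by_res[resnum]
        if "CB" not in pair or "CG" not in pair:
            continue   # no call without both shifts
        delta, call = proline_isomer(pair["CB"], pair["CG"])
        rows.append({"residue_number": resnum, "CB": pair["CB"], "CG": pair["CG"],
                     "delta": delta, "call": call})
    return pd.DataFrame(rows)
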