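"""Bundled reference tables for murine titin domain I82.

Small published data tables that the analysis consumes directly: proline
Cbeta/Cgamma shifts (BMRB 34980/34981), the conformer-specific EF-loop NOE
distances against the deposited IN/OUT conformers (PDB 9IBI/9IBK), and the
EF-loop backbone dihedrals of the two conformers.  The deposited coordinate
files themselves are not bundled; functions that need them take a path.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_table


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("igdyn") / "data" / name) as path:
        return read_table(path)


def i82_proline_shifts() -> pd.DataFrame:
    """Proline CB/CG shifts (ppm): columns residue_number, residue_name, CB, CG."""
    return _load("i82_proline_shifts.tsv")


def i82_ef_loop_restraints() -> pd.DataFrame:
    """Conformer-specific NOE restraints with distances in both conformers.

    Columns: tag (IN|OUT), atom1, res1, atom2, res2, upper_A, d_in, d_out.
    """
    return _load("i82_ef_loop_restraints.tsv")


def i82_ef_loop_dihedrals() -> pd.DataFrame:
    """EF-loop phi/psi angles (degrees) in the IN and OUT conformers."""
    return _load("i82_ef_loop_dihedrals.tsv")
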