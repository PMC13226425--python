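"""Exponential decay fitting and heteronuclear-NOE ratios.

Converts raw peak-volume series from pseudo-3D T1/T2 experiments into R1/R2
rates with standard errors from the nonlinear-fit covariance, and computes
1H-15N NOE values as saturated/reference volume ratios with the
replicate-difference error convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import read_table, write_table

# Inversion-recovery / CPMG relaxation delays (s) of the I82 experiments;
# convenient defaults for simulation and examples.
T1_DELAYS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.80, 1.20, 1.50)
T2_DELAYS = (0.01696, 0.03392, 0.05088, 0.06784, 0.0848,
             0.10176, 0.11872, 0.13568, 0.15264, 0.1696)


@dataclass(frozen=True)
class DecaySeries:
    """Peak volumes of one residue as a function of relaxation delay."""

    residue_id: int
    delays: tuple    # s
    volumes: tuple   # arbitrary units

    def __post_init__(self) -> None:
        if len(self.delays) != len(self.volumes):
            raise ValueError("delays and volumes must have the same length")
        if len(set(self.delays)) < 3:
            raise ValueError("need at least 3 distinct delays")
        if not all(math.isfinite(v) for v in self.volumes):
            raise ValueError("volumes must be finite")


@dataclass
class RelaxationRecord:
    """Per-residue relaxation observables; any observable may be missing (None)."""

    residue_id: int
    R1: float | None = None
    R1_err: float | None = None
    R2: float | None = None
    R2_err: float | None = None
    NOE: float | None = None
    NOE_err: float | None = None

    def __post_init__(self) -> None:
        for value, err, name in (
            (self.R1, self.R1_err, "R1"),
            (self.R2, self.R2_err, "R2"),
        ):
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when present")
            if err is not None and err < 0:
                raise ValueError(f"{name}_err must be non-negative")
        if self.NOE_err is not None and self.NOE_err < 0:
            raise ValueError("NOE_err must be non-negative")

    @property
    def complete(self) -> bool:
        return None not in (self.R1, self.R2, self.NOE)


class FitFailure:
    """Marker for a residue whose decay could not be fitted."""

    def __init__(self, residue_id: int, reason: str):
        self.residue_id = residue_id
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover
        return f"FitFailure(residue {self.residue_id}: {self.reason})"


def fit_exponential(series: DecaySeries) -> tuple[float, float] | FitFailure:
    """Fit V(t) = V0 exp(-R t); return (R, sigma_R) in s^-1.

    The fit is nonlinear least squares.  V0 starts from the first point and R
    from a two-point log estimate, which keeps the optimiser robust when the
    tail of the decay is noisy.  Non-convergence or a non-positive fitted rate
    is reported as a :class:`FitFailure`, never as an exception, so batch
    processing of a full residue table does not abort.
    """
    t = np.asarray(series.delays, dtype=float)
    v = np.asarray(series.volumes, dtype=float)
    order = np.argsort(t)
    t, v = t[order], v[order]

    v0_init = v[0]
    if v0_init == 0 or v[-1] == 0 or v[0] * v[-1] <= 0:
        r_init = 1.0 / max(t[-1] - t[0], 1e-6)
    else:
        r_init = math.log(abs(v[0] / v[-1])) / (t[-1] - t[0])
    r_init = max(r_init, 1e-3)

    try:
        popt, pcov = curve_fit(
            lambda tt, v0, r: v0 * np.exp(-r * tt),
            t, v, p0=(v0_init, r_init), maxfev=10000,
        )
    except RuntimeError as exc:
        return FitFailure(series.residue_id, f"no convergence: {exc}")
    rate = popt[1]
    if not (math.isfinite(rate) and rate > 0):
        return FitFailure(series.residue_id, f"non-positive fitted rate {rate:.3g}")
    sigma = math.sqrt(pcov[1, 1]) if np.isfinite(pcov[1, 1]) else 0.0
    return rate, sigma


def compute_hetnoe(
    sat_volume: float,
    ref_volume: float,
    sat_volume_rep: float,
    ref_volume_rep: float,
) -> tuple[float, float] | FitFailure:
    """NOE = sat/ref; sigma = |NOE - NOE_replicate|.

    Volumes may be negative (mobile termini invert the saturated peak); only a
    zero reference volume is an error.
    """
    if ref_volume == 0 or ref_volume_rep == 0:
        return FitFailure(-1, "zero reference volume")
    noe = sat_volume / ref_volume
    noe_rep = sat_volume_rep / ref_volume_rep
    return noe, abs(noe - noe_rep)


# ---------------------------------------------------------------------------
# batch driver and table I/O

def fit_decay_table(df: pd.DataFrame) -> list[RelaxationRecord]:
    """Turn a long-format decay/NOE table into RelaxationRecords.

    Expected columns: residue_id, delay_s, volume, experiment_tag with tags
    t1 | t2 | noe_sat | noe_ref | noe_sat_rep | noe_ref_rep.  For the NOE tags
    the delay column is ignored.  Residues with unusable data (fewer than
    3 points, failed fits, zero NOE reference) get missing fields.
    """
    records: dict[int, RelaxationRecord] = {}
    for rid, sub in df.groupby("residue_id"):
        rec = RelaxationRecord(residue_id=int(rid))
        for tag, attr in (("t1", "R1"), ("t2", "R2")):
            rows = sub[sub.experiment_tag == tag]
            if len(rows) < 3:
                continue
            try:
                series = DecaySeries(int(rid), tuple(rows.delay_s), tuple(rows.volume))
            except ValueError:
                continue
            result = fit_exponential(series)
            if not isinstance(result, FitFailure):
                setattr(rec, attr, result[0])
                setattr(rec, attr + "_err", result[1])
        vols = {}
        for tag in ("noe_sat", "noe_ref", "noe_sat_rep", "noe_ref_rep"):
            rows = sub[sub.experiment_tag == tag]
            if len(rows) == 1:
                vols[tag] = float(rows.volume.iloc[0])
        if len(vols) == 4:
            result = compute_hetnoe(
                vols["noe_sat"], vols["noe_ref"],
                vols["noe_sat_rep"], vols["noe_ref_rep"],
            )
            if not isinstance(result, FitFailure):
                rec.NOE, rec.NOE_err = result
        records[int(rid)] = rec
    return [records[rid] for rid in sorted(records)]


def read_decay_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"residue_id", "delay_s", "volume", "experiment_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def records_to_frame(records: Iterable[RelaxationRecord]) -> pd.DataFrame:
    rows = [
        {
            "residue_id": r.residue_id,
            "R1": r.R1, "R1_err": r.R1_err,
            "R2": r.R2, "R2_err": r.R2_err,
            "NOE": r.NOE, "NOE_err": r.NOE_err,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=[
        "residue_id", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err",
    ])


def frame_to_records(df: pd.DataFrame) -> list[RelaxationRecord]:
    def _get(row, col):
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    return [
        RelaxationRecord(
            residue_id=int(row["residue_id"]),
            R1=_get(row, "R1"), R1_err=_get(row, "R1_err"),
            R2=_get(row, "R2"), R2_err=_get(row, "R2_err"),
            NOE=_get(row, "NOE"), NOE_err=_get(row, "NOE_err"),
        )
        for _, row in df.iterrows()
    ]


def write_relaxation_table(
    records: Sequence[RelaxationRecord], path: str | Path, **kwargs
) -> None:
    write_table(records_to_frame(records), path, **kwargs)


def read_relaxation_table(path: str | Path) -> list[RelaxationRecord]:
    return frame_to_records(read_table(path))
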