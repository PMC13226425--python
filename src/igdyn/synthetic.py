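"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised offline: mono-exponential decay
series with multiplicative noise, per-residue relaxation profiles shaped like
a small Ig domain (rigid core, highly mobile termini with negative NOEs, an
exchange-broadened loop), toy two-conformer ensembles with restraint sets
compatible with only one conformer each, and proline shift tables drawn from
the published trans/cis difference distributions.  Ground truth always
accompanies generated observables.  All generators take an explicit seed and
are bit-reproducible; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .decay_fitting import DecaySeries, RelaxationRecord
from .shifts import ShiftRecord
from .spin_physics import FieldContext, MotionalParameters, back_calculate_rates, make_field
from .structure import DistanceRestraint, StructureEnsemble, evaluate_restraint


def gen_decay(
    rate: float,
    delays,
    v0: float = 1000.0,
    noise_frac: float = 0.0,
    seed: int = 0,
    residue_id: int = 1,
) -> DecaySeries:
    """Mono-exponential decay with multiplicative Gaussian noise.

    volumes = v0 * exp(-rate * t) * (1 + eps), eps ~ N(0, noise_frac).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(delays, dtype=float)
    v = v0 * np.exp(-rate * t)
    if noise_frac > 0:
        v = v * (1.0 + rng.normal(0.0, noise_frac, size=len(t)))
    return DecaySeries(residue_id, tuple(t), tuple(v))


@dataclass(frozen=True)
class SyntheticProfile:
    """Study conditions for an I82-like relaxation dataset.

    Defaults mimic the observed profile of the domain: a rigid core
    (S2 ~ 0.85 +/- 0.03), disordered termini with low order parameters and
    sub-ns internal motion (giving negative heteronuclear NOEs at 800 MHz),
    and an exchange-broadened five-residue loop (Rex of several 1/s), all
    tumbling at tau_c = 6.6 ns.  Rate noise is fractional, NOE noise absolute.
    """

    n_residues: int = 102
    core_S2: tuple = (0.85, 0.03)
    termini: tuple = ((1, 6), (95, 102))
    termini_S2: float = 0.2
    termini_tau_e: float = 400e-12   # s; sub-ns, so terminal NOEs go negative
                                     # while R1 still exceeds the core value
    rex_loop: tuple = (73, 77)
    rex_range: tuple = (3.0, 10.0)    # s^-1, uniform
    loop_S2: tuple = (0.80, 0.03)
    tau_c: float = 6.6                # ns
    field_MHz: float = 800.13
    noise_rate_frac: float = 0.02
    noise_noe: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (*self.termini, self.rex_loop):
            if not 1 <= lo <= hi <= self.n_residues:
                raise ValueError("region ranges must lie within [1, n_residues]")
        if self.noise_rate_frac < 0 or self.noise_noe < 0:
            raise ValueError("noise levels must be non-negative")


def _region(profile: SyntheticProfile, resid: int) -> str:
    for lo, hi in profile.termini:
        if lo <= resid <= hi:
            return "terminus"
    lo, hi = profile.rex_loop
    if lo <= resid <= hi:
        return "rex_loop"
    return "core"


def gen_relaxation_dataset(
    profile: SyntheticProfile | None = None,
) -> tuple[list[RelaxationRecord], pd.DataFrame]:
    """Per-residue relaxation records plus the generating ground truth.

    Motional parameters are drawn per region, observables back-calculated
    through the spin physics and then noised; reported errors equal the
    generating noise levels.  The truth table carries residue_id, region,
    model, S2, tau_e_s, Rex and the noise-free observables.
    """
    profile = profile or SyntheticProfile()
    rng = np.random.default_rng(profile.seed)
    field = make_field(profile.field_MHz)
    tau_c_s = profile.tau_c * 1e-9

    records, truth = [], []
    for resid in range(1, profile.n_residues + 1):
        region = _region(profile, resid)
        if region == "terminus":
            params = MotionalParameters(
                3, S2=profile.termini_S2, tau_e=profile.termini_tau_e)
        elif region == "rex_loop":
            s2 = float(np.clip(rng.normal(*profile.loop_S2), 0.0, 1.0))
            rex = float(rng.uniform(*profile.rex_range))
            params = MotionalParameters(2, S2=s2, R_ex=rex)
        else:
            s2 = float(np.clip(rng.normal(*profile.core_S2), 0.0, 1.0))
            params = MotionalParameters(1, S2=s2)
        rates = back_calculate_rates(params, tau_c_s, field)

        r1 = rates.R1 * (1.0 + rng.normal(0.0, profile.noise_rate_frac)) \
            if profile.noise_rate_frac else rates.R1
        r2 = rates.R2 * (1.0 + rng.normal(0.0, profile.noise_rate_frac)) \
            if profile.noise_rate_frac else rates.R2
        noe = rates.NOE + (rng.normal(0.0, profile.noise_noe)
                           if profile.noise_noe else 0.0)
        records.append(RelaxationRecord(
            residue_id=resid,
            R1=max(r1, 1e-6), R1_err=profile.noise_rate_frac * rates.R1,
            R2=max(r2, 1e-6), R2_err=profile.noise_rate_frac * rates.R2,
            NOE=noe, NOE_err=profile.noise_noe,
        ))
        truth.append({
            "residue_id": resid, "region": region, "model": params.model_id,
            "S2": params.S2, "tau_e_s": params.tau_e, "Rex": params.R_ex,
            "R1_true": rates.R1, "R2_true": rates.R2, "NOE_true": rates.NOE,
        })
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# axially symmetric relaxation data (for diffusion-tensor recovery tests)


def gen_axial_relaxation(
    d_iso: float,
    d_ratio: float,
    axis: np.ndarray,
    n_residues: int = 60,
    noise_frac: float = 0.0,
    seed: int = 0,
    field: FieldContext | None = None,
) -> tuple[list[RelaxationRecord], dict[int, np.ndarray]]:
    """Rigid-limit records under an axially symmetric tensor plus N-H vectors.

    N-H orientations are quasi-uniform on the sphere; NOE is set to the rigid
    isotropic value so the records pass the diffusion-fit NOE filter.
    """
    from .diffusion import _axial_spectral_density
    from .structure import _sphere_points

    field = field or make_field()
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    d_par = 3.0 * d_iso * d_ratio / (2.0 + d_ratio)
    d_perp = d_par / d_ratio
    rng = np.random.default_rng(seed)
    vecs = _sphere_points(n_residues)

    wh, wn = field.omega_H, field.omega_N
    records, nh = [], {}
    for i, v in enumerate(vecs, start=1):
        theta = float(np.arccos(np.clip(v @ axis, -1.0, 1.0)))
        j = {w: _axial_spectral_density(w, theta, d_par, d_perp)
             for w in (0.0, wn, wh, wh - wn, wh + wn)}
        d2, c2 = field.d2, field.c2
        r1 = d2 / 4.0 * (j[wh - wn] + 3.0 * j[wn] + 6.0 * j[wh + wn]) + c2 * j[wn]
        r2 = (d2 / 8.0 * (4.0 * j[0.0] + j[wh - wn] + 3.0 * j[wn]
                          + 6.0 * j[wh] + 6.0 * j[wh + wn])
              + c2 / 6.0 * (4.0 * j[0.0] + 3.0 * j[wn]))
        if noise_frac:
            r1 *= 1.0 + rng.normal(0.0, noise_frac)
            r2 *= 1.0 + rng.normal(0.0, noise_frac)
        records.append(RelaxationRecord(
            residue_id=i, R1=r1, R1_err=noise_frac * r1 or 1e-3 * r1,
            R2=r2, R2_err=noise_frac * r2 or 1e-3 * r2,
            NOE=0.8, NOE_err=0.02,
        ))
        nh[i] = v
    return records, nh


# ---------------------------------------------------------------------------
# toy two-conformer ensemble


def _frame(t_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = t_raw / np.linalg.norm(t_raw)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, t)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return t, u, v


def _build_chain(ca: np.ndarray, ca_frame: np.ndarray | None = None) -> tuple[dict, np.ndarray]:
    """Alanine-like residues around given CA positions (toy geometry).

    Local frames come from *ca_frame* (default: *ca* itself); passing a
    conformer-independent path keeps atoms of unmoved residues identical
    across conformers.
    """
    n = len(ca)
    if ca_frame is None:
        ca_frame = ca
    atoms = {"chain": [], "resnum": [], "resname": [], "name": [], "element": []}
    coords = []

    def add(resnum, name, element, pos):
        atoms["chain"].append("A")
        atoms["resnum"].append(resnum)
        atoms["resname"].append("ALA")
        atoms["name"].append(name)
        atoms["element"].append(element)
        coords.append(pos)

    for i in range(n):
        prev_ca = ca_frame[i - 1] if i > 0 else ca_frame[i] - (ca_frame[i + 1] - ca_frame[i])
        next_ca = ca_frame[i + 1] if i < n - 1 else ca_frame[i] + (ca_frame[i] - ca_frame[i - 1])
        t, u, v = _frame(next_ca - prev_ca)
        r = i + 1
        npos = ca[i] - 1.2 * t + 0.6 * u
        cpos = ca[i] + 1.2 * t + 0.6 * u
        add(r, "N", "N", npos)
        add(r, "H", "H", npos + 1.0 * u)
        add(r, "CA", "C", ca[i])
        add(r, "HA", "H", ca[i] - 1.09 * v)
        add(r, "CB", "C", ca[i] + 1.53 * v)
        for k, dvec in enumerate((t, -t, u), start=1):
            hb = ca[i] + 1.53 * v + 1.09 * (0.5 * v + 0.866 * dvec / np.linalg.norm(dvec))
            add(r, f"HB{k}", "H", hb)
        add(r, "C", "C", cpos)
        add(r, "O", "O", cpos + 1.23 * u)
    return atoms, np.array(coords)


LOOP_RESIDUES = (7, 8, 9, 10, 11)
_N_RES = 15
_N_MODELS = 10
_JITTER = 0.02     # A, family spread around the best model
UPPER_MARGIN = 0.2  # A added to the true distance when deriving an upper bound


def _ca_trace(direction: float) -> np.ndarray:
    """CA path: two antiparallel segments joined by a 5-residue loop bulging
    towards +z (direction=+1, OUT) or -z (direction=-1, IN)."""
    ca = np.zeros((_N_RES, 3))
    for i in range(6):                       # residues 1-6
        ca[i] = (3.8 * i, 0.0, 0.0)
    bump = np.array([1.0, 2.0, 2.5, 2.0, 1.0]) * direction
    for k in range(5):                       # loop residues 7-11
        frac = (k + 1) / 6.0
        ca[6 + k] = (19.0 + 3.0 * np.sin(np.pi * frac),
                     4.8 * frac,
                     bump[k])
    for i in range(4):                       # residues 12-15
        ca[11 + i] = (19.0 - 3.8 * (i + 1), 4.8, 0.0)
    return ca


def gen_two_conformer_ensemble(seed: int = 0) -> tuple[
    StructureEnsemble, StructureEnsemble,
    list[DistanceRestraint], list[DistanceRestraint], list[DistanceRestraint],
]:
    """Toy IN/OUT ensembles of a 15-residue scaffold with a flipped loop.

    Returns (ensIN, ensOUT, shared, in_specific, out_specific) restraint
    lists.  The loop (residues 7-11) bulges to opposite sides of the scaffold
    in the two conformers (central CA displaced by 5 A); restraint upper
    bounds are the true distance in the compatible conformer plus 0.2 A, so
    each conformer-specific set is satisfied only in its own ensemble.
    """
    rng = np.random.default_rng(seed)
    ensembles = {}
    base_path = _ca_trace(0.0)
    for tag, direction in (("IN", -1.0), ("OUT", +1.0)):
        atoms, best = _build_chain(_ca_trace(direction), ca_frame=base_path)
        xyz = [best] + [
            best + rng.normal(0.0, _JITTER, size=best.shape)
            for _ in range(_N_MODELS - 1)
        ]
        ensembles[tag] = StructureEnsemble(
            atoms, np.stack(xyz), source_id=f"synthetic-{tag}-seed{seed}")
    ens_in, ens_out = ensembles["IN"], ensembles["OUT"]

    loop = set(LOOP_RESIDUES)
    scaffold = [r for r in range(1, _N_RES + 1) if r not in loop]
    proton_sels = ["H", "HA", "HB#"]

    def distances(res1, a1, res2, a2):
        rst = DistanceRestraint(res1, a1, res2, a2, upper=99.0)
        return (evaluate_restraint(rst, ens_in), evaluate_restraint(rst, ens_out))

    shared, in_specific, out_specific = [], [], []
    for lr in loop:
        for la in proton_sels:
            for sr in scaffold:
                for sa in proton_sels:
                    d_in, d_out = distances(lr, la, sr, sa)
                    if d_in <= 4.5 and d_out - d_in >= 1.0:
                        in_specific.append(DistanceRestraint(
                            lr, la, sr, sa, upper=d_in + UPPER_MARGIN,
                            conformer_tag="IN"))
                    elif d_out <= 4.5 and d_in - d_out >= 1.0:
                        out_specific.append(DistanceRestraint(
                            lr, la, sr, sa, upper=d_out + UPPER_MARGIN,
                            conformer_tag="OUT"))
    # scaffold-scaffold contacts are conformation independent
    for i, r1 in enumerate(scaffold):
        for r2 in scaffold[i + 1:]:
            d_in, d_out = distances(r1, "HA", r2, "HA")
            if max(d_in, d_out) <= 5.5 and abs(d_in - d_out) < 0.05:
                shared.append(DistanceRestraint(
                    r1, "HA", r2, "HA",
                    upper=max(d_in, d_out) + UPPER_MARGIN, conformer_tag="shared"))
    return ens_in, ens_out, shared, in_specific, out_specific


def gen_shift_table(
    n_trans: int, n_cis: int, seed: int = 0
) -> tuple[list[ShiftRecord], pd.DataFrame]:
    """Proline CB/CG shift pairs drawn from the trans/cis difference Normals.

    Returns the shift records (two per proline) and a truth table with the
    generating isomer per residue.
    """
    from .shifts import CIS_MEAN, CIS_SD, TRANS_MEAN, TRANS_SD

    if n_trans < 0 or n_cis < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    records, truth = [], []
    labels = ["trans"] * n_trans + ["cis"] * n_cis
    for resnum, label in enumerate(labels, start=1):
        cg = rng.normal(27.0, 0.5)
        if label == "trans":
            delta = rng.normal(TRANS_MEAN, TRANS_SD)
        else:
            delta = rng.normal(CIS_MEAN, CIS_SD)
        records.append(ShiftRecord(resnum, "PRO", "CB", cg + delta))
        records.append(ShiftRecord(resnum, "PRO", "CG", cg))
        truth.append({"residue_number": resnum, "isomer": label, "delta": delta})
    return records, pd.DataFrame(truth, columns=["residue_number", "isomer", "delta"])
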