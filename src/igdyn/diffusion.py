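"""Global rotational diffusion from 15N R2/R1 ratios and molecular shape.

The overall tumbling of the domain is characterised three ways, mirroring the
classical workflow (pdbinertia / r2r1_diffusion):

* per-residue apparent correlation times from inverting the rigid-limit
  R2/R1 ratio;
* a one-parameter spherical (isotropic) fit of all ratios for residues with
  heteronuclear NOE above a cutoff (default 0.6), yielding tau_c;
* a four-parameter axially symmetric tensor fit (D_iso, D_par/D_perp and the
  polar angles of the unique axis), searched with the quadric local-diffusion
  approximation and refined/scored against the full three-exponential axially
  symmetric spectral density.

A nested F-test decides whether the axial model improves on the sphere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize, stats

from .decay_fitting import RelaxationRecord
from .spin_physics import FieldContext, MotionalParameters, back_calculate_rates

_RIGID = MotionalParameters(model_id=1, S2=1.0)

TAU_BRACKET_NS = (0.1, 50.0)

# atomic masses for the inertia tensor (heavy atoms only)
_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
           "SE": 78.971}


@dataclass(frozen=True)
class DiffusionModel:
    """Fitted global-tumbling description with its goodness of fit."""

    kind: str                   # "sphere" | "axial"
    tau_c: float                # ns (isotropic equivalent: 1/(6 D_iso))
    chi2: float
    n_residues: int
    n_params: int
    tau_c_err: float = 0.0      # ns, sphere only
    D_iso: float | None = None  # s^-1
    D_ratio: float | None = None
    axis_polar_angles: tuple | None = None  # (theta, phi) degrees

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "axial"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.chi2 < 0 or self.tau_c <= 0:
            raise ValueError("chi2 must be >= 0 and tau_c > 0")
        expected = 1 if self.kind == "sphere" else 4
        if self.n_params != expected:
            raise ValueError(f"{self.kind} model must have {expected} parameters")


@dataclass(frozen=True)
class PrincipalAxes:
    """Inertia-tensor summary of a model's shape.

    ``moments`` are the principal moments of inertia sorted descending and
    ``ratios`` the same normalised to the largest (1.00 first) — the
    convention in which an elongated Ig domain reads ~1.00:0.98:0.55.
    ``semi_axes`` are the equivalent uniform-ellipsoid semi-axes (largest
    first, normalised to 1.00).
    """

    moments: tuple
    ratios: tuple
    semi_axes: tuple
    axes: np.ndarray = dc_field(repr=False, default=None)  # rows = principal axes


def _rigid_rates(tau_c_s: float, field: FieldContext):
    return back_calculate_rates(_RIGID, tau_c_s, field)


def _rigid_ratio(tau_c_ns: float, field: FieldContext) -> float:
    rates = _rigid_rates(tau_c_ns * 1e-9, field)
    return rates.R2 / rates.R1


def residue_tauc(record: RelaxationRecord, field: FieldContext) -> float | None:
    """Apparent rotational correlation time (ns) from one residue's R2/R1.

    Solves R2(tau)/R1(tau) = R2_obs/R1_obs under S2 = 1, Rex = 0, bracketed in
    [0.1, 50] ns.  Returns None when the observed ratio is outside the range
    achievable in the bracket (the residue is then excluded upstream).
    """
    if record.R1 is None or record.R2 is None:
        raise ValueError(f"residue {record.residue_id}: R1 and R2 required")
    target = record.R2 / record.R1
    lo, hi = TAU_BRACKET_NS
    f = lambda tau: _rigid_ratio(tau, field) - target
    if f(lo) > 0 or f(hi) < 0:   # ratio is monotone increasing in tau
        return None
    return optimize.brentq(f, lo, hi, xtol=1e-6)


def _usable(records, field, noe_cutoff):
    """Records entering a diffusion fit: complete, NOE above cutoff, ratio invertible."""
    out = []
    for rec in records:
        if not rec.complete or rec.NOE <= noe_cutoff:
            continue
        if residue_tauc(rec, field) is None:
            continue
        out.append(rec)
    return out


def _ratio_and_sigma(rec: RelaxationRecord):
    ratio = rec.R2 / rec.R1
    r1e = rec.R1_err or 0.0
    r2e = rec.R2_err or 0.0
    sigma = ratio * math.sqrt((r1e / rec.R1) ** 2 + (r2e / rec.R2) ** 2)
    return ratio, (sigma if sigma > 0 else 1e-3 * ratio)


def fit_isotropic(
    records: list[RelaxationRecord],
    field: FieldContext,
    noe_cutoff: float = 0.6,
) -> DiffusionModel:
    """Single-parameter spherical fit of R2/R1 ratios.

    chi2 = sum_i [(ratio_obs,i - ratio_calc(tau))/sigma_ratio,i]^2 over the
    residues passing the NOE filter; sigma_ratio by first-order error
    propagation.  tau_c error is taken from the curvature of chi2 at the
    minimum (sigma = sqrt(2/chi2'')).
    """
    usable = _usable(records, field, noe_cutoff)
    if len(usable) < 5:
        raise ValueError(
            f"only {len(usable)} usable residues after NOE > {noe_cutoff} filter; need >= 5"
        )
    ratios = np.array([_ratio_and_sigma(r) for r in usable])
    obs, sig = ratios[:, 0], ratios[:, 1]

    def chi2(tau_ns):
        calc = _rigid_ratio(tau_ns, field)
        return float(np.sum(((obs - calc) / sig) ** 2))

    res = optimize.minimize_scalar(chi2, bounds=TAU_BRACKET_NS, method="bounded",
                                   options={"xatol": 1e-6})
    tau = float(res.x)
    h = 1e-3
    curv = (chi2(tau + h) - 2.0 * chi2(tau) + chi2(tau - h)) / h**2
    err = math.sqrt(2.0 / curv) if curv > 0 else 0.0
    return DiffusionModel(
        kind="sphere", tau_c=tau, tau_c_err=err, chi2=float(res.fun),
        n_residues=len(usable), n_params=1,
    )


# ---------------------------------------------------------------------------
# shape from coordinates

def inertia_axes(structure, model_index: int = 1, residue_range=None) -> PrincipalAxes:
    """Principal moments of inertia of heavy atoms of one model.

    *structure* is a :class:`igdyn.structure.StructureEnsemble`;
    ``model_index`` is 1-based as in PDB files.  ``residue_range`` is an
    inclusive (first, last) pair, e.g. the rigid core of the domain.
    Element masses are used and hydrogens are excluded.
    """
    atoms = structure.atoms
    mask = np.array([e.upper() != "H" for e in atoms["element"]])
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (atoms["resnum"] >= lo) & (atoms["resnum"] <= hi)
    if not mask.any():
        raise ValueError("empty atom selection for inertia tensor")
    xyz = structure.coords(model_index)[mask]
    masses = np.array([_MASSES.get(e.upper(), 12.011) for e in atoms["element"][mask]])

    com = np.average(xyz, axis=0, weights=masses)
    d = xyz - com
    r2 = np.sum(d * d, axis=1)
    tensor = (masses[:, None, None] *
              (r2[:, None, None] * np.eye(3)[None] - d[:, :, None] * d[:, None, :])
              ).sum(axis=0)
    moments, vecs = np.linalg.eigh(tensor)
    order = np.argsort(moments)[::-1]          # descending
    moments = moments[order]
    vecs = vecs[:, order]
    ratios = tuple(moments / moments[0])

    total_mass = masses.sum()
    # uniform-ellipsoid equivalence: I_a = M/5 (b^2 + c^2) and cyclic
    sq = np.array([
        moments[1] + moments[2] - moments[0],   # axis with largest moment
        moments[0] + moments[2] - moments[1],
        moments[0] + moments[1] - moments[2],   # axis with smallest moment -> longest
    ]) * 2.5 / total_mass
    semi = np.sqrt(np.clip(sq, 0.0, None))[::-1]   # largest first
    semi_axes = tuple(semi / semi[0])
    return PrincipalAxes(moments=tuple(moments), ratios=ratios,
                         semi_axes=semi_axes, axes=vecs.T)


def nh_vectors(structure, model_number: int = 1) -> dict[int, np.ndarray]:
    """Unit amide N->H vectors per residue of one model.

    Residues without an amide proton (prolines, termini) are simply absent
    from the returned dict.
    """
    atoms = structure.atoms
    xyz = structure.coords(model_number)
    out: dict[int, np.ndarray] = {}
    for resnum in structure.residue_numbers():
        sel = atoms["resnum"] == resnum
        i_n = np.nonzero(sel & (atoms["name"] == "N"))[0]
        i_h = np.nonzero(sel & (atoms["name"] == "H"))[0]
        if len(i_n) and len(i_h):
            v = xyz[i_h[0]] - xyz[i_n[0]]
            out[int(resnum)] = v / np.linalg.norm(v)
    return out


# ---------------------------------------------------------------------------
# axially symmetric tensor

def _axial_spectral_density(omega, theta, d_par, d_perp):
    """Rigid three-exponential J(omega) for an N-H vector at angle theta to the axis."""
    ct2 = math.cos(theta) ** 2
    st2 = 1.0 - ct2
    amps = ((3.0 * ct2 - 1.0) ** 2 / 4.0, 3.0 * st2 * ct2, 0.75 * st2 * st2)
    taus = (1.0 / (6.0 * d_perp),
            1.0 / (5.0 * d_perp + d_par),
            1.0 / (2.0 * d_perp + 4.0 * d_par))
    return 0.4 * sum(a * t / (1.0 + (omega * t) ** 2) for a, t in zip(amps, taus))


def _axial_ratio(theta, d_par, d_perp, field: FieldContext) -> float:
    wh, wn = field.omega_H, field.omega_N
    j = {w: _axial_spectral_density(w, theta, d_par, d_perp)
         for w in (0.0, wn, wh, wh - wn, wh + wn)}
    d2, c2 = field.d2, field.c2
    r1 = d2 / 4.0 * (j[wh - wn] + 3.0 * j[wn] + 6.0 * j[wh + wn]) + c2 * j[wn]
    r2 = (d2 / 8.0 * (4.0 * j[0.0] + j[wh - wn] + 3.0 * j[wn] + 6.0 * j[wh]
                      + 6.0 * j[wh + wn])
          + c2 / 6.0 * (4.0 * j[0.0] + 3.0 * j[wn]))
    return r2 / r1


def _unit_axis(theta, phi):
    return np.array([math.sin(theta) * math.cos(phi),
                     math.sin(theta) * math.sin(phi),
                     math.cos(theta)])


def fit_axial(
    records: list[RelaxationRecord],
    nh_vectors: dict[int, np.ndarray],
    field: FieldContext,
    noe_cutoff: float = 0.6,
) -> DiffusionModel:
    """Axially symmetric diffusion-tensor fit (D_iso, D_par/D_perp, axis angles).

    The search minimises the quadric local-diffusion chi2 (fast, smooth) from a
    coarse grid of starting axis orientations, then refines against — and
    reports — the chi2 of observed vs back-calculated R2/R1 ratios under the
    full axially symmetric spectral density.  Residues lacking an N-H vector
    are dropped with a warning.
    """
    usable = []
    for rec in _usable(records, field, noe_cutoff):
        if rec.residue_id not in nh_vectors:
            warnings.warn(f"residue {rec.residue_id}: no amide N-H vector, dropped")
            continue
        usable.append(rec)
    if len(usable) < 6:
        raise ValueError(f"only {len(usable)} usable residues with N-H vectors; need >= 6")

    vecs = np.array([np.asarray(nh_vectors[r.residue_id], dtype=float) for r in usable])
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)

    # local diffusion coefficients and their uncertainties
    d_loc, d_sig = [], []
    for rec in usable:
        tau = residue_tauc(rec, field)          # ns
        ratio, sig_ratio = _ratio_and_sigma(rec)
        h = 1e-4 * tau
        dratio_dtau = (_rigid_ratio(tau + h, field) - _rigid_ratio(tau - h, field)) / (2 * h)
        sig_tau = sig_ratio / abs(dratio_dtau)
        d = 1.0 / (6.0 * tau * 1e-9)
        d_loc.append(d)
        d_sig.append(d * sig_tau / tau)
    d_loc, d_sig = np.array(d_loc), np.array(d_sig)

    obs_sig = np.array([_ratio_and_sigma(r) for r in usable])
    obs, sig = obs_sig[:, 0], obs_sig[:, 1]

    def split(d_iso, ratio):
        d_par = 3.0 * d_iso * ratio / (2.0 + ratio)
        return d_par, d_par / ratio

    def quadric_chi2(p):
        d_iso, ratio, theta, phi = p
        d_par, d_perp = split(d_iso, ratio)
        ct2 = (vecs @ _unit_axis(theta, phi)) ** 2
        d_eff = (1.0 - ct2) * 0.5 * (d_par + d_perp) + ct2 * d_perp
        return float(np.sum(((d_loc - d_eff) / d_sig) ** 2))

    def full_chi2(p):
        d_iso, ratio, theta, phi = p
        d_par, d_perp = split(d_iso, ratio)
        cosang = np.clip(vecs @ _unit_axis(theta, phi), -1.0, 1.0)
        calc = np.array([_axial_ratio(math.acos(c), d_par, d_perp, field)
                         for c in cosang])
        return float(np.sum(((obs - calc) / sig) ** 2))

    d_iso0 = float(np.mean(d_loc))
    best = None
    for theta0 in np.deg2rad([10.0, 45.0, 80.0]):
        for phi0 in np.deg2rad([0.0, 60.0, 120.0]):
            res = optimize.minimize(
                quadric_chi2, x0=[d_iso0, 1.2, theta0, phi0],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
    refined = optimize.minimize(
        full_chi2, x0=best.x, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
    )
    d_iso, ratio, theta, phi = refined.x
    theta_deg = math.degrees(theta) % 180.0
    phi_deg = math.degrees(phi) % 360.0
    return DiffusionModel(
        kind="axial",
        tau_c=1.0 / (6.0 * d_iso) * 1e9,
        chi2=float(refined.fun),
        n_residues=len(usable),
        n_params=4,
        D_iso=float(d_iso),
        D_ratio=float(ratio),
        axis_polar_angles=(theta_deg, phi_deg),
    )


def compare_diffusion_models(
    sphere: DiffusionModel, axial: DiffusionModel
) -> tuple[float, float]:
    """F-test of the axial (4-parameter) against the spherical (1-parameter) fit.

    F = [(chi2_sph - chi2_ax)/3] / [chi2_ax/(n - 4)], p from F(3, n - 4).
    """
    if sphere.n_residues != axial.n_residues:
        raise ValueError("models were fitted on different residue sets")
    if axial.n_params <= sphere.n_params:
        raise ValueError("axial model must have more parameters than sphere")
    n = sphere.n_residues
    dof1 = axial.n_params - sphere.n_params
    dof2 = n - axial.n_params
    if dof2 <= 0:
        raise ValueError(f"need more than {axial.n_params} residues, have {n}")
    if axial.chi2 == 0.0:
        if sphere.chi2 == 0.0:
            return 0.0, 1.0
        warnings.warn("axial chi2 is zero with non-zero sphere chi2; p = 0")
        return math.inf, 0.0
    f = ((sphere.chi2 - axial.chi2) / dof1) / (axial.chi2 / dof2)
    if f <= 0:
        return max(f, 0.0), 1.0
    return f, float(stats.f.sf(f, dof1, dof2))
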