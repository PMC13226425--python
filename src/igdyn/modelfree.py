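"""Per-residue Lipari-Szabo fitting with F-test / critical-chi2 model selection.

For each residue the three observables (R1, R2, NOE) are fitted against
models 1-5 (see :mod:`igdyn.spin_physics`) at a fixed global tau_c.  Model
complexity is admitted conservatively:

* models 2 and 3 replace model 1 only if a nested F-test on the chi2 drop is
  significant at p < 0.05 (with three observables the test has (1, 1) degrees
  of freedom — one extra parameter, one residual degree of freedom);
* a model is *satisfactory* when its chi2 lies below a critical chi2, the 95%
  quantile of a Monte-Carlo chi2 distribution obtained by refitting the same
  model to synthetic observables drawn from the back-calculated rates with the
  experimental errors;
* models 4 and 5 (zero residual degrees of freedom) are considered only when
  none of models 1-3 is satisfactory, and accepted only if their chi2 beats
  their own critical chi2.

Parameter uncertainties are the standard deviations of the Monte-Carlo refit
distribution of the selected model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .decay_fitting import RelaxationRecord
from .spin_physics import FieldContext, MotionalParameters, back_calculate_rates

P_THRESHOLD = 0.05
N_OBS = 3
N_PARAMS = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3}

TAU_E_MAX = 10e-9   # s
TAU_I_MAX = 10e-9   # s
REX_MAX = 50.0      # s^-1

# fallback relative (R1, R2) / absolute (NOE) uncertainties when a record
# carries no error estimate; only used to keep chi2 well defined
_FALLBACK_FRAC = 0.02
_FALLBACK_NOE = 0.02


@dataclass
class ModelFit:
    """Result of fitting one motional model to one residue."""

    residue_id: int
    model_id: int
    params: MotionalParameters
    chi2: float
    param_errs: dict = dc_field(default_factory=dict)
    chi2_critical: float | None = None
    p_vs_simpler: float | None = None
    satisfactory: bool | None = None
    decision_path: str = ""


def _sigmas(record: RelaxationRecord) -> np.ndarray:
    s1 = record.R1_err if record.R1_err else _FALLBACK_FRAC * record.R1
    s2 = record.R2_err if record.R2_err else _FALLBACK_FRAC * record.R2
    sn = record.NOE_err if record.NOE_err else _FALLBACK_NOE
    return np.array([s1, s2, sn])


def _observables(record: RelaxationRecord) -> np.ndarray:
    return np.array([record.R1, record.R2, record.NOE])


def _calc(params: MotionalParameters, tau_c_s: float, field: FieldContext) -> np.ndarray:
    rates = back_calculate_rates(params, tau_c_s, field)
    return np.array([rates.R1, rates.R2, rates.NOE])


def _to_params(model_id: int, x: np.ndarray) -> MotionalParameters:
    """Map an optimiser vector onto MotionalParameters for the given model."""
    if model_id == 1:
        return MotionalParameters(1, S2=float(x[0]))
    if model_id == 2:
        return MotionalParameters(2, S2=float(x[0]), R_ex=float(x[1]))
    if model_id == 3:
        return MotionalParameters(3, S2=float(x[0]), tau_e=float(x[1]))
    if model_id == 4:
        return MotionalParameters(4, S2=float(x[0]), tau_e=float(x[1]), R_ex=float(x[2]))
    # model 5: x = (S2_f, s, tau_i) with S2 = s * S2_f so the S2 <= S2_f
    # constraint is built into the box bounds
    s2f, s, tau_i = float(x[0]), float(x[1]), float(x[2])
    return MotionalParameters(5, S2=s * s2f, S2_f=s2f, tau_i=tau_i)


_BOUNDS = {
    1: ([0.0], [1.0]),
    2: ([0.0, 0.0], [1.0, REX_MAX]),
    3: ([0.0, 0.0], [1.0, TAU_E_MAX]),
    4: ([0.0, 0.0, 0.0], [1.0, TAU_E_MAX, REX_MAX]),
    5: ([0.0, 0.0, 0.0], [1.0, 1.0, TAU_I_MAX]),
}

_X_SCALE = {
    1: [0.1],
    2: [0.1, 1.0],
    3: [0.1, 1e-10],
    4: [0.1, 1e-10, 1.0],
    5: [0.1, 0.1, 1e-9],
}


def _starts(model_id: int, s2_guess: float) -> list[list[float]]:
    s2 = min(max(s2_guess, 0.05), 0.98)
    if model_id == 1:
        return [[s2]]
    if model_id == 2:
        return [[s2, 1.0], [s2, 8.0]]
    if model_id == 3:
        return [[s2, 30e-12], [s2, 300e-12], [min(s2, 0.5), 2e-9]]
    if model_id == 4:
        return [[s2, 30e-12, 2.0], [s2, 300e-12, 8.0], [min(s2, 0.5), 1e-9, 2.0]]
    return [[0.9, s2 / 0.9 if s2 < 0.9 else 0.95, 0.5e-9],
            [0.95, 0.7, 2e-9], [0.85, 0.8, 5e-9]]


def fit_model(
    record: RelaxationRecord,
    tau_c: float,
    model_id: int,
    field: FieldContext,
    x0_list: list | None = None,
) -> ModelFit:
    """Least-squares fit of one motional model; *tau_c* in ns.

    chi2 = sum over the three observables of ((obs - calc)/sigma_obs)^2,
    minimised over box-bounded parameters from a small multi-start grid
    (or from the explicit start vectors in *x0_list*).
    """
    if not record.complete:
        raise ValueError(f"residue {record.residue_id}: R1, R2 and NOE all required")
    tau_c_s = tau_c * 1e-9
    obs = _observables(record)
    sig = _sigmas(record)

    def residuals(x):
        return (obs - _calc(_to_params(model_id, x), tau_c_s, field)) / sig

    if model_id == 1:
        res = optimize.minimize_scalar(
            lambda s2: float(np.sum(residuals([s2]) ** 2)),
            bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-10},
        )
        best_x, best_chi2 = np.array([res.x]), float(res.fun)
    else:
        lo, hi = _BOUNDS[model_id]
        if x0_list is None:
            # crude S2 guess from R1 against the rigid value
            rigid = _calc(MotionalParameters(1, S2=1.0), tau_c_s, field)
            x0_list = _starts(model_id, obs[0] / rigid[0])
        best_x, best_chi2 = None, math.inf
        for x0 in x0_list:
            sol = optimize.least_squares(
                residuals, x0=np.clip(x0, lo, hi), bounds=(lo, hi),
                x_scale=_X_SCALE[model_id], xtol=1e-12, ftol=1e-12, gtol=None,
            )
            chi2 = float(2.0 * sol.cost)
            if chi2 < best_chi2:
                best_x, best_chi2 = sol.x, chi2
    return ModelFit(
        residue_id=record.residue_id,
        model_id=model_id,
        params=_to_params(model_id, best_x),
        chi2=best_chi2,
    )


def ftest_nested(
    chi2_simple: float,
    chi2_complex: float,
    n_obs: int = N_OBS,
    p_simple: int = 1,
    p_complex: int = 2,
) -> tuple[float, float]:
    """Nested-model F-test on chi2 values.

    F = [(chi2_s - chi2_c)/(p_c - p_s)] / [chi2_c/(n_obs - p_c)], with p from
    the F distribution on (p_c - p_s, n_obs - p_c) degrees of freedom.
    """
    if p_complex <= p_simple:
        raise ValueError("complex model must have more parameters")
    if chi2_simple < 0 or chi2_complex < 0:
        raise ValueError("chi2 values must be non-negative")
    dof1, dof2 = p_complex - p_simple, n_obs - p_complex
    if dof2 <= 0:
        raise ValueError("no residual degrees of freedom for the complex model")
    drop = chi2_simple - chi2_complex
    if drop <= 0:
        return 0.0, 1.0
    if chi2_complex == 0.0:
        warnings.warn("complex-model chi2 is zero; reporting p = 0")
        return math.inf, 0.0
    f = (drop / dof1) / (chi2_complex / dof2)
    return f, float(stats.f.sf(f, dof1, dof2))


def _rng_for_residue(seed: int, residue_id: int) -> np.random.Generator:
    # per-residue substream: results independent of processing order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(residue_id,)))


def critical_chi2(
    record_sigmas: np.ndarray,
    model_id: int,
    best_fit_params: MotionalParameters,
    tau_c: float,
    field: FieldContext,
    n_sim: int = 500,
    confidence: float = 0.95,
    seed: int = 0,
    residue_id: int = 0,
    _collect: list | None = None,
) -> float:
    """Monte-Carlo critical chi2 for one model at one residue's error level.

    Synthetic (R1, R2, NOE) triples are drawn around the back-calculated rates
    at *best_fit_params* with Gaussian noise of the experimental sigmas, the
    same model is refitted to each, and the *confidence* quantile
    (nearest-rank order statistic) of the refit chi2 values is returned.
    *tau_c* in ns.  If *_collect* is given, refit parameter vectors are
    appended to it (used for Monte-Carlo parameter uncertainties).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    sig = np.asarray(record_sigmas, dtype=float)
    tau_c_s = tau_c * 1e-9
    truth = _calc(best_fit_params, tau_c_s, field)
    rng = _rng_for_residue(seed, residue_id)
    noise = rng.normal(0.0, 1.0, size=(n_sim, N_OBS)) * sig

    # refits start from the generating parameters: the noised observables stay
    # in their basin, so a single start is sufficient and much faster
    p = best_fit_params
    if model_id == 1:
        x0_list = None
    elif model_id == 2:
        x0_list = [[p.S2, p.R_ex]]
    elif model_id == 3:
        x0_list = [[p.S2, p.tau_e]]
    elif model_id == 4:
        x0_list = [[p.S2, p.tau_e, p.R_ex]]
    else:
        x0_list = [[p.S2_f, p.S2 / p.S2_f if p.S2_f > 0 else 1.0, p.tau_i]]

    chi2s = np.empty(n_sim)
    for i in range(n_sim):
        obs = truth + noise[i]
        rec = RelaxationRecord(
            residue_id=residue_id,
            R1=max(obs[0], 1e-6), R1_err=sig[0],
            R2=max(obs[1], 1e-6), R2_err=sig[1],
            NOE=obs[2], NOE_err=sig[2],
        )
        fit = fit_model(rec, tau_c, model_id, field, x0_list=x0_list)
        chi2s[i] = fit.chi2
        if _collect is not None:
            p = fit.params
            _collect.append((p.S2, p.tau_e, p.R_ex, p.S2_f, p.tau_i))
    chi2s.sort()
    rank = max(int(math.ceil(confidence * n_sim)) - 1, 0)
    return float(chi2s[rank])


_ERR_KEYS = ("S2", "tau_e", "R_ex", "S2_f", "tau_i")
_MODEL_PARAMS = {1: ("S2",), 2: ("S2", "R_ex"), 3: ("S2", "tau_e"),
                 4: ("S2", "tau_e", "R_ex"), 5: ("S2", "S2_f", "tau_i")}


def select_model(
    record: RelaxationRecord,
    tau_c: float,
    field: FieldContext,
    n_sim: int = 500,
    seed: int = 0,
    confidence: float = 0.95,
) -> ModelFit:
    """Full model-selection for one residue; *tau_c* in ns.

    Decision path: fit models 1-3; replace model 1 by model 2 or 3 only if the
    nested F-test is significant (both significant -> lower chi2, tie -> model
    2); accept the justified model if its chi2 beats its Monte-Carlo critical
    chi2, otherwise fall back to any satisfactory model among 1-3 (lowest chi2
    first); only when all of 1-3 are unsatisfactory are models 4 and 5 fitted,
    and one of them returned only if it beats its own critical chi2.  If
    nothing is satisfactory the lowest-chi2 fit is returned flagged
    unsatisfactory.
    """
    sig = _sigmas(record)
    fits = {m: fit_model(record, tau_c, m, field) for m in (1, 2, 3)}
    path = []

    candidates = []
    for m in (2, 3):
        _, p = ftest_nested(fits[1].chi2, fits[m].chi2,
                            p_simple=N_PARAMS[1], p_complex=N_PARAMS[m])
        fits[m].p_vs_simpler = p
        path.append(f"F(1->{m}) p={p:.3g}")
        if p < P_THRESHOLD:
            candidates.append(m)
    if not candidates:
        justified = 1
    elif len(candidates) == 1:
        justified = candidates[0]
    else:
        justified = 2 if fits[2].chi2 <= fits[3].chi2 else 3
    path.append(f"justified=m{justified}")

    crit_cache: dict[int, tuple[float, list]] = {}

    def crit_for(m: int, fit: ModelFit) -> float:
        if m not in crit_cache:
            collect: list = []
            value = critical_chi2(
                sig, m, fit.params, tau_c, field,
                n_sim=n_sim, confidence=confidence, seed=seed,
                residue_id=record.residue_id, _collect=collect,
            )
            crit_cache[m] = (value, collect)
        return crit_cache[m][0]

    def finalise(fit: ModelFit, satisfactory: bool) -> ModelFit:
        value, collect = crit_cache[fit.model_id]
        fit.chi2_critical = value
        fit.satisfactory = satisfactory
        arr = np.array(collect)
        errs = dict(zip(_ERR_KEYS, arr.std(axis=0, ddof=1)))
        fit.param_errs = {k: float(errs[k]) for k in _MODEL_PARAMS[fit.model_id]}
        fit.decision_path = ";".join(path)
        return fit

    # models 2/3 are admissible only when the F-test passed; model 1 always is
    admissible = [justified] + sorted(
        (m for m in (1, 2, 3) if m != justified and (m == 1 or m in candidates)),
        key=lambda m: fits[m].chi2,
    )
    for m in admissible:
        if fits[m].chi2 < crit_for(m, fits[m]):
            path.append(f"m{m} chi2<crit -> selected")
            return finalise(fits[m], True)
        path.append(f"m{m} unsatisfactory")

    if all(fits[m].chi2 >= crit_for(m, fits[m]) for m in (1, 2, 3)):
        for m in (4, 5):
            fits[m] = fit_model(record, tau_c, m, field)
        accepted = [m for m in (4, 5) if fits[m].chi2 < crit_for(m, fits[m])]
        if accepted:
            m = min(accepted, key=lambda m: fits[m].chi2)
            path.append(f"m{m} chi2<crit -> selected")
            return finalise(fits[m], True)

    m = min(fits, key=lambda m: fits[m].chi2)
    path.append(f"no model satisfactory -> best chi2 m{m}")
    crit_for(m, fits[m])
    return finalise(fits[m], False)


def fit_dataset(
    records: list[RelaxationRecord],
    tau_c: float,
    field: FieldContext,
    n_sim: int = 500,
    seed: int = 0,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Run select_model over all complete records; returns the results table.

    Incomplete records (missing R1, R2 or NOE) are skipped with a warning.
    Columns follow the fits-table dialect: residue_id, model, S2, S2_err,
    te_ps, te_err, Rex, Rex_err, S2f, S2f_err, ti_ns, ti_err, chi2, chi2_crit,
    decision_path.
    """
    rows = []
    for rec in records:
        if not rec.complete:
            warnings.warn(f"residue {rec.residue_id}: incomplete record, skipped")
            continue
        fit = select_model(rec, tau_c, field, n_sim=n_sim, seed=seed,
                           confidence=confidence)
        p, e = fit.params, fit.param_errs
        rows.append({
            "residue_id": rec.residue_id,
            "model": fit.model_id,
            "S2": p.S2, "S2_err": e.get("S2"),
            "te_ps": p.tau_e * 1e12 if fit.model_id in (3, 4) else None,
            "te_err": e.get("tau_e", 0.0) * 1e12 if fit.model_id in (3, 4) else None,
            "Rex": p.R_ex if fit.model_id in (2, 4) else None,
            "Rex_err": e.get("R_ex") if fit.model_id in (2, 4) else None,
            "S2f": p.S2_f if fit.model_id == 5 else None,
            "S2f_err": e.get("S2_f") if fit.model_id == 5 else None,
            "ti_ns": p.tau_i * 1e9 if fit.model_id == 5 else None,
            "ti_err": e.get("tau_i", 0.0) * 1e9 if fit.model_id == 5 else None,
            "chi2": fit.chi2,
            "chi2_crit": fit.chi2_critical,
            "decision_path": fit.decision_path,
        })
    return pd.DataFrame(rows)
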