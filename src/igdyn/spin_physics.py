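"""Lipari-Szabo spectral densities and 15N relaxation back-calculation.

Closed forms for J(omega) under motional models 1-5 and the standard
dipolar + CSA expressions for 15N R1, R2 and the steady-state 1H-15N NOE.
All internal math is in SI units (s, rad/s); interfaces use ns and s^-1.

Model conventions (three experimental observables per residue):

=====  ====================  =========================================
model  fitted parameters     spectral density
=====  ====================  =========================================
1      S2                    single Lorentzian, amplitude S2
2      S2, Rex               as model 1; Rex added to R2 only
3      S2, tau_e             + (1-S2) internal term, 1/tau' = 1/tau_c + 1/tau_e
4      S2, tau_e, Rex        as model 3 plus Rex
5      S2, S2_f, tau_i       extended form: S2*tau_c term + (S2_f-S2)*tau' term,
                             1/tau' = 1/tau_c + 1/tau_i (fast motion infinitely fast)
=====  ====================  =========================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import RunConfig

# CODATA values; signs handled via the configured gamma ratio.
MU0_OVER_4PI = 1e-7          # T m / A
HBAR = 1.054571817e-34       # J s
GAMMA_H = 2.6752218744e8     # rad s^-1 T^-1

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class FieldContext:
    """Magnetic-field dependent constants for an amide 15N spin pair.

    Build with :func:`make_field` rather than directly; the derived members
    (angular frequencies, squared dipolar/CSA constants) must stay consistent
    with the primary ones.
    """

    proton_frequency: float   # MHz
    omega_H: float            # rad/s, positive magnitude
    omega_N: float            # rad/s, positive magnitude
    gamma_ratio: float        # gammaH/gammaN, signed (negative for 15N)
    r_NH: float               # Angstrom
    delta_sigma: float        # ppm
    d2: float                 # dipolar constant squared, s^-2
    c2: float                 # CSA constant squared, s^-2


def make_field(
    proton_frequency: float | None = None,
    r_NH: float | None = None,
    delta_sigma: float | None = None,
    gamma_ratio: float | None = None,
    config: RunConfig | None = None,
) -> FieldContext:
    """Assemble a :class:`FieldContext` from a proton frequency in MHz.

    Arguments default to the values in *config* (or the package defaults).
    The dipolar constant is d = (mu0/4pi) hbar gammaH gammaN / rNH^3 and the
    CSA constant obeys c^2 = (delta_sigma * omegaN)^2 / 3; both enter the rate
    expressions only squared, so signs are irrelevant there.
    """
    cfg = config or RunConfig()
    mhz = cfg.field_MHz if proton_frequency is None else proton_frequency
    r = cfg.r_NH if r_NH is None else r_NH
    dsig = cfg.delta_sigma if delta_sigma is None else delta_sigma
    gratio = cfg.gamma_ratio if gamma_ratio is None else gamma_ratio
    if mhz <= 0 or r <= 0:
        raise ValueError("proton frequency and r_NH must be positive")

    omega_h = TWO_PI * mhz * 1e6
    omega_n = omega_h / abs(gratio)
    gamma_n = GAMMA_H / abs(gratio)
    d = MU0_OVER_4PI * HBAR * GAMMA_H * gamma_n / (r * 1e-10) ** 3
    c2 = (omega_n * dsig * 1e-6) ** 2 / 3.0
    return FieldContext(
        proton_frequency=mhz,
        omega_H=omega_h,
        omega_N=omega_n,
        gamma_ratio=gratio,
        r_NH=r,
        delta_sigma=dsig,
        d2=d * d,
        c2=c2,
    )


@dataclass(frozen=True)
class MotionalParameters:
    """Per-residue Lipari-Szabo parameters for one of models 1-5.

    Parameters not belonging to ``model_id`` must be left at their defaults
    (0 for rates/times, 1 for S2_f).
    """

    model_id: int
    S2: float
    tau_e: float = 0.0    # s; models 3, 4
    R_ex: float = 0.0     # s^-1; models 2, 4
    S2_f: float = 1.0     # models 5
    tau_i: float = 0.0    # s; model 5

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4, 5):
            raise ValueError(f"model_id must be 1..5, got {self.model_id}")
        if not 0.0 <= self.S2 <= 1.0:
            raise ValueError(f"S2 must be in [0, 1], got {self.S2}")
        if self.tau_e < 0 or self.tau_i < 0 or self.R_ex < 0:
            raise ValueError("tau_e, tau_i and R_ex must be non-negative")
        if self.model_id == 5:
            if not self.S2 <= self.S2_f <= 1.0:
                raise ValueError("model 5 requires S2 <= S2_f <= 1")
        if self.model_id in (1, 2) and self.tau_e != 0.0:
            raise ValueError(f"tau_e does not belong to model {self.model_id}")
        if self.model_id in (1, 3, 5) and self.R_ex != 0.0:
            raise ValueError(f"R_ex does not belong to model {self.model_id}")
        if self.model_id != 5 and (self.S2_f != 1.0 or self.tau_i != 0.0):
            raise ValueError("S2_f/tau_i belong to model 5 only")


@dataclass(frozen=True)
class RelaxationRates:
    """Back-calculated 15N relaxation observables."""

    R1: float      # s^-1
    R2: float      # s^-1
    NOE: float     # dimensionless

    def __post_init__(self) -> None:
        if not (self.R1 > 0 and self.R2 > 0):
            raise ValueError("R1 and R2 must be positive")


def _lorentzian(tau: float, omega: float) -> float:
    return tau / (1.0 + (omega * tau) ** 2)


def spectral_density(params: MotionalParameters, tau_c: float, omega: float) -> float:
    """J(omega) in s/rad for the given model, with the 2/5 normalisation.

    ``tau_c`` is the overall (isotropic) rotational correlation time in
    seconds; ``omega`` is an angular frequency in rad/s.
    """
    if not (math.isfinite(tau_c) and tau_c > 0):
        raise ValueError(f"tau_c must be finite and positive, got {tau_c}")
    if omega < 0:
        raise ValueError("omega must be non-negative")

    j = params.S2 * _lorentzian(tau_c, omega)
    if params.model_id in (3, 4) and params.tau_e > 0:
        tau_p = 1.0 / (1.0 / tau_c + 1.0 / params.tau_e)
        j += (1.0 - params.S2) * _lorentzian(tau_p, omega)
    elif params.model_id == 5 and params.tau_i > 0:
        tau_p = 1.0 / (1.0 / tau_c + 1.0 / params.tau_i)
        j += (params.S2_f - params.S2) * _lorentzian(tau_p, omega)
    return 0.4 * j


def back_calculate_rates(
    params: MotionalParameters, tau_c: float, field: FieldContext
) -> RelaxationRates:
    """15N R1/R2/NOE from motional parameters and a global tau_c (seconds)."""
    wh, wn = field.omega_H, field.omega_N
    j0 = spectral_density(params, tau_c, 0.0)
    jn = spectral_density(params, tau_c, wn)
    jh = spectral_density(params, tau_c, wh)
    jhmn = spectral_density(params, tau_c, wh - wn)
    jhpn = spectral_density(params, tau_c, wh + wn)
    d2, c2 = field.d2, field.c2

    r1 = d2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (
        d2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
        + c2 / 6.0 * (4.0 * j0 + 3.0 * jn)
        + params.R_ex
    )
    noe = 1.0 + d2 / 4.0 * field.gamma_ratio / r1 * (6.0 * jhpn - jhmn)
    return RelaxationRates(R1=r1, R2=r2, NOE=noe)
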