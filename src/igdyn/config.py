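"""Run-wide configuration.

Defaults reproduce the experimental settings of the I82 study where those are
known (800.13 MHz proton frequency, heteronuclear-NOE cutoff 0.6 for the
diffusion fit, 0.3 A restraint tolerance) and standard literature values for
the physical constants the relaxation equations need (rNH, 15N CSA, gyromagnetic
ratio).  Everything here can be overridden per call, via a flat ``key = value``
config file, or on the command line (flag > file > default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Global knobs shared across the pipeline.

    Attributes
    ----------
    field_MHz:
        Proton Larmor frequency in MHz.
    r_NH:
        Amide N-H bond length in Angstrom used for the dipolar constant.
    delta_sigma:
        15N chemical-shift anisotropy in ppm (axially symmetric).
    gamma_ratio:
        Signed gyromagnetic-ratio ratio gammaH/gammaN (negative for 15N).
    noe_cutoff:
        Heteronuclear-NOE threshold above which residues enter the
        rotational-diffusion fit.
    tolerance_A:
        Maximal allowed restraint violation (A) when deciding whether a
        distance restraint is compatible with a conformer.
    n_sim:
        Monte-Carlo sample size for critical-chi2 estimation.
    confidence:
        Quantile of the Monte-Carlo chi2 distribution used as critical chi2.
    seed:
        Master seed for all stochastic steps.
    verbosity:
        0 = quiet, 1 = notices, 2 = debug.
    """

    field_MHz: float = 800.13
    r_NH: float = 1.02
    delta_sigma: float = -160.0
    gamma_ratio: float = -9.8656
    noe_cutoff: float = 0.6
    tolerance_A: float = 0.3
    n_sim: int = 500
    confidence: float = 0.95
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.field_MHz <= 0:
            raise ValueError("field_MHz must be positive")
        if self.r_NH <= 0:
            raise ValueError("r_NH must be positive")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


_NUMERIC = {f.name: f.type for f in fields(RunConfig)}


def read_config_file(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file ('#' comments, blank lines ok)."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _NUMERIC:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        caster = int if key in ("n_sim", "seed", "verbosity") else float
        values[key] = caster(value)
    return values


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig with precedence: explicit overrides > file > defaults."""
    values = read_config_file(path) if path is not None else {}
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
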