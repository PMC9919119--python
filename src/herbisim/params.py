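"""Model parameters: definition, defaults, validation, config I/O, RNG contract.

All proportion-typed parameters (costs, benefits, rates, initial frequencies)
are dimensionless fractions in [0, 1].  ``Params`` is the single source of
truth for a run: two simulations constructed from equal ``Params`` (including
``seed``) are byte-identical.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import numpy as np

MODELS = ("multiplicative", "additive")
SELFING_MODES = ("heritable", "non_heritable", "none")


class ConfigError(ValueError):
    """A configuration file could not be read or contained bad keys/values."""


class ParamsError(ValueError):
    """One or more parameter invariants are violated.

    ``errors`` lists every violation (the check is aggregated, not
    fail-fast), each naming the offending field.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclasses.dataclass(frozen=True)
class Params:
    """All model and structural parameters of a simulation run.

    The biological parameters (``w0`` .. ``l``) carry the model's default
    values; the structural parameters (population sizes, genome size,
    mutation rate, horizon, initial frequencies) are configuration choices
    of this package.
    """

    # --- fitness-equation parameters -------------------------------------
    w0: float = 25.0          # base fitness: expected seeds per unimpaired plant
    c_r: float = 0.15         # maximum resistance cost (proportion)
    c_t: float = 0.4          # maximum tolerance cost (proportion)
    c_h: float = 0.75         # maximum herbivory cost (proportion)
    b_t: float = 0.25         # maximum tolerance benefit (proportion)
    c_a: float = 0.4          # maximum anti-resistance cost in herbivores
    k: float = 0.3            # overdominance shape parameter
    H: float = 0.25           # population reference heterozygosity (constant)
    s: float = 0.005          # selection coefficient per detrimental allele
    l: float = 1.0            # linearity/shape exponent (0.2-5.0)
    model: str = "multiplicative"
    selfing_mode: str = "none"

    # --- genome / mutation ------------------------------------------------
    mu: float = 0.00245       # per-allele per-load-gene detrimental mutation rate
    n_genome_genes: int = 100

    # --- populations and run structure ------------------------------------
    K_plants: int = 500
    K_herbivores: int = 500
    generations: int = 15000
    replicates: int = 3
    init_freq_resistance: float = 0.5
    init_freq_tolerance: float = 0.5
    init_freq_selfing: float = 0.5
    init_freq_antiresistance: float = 0.5
    init_selfer_fraction: float = 0.5
    init_genome_het: float = 0.5
    herbivore_base_fecundity: float = 25.0
    herbivore_failure_cost: float = 0.75
    selfers_donate_pollen: bool = True
    o2_sign_verbatim: bool = False
    seed: int = 1

    @property
    def U(self) -> float:
        """Diploid genomic detrimental mutation rate, U = 2 * n_genes * mu."""
        return 2.0 * self.n_genome_genes * self.mu


_PROPORTION_FIELDS = (
    "c_r", "c_t", "c_h", "b_t", "c_a", "k", "H", "s", "mu",
    "init_freq_resistance", "init_freq_tolerance", "init_freq_selfing",
    "init_freq_antiresistance", "init_selfer_fraction", "init_genome_het",
    "herbivore_failure_cost",
)
_INT_FIELDS = ("n_genome_genes", "K_plants", "K_herbivores", "generations",
               "replicates", "seed")
_BOOL_FIELDS = ("selfers_donate_pollen", "o2_sign_verbatim")
_STR_FIELDS = ("model", "selfing_mode")

_FIELD_NAMES = {f.name for f in dataclasses.fields(Params)}


def default_params(**overrides) -> Params:
    """Return a validated ``Params`` with defaults, optionally overridden."""
    return validate_params(Params(**overrides))


def validate_params(p: Params) -> Params:
    """Check every invariant of ``p``; return it unchanged if all hold.

    Raises ``ParamsError`` listing every violated invariant.
    """
    errors: list[str] = []
    for name in _PROPORTION_FIELDS:
        v = getattr(p, name)
        if not (0.0 <= v <= 1.0):
            errors.append(f"{name} must lie in [0, 1], got {v!r}")
    if not (0.2 <= p.l <= 5.0):
        errors.append(f"l must lie in [0.2, 5.0], got {p.l!r}")
    if not p.w0 > 0:
        errors.append(f"w0 must be positive, got {p.w0!r}")
    if not p.herbivore_base_fecundity > 0:
        errors.append("herbivore_base_fecundity must be positive, "
                      f"got {p.herbivore_base_fecundity!r}")
    if p.model not in MODELS:
        errors.append(f"model must be one of {MODELS}, got {p.model!r}")
    if p.selfing_mode not in SELFING_MODES:
        errors.append(f"selfing_mode must be one of {SELFING_MODES}, "
                      f"got {p.selfing_mode!r}")
    if p.K_plants < 2:
        errors.append(f"K_plants must be >= 2, got {p.K_plants!r}")
    if p.K_herbivores < 2:
        errors.append(f"K_herbivores must be >= 2, got {p.K_herbivores!r}")
    if p.n_genome_genes < 1:
        errors.append(f"n_genome_genes must be >= 1, got {p.n_genome_genes!r}")
    if p.generations < 0:
        errors.append(f"generations must be >= 0, got {p.generations!r}")
    if p.replicates < 1:
        errors.append(f"replicates must be >= 1, got {p.replicates!r}")
    if errors:
        raise ParamsError(errors)
    return p


def _coerce(key: str, value) -> object:
    if key in _BOOL_FIELDS:
        if not isinstance(value, bool):
            raise ConfigError(f"{key}: expected true/false, got {value!r}")
        return value
    if key in _STR_FIELDS:
        if not isinstance(value, str):
            raise ConfigError(f"{key}: expected a quoted string, got {value!r}")
        return value
    if key in _INT_FIELDS:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{key}: expected an integer, got {value!r}")
        return value
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{key}: expected a number, got {value!r}")
    return float(value)


def load_config(path: str | Path) -> Params:
    """Load a plain-text key=value (section-less TOML) config into ``Params``.

    Unspecified keys take their defaults; unknown keys are rejected; the
    loaded ``seed`` fully determines all stochastic output of a run.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"config parse failure in {path}: {exc}") from exc
    kwargs = {}
    for key, value in raw.items():
        if key not in _FIELD_NAMES:
            raise ConfigError(f"unknown config key: {key}")
        kwargs[key] = _coerce(key, value)
    return validate_params(Params(**kwargs))


def dumps_config(p: Params) -> str:
    """Serialize ``p`` as the key=value dialect accepted by ``load_config``."""
    lines = []
    for f in dataclasses.fields(Params):
        v = getattr(p, f.name)
        if isinstance(v, bool):
            text = "true" if v else "false"
        elif isinstance(v, str):
            text = f'"{v}"'
        else:
            text = repr(v)
        lines.append(f"{f.name} = {text}")
    return "\n".join(lines) + "\n"


def save_config(p: Params, path: str | Path) -> None:
    Path(path).write_text(dumps_config(p))


def rng_for_replicate(p: Params, replicate: int,
                      cell: int | None = None) -> np.random.Generator:
    """RNG splitting contract: one independent stream per replicate.

    The stream is seeded from ``SeedSequence([seed, replicate])`` (or
    ``[seed, cell, replicate]`` inside a sweep), so runs are reproducible
    and replicates statistically independent.
    """
    entropy = [int(p.seed)]
    if cell is not None:
        entropy.append(int(cell))
    entropy.append(int(replicate))
    return np.random.default_rng(np.random.SeedSequence(entropy))
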