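"""Ionic parameter set: conductances, capacitance and the gate rate table.

The shipped constant table (``data/brdr_v1.params``) is a versioned
plain-text key = value file; an alternative file may be supplied on the
command line or through :func:`IonicParams.from_file`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigError, InvalidInputError
from .rates import RateSpec

#: rate-table row order used by the packed (12, 9) kernel array
GATE_RATE_ORDER = (
    "m.alpha", "m.beta", "h.alpha", "h.beta", "j.alpha", "j.beta",
    "d.alpha", "d.beta", "f.alpha", "f.beta", "x1.alpha", "x1.beta",
)

#: rows whose rates the slow-inward (calcium) speedup factor multiplies
_CA_SPEEDUP_KEYS = ("d.alpha", "d.beta", "f.alpha", "f.beta")

_SCALAR_KEYS = {
    "g_na": float, "e_na": float, "g_nac": float, "g_s": float,
    "c_m": float, "use_j_gate": bool, "cai_init": float,
    "cai_floor": float, "singular_halfwidth": float,
    "format_version": int,
}
_RATE_FIELDS = {"c1", "c2", "c3", "c4", "c5", "c6", "c7",
                "singular_v", "singular_limit"}

DEFAULT_PARAMS_RESOURCE = "brdr_v1.params"


@dataclass(eq=False)
class IonicParams:
    """Membrane model parameters.

    Attributes
    ----------
    g_na, g_nac : float
        Fast and background sodium conductances, mS/cm^2.
    e_na : float
        Sodium reversal potential, mV.
    g_s : float
        Slow-inward (calcium) conductance, mS/cm^2.
    c_m : float
        Membrane capacitance, uF/cm^2.
    use_j_gate : bool
        Whether the slow sodium inactivation gate participates in I_Na and
        is integrated.  The Drouhard-Roberge sodium formulation drops it.
    ca_speedup : float
        Multiplier on the d/f gate rate functions.  1.0 is the published
        kinetics; >1 shortens the action potential (the standard device for
        fitting rotors into tractable domains in this model family).
    rate_table : dict[str, RateSpec]
        One spec per (gate, alpha/beta) pair, keys as in GATE_RATE_ORDER.
    """

    g_na: float = 15.0
    e_na: float = 40.0
    g_nac: float = 0.003
    g_s: float = 0.09
    c_m: float = 1.0
    use_j_gate: bool = False
    cai_init: float = 2e-7
    cai_floor: float = 1e-10
    singular_halfwidth: float = 1e-6
    ca_speedup: float = 1.0
    rate_table: dict = field(default_factory=dict)
    source: str = "<builtin>"
    source_sha256: str = ""

    def validate(self) -> None:
        if min(self.g_na, self.g_nac, self.g_s) < 0.0:
            raise InvalidInputError("conductances must be >= 0")
        if self.c_m <= 0.0:
            raise InvalidInputError("C_m must be > 0")
        if self.ca_speedup <= 0.0:
            raise InvalidInputError("ca_speedup must be > 0")
        missing = [k for k in GATE_RATE_ORDER if k not in self.rate_table]
        if missing:
            raise ConfigError(f"rate table incomplete, missing: {missing}")

    # -- kernel packing -----------------------------------------------------
    def packed_rates(self) -> np.ndarray:
        """(12, 9) float64 rate table with ca_speedup folded in."""
        rows = []
        for key in GATE_RATE_ORDER:
            spec = self.rate_table[key]
            if self.ca_speedup != 1.0 and key in _CA_SPEEDUP_KEYS:
                spec = spec.scaled(self.ca_speedup)
            rows.append(spec.packed())
        return np.ascontiguousarray(np.vstack(rows))

    def packed_scalars(self) -> np.ndarray:
        return np.array([
            self.g_na, self.e_na, self.g_nac, self.g_s, self.c_m,
            1.0 if self.use_j_gate else 0.0,
            self.cai_floor, self.singular_halfwidth,
        ], dtype=np.float64)

    def effective_spec(self, key: str) -> RateSpec:
        """Rate spec for ``key`` with the ca_speedup factor applied."""
        spec = self.rate_table[key]
        if self.ca_speedup != 1.0 and key in _CA_SPEEDUP_KEYS:
            spec = spec.scaled(self.ca_speedup)
        return spec

    def replace(self, **kw) -> "IonicParams":
        return replace(self, **kw)

    # -- construction -------------------------------------------------------
    @classmethod
    def default(cls, **overrides) -> "IonicParams":
        """Load the shipped Beeler-Reuter / Drouhard-Roberge table."""
        ref = resources.files("cardiowave") / "data" / DEFAULT_PARAMS_RESOURCE
        text = ref.read_text()
        p = cls._from_text(text, source=f"builtin:{DEFAULT_PARAMS_RESOURCE}")
        return p.replace(**overrides) if overrides else p

    @classmethod
    def from_file(cls, path, **overrides) -> "IonicParams":
        path = Path(path)
        p = cls._from_text(path.read_text(), source=str(path))
        return p.replace(**overrides) if overrides else p

    @classmethod
    def _from_text(cls, text: str, source: str) -> "IonicParams":
        scalars = {}
        rate_fields: dict[str, dict] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{source}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("rate."):
                parts = key.split(".")
                if len(parts) != 4 or parts[3] not in _RATE_FIELDS:
                    raise ConfigError(f"{source}:{lineno}: unknown key {key!r}")
                gate_key = f"{parts[1]}.{parts[2]}"
                rate_fields.setdefault(gate_key, {})[parts[3]] = float(value)
            elif key in _SCALAR_KEYS:
                typ = _SCALAR_KEYS[key]
                if typ is bool:
                    if value.lower() not in ("true", "false"):
                        raise ConfigError(
                            f"{source}:{lineno}: boolean expected for {key}")
                    scalars[key] = value.lower() == "true"
                else:
                    scalars[key] = typ(value)
            else:
                raise ConfigError(f"{source}:{lineno}: unknown key {key!r}")
        version = scalars.pop("format_version", None)
        if version != 1:
            raise ConfigError(f"{source}: unsupported format_version {version}")
        table = {k: RateSpec(**v) for k, v in rate_fields.items()}
        sha = hashlib.sha256(text.encode()).hexdigest()
        p = cls(rate_table=table, source=source, source_sha256=sha, **scalars)
        p.validate()
        return p
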