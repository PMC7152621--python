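"""Run configuration: JSON/YAML files merged with command-line flags.

A run is specified by exactly one of a full payoff matrix (a, b, c, d) or
the reduced pair (t1, t2); by therapy parameters given either as the
composite e (expanded as w = e, j = 1, l = 1) or as an explicit (w, j, l)
triple; plus initial conditions and integration settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .dynamics import IntegrationSettings, TherapyParams
from .game_core import InvalidInputError, PayoffMatrix, TParams, derive_t_parameters

__all__ = ["RunConfig", "load_config_file"]

_PAYOFF_KEYS = ("a", "b", "c", "d")
_T_KEYS = ("t1", "t2")
_THERAPY_KEYS = ("w", "j", "l")
_SETTINGS_KEYS = ("method", "rtol", "atol", "convergence_tol", "horizon", "max_doublings")


def load_config_file(path) -> dict:
    """Parse a JSON or YAML config file into a flat mapping."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidInputError(f"config file {path} must contain a mapping")
    return data


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved model/therapy/integration configuration."""

    payoff: PayoffMatrix
    t: TParams
    therapy: Optional[TherapyParams]
    x0: float
    z0: float
    settings: IntegrationSettings
    seed: Optional[int] = None

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        """Build a config from a flat mapping (file contents and/or flags).

        Exactly one of {a,b,c,d} or {t1,t2} must be present.  If ``e`` is
        given without (w, j, l) it expands as w = e, j = 1, l = 1.
        """
        has_payoff = any(data.get(k) is not None for k in _PAYOFF_KEYS)
        has_t = any(data.get(k) is not None for k in _T_KEYS)
        if has_payoff and has_t:
            raise InvalidInputError("give either the payoff matrix (a,b,c,d) or (t1,t2), not both")
        if has_payoff:
            missing = [k for k in _PAYOFF_KEYS if data.get(k) is None]
            if missing:
                raise InvalidInputError(f"incomplete payoff matrix: missing {missing}")
            payoff = PayoffMatrix(*(float(data[k]) for k in _PAYOFF_KEYS))
            t = derive_t_parameters(payoff)
        elif has_t:
            missing = [k for k in _T_KEYS if data.get(k) is None]
            if missing:
                raise InvalidInputError(f"incomplete reduced parameters: missing {missing}")
            t = TParams(float(data["t1"]), float(data["t2"]))
            payoff = PayoffMatrix.from_t_params(t.t1, t.t2)
        else:
            raise InvalidInputError("model parameters required: (a,b,c,d) or (t1,t2)")

        therapy: Optional[TherapyParams] = None
        has_wjl = any(data.get(k) is not None for k in _THERAPY_KEYS)
        if data.get("e") is not None and not has_wjl:
            therapy = TherapyParams.from_e(float(data["e"]))
        elif has_wjl:
            w = float(data.get("w", 0.0) or 0.0)
            j = float(data["j"]) if data.get("j") is not None else 1.0
            l = float(data["l"]) if data.get("l") is not None else 1.0
            therapy = TherapyParams(w=w, j=j, l=l)
            if data.get("e") is not None and abs(therapy.e - float(data["e"])) > 1e-12:
                raise InvalidInputError(
                    f"inconsistent therapy spec: wj/l = {therapy.e!r} but e = {data['e']!r}"
                )

        skw = {k: data[k] for k in _SETTINGS_KEYS if data.get(k) is not None}
        settings = IntegrationSettings(**skw)
        return cls(
            payoff=payoff,
            t=t,
            therapy=therapy,
            x0=float(data.get("x0", 0.5)),
            z0=float(data.get("z0", 0.0)),
            settings=settings,
            seed=None if data.get("seed") is None else int(data["seed"]),
        )


def merge_flags(config: Optional[dict], **flags) -> dict:
    """Overlay non-None CLI flags onto the config-file mapping."""
    merged = dict(config or {})
    for key, value in flags.items():
        if value is not None:
            merged[key] = value
    return merged
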