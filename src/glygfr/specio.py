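"""Serialization of :class:`~glygfr.equations.EquationSpec` and built-in specs.

Specs are stored as flat JSON: name, per-variable scaling divisors, and one
object per stratum (sex, half-open creatinine interval, intercept,
coefficient map).  Round trips are bit-exact because JSON floats preserve
the binary values via ``repr``.

The built-in ``"pima"`` spec ships as a packaged resource.  Its stratum
coefficients are the published glycemia-aware approximating equations for
diabetic Pima adults (eight sex x creatinine-quartile strata on the log
scale).  Two caveats apply to that resource:

* The published table's variable scaling is not stated; the shipped
  divisors (age in decades, FPG per 100 mg/dL, HbA1c and SCR raw) are an
  inference from the companion regression models and cohort means, and
  predictions from this spec should be treated as provisional.  Re-deriving
  coefficients from data via :mod:`glygfr.derivation` is the trustworthy
  route.
* Two typographic anomalies in the source table are normalized: the men's
  top-stratum HbA1c coefficient "00.328" is encoded as 0.0328, and its
  interval label "SCR >= -0.90" as SCR >= 0.90.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

from .equations import EquationSpec, Stratum
from .errors import InputError, ValidationError

__all__ = ["spec_to_dict", "spec_from_dict", "write_equation_spec",
           "read_equation_spec", "load_builtin", "BUILTIN_SPECS"]

#: Names accepted by :func:`load_builtin`.
BUILTIN_SPECS = ("pima",)


def spec_to_dict(spec: EquationSpec) -> dict:
    return {
        "name": spec.name,
        "scaling": dict(spec.scaling),
        "strata": [
            {
                "sex": s.sex,
                "scr_lo": s.scr_lo,
                "scr_hi": s.scr_hi,
                "intercept": s.intercept,
                "coefficients": dict(s.coefficients),
            }
            for s in spec.strata
        ],
    }


def spec_from_dict(d: dict) -> EquationSpec:
    try:
        strata = [
            Stratum(
                sex=s["sex"],
                scr_lo=float(s["scr_lo"]),
                scr_hi=float(s["scr_hi"]),
                intercept=float(s["intercept"]),
                coefficients={k: float(v) for k, v in s["coefficients"].items()},
            )
            for s in d["strata"]
        ]
        return EquationSpec(
            name=d["name"],
            strata=strata,
            scaling={k: float(v) for k, v in d.get("scaling", {}).items()},
        )
    except KeyError as e:  # missing field
        raise ValidationError(f"equation-spec document lacks field {e}") from e


def write_equation_spec(spec: EquationSpec, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2) + "\n")


def read_equation_spec(path: Union[str, Path]) -> EquationSpec:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"{path}: not a valid equation-spec file: {e}") from e
    return spec_from_dict(d)


def load_builtin(name: str) -> EquationSpec:
    """Load a packaged equation spec by name (currently only ``"pima"``)."""
    if name not in BUILTIN_SPECS:
        raise InputError(
            f"unknown built-in spec {name!r}; available: {', '.join(BUILTIN_SPECS)}"
        )
    text = resources.files("glygfr.resources").joinpath(f"{name}_equations.json").read_text()
    return spec_from_dict(json.loads(text))
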