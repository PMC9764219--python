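"""Configuration-file support for the physical and numerical constants.

A config file is a flat-ish JSON document; every key is optional and
falls back to the library default:

```json
{
 "density": 1060.0,
 "plasma_viscosity_cP": 1.2,
 "alpha": 1.1,
 "wall": {"h_mm": 0.945, "E_MPa": 1.41, "nu": 0.5, "Pext_Pa": 0.0,
          "stiffness_multiplier": 1.0},
 "solver": {"dt_s": 1e-5, "dx_um": 500.0, "max_cycles": 20,
            "min_cycles": 3, "l2_tol": 1e-3, "cfl_number": 0.9}
}
```
"""

from __future__ import annotations

import json
from typing import Optional, Tuple

from .constitutive import BloodProperties, WallLaw
from .errors import ParseError
from .solver import SolverControls


def load_config(path, hematocrit_pct: Optional[float] = None
                ) -> Tuple[BloodProperties, WallLaw, SolverControls]:
    """Build (blood, wall, controls) from a JSON config file."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    return config_from_dict(doc, hematocrit_pct)


def config_from_dict(doc: dict, hematocrit_pct: Optional[float] = None
                     ) -> Tuple[BloodProperties, WallLaw, SolverControls]:
    blood_kw = {}
    if "density" in doc:
        blood_kw["rho"] = float(doc["density"])
    if "plasma_viscosity_cP" in doc:
        blood_kw["mu0_cP"] = float(doc["plasma_viscosity_cP"])
    if "alpha" in doc:
        blood_kw["alpha"] = float(doc["alpha"])
    if "hematocrit_pct" in doc:
        blood_kw["hematocrit"] = float(doc["hematocrit_pct"]) / 100.0
    elif hematocrit_pct is not None:
        blood_kw["hematocrit"] = hematocrit_pct / 100.0
    blood = BloodProperties(**blood_kw)

    w = doc.get("wall", {})
    wall = WallLaw(h_mm=float(w.get("h_mm", 0.945)),
                   E_MPa=float(w.get("E_MPa", 1.41)),
                   nu=float(w.get("nu", 0.5)),
                   Pext=float(w.get("Pext_Pa", 0.0)),
                   stiffness_multiplier=float(
                       w.get("stiffness_multiplier", 1.0)))

    s = doc.get("solver", {})
    controls = SolverControls(
        dt_s=s.get("dt_s", 1e-5),
        dx_um=float(s.get("dx_um", 500.0)),
        max_cycles=int(s.get("max_cycles", 20)),
        min_cycles=int(s.get("min_cycles", 3)),
        l2_tol=float(s.get("l2_tol", 1e-3)),
        cfl_number=float(s.get("cfl_number", 0.9)))
    return blood, wall, controls
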