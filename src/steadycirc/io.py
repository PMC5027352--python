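"""Model configs, run reports and tabular serialization.

Model-definition config
-----------------------
A versioned YAML document (``format: steadycirc-model/1``) with
sections ``heart_right``, ``heart_left``, ``compartments`` (list with
id, circuit, C, V0n, P_ext, RA, RV), ``topology`` (one entry per
circuit; a plain id is a leaf, a list means *series* ordered from the
arterial to the venous side, and ``{parallel: [...]}`` a parallel
group) and ``volumes`` (BV, V0).  An optional ``pressure_groups``
section names shared external pressures.  A model written with
:func:`write_model` and reloaded with :func:`read_model` compares equal
field-for-field.

Run reports
-----------
:func:`solve_report` solves a model and packages the reduced form,
the steady state and the derived hemodynamics.  Reports are fully
deterministic: regenerating from the same config and package version
yields byte-identical output (provenance carries the config path,
scenario and version — deliberately no timestamp).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Union

import yaml

from . import __version__
from .errors import InvalidModelError, ModelError, SpecialCaseError
from .five_compartment import DerivedHemodynamics, derived_hemodynamics
from .model import (
    CardiacCurve,
    CirculationModel,
    Compartment,
    PressureGroup,
    ReducedForm,
    SteadyState,
)
from .network import Leaf, Node, Parallel, Series
from .solvers import reduced_mu_lambda, steady_state

__all__ = [
    "MODEL_FORMAT",
    "model_to_dict",
    "model_from_dict",
    "read_model",
    "write_model",
    "RunReport",
    "solve_report",
]

MODEL_FORMAT = "steadycirc-model/1"


# --------------------------------------------------------------------------
# Topology <-> plain data


def _encode_topology(node: Node):
    if isinstance(node, Leaf):
        return node.compartment
    if isinstance(node, Series):
        return [_encode_topology(c) for c in node.children]
    if isinstance(node, Parallel):
        return {"parallel": [_encode_topology(b) for b in node.branches]}
    raise InvalidModelError(f"cannot encode topology node {node!r}")


def _decode_topology(spec) -> Node:
    if isinstance(spec, str):
        return Leaf(spec)
    if isinstance(spec, list):
        children = tuple(_decode_topology(s) for s in spec)
        return children[0] if len(children) == 1 else Series(children)
    if isinstance(spec, dict) and set(spec) == {"parallel"}:
        branches = tuple(_decode_topology(s) for s in spec["parallel"])
        return branches[0] if len(branches) == 1 else Parallel(branches)
    raise InvalidModelError(
        f"malformed topology entry {spec!r}: expected an id, a series list "
        "or {parallel: [...]}"
    )


# --------------------------------------------------------------------------
# Model <-> plain data


def _heart_dict(h: CardiacCurve) -> Dict[str, float]:
    return {"K": h.K, "alpha": h.alpha, "beta": h.beta, "P_ext": h.P_ext}


def model_to_dict(model: CirculationModel) -> Dict:
    comps = []
    for c in model.compartments:
        d = {"id": c.id, "circuit": c.circuit, "C": c.C, "V0n": c.V0n,
             "P_ext": c.P_ext}
        if not c.is_atrium:
            d["RA"] = c.RA
            d["RV"] = c.RV
        comps.append(d)
    out = {
        "format": MODEL_FORMAT,
        "heart_right": _heart_dict(model.right_heart),
        "heart_left": _heart_dict(model.left_heart),
        "compartments": comps,
        "topology": {
            "pulmonary": _encode_topology(model.pulmonary_topology),
            "systemic": _encode_topology(model.systemic_topology),
        },
        "volumes": {"BV": model.BV, "V0": model.V0},
    }
    if model.pressure_groups:
        out["pressure_groups"] = {
            g.name: {
                "compartments": list(g.compartments),
                "include_heart": g.include_heart,
            }
            for g in model.pressure_groups
        }
    return out


def model_from_dict(data: Dict) -> CirculationModel:
    if not isinstance(data, dict):
        raise InvalidModelError("config root must be a mapping")
    fmt = data.get("format")
    if fmt != MODEL_FORMAT:
        raise InvalidModelError(
            f"unsupported config format {fmt!r} (expected {MODEL_FORMAT!r})"
        )
    try:
        hearts = {
            side: CardiacCurve(**{k: float(v) for k, v in data[f"heart_{side}"].items()})
            for side in ("right", "left")
        }
        comps = tuple(
            Compartment(
                id=str(c["id"]),
                circuit=str(c["circuit"]),
                C=float(c["C"]),
                V0n=float(c["V0n"]),
                P_ext=float(c.get("P_ext", 0.0)),
                RA=float(c["RA"]) if "RA" in c else None,
                RV=float(c["RV"]) if "RV" in c else None,
            )
            for c in data["compartments"]
        )
        topo = data["topology"]
        groups = tuple(
            PressureGroup(
                name=str(name),
                compartments=tuple(g["compartments"]),
                include_heart=bool(g.get("include_heart", False)),
            )
            for name, g in data.get("pressure_groups", {}).items()
        )
        return CirculationModel(
            right_heart=hearts["right"],
            left_heart=hearts["left"],
            compartments=comps,
            pulmonary_topology=_decode_topology(topo["pulmonary"]),
            systemic_topology=_decode_topology(topo["systemic"]),
            BV=float(data["volumes"]["BV"]),
            V0=float(data["volumes"]["V0"]),
            pressure_groups=groups,
        )
    except (KeyError, TypeError) as exc:
        raise InvalidModelError(f"malformed model config: {exc!r}") from exc


def read_model(path: Union[str, Path]) -> CirculationModel:
    """Load a model from a YAML config file."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise InvalidModelError(f"cannot parse {path}: {exc}") from exc
    return model_from_dict(data)


def write_model(model: CirculationModel, path: Union[str, Path]) -> None:
    """Write a model config; ``read_model(path)`` restores an equal model."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Run reports


@dataclass(frozen=True)
class RunReport:
    """A solved model packaged for serialization.

    Every numeric field equals the in-memory double; rounding happens
    only in the human-readable rendering.
    """

    reduced: ReducedForm
    state: SteadyState
    derived: Optional[DerivedHemodynamics]
    provenance: Dict[str, Optional[str]]

    def to_dict(self) -> Dict:
        out = {
            "provenance": dict(self.provenance),
            "reduced": {k: v for k, v in asdict(self.reduced).items() if v is not None},
            "steady_state": {
                "Q": self.state.Q,
                "Z": self.state.Z,
                "P_R": self.state.P_R,
                "P_L": self.state.P_L,
                "pressures": dict(self.state.pressures),
                "volumes": dict(self.state.volumes),
                "residuals": {
                    "volume": self.state.residual_volume,
                    "flow_right": self.state.flow_mismatch_right,
                    "flow_left": self.state.flow_mismatch_left,
                },
            },
        }
        if self.derived is not None:
            out["derived"] = {
                "TPR": self.derived.TPR,
                "f4": self.derived.f4,
                "f5": self.derived.f5,
                "PA": self.derived.PA,
                "PPA": self.derived.PPA,
            }
        return out

    def state_table(self):
        """Steady-state variables as a tidy (variable, description, value)
        table, one row per physiological quantity."""
        import pandas as pd

        rows = []
        rf = self.reduced
        if rf.mu is not None:
            rows += [
                ("mu", "dimensionless conservation parameter", rf.mu),
                ("lambda", "dimensionless coupling parameter", rf.lam),
            ]
        rows += [
            ("Z", "scaled cardiac output Q/K", self.state.Z),
            ("Q", "cardiac output (L/min)", self.state.Q),
            ("P_R", "right atrial pressure = CVP (mmHg)", self.state.P_R),
            ("P_L", "left atrial pressure (mmHg)", self.state.P_L),
        ]
        for cid, p in self.state.pressures.items():
            if cid not in ("right_atrium", "left_atrium"):
                rows.append((f"P_{cid}", f"{cid} pressure (mmHg)", p))
        if self.derived is not None:
            rows += [
                ("PA", "arterial pressure (mmHg)", self.derived.PA),
                ("PPA", "pulmonary arterial pressure (mmHg)", self.derived.PPA),
            ]
        for cid, v in self.state.volumes.items():
            rows.append((f"V_{cid}", f"{cid} volume (L)", v))
        if self.derived is not None:
            rows += [
                ("TPR", "total peripheral resistance (mmHg/(L/min))", self.derived.TPR),
                ("f4", "visceral flow fraction", self.derived.f4),
                ("f5", "peripheral flow fraction", self.derived.f5),
            ]
        return pd.DataFrame(rows, columns=["variable", "description", "value"])


def solve_report(
    model: CirculationModel,
    config_path: Optional[str] = None,
    scenario: Optional[str] = None,
) -> RunReport:
    """Solve a model and package the result.

    The reduced (mu, lambda) pair is included when the model is
    balanced; derived hemodynamics when the systemic bed supports the
    visceral/peripheral split.
    """
    state = steady_state(model)
    try:
        reduced = reduced_mu_lambda(model)
    except SpecialCaseError:
        from .model import conservation_coefficients

        reduced = conservation_coefficients(model)
    try:
        derived = derived_hemodynamics(model, state)
    except ModelError:
        derived = None
    return RunReport(
        reduced=reduced,
        state=state,
        derived=derived,
        provenance={
            "tool": "steadycirc",
            "version": __version__,
            "config": str(config_path) if config_path else None,
            "scenario": scenario,
        },
    )
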