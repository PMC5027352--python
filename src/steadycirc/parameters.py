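"""Named-parameter access for circulation models.

A flat name space over every scalar a model owns, used by scenario
overrides, CLI ``--set`` flags and the sensitivity calculus:

==================  =====================================================
name                meaning
==================  =====================================================
``BV``, ``V0``      total / non-capacitive blood volume, L
``K``               both hearts' maximum output (balanced models), L/min
``K_R``, ``K_L``    per-side maximum output, L/min
``alpha_R`` ...     per-side curve shape / steepness (``alpha_L``,
                    ``beta_R``, ``beta_L``)
``P_ext_R/L``       per-side heart external pressure, mmHg
group names         shared external pressures declared by the model's
                    pressure groups (e.g. ``P_e``, ``P_a``), mmHg
``C_<id>``          compartment compliance, L/mmHg
``V0_<id>``         compartment unstressed volume, L
``RA_<id>``         compartment arterial resistance, mmHg/(L/min)
``RV_<id>``         compartment venous resistance, mmHg/(L/min)
``P_ext_<id>``      compartment external pressure, mmHg
==================  =====================================================

Setting a parameter returns a **new** model (value semantics); setting
a pressure-group name updates every member compartment and, when the
group includes the heart, both cardiac curves.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List

from .errors import SpecialCaseError
from .model import CirculationModel

__all__ = ["parameter_names", "get_parameter", "set_parameter"]


def parameter_names(model: CirculationModel) -> List[str]:
    """All settable parameter names for this model."""
    names = ["BV", "V0", "K_R", "K_L", "alpha_R", "beta_R", "alpha_L",
             "beta_L", "P_ext_R", "P_ext_L"]
    if model.balanced:
        names.insert(2, "K")
    names.extend(g.name for g in model.pressure_groups)
    for c in model.compartments:
        names.append(f"C_{c.id}")
        names.append(f"V0_{c.id}")
        names.append(f"P_ext_{c.id}")
        if not c.is_atrium:
            names.append(f"RA_{c.id}")
            names.append(f"RV_{c.id}")
    return names


def _group(model: CirculationModel, name: str):
    for g in model.pressure_groups:
        if g.name == name:
            return g
    return None


def get_parameter(model: CirculationModel, name: str) -> float:
    """Current value of a named parameter."""
    simple = {
        "BV": model.BV,
        "V0": model.V0,
        "K_R": model.right_heart.K,
        "K_L": model.left_heart.K,
        "alpha_R": model.right_heart.alpha,
        "beta_R": model.right_heart.beta,
        "alpha_L": model.left_heart.alpha,
        "beta_L": model.left_heart.beta,
        "P_ext_R": model.right_heart.P_ext,
        "P_ext_L": model.left_heart.P_ext,
    }
    if name == "K":
        if not model.balanced:
            raise SpecialCaseError(
                "parameter 'K' refers to both hearts jointly; this model is "
                "unbalanced — use 'K_R'/'K_L'"
            )
        return model.right_heart.K
    if name in simple:
        return simple[name]
    g = _group(model, name)
    if g is not None:
        values = [model.compartment(cid).P_ext for cid in g.compartments]
        if g.include_heart:
            values += [model.right_heart.P_ext, model.left_heart.P_ext]
        if max(values) - min(values) > 1e-12:
            raise ValueError(
                f"pressure group {name!r} members disagree ({values}); "
                "the group value is undefined"
            )
        return values[0]
    for prefix, fieldname in (
        ("C_", "C"), ("V0_", "V0n"), ("RA_", "RA"), ("RV_", "RV"),
        ("P_ext_", "P_ext"),
    ):
        if name.startswith(prefix):
            cid = name[len(prefix):]
            try:
                comp = model.compartment(cid)
            except KeyError:
                break
            value = getattr(comp, fieldname)
            if value is None:
                raise KeyError(f"compartment {cid!r} has no {fieldname}")
            return value
    raise KeyError(
        f"unknown parameter {name!r}; available: {', '.join(parameter_names(model))}"
    )


def set_parameter(model: CirculationModel, name: str, value: float) -> CirculationModel:
    """Return a copy of ``model`` with one named parameter changed."""
    value = float(value)
    if name == "BV":
        return replace(model, BV=value)
    if name == "V0":
        return replace(model, V0=value)
    if name == "K":
        get_parameter(model, "K")  # balanced check
        return replace(
            model,
            right_heart=replace(model.right_heart, K=value),
            left_heart=replace(model.left_heart, K=value),
        )
    heart_fields = {
        "K_R": ("right_heart", "K"),
        "K_L": ("left_heart", "K"),
        "alpha_R": ("right_heart", "alpha"),
        "beta_R": ("right_heart", "beta"),
        "alpha_L": ("left_heart", "alpha"),
        "beta_L": ("left_heart", "beta"),
        "P_ext_R": ("right_heart", "P_ext"),
        "P_ext_L": ("left_heart", "P_ext"),
    }
    if name in heart_fields:
        attr, fieldname = heart_fields[name]
        return replace(model, **{attr: replace(getattr(model, attr), **{fieldname: value})})
    g = _group(model, name)
    if g is not None:
        out = model
        for cid in g.compartments:
            out = out.replace_compartment(cid, P_ext=value)
        if g.include_heart:
            out = replace(
                out,
                right_heart=replace(out.right_heart, P_ext=value),
                left_heart=replace(out.left_heart, P_ext=value),
            )
        return out
    for prefix, fieldname in (
        ("C_", "C"), ("V0_", "V0n"), ("RA_", "RA"), ("RV_", "RV"),
        ("P_ext_", "P_ext"),
    ):
        if name.startswith(prefix):
            cid = name[len(prefix):]
            try:
                model.compartment(cid)
            except KeyError:
                break
            return model.replace_compartment(cid, **{fieldname: value})
    raise KeyError(
        f"unknown parameter {name!r}; available: {', '.join(parameter_names(model))}"
    )
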