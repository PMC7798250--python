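"""Scaled (logarithmic) sensitivity coefficients of model outputs.

The scaled sensitivity of an output y with respect to a parameter p is
the dimensionless elasticity (p/y)·∂y/∂p, estimated here by a central
finite difference on a multiplicative perturbation,

    [y(p·(1+δ)) − y(p·(1−δ))] / (2·δ·y(p)),

which is O(δ²)-accurate and exact for outputs linear in p.  Each
perturbed evaluation re-solves the model from scratch.

Parameters are addressed by string references:

``"<reaction_id>.k_f"`` / ``"<reaction_id>.k_r"``
    one rate constant of a mass-action reaction;
``"<reaction_id>.k"``
    both constants of that reaction together (a transport rate);
``"<name>"``
    a named scalar in ``model.parameters``.

A tuple/list of such references is perturbed *concomitantly by the same
factor* — the probe used to ask whether a model is robust against
rescaling all transport steps at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ModelError, SensitivityError
from .model import Model
from .simulate import integrate, steady_state

__all__ = ["SensitivityTable", "scaled_sensitivity", "ratio_sensitivity"]

OUTPUT_KINDS = ("steady_state", "transient_max")


def _atomic_refs(model: Model, ref: str) -> list[tuple[str, str]]:
    """Expand one string reference into [(kind, target)] atoms."""
    if ref in model.parameters:
        return [("global", ref)]
    if "." in ref:
        rid, attr = ref.rsplit(".", 1)
        rxn = model.reaction(rid)
        if rxn.rate_expression is not None:
            raise ModelError(f"reaction {rid!r} uses an expression law; perturb its "
                             f"named parameters instead")
        if attr == "k":
            return [("reaction", f"{rid}.k_f"), ("reaction", f"{rid}.k_r")]
        if attr in ("k_f", "k_r"):
            return [("reaction", ref)]
    raise ModelError(f"cannot resolve parameter reference {ref!r}")


def _scaled_model(model: Model, atoms: Sequence[tuple[str, str]], factor: float) -> Model:
    new = model.copy()
    for kind, target in atoms:
        if kind == "global":
            new.parameters[target] = new.parameters[target] * factor
        else:
            rid, attr = target.rsplit(".", 1)
            new.reactions = [
                replace(r, **{attr: getattr(r, attr) * factor}) if r.id == rid else r
                for r in new.reactions
            ]
    return new


def _current_values(model: Model, atoms) -> list[float]:
    vals = []
    for kind, target in atoms:
        if kind == "global":
            vals.append(model.parameters[target])
        else:
            rid, attr = target.rsplit(".", 1)
            vals.append(getattr(model.reaction(rid), attr))
    return vals


def _output_label(output: tuple[str, str]) -> str:
    return f"{output[0]}:{output[1]}"


@dataclass
class SensitivityTable:
    """Rows = outputs (species × kind), columns = parameters; entries are
    dimensionless scaled coefficients.  Cells whose base output is zero are
    undefined — stored as NaN *and* listed in :attr:`undefined` so they are
    never mistaken for a numeric result."""

    table: pd.DataFrame
    undefined: frozenset[tuple[str, str]]
    delta: float

    def entry(self, output: tuple[str, str] | str, param: str) -> float:
        row = _output_label(output) if isinstance(output, tuple) else output
        if (row, param) in self.undefined:
            raise SensitivityError(
                f"sensitivity of {row!r} w.r.t. {param!r} is undefined (base output is 0)"
            )
        return float(self.table.loc[row, param])


def _param_label(spec) -> str:
    if isinstance(spec, str):
        return spec
    return "+".join(spec)


def scaled_sensitivity(model: Model, outputs: Sequence[tuple[str, str]],
                       parameters: Sequence, delta: float = 1e-3,
                       t_end: float | None = None, n_points: int = 2001,
                       rtol: float = 1e-8, atol: float = 1e-12) -> SensitivityTable:
    """Scaled sensitivities of steady states / transient maxima.

    ``outputs`` is a sequence of (species_id, kind) with kind one of
    ``"steady_state"`` or ``"transient_max"``; transient maxima need a
    ``t_end`` and are read off a dense grid (``n_points`` ≥ 1000 bounds the
    discretisation error; ties broken by earliest time).
    """
    if not (0.0 < delta <= 0.1):
        raise ModelError(f"delta must lie in (0, 0.1], got {delta}")
    for sid, kind in outputs:
        model.species_by_id(sid)
        if kind not in OUTPUT_KINDS:
            raise ModelError(f"unknown output kind {kind!r}; expected one of {OUTPUT_KINDS}")
    needs_tmax = any(kind == "transient_max" for _, kind in outputs)
    if needs_tmax:
        if t_end is None:
            raise ModelError("transient_max outputs require t_end")
        if n_points < 1000:
            raise ModelError("transient_max outputs require n_points >= 1000")

    param_atoms = []
    for spec in parameters:
        refs = [spec] if isinstance(spec, str) else list(spec)
        atoms = [a for ref in refs for a in _atomic_refs(model, ref)]
        for v in _current_values(model, atoms):
            if v <= 0:
                raise ModelError(
                    f"parameter group {_param_label(spec)!r} contains a non-positive "
                    f"value; multiplicative perturbation is undefined"
                )
        param_atoms.append((_param_label(spec), atoms))

    def evaluate(m: Model, context: str) -> dict[str, float]:
        try:
            vals: dict[str, float] = {}
            if any(kind == "steady_state" for _, kind in outputs):
                ss = steady_state(m, rtol=rtol, atol=atol)
                for sid, kind in outputs:
                    if kind == "steady_state":
                        vals[_output_label((sid, kind))] = ss.concentrations[sid]
            if needs_tmax:
                traj = integrate(m, t_end, n_points=n_points, rtol=rtol, atol=atol)
                for sid, kind in outputs:
                    if kind == "transient_max":
                        vals[_output_label((sid, kind))] = float(np.max(traj.concentration(sid)))
            return vals
        except Exception as exc:
            raise SensitivityError(f"model solve failed at {context}: {exc}") from exc

    y0 = evaluate(model, "base point")
    rows = [_output_label(o) for o in outputs]
    data = np.full((len(rows), len(param_atoms)), np.nan)
    undefined: set[tuple[str, str]] = set()
    for j, (label, atoms) in enumerate(param_atoms):
        y_plus = evaluate(_scaled_model(model, atoms, 1.0 + delta), f"{label} * (1+delta)")
        y_minus = evaluate(_scaled_model(model, atoms, 1.0 - delta), f"{label} * (1-delta)")
        for i, row in enumerate(rows):
            if y0[row] == 0.0:
                undefined.add((row, label))
                continue
            data[i, j] = (y_plus[row] - y_minus[row]) / (2.0 * delta * y0[row])
    frame = pd.DataFrame(data, index=rows, columns=[lbl for lbl, _ in param_atoms])
    return SensitivityTable(table=frame, undefined=frozenset(undefined), delta=delta)


def ratio_sensitivity(table: SensitivityTable, numerator: tuple[str, str] | str,
                      denominator: tuple[str, str] | str, param: str) -> float:
    """Scaled sensitivity of the ratio of two outputs.

    Scaled coefficients are logarithmic derivatives, so the coefficient of
    y₁/y₂ is the difference of the individual coefficients.
    """
    return table.entry(numerator, param) - table.entry(denominator, param)
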