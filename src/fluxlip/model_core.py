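"""Constraint-based metabolic models: loading, validation, FBA and FVA.

The model container wraps :mod:`cobra` and exposes the pieces the rest of
the pipeline needs directly: the stoichiometric matrix, reaction bounds,
subsystem labels and gene--reaction rules.  Models are read either from
SBML (Level 3 with the ``fbc`` package) or from the COBRA community JSON
dialect, so small curated submodels can be dropped in without conversion.

Sign convention used throughout the package: positive flux on an exchange
reaction is secretion (export), negative is uptake.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import cobra
import numpy as np
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "MetabolicModel",
    "FluxVector",
    "ModelFormatError",
    "ModelValidationError",
    "InfeasibleModelError",
    "load_model",
    "model_from_cobra",
    "fba",
    "fva",
    "EPS_MASS",
    "EPS_BOUND",
]

#: mass-balance residual tolerance for a flux vector (‖S·v‖∞)
EPS_MASS = 1e-6
#: bound-violation tolerance for a flux vector
EPS_BOUND = 1e-9


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed in the named format."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates structural invariants."""


class InfeasibleModelError(RuntimeError):
    """Raised when an LP over the model has no feasible solution."""


@dataclass
class FluxVector:
    """A single feasible flux state, keyed by reaction ID."""

    values: dict[str, float]

    def as_array(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.values[r] for r in reaction_ids], dtype=float)

    def __getitem__(self, reaction_id: str) -> float:
        return self.values[reaction_id]


@dataclass
class MetabolicModel:
    """A validated stoichiometric model.

    Attributes
    ----------
    cobra_model:
        The underlying :class:`cobra.Model`; the single source of truth for
        stoichiometry, bounds and the objective.
    """

    cobra_model: cobra.Model
    metadata: dict = field(default_factory=dict)

    # -- structural accessors -------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.cobra_model.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.cobra_model.metabolites]

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.cobra_model.genes]

    @property
    def n_reactions(self) -> int:
        return len(self.cobra_model.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.cobra_model.metabolites)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, metabolites x reactions, column order = reaction_ids."""
        return create_stoichiometric_matrix(self.cobra_model)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.cobra_model.reactions])
        ub = np.array([r.upper_bound for r in self.cobra_model.reactions])
        return lb, ub

    def subsystems(self) -> dict[str, str]:
        """Reaction ID -> subsystem label (empty string when unannotated)."""
        return {r.id: (r.subsystem or "") for r in self.cobra_model.reactions}

    def gene_reaction_rules(self) -> dict[str, str]:
        return {r.id: r.gene_reaction_rule for r in self.cobra_model.reactions}

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.cobra_model.exchanges]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.cobra_model.copy(), dict(self.metadata))

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ModelValidationError`."""
        declared = set(self.metabolite_ids)
        for rxn in self.cobra_model.reactions:
            for met in rxn.metabolites:
                if met.id not in declared:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met.id!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
            if rxn.subsystem is None:
                rxn.subsystem = ""
        obj_rxns = [
            v for v in cobra.util.solver.linear_reaction_coefficients(self.cobra_model)
        ]
        if not obj_rxns:
            raise ModelValidationError("model declares no objective reaction")

    def check_flux_vector(
        self,
        v: FluxVector | np.ndarray,
        eps_mass: float = EPS_MASS,
        eps_bound: float = EPS_BOUND,
    ) -> bool:
        """True iff ``v`` satisfies S·v = 0 and the bounds within tolerance."""
        arr = v.as_array(self.reaction_ids) if isinstance(v, FluxVector) else np.asarray(v)
        S = self.stoichiometric_matrix()
        if S.size and np.max(np.abs(S @ arr)) > eps_mass:
            return False
        lb, ub = self.bounds()
        return bool(np.all(arr >= lb - eps_bound) and np.all(arr <= ub + eps_bound))

    def summary_text(self) -> str:
        subs = sorted({s for s in self.subsystems().values() if s})
        lines = [
            f"model: {self.cobra_model.id or '<unnamed>'}",
            f"metabolites: {self.n_metabolites}",
            f"reactions: {self.n_reactions}",
            f"genes: {len(self.cobra_model.genes)}",
            f"exchanges: {len(self.exchange_ids())}",
            f"subsystems: {len(subs)}",
            "sign convention: positive exchange flux = secretion, negative = uptake",
        ]
        return "\n".join(lines)


def model_from_cobra(model: cobra.Model, **metadata) -> MetabolicModel:
    """Wrap and validate an in-memory cobra model."""
    model.solver = "glpk"
    wrapped = MetabolicModel(model, dict(metadata))
    wrapped.validate()
    return wrapped


def load_model(path: str, format: str | None = None) -> MetabolicModel:
    """Load a model from ``path`` in SBML or COBRA-JSON format.

    ``format`` is ``"sbml"`` or ``"json"``; when *None* it is inferred from
    the file extension.  Unknown annotations survive on the underlying cobra
    objects as opaque metadata.
    """
    if format is None:
        format = "sbml" if str(path).endswith((".xml", ".sbml")) else "json"
    if format not in ("sbml", "json"):
        raise ValueError(f"unknown model format {format!r}; expected 'sbml' or 'json'")
    try:
        if format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = _load_json_validated(str(path))
    except (ModelValidationError, FileNotFoundError):
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc
    return model_from_cobra(model, source_path=str(path), source_format=format)


def _load_json_validated(path: str) -> cobra.Model:
    """Load COBRA JSON, checking stoichiometry references before cobra does.

    cobra's JSON reader raises an opaque KeyError on undeclared metabolites;
    pre-checking lets us name the offending reaction and metabolite.
    """
    with open(path) as fh:
        doc = json.load(fh)
    declared = {m["id"] for m in doc.get("metabolites", [])}
    for rxn in doc.get("reactions", []):
        for met_id in rxn.get("metabolites", {}):
            if met_id not in declared:
                raise ModelValidationError(
                    f"reaction {rxn.get('id')!r} references undeclared "
                    f"metabolite {met_id!r}"
                )
    return cobra.io.load_json_model(path)


def save_json(model: MetabolicModel, path: str) -> None:
    cobra.io.save_json_model(model.cobra_model, str(path))


def fba(model: MetabolicModel) -> tuple[float, FluxVector]:
    """Flux balance analysis: maximize/minimize the declared objective.

    Returns the LP optimum and one optimal flux vector.  Degenerate optima
    are resolved arbitrarily by the solver; only the objective value is
    guaranteed.  Raises :class:`InfeasibleModelError` on infeasibility.
    """
    sol = model.cobra_model.optimize()
    if sol.status != "optimal":
        raise InfeasibleModelError(f"FBA terminated with status {sol.status!r}")
    vec = FluxVector({r: float(sol.fluxes[r]) for r in model.reaction_ids})
    return float(sol.objective_value), vec


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reaction_ids: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis under ``objective >= fraction * optimum``."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    rxns = reaction_ids if reaction_ids is not None else model.reaction_ids
    try:
        df = cobra.flux_analysis.flux_variability_analysis(
            model.cobra_model,
            reaction_list=list(rxns),
            fraction_of_optimum=fraction_of_optimum,
        )
    except Exception as exc:
        raise InfeasibleModelError(f"FVA failed: {exc}") from exc
    out: dict[str, tuple[float, float]] = {}
    for rid in rxns:
        lo = float(df.loc[rid, "minimum"])
        hi = float(df.loc[rid, "maximum"])
        # solver jitter can invert by ~1e-9; clamp
        if lo > hi:
            lo = hi = 0.5 * (lo + hi)
        out[rid] = (lo, hi)
    return out
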