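"""Condition-specific model construction.

Turns a base stoichiometric model into wildtype- or knockout-specific
variants by (a) soft-scaling reaction bounds from transcript abundance
through the gene--reaction rules (GIMME-like: LP-only, deterministic),
(b) imposing exchange-flux constraints derived from metabolite
measurements, and (c) simulating gene or reaction knockouts.

Exchange sign convention: positive flux = secretion, negative = uptake.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .model_core import InfeasibleModelError, MetabolicModel, fba

__all__ = [
    "ExpressionProfile",
    "MetaboliteConstraint",
    "GPRParseError",
    "evaluate_gpr",
    "apply_expression_constraints",
    "apply_metabolite_constraints",
    "knockout",
    "read_expression_tsv",
    "read_constraints_tsv",
]


class GPRParseError(ValueError):
    """Malformed gene--reaction rule."""


@dataclass
class ExpressionProfile:
    """Gene expression values for one condition (nonnegative, any platform units)."""

    values: dict[str, float]
    condition: str = ""

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if v < 0}
        if bad:
            raise ValueError(f"negative expression values: {sorted(bad)[:5]}")

    def get(self, gene: str, default: float) -> float:
        return self.values.get(gene, default)


@dataclass
class MetaboliteConstraint:
    """One exchange-level constraint derived from a metabolite measurement."""

    metabolite_id: str
    direction: Literal["secretion_min", "uptake_min", "blocked"]
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("secretion_min", "uptake_min", "blocked"):
            raise ValueError(f"unknown constraint direction {self.direction!r}")
        if self.magnitude < 0:
            raise ValueError("constraint magnitude must be >= 0")


# -- GPR evaluation ----------------------------------------------------------


def _parse_rule(rule: str) -> ast.expr:
    try:
        tree = ast.parse(rule, mode="eval")
    except SyntaxError as exc:
        raise GPRParseError(
            f"malformed gene-reaction rule at offset {exc.offset}: {rule!r}"
        ) from exc
    return tree.body


def _eval_node(node: ast.expr, lookup) -> float:
    if isinstance(node, ast.BoolOp):
        child = [_eval_node(v, lookup) for v in node.values]
        if isinstance(node.op, ast.And):
            return min(child)
        return max(child)
    if isinstance(node, ast.Name):
        return lookup(node.id)
    raise GPRParseError(f"unsupported element {ast.dump(node)} in gene-reaction rule")


def evaluate_gpr(
    rule: str,
    profile: ExpressionProfile,
    missing_default: float | None = None,
) -> float:
    """Score a reaction from its boolean gene rule and an expression profile.

    AND combines by minimum, OR by maximum.  Genes absent from the profile
    score ``missing_default``; when that is *None* the profile median is
    used (so unmeasured genes never spuriously close a reaction).  An empty
    rule raises ``ValueError`` — callers treat rule-less reactions as
    unconstrained.
    """
    if not rule or not rule.strip():
        raise ValueError("empty gene-reaction rule has no activity score")
    if missing_default is None:
        missing_default = median(profile.values.values()) if profile.values else 0.0
    node = _parse_rule(rule)
    return float(_eval_node(node, lambda g: profile.get(g, missing_default)))


def _rule_genes(rule: str) -> set[str]:
    if not rule.strip():
        return set()
    return {n.id for n in ast.walk(_parse_rule(rule)) if isinstance(n, ast.Name)}


# -- expression constraints --------------------------------------------------


def apply_expression_constraints(
    model: MetabolicModel,
    profile: ExpressionProfile,
    threshold: float | None = None,
    floor: float = 0.0,
) -> MetabolicModel:
    """Scale down bounds of reactions whose expression support is low.

    A reaction with activity score ``a < threshold`` has both bounds
    multiplied by ``max(floor, a / threshold)``; reactions at or above the
    threshold, and reactions without a gene rule, are untouched.  The
    default threshold is the 25th percentile of expression over genes
    present in the model.  Returns a new model; the input is unmodified.
    """
    if not 0.0 <= floor < 1.0:
        raise ValueError("floor must lie in [0, 1)")
    model_genes = set(model.gene_ids) or {
        g for rule in model.gene_reaction_rules().values() for g in _rule_genes(rule)
    }
    overlap = model_genes & set(profile.values)
    if model_genes and not overlap:
        raise ValueError(
            "expression profile shares no genes with the model; "
            "check gene identifier namespaces"
        )
    if threshold is None:
        threshold = float(np.percentile([profile.values[g] for g in overlap], 25))
    if threshold <= 0:
        raise ValueError("expression threshold must be > 0")

    out = model.copy()
    # scale from base bounds (recorded on first application) so applying the
    # same profile twice equals applying it once
    base_bounds = out.metadata.get("context", {}).get("base_bounds")
    if base_bounds is None:
        base_bounds = {r.id: (r.lower_bound, r.upper_bound) for r in out.cobra_model.reactions}
    scaled = {}
    for rxn in out.cobra_model.reactions:
        rule = rxn.gene_reaction_rule
        if not rule.strip():
            continue
        a = evaluate_gpr(rule, profile)
        if a >= threshold:
            continue
        s = max(floor, a / threshold)
        lb0, ub0 = base_bounds.get(rxn.id, (rxn.lower_bound, rxn.upper_bound))
        rxn.bounds = (lb0 * s, ub0 * s)
        scaled[rxn.id] = s
    out.metadata.setdefault("context", {}).update(
        {
            "condition": profile.condition,
            "threshold": threshold,
            "floor": floor,
            "scaled_reactions": scaled,
            "base_bounds": base_bounds,
        }
    )
    return out


# -- metabolite constraints --------------------------------------------------


def _exchange_for(model: MetabolicModel, metabolite_id: str) -> str | None:
    for rxn in model.cobra_model.exchanges:
        if any(m.id == metabolite_id for m in rxn.metabolites):
            return rxn.id
    return None


def apply_metabolite_constraints(
    model: MetabolicModel,
    constraints: Iterable[MetaboliteConstraint],
) -> MetabolicModel:
    """Impose measured-metabolite constraints on exchange reactions.

    ``secretion_min`` raises the exchange lower bound to at least the
    magnitude; ``uptake_min`` forces uptake by capping the upper bound at
    ``-magnitude``; ``blocked`` closes the exchange.  Feasibility of the
    result is re-checked; an infeasible combination raises
    :class:`InfeasibleModelError` listing the constraint set.
    """
    constraints = list(constraints)
    missing = [
        c.metabolite_id for c in constraints if _exchange_for(model, c.metabolite_id) is None
    ]
    if missing:
        raise ValueError(f"no exchange reaction for metabolites: {missing}")

    out = model.copy()
    for c in constraints:
        rid = _exchange_for(out, c.metabolite_id)
        rxn = out.cobra_model.reactions.get_by_id(rid)
        if c.direction == "blocked":
            rxn.bounds = (0.0, 0.0)
        elif c.direction == "secretion_min":
            lb = max(rxn.lower_bound, c.magnitude)
            if lb > rxn.upper_bound:
                raise InfeasibleModelError(
                    f"secretion_min {c.magnitude} on {rid} conflicts with upper "
                    f"bound {rxn.upper_bound}; constraint set: {constraints}"
                )
            rxn.lower_bound = lb
        else:  # uptake_min
            ub = min(rxn.upper_bound, -c.magnitude)
            if ub < rxn.lower_bound:
                raise InfeasibleModelError(
                    f"uptake_min {c.magnitude} on {rid} conflicts with lower "
                    f"bound {rxn.lower_bound}; constraint set: {constraints}"
                )
            rxn.upper_bound = ub
    try:
        fba(out)
    except InfeasibleModelError as exc:
        raise InfeasibleModelError(
            f"metabolite constraints make the model infeasible: {constraints}"
        ) from exc
    out.metadata.setdefault("context", {})["metabolite_constraints"] = [
        (c.metabolite_id, c.direction, c.magnitude) for c in constraints
    ]
    return out


# -- knockout ----------------------------------------------------------------


def knockout(model: MetabolicModel, target: str) -> MetabolicModel:
    """Knock out a reaction (close its bounds) or a gene (via the GPRs).

    Gene knockout re-evaluates every rule containing the gene under pure
    boolean semantics with the target forced to 0 and all other genes to 1;
    reactions whose rule evaluates to 0 are closed.
    """
    out = model.copy()
    rxn_ids = set(out.reaction_ids)
    if target in rxn_ids:
        out.cobra_model.reactions.get_by_id(target).bounds = (0.0, 0.0)
        out.metadata["knockout"] = {"kind": "reaction", "target": target}
        return out
    gene_ids = set(out.gene_ids) or {
        g for rule in out.gene_reaction_rules().values() for g in _rule_genes(rule)
    }
    if target not in gene_ids:
        raise ValueError(f"unknown knockout target {target!r}: not a reaction or gene ID")
    closed = []
    for rxn in out.cobra_model.reactions:
        rule = rxn.gene_reaction_rule
        if target not in _rule_genes(rule):
            continue
        node = _parse_rule(rule)
        activity = _eval_node(node, lambda g: 0.0 if g == target else 1.0)
        if activity == 0.0:
            rxn.bounds = (0.0, 0.0)
            closed.append(rxn.id)
    out.metadata["knockout"] = {"kind": "gene", "target": target, "closed": closed}
    return out


# -- file readers ------------------------------------------------------------


def read_expression_tsv(path: str, condition: str = "") -> ExpressionProfile:
    """Two-column TSV (gene_id, value), header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, value)")
    first = df.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    values = {str(g): float(v) for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return ExpressionProfile(values, condition=condition)


def read_constraints_tsv(path: str) -> list[MetaboliteConstraint]:
    """TSV with columns metabolite_id, direction, magnitude."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    need = ["metabolite_id", "direction", "magnitude"]
    if not all(c in cols for c in need):
        raise ValueError(f"{path}: expected columns {need}, got {list(df.columns)}")
    return [
        MetaboliteConstraint(
            str(row[cols["metabolite_id"]]),
            str(row[cols["direction"]]),
            float(row[cols["magnitude"]]),
        )
        for _, row in df.iterrows()
    ]
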