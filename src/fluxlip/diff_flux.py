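"""Differential flux-state calling between two sampled conditions.

Per reaction, a one-way two-group ANOVA F statistic is computed on the
(normalized) flux samples, a fold change is taken on the absolute sampled
means, and reactions passing both the p-value and fold-change filters are
flagged altered.  Altered reactions are then rolled up to subsystem tallies
and to the set of metabolites they touch, with a keyword-based lipid
annotation of subsystem labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .flux_sampler import FluxSampleSet
from .model_core import MetabolicModel

__all__ = [
    "LIPID_KEYWORDS",
    "DiffFluxResult",
    "RollupReport",
    "reaction_ftest",
    "call_altered_reactions",
    "rollup",
    "bh_adjust_column",
]

#: subsystem keywords treated as lipid-related (case-insensitive substring match)
LIPID_KEYWORDS = [
    "fatty acid",
    "bile acid",
    "eicosanoid",
    "prostaglandin",
    "sphingolipid",
    "glycerolipid",
    "glycerophospholipid",
    "cholesterol",
    "steroid",
    "carnitine",
    "squalene",
    "phosphatidylinositol",
]

EPS_FC = 1e-9  # pseudocount guarding the fold-change denominator


def reaction_ftest(wt_samples, ko_samples) -> tuple[float, float]:
    """Two-group one-way ANOVA F test on sampled fluxes of one reaction.

    ``F = MS_between / MS_within`` with (1, n1 + n2 - 2) degrees of freedom;
    algebraically ``F == t_pooled ** 2``.  Degenerate inputs (zero within-
    group variance in both groups) give ``(0, 1)`` for equal means and
    ``(inf, 0)`` otherwise.
    """
    a = np.asarray(wt_samples, dtype=float)
    b = np.asarray(ko_samples, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per condition")
    grand = (a.sum() + b.sum()) / (n1 + n2)
    ss_between = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_between = 1
    df_within = n1 + n2 - 2
    if ss_within <= 0:
        if ss_between <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return float(F), p


def fold_change_abs(wt_mean: float, ko_mean: float, eps: float = EPS_FC) -> float:
    """KO/WT ratio on absolute means with a pseudocount."""
    return (abs(ko_mean) + eps) / (abs(wt_mean) + eps)


@dataclass
class DiffFluxResult:
    """Per-reaction differential statistics plus the thresholds used."""

    table: pd.DataFrame  # index: reaction_id
    alpha: float
    fc_hi: float
    fc_lo: float

    @property
    def altered_reactions(self) -> list[str]:
        return list(self.table.index[self.table["altered"]])

    @property
    def n_altered(self) -> int:
        return int(self.table["altered"].sum())

    def save_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="reaction_id")


def call_altered_reactions(
    wt: FluxSampleSet,
    ko: FluxSampleSet,
    alpha_flux: float = 0.001,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    subsystems: dict[str, str] | None = None,
    bh_adjust: bool = False,
) -> DiffFluxResult:
    """Call differentially altered reactions between two sample sets.

    A reaction is flagged altered iff ``p < alpha_flux`` and the KO/WT fold
    change on absolute means is ``> fc_hi`` or ``< fc_lo``.  Sample sets
    must cover the same reactions in the same order-insensitive sense.
    ``bh_adjust=True`` adds a Benjamini-Hochberg column (the filter still
    uses raw p, matching the raw-threshold convention).
    """
    wt_ids, ko_ids = set(wt.reaction_ids), set(ko.reaction_ids)
    if wt_ids != ko_ids:
        diff = sorted(wt_ids ^ ko_ids)
        raise ValueError(f"sample sets cover different reactions: {diff[:10]}")
    rids = list(wt.reaction_ids)
    ko_frame = ko.to_frame()[rids]

    wt_m = wt.samples.mean(axis=0)
    ko_arr = ko_frame.to_numpy(dtype=float)
    ko_m = ko_arr.mean(axis=0)

    rows = []
    for j, rid in enumerate(rids):
        F, p = reaction_ftest(wt.samples[:, j], ko_arr[:, j])
        fc = fold_change_abs(wt_m[j], ko_m[j])
        sign_change = wt_m[j] * ko_m[j] < 0 and min(abs(wt_m[j]), abs(ko_m[j])) > EPS_FC
        altered = (p < alpha_flux) and (fc > fc_hi or fc < fc_lo)
        rows.append(
            {
                "reaction_id": rid,
                "subsystem": (subsystems or {}).get(rid, ""),
                "wt_mean": wt_m[j],
                "ko_mean": ko_m[j],
                "fold_change": fc,
                "sign_change": sign_change,
                "F": F,
                "p": p,
                "altered": altered,
            }
        )
    table = pd.DataFrame(rows).set_index("reaction_id")
    if bh_adjust:
        table["p_bh"] = bh_adjust_column(table["p"].to_numpy())
    return DiffFluxResult(table, alpha_flux, fc_hi, fc_lo)


def bh_adjust_column(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


@dataclass
class RollupReport:
    """Subsystem tallies and affected/lipid metabolite sets."""

    subsystem_tally: dict[str, int]
    affected_metabolites: set[str]
    lipid_metabolites: set[str]
    mode: str = "all"

    @property
    def lipid_share_percent(self) -> int:
        """Integer percent of affected metabolites carrying a lipid annotation."""
        if not self.affected_metabolites:
            return 0
        return round(100 * len(self.lipid_metabolites) / len(self.affected_metabolites))

    def to_dict(self) -> dict:
        return {
            "subsystem_tally": dict(sorted(self.subsystem_tally.items())),
            "n_altered_reactions": sum(self.subsystem_tally.values()),
            "n_affected_metabolites": len(self.affected_metabolites),
            "n_lipid_metabolites": len(self.lipid_metabolites),
            "lipid_share_percent": self.lipid_share_percent,
            "mode": self.mode,
        }


def rollup(
    result: DiffFluxResult,
    model: MetabolicModel,
    lipid_subsystems: list[str] | None = None,
    affected_mode: str = "all",
) -> RollupReport:
    """Roll altered reactions up to subsystems and affected metabolites.

    A metabolite counts as affected iff it appears with nonzero
    stoichiometry in at least one altered reaction (``affected_mode="all"``)
    or altered exchange reaction (``"exchange"``); it is lipid-annotated iff
    one of those reactions' subsystem labels contains a lipid keyword
    (case-insensitive substring).
    """
    if affected_mode not in ("all", "exchange"):
        raise ValueError("affected_mode must be 'all' or 'exchange'")
    if lipid_subsystems is None:
        lipid_subsystems = LIPID_KEYWORDS
    keywords = [k.lower() for k in lipid_subsystems]
    if not keywords:
        import warnings

        warnings.warn("empty lipid subsystem list; lipid subset will be empty")

    subsys = model.subsystems()
    exchange = set(model.exchange_ids())
    tally: dict[str, int] = {}
    affected: set[str] = set()
    lipid: set[str] = set()
    altered = set(result.altered_reactions)
    for rid in altered:
        label = subsys.get(rid, "")
        tally[label] = tally.get(label, 0) + 1
        if affected_mode == "exchange" and rid not in exchange:
            continue
        rxn = model.cobra_model.reactions.get_by_id(rid)
        mets = {m.id for m, c in rxn.metabolites.items() if c != 0}
        affected |= mets
        if any(k in label.lower() for k in keywords):
            lipid |= mets
    return RollupReport(tally, affected, lipid, mode=affected_mode)
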