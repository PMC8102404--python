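"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators: toy metabolic networks with a deletable uptake exchange
(the transporter-knockout stand-in), metabolomics tables with planted
group effects, and two structural classes of lipid SMILES (acyclic
carboxylic chains vs polycyclic / charged species).  All generators are
deterministic under their seed, and ground-truth sets are exact (derived
by construction or exhaustive FVA), never sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .chem_ml import MoleculeRecord
from .metabolomics_stats import MetaboliteTable
from .model_core import MetabolicModel, fva, model_from_cobra

__all__ = [
    "SyntheticSpec",
    "make_toy_network",
    "make_metabolomics",
    "make_lipid_classes",
    "toy_chain_model",
    "branched_toy_model",
    "box_model",
]

LIPID_SUBSYSTEMS = [
    "Fatty acid oxidation",
    "Bile acid synthesis",
    "Sphingolipid metabolism",
    "Glycerophospholipid metabolism",
    "Cholesterol metabolism",
    "Eicosanoid metabolism",
]
NONLIPID_SUBSYSTEMS = [
    "Glycolysis/gluconeogenesis",
    "Citric acid cycle",
    "Nucleotide interconversion",
    "Amino acid metabolism",
]


@dataclass
class SyntheticSpec:
    """Knobs for all three generators; counts must be positive."""

    seed: int = 0
    # network
    n_pathways: int = 3
    pathway_length: int = 3
    branch_count: int = 0
    knockout_pathway: int = 1
    uptake_bound: float = 10.0
    # metabolomics
    n_samples_per_group: int = 5
    n_metabolites: int = 342
    planted_fraction: float = 0.3
    effect_fold: float = 4.0
    noise_sigma: float = 0.3
    missing_rate: float = 0.05
    # chem
    n_elevated: int = 86
    n_decreased: int = 40
    chain_length_range: tuple[int, int] = (6, 26)

    def __post_init__(self) -> None:
        for name in (
            "n_pathways",
            "pathway_length",
            "n_samples_per_group",
            "n_metabolites",
            "n_elevated",
            "n_decreased",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_fold <= 0:
            raise ValueError("effect_fold must be > 0")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")


# -- small fixed models ------------------------------------------------------


def _new_model(mid: str) -> cobra.Model:
    m = cobra.Model(mid)
    m.solver = "glpk"
    return m


def toy_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_A (uptake <= ``uptake``) -> A -> B -> EX_B, maximize EX_B."""
    m = _new_model("toy_chain")
    A = cobra.Metabolite("A", compartment="c")
    B = cobra.Metabolite("B", compartment="c")
    ex_a = cobra.Reaction("EX_A")
    ex_a.add_metabolites({A: -1})
    ex_a.bounds = (-uptake, 0)
    ex_a.subsystem = "Transport, extracellular"
    r1 = cobra.Reaction("R1")
    r1.add_metabolites({A: -1, B: 1})
    r1.bounds = (0, 1000)
    r1.subsystem = "Fatty acid oxidation"
    ex_b = cobra.Reaction("EX_B")
    ex_b.add_metabolites({B: -1})
    ex_b.bounds = (0, 1000)
    ex_b.subsystem = "Transport, extracellular"
    m.add_reactions([ex_a, r1, ex_b])
    m.objective = "EX_B"
    return model_from_cobra(m)


def branched_toy_model(
    uptake: float = 10.0, route1_cap: float = 4.0, route2_cap: float = 3.0
) -> MetabolicModel:
    """Two routes A->B: direct (capped ``route1_cap``) and via C (``route2_cap``)."""
    m = _new_model("branched_toy")
    A = cobra.Metabolite("A", compartment="c")
    B = cobra.Metabolite("B", compartment="c")
    C = cobra.Metabolite("C", compartment="c")
    ex_a = cobra.Reaction("EX_A")
    ex_a.add_metabolites({A: -1})
    ex_a.bounds = (-uptake, 0)
    r1 = cobra.Reaction("R1")
    r1.add_metabolites({A: -1, B: 1})
    r1.bounds = (0, route1_cap)
    r2a = cobra.Reaction("R2a")
    r2a.add_metabolites({A: -1, C: 1})
    r2a.bounds = (0, route2_cap)
    r2b = cobra.Reaction("R2b")
    r2b.add_metabolites({C: -1, B: 1})
    r2b.bounds = (0, 1000)
    ex_b = cobra.Reaction("EX_B")
    ex_b.add_metabolites({B: -1})
    ex_b.bounds = (0, 1000)
    m.add_reactions([ex_a, r1, r2a, r2b, ex_b])
    m.objective = "EX_B"
    return model_from_cobra(m)


def box_model(bounds: list[tuple[float, float]]) -> MetabolicModel:
    """Axis-aligned box polytope: independent source->sink coordinate pairs.

    Coordinate ``i`` is realized as ``SRC_i`` (makes ``A_i``) coupled to
    ``SNK_i`` (consumes it), both bounded by ``bounds[i]``; the feasible
    region projects to the product box, with analytic centroid at the bound
    midpoints.
    """
    m = _new_model("box")
    rxns = []
    for i, (lo, hi) in enumerate(bounds):
        if lo > hi:
            raise ValueError(f"bounds[{i}] inverted")
        met = cobra.Metabolite(f"A{i}", compartment="c")
        src = cobra.Reaction(f"SRC_{i}")
        src.add_metabolites({met: 1})
        src.bounds = (lo, hi)
        snk = cobra.Reaction(f"SNK_{i}")
        snk.add_metabolites({met: -1})
        snk.bounds = (lo, hi)
        rxns += [src, snk]
    m.add_reactions(rxns)
    m.objective = "SNK_0"
    return model_from_cobra(m)


# -- toy network with planted knockout ---------------------------------------


def make_toy_network(spec: SyntheticSpec) -> tuple[MetabolicModel, MetabolicModel, set[str]]:
    """Parallel linear pathways sharing a cofactor, with a planted knockout.

    Returns ``(wildtype, knockout, ground_truth)`` where the knockout model
    closes the designated pathway's uptake exchange and ``ground_truth`` is
    the exact set of reactions whose FVA range changes under the knockout.
    """
    if not 0 <= spec.knockout_pathway < spec.n_pathways:
        raise ValueError(
            f"knockout_pathway {spec.knockout_pathway} outside 0..{spec.n_pathways - 1}"
        )
    rng = np.random.default_rng(spec.seed)
    m = _new_model(f"toy_network_seed{spec.seed}")
    cof_a = cobra.Metabolite("cof_a", compartment="c")
    cof_b = cobra.Metabolite("cof_b", compartment="c")
    rxns: list[cobra.Reaction] = []
    subsystems = LIPID_SUBSYSTEMS + NONLIPID_SUBSYSTEMS
    for p in range(spec.n_pathways):
        sub = subsystems[p % len(subsystems)]
        mets = [
            cobra.Metabolite(f"M{p}_{j}", compartment="c")
            for j in range(spec.pathway_length + 1)
        ]
        upt = cobra.Reaction(f"EX_upt_{p}")
        upt.add_metabolites({mets[0]: -1})
        upt.bounds = (-spec.uptake_bound, 0)
        upt.subsystem = "Transport, extracellular"
        rxns.append(upt)
        for j in range(spec.pathway_length):
            r = cobra.Reaction(f"R{p}_{j}")
            stoich = {mets[j]: -1, mets[j + 1]: 1}
            if j == 0:
                stoich.update({cof_a: -1, cof_b: 1})
            r.add_metabolites(stoich)
            r.bounds = (0, 1000)
            r.subsystem = sub
            r.gene_reaction_rule = f"g{p}_{j}"
            rxns.append(r)
            if j == 1 and p < spec.branch_count:
                alt = cobra.Reaction(f"R{p}_{j}alt")
                alt.add_metabolites({mets[j]: -1, mets[j + 1]: 1})
                alt.bounds = (0, float(rng.integers(1, 5)))
                alt.subsystem = sub
                alt.gene_reaction_rule = f"g{p}_{j}alt or g{p}_{j}"
                rxns.append(alt)
        sec = cobra.Reaction(f"EX_sec_{p}")
        sec.add_metabolites({mets[-1]: -1})
        sec.bounds = (0, 1000)
        sec.subsystem = "Transport, extracellular"
        rxns.append(sec)
    recycle = cobra.Reaction("R_cof")
    recycle.add_metabolites({cof_b: -1, cof_a: 1})
    recycle.bounds = (0, 1000)
    recycle.subsystem = "Citric acid cycle"
    rxns.append(recycle)
    m.add_reactions(rxns)
    m.objective = "EX_sec_0"
    wt = model_from_cobra(m, seed=spec.seed)

    ko = wt.copy()
    ko.cobra_model.reactions.get_by_id(f"EX_upt_{spec.knockout_pathway}").bounds = (0, 0)
    ko.metadata["knockout"] = {
        "kind": "reaction",
        "target": f"EX_upt_{spec.knockout_pathway}",
    }

    wt_fva = fva(wt, fraction_of_optimum=0.0)
    ko_fva = fva(ko, fraction_of_optimum=0.0)
    tol = 1e-6
    truth = {
        rid
        for rid in wt.reaction_ids
        if abs(wt_fva[rid][0] - ko_fva[rid][0]) > tol
        or abs(wt_fva[rid][1] - ko_fva[rid][1]) > tol
    }
    return wt, ko, truth


# -- metabolomics tables -----------------------------------------------------


def make_metabolomics(spec: SyntheticSpec) -> tuple[MetaboliteTable, dict[str, str]]:
    """Lognormal abundance table with planted directional group effects.

    Half of the planted metabolites are elevated in the KO group by
    ``effect_fold``, half decreased by its reciprocal.  Metabolites are
    partitioned into subpathways of size 3-30, filled in planted-first
    order so some subpathways concentrate planted effects (exercising the
    enrichment statistics).  Missing cells are MCAR at ``missing_rate``.
    Returns the table and the exact metabolite -> direction ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n_met = spec.n_metabolites
    mets = [f"met_{i:04d}" for i in range(n_met)]
    n_planted = int(round(spec.planted_fraction * n_met))
    n_up = n_planted // 2
    planted = list(rng.choice(n_met, size=n_planted, replace=False))
    truth = {mets[i]: ("elevated" if r < n_up else "decreased") for r, i in enumerate(planted)}

    samples = [f"WT_{i}" for i in range(spec.n_samples_per_group)] + [
        f"KO_{i}" for i in range(spec.n_samples_per_group)
    ]
    groups = pd.Series(
        ["WT"] * spec.n_samples_per_group + ["KO"] * spec.n_samples_per_group,
        index=samples,
        name="group",
    )

    base = rng.uniform(math.log(50), math.log(5000), size=n_met)
    log_ab = rng.normal(0.0, spec.noise_sigma, size=(len(samples), n_met)) + base
    ko_rows = groups.to_numpy() == "KO"
    for met, direction in truth.items():
        j = mets.index(met)
        shift = math.log(spec.effect_fold if direction == "elevated" else 1 / spec.effect_fold)
        log_ab[ko_rows, j] += shift
    ab = pd.DataFrame(np.exp(log_ab), index=samples, columns=mets)

    if spec.missing_rate > 0:
        mask = rng.random(ab.shape) < spec.missing_rate
        ab = ab.mask(mask)

    # subpathways filled planted-first so effects concentrate in early bins
    order = planted + [i for i in range(n_met) if i not in set(planted)]
    sub_of: dict[str, str] = {}
    sub_idx = 0
    pos = 0
    while pos < n_met:
        size = int(rng.integers(3, 31))
        for i in order[pos : pos + size]:
            sub_of[mets[i]] = f"subpathway_{sub_idx:02d}"
        pos += size
        sub_idx += 1
    annotations = pd.DataFrame(
        {
            "superpathway": ["Lipid"] * n_met,
            "subpathway": [sub_of[m] for m in mets],
            "hmdb_id": [f"HMDB{i:07d}" for i in range(n_met)],
        },
        index=pd.Index(mets, name="metabolite_id"),
    )
    return MetaboliteTable(ab, groups, annotations), truth


# -- lipid structure classes -------------------------------------------------

# fused-ring cores for the decreased class (validated at import by RDKit in
# chem_ml when descriptors are computed); ring counts 2-4
_RING_CORES = [
    "C1CCC2CCCCC2C1",  # decalin, 2 rings
    "C1CCC2C(C1)CCC3CCCCC23",  # perhydrophenanthrene, 3 rings
    "C1CCC2C(C1)CCC3C2CCC4CCCC34",  # steroid-like, 4 rings
    "OC1CCC2C(C1)CCC3C2CCC4CCCC34",  # hydroxylated steroid-like, 4 rings
]
_CHARGED_HEADS = ["[N+](C)(C)C", "[NH3+]"]


def _chain_smiles(length: int, n_oh: int, diacid: bool, n_db: int) -> str:
    """Acyclic (di)carboxylic chain with hydroxyl decorations and cis-free
    double bonds, assembled from a linear grammar (no ring tokens)."""
    units = ["C"] * length
    # spread double bonds along the chain interior
    for k in range(n_db):
        pos = 2 + 3 * k
        if pos + 1 < length - 1:
            units[pos] = "C=C"
            units[pos + 1] = ""
    # hydroxyl decorations on interior carbons
    placed = 0
    for k in range(1, length - 1):
        if placed >= n_oh:
            break
        if units[k] == "C":
            units[k] = "C(O)"
            placed += 1
    body = "".join(units)
    head = "OC(=O)" if diacid else "C"
    return head + body + "C(=O)O"


def make_lipid_classes(spec: SyntheticSpec) -> list[MoleculeRecord]:
    """Two-class lipid set: acyclic acids (elevated) vs polycyclics (decreased).

    The elevated class is generated from a chain grammar with no ring
    tokens (so ``nof_Rings`` is 0 by construction); the decreased class is
    built from fused-ring templates, some with charged head groups, so every
    member has at least two rings.  Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.chain_length_range
    if lo < 4 or hi <= lo:
        raise ValueError("chain_length_range must satisfy 4 <= lo < hi")

    elevated: list[MoleculeRecord] = []
    seen: set[str] = set()
    sub_cycle = ["Long-chain fatty acid", "Polyunsaturated fatty acid", "Diacylglycerol"]
    i = 0
    while len(elevated) < spec.n_elevated:
        length = int(rng.integers(lo, hi + 1))
        n_oh = int(rng.integers(0, 3))
        diacid = bool(rng.random() < 0.3)
        n_db = int(rng.integers(0, 4))
        smi = _chain_smiles(length, n_oh, diacid, n_db)
        if smi in seen:
            i += 1
            continue
        seen.add(smi)
        elevated.append(
            MoleculeRecord(
                name=f"elev_{len(elevated):03d}",
                smiles=smi,
                direction="elevated",
                subpathway=sub_cycle[len(elevated) % len(sub_cycle)],
            )
        )
        i += 1
        if i > 50 * spec.n_elevated:
            raise RuntimeError("chain grammar exhausted before reaching class size")

    decreased: list[MoleculeRecord] = []
    sub_cycle_d = ["Primary bile acid metabolism", "Ceramides", "Sphingolipid metabolism"]
    i = 0
    while len(decreased) < spec.n_decreased:
        core = _RING_CORES[int(rng.integers(len(_RING_CORES)))]
        tail = "C" * int(rng.integers(0, 9))
        head = ""
        if rng.random() < 0.5:
            head = _CHARGED_HEADS[int(rng.integers(len(_CHARGED_HEADS)))]
        smi = core + tail + head if (tail or head) else core
        if smi in seen:
            i += 1
            if i > 50 * spec.n_decreased:
                raise RuntimeError("ring templates exhausted before reaching class size")
            continue
        seen.add(smi)
        decreased.append(
            MoleculeRecord(
                name=f"decr_{len(decreased):03d}",
                smiles=smi,
                direction="decreased",
                subpathway=sub_cycle_d[len(decreased) % len(sub_cycle_d)],
            )
        )
        i += 1
    return elevated + decreased
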