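"""Chemoinformatics of elevated vs decreased lipids.

Computes a ~32-feature molecular descriptor panel from SMILES, selects
discriminative features (correlation pruning + information gain), balances
the classes, validates classifiers with leave-one-out, and produces a
force-optimized FreeViz-style 2-D projection.

Descriptor definitions (the named panel):

* ``nof_Rings`` — smallest set of smallest rings count.
* ``nof_COOH`` — carboxylic acid / carboxylate substructures.
* ``nof_OH`` — hydroxyls excluding carboxyl hydroxyls.
* ``nof_RotB`` — rotatable bonds (strict: amide C-N excluded).
* ``nof_Chirals`` — tetrahedral stereocenters, assigned + unassigned.
* ``C_sp3`` — sp3-hybridized carbons; ``C_R0`` — carbons in no ring.
* ``posCharge_per_volume`` — summed positive Gasteiger partial charges
  (iterative electronegativity equalization) over an additive
  atomic-contribution (McGowan) molecular volume.
* ``complexity`` — Bertz graph-complexity index, a proxy for
  platform-reported complexity values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MoleculeRecord",
    "ClassificationReport",
    "compute_descriptors",
    "descriptor_table",
    "select_features",
    "information_gain",
    "balance",
    "loo_evaluate",
    "freeviz_project",
    "read_molecules_tsv",
    "MODEL_NAMES",
]

MODEL_NAMES = ("decision_tree", "random_forest", "knn", "logistic")
SAMPLING_SCHEMES = ("downsample", "upsample", "combined")

_SMARTS_COOH = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_SMARTS_COO_ANION = Chem.MolFromSmarts("[CX3](=O)[OX1-]")
_SMARTS_OH = Chem.MolFromSmarts("[OX2H]")
_SMARTS_AMIDE = Chem.MolFromSmarts("[NX3][CX3](=[OX1])")

# McGowan characteristic volumes (cm^3/mol divided by 100), minus 6.56 per bond
_MCGOWAN = {
    "H": 8.71, "C": 16.35, "N": 14.39, "O": 12.43, "F": 10.48, "Si": 26.83,
    "P": 24.87, "S": 22.91, "Cl": 20.95, "Br": 26.21, "I": 34.53, "B": 18.32,
}


@dataclass
class MoleculeRecord:
    """One lipid: name, structure, direction label and descriptor vector."""

    name: str
    smiles: str
    direction: str  # "elevated" or "decreased"
    subpathway: str = ""
    descriptors: dict[str, float] | None = None

    def with_descriptors(self) -> "MoleculeRecord":
        if self.descriptors is not None:
            return self
        return replace(self, descriptors=compute_descriptors(self.smiles, name=self.name))


def _mcgowan_volume(mol: Chem.Mol) -> float:
    molH = Chem.AddHs(mol)
    vol = 0.0
    for atom in molH.GetAtoms():
        vol += _MCGOWAN.get(atom.GetSymbol(), 16.35)
    vol -= 6.56 * molH.GetNumBonds()
    return vol


def _gasteiger_positive_sum(mol: Chem.Mol, name: str) -> float:
    molH = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(molH)
    charges = [atom.GetDoubleProp("_GasteigerCharge") for atom in molH.GetAtoms()]
    if any(math.isnan(c) or math.isinf(c) for c in charges):
        warnings.warn(f"Gasteiger charges did not converge for {name!r}; feature set to 0")
        return 0.0
    return float(sum(c for c in charges if c > 0))


def compute_descriptors(smiles: str, name: str = "") -> dict[str, float]:
    """Full descriptor panel for one SMILES; raises on unparseable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for record {name!r}: {smiles!r}")

    cooh = mol.GetSubstructMatches(_SMARTS_COOH) + mol.GetSubstructMatches(_SMARTS_COO_ANION)
    cooh_oxygens = {m[-1] for m in cooh}
    oh_all = mol.GetSubstructMatches(_SMARTS_OH)
    n_oh = sum(1 for (o,) in oh_all if o not in cooh_oxygens)

    carbons = [a for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    c_sp3 = sum(1 for a in carbons if a.GetHybridization() == Chem.HybridizationType.SP3)
    c_r0 = sum(1 for a in carbons if not a.IsInRing())

    chirals = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    volume = _mcgowan_volume(mol)
    pos_charge = _gasteiger_positive_sum(mol, name)

    d: dict[str, float] = {
        "nof_Rings": float(rdMolDescriptors.CalcNumRings(mol)),
        "nof_COOH": float(len(cooh)),
        "nof_OH": float(n_oh),
        "nof_RotB": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "nof_Chirals": float(len(chirals)),
        "C_sp3": float(c_sp3),
        "C_R0": float(c_r0),
        "posCharge_per_volume": pos_charge / volume if volume > 0 else 0.0,
        "complexity": float(Descriptors.BertzCT(mol)),
        # standard supplementary panel
        "mol_weight": float(Descriptors.MolWt(mol)),
        "mol_volume": volume,
        "mol_area": float(Descriptors.LabuteASA(mol)),
        "tpsa": float(Descriptors.TPSA(mol)),
        "logp": float(Crippen.MolLogP(mol)),
        "hbd": float(Lipinski.NumHDonors(mol)),
        "hba": float(Lipinski.NumHAcceptors(mol)),
        "heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "n_carbon": float(len(carbons)),
        "n_nitrogen": float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N")),
        "n_oxygen": float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "O")),
        "n_sulfur": float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "S")),
        "n_heteroatoms": float(rdMolDescriptors.CalcNumHeteroatoms(mol)),
        "aromatic_rings": float(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "ring_atoms": float(sum(1 for a in mol.GetAtoms() if a.IsInRing())),
        "frac_C_sp3": float(rdMolDescriptors.CalcFractionCSP3(mol)),
        "n_double_bonds": float(
            sum(1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE)
        ),
        "n_amide": float(len(mol.GetSubstructMatches(_SMARTS_AMIDE))),
        "formal_charge": float(Chem.GetFormalCharge(mol)),
        "pos_charge_sum": pos_charge,
        "n_pos_atoms": float(sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() > 0)),
        "n_neg_atoms": float(sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() < 0)),
        "n_bonds": float(mol.GetNumBonds()),
    }
    return d


def descriptor_table(records: list[MoleculeRecord]) -> pd.DataFrame:
    """Descriptor matrix (rows = molecules) for a record list."""
    recs = [r.with_descriptors() for r in records]
    df = pd.DataFrame([r.descriptors for r in recs], index=[r.name for r in recs])
    if df.isna().any().any():
        raise ValueError("descriptor vectors must be complete")
    return df


# -- feature selection -------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(x: np.ndarray, y: np.ndarray, bins: int = 4) -> float:
    """Information gain of class ``y`` from equal-frequency discretized ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    h_y = _entropy(np.bincount(y_idx))
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    b = np.searchsorted(edges, x, side="right")
    h_cond = 0.0
    for bv in np.unique(b):
        mask = b == bv
        h_cond += mask.mean() * _entropy(np.bincount(y_idx[mask], minlength=len(classes)))
    return h_y - h_cond


def select_features(
    records: list[MoleculeRecord],
    target_count: int = 6,
    corr_cutoff: float = 0.9,
) -> list[str]:
    """Pick an ordered discriminative feature subset.

    First the lower-ranked member of every feature pair with absolute
    Pearson correlation above ``corr_cutoff`` is dropped (rank = information
    gain of the direction label under equal-frequency 4-bin discretization,
    ties broken by name); then the top ``target_count`` survivors are
    returned in rank order.
    """
    if target_count < 2:
        raise ValueError("target_count must be >= 2")
    df = descriptor_table(records)
    y = np.array([r.direction for r in records])
    gains = {
        f: information_gain(df[f].to_numpy(), y) for f in df.columns
    }
    ranked = sorted(df.columns, key=lambda f: (-gains[f], f))
    corr = df.corr().abs()
    kept: list[str] = []
    for f in ranked:
        if df[f].std() == 0:
            continue
        if any(corr.loc[f, k] > corr_cutoff for k in kept):
            continue
        kept.append(f)
    if len(kept) < target_count:
        warnings.warn(
            f"only {len(kept)} features survive correlation pruning "
            f"(requested {target_count}); returning all"
        )
        return kept
    return kept[:target_count]


# -- class balancing ---------------------------------------------------------


def balance(
    records: list[MoleculeRecord], scheme: str = "downsample", seed: int = 0
) -> list[MoleculeRecord]:
    """Balance the two direction classes by resampling.

    ``downsample`` reduces the majority class to the minority size;
    ``upsample`` resamples the minority with replacement up to the majority
    size; ``combined`` brings both classes to the rounded geometric mean of
    the sizes.  Deterministic under ``seed``.
    """
    if scheme not in SAMPLING_SCHEMES:
        raise ValueError(f"unknown sampling scheme {scheme!r}; choose {SAMPLING_SCHEMES}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[MoleculeRecord]] = {}
    for r in records:
        by_class.setdefault(r.direction, []).append(r)
    if len(by_class) != 2 or any(len(v) == 0 for v in by_class.values()):
        raise ValueError("balancing needs two nonempty classes")
    sizes = {c: len(v) for c, v in by_class.items()}
    if scheme == "downsample":
        target = min(sizes.values())
    elif scheme == "upsample":
        target = max(sizes.values())
    else:
        target = round(math.sqrt(math.prod(sizes.values())))
    out: list[MoleculeRecord] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) == target:
            out.extend(members)
        elif len(members) > target:
            idx = rng.choice(len(members), size=target, replace=False)
            out.extend(members[i] for i in sorted(idx))
        else:
            idx = rng.choice(len(members), size=target, replace=True)
            out.extend(members[i] for i in sorted(idx))
    return out


# -- leave-one-out evaluation ------------------------------------------------


@dataclass
class ClassificationReport:
    """LOO validation result for one model/sampling combination."""

    model_name: str
    sampling: str
    seed: int
    features: list[str]
    accuracy: float
    confusion: np.ndarray  # rows: true (decreased, elevated); cols: predicted
    predictions: pd.DataFrame  # name, true, predicted, subpathway
    classes: tuple[str, str] = ("decreased", "elevated")

    @property
    def misclassified(self) -> pd.DataFrame:
        return self.predictions[self.predictions["true"] != self.predictions["predicted"]]

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "sampling": self.sampling,
            "seed": self.seed,
            "features": self.features,
            "loo_accuracy": self.accuracy,
            "confusion_matrix": self.confusion.tolist(),
            "classes": list(self.classes),
            "misclassified": self.misclassified.to_dict(orient="records"),
        }


def _make_model(name: str, seed: int):
    if name == "decision_tree":
        return DecisionTreeClassifier(min_samples_leaf=2, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, min_samples_leaf=2, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown model {name!r}; supported: {MODEL_NAMES}")


def loo_evaluate(
    records: list[MoleculeRecord],
    features: list[str],
    model_name: str,
    seed: int = 0,
    sampling: str = "downsample",
) -> ClassificationReport:
    """Leave-one-out validation with in-fold balancing and standardization.

    Per fold the held-out molecule is removed, the remainder is balanced
    (so resampled duplicates of the held-out molecule can never leak into
    training), features are standardized with training-fold statistics
    only, and the named model predicts the held-out label.
    """
    _make_model(model_name, 0)  # validate the name early
    recs = [r.with_descriptors() for r in records]
    classes = ("decreased", "elevated")
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((2, 2), dtype=int)
    rows = []
    for i, held in enumerate(recs):
        train = recs[:i] + recs[i + 1 :]
        train = balance(train, scheme=sampling, seed=seed + i)
        X = np.array([[r.descriptors[f] for f in features] for r in train])
        y = np.array([r.direction for r in train])
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = _make_model(model_name, seed)
        clf.fit((X - mu) / sd, y)
        x_held = (np.array([[held.descriptors[f] for f in features]]) - mu) / sd
        pred = str(clf.predict(x_held)[0])
        conf[idx[held.direction], idx[pred]] += 1
        rows.append(
            {
                "name": held.name,
                "true": held.direction,
                "predicted": pred,
                "subpathway": held.subpathway,
            }
        )
    predictions = pd.DataFrame(rows)
    accuracy = float(np.trace(conf)) / len(recs)
    return ClassificationReport(
        model_name, sampling, seed, list(features), accuracy, conf, predictions, classes
    )


# -- FreeViz-style projection ------------------------------------------------


def _freeviz_energy(Y: np.ndarray, same: np.ndarray, diff: np.ndarray) -> float:
    d_same = np.linalg.norm(Y[same[:, 0]] - Y[same[:, 1]], axis=1)
    d_diff = np.linalg.norm(Y[diff[:, 0]] - Y[diff[:, 1]], axis=1)
    return float(0.5 * (d_same**2).sum() - np.log(np.maximum(d_diff, 1e-12)).sum())


def freeviz_project(
    records: list[MoleculeRecord],
    features: list[str],
    seed: int = 0,
    max_iter: int = 500,
    learning_rate: float = 0.05,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Force-optimized linear projection onto 2-D feature anchors.

    The embedding is the standardized feature matrix times the anchor
    matrix.  Anchors start on the unit circle (seeded) and follow gradient
    steps on an attract/repel objective: same-class point pairs attract
    with force proportional to distance, different-class pairs repel
    proportional to inverse distance.  After each step anchors are rescaled
    so the longest has unit length.  Returns (anchor table, embedding
    table).
    """
    if len(features) < 2:
        raise ValueError("FreeViz needs at least 2 features")
    recs = [r.with_descriptors() for r in records]
    X = np.array([[r.descriptors[f] for f in features] for r in recs])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    y = np.array([r.direction for r in recs])
    n, k = X.shape

    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    same = pairs[y[pairs[:, 0]] == y[pairs[:, 1]]]
    diff = pairs[y[pairs[:, 0]] != y[pairs[:, 1]]]

    rng = np.random.default_rng(seed)
    angles = rng.uniform(0, 2 * np.pi, size=k)
    A = np.column_stack([np.cos(angles), np.sin(angles)])

    prev = np.inf
    lr = learning_rate / max(n, 1)
    for _ in range(max_iter):
        Y = X @ A
        # gradient of the pair energy wrt the embedded points
        G = np.zeros_like(Y)
        dv = Y[same[:, 0]] - Y[same[:, 1]]
        np.add.at(G, same[:, 0], dv)
        np.add.at(G, same[:, 1], -dv)
        dv = Y[diff[:, 0]] - Y[diff[:, 1]]
        d2 = np.maximum((dv**2).sum(axis=1, keepdims=True), 1e-12)
        np.add.at(G, diff[:, 0], -dv / d2)
        np.add.at(G, diff[:, 1], dv / d2)
        A = A - lr * (X.T @ G)
        norms = np.linalg.norm(A, axis=1)
        A = A / max(norms.max(), 1e-12)
        energy = _freeviz_energy(X @ A, same, diff)
        if abs(prev - energy) < tol * (1 + abs(energy)):
            break
        prev = energy

    anchors = pd.DataFrame(A, index=features, columns=["x", "y"])
    emb = pd.DataFrame(X @ A, columns=["x", "y"])
    emb.insert(0, "name", [r.name for r in recs])
    emb["direction"] = y
    emb["subpathway"] = [r.subpathway for r in recs]
    return anchors, emb


# -- I/O ---------------------------------------------------------------------


def read_molecules_tsv(path: str) -> list[MoleculeRecord]:
    """TSV with columns name, smiles, direction and optional subpathway."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for need in ("name", "smiles", "direction"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r}")
    return [
        MoleculeRecord(
            name=str(row[cols["name"]]),
            smiles=str(row[cols["smiles"]]),
            direction=str(row[cols["direction"]]),
            subpathway=str(row[cols["subpathway"]]) if "subpathway" in cols else "",
        )
        for _, row in df.iterrows()
    ]
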