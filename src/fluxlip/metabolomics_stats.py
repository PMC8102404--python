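"""Differential-abundance statistics and subpathway enrichment for
targeted metabolomics tables.

Pipeline order mirrors standard platform practice: group-minimum
imputation first, then per-metabolite two-sample tests (Welch by default,
pooled Student as an option), effect sizes, Benjamini-Hochberg adjustment,
tier/direction classification and per-subpathway enrichment ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetaboliteTable",
    "impute_group_min",
    "welch_test",
    "student_test",
    "effect_sizes",
    "bh_adjust",
    "classify_tiers",
    "differential_stats",
    "tier_direction_summary",
    "subpathway_summary",
    "enrichment",
    "enrichment_table",
    "overlap_with_predictions",
]


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundances with group labels and annotations.

    ``abundance``: DataFrame indexed by sample ID, columns = metabolite IDs,
    nonnegative values, NaN = missing.  ``groups``: Series sample -> group
    label covering every sample.  ``annotations``: DataFrame indexed by
    metabolite ID with columns ``superpathway``, ``subpathway`` and
    optionally ``hmdb_id``.
    """

    abundance: pd.DataFrame
    groups: pd.Series
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.abundance.index) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        if (self.abundance.fillna(0) < 0).any().any():
            raise ValueError("abundances must be nonnegative")
        for col in ("superpathway", "subpathway"):
            if col not in self.annotations.columns:
                raise ValueError(f"annotations lack required column {col!r}")

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def group_block(self, group: str) -> pd.DataFrame:
        return self.abundance.loc[self.groups[self.groups == group].index]

    def save(self, prefix: str) -> None:
        self.abundance.to_csv(f"{prefix}_abundance.tsv", sep="\t", index_label="sample_id")
        self.groups.rename("group").to_csv(f"{prefix}_groups.tsv", sep="\t", index_label="sample_id")
        self.annotations.to_csv(f"{prefix}_annotations.tsv", sep="\t", index_label="metabolite_id")

    @classmethod
    def load(cls, prefix: str) -> "MetaboliteTable":
        ab = pd.read_csv(f"{prefix}_abundance.tsv", sep="\t", index_col="sample_id")
        gr = pd.read_csv(f"{prefix}_groups.tsv", sep="\t", index_col="sample_id")["group"]
        an = pd.read_csv(f"{prefix}_annotations.tsv", sep="\t", index_col="metabolite_id")
        return cls(ab, gr, an)


def impute_group_min(table: MetaboliteTable) -> MetaboliteTable:
    """Fill each missing cell with the metabolite's group minimum.

    Observed cells are never touched.  A metabolite-group pair with no
    observed value at all stays missing and triggers a warning; such
    metabolites are excluded from testing downstream.
    """
    filled = table.abundance.copy()
    fully_missing: list[tuple[str, str]] = []
    for group in table.group_names:
        idx = table.groups[table.groups == group].index
        block = filled.loc[idx]
        mins = block.min(axis=0, skipna=True)
        for met in block.columns[block.isna().any(axis=0)]:
            if math.isnan(mins[met]):
                fully_missing.append((met, group))
                continue
            filled.loc[idx, met] = block[met].fillna(mins[met])
    if fully_missing:
        warnings.warn(
            f"{len(fully_missing)} metabolite-group blocks entirely missing "
            f"(first few: {fully_missing[:3]}); excluded from testing"
        )
    return MetaboliteTable(filled, table.groups.copy(), table.annotations.copy())


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-tailed t test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Both-variance-zero inputs degenerate to ``p = 1`` for equal means and
    ``p = 0`` otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def student_test(a, b) -> tuple[float, float, float]:
    """Pooled-variance two-tailed Student t test; returns ``(t, df, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 values per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), float(df), 0.0
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def effect_sizes(case, control) -> tuple[float, float]:
    """Fold change (case mean / control mean) and Cohen's d.

    Cohen's d uses the pooled SD with the ``n_a + n_b - 2`` denominator.
    A zero control mean yields ``fold_change = nan`` (undefined-flagged).
    """
    a = np.asarray(case, dtype=float)
    b = np.asarray(control, dtype=float)
    fc = a.mean() / b.mean() if b.mean() != 0 else float("nan")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    d = (a.mean() - b.mean()) / math.sqrt(sp2) if sp2 > 0 else (
        0.0 if a.mean() == b.mean() else float("inf") * np.sign(a.mean() - b.mean())
    )
    return float(fc), float(d)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Adjusted values are >= raw, monotone in the raw ordering and capped
    at 1; the input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def classify_tiers(p: float, fold_change: float) -> tuple[str, str]:
    """Tier and direction labels for one metabolite.

    Tier: ``significant`` (p <= 0.05), ``trend`` (0.05 < p <= 0.10) or
    ``ns``.  Direction (non-ns only): ``elevated`` for fold change > 1,
    ``decreased`` for < 1, empty otherwise.
    """
    if p <= 0.05:
        tier = "significant"
    elif p <= 0.10:
        tier = "trend"
    else:
        tier = "ns"
    direction = ""
    if tier != "ns":
        if fold_change > 1:
            direction = "elevated"
        elif fold_change < 1:
            direction = "decreased"
    return tier, direction


def differential_stats(
    table: MetaboliteTable,
    case: str,
    control: str,
    test: str = "welch",
    impute: bool = True,
) -> pd.DataFrame:
    """Per-metabolite differential statistics between two groups.

    Returns a DataFrame indexed by metabolite ID with group means, fold
    change (case/control), t, df, p, BH-adjusted p, Cohen's d, tier and
    direction.  Metabolites with an all-missing group block or fewer than
    two values per group are dropped (with the imputation warning).
    """
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    if impute:
        table = impute_group_min(table)
    test_fn = welch_test if test == "welch" else student_test
    ca = table.group_block(case)
    co = table.group_block(control)
    rows = []
    for met in table.abundance.columns:
        a = ca[met].dropna().to_numpy()
        b = co[met].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        t, df, p = test_fn(a, b)
        fc, d = effect_sizes(a, b)
        rows.append(
            {
                "metabolite_id": met,
                "case_mean": a.mean(),
                "control_mean": b.mean(),
                "fold_change": fc,
                "t": t,
                "df": df,
                "p": p,
                "cohens_d": d,
            }
        )
    stats = pd.DataFrame(rows).set_index("metabolite_id")
    stats["p_bh"] = bh_adjust(stats["p"].to_numpy())
    tiers = [classify_tiers(p, fc) for p, fc in zip(stats["p"], stats["fold_change"])]
    stats["tier"] = [t for t, _ in tiers]
    stats["direction"] = [d for _, d in tiers]
    for col in ("superpathway", "subpathway", "hmdb_id"):
        if col in table.annotations.columns:
            stats[col] = table.annotations[col].reindex(stats.index)
    return stats


def tier_direction_summary(stats: pd.DataFrame, n_detected: int | None = None) -> dict:
    """Partition counts over tiers and directions.

    ``altered`` is the union of the significant and trend tiers; its total
    equals elevated + decreased.  ``n_detected`` defaults to the number of
    tested metabolites and feeds the integer-percent shares.
    """
    n_tested = len(stats)
    if n_detected is None:
        n_detected = n_tested
    n_sig = int((stats["tier"] == "significant").sum())
    n_trend = int((stats["tier"] == "trend").sum())
    n_elev = int((stats["direction"] == "elevated").sum())
    n_decr = int((stats["direction"] == "decreased").sum())
    return {
        "n_detected": int(n_detected),
        "n_tested": n_tested,
        "n_significant": n_sig,
        "n_trend": n_trend,
        "n_ns": n_tested - n_sig - n_trend,
        "n_elevated": n_elev,
        "n_decreased": n_decr,
        "n_altered": n_elev + n_decr,
        "percent_elevated": round(100 * n_elev / n_detected) if n_detected else 0,
        "percent_decreased": round(100 * n_decr / n_detected) if n_detected else 0,
    }


def subpathway_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-subpathway altered counts and integer-percent shares."""
    if "subpathway" not in stats.columns:
        raise ValueError("stats table lacks subpathway annotations")
    rows = []
    for sub, block in stats.groupby("subpathway"):
        m = len(block)
        k_e = int((block["direction"] == "elevated").sum())
        k_d = int((block["direction"] == "decreased").sum())
        rows.append(
            {
                "subpathway": sub,
                "m": m,
                "k_elevated": k_e,
                "k_decreased": k_d,
                "percent_elevated": round(100 * k_e / m),
                "percent_decreased": round(100 * k_d / m),
            }
        )
    return pd.DataFrame(rows).set_index("subpathway")


def enrichment(k: int, m: int, n: int, N: int) -> float:
    """Subpathway enrichment ratio ``E = (k/m) / ((n-k)/(N-m))``.

    k: altered metabolites in the subpathway; m: subpathway size; n:
    altered metabolites in the dataset; N: dataset size.  Only subpathways
    with more than five metabolites qualify.
    """
    if m <= 5:
        raise ValueError("enrichment is only reported for subpathways with m > 5")
    if not (0 <= k <= min(m, n)):
        raise ValueError(f"require 0 <= k <= min(m, n); got k={k}, m={m}, n={n}")
    if N <= m:
        raise ValueError("dataset size N must exceed subpathway size m")
    if k == 0:
        return 0.0
    if n == k:
        return float("nan")  # no altered metabolites outside the subpathway
    return (k / m) / ((n - k) / (N - m))


def enrichment_table(
    stats: pd.DataFrame,
    direction: str,
    min_size: int = 6,
    strict: bool = False,
) -> pd.DataFrame:
    """Direction-specific enrichment ratios per subpathway.

    ``direction`` is ``elevated`` or ``decreased``; ``n`` is the number of
    altered metabolites with that direction across the dataset.  With
    ``strict=True`` only the significant tier counts as altered (default
    includes trend).  Subpathways smaller than ``min_size`` are skipped.
    """
    if direction not in ("elevated", "decreased"):
        raise ValueError("direction must be 'elevated' or 'decreased'")
    altered_mask = stats["direction"] == direction
    if strict:
        altered_mask &= stats["tier"] == "significant"
    N = len(stats)
    n = int(altered_mask.sum())
    rows = []
    for sub, block in stats.groupby("subpathway"):
        m = len(block)
        if m < min_size:
            continue
        k = int(altered_mask.loc[block.index].sum())
        rows.append(
            {
                "subpathway": sub,
                "direction": direction,
                "k": k,
                "m": m,
                "n": n,
                "N": N,
                "enrichment": enrichment(k, m, n, N),
            }
        )
    return pd.DataFrame(rows).set_index("subpathway")


def overlap_with_predictions(
    predicted: set[str],
    knockout_altered: set[str],
    drug_altered: set[str],
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join model-predicted altered metabolites with measured alterations.

    All sets are HMDB IDs; ``id_map`` optionally translates predicted IDs
    to HMDB first (unmapped predictions are reported with experiment label
    ``unmatched``).  Each overlapping metabolite is labeled ``Knockout``,
    ``Drug treated`` or ``Both``.
    """
    rows = []
    for met in sorted(predicted):
        hmdb = id_map.get(met) if id_map is not None else met
        if hmdb is None:
            rows.append({"metabolite": met, "hmdb_id": "", "experiment": "unmatched"})
            continue
        in_ko = hmdb in knockout_altered
        in_drug = hmdb in drug_altered
        if in_ko and in_drug:
            label = "Both"
        elif in_ko:
            label = "Knockout"
        elif in_drug:
            label = "Drug treated"
        else:
            continue
        rows.append({"metabolite": met, "hmdb_id": hmdb, "experiment": label})
    return pd.DataFrame(rows, columns=["metabolite", "hmdb_id", "experiment"])
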