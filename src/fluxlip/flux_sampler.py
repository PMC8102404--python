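"""Uniform sampling of the feasible flux polytope.

Implements artificial-centering hit-and-run (ACHR) over the polytope
``{v : S·v = 0, lb <= v <= ub}``.  Warmup points come from alternating
per-reaction min/max optimizations (FVA corners), so every stored point
already satisfies mass balance; chord directions are differences of
feasible points and therefore stay inside the affine subspace, with a
periodic null-space re-projection to control floating-point drift.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .model_core import EPS_BOUND, EPS_MASS, InfeasibleModelError, MetabolicModel, fva

__all__ = ["FluxSampleSet", "warmup_points", "sample", "normalize_samples"]

_DIR_TOL = 1e-11  # minimum |direction component| that limits the chord
_DEGENERATE_TOL = 1e-9  # polytope width below which it is a single point
_MAX_REJECT = 10_000  # consecutive empty chords before declaring a stall


@dataclass
class FluxSampleSet:
    """Matrix of sampled feasible flux states for one condition."""

    condition: str
    samples: np.ndarray  # n_samples x n_reactions
    reaction_ids: list[str]
    seed: int | None
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def mean(self) -> pd.Series:
        return pd.Series(self.samples.mean(axis=0), index=self.reaction_ids)

    def save(self, path: str) -> None:
        """Persist as TSV plus a JSON sidecar with provenance."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "condition": self.condition,
            "seed": self.seed,
            "n_samples": int(self.n_samples),
            **{k: v for k, v in self.metadata.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str) -> "FluxSampleSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        return cls(
            condition=meta.pop("condition", ""),
            samples=df.to_numpy(dtype=float),
            reaction_ids=list(df.columns),
            seed=meta.pop("seed", None),
            metadata=meta,
        )


def warmup_points(model: MetabolicModel, count: int | None = None) -> np.ndarray:
    """FVA-corner warmup points spanning the flux polytope.

    Alternates per-reaction minimization and maximization (objective fraction
    0, i.e. pure feasibility), yielding ``count`` rows (default ``2 * n``).
    Raises :class:`InfeasibleModelError` when the model has no feasible
    point.
    """
    n = model.n_reactions
    if count is None:
        count = 2 * n
    if count < 2:
        raise ValueError("need at least 2 warmup points")
    rows = []
    # fresh copy: GLPK warm-start state on the caller's model would make
    # repeated warmup runs return different degenerate vertices
    cm = model.cobra_model.copy()
    with cm:
        # zero out the objective so corners cover the whole polytope
        cm.objective = cm.problem.Objective(0)
        i = 0
        while len(rows) < count:
            rxn = cm.reactions[(i // 2) % n]
            sense = "min" if i % 2 == 0 else "max"
            with cm:
                cm.objective = rxn
                cm.objective_direction = sense
                sol = cm.optimize()
                if sol.status != "optimal":
                    raise InfeasibleModelError(
                        f"warmup optimization infeasible (status {sol.status!r})"
                    )
                rows.append(sol.fluxes.loc[model.reaction_ids].to_numpy(dtype=float))
            i += 1
    # no clipping: simplex vertices satisfy bounds to solver precision, and
    # clipping would trade a ~1e-12 bound slack for a mass-balance error
    return np.asarray(rows)


def sample(
    model: MetabolicModel,
    n_samples: int,
    seed: int,
    thinning: int = 100,
    warmup: np.ndarray | None = None,
    condition: str = "",
) -> FluxSampleSet:
    """ACHR sampling of the flux polytope.

    Every ``thinning`` hit-and-run steps one state is emitted, until
    ``n_samples`` rows are collected.  The chord direction at each step is
    (randomly chosen retained point - running center); step length is drawn
    uniformly from the segment of the chord inside the bound box.  Identical
    ``(model, n_samples, seed, thinning)`` give identical output.

    A polytope of dimension zero yields ``n_samples`` copies of its unique
    point and sets ``metadata['degenerate']``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    rng = np.random.default_rng(seed)
    lb, ub = model.bounds()
    n_rxn = model.n_reactions

    if warmup is None:
        warmup = warmup_points(model, max(2 * n_rxn, 50))
    warmup = np.asarray(warmup, dtype=float)
    if warmup.ndim != 2 or warmup.shape[1] != n_rxn:
        raise ValueError("warmup must be a (count, n_reactions) matrix")

    meta = {
        "warmup_count": int(warmup.shape[0]),
        "thinning": int(thinning),
        "iterations": int(n_samples * thinning),
        "normalization": "none",
    }

    span = warmup.max(axis=0) - warmup.min(axis=0)
    if np.all(span <= _DEGENERATE_TOL):
        warnings.warn("flux polytope has dimension 0; returning the unique point")
        meta["degenerate"] = True
        pts = np.tile(warmup[0], (n_samples, 1))
        return FluxSampleSet(condition, pts, list(model.reaction_ids), seed, meta)

    S = model.stoichiometric_matrix()
    N = null_space(S) if S.size else np.eye(n_rxn)

    # retained point pool: warmup points plus every emitted sample
    n_warm = warmup.shape[0]
    stored = np.empty((n_warm + n_samples, n_rxn))
    stored[:n_warm] = warmup
    n_stored = n_warm
    center = warmup.mean(axis=0)
    x = center.copy()
    out = stored[n_warm:]  # emitted samples view
    emitted = 0
    it = 0
    rejected = 0
    while emitted < n_samples:
        it += 1
        p = stored[rng.integers(n_stored)]
        # project the chord direction onto the null space and normalize:
        # keeps fp drift from feeding back through the running center
        u = p - center
        u = N @ (N.T @ u)
        nrm = np.sqrt(u @ u)
        if nrm <= _DIR_TOL:
            rejected += 1
            if rejected > _MAX_REJECT:
                raise RuntimeError("hit-and-run stalled: no usable chord direction")
            continue
        u = u / nrm
        # fp leakage of the projection into fixed coordinates would collapse
        # every chord (0-width ratio at a pinned bound); treat it as zero
        u[np.abs(u) < 1e-12] = 0.0
        # chord limits from the box: lb <= x + a*u <= ub.  Elementwise
        # min/max of the two bound ratios handles direction signs; zero
        # components give +-inf (unconstraining) or nan (0/0, skipped).
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lb - x) / u
            t2 = (ub - x) / u
        a_lo = np.nanmax(np.minimum(t1, t2))
        a_hi = np.nanmin(np.maximum(t1, t2))
        if not np.isfinite(a_hi) or not np.isfinite(a_lo) or a_hi - a_lo <= _DIR_TOL:
            rejected += 1
            if rejected % 100 == 0:
                # fp rounding can strand x marginally outside a vertex where
                # every chord is empty; the running center is a convex
                # combination of feasible points, so restart from there
                x = center.copy()
            if rejected > _MAX_REJECT:
                raise RuntimeError("hit-and-run stalled: chord repeatedly empty")
            continue
        rejected = 0
        # no clipping (it would break S.v=0) and no reprojection of x (it
        # would nudge coordinates pinned at exact bounds outside the box);
        # instead keep a sliver of margin off each chord end.  Drift stays
        # bounded because every direction is projected before use.
        margin = 1e-6 * (a_hi - a_lo)
        x = x + rng.uniform(a_lo + margin, a_hi - margin) * u
        center += (x - center) / (n_stored + it)
        if it % thinning == 0:
            out[emitted] = x
            emitted += 1
            n_stored += 1
    meta["iterations"] = int(it)
    out = out.copy()
    return FluxSampleSet(condition, out, list(model.reaction_ids), seed, meta)


def normalize_samples(sample_set: FluxSampleSet, mode: str = "l1") -> FluxSampleSet:
    """Normalize each sampled flux state.

    ``l1`` divides each row by its total absolute flux so states are
    comparable across conditions whose overall flux capacity differs;
    all-zero rows are left untouched and flagged.  ``none`` is the identity.
    """
    if mode == "none":
        meta = dict(sample_set.metadata, normalization="none")
        return FluxSampleSet(
            sample_set.condition,
            sample_set.samples.copy(),
            list(sample_set.reaction_ids),
            sample_set.seed,
            meta,
        )
    if mode != "l1":
        raise ValueError(f"unknown normalization mode {mode!r}")
    totals = np.abs(sample_set.samples).sum(axis=1)
    zero_rows = totals <= 0
    safe = np.where(zero_rows, 1.0, totals)
    normed = sample_set.samples / safe[:, None]
    meta = dict(
        sample_set.metadata,
        normalization="l1",
        zero_flux_rows=int(zero_rows.sum()),
    )
    return FluxSampleSet(
        sample_set.condition, normed, list(sample_set.reaction_ids), sample_set.seed, meta
    )
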