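"""Matched-cohort construction by case-based reasoning.

The matching engine pairs each aneurysm of interest (AOI, interhemispheric
arm) with its most similar reference case (pterional arm) using k-nearest
neighbor retrieval under a weighted Euclidean dissimilarity on Z-score
standardized features:

    dist(x, q) = sqrt( sum_l fw_l * (x_l - q_l)^2 )

with all feature weights fw_l = 1 by default and k = 3. Matching is
constrained to strata of identical rupture status and frontal base-dome-angle
(FDA) category; an AOI whose FDA category holds no reference case is merged
into a configurable fallback category (logged). AOIs are processed
sequentially in ascending case id; 1:1 assignment without replacement is
enforced, and when two AOIs claim the same reference the case goes to the
closer claimant while the loser falls back to its second, then third,
not-yet-assigned neighbor.

Three k-NN weighting variants are provided: ``plain`` (equal weights 1/k),
``inverse_distance`` (weights proportional to 1/distance) and
``minmax_inverse`` (distances first min-max scaled to [0, 1] over the pool,
then inverse-weighted). All variants rank neighbors by the same raw distance,
so the retrieved neighbor set is identical; only the reported weights differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MatchingError, UnmatchableError

__all__ = [
    "Feature",
    "FeatureSpec",
    "StandardizedMatrix",
    "NeighborSet",
    "MatchedCohort",
    "CODEBOOK",
    "encode_features",
    "zscore_standardize",
    "weighted_distance",
    "knn",
    "select_matching_features",
    "stratify",
    "resolve_conflicts",
    "sequential_match",
    "distance_matrix",
]

VARIANTS = ("plain", "inverse_distance", "minmax_inverse")

#: 0/1 encodings for categorical matching features
CODEBOOK: dict[str, dict[str, int]] = {
    "gender": {"male": 0, "female": 1},
    "shape": {"regular": 0, "irregular": 1},
}

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # binary | ordinal | continuous
    weight: float = 1.0


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered matching feature list with per-feature weights and k."""

    features: tuple[Feature, ...]
    k: int = 3

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise MatchingError("feature names must be unique")
        if self.k < 1:
            raise MatchingError("k must be >= 1")
        for f in self.features:
            if f.weight < 0:
                raise MatchingError(f"feature {f.name!r} has negative weight")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.features], dtype=float)


def select_matching_features(ruptured: bool, k: int = 3) -> FeatureSpec:
    """Feature set for one rupture stratum, all weights 1.

    Unruptured cases match on gender, age at surgery, aneurysm shape and
    aneurysm size; ruptured cases additionally match on the Hunt & Hess score
    and the Fisher grade.
    """
    feats = [Feature("gender", "binary"), Feature("age", "continuous")]
    if ruptured:
        feats += [Feature("hunt_hess", "ordinal"), Feature("fisher_grade", "ordinal")]
    feats += [Feature("shape", "binary"), Feature("size_mm", "continuous")]
    return FeatureSpec(features=tuple(feats), k=k)


def encode_features(cases: pd.DataFrame, spec: FeatureSpec) -> tuple[np.ndarray, list[str]]:
    """Encode the spec's features as a dense float matrix, row order preserved.

    Binary categoricals go through :data:`CODEBOOK`; ordinal grades enter as
    their integer level; continuous features pass through. A missing value or
    unknown category raises a :class:`MatchingError` naming case and feature.
    """
    ids = list(cases["case_id"])
    cols = []
    for f in spec.features:
        if f.name not in cases.columns:
            raise MatchingError(f"feature {f.name!r} missing from case table")
        raw = cases[f.name]
        if f.name in CODEBOOK:
            book = CODEBOOK[f.name]
            vals = np.empty(len(raw))
            for i, v in enumerate(raw):
                if pd.isna(v):
                    raise MatchingError(f"case {ids[i]!r}: missing value for feature {f.name!r}")
                if v not in book:
                    raise MatchingError(
                        f"case {ids[i]!r}: unknown category {v!r} for feature {f.name!r}"
                    )
                vals[i] = book[v]
        else:
            numeric = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float, na_value=np.nan)
            if np.isnan(numeric).any():
                bad = ids[int(np.flatnonzero(np.isnan(numeric))[0])]
                raise MatchingError(f"case {bad!r}: missing value for feature {f.name!r}")
            vals = numeric
        cols.append(vals)
    return np.column_stack(cols), ids


@dataclass
class StandardizedMatrix:
    """Z-scored feature matrix with the scaling actually applied."""

    ids: list[str]
    names: list[str]
    values: np.ndarray  # shape (n cases, n features)
    means: np.ndarray
    sds: np.ndarray  # sample sd (denominator n-1); 0 marks a constant column
    constant_columns: list[str] = field(default_factory=list)

    def row(self, case_id: str) -> np.ndarray:
        return self.values[self.ids.index(case_id)]


def zscore_standardize(matrix: np.ndarray, ids: list[str], names: list[str]) -> StandardizedMatrix:
    """Column-wise Z-score standardization with sample sd (denominator n-1).

    Constant columns cannot be scaled; they are mapped to all-zero and flagged
    so they contribute nothing to any distance.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise MatchingError("standardization requires at least 2 rows")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    constant = sds <= _ZERO_TOL
    safe = np.where(constant, 1.0, sds)
    values = (matrix - means) / safe
    values[:, constant] = 0.0
    return StandardizedMatrix(
        ids=list(ids),
        names=list(names),
        values=values,
        means=means,
        sds=np.where(constant, 0.0, sds),
        constant_columns=[n for n, c in zip(names, constant) if c],
    )


def weighted_distance(x: np.ndarray, q: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted Euclidean dissimilarity sqrt(sum_l fw_l (x_l - q_l)^2)."""
    x = np.asarray(x, dtype=float)
    q = np.asarray(q, dtype=float)
    if x.shape != q.shape:
        raise MatchingError(f"length mismatch: {x.shape} vs {q.shape}")
    if weights is None:
        weights = np.ones_like(x)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != x.shape:
        raise MatchingError("weights must match the feature vector length")
    if (weights < 0).any():
        raise MatchingError("feature weights must be non-negative")
    return float(np.sqrt(np.sum(weights * (x - q) ** 2)))


@dataclass
class NeighborSet:
    """The k nearest reference cases for one AOI under one weighting variant."""

    aoi_id: str
    variant: str
    neighbors: list[tuple[str, float, float]]  # (reference_id, raw_distance, weight)

    @property
    def reference_ids(self) -> list[str]:
        return [r for r, _, _ in self.neighbors]


def _variant_weights(dists: np.ndarray, variant: str, pool_dists: np.ndarray) -> np.ndarray:
    """Neighbor weights for the selected k distances; always sum to 1."""
    k = len(dists)
    if variant == "plain":
        return np.full(k, 1.0 / k)
    if variant == "minmax_inverse":
        dmin, dmax = pool_dists.min(), pool_dists.max()
        if dmax - dmin <= _ZERO_TOL:
            return np.full(k, 1.0 / k)
        dists = (dists - dmin) / (dmax - dmin)
    zero = dists <= _ZERO_TOL
    if zero.any():
        w = np.where(zero, 1.0, 0.0)
    else:
        w = 1.0 / dists
    return w / w.sum()


def knn(
    aoi_id: str,
    query: np.ndarray,
    pool: StandardizedMatrix,
    spec: FeatureSpec,
    variant: str = "plain",
) -> NeighborSet:
    """Retrieve the min(k, pool size) nearest references to ``query``.

    Ties on distance are broken by ascending reference id so retrieval is
    deterministic.
    """
    if variant not in VARIANTS:
        raise MatchingError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if len(pool.ids) == 0:
        raise MatchingError(f"empty reference pool for AOI {aoi_id!r}")
    w = spec.weights
    dists = np.array([weighted_distance(query, row, w) for row in pool.values])
    order = sorted(range(len(dists)), key=lambda i: (dists[i], pool.ids[i]))
    k_eff = min(spec.k, len(order))
    chosen = order[:k_eff]
    weights = _variant_weights(dists[chosen], variant, dists)
    return NeighborSet(
        aoi_id=aoi_id,
        variant=variant,
        neighbors=[(pool.ids[i], float(dists[i]), float(wt)) for i, wt in zip(chosen, weights)],
    )


# ---------------------------------------------------------------------------
# stratification

#: default fallback chain per FDA category: angularly adjacent quadrants first
#: (the quadrants sit on a circle, so 1 neighbors 2 and 4), preferring the
#: upward neighbor as in the canonical 3 -> 4 merge; the opposite quadrant is
#: a last resort
DEFAULT_FDA_FALLBACK: dict[int, tuple[int, ...]] = {
    1: (2, 4, 3),
    2: (3, 1, 4),
    3: (4, 2, 1),
    4: (3, 1, 2),
}


@dataclass
class Stratum:
    ruptured: bool
    categories: tuple[int, ...]  # one category, or two after a fallback merge
    aoi_ids: list[str]
    reference_ids: list[str]
    merged: bool = False

    @property
    def label(self) -> str:
        cats = "+".join(str(c) for c in self.categories)
        status = "ruptured" if self.ruptured else "unruptured"
        return f"{status}/fda{cats}" + ("(merged)" if self.merged else "")


def stratify(
    aois: pd.DataFrame,
    references: pd.DataFrame,
    fallback: dict[int, int] | None = None,
) -> tuple[list[Stratum], list[str]]:
    """Group AOIs with their candidate references by (rupture, FDA category).

    If an AOI's category holds no reference case — or fewer references than
    AOIs, which makes 1:1 matching infeasible — fallback neighbor categories
    are merged in, one at a time along the configured chain (default sends
    3 -> 4 first), until the pool can support 1:1 matching; every merge is
    logged. An AOI with no candidates even after merging raises
    :class:`UnmatchableError`.
    """
    fallback = DEFAULT_FDA_FALLBACK if fallback is None else fallback
    for frame, label in ((aois, "AOI"), (references, "reference")):
        for col in ("ruptured", "fda_category"):
            if col not in frame.columns or frame[col].isna().any():
                raise MatchingError(f"every {label} case needs a non-missing {col!r}")

    merges: list[str] = []
    ref_ids_by: dict[tuple[bool, int], list[str]] = {
        (bool(r), int(c)): sorted(g["case_id"])
        for (r, c), g in references.groupby(["ruptured", "fda_category"], sort=True)
    }

    def _chain(cat: int) -> tuple[int, ...]:
        chain = fallback.get(cat, ())
        return (chain,) if isinstance(chain, int) else tuple(chain)

    def _status(rupt: bool) -> str:
        return "ruptured" if rupt else "unruptured"

    # seed one group per (rupture status, FDA category), expanding deficient
    # groups along the fallback chain
    groups: list[dict] = []
    for (rupt, cat), group in aois.groupby(["ruptured", "fda_category"], sort=True):
        rupt = bool(rupt)
        cat = int(cat)
        cats = [cat]
        n_refs = len(ref_ids_by.get((rupt, cat), []))
        for fb in _chain(cat):
            if n_refs >= len(group):
                break
            extra = ref_ids_by.get((rupt, fb), [])
            if not extra:
                continue
            reason = "no" if n_refs == 0 else f"only {n_refs}"
            merges.append(
                f"FDA category {cat} ({_status(rupt)}) has {reason} reference(s) for "
                f"{len(group)} AOI(s); merged with category {fb}"
            )
            cats.append(fb)
            n_refs += len(extra)
        if n_refs == 0:
            raise UnmatchableError(
                f"AOI case(s) {sorted(group['case_id'])} in stratum "
                f"({_status(rupt)}, FDA {cat}) have no candidate references"
            )
        groups.append(
            {"rupt": rupt, "cats": set(cats), "seed_cats": {cat}, "aoi_ids": list(group["case_id"]),
             "merged": len(cats) > 1}
        )

    # Groups of the same rupture status whose category sets overlap draw on
    # shared references, so 1:1 feasibility must be checked jointly: union
    # overlapping groups, extend any still-deficient union along its members'
    # chains, and repeat until stable (an extension can create a new overlap).
    def _pool(g: dict) -> int:
        return sum(len(ref_ids_by.get((g["rupt"], c), [])) for c in g["cats"])

    stable = False
    while not stable:
        stable = True
        # union step
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    a, b = groups[i], groups[j]
                    if a["rupt"] == b["rupt"] and a["cats"] & b["cats"]:
                        a["cats"] |= b["cats"]
                        a["seed_cats"] |= b["seed_cats"]
                        a["aoi_ids"] += b["aoi_ids"]
                        a["merged"] = a["merged"] or b["merged"]
                        del groups[j]
                        changed = True
                        break
                if changed:
                    break
        # extension step for deficient unions
        for g in groups:
            if _pool(g) >= len(g["aoi_ids"]):
                continue
            for cat in sorted(g["seed_cats"]):
                extended = False
                for fb in _chain(cat):
                    if fb not in g["cats"] and ref_ids_by.get((g["rupt"], fb)):
                        merges.append(
                            f"combined FDA categories {sorted(g['cats'])} ({_status(g['rupt'])}) "
                            f"have only {_pool(g)} reference(s) for {len(g['aoi_ids'])} AOI(s); "
                            f"merged with category {fb}"
                        )
                        g["cats"].add(fb)
                        g["merged"] = True
                        stable = False
                        extended = True
                        break
                if extended:
                    break

    strata = [
        Stratum(
            ruptured=g["rupt"],
            categories=tuple(sorted(g["cats"])),
            aoi_ids=sorted(g["aoi_ids"]),
            reference_ids=sorted(
                itertools.chain.from_iterable(
                    ref_ids_by.get((g["rupt"], c), []) for c in g["cats"]
                )
            ),
            merged=g["merged"],
        )
        for g in groups
    ]
    return strata, merges


# ---------------------------------------------------------------------------
# sequential assignment and conflict resolution


@dataclass
class ConflictRecord:
    reference_id: str
    claimants: list[tuple[str, float]]  # (aoi_id, raw distance)
    winner: str
    resolution: str


@dataclass
class MatchedCohort:
    """1:1 matched pairs plus the full adjudication trail."""

    pairs: pd.DataFrame  # columns: aoi_id, reference_id, distance, stratum
    conflicts: list[ConflictRecord] = field(default_factory=list)
    merges: list[str] = field(default_factory=list)
    neighbor_sets: dict[str, NeighborSet] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)  # e.g. beyond-k fallbacks


def resolve_conflicts(
    reference_id: str,
    claimants: list[tuple[str, float]],
) -> str:
    """Default deterministic adjudicator for a contested reference.

    The contested case goes to the claimant at the smaller raw distance; ties
    are broken by ascending AOI case id. (The interactive study this mirrors
    sent such conflicts to two independent neurosurgeons; this hook is
    pluggable via ``sequential_match(adjudicator=...)``.)
    """
    if len(claimants) < 2:
        raise MatchingError("a conflict needs at least two claimants")
    return min(claimants, key=lambda c: (c[1], c[0]))[0]


def _next_free(ranking: list[tuple[str, float]], assigned: set[str]) -> tuple[int, str, float] | None:
    for rank, (ref, dist) in enumerate(ranking):
        if ref not in assigned:
            return rank, ref, dist
    return None


def sequential_match(
    aois: pd.DataFrame,
    references: pd.DataFrame,
    variant: str = "plain",
    k: int = 3,
    fallback: dict[int, int] | None = None,
    adjudicator=None,
) -> MatchedCohort:
    """Build the full matched cohort.

    AOIs are processed in ascending case id. Each AOI's k-NN set is computed
    within its (rupture status, FDA category) stratum, with Z-scores fit on
    the union of the stratum's AOIs and candidate references. The top
    neighbor is proposed; if it is already held by another AOI the
    adjudicator decides and the loser falls back to its next not-yet-assigned
    neighbor (second, then third). A claimant whose k nearest are all taken
    continues down its full within-stratum distance ranking (logged as a
    beyond-k fallback); only a fully consumed stratum pool raises
    :class:`UnmatchableError`.
    """
    adjudicator = resolve_conflicts if adjudicator is None else adjudicator
    strata, merges = stratify(aois, references, fallback=fallback)

    neighbor_sets: dict[str, NeighborSet] = {}
    ranking_of: dict[str, list[tuple[str, float]]] = {}  # full stratum-pool ranking
    stratum_of: dict[str, str] = {}
    for st in strata:
        spec = select_matching_features(st.ruptured, k=k)
        pool_cases = pd.concat(
            [
                aois[aois["case_id"].isin(st.aoi_ids)],
                references[references["case_id"].isin(st.reference_ids)],
            ],
            ignore_index=True,
        )
        matrix, ids = encode_features(pool_cases, spec)
        std = zscore_standardize(matrix, ids, spec.names)
        ref_mask = [i in set(st.reference_ids) for i in std.ids]
        ref_std = StandardizedMatrix(
            ids=[i for i, m in zip(std.ids, ref_mask) if m],
            names=std.names,
            values=std.values[np.array(ref_mask)],
            means=std.means,
            sds=std.sds,
            constant_columns=std.constant_columns,
        )
        for aoi_id in st.aoi_ids:
            neighbor_sets[aoi_id] = knn(aoi_id, std.row(aoi_id), ref_std, spec, variant=variant)
            w = spec.weights
            q = std.row(aoi_id)
            dists = [(rid, weighted_distance(q, ref_std.row(rid), w)) for rid in ref_std.ids]
            ranking_of[aoi_id] = sorted(dists, key=lambda t: (t[1], t[0]))
            stratum_of[aoi_id] = st.label

    assignment: dict[str, tuple[str, float]] = {}  # reference -> (aoi, distance)
    holder_of: dict[str, tuple[str, float]] = {}  # aoi -> (reference, distance)
    conflicts: list[ConflictRecord] = []
    notes: list[str] = []
    queue = sorted(neighbor_sets)
    while queue:
        aoi_id = queue.pop(0)
        ns = neighbor_sets[aoi_id]
        top_ref, top_dist, _ = ns.neighbors[0]
        if top_ref not in assignment:
            assignment[top_ref] = (aoi_id, top_dist)
            holder_of[aoi_id] = (top_ref, top_dist)
            continue
        incumbent_id, incumbent_dist = assignment[top_ref]
        claimants = [(incumbent_id, incumbent_dist), (aoi_id, top_dist)]
        winner = adjudicator(top_ref, claimants)
        loser = incumbent_id if winner == aoi_id else aoi_id
        if winner == aoi_id:
            assignment[top_ref] = (aoi_id, top_dist)
            holder_of[aoi_id] = (top_ref, top_dist)
            del holder_of[incumbent_id]
        nxt = _next_free(ranking_of[loser], set(assignment))
        if nxt is None:
            raise UnmatchableError(
                f"AOI {loser!r} has no free reference left in its stratum pool"
            )
        rank, ref, dist = nxt
        k_eff = len(neighbor_sets[loser].neighbors)
        if rank >= k_eff:
            notes.append(
                f"{loser} fell back beyond its {k_eff} nearest neighbors to "
                f"rank-{rank + 1} reference {ref}"
            )
        assignment[ref] = (loser, dist)
        holder_of[loser] = (ref, dist)
        conflicts.append(
            ConflictRecord(
                reference_id=top_ref,
                claimants=claimants,
                winner=winner,
                resolution=f"{winner} keeps {top_ref}; {loser} falls back to {ref}",
            )
        )

    pairs = pd.DataFrame(
        [
            {
                "aoi_id": aoi_id,
                "reference_id": ref,
                "distance": dist,
                "stratum": stratum_of[aoi_id],
            }
            for aoi_id, (ref, dist) in sorted(holder_of.items())
        ]
    )
    return MatchedCohort(
        pairs=pairs, conflicts=conflicts, merges=merges, neighbor_sets=neighbor_sets, notes=notes
    )


def distance_matrix(
    aois: pd.DataFrame,
    references: pd.DataFrame,
    k: int = 3,
    fallback: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Full AOI x reference distance table (NaN outside a shared stratum).

    Static export standing in for the interactive heat-map view of the
    original matching tool.
    """
    strata, _ = stratify(aois, references, fallback=fallback)
    out = pd.DataFrame(
        np.nan, index=sorted(aois["case_id"]), columns=sorted(references["case_id"])
    )
    for st in strata:
        spec = select_matching_features(st.ruptured, k=k)
        pool_cases = pd.concat(
            [
                aois[aois["case_id"].isin(st.aoi_ids)],
                references[references["case_id"].isin(st.reference_ids)],
            ],
            ignore_index=True,
        )
        matrix, ids = encode_features(pool_cases, spec)
        std = zscore_standardize(matrix, ids, spec.names)
        for aoi_id in st.aoi_ids:
            q = std.row(aoi_id)
            for ref_id in st.reference_ids:
                out.loc[aoi_id, ref_id] = weighted_distance(q, std.row(ref_id), spec.weights)
    return out
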