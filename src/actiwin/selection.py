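"""Correlation-based feature selection searched by sequential scatter search.

CFS scores a candidate subset S of k features by its merit

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where r_cf is the mean feature-to-class relevance over S and r_ff the mean
pairwise absolute Pearson correlation within S: good subsets are strongly
class-correlated but mutually uncorrelated.  Relevance of one feature to a
multiclass (nominal) label is taken as the class-prior-weighted mean of the
absolute point-biserial correlations against each one-vs-rest indicator —
a nominal 12-level label has no single Pearson correlation, and integer
coding would make relevance depend on an arbitrary class order.

The merit landscape is searched by a sequential scatter search with reduced
greedy combination (SS-RGS): a diversified pool of subsets is locally
improved, a reference set is kept (half best-merit, half most diverse by
symmetric-difference distance), every pair of reference solutions is
combined by greedy forward selection restricted to the pair's union, the
children are improved, and the reference set is re-ranked; the loop stops
when an iteration inserts no new member or at the iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .features import FeatureMatrix

#: Strict-improvement tolerance for greedy/hill-climbing merit comparisons.
MERIT_TOL = 1e-12


@dataclass(frozen=True)
class FeatureSubset:
    """A sorted index set over feature columns together with its CFS merit."""

    indices: tuple[int, ...]
    merit: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(sorted(self.indices)))
        if len(set(self.indices)) != len(self.indices):
            raise DomainError("subset indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def names(self, fm: FeatureMatrix) -> list[str]:
        return [fm.names[i] for i in self.indices]


@dataclass(frozen=True)
class SSRGSConfig:
    """Scatter-search parameters.

    refset_size
        Reference-set size, split evenly between a best-merit half and a
        max-diversity half; must be even and >= 4.
    pool_size
        Size of the diversified initial pool; must exceed refset_size.
    max_iterations
        Hard cap on combine/improve/update cycles; the usual exit is
        stagnation (an iteration that inserts no new reference solution).
    seed
        Seed for the diversification generator; the whole search is
        deterministic given (data, config).
    """

    refset_size: int = 10
    pool_size: int = 30
    max_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refset_size < 4 or self.refset_size % 2:
            raise DomainError("refset_size must be even and >= 4")
        if self.pool_size <= self.refset_size:
            raise DomainError("pool_size must exceed refset_size")


class CorrelationCache:
    """Feature-class relevances and absolute feature-feature correlations.

    Deterministic for a fixed matrix; the feature-feature half is filled
    column-by-column on demand so wide matrices only pay for the columns a
    search actually touches.
    """

    def __init__(self, values: np.ndarray, labels: np.ndarray):
        self.values = np.asarray(values, dtype=np.float64)
        labels = np.asarray(labels)
        n, width = self.values.shape
        if n < 2:
            raise DomainError("need at least 2 instances")
        self.width = width
        self._std = self.values.std(axis=0)  # population
        self._centered = self.values - self.values.mean(axis=0)
        self.relevance = np.array(
            [class_relevance(self.values[:, j], labels) for j in range(width)]
        )
        self._corr = np.full((width, width), np.nan)
        np.fill_diagonal(self._corr, 1.0)

    @classmethod
    def from_matrix(cls, fm: FeatureMatrix) -> "CorrelationCache":
        return cls(fm.values, fm.labels)

    def _fill_column(self, j: int) -> None:
        if not np.isnan(self._corr[0, j]) and not np.isnan(self._corr[:, j]).any():
            return
        n = len(self.values)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = self._centered.T @ self._centered[:, j] / n
            r = cov / (self._std * self._std[j])
        r = np.abs(np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0))
        r = np.clip(r, 0.0, 1.0)
        r[j] = 1.0
        self._corr[:, j] = r
        self._corr[j, :] = r

    def corr(self, indices) -> np.ndarray:
        """|r| submatrix for the given feature indices (diagonal 1)."""
        idx = np.asarray(list(indices), dtype=int)
        for j in idx:
            self._fill_column(int(j))
        return self._corr[np.ix_(idx, idx)]

    def corr_to(self, indices, candidates) -> np.ndarray:
        """|r| block between subset ``indices`` (rows) and ``candidates`` (cols)."""
        idx = np.asarray(list(indices), dtype=int)
        cand = np.asarray(list(candidates), dtype=int)
        for j in cand:
            self._fill_column(int(j))
        return self._corr[np.ix_(idx, cand)]


def class_relevance(feature: np.ndarray, labels) -> float:
    """Prior-weighted mean |point-biserial correlation| over one-vs-rest indicators.

    Returns a value in [0, 1]; a constant feature has relevance 0 by guard.
    """
    feature = np.asarray(feature, dtype=np.float64)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DomainError("need at least 2 distinct class labels")
    sf = feature.std()
    if sf < 1e-15:
        return 0.0
    n = len(feature)
    centered = feature - feature.mean()
    total = 0.0
    for c, cnt in zip(classes, counts):
        ind = (labels == c).astype(np.float64)
        si = ind.std()
        if si < 1e-15:
            continue
        r = (centered * (ind - ind.mean())).mean() / (sf * si)
        total += (cnt / n) * abs(r)
    return float(min(total, 1.0))


def cfs_merit(indices, cache: CorrelationCache) -> float:
    """CFS merit k*r_cf / sqrt(k + k(k-1)*r_ff) of a nonempty index set."""
    idx = tuple(indices)
    k = len(idx)
    if k == 0:
        raise DomainError("merit of the empty subset is undefined")
    rcf = float(cache.relevance[list(idx)].mean())
    if k == 1:
        return rcf
    sub = cache.corr(idx)
    rff = float((sub.sum() - k) / (k * (k - 1)))
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


def _merit_from_sums(k: int, rel_sum, pair_sum):
    """Merit from the subset's relevance sum and off-diagonal |r| sum (vector-friendly)."""
    rcf = rel_sum / k
    if k == 1:
        return rcf
    rff = pair_sum / (k * (k - 1))
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


class _Evaluator:
    """Incremental merit bookkeeping for greedy moves over one subset."""

    def __init__(self, cache: CorrelationCache, indices=()):
        self.cache = cache
        self.idx: list[int] = sorted(int(i) for i in indices)
        self._recompute()

    def _recompute(self) -> None:
        k = len(self.idx)
        self.rel_sum = float(self.cache.relevance[self.idx].sum()) if k else 0.0
        self.pair_sum = float(self.cache.corr(self.idx).sum() - k) if k else 0.0

    @property
    def merit(self) -> float:
        if not self.idx:
            return -np.inf
        return float(_merit_from_sums(len(self.idx), self.rel_sum, self.pair_sum))

    def addition_merits(self, candidates) -> np.ndarray:
        """Merit of S + {c} for every candidate c, in one vectorized sweep."""
        cand = list(candidates)
        k = len(self.idx)
        rel = self.rel_sum + self.cache.relevance[cand]
        if k == 0:
            return rel  # singleton merit equals relevance
        cross = self.cache.corr_to(self.idx, cand).sum(axis=0)
        pair = self.pair_sum + 2.0 * cross
        return np.asarray(_merit_from_sums(k + 1, rel, pair))

    def removal_merits(self) -> np.ndarray:
        """Merit of S - {i} for every member i (k must be >= 2)."""
        k = len(self.idx)
        rel = self.rel_sum - self.cache.relevance[self.idx]
        cross = self.cache.corr(self.idx).sum(axis=0) - 1.0
        pair = self.pair_sum - 2.0 * cross
        return np.asarray(_merit_from_sums(k - 1, rel, pair))

    def add(self, j: int) -> None:
        cross = float(self.cache.corr_to(self.idx, [j]).sum()) if self.idx else 0.0
        self.rel_sum += float(self.cache.relevance[j])
        self.pair_sum += 2.0 * cross
        self.idx = sorted(self.idx + [int(j)])

    def remove(self, j: int) -> None:
        pos = self.idx.index(int(j))
        cross = float(self.cache.corr(self.idx).sum(axis=0)[pos] - 1.0)
        self.rel_sum -= float(self.cache.relevance[j])
        self.pair_sum -= 2.0 * cross
        self.idx.remove(int(j))


def improve(subset: FeatureSubset | tuple, cache: CorrelationCache) -> FeatureSubset:
    """Best-improvement hill climbing over single additions and removals.

    Terminates at a local optimum of the merit, so the result is a fixed
    point (improve is idempotent) and its merit never falls below the
    input's.  Ties are broken toward the lowest feature index for
    determinism.
    """
    indices = subset.indices if isinstance(subset, FeatureSubset) else tuple(subset)
    if len(indices) == 0:
        raise DomainError("cannot improve the empty subset")
    ev = _Evaluator(cache, indices)
    all_features = np.arange(cache.width)
    while True:
        current = ev.merit
        best_gain, best_move = MERIT_TOL, None
        outside = np.setdiff1d(all_features, ev.idx, assume_unique=False)
        if len(outside):
            add_m = ev.addition_merits(outside)
            j = int(np.argmax(add_m))
            if add_m[j] - current > best_gain:
                best_gain, best_move = add_m[j] - current, ("add", int(outside[j]))
        if len(ev.idx) >= 2:
            rem_m = ev.removal_merits()
            j = int(np.argmax(rem_m))
            if rem_m[j] - current > best_gain:
                best_gain, best_move = rem_m[j] - current, ("remove", ev.idx[j])
        if best_move is None:
            break
        op, j = best_move
        ev.add(j) if op == "add" else ev.remove(j)
    return FeatureSubset(tuple(ev.idx), ev.merit)


def diversify(pool_size: int, width: int, seed_or_rng) -> list[FeatureSubset]:
    """Generate a diverse pool of candidate subsets (no merits attached yet).

    Sizes are stratified over 1..max(1, width // 2); membership is drawn
    least-used-feature-first with random tie-breaking, so every feature
    appears in at least one pool member whenever pool_size >= width.
    Deterministic under a fixed seed; duplicates are rejected.
    """
    if width < 2:
        raise DomainError("need at least 2 features to diversify")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    max_size = max(1, width // 2)
    sizes = [(i % max_size) + 1 for i in range(pool_size)]
    usage = np.zeros(width, dtype=int)
    seen: set[tuple[int, ...]] = set()
    pool: list[FeatureSubset] = []
    for size in sizes:
        members = None
        for trial_size in [size] + [s for s in range(1, max_size + 1) if s != size]:
            for _ in range(50):
                noise = rng.random(width)
                order = np.lexsort((noise, usage))  # least-used first, random ties
                cand = tuple(sorted(int(i) for i in order[:trial_size]))
                if cand not in seen:
                    members = cand
                    break
            if members is not None:
                break
        if members is None:
            break  # distinct subsets exhausted (tiny widths): return a smaller pool
        seen.add(members)
        usage[list(members)] += 1
        pool.append(FeatureSubset(members, np.nan))
    return pool


def combine_reduced_greedy(
    a: FeatureSubset, b: FeatureSubset, cache: CorrelationCache
) -> FeatureSubset:
    """Reduced greedy combination of two parent subsets.

    Starting from the intersection, repeatedly add the merit-maximizing
    feature drawn only from the parents' union, stopping when no addition
    improves the merit.  The child is always a subset of the union, and its
    merit is at least that of a nonempty intersection.
    """
    inter = sorted(set(a.indices) & set(b.indices))
    union = sorted(set(a.indices) | set(b.indices))
    ev = _Evaluator(cache, inter)
    while True:
        cand = [j for j in union if j not in ev.idx]
        if not cand:
            break
        merits = ev.addition_merits(cand)
        j = int(np.argmax(merits))
        if merits[j] <= ev.merit + MERIT_TOL:
            break
        ev.add(cand[j])
    if not ev.idx:  # empty intersection and no improving singleton cannot happen
        raise DomainError("combination produced an empty subset")
    return FeatureSubset(tuple(ev.idx), ev.merit)


def _symmetric_difference(a: tuple, b: tuple) -> int:
    return len(set(a) ^ set(b))


def run_ssrgs(fm: FeatureMatrix, cfg: SSRGSConfig | None = None) -> FeatureSubset:
    """Full SS-RGS search over a feature matrix; returns the best-merit subset.

    Pipeline: diversify -> improve pool -> reference set (best-merit half +
    max-diversity half) -> loop {combine all pairs, improve children,
    static re-rank of the reference set} until stagnation or the iteration
    cap.  Fully reproducible for a fixed seed.
    """
    cfg = cfg or SSRGSConfig()
    if fm.width < 2:
        raise DomainError("need at least 2 features")
    if len(np.unique(fm.labels)) < 2:
        raise DomainError("need at least 2 classes")
    cache = CorrelationCache.from_matrix(fm)
    rng = np.random.default_rng(cfg.seed)

    pool = [improve(s, cache) for s in diversify(cfg.pool_size, fm.width, rng)]
    pool = _dedupe(pool)
    pool.sort(key=_rank_key)
    half = cfg.refset_size // 2
    refset = pool[:half]
    rest = pool[half:]
    # diversity half: greedily add the candidate farthest (min symmetric
    # difference to current members maximized) from the reference set
    while rest and len(refset) < cfg.refset_size:
        dists = [
            min(_symmetric_difference(c.indices, m.indices) for m in refset) for c in rest
        ]
        pick = int(np.argmax(dists))
        refset.append(rest.pop(pick))

    for _ in range(cfg.max_iterations):
        members = {s.indices for s in refset}
        children = []
        for i in range(len(refset)):
            for j in range(i + 1, len(refset)):
                child = improve(
                    combine_reduced_greedy(refset[i], refset[j], cache), cache
                )
                children.append(child)
        merged = _dedupe(refset + children)
        merged.sort(key=_rank_key)
        refset = merged[: cfg.refset_size]
        if {s.indices for s in refset} == members:
            break  # stagnation: no new reference solution inserted
    return min(refset, key=_rank_key)


def _rank_key(s: FeatureSubset):
    return (-s.merit, len(s.indices), s.indices)


def _dedupe(subsets: list[FeatureSubset]) -> list[FeatureSubset]:
    seen: set[tuple[int, ...]] = set()
    out = []
    for s in subsets:
        if s.indices not in seen:
            seen.add(s.indices)
            out.append(s)
    return out


def exhaustive_best_subset(fm: FeatureMatrix) -> FeatureSubset:
    """Brute-force CFS optimum over all nonempty subsets (oracle; <= ~15 features)."""
    if fm.width > 20:
        raise DomainError("exhaustive search is only for small matrices")
    cache = CorrelationCache.from_matrix(fm)
    best: FeatureSubset | None = None
    for mask in range(1, 1 << fm.width):
        idx = tuple(i for i in range(fm.width) if mask >> i & 1)
        m = cfs_merit(idx, cache)
        cand = FeatureSubset(idx, m)
        if best is None or _rank_key(cand) < _rank_key(best):
            best = cand
    return best
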