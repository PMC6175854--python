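"""Prior inclusion probabilities from causal discovery and PPI scores.

The protein-protein prior for the Bayesian regressions is calibrated in two
parts: (1) directional stability weights from the PC algorithm run over
random half-subsamples and a grid of test levels, restricted to the edge set
found on the full data; (2) undirected STRING-style interaction confidences.
The prior inclusion probability of regulator i for target j is the edge-wise
average of the two sources.

The PC algorithm is implemented here directly (skeleton search with
Gaussian partial-correlation Fisher-z tests, v-structure orientation, Meek
rules R1-R3); no suitable implementation ships with the supported
environment.  Edges whose direction remains unidentifiable stay undirected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AnalysisConfig, ExpressionMatrix, PPITable

logger = logging.getLogger(__name__)

__all__ = [
    "PCGraph",
    "CausalWeightMatrix",
    "PriorInclusionMatrix",
    "pc_skeleton",
    "stability_weights",
    "combine_prior",
]


# ---------------------------------------------------------------------------
# Conditional-independence testing with caching
# ---------------------------------------------------------------------------


class _FisherZTester:
    """Cached Gaussian CI tests (partial correlation + Fisher z transform).

    p-values depend only on (i, j, S), never on alpha, so one cache serves
    every grid level on the same (sub)sample.
    """

    def __init__(self, data: np.ndarray):
        self.n = data.shape[0]
        sd = data.std(axis=0)
        if np.any(sd == 0):
            bad = [int(k) for k in np.where(sd == 0)[0]]
            raise ValueError(f"constant column(s) at positions {bad}")
        self.corr = np.corrcoef(data, rowvar=False)
        self._cache: dict[tuple[int, int, tuple[int, ...]], float] = {}

    def pvalue(self, i: int, j: int, cond: tuple[int, ...]) -> float:
        if i > j:
            i, j = j, i
        key = (i, j, cond)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        idx = [i, j, *cond]
        sub = self.corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
            r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        except np.linalg.LinAlgError:
            r = 0.0
        r = float(np.clip(r, -0.9999999, 0.9999999))
        dof = self.n - len(cond) - 3
        if dof < 1:
            p = 1.0
        else:
            z = 0.5 * np.log((1 + r) / (1 - r))
            p = 2.0 * stats.norm.sf(np.sqrt(dof) * abs(z))
        self._cache[key] = p
        return p


# ---------------------------------------------------------------------------
# Graph containers
# ---------------------------------------------------------------------------


@dataclass
class PCGraph:
    """CPDAG-style output: ``amat[i, j] and not amat[j, i]`` means i -> j;
    both set means the direction is not identifiable (undirected)."""

    nodes: list[str]
    amat: np.ndarray  # bool, p x p

    def edges(self) -> list[tuple[str, str, str]]:
        """List of (a, b, kind) with kind in {'directed', 'undirected'}."""
        out = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(p):
                if i < j and self.amat[i, j] and self.amat[j, i]:
                    out.append((self.nodes[i], self.nodes[j], "undirected"))
                elif self.amat[i, j] and not self.amat[j, i]:
                    out.append((self.nodes[i], self.nodes[j], "directed"))
        return out

    def skeleton_pairs(self) -> set[tuple[int, int]]:
        p = len(self.nodes)
        return {
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if self.amat[i, j] or self.amat[j, i]
        }


@dataclass
class CausalWeightMatrix:
    """Directional stability weights restricted to the initial edge set."""

    proteins: list[str]
    weights: np.ndarray  # p x p in [0, 1], diagonal zero
    skeleton: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        w = self.weights
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal of stability weights must be zero")
        if np.any((w < 0) | (w > 1)):
            raise ValueError("stability weights must lie in [0,1]")


@dataclass
class PriorInclusionMatrix:
    """w[i, j] = prior inclusion probability of protein i regulating j."""

    proteins: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diag(self.w) != 0):
            raise ValueError("diagonal of prior matrix must be zero")
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("prior inclusion probabilities must lie in [0,1]")

    def regulators_of(self, target: str) -> list[str]:
        """upa(target): proteins with strictly positive prior weight."""
        j = self.proteins.index(target)
        return [
            self.proteins[i]
            for i in range(len(self.proteins))
            if i != j and self.w[i, j] > 0
        ]

    def weight(self, regulator: str, target: str) -> float:
        return float(
            self.w[self.proteins.index(regulator), self.proteins.index(target)]
        )


# ---------------------------------------------------------------------------
# PC algorithm
# ---------------------------------------------------------------------------


def _pc_from_tester(tester: _FisherZTester, p: int, alpha: float) -> np.ndarray:
    """Run PC on cached tests; returns the boolean adjacency mark matrix."""
    adj = [set(range(p)) - {i} for i in range(p)]
    sepset: dict[tuple[int, int], frozenset[int]] = {}

    level = 0
    while True:
        any_testable = False
        # snapshot of adjacencies for the "stable" variant
        frozen = [frozenset(a) for a in adj]
        for i in range(p):
            for j in sorted(frozen[i]):
                if j not in adj[i]:
                    continue
                others = sorted(frozen[i] - {j})
                if len(others) < level:
                    continue
                any_testable = True
                removed = False
                for cond in itertools.combinations(others, level):
                    if tester.pvalue(i, j, cond) > alpha:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepset[(i, j)] = sepset[(j, i)] = frozenset(cond)
                        removed = True
                        break
                if removed:
                    continue
        if not any_testable:
            break
        level += 1

    amat = np.zeros((p, p), dtype=bool)
    for i in range(p):
        for j in adj[i]:
            amat[i, j] = True

    # v-structures i -> k <- j when k is not in sepset(i, j)
    for k in range(p):
        neighbors = sorted(np.where(amat[k] & amat[:, k])[0])
        for i, j in itertools.combinations(neighbors, 2):
            if amat[i, j] or amat[j, i]:
                continue
            if k not in sepset.get((i, j), frozenset()):
                # orient both arrowheads into k unless that would delete an edge
                if amat[i, k] and amat[k, i]:
                    amat[k, i] = False
                if amat[j, k] and amat[k, j]:
                    amat[k, j] = False

    # Meek rules R1-R3 to closure
    changed = True
    while changed:
        changed = False
        und = [
            (i, j)
            for i in range(p)
            for j in range(p)
            if i < j and amat[i, j] and amat[j, i]
        ]
        for i, j in und:
            for a, b in ((i, j), (j, i)):
                if not (amat[a, b] and amat[b, a]):
                    continue  # already oriented by an earlier rule
                # R1: c -> a, a - b, c and b nonadjacent  =>  a -> b
                for c in range(p):
                    if c in (a, b):
                        continue
                    if (
                        amat[c, a]
                        and not amat[a, c]
                        and not (amat[c, b] or amat[b, c])
                    ):
                        if amat[b, a]:
                            amat[b, a] = False
                            changed = True
                        break
                if not amat[b, a]:
                    continue
                # R2: a -> c -> b with a - b  =>  a -> b
                for c in range(p):
                    if c in (a, b):
                        continue
                    if amat[a, c] and not amat[c, a] and amat[c, b] and not amat[b, c]:
                        if amat[b, a]:
                            amat[b, a] = False
                            changed = True
                        break
                if not amat[b, a]:
                    continue
                # R3: a - c -> b and a - d -> b, c,d nonadjacent  =>  a -> b
                spokes = [
                    c
                    for c in range(p)
                    if c not in (a, b)
                    and amat[a, c]
                    and amat[c, a]
                    and amat[c, b]
                    and not amat[b, c]
                ]
                done = False
                for c, d in itertools.combinations(spokes, 2):
                    if not (amat[c, d] or amat[d, c]):
                        amat[b, a] = False
                        changed = True
                        done = True
                        break
                if done:
                    continue
    return amat


def pc_skeleton(data: ExpressionMatrix | np.ndarray, alpha: float,
                nodes: list[str] | None = None) -> PCGraph:
    """Estimate the partially directed causal structure of the proteins.

    Uses Gaussian partial-correlation Fisher-z conditional-independence
    tests at level ``alpha`` (order-independent "stable" skeleton phase),
    then v-structure orientation and Meek rules.  Edges left undirected mean
    the direction is not identifiable from the data.
    """
    if isinstance(data, ExpressionMatrix):
        X = data.values
        nodes = data.feature_ids
    else:
        X = np.asarray(data, dtype=float)
        if nodes is None:
            nodes = [f"V{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 samples for CI tests, got {n}")
    if p < 2:
        raise ValueError("need at least 2 features")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [nodes[k] for k in np.where(sd == 0)[0]]
        raise ValueError(f"constant feature(s): {bad}")
    tester = _FisherZTester(X)
    return PCGraph(nodes=list(nodes), amat=_pc_from_tester(tester, p, float(alpha)))


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


def stability_weights(
    data: ExpressionMatrix,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> CausalWeightMatrix:
    """Directional edge weights by subsampling stability of the PC output.

    The initial edge set E-hat comes from one PC fit on the full data at
    ``alpha_init``.  Each of ``n_subsamples`` half-samples (size floor(n/2),
    without replacement) is re-analysed at every grid level; a directed edge
    occurrence credits its direction fully, an undirected occurrence credits
    both directions at half weight.  Per direction, the selection
    probability at each alpha is the fraction of subsamples carrying it, and
    the final weight is the maximum over the grid, restricted to E-hat.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = data.values
    nodes = data.feature_ids
    n, p = X.shape
    half = n // 2
    if half < 10:
        raise ValueError(f"subsample size {half} too small for CI tests")

    full = pc_skeleton(data, config.alpha_init)
    skeleton = full.skeleton_pairs()

    grid = list(config.alpha_grid)
    counts = np.zeros((len(grid), p, p))
    for _ in range(config.n_subsamples):
        idx = rng.choice(n, size=half, replace=False)
        sub = X[idx]
        if np.any(sub.std(axis=0) == 0):  # pragma: no cover - continuous data
            continue
        tester = _FisherZTester(sub)
        for a_i, alpha in enumerate(grid):
            amat = _pc_from_tester(tester, p, float(alpha))
            directed = amat & ~amat.T
            undirected = amat & amat.T
            counts[a_i] += directed
            counts[a_i] += 0.5 * undirected

    freq = counts / float(config.n_subsamples)
    weights = freq.max(axis=0)
    mask = np.zeros((p, p), dtype=bool)
    for i, j in skeleton:
        mask[i, j] = mask[j, i] = True
    weights = np.where(mask, weights, 0.0)
    np.fill_diagonal(weights, 0.0)
    weights = np.clip(weights, 0.0, 1.0)
    return CausalWeightMatrix(proteins=nodes, weights=weights, skeleton=skeleton)


# ---------------------------------------------------------------------------
# Prior combination
# ---------------------------------------------------------------------------


def combine_prior(causal: CausalWeightMatrix, ppi: PPITable) -> PriorInclusionMatrix:
    """Edge-wise average of causal stability weights and PPI confidences.

    The undirected PPI score enters both directed entries; the denominator
    is always 2 with a missing source contributing 0.  Pairs where both
    sources are zero stay exactly zero, so they are excluded from the
    candidate regulator sets.
    """
    p = len(causal.proteins)
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            c = float(causal.weights[i, j])
            s = ppi.score(causal.proteins[i], causal.proteins[j])
            if c > 0 or s > 0:
                w[i, j] = (c + s) / 2.0
    return PriorInclusionMatrix(proteins=list(causal.proteins), w=w)
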