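"""Pan-cancer stratification on the combined pathway score matrix.

Patients are clustered by Ward's method on Euclidean distances of the
patients x pathways matrix of combined (activated + suppressed) scores.
The number of clusters is chosen with the gap statistic against uniform
reference data drawn over each feature's observed range: the selected k is
the smallest one with Gap(k) >= Gap(k+1) - s_{k+1}.

Cluster-level summaries: a Beta-Binomial enrichment probability (posterior
probability that a category's in-cluster proportion exceeds the
complement's, under independent Beta(1,1) priors) and normalized mutual
information between partitions (sqrt normalization by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import normalized_mutual_info_score

from .io import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "build_score_matrix",
    "cluster_patients",
    "enrichment_probability",
    "normalized_mutual_information",
]


def build_score_matrix(scores: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the patients x pathways matrix of combined scores.

    ``scores`` maps pathway name to the per-patient score frame produced by
    :func:`precisenet.scoring.precise_scores`.  Patients missing any pathway
    are dropped (inner join) with a warning.
    """
    if not scores:
        raise ValueError("no score tables given")
    columns = {}
    common: pd.Index | None = None
    for name, frame in scores.items():
        col = frame["combined"]
        columns[name] = col
        common = col.index if common is None else common.intersection(col.index)
    if common is None or len(common) == 0:
        raise ValueError("no patients scored on every pathway")
    n_all = max(len(frame) for frame in scores.values())
    if len(common) < n_all:
        logger.warning(
            "dropping %d patient(s) not scored on every pathway", n_all - len(common)
        )
    mat = pd.DataFrame(
        {name: col.loc[common] for name, col in columns.items()}, index=common
    )
    mat.index.name = "sample"
    return mat


# ---------------------------------------------------------------------------
# Ward clustering with gap-statistic model selection
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: pd.Series  # per-patient cluster id in 1..k_selected
    k_selected: int
    gap_curve: pd.DataFrame  # columns k, gap, sk, log_w
    linkage_record: np.ndarray | None


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def _gap_logw(X: np.ndarray, k_max: int) -> np.ndarray:
    Z = linkage(X, method="ward")
    floor = max(float(((X - X.mean(axis=0)) ** 2).sum()), 1.0) * 1e-12
    logw = np.empty(k_max)
    for k in range(1, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        logw[k - 1] = np.log(max(_within_ss(X, labels), floor))
    return logw


def cluster_patients(
    matrix: pd.DataFrame,
    k_max: int,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Ward/Euclidean hierarchical clustering with gap-statistic selection."""
    if config is None:
        config = AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < k_max:
        raise ValueError("need at least k_max patients")
    if np.allclose(X, X[0]):
        warnings.warn("constant score matrix; returning a single cluster")
        labels = pd.Series(np.ones(n, dtype=int), index=matrix.index, name="cluster")
        return ClusterResult(labels, 1, pd.DataFrame(columns=["k", "gap", "sk", "log_w"]), None)

    Z = linkage(X, method="ward")
    logw = _gap_logw(X, k_max)

    lo = X.min(axis=0)
    hi = X.max(axis=0)
    B = config.gap_B
    ref_logw = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_logw[b] = _gap_logw(ref, k_max)
    gap = ref_logw.mean(axis=0) - logw
    sk = ref_logw.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    k_selected = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - sk[k]:
            k_selected = k
            break
    labels = pd.Series(
        fcluster(Z, t=k_selected, criterion="maxclust"),
        index=matrix.index,
        name="cluster",
    )
    curve = pd.DataFrame(
        {"k": np.arange(1, k_max + 1), "gap": gap, "sk": sk, "log_w": logw}
    )
    return ClusterResult(labels, int(k_selected), curve, Z)


# ---------------------------------------------------------------------------
# Enrichment probability
# ---------------------------------------------------------------------------


def enrichment_probability(
    x_in: int,
    n_cat: int,
    x_out: int,
    n_other: int,
    draws: int = 200_000,
    seed: int = 0,
) -> float:
    """P(theta_cat > theta_other) under independent Beta(1+x, 1+n-x) posteriors.

    Monte Carlo with ``draws`` paired samples; deterministic for a given
    seed.
    """
    if n_cat < 1 or n_other < 1:
        raise ValueError("both group sizes must be >= 1")
    if not (0 <= x_in <= n_cat) or not (0 <= x_out <= n_other):
        raise ValueError("counts must satisfy 0 <= x <= n")
    rng = np.random.default_rng(seed)
    theta_cat = rng.beta(1 + x_in, 1 + n_cat - x_in, size=draws)
    theta_other = rng.beta(1 + x_out, 1 + n_other - x_out, size=draws)
    return float(np.mean(theta_cat > theta_other))


def enrichment_report(
    labels: pd.Series, categories: pd.Series, draws: int = 200_000, seed: int = 0
) -> pd.DataFrame:
    """EP of every (cluster, category) combination with its counts."""
    common = labels.index.intersection(categories.index)
    if len(common) == 0:
        raise ValueError("labels and categories share no samples")
    labels = labels.loc[common]
    categories = categories.loc[common]
    rows = []
    for cluster in sorted(labels.unique()):
        in_cluster = labels == cluster
        for cat in sorted(categories.unique()):
            is_cat = categories == cat
            n_cat = int(is_cat.sum())
            n_other = int((~is_cat).sum())
            if n_cat == 0 or n_other == 0:
                continue
            x_in = int((in_cluster & is_cat).sum())
            x_out = int((in_cluster & ~is_cat).sum())
            ep = enrichment_probability(
                x_in, n_cat, x_out, n_other, draws=draws, seed=seed
            )
            rows.append(
                {
                    "cluster": cluster,
                    "category": cat,
                    "ep": ep,
                    "x_in": x_in,
                    "n_category": n_cat,
                    "x_out": x_out,
                    "n_other": n_other,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normalized mutual information
# ---------------------------------------------------------------------------

_NMI_VARIANTS = {"sqrt": "geometric", "arithmetic": "arithmetic", "min": "min", "max": "max"}


def normalized_mutual_information(labels_a, labels_b, variant: str = "sqrt") -> float:
    """NMI(A;B) = I(A;B) / sqrt(H(A) H(B)) by default; 0/0 guarded to 0.

    Accepts plain sequences (matched by position) or pandas Series (matched
    by index; mismatched sample sets raise).
    """
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        if set(labels_a.index) != set(labels_b.index):
            raise ValueError("partitions cover different sample sets")
        labels_b = labels_b.loc[labels_a.index]
        a = labels_a.to_numpy()
        b = labels_b.to_numpy()
    else:
        a = np.asarray(list(labels_a))
        b = np.asarray(list(labels_b))
        if len(a) != len(b):
            raise ValueError("partitions have different lengths")
    if len(a) == 0:
        raise ValueError("empty partitions")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0.0
    if variant not in _NMI_VARIANTS:
        raise ValueError(f"unknown NMI variant {variant!r}")
    return float(
        normalized_mutual_info_score(a, b, average_method=_NMI_VARIANTS[variant])
    )
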