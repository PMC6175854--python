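"""Node-wise Bayesian sparse regression and the integrated network.

Each protein i is regressed on (a) candidate protein regulators drawn from
the prior inclusion matrix (upa(i) = regulators with positive prior weight)
and (b) upstream covariates built from the protein's own gene: the
methylation-modulated and methylation-independent components of its mRNA
plus the expression of miRNAs annotated to the gene.

The coefficient prior is Zellner's g-prior, beta | g ~ N(0, sigma^2 g
(Z'Z)^-1) with the unit-information default g = n, combined with the scale
prior p(sigma) proportional to 1/sigma on the centered response.  The
marginal likelihood of a model M with k covariates and coefficient of
determination R^2 is available in closed form,

    log m(M) = -(n/2) log(2 pi) + log Gamma(n/2) + (n/2 - 1) log 2
               - (k/2) log(1 + g) - (n/2) log Q,
    Q = y'y (1 + g (1 - R^2)) / (1 + g),

so posterior model probabilities follow by combining with the independent
Bernoulli model prior built from the per-candidate prior inclusion weights.
Small candidate sets are enumerated exactly; larger ones are explored with
an MC3 add/delete/swap sampler.  The median probability model (candidates
with posterior inclusion probability strictly above 0.5) defines the graph:
one-way selection between two proteins yields a directed regulatory edge,
mutual selection a single undirected correlative edge.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import AnalysisConfig, ExpressionMatrix
from .prior import PriorInclusionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Covariate",
    "RegressionProblem",
    "NodeFit",
    "IntegratedNetwork",
    "construct_upstream_covariates",
    "log_marginal_likelihood",
    "model_posterior",
    "build_integrated_network",
    "fit_pathway_network",
    "PathwayFit",
]


# ---------------------------------------------------------------------------
# Upstream covariates (iBAG-style mRNA decomposition + miRNAs)
# ---------------------------------------------------------------------------


@dataclass
class Covariate:
    name: str
    kind: str  # protein | mrna-modulated | mrna-independent | mirna
    values: np.ndarray


def construct_upstream_covariates(
    mrna: ExpressionMatrix | None,
    methylation: ExpressionMatrix | None,
    mirna: ExpressionMatrix | None,
    gene: str,
    mirna_map: dict[str, list[str]] | None = None,
) -> list[Covariate]:
    """Build the upstream covariates for one protein's gene.

    The gene's mRNA is regressed on its methylation probe by least squares;
    the fitted values are the methylation-modulated component and the
    residuals the methylation-independent component.  Expression vectors of
    miRNAs annotated to the gene are appended as-is.
    """
    covs: list[Covariate] = []
    have_mrna = mrna is not None and gene in mrna.data.columns
    if mrna is not None and not have_mrna:
        logger.warning("gene %s absent from mRNA matrix; using miRNAs only", gene)
    if have_mrna:
        x = mrna.data[gene].to_numpy(dtype=float)
        if methylation is not None and gene in methylation.data.columns:
            m = methylation.data[gene].to_numpy(dtype=float)
            design = np.column_stack([np.ones_like(m), m])
            coefs, *_ = np.linalg.lstsq(design, x, rcond=None)
            fitted = design @ coefs
            covs.append(Covariate(f"{gene}:mrna_mod", "mrna-modulated", fitted))
            covs.append(Covariate(f"{gene}:mrna_ind", "mrna-independent", x - fitted))
        else:
            if methylation is not None:
                logger.warning(
                    "gene %s absent from methylation matrix; mRNA used whole", gene
                )
            covs.append(Covariate(f"{gene}:mrna_ind", "mrna-independent", x.copy()))
    if mirna is not None and mirna_map:
        for mir in mirna_map.get(gene, []):
            if mir in mirna.data.columns:
                covs.append(
                    Covariate(mir, "mirna", mirna.data[mir].to_numpy(dtype=float))
                )
    return covs


# ---------------------------------------------------------------------------
# Regression problem
# ---------------------------------------------------------------------------


@dataclass
class RegressionProblem:
    """Centered response and standardized candidate design for one protein."""

    target: str
    y: np.ndarray  # centered response
    candidates: list[str]
    kinds: list[str]
    prior_w: np.ndarray
    Z: np.ndarray  # n x k, columns centered and unit-scaled
    g: float
    sample_ids: list[str]
    y_center: float = 0.0

    def __post_init__(self) -> None:
        if abs(float(np.mean(self.y))) > 1e-10:
            raise ValueError("response must be centered")
        if np.any(self.prior_w <= 0):
            raise ValueError("candidate prior weights must be positive")
        # precomputed cross-products reused by every model evaluation
        self._G = self.Z.T @ self.Z
        self._c = self.Z.T @ self.y
        self._yty = float(self.y @ self.y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return len(self.candidates)

    @classmethod
    def build(
        cls,
        protein: ExpressionMatrix,
        target: str,
        prior: PriorInclusionMatrix,
        config: AnalysisConfig,
        upstream: list[Covariate] | None = None,
        candidate_pool: list[str] | None = None,
    ) -> "RegressionProblem":
        """Assemble the problem for one target from matrix, prior, upstream.

        ``candidate_pool`` restricts protein candidates (typically the
        pathway's proteins); upa(target) is intersected with it.
        """
        y_raw = protein.data[target].to_numpy(dtype=float)
        y_center = float(y_raw.mean())
        y = y_raw - y_center

        pool = candidate_pool if candidate_pool is not None else protein.feature_ids
        names: list[str] = []
        kinds: list[str] = []
        weights: list[float] = []
        cols: list[np.ndarray] = []
        if target in prior.proteins:
            for reg in prior.regulators_of(target):
                if reg == target or reg not in pool or reg not in protein.data.columns:
                    continue
                names.append(reg)
                kinds.append("protein")
                weights.append(prior.weight(reg, target))
                cols.append(protein.data[reg].to_numpy(dtype=float))
        for cov in upstream or []:
            names.append(cov.name)
            kinds.append(cov.kind)
            weights.append(config.default_upstream_prior)
            cols.append(np.asarray(cov.values, dtype=float))

        keep_names, keep_kinds, keep_w, keep_cols = [], [], [], []
        for name, kind, w, col in zip(names, kinds, weights, cols):
            sd = col.std()
            if sd == 0 or not np.isfinite(sd):
                logger.warning(
                    "dropping constant candidate %s for target %s", name, target
                )
                continue
            keep_names.append(name)
            keep_kinds.append(kind)
            keep_w.append(float(np.clip(w, 1e-12, 1.0)))
            keep_cols.append((col - col.mean()) / sd)
        Z = (
            np.column_stack(keep_cols)
            if keep_cols
            else np.zeros((len(y), 0))
        )
        g = float(config.g) if config.g is not None else float(len(y))
        return cls(
            target=target,
            y=y,
            candidates=keep_names,
            kinds=keep_kinds,
            prior_w=np.asarray(keep_w, dtype=float),
            Z=Z,
            g=g,
            sample_ids=protein.sample_ids,
            y_center=y_center,
        )


# ---------------------------------------------------------------------------
# Closed-form marginal likelihood
# ---------------------------------------------------------------------------


def _model_r2(problem: RegressionProblem, model: tuple[int, ...]) -> float:
    if not model:
        return 0.0
    idx = list(model)
    G = problem._G[np.ix_(idx, idx)]
    c = problem._c[idx]
    try:
        beta = np.linalg.solve(G, c)
    except np.linalg.LinAlgError:
        logger.warning(
            "rank-deficient design for %s model %s; using pseudo-inverse",
            problem.target,
            model,
        )
        beta = np.linalg.lstsq(G, c, rcond=None)[0]
    r2 = float(c @ beta) / problem._yty if problem._yty > 0 else 0.0
    if r2 > 1.0 - 1e-12 or not np.isfinite(r2):
        beta = np.linalg.lstsq(problem.Z[:, idx], problem.y, rcond=None)[0]
        fitted = problem.Z[:, idx] @ beta
        r2 = float(fitted @ fitted) / problem._yty if problem._yty > 0 else 0.0
    return float(np.clip(r2, 0.0, 1.0 - 1e-12))


def log_marginal_likelihood(
    problem: RegressionProblem, model: tuple[int, ...] | list[int]
) -> float:
    """Exact log marginal likelihood of one candidate subset.

    Closed form under the g-prior and p(sigma) ~ 1/sigma on the centered
    response (see module docstring).  The empty model has R^2 = 0 and
    serves as the Bayes-factor reference.
    """
    model = tuple(sorted(int(m) for m in model))
    k = len(model)
    n = problem.n
    if k >= n - 1:
        raise ValueError(f"model size {k} must be < n-1 = {n - 1}")
    g = problem.g
    r2 = _model_r2(problem, model)
    q = problem._yty * (1.0 + g * (1.0 - r2)) / (1.0 + g)
    return float(
        -0.5 * n * math.log(2 * math.pi)
        + gammaln(n / 2.0)
        + (n / 2.0 - 1.0) * math.log(2.0)
        - 0.5 * k * math.log(1.0 + g)
        - 0.5 * n * math.log(q)
    )


def _log_model_prior(problem: RegressionProblem, mask: int) -> float:
    lp = 0.0
    for c in range(problem.k):
        w = problem.prior_w[c]
        if mask >> c & 1:
            lp += math.log(w)
        else:
            lp += math.log1p(-w) if w < 1.0 else -math.inf
    return lp


def _mask_to_model(mask: int, k: int) -> tuple[int, ...]:
    return tuple(c for c in range(k) if mask >> c & 1)


# ---------------------------------------------------------------------------
# Posterior over models
# ---------------------------------------------------------------------------


@dataclass
class NodeFit:
    """Posterior summaries of one protein's regression."""

    target: str
    candidates: list[str]
    kinds: list[str]
    pips: np.ndarray
    mpm: list[str]
    coefficients: dict[str, tuple[float, float]]  # name -> (post mean, post sd)
    sigma2: float
    method: str  # enumeration | mc3
    log_evidence: dict = field(default_factory=dict)
    model_masks: np.ndarray | None = None  # enumeration only
    model_probs: np.ndarray | None = None

    @property
    def mpm_indices(self) -> list[int]:
        return [self.candidates.index(name) for name in self.mpm]


def _mpm_summaries(problem: RegressionProblem, mpm_idx: list[int]):
    """Posterior coefficient mean/sd and sigma^2 summary under the MPM."""
    n, g = problem.n, problem.g
    shrink = g / (1.0 + g)
    if not mpm_idx:
        q = problem._yty
        return {}, q / max(n - 2, 1)
    idx = list(mpm_idx)
    G = problem._G[np.ix_(idx, idx)]
    c = problem._c[idx]
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
    beta_hat = Ginv @ c
    r2 = float(np.clip(c @ beta_hat / problem._yty, 0.0, 1.0 - 1e-12))
    q = problem._yty * (1.0 + g * (1.0 - r2)) / (1.0 + g)
    sigma2 = q / max(n - 2, 1)
    post_mean = shrink * beta_hat
    post_var = sigma2 * shrink * np.diag(Ginv)
    coefs = {
        problem.candidates[ci]: (float(post_mean[t]), float(np.sqrt(max(post_var[t], 0.0))))
        for t, ci in enumerate(idx)
    }
    return coefs, float(sigma2)


def model_posterior(
    problem: RegressionProblem,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> NodeFit:
    """Posterior inclusion probabilities and the median probability model.

    Candidate sets up to ``config.enumeration_limit`` are enumerated
    exactly (posterior model probabilities normalised over all 2^k
    subsets); larger sets are sampled with MC3 (add/delete/swap
    Metropolis-Hastings, cached marginals, 10% burn-in) and pips become
    visit frequencies.  The MPM keeps candidates with pip strictly greater
    than 0.5.
    """
    k = problem.k
    if k == 0:
        _, sigma2 = _mpm_summaries(problem, [])
        return NodeFit(
            target=problem.target,
            candidates=[],
            kinds=[],
            pips=np.zeros(0),
            mpm=[],
            coefficients={},
            sigma2=sigma2,
            method="enumeration",
            model_masks=np.zeros(1, dtype=np.int64),
            model_probs=np.ones(1),
        )

    if k <= config.enumeration_limit:
        masks = np.arange(2**k, dtype=np.int64)
        logpost = np.empty(len(masks))
        for mask in masks:
            model = _mask_to_model(int(mask), k)
            logpost[mask] = log_marginal_likelihood(problem, model) + _log_model_prior(
                problem, int(mask)
            )
        logz = logsumexp(logpost)
        probs = np.exp(logpost - logz)
        pips = np.zeros(k)
        for c in range(k):
            sel = (masks >> c & 1).astype(bool)
            pips[c] = probs[sel].sum()
        method = "enumeration"
        model_masks, model_probs = masks, probs
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        iters = int(config.mcmc_iters)
        burn = iters // 10
        cache: dict[int, float] = {}

        def logpost_of(mask: int) -> float:
            val = cache.get(mask)
            if val is None:
                val = log_marginal_likelihood(
                    problem, _mask_to_model(mask, k)
                ) + _log_model_prior(problem, mask)
                cache[mask] = val
            return val

        mask = 0
        for c in range(k):  # force candidates the prior makes mandatory
            if problem.prior_w[c] >= 1.0:
                mask |= 1 << c
        current = logpost_of(mask)
        counts = np.zeros(k)
        kept = 0
        for it in range(iters):
            if rng.random() < 0.5 or mask in (0, (1 << k) - 1):
                c = int(rng.integers(k))
                prop = mask ^ (1 << c)
            else:
                inc = [c for c in range(k) if mask >> c & 1]
                exc = [c for c in range(k) if not mask >> c & 1]
                prop = mask ^ (1 << inc[int(rng.integers(len(inc)))])
                prop ^= 1 << exc[int(rng.integers(len(exc)))]
            if bin(prop).count("1") >= problem.n - 1:
                lp = -math.inf
            else:
                lp = logpost_of(prop)
            if lp - current > math.log(rng.random() + 1e-300):
                mask, current = prop, lp
            if it >= burn:
                kept += 1
                for c in range(k):
                    if mask >> c & 1:
                        counts[c] += 1
        pips = counts / max(kept, 1)
        method = "mc3"
        model_masks = model_probs = None

    mpm_idx = [c for c in range(k) if pips[c] > 0.5]
    coefs, sigma2 = _mpm_summaries(problem, mpm_idx)
    return NodeFit(
        target=problem.target,
        candidates=list(problem.candidates),
        kinds=list(problem.kinds),
        pips=pips,
        mpm=[problem.candidates[c] for c in mpm_idx],
        coefficients=coefs,
        sigma2=sigma2,
        method=method,
        log_evidence={"n_models": 2**k if method == "enumeration" else None},
        model_masks=model_masks,
        model_probs=model_probs,
    )


# ---------------------------------------------------------------------------
# Integrated network
# ---------------------------------------------------------------------------


@dataclass
class ProteinEdge:
    src: str
    dst: str
    kind: str  # regulatory | correlative
    pip: float
    pip_reverse: float | None = None  # raw reverse pip for correlative edges


@dataclass
class UpstreamEdge:
    covariate: str
    kind: str
    target: str
    pip: float


@dataclass
class IntegratedNetwork:
    """Cancer-specific pathway network from the node-wise MPMs.

    ``out_degree[i]`` (C_i) counts targets of regulatory edges from i plus
    correlative partners of i; upstream edges are reported but never enter
    C_i or connectivity summaries.
    """

    cancer_type: str
    pathway: str
    proteins: list[str]
    protein_edges: list[ProteinEdge]
    upstream_edges: list[UpstreamEdge]
    out_degree: dict[str, int]

    def edge_pairs(self) -> set[frozenset]:
        return {frozenset((e.src, e.dst)) for e in self.protein_edges}

    # -- serialisation ------------------------------------------------------
    def to_json_dict(self) -> dict:
        nodes = [{"id": p, "type": "protein"} for p in self.proteins]
        seen_cov = set()
        for e in self.upstream_edges:
            if e.covariate not in seen_cov:
                nodes.append({"id": e.covariate, "type": "upstream"})
                seen_cov.add(e.covariate)
        edges = []
        for e in self.protein_edges:
            rec = {"src": e.src, "dst": e.dst, "kind": e.kind, "pip": e.pip}
            if e.pip_reverse is not None:
                rec["pip_reverse"] = e.pip_reverse
            edges.append(rec)
        for e in self.upstream_edges:
            edges.append(
                {"src": e.covariate, "dst": e.target, "kind": "upstream", "pip": e.pip}
            )
        return {
            "cancer_type": self.cancer_type,
            "pathway": self.pathway,
            "nodes": nodes,
            "edges": edges,
            "out_degree": self.out_degree,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "IntegratedNetwork":
        proteins = [n["id"] for n in d["nodes"] if n["type"] == "protein"]
        protein_edges, upstream_edges = [], []
        for e in d["edges"]:
            if e["kind"] == "upstream":
                upstream_edges.append(
                    UpstreamEdge(e["src"], "upstream", e["dst"], float(e["pip"]))
                )
            else:
                protein_edges.append(
                    ProteinEdge(
                        e["src"],
                        e["dst"],
                        e["kind"],
                        float(e["pip"]),
                        e.get("pip_reverse"),
                    )
                )
        return cls(
            cancer_type=d.get("cancer_type", "NA"),
            pathway=d.get("pathway", "NA"),
            proteins=proteins,
            protein_edges=protein_edges,
            upstream_edges=upstream_edges,
            out_degree={k: int(v) for k, v in d.get("out_degree", {}).items()},
        )

    def to_sif(self) -> str:
        lines = []
        for e in self.protein_edges:
            rel = "regulates" if e.kind == "regulatory" else "correlates"
            lines.append(f"{e.src}\t{rel}\t{e.dst}")
        for e in self.upstream_edges:
            lines.append(f"{e.covariate}\tupstream\t{e.target}")
        return "\n".join(lines) + ("\n" if lines else "")


def build_integrated_network(
    fits: dict[str, NodeFit],
    proteins: list[str] | None = None,
    cancer_type: str = "NA",
    pathway: str = "NA",
) -> IntegratedNetwork:
    """Type the MPM selections into regulatory / correlative edges.

    i selected for j but not vice versa: regulatory edge i -> j.  Mutual
    selection: one correlative edge carrying the larger pip (both raw pips
    retained).  Selected upstream covariates become upstream edges.
    """
    if proteins is None:
        proteins = sorted(fits)
    pip_of: dict[tuple[str, str], float] = {}
    selected: set[tuple[str, str]] = set()
    upstream_edges: list[UpstreamEdge] = []
    for target, fit in fits.items():
        for name, kind, pip in zip(fit.candidates, fit.kinds, fit.pips):
            if kind == "protein":
                pip_of[(name, target)] = float(pip)
                if name in fit.mpm:
                    selected.add((name, target))
            elif name in fit.mpm:
                upstream_edges.append(UpstreamEdge(name, kind, target, float(pip)))

    protein_edges: list[ProteinEdge] = []
    out_degree = {p: 0 for p in proteins}
    done_pairs: set[frozenset] = set()
    for i, j in sorted(selected):
        pair = frozenset((i, j))
        if pair in done_pairs:
            continue
        if (j, i) in selected:
            done_pairs.add(pair)
            pij, pji = pip_of[(i, j)], pip_of[(j, i)]
            a, b = sorted((i, j))
            pab = pip_of[(a, b)]
            pba = pip_of[(b, a)]
            protein_edges.append(
                ProteinEdge(a, b, "correlative", max(pab, pba), pip_reverse=pba)
            )
            out_degree[i] += 1
            out_degree[j] += 1
        else:
            protein_edges.append(ProteinEdge(i, j, "regulatory", pip_of[(i, j)]))
            out_degree[i] += 1
    return IntegratedNetwork(
        cancer_type=cancer_type,
        pathway=pathway,
        proteins=list(proteins),
        protein_edges=protein_edges,
        upstream_edges=upstream_edges,
        out_degree=out_degree,
    )


# ---------------------------------------------------------------------------
# Pathway-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class PathwayFit:
    """Everything Step 1 produces for one pathway."""

    network: IntegratedNetwork
    fits: dict[str, NodeFit]
    problems: dict[str, RegressionProblem]


def fit_pathway_network(
    protein: ExpressionMatrix,
    pathway,
    prior: PriorInclusionMatrix,
    config: AnalysisConfig,
    mrna: ExpressionMatrix | None = None,
    methylation: ExpressionMatrix | None = None,
    mirna: ExpressionMatrix | None = None,
    mirna_map: dict[str, list[str]] | None = None,
    rng: np.random.Generator | None = None,
) -> PathwayFit:
    """Run the node-wise regressions for every protein of one pathway."""
    members = [p for p in pathway.proteins if p in protein.data.columns]
    missing = [p for p in pathway.proteins if p not in protein.data.columns]
    if missing:
        logger.warning(
            "pathway %s: dropping members absent from protein data: %s",
            pathway.name,
            missing,
        )
    if not members:
        raise ValueError(f"pathway {pathway.name}: no members in protein matrix")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fits: dict[str, NodeFit] = {}
    problems: dict[str, RegressionProblem] = {}
    for target in members:
        upstream = construct_upstream_covariates(
            mrna, methylation, mirna, pathway.gene_of(target), mirna_map
        )
        problem = RegressionProblem.build(
            protein, target, prior, config, upstream=upstream, candidate_pool=members
        )
        fits[target] = model_posterior(problem, config, rng=rng)
        problems[target] = problem
    network = build_integrated_network(
        fits, proteins=members, cancer_type=protein.cancer_type, pathway=pathway.name
    )
    return PathwayFit(network=network, fits=fits, problems=problems)


def pips_frame(fits: dict[str, NodeFit]) -> pd.DataFrame:
    """Long table of posterior inclusion probabilities across node fits."""
    rows = []
    for target, fit in fits.items():
        for name, kind, pip in zip(fit.candidates, fit.kinds, fit.pips):
            rows.append(
                {
                    "target": target,
                    "candidate": name,
                    "kind": kind,
                    "pip": float(pip),
                    "in_mpm": name in fit.mpm,
                }
            )
    return pd.DataFrame(rows, columns=["target", "candidate", "kind", "pip", "in_mpm"])
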