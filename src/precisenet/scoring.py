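"""Patient-level activation probabilities and pathway activity scores.

Given a fitted node-wise regression, the posterior predictive of protein i
at a patient's own covariate row z* is Student-t with n degrees of freedom,

    location  mu* = (g/(1+g)) z*' beta_hat,
    scale^2   s^2 = (Q/n) (1 + (g/(1+g)) z*' (Z'Z)^-1 z*),

where beta_hat is the OLS fit on the selected columns and Q the shrunken
residual sum of squares entering the marginal likelihood.  The suppressed /
neutral / activated probabilities are the predictive masses below -delta,
inside [-delta, delta], and above delta on the centered protein scale.  An
empty median probability model yields the null-model predictive centered at
zero with the marginal scale of y.

Pathway scores weight each protein's probabilities by its out-degree plus
one, so hub proteins dominate:

    kappa_j(+|-|0) = (1/p) sum_i p_ij(+|-|0) (C_i + 1).

The three kappas always add up to (1/p) sum_i (C_i + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PathwayDefinition
from .network import IntegratedNetwork, NodeFit, PathwayFit, RegressionProblem

logger = logging.getLogger(__name__)

__all__ = [
    "PatientProbabilityTensor",
    "predictive_probabilities",
    "patient_probability_tensor",
    "patient_network",
    "precise_scores",
    "naive_score",
    "native_score",
]

STATUSES = ("suppressed", "neutral", "activated")


def _status_from_triple(p_minus: float, p_zero: float, p_plus: float) -> str:
    """Argmax with exact ties resolved to neutral (conservative)."""
    triple = np.array([p_minus, p_zero, p_plus])
    best = triple.max()
    if (triple == best).sum() > 1:
        return "neutral"
    return STATUSES[int(triple.argmax())]


# ---------------------------------------------------------------------------
# Posterior predictive
# ---------------------------------------------------------------------------


def _predictive_params(
    problem: RegressionProblem, model_idx: list[int], patient: int
) -> tuple[float, float, float]:
    """(location, scale, df) of the Student-t predictive at one patient."""
    n, g = problem.n, problem.g
    shrink = g / (1.0 + g)
    if not model_idx:
        q = problem._yty
        scale = np.sqrt(q / n)
        return 0.0, float(scale), float(n)
    idx = list(model_idx)
    G = problem._G[np.ix_(idx, idx)]
    c = problem._c[idx]
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
    beta_hat = Ginv @ c
    r2 = float(np.clip(c @ beta_hat / problem._yty, 0.0, 1.0 - 1e-12))
    q = problem._yty * (1.0 + g * (1.0 - r2)) / (1.0 + g)
    z = problem.Z[patient, idx]
    loc = shrink * float(z @ beta_hat)
    scale2 = (q / n) * (1.0 + shrink * float(z @ Ginv @ z))
    return loc, float(np.sqrt(max(scale2, 1e-300))), float(n)


def _triple_from_t(loc: float, scale: float, df: float, delta: float):
    p_plus = float(stats.t.sf((delta - loc) / scale, df))
    p_minus = float(stats.t.cdf((-delta - loc) / scale, df))
    p_zero = max(1.0 - p_plus - p_minus, 0.0)
    total = p_minus + p_zero + p_plus
    return p_minus / total, p_zero / total, p_plus / total


def predictive_probabilities(
    fit: NodeFit,
    problem: RegressionProblem,
    patient: int,
    delta: float = 0.5,
    model_averaging: bool = False,
) -> tuple[float, float, float]:
    """(p-, p0, p+) for one protein and patient.

    By default the predictive conditions on the median probability model;
    with ``model_averaging`` (enumeration fits only) the triple is the
    posterior-weighted average over all models.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if model_averaging and fit.model_masks is not None:
        k = len(fit.candidates)
        triple = np.zeros(3)
        for mask, prob in zip(fit.model_masks, fit.model_probs):
            if prob < 1e-12:
                continue
            idx = [c for c in range(k) if int(mask) >> c & 1]
            loc, scale, df = _predictive_params(problem, idx, patient)
            triple += prob * np.array(_triple_from_t(loc, scale, df, delta))
        triple /= triple.sum()
        return float(triple[0]), float(triple[1]), float(triple[2])
    loc, scale, df = _predictive_params(problem, fit.mpm_indices, patient)
    return _triple_from_t(loc, scale, df, delta)


# ---------------------------------------------------------------------------
# Tensor across patients and proteins
# ---------------------------------------------------------------------------


@dataclass
class PatientProbabilityTensor:
    """Per (patient, protein) triple of status probabilities plus the call."""

    sample_ids: list[str]
    proteins: list[str]
    probs: np.ndarray  # n x p x 3, order (p-, p0, p+)
    status: np.ndarray  # n x p of {suppressed, neutral, activated}
    delta: float

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("probability triples must sum to 1")

    def triple(self, sample: str, protein: str) -> tuple[float, float, float]:
        i = self.sample_ids.index(sample)
        j = self.proteins.index(protein)
        return tuple(float(x) for x in self.probs[i, j])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sample_ids):
            for j, p in enumerate(self.proteins):
                rows.append(
                    {
                        "sample": s,
                        "protein": p,
                        "p_minus": self.probs[i, j, 0],
                        "p_zero": self.probs[i, j, 1],
                        "p_plus": self.probs[i, j, 2],
                        "status": self.status[i, j],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, delta: float = 0.5):
        samples = list(dict.fromkeys(df["sample"]))
        proteins = list(dict.fromkeys(df["protein"]))
        probs = np.zeros((len(samples), len(proteins), 3))
        status = np.full((len(samples), len(proteins)), "neutral", dtype=object)
        si = {s: i for i, s in enumerate(samples)}
        pi = {p: j for j, p in enumerate(proteins)}
        for _, row in df.iterrows():
            i, j = si[row["sample"]], pi[row["protein"]]
            probs[i, j] = (row["p_minus"], row["p_zero"], row["p_plus"])
            status[i, j] = row["status"]
        return cls(samples, proteins, probs, status, delta)


def patient_probability_tensor(
    pathway_fit: PathwayFit, delta: float = 0.5, model_averaging: bool = False
) -> PatientProbabilityTensor:
    """Evaluate the predictive triples for every patient and pathway protein."""
    proteins = list(pathway_fit.fits)
    any_problem = next(iter(pathway_fit.problems.values()))
    samples = any_problem.sample_ids
    n = len(samples)
    probs = np.zeros((n, len(proteins), 3))
    status = np.empty((n, len(proteins)), dtype=object)
    for j, prot in enumerate(proteins):
        fit = pathway_fit.fits[prot]
        problem = pathway_fit.problems[prot]
        for i in range(n):
            triple = predictive_probabilities(
                fit, problem, i, delta=delta, model_averaging=model_averaging
            )
            probs[i, j] = triple
            status[i, j] = _status_from_triple(*triple)
    return PatientProbabilityTensor(
        sample_ids=list(samples),
        proteins=proteins,
        probs=probs,
        status=status,
        delta=delta,
    )


def patient_network(
    network: IntegratedNetwork, tensor: PatientProbabilityTensor, patient: str
) -> dict:
    """Shared cancer-specific topology with this patient's node labels."""
    missing = [p for p in network.proteins if p not in tensor.proteins]
    if missing:
        raise ValueError(f"tensor missing protein(s): {missing}")
    i = tensor.sample_ids.index(patient)
    labels = {
        p: str(tensor.status[i, tensor.proteins.index(p)]) for p in network.proteins
    }
    d = network.to_json_dict()
    for node in d["nodes"]:
        if node["type"] == "protein":
            node["status"] = labels[node["id"]]
    d["patient"] = patient
    return d


# ---------------------------------------------------------------------------
# Pathway scores
# ---------------------------------------------------------------------------


def precise_scores(
    tensor: PatientProbabilityTensor,
    network: IntegratedNetwork,
    pathway: PathwayDefinition,
) -> pd.DataFrame:
    """Out-degree-weighted pathway activity scores per patient.

    Returns a frame indexed by sample with columns kappa_plus, kappa_minus,
    kappa_zero, combined (= kappa_plus + kappa_minus) and status (argmax of
    the three kappas, ties resolved to neutral).
    """
    members = [p for p in pathway.proteins if p in tensor.proteins]
    dropped = [p for p in pathway.proteins if p not in tensor.proteins]
    if dropped:
        logger.warning(
            "pathway %s: dropping members without probabilities: %s",
            pathway.name,
            dropped,
        )
    if not members:
        raise ValueError(f"pathway {pathway.name}: no scored members")
    p = len(members)
    weights = np.array(
        [network.out_degree.get(prot, 0) + 1 for prot in members], dtype=float
    )
    cols = [tensor.proteins.index(prot) for prot in members]
    sub = tensor.probs[:, cols, :]  # n x p x 3
    kappa = (sub * weights[None, :, None]).sum(axis=1) / p  # n x 3 (minus, zero, plus)
    status = [
        _status_from_triple(kappa[i, 0], kappa[i, 1], kappa[i, 2])
        for i in range(kappa.shape[0])
    ]
    return pd.DataFrame(
        {
            "kappa_plus": kappa[:, 2],
            "kappa_minus": kappa[:, 0],
            "kappa_zero": kappa[:, 1],
            "combined": kappa[:, 2] + kappa[:, 0],
            "status": status,
        },
        index=pd.Index(tensor.sample_ids, name="sample"),
    )


def naive_score(
    protein_data: ExpressionMatrix, pathway: PathwayDefinition
) -> pd.Series:
    """Per-patient cumulative sum of the pathway's protein expression."""
    members = [p for p in pathway.proteins if p in protein_data.data.columns]
    missing = [p for p in pathway.proteins if p not in protein_data.data.columns]
    if missing:
        logger.warning("pathway %s: naive score drops %s", pathway.name, missing)
    if not members:
        raise ValueError(f"pathway {pathway.name}: no members in protein data")
    return protein_data.data[members].sum(axis=1).rename(pathway.name)


def native_score(
    protein_data: ExpressionMatrix, pathway: PathwayDefinition
) -> pd.Series:
    """Signed sum: positive regulatory members minus negative ones."""
    members = [p for p in pathway.proteins if p in protein_data.data.columns]
    missing = [p for p in pathway.proteins if p not in protein_data.data.columns]
    if missing:
        logger.warning("pathway %s: native score drops %s", pathway.name, missing)
    if not members:
        raise ValueError(f"pathway {pathway.name}: no members in protein data")
    signs = np.array([pathway.sign_of(p) for p in members], dtype=float)
    return (
        (protein_data.data[members] * signs).sum(axis=1).rename(pathway.name)
    )
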