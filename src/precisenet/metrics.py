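"""Cross-lineage network summaries.

Connectivity score (CS): fraction of realized unordered protein pairs in a
pathway network, with a permutation p-value obtained by independently
permuting each protein column's sample order (destroying inter-protein
dependence, preserving marginals), refitting the network with the same
prior, and applying add-one smoothing.  Diversity: sample SD of a pathway's
CS across lineages.  Edge consistency (EC): number of lineages whose
network holds a given protein pair, split into known (PPI score > 0.5) and
new findings.  Concordance: the predictive probability mass a patient's
tensor assigns to the delta-category of the observed protein value.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .io import AnalysisConfig, ExpressionMatrix, PPITable
from .network import IntegratedNetwork, fit_pathway_network
from .scoring import PatientProbabilityTensor

logger = logging.getLogger(__name__)

__all__ = [
    "connectivity_score",
    "connectivity_pvalue",
    "diversity_score",
    "edge_consistency",
    "concordance_score",
]


def connectivity_score(network: IntegratedNetwork) -> tuple[float, int, int]:
    """(CS, n_edges, n_possible): realized fraction of unordered pairs.

    Regulatory and correlative edges each count a pair once; direction is
    ignored, so CS is always in [0, 1].
    """
    p = len(network.proteins)
    if p < 2:
        raise ValueError("connectivity needs at least 2 proteins")
    n_possible = p * (p - 1) // 2
    n_edges = len(network.edge_pairs())
    return n_edges / n_possible, n_edges, n_possible


def connectivity_pvalue(
    protein: ExpressionMatrix,
    pathway,
    prior,
    config: AnalysisConfig,
    reps: int | None = None,
    rng: np.random.Generator | None = None,
    observed: IntegratedNetwork | None = None,
    **fit_kwargs,
) -> tuple[float, float]:
    """Permutation p-value of the observed connectivity score.

    Returns ``(cs_observed, p_cs)`` with p = (1 + #{null CS >= observed}) /
    (reps + 1).  Each null replicate permutes every protein column
    independently and reruns the full network fit with the same prior and
    configuration.
    """
    reps = int(config.permutation_reps if reps is None else reps)
    if reps < 20:
        raise ValueError("permutation_reps must be >= 20")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if observed is None:
        observed = fit_pathway_network(
            protein, pathway, prior, config, rng=rng, **fit_kwargs
        ).network
    cs_obs, _, _ = connectivity_score(observed)
    n = protein.n
    exceed = 0
    values = protein.values
    for _ in range(reps):
        permuted = np.column_stack(
            [values[rng.permutation(n), j] for j in range(values.shape[1])]
        )
        null_em = replace(
            protein,
            data=pd.DataFrame(
                permuted, index=protein.data.index, columns=protein.data.columns
            ),
        )
        null_net = fit_pathway_network(
            null_em, pathway, prior, config, rng=rng, **fit_kwargs
        ).network
        cs_null, _, _ = connectivity_score(null_net)
        if cs_null >= cs_obs:
            exceed += 1
    p_cs = (1.0 + exceed) / (reps + 1.0)
    return cs_obs, p_cs


def diversity_score(cs_values) -> float:
    """Sample standard deviation of a pathway's CS across lineages."""
    vals = np.asarray(list(cs_values), dtype=float)
    if vals.size < 2:
        raise ValueError("diversity needs CS values from at least 2 lineages")
    return float(np.std(vals, ddof=1))


def connectivity_report(
    networks: dict[str, dict[str, IntegratedNetwork]]
) -> pd.DataFrame:
    """CS per (lineage, pathway) plus per-pathway diversity.

    ``networks[lineage][pathway]`` holds the fitted networks.
    """
    rows = []
    for lineage, by_pathway in networks.items():
        for pathway, net in by_pathway.items():
            cs, n_edges, n_possible = connectivity_score(net)
            rows.append(
                {
                    "lineage": lineage,
                    "pathway": pathway,
                    "cs": cs,
                    "n_edges": n_edges,
                    "n_possible": n_possible,
                }
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        div = (
            frame.groupby("pathway")["cs"]
            .apply(lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
            .rename("diversity")
        )
        frame = frame.merge(div, on="pathway", how="left")
    return frame


def edge_consistency(
    networks: dict[str, IntegratedNetwork], ppi: PPITable | None = None
) -> pd.DataFrame:
    """Per protein pair: lineages holding the edge plus direction counts.

    A pair absent from every lineage is omitted.  ``n_forward`` counts
    lineages with a regulatory edge a -> b (a < b lexicographically),
    ``n_reverse`` the opposite direction, ``n_correlative`` undirected
    occurrences.  ``known`` flags PPI score > 0.5 when a table is given.
    """
    records: dict[tuple[str, str], dict] = {}
    for lineage, net in networks.items():
        for edge in net.protein_edges:
            a, b = sorted((edge.src, edge.dst))
            rec = records.setdefault(
                (a, b),
                {"ec": 0, "n_forward": 0, "n_reverse": 0, "n_correlative": 0},
            )
            rec["ec"] += 1
            if edge.kind == "correlative":
                rec["n_correlative"] += 1
            elif (edge.src, edge.dst) == (a, b):
                rec["n_forward"] += 1
            else:
                rec["n_reverse"] += 1
    rows = []
    for (a, b), rec in sorted(records.items()):
        row = {"protein_a": a, "protein_b": b, **rec}
        if ppi is not None:
            row["ppi_score"] = ppi.score(a, b)
            row["known"] = ppi.score(a, b) > 0.5
        rows.append(row)
    return pd.DataFrame(rows)


def concordance_score(
    tensor: PatientProbabilityTensor,
    observed: ExpressionMatrix,
    delta: float | None = None,
    center: bool = True,
) -> pd.DataFrame:
    """Predictive mass on the observed delta-category, per sample x protein.

    The observed value (centered by the cohort mean by default, matching
    the centered scale of the predictive) is categorised by the same delta
    rule; concordance is the probability the tensor assigned to that
    category.  Values lie in [0, 1]; high means the prediction agrees with
    the observation.
    """
    if delta is None:
        delta = tensor.delta
    missing_p = [p for p in tensor.proteins if p not in observed.data.columns]
    if missing_p:
        raise ValueError(f"observed matrix missing protein(s): {missing_p}")
    missing_s = [s for s in tensor.sample_ids if s not in observed.data.index]
    if missing_s:
        raise ValueError(f"observed matrix missing sample(s): {missing_s[:5]}")
    obs = observed.data.loc[tensor.sample_ids, tensor.proteins].to_numpy(dtype=float)
    if center:
        obs = obs - obs.mean(axis=0, keepdims=True)
    category = np.where(obs > delta, 2, np.where(obs < -delta, 0, 1))
    n, p = obs.shape
    conc = np.take_along_axis(tensor.probs, category[:, :, None], axis=2)[:, :, 0]
    return pd.DataFrame(
        conc, index=pd.Index(tensor.sample_ids, name="sample"), columns=tensor.proteins
    )


def mean_concordance(conc: pd.DataFrame, labels: pd.Series | None = None):
    """Per-sample mean concordance; per-lineage means when labels given."""
    per_sample = conc.mean(axis=1).rename("concordance")
    if labels is None:
        return per_sample
    aligned = labels.loc[per_sample.index]
    return per_sample.groupby(aligned).mean().rename("concordance")
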