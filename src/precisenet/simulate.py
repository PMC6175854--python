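"""Synthetic multi-platform cohorts with known ground truth.

The generator emulates the data model assumed by the node-wise regression:
proteins follow linear-Gaussian structural equations on a sparse DAG; each
protein's gene contributes an mRNA signal split into a methylation-modulated
part and a methylation-independent part; miRNAs are annotated to genes;
several lineages can carry rewired versions of the same network; and patient
subgroups can carry mean shifts of a pathway's activity.

Subgroup shifts are applied after the structural equations have been
evaluated: the shift is added to the pathway's protein columns and to the
corresponding genes' mRNA columns, so the activation is visible on both
platforms but does not cascade through the protein wiring.  The recorded
truth status of a protein is therefore the categorisation of its shift
against the neutral half-width delta.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PathwayDefinition, write_expression_matrix

__all__ = [
    "SimulationSpec",
    "SimulatedCohort",
    "simulate_truth_network",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Stated world for one simulated cohort.

    Attributes
    ----------
    n_samples : int
        Patients in the cohort (shared across platforms).
    pathway_sizes : tuple of int
        Number of proteins per simulated pathway.
    edge_density : float
        Probability of each forward edge in the protein DAG.
    coefficient_range : (float, float)
        Magnitude bounds for structural coefficients; the sign is random.
        Magnitudes are bounded away from zero so structure recovery is
        feasible at moderate sample sizes.
    noise_sd : float
        SD of each protein's structural noise term.
    n_lineages : int
        Number of lineages; each lineage beyond the first carries a rewired
        copy of the base DAG.
    rewire_fraction : float
        Fraction of edges removed and re-added (at random, respecting the
        fixed topological order) per non-base lineage.
    n_mirna_per_gene : int
        miRNAs annotated to each gene.
    methylation_effect : float
        Linear effect of a gene's methylation on its mRNA.
    mrna_loading, mirna_loading : float
        Loadings of a protein's own-gene mRNA and miRNAs in its structural
        equation.
    subgroup_shifts : tuple of (int, float)
        Each entry designates a pathway index and a mean shift.  Patients
        are split into a control subgroup plus one subgroup per entry, with
        the control taking two shares and each shifted subgroup one (an
        activated molecular subtype is a minority of a cohort, and a
        majority shift would be absorbed by cohort centering).
    status_delta : float
        Neutral half-width used to record truth status (kept equal to the
        analysis delta so simulator and scorer are commensurable).
    seed : int
    """

    n_samples: int = 300
    pathway_sizes: tuple[int, ...] = (12,)
    edge_density: float = 0.15
    coefficient_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.3
    n_lineages: int = 1
    rewire_fraction: float = 0.0
    n_mirna_per_gene: int = 1
    methylation_effect: float = 0.7
    mrna_loading: float = 0.5
    mirna_loading: float = 0.3
    subgroup_shifts: tuple[tuple[int, float], ...] = ()
    status_delta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_lineages < 1 or self.n_mirna_per_gene < 0:
            raise ValueError("counts must be >= 1 (n_mirna_per_gene >= 0)")
        if not all(int(p) >= 1 for p in self.pathway_sizes):
            raise ValueError("pathway sizes must be >= 1")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in [0,1]")
        if not (0.0 <= self.rewire_fraction <= 1.0):
            raise ValueError("rewire_fraction must lie in [0,1]")
        lo, hi = self.coefficient_range
        if not (0.0 < lo <= hi):
            raise ValueError("coefficient_range must satisfy 0 < low <= high")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for pw, _ in self.subgroup_shifts:
            if not (0 <= int(pw) < len(self.pathway_sizes)):
                raise ValueError(f"subgroup shift refers to unknown pathway {pw}")


@dataclass
class SimulatedCohort:
    """Simulated matrices plus everything tests need to score recovery."""

    spec: SimulationSpec
    matrices: dict[str, ExpressionMatrix]
    truth_dags: dict[int, list[tuple[str, str, float]]]  # lineage -> edges
    truth_status: pd.DataFrame  # samples x proteins, in {suppressed,neutral,activated}
    labels: pd.DataFrame  # sample, lineage, subgroup
    pathways: list[PathwayDefinition]
    protein_gene: dict[str, str]
    mirna_map: dict[str, list[str]]

    @property
    def sample_ids(self) -> list[str]:
        return self.matrices["protein"].sample_ids


def _protein_names(pathway: int, size: int) -> list[str]:
    return [f"PW{pathway}_P{i:02d}" for i in range(size)]


def simulate_truth_network(
    spec: SimulationSpec, pathway: int
) -> list[tuple[str, str, float]]:
    """Erdos-Renyi-style weighted DAG over one pathway's proteins.

    Edges run only forward in the fixed index (topological) order; the
    coefficient magnitude is uniform on ``coefficient_range`` with a random
    sign.  Deterministic for a given spec seed and pathway index.
    """
    size = int(spec.pathway_sizes[pathway])
    names = _protein_names(pathway, size)
    rng = np.random.default_rng([int(spec.seed), 7, pathway])
    lo, hi = spec.coefficient_range
    edges: list[tuple[str, str, float]] = []
    for i in range(size):
        for j in range(i + 1, size):
            if rng.random() < spec.edge_density:
                coef = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
                edges.append((names[i], names[j], float(coef)))
    if spec.edge_density > 0 and spec.edge_density * size * (size - 1) / 2 < 1:
        warnings.warn("expected edge count below 1; network likely empty")
    return edges


def _rewire(
    edges: list[tuple[str, str, float]],
    names: list[str],
    fraction: float,
    rng: np.random.Generator,
    coefficient_range: tuple[float, float],
) -> list[tuple[str, str, float]]:
    """Remove and add the stated fraction of edges, preserving acyclicity."""
    if fraction == 0.0 or not edges:
        return list(edges)
    order = {name: k for k, name in enumerate(names)}
    n_change = int(round(fraction * len(edges)))
    keep_idx = set(range(len(edges)))
    drop = rng.choice(len(edges), size=min(n_change, len(edges)), replace=False)
    keep_idx -= set(int(d) for d in drop)
    kept = [edges[k] for k in sorted(keep_idx)]
    present = {(a, b) for a, b, _ in kept}
    absent = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if (names[i], names[j]) not in present
    ]
    lo, hi = coefficient_range
    add_n = min(n_change, len(absent))
    if add_n:
        picks = rng.choice(len(absent), size=add_n, replace=False)
        for k in picks:
            a, b = absent[int(k)]
            assert order[a] < order[b]
            coef = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
            kept.append((a, b, float(coef)))
    return kept


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate all four platform matrices plus ground truth.

    Proteins follow the structural equations over the (lineage-specific)
    truth DAG, receiving their own gene's mRNA and miRNA signals as stated
    loadings.  See the module docstring for how subgroup shifts enter.
    """
    rng = np.random.default_rng([int(spec.seed), 11])
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    lineage = np.array([i * spec.n_lineages // n for i in range(n)], dtype=int)
    # control takes two shares, each shifted subgroup one share
    pattern = [0, 0] + list(range(1, len(spec.subgroup_shifts) + 1))
    subgroup = np.array([pattern[i % len(pattern)] for i in range(n)], dtype=int)

    protein_cols: list[str] = []
    gene_cols: list[str] = []
    protein_gene: dict[str, str] = {}
    mirna_map: dict[str, list[str]] = {}
    pathways: list[PathwayDefinition] = []
    for pw, size in enumerate(spec.pathway_sizes):
        names = _protein_names(pw, int(size))
        genes = [f"PW{pw}_G{i:02d}" for i in range(int(size))]
        members = []
        for prot, gene in zip(names, genes):
            protein_gene[prot] = gene
            mirna_map[gene] = [
                f"{gene}_MIR{r}" for r in range(spec.n_mirna_per_gene)
            ]
            members.append((prot, gene, 1))
        pathways.append(PathwayDefinition(name=f"pathway_{pw}", members=members))
        protein_cols.extend(names)
        gene_cols.extend(genes)

    mirna_cols = [m for gene in gene_cols for m in mirna_map[gene]]

    # upstream platforms (global across lineages)
    methyl = rng.standard_normal((n, len(gene_cols)))
    mrna = spec.methylation_effect * methyl + rng.standard_normal((n, len(gene_cols)))
    mirna = (
        rng.standard_normal((n, len(mirna_cols)))
        if mirna_cols
        else np.zeros((n, 0))
    )
    gene_idx = {g: k for k, g in enumerate(gene_cols)}
    mirna_idx = {m: k for k, m in enumerate(mirna_cols)}

    # per-lineage truth DAGs
    truth_dags: dict[int, list[tuple[str, str, float]]] = {}
    for lin in range(spec.n_lineages):
        edges: list[tuple[str, str, float]] = []
        for pw in range(len(spec.pathway_sizes)):
            base = simulate_truth_network(spec, pw)
            if lin == 0:
                edges.extend(base)
            else:
                rr = np.random.default_rng([int(spec.seed), 13, lin, pw])
                edges.extend(
                    _rewire(
                        base,
                        _protein_names(pw, int(spec.pathway_sizes[pw])),
                        spec.rewire_fraction,
                        rr,
                        spec.coefficient_range,
                    )
                )
        truth_dags[lin] = edges

    # proteins via SEM, lineage by lineage, in topological (index) order
    prot_idx = {p: k for k, p in enumerate(protein_cols)}
    protein = np.zeros((n, len(protein_cols)))
    for lin in range(spec.n_lineages):
        rows = np.where(lineage == lin)[0]
        if rows.size == 0:
            continue
        parents: dict[str, list[tuple[str, float]]] = {p: [] for p in protein_cols}
        for a, b, coef in truth_dags[lin]:
            parents[b].append((a, coef))
        noise = np.random.default_rng([int(spec.seed), 17, lin]).standard_normal(
            (rows.size, len(protein_cols))
        )
        for p in protein_cols:  # index order is topological
            k = prot_idx[p]
            gene = protein_gene[p]
            y = spec.mrna_loading * mrna[rows, gene_idx[gene]].copy()
            for m in mirna_map[gene]:
                y = y + spec.mirna_loading * mirna[rows, mirna_idx[m]]
            for a, coef in parents[p]:
                y = y + coef * protein[rows, prot_idx[a]]
            y = y + spec.noise_sd * noise[:, k]
            protein[rows, k] = y

    # subgroup shifts: post-hoc mean shifts on protein and mRNA columns
    shift_per_sample_protein = np.zeros((n, len(protein_cols)))
    for q, (pw, shift) in enumerate(spec.subgroup_shifts, start=1):
        members = set(_protein_names(pw, int(spec.pathway_sizes[pw])))
        in_group = subgroup == q
        for p in protein_cols:
            if p in members:
                protein[in_group, prot_idx[p]] += shift
                shift_per_sample_protein[in_group, prot_idx[p]] += shift
                mrna[in_group, gene_idx[protein_gene[p]]] += shift

    delta = spec.status_delta
    status = np.where(
        shift_per_sample_protein > delta,
        "activated",
        np.where(shift_per_sample_protein < -delta, "suppressed", "neutral"),
    )

    def _em(platform: str, cols: list[str], values: np.ndarray) -> ExpressionMatrix:
        frame = pd.DataFrame(values, index=pd.Index(samples, name="sample"), columns=cols)
        return ExpressionMatrix(platform=platform, data=frame, cancer_type="SIM")

    matrices = {
        "protein": _em("protein", protein_cols, protein),
        "mrna": _em("mrna", gene_cols, mrna),
        "methylation": _em("methylation", gene_cols, methyl),
    }
    if mirna_cols:
        matrices["mirna"] = _em("mirna", mirna_cols, mirna)

    return SimulatedCohort(
        spec=spec,
        matrices=matrices,
        truth_dags=truth_dags,
        truth_status=pd.DataFrame(status, index=samples, columns=protein_cols),
        labels=pd.DataFrame(
            {"sample": samples, "lineage": lineage, "subgroup": subgroup}
        ),
        pathways=pathways,
        protein_gene=protein_gene,
        mirna_map=mirna_map,
    )


def sem_implied_covariance(
    edges: Sequence[tuple[str, str, float]],
    proteins: Sequence[str],
    spec: SimulationSpec,
) -> pd.DataFrame:
    """Closed-form protein covariance implied by the structural equations.

    Solves Sigma = (I - B)^-T Psi (I - B)^-1 where B holds the DAG
    coefficients and Psi the exogenous variances (structural noise plus the
    upstream mRNA/miRNA contributions, which are independent across genes).
    """
    p = len(proteins)
    idx = {name: k for k, name in enumerate(proteins)}
    B = np.zeros((p, p))
    for a, b, coef in edges:
        B[idx[a], idx[b]] = coef
    var_mrna = spec.methylation_effect**2 + 1.0
    exo = (
        spec.noise_sd**2
        + spec.mrna_loading**2 * var_mrna
        + spec.n_mirna_per_gene * spec.mirna_loading**2
    )
    psi = np.eye(p) * exo
    inv = np.linalg.inv(np.eye(p) - B)
    sigma = inv.T @ psi @ inv
    return pd.DataFrame(sigma, index=list(proteins), columns=list(proteins))


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the platform TSVs plus a truth JSON (consumed only by tests)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for platform, em in cohort.matrices.items():
        write_expression_matrix(em, outdir / f"{platform}.tsv")
    truth = {
        "dags": {
            str(lin): [[a, b, coef] for a, b, coef in edges]
            for lin, edges in cohort.truth_dags.items()
        },
        "status": {
            s: cohort.truth_status.loc[s].tolist() for s in cohort.truth_status.index
        },
        "proteins": list(cohort.truth_status.columns),
        "labels": cohort.labels.to_dict(orient="list"),
        "protein_gene": cohort.protein_gene,
        "mirna_map": cohort.mirna_map,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
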