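"""Model/Results facade over the full pipeline.

:class:`PreciseModel` bundles the multi-platform matrices, pathway
definitions and prior information; :meth:`PreciseModel.fit` runs prior
calibration (unless a prior matrix is supplied), the node-wise Bayesian
regressions, the patient-level predictive probabilities and the pathway
scores, returning a :class:`PreciseResults` that carries the estimated
networks, probability tensors, score tables and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterResult, build_score_matrix, cluster_patients
from .io import AnalysisConfig, ExpressionMatrix, PathwayDefinition, PPITable
from .metrics import concordance_score, connectivity_score, mean_concordance
from .network import PathwayFit, fit_pathway_network, pips_frame
from .prior import PriorInclusionMatrix, combine_prior, stability_weights
from .scoring import PatientProbabilityTensor, patient_probability_tensor, precise_scores
from .simulate import SimulatedCohort

logger = logging.getLogger(__name__)

__all__ = ["PreciseModel", "PreciseResults"]


class PreciseModel:
    """Integrative network model for one cancer type.

    Parameters
    ----------
    protein : ExpressionMatrix
        RPPA-style protein matrix (samples x proteins); the response
        platform.
    pathways : list of PathwayDefinition
        Pathways to model; each is fitted independently.
    ppi : PPITable, optional
        Interaction confidences entering the prior average.
    prior : PriorInclusionMatrix, optional
        Precomputed prior inclusion matrix; when omitted it is calibrated
        per pathway from PC-algorithm stability weights and the PPI table.
    mrna, methylation, mirna : ExpressionMatrix, optional
        Upstream platforms (matched samples).
    mirna_map : dict, optional
        gene -> list of miRNA feature ids.
    config : AnalysisConfig, optional
    """

    def __init__(
        self,
        protein: ExpressionMatrix,
        pathways: list[PathwayDefinition],
        ppi: PPITable | None = None,
        prior: PriorInclusionMatrix | None = None,
        mrna: ExpressionMatrix | None = None,
        methylation: ExpressionMatrix | None = None,
        mirna: ExpressionMatrix | None = None,
        mirna_map: dict[str, list[str]] | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.protein = protein
        self.pathways = list(pathways)
        self.ppi = ppi if ppi is not None else PPITable()
        self.prior = prior
        self.mrna = mrna
        self.methylation = methylation
        self.mirna = mirna
        self.mirna_map = mirna_map or {}
        self.config = config if config is not None else AnalysisConfig()

    @classmethod
    def from_cohort(
        cls,
        cohort: SimulatedCohort,
        config: AnalysisConfig | None = None,
        ppi: PPITable | None = None,
        prior: PriorInclusionMatrix | None = None,
        lineage: int | None = None,
    ) -> "PreciseModel":
        """Build the model straight from a simulated cohort."""
        matrices = dict(cohort.matrices)
        if lineage is not None:
            keep = cohort.labels.loc[cohort.labels["lineage"] == lineage, "sample"]
            matrices = {
                k: ExpressionMatrix(v.platform, v.data.loc[keep], v.cancer_type)
                for k, v in matrices.items()
            }
        return cls(
            protein=matrices["protein"],
            pathways=cohort.pathways,
            ppi=ppi,
            prior=prior,
            mrna=matrices.get("mrna"),
            methylation=matrices.get("methylation"),
            mirna=matrices.get("mirna"),
            mirna_map=cohort.mirna_map,
            config=config,
        )

    # ------------------------------------------------------------------
    def calibrate_prior(self, pathway: PathwayDefinition) -> PriorInclusionMatrix:
        """Stability-selection causal weights averaged with PPI scores."""
        members = [p for p in pathway.proteins if p in self.protein.data.columns]
        sub = self.protein.restrict(members)
        causal = stability_weights(
            sub, self.config, rng=np.random.default_rng(self.config.seed)
        )
        return combine_prior(causal, self.ppi)

    def fit(self, model_averaging: bool = False) -> "PreciseResults":
        """Run Steps 1-3 for every pathway."""
        cfg = self.config
        networks: dict[str, object] = {}
        pathway_fits: dict[str, PathwayFit] = {}
        tensors: dict[str, PatientProbabilityTensor] = {}
        scores: dict[str, pd.DataFrame] = {}
        priors: dict[str, PriorInclusionMatrix] = {}
        for pathway in self.pathways:
            prior = self.prior if self.prior is not None else self.calibrate_prior(pathway)
            priors[pathway.name] = prior
            pf = fit_pathway_network(
                self.protein,
                pathway,
                prior,
                cfg,
                mrna=self.mrna,
                methylation=self.methylation,
                mirna=self.mirna,
                mirna_map=self.mirna_map,
                rng=np.random.default_rng(cfg.seed),
            )
            tensor = patient_probability_tensor(
                pf, delta=cfg.delta, model_averaging=model_averaging
            )
            pathway_fits[pathway.name] = pf
            networks[pathway.name] = pf.network
            tensors[pathway.name] = tensor
            scores[pathway.name] = precise_scores(tensor, pf.network, pathway)
        return PreciseResults(
            model=self,
            networks=networks,
            pathway_fits=pathway_fits,
            tensors=tensors,
            scores=scores,
            priors=priors,
        )


@dataclass
class PreciseResults:
    """Fitted networks, patient probabilities and pathway scores."""

    model: PreciseModel
    networks: dict
    pathway_fits: dict[str, PathwayFit]
    tensors: dict[str, PatientProbabilityTensor]
    scores: dict[str, pd.DataFrame]
    priors: dict[str, PriorInclusionMatrix]
    _score_matrix: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def score_matrix(self) -> pd.DataFrame:
        if self._score_matrix is None:
            self._score_matrix = build_score_matrix(self.scores)
        return self._score_matrix

    def pips(self, pathway: str) -> pd.DataFrame:
        return pips_frame(self.pathway_fits[pathway].fits)

    def cluster(self, k_max: int, rng: np.random.Generator | None = None) -> ClusterResult:
        """Ward + gap-statistic stratification on the combined score matrix."""
        return cluster_patients(self.score_matrix, k_max, self.model.config, rng=rng)

    def concordance(self, pathway: str) -> pd.Series:
        conc = concordance_score(self.tensors[pathway], self.model.protein)
        return mean_concordance(conc)

    def summary(self) -> str:
        """Human-readable per-pathway fit summary."""
        lines = [
            "Integrated network estimation results",
            f"  cancer type: {self.model.protein.cancer_type}"
            f"   patients: {self.model.protein.n}",
            "",
            f"{'pathway':<20}{'p':>4}{'reg':>5}{'corr':>6}{'upstr':>7}{'CS':>8}"
            f"{'mean k+':>9}{'mean k-':>9}",
        ]
        for name, net in self.networks.items():
            reg = sum(1 for e in net.protein_edges if e.kind == "regulatory")
            corr = sum(1 for e in net.protein_edges if e.kind == "correlative")
            cs = connectivity_score(net)[0] if len(net.proteins) > 1 else float("nan")
            sc = self.scores[name]
            lines.append(
                f"{name:<20}{len(net.proteins):>4}{reg:>5}{corr:>6}"
                f"{len(net.upstream_edges):>7}{cs:>8.3f}"
                f"{sc['kappa_plus'].mean():>9.3f}{sc['kappa_minus'].mean():>9.3f}"
            )
        return "\n".join(lines)
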