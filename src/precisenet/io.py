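"""Readers, writers and configuration for the pipeline's external formats.

All tabular formats are plain TSV.  Expression matrices are stored with
samples in rows and features in columns (one fixed orientation everywhere in
the package).  Pathway membership uses standard GMT with an optional sidecar
TSV carrying protein->gene mapping and regulatory signs.  Protein-protein
interaction confidence uses a three-column edge list with scores in [0, 1]
(raw STRING combined scores in 0-1000 are rescaled on request).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PLATFORMS = ("protein", "mrna", "mirna", "methylation")


class FormatError(ValueError):
    """Raised when an external file violates the format contract."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """One platform's samples x features matrix for one cancer type.

    Parameters
    ----------
    platform : str
        One of ``protein``, ``mrna``, ``mirna``, ``methylation``.
    data : pandas.DataFrame
        Samples in rows, features in columns, finite floats.
    cancer_type : str
        TCGA-style lineage code (free-form; ``NA`` when unknown).
    """

    platform: str
    data: pd.DataFrame
    cancer_type: str = "NA"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise FormatError(f"unknown platform {self.platform!r}")
        dup_s = self.data.index[self.data.index.duplicated()].tolist()
        if dup_s:
            raise FormatError(f"duplicate sample id(s): {sorted(set(dup_s))}")
        dup_f = self.data.columns[self.data.columns.duplicated()].tolist()
        if dup_f:
            raise FormatError(f"duplicate feature id(s): {sorted(set(dup_f))}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("empty expression matrix")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if not np.isfinite(values).all():
            raise FormatError("non-finite values in expression matrix")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    def restrict(self, features: Sequence[str]) -> "ExpressionMatrix":
        """Sub-matrix keeping the given features (order preserved)."""
        keep = [f for f in features if f in self.data.columns]
        return replace(self, data=self.data.loc[:, keep])


def read_expression_matrix(
    path: str | Path, platform: str, cancer_type: str = "NA"
) -> ExpressionMatrix:
    """Read a samples x features TSV (first column sample ids, header features).

    Features containing any missing value are dropped with a warning; the
    remaining matrix must be fully finite numeric.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    feat = header.rstrip("\n").split("\t")[1:]
    dups = {f for f in feat if feat.count(f) > 1}
    if dups:
        raise FormatError(f"{path}: duplicate feature id(s): {sorted(dups)}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas edge cases
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    dup_s = df.index[df.index.duplicated()].tolist()
    if dup_s:
        raise FormatError(f"{path}: duplicate sample id(s): {sorted(set(dup_s))}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric value in feature {col!r}")
    incomplete = [c for c in df.columns if df[c].isna().any()]
    if incomplete:
        logger.warning(
            "%s: dropping %d feature(s) with missing values: %s",
            path,
            len(incomplete),
            incomplete[:10],
        )
        df = df.drop(columns=incomplete)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no complete features left after dropping missing")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(platform=platform, data=df.astype(float), cancer_type=cancer_type)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------


@dataclass
class PathwayDefinition:
    """A signaling pathway: named membership with protein->gene map and signs.

    ``members`` is a list of ``(protein_id, gene_id, sign)`` with sign in
    {+1, -1}; signs are only consumed by the sign-aware (native) pathway
    score.  ``p`` is the member count.
    """

    name: str
    members: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise FormatError(f"pathway {self.name!r} has no members")
        prots = [m[0] for m in self.members]
        if len(set(prots)) != len(prots):
            raise FormatError(f"pathway {self.name!r} has duplicate protein ids")
        for _, _, sign in self.members:
            if sign not in (1, -1):
                raise FormatError(
                    f"pathway {self.name!r}: sign must be +1 or -1, got {sign}"
                )

    @property
    def p(self) -> int:
        return len(self.members)

    @property
    def proteins(self) -> list[str]:
        return [m[0] for m in self.members]

    def gene_of(self, protein: str) -> str:
        for prot, gene, _ in self.members:
            if prot == protein:
                return gene
        raise KeyError(protein)

    def sign_of(self, protein: str) -> int:
        for prot, _, sign in self.members:
            if prot == protein:
                return sign
        raise KeyError(protein)


def read_pathways(
    gmt_path: str | Path, sign_path: str | Path | None = None
) -> list[PathwayDefinition]:
    """Parse a GMT file; the optional sidecar TSV maps protein->gene and sign.

    Sidecar columns: ``protein``, ``gene``, ``sign``.  Members absent from the
    sidecar default to gene_id = protein_id and sign = +1.
    """
    mapping: dict[str, tuple[str, int]] = {}
    if sign_path is not None:
        side = pd.read_csv(sign_path, sep="\t", dtype={"protein": str, "gene": str})
        for col in ("protein", "gene", "sign"):
            if col not in side.columns:
                raise FormatError(f"{sign_path}: missing column {col!r}")
        for _, row in side.iterrows():
            sign = int(row["sign"])
            if sign not in (1, -1):
                raise FormatError(
                    f"{sign_path}: sign for {row['protein']!r} must be +1/-1, got {sign}"
                )
            mapping[str(row["protein"])] = (str(row["gene"]), sign)

    pathways: list[PathwayDefinition] = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise FormatError(f"{gmt_path}:{lineno}: pathway with no members")
            name = parts[0]
            members = []
            for prot in parts[2:]:
                prot = prot.strip()
                if not prot:
                    continue
                gene, sign = mapping.get(prot, (prot, 1))
                members.append((prot, gene, sign))
            pathways.append(PathwayDefinition(name=name, members=members))
    if not pathways:
        raise FormatError(f"{gmt_path}: no pathways found")
    return pathways


def write_pathways(
    pathways: Sequence[PathwayDefinition],
    gmt_path: str | Path,
    sign_path: str | Path | None = None,
) -> None:
    with open(gmt_path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, "na"] + [m[0] for m in pw.members]) + "\n")
    if sign_path is not None:
        rows = []
        for pw in pathways:
            for prot, gene, sign in pw.members:
                rows.append((prot, gene, sign))
        pd.DataFrame(rows, columns=["protein", "gene", "sign"]).drop_duplicates(
            subset="protein"
        ).to_csv(sign_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein-protein interaction table
# ---------------------------------------------------------------------------


@dataclass
class PPITable:
    """Symmetric protein-pair confidence scores in [0, 1].

    Pairs absent from the table score 0.  Duplicate / reciprocal rows are
    collapsed by maximum at load time.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.entries.get(self._key(a, b), 0.0)

    def set(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise FormatError(f"self-interaction {a!r} not allowed")
        if not (0.0 <= score <= 1.0):
            raise FormatError(f"PPI score for ({a},{b}) outside [0,1]: {score}")
        key = self._key(a, b)
        self.entries[key] = max(score, self.entries.get(key, 0.0))

    def __len__(self) -> int:
        return len(self.entries)


def read_ppi(path: str | Path, rescale: bool = False) -> PPITable:
    """Read a protein_a / protein_b / score edge list.

    With ``rescale`` raw 0-1000 combined scores are divided by 1000.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    for col in ("protein_a", "protein_b", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    table = PPITable()
    for _, row in df.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        score = float(row["score"])
        if rescale:
            score /= 1000.0
        if a == b:
            logger.warning("%s: dropping self-pair %r", path, a)
            continue
        if not (0.0 <= score <= 1.0):
            raise FormatError(
                f"{path}: score for ({a},{b}) outside [0,1] after rescale: {score}"
            )
        table.set(a, b, score)
    return table


def write_ppi(table: PPITable, path: str | Path) -> None:
    rows = sorted((a, b, s) for (a, b), s in table.entries.items())
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


def _default_alpha_grid() -> tuple[float, ...]:
    # 100 equally spaced points strictly inside (0, 0.1)
    return tuple(np.linspace(0.0, 0.1, 102)[1:-1])


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across the pipeline stages.

    Attributes
    ----------
    g : float or None
        Zellner g-prior scale; ``None`` means the unit-information choice
        g = n (sample size of the regression at hand).
    delta : float
        Half-width of the neutral interval around zero on the centered
        protein scale used for suppressed/neutral/activated calls.
    alpha_init : float
        Significance level of the conditional-independence tests for the
        initial PC-algorithm edge set.
    alpha_grid : tuple of float
        Tuning grid for stability selection (strictly increasing, in (0,1)).
    n_subsamples : int
        Number of half-sample draws for stability selection.
    enumeration_limit : int
        Largest candidate count for which the model space is enumerated
        exactly; larger problems use the MC3 sampler.
    mcmc_iters : int
        MC3 iterations (10% burn-in).
    default_upstream_prior : float
        Prior inclusion probability for upstream (mRNA/miRNA) covariates.
    seed : int
        Base seed for every stochastic stage.
    permutation_reps : int
        Permutation replicates for the connectivity-score p-value.
    gap_B : int
        Reference datasets for the gap statistic.
    """

    g: float | None = None
    delta: float = 0.5
    alpha_init: float = 0.1
    alpha_grid: tuple[float, ...] = field(default_factory=_default_alpha_grid)
    n_subsamples: int = 100
    enumeration_limit: int = 12
    mcmc_iters: int = 50_000
    default_upstream_prior: float = 0.5
    seed: int = 0
    permutation_reps: int = 100
    gap_B: int = 50

    def __post_init__(self) -> None:
        if self.g is not None and self.g <= 0:
            raise ValueError("g must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0.0 < self.alpha_init < 1.0):
            raise ValueError("alpha_init must lie in (0,1)")
        grid = tuple(float(a) for a in self.alpha_grid)
        if any(not (0.0 < a < 1.0) for a in grid):
            raise ValueError("alpha_grid values must lie in (0,1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("alpha_grid must be strictly increasing")
        object.__setattr__(self, "alpha_grid", grid)
        if not (0.0 < self.default_upstream_prior < 1.0):
            raise ValueError("default_upstream_prior must lie in (0,1)")
        for name in ("n_subsamples", "enumeration_limit", "mcmc_iters",
                     "permutation_reps", "gap_B"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "g": self.g,
            "delta": self.delta,
            "alpha_init": self.alpha_init,
            "alpha_grid": list(self.alpha_grid),
            "n_subsamples": self.n_subsamples,
            "enumeration_limit": self.enumeration_limit,
            "mcmc_iters": self.mcmc_iters,
            "default_upstream_prior": self.default_upstream_prior,
            "seed": self.seed,
            "permutation_reps": self.permutation_reps,
            "gap_B": self.gap_B,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "alpha_grid" in raw and raw["alpha_grid"] is not None:
            raw["alpha_grid"] = tuple(raw["alpha_grid"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Prior inclusion matrix TSV (rows = regulator, cols = target)
# ---------------------------------------------------------------------------


def read_prior_matrix(path: str | Path):
    from .prior import PriorInclusionMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: prior matrix rows/columns must match")
    return PriorInclusionMatrix(proteins=[str(x) for x in df.index], w=df.to_numpy(float))


def write_prior_matrix(prior, path: str | Path) -> None:
    df = pd.DataFrame(prior.w, index=prior.proteins, columns=prior.proteins)
    df.index.name = "regulator"
    df.to_csv(path, sep="\t")


def write_long_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format (tidy) TSV without the index column."""
    df.to_csv(path, sep="\t", index=False)
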