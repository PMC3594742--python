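"""Core containers shared across the MICA pipeline.

All containers are thin dataclasses around numpy arrays with ID lists,
validated on construction. They convert to/from pandas for I/O but the
numerical code works on the raw arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNPLACED = 0  # module label reserved for genes outside every module


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity table; the universal input.

    Values may be on any intensity scale (including log scale, hence
    possibly negative); rows are genes, columns are samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} IDs: {dupes}")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(dtype=float),
        )


@dataclass
class GeneFilterReport:
    """Bookkeeping for the intensity/CV gene pre-filters."""

    n_input: int
    n_after_intensity: int
    n_after_cv: int
    kept_gene_ids: list[str]

    def __post_init__(self) -> None:
        if not (self.n_after_cv <= self.n_after_intensity <= self.n_input):
            raise ValueError("filter counts must be non-increasing")
        if len(self.kept_gene_ids) != self.n_after_cv:
            raise ValueError("kept_gene_ids length must equal n_after_cv")


@dataclass
class AssociationMatrix:
    """Symmetric gene x gene association scores in [0, 1]."""

    gene_ids: list[str]
    scores: np.ndarray
    measure_tag: str = "mic"  # {mic, pearson, pearson_abs, pearson_power}

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError("association matrix must be square over gene_ids")
        if not np.allclose(self.scores, self.scores.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_genes, k=1)
        return self.scores[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class EdgeList:
    """Unweighted network: node list plus a set of unordered ID pairs."""

    nodes: list[str]
    edges: set[frozenset]
    cutoff_used: float | None = None

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= known:
                raise ValueError(f"edge endpoint outside node list: {set(e)}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as parallel (src, dst) integer arrays in node order."""
        pos = {g: i for i, g in enumerate(self.nodes)}
        pairs = sorted(tuple(sorted(e)) for e in self.edges)
        src = np.array([pos[a] for a, _ in pairs], dtype=np.int64)
        dst = np.array([pos[b] for _, b in pairs], dtype=np.int64)
        return src, dst

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=np.int64)
        src, dst = self.to_index_arrays()
        np.add.at(deg, src, 1)
        np.add.at(deg, dst, 1)
        return deg


@dataclass
class MembershipMatrix:
    """Fuzzy gene x module membership proportions; rows sum to 1.

    ``supported`` flags genes whose memberships are backed by network
    links; genes with no links get uniform rows and ``supported=False``.
    """

    gene_ids: list[str]
    mm: np.ndarray
    supported: np.ndarray | None = None
    n_samples_used: int = 0

    def __post_init__(self) -> None:
        self.mm = np.asarray(self.mm, dtype=float)
        if self.mm.shape[0] != len(self.gene_ids):
            raise ValueError("mm rows must match gene_ids")
        if np.any(self.mm < -1e-12):
            raise ValueError("memberships must be nonnegative")
        if not np.allclose(self.mm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if self.supported is None:
            self.supported = np.ones(len(self.gene_ids), dtype=bool)
        else:
            self.supported = np.asarray(self.supported, dtype=bool)

    @property
    def n_modules(self) -> int:
        return self.mm.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"module_{k + 1}" for k in range(self.n_modules)]
        return pd.DataFrame(self.mm, index=self.gene_ids, columns=cols)


@dataclass
class ModulePartition:
    """Gene -> module assignment; supports multi-assignment.

    Module labels are 1..n_modules; a gene's assignment is a frozenset of
    labels, empty meaning unplaced. Hard partitions have singleton sets.
    """

    gene_ids: list[str]
    assignments: list[frozenset]
    n_modules: int

    def __post_init__(self) -> None:
        if len(self.assignments) != len(self.gene_ids):
            raise ValueError("one assignment set per gene required")
        self.assignments = [frozenset(a) for a in self.assignments]
        for a in self.assignments:
            if any(m < 1 or m > self.n_modules for m in a):
                raise ValueError("module labels must lie in 1..n_modules")

    @property
    def is_hard(self) -> bool:
        return all(len(a) <= 1 for a in self.assignments)

    def labels(self) -> np.ndarray:
        """Hard labels with 0 = unplaced; errors on multi-assignment."""
        if not self.is_hard:
            raise ValueError("partition has multi-assigned genes")
        return np.array(
            [next(iter(a)) if a else UNPLACED for a in self.assignments],
            dtype=np.int64,
        )

    def module_genes(self, module: int) -> list[str]:
        return [g for g, a in zip(self.gene_ids, self.assignments) if module in a]

    def module_sizes(self) -> dict:
        return {
            m: len(self.module_genes(m)) for m in range(1, self.n_modules + 1)
        }

    @property
    def unplaced_ids(self) -> list[str]:
        return [g for g, a in zip(self.gene_ids, self.assignments) if not a]

    @property
    def n_unplaced(self) -> int:
        return sum(1 for a in self.assignments if not a)

    def to_frame(self) -> pd.DataFrame:
        lab = [
            "unplaced" if not a else ";".join(str(m) for m in sorted(a))
            for a in self.assignments
        ]
        return pd.DataFrame({"module": lab}, index=self.gene_ids)


@dataclass
class Eigengene:
    """Unit-norm first principal component summarizing a module."""

    module_id: object
    sample_ids: list[str]
    values: np.ndarray
    variance_explained: float
    n_genes: int = 0
    is_defined: bool = True

    def __post_init__(self) -> None:
        if self.is_defined:
            self.values = np.asarray(self.values, dtype=float)
            nrm = float(np.linalg.norm(self.values))
            if not np.isclose(nrm, 1.0, atol=1e-8):
                raise ValueError("eigengene must be unit norm")


@dataclass
class SFTFit:
    """Signed-R2 power-law fit of the connectivity distribution per power."""

    powers: list[int]
    r2_signed: list[float]
    slope: list[float]
    n_bins: int

    def __post_init__(self) -> None:
        if not (len(self.powers) == len(self.r2_signed) == len(self.slope)):
            raise ValueError("per-power lists must align")


@dataclass
class GridPartition:
    x_bins: int
    y_bins: int
    x_cuts: tuple = ()
    y_cuts: tuple = ()


@dataclass
class MICResult:
    mic: float
    best_grid: GridPartition | None
    n: int
    exponent: float = 0.6

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.mic <= 1 + 1e-12):
            raise ValueError("mic must lie in [0, 1]")
        self.mic = float(min(max(self.mic, 0.0), 1.0))
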