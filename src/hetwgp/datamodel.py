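"""Domain types and file plumbing for whole-genome prediction.

Containers for SNP dosages, training data and the pedigree-based additive
relationship matrix, plus readers/writers for the delimited-text exchange
formats and construction of the variance-model design matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TrainingData",
    "AMatrix",
    "ModelSpec",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "compute_maf",
    "build_a_matrix",
    "build_variance_designs",
]

MARKER_PRIORS = ("rrblup", "bayesa", "bayesb", "bayescpi")


class IntegrityError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class GenotypeMatrix:
    """An n x p matrix of minor-allele dosages (0/1/2) with locus metadata.

    ``map_positions`` is an optional DataFrame with columns ``chromosome``
    and ``position`` (genetic position in Morgans), one row per locus.
    """

    dosages: np.ndarray
    locus_ids: np.ndarray
    individual_ids: np.ndarray
    map_positions: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, p = self.dosages.shape
        if len(self.individual_ids) != n or len(self.locus_ids) != p:
            raise IntegrityError("dosage matrix shape inconsistent with id labels")
        if len(set(self.locus_ids)) != p:
            raise IntegrityError("duplicate locus IDs")
        if len(set(self.individual_ids)) != n:
            raise IntegrityError("duplicate individual IDs")
        vals = np.unique(self.dosages)
        if not np.isin(vals, [0, 1, 2]).all():
            raise IntegrityError(f"dosages outside {{0,1,2}}: found {vals[:5]}")
        if self.map_positions is not None:
            mp = self.map_positions
            if len(mp) != p:
                raise IntegrityError("map_positions length mismatch")
            for _, grp in mp.groupby("chromosome", sort=False):
                if not np.all(np.diff(grp["position"].to_numpy()) >= 0):
                    raise IntegrityError("map positions decrease within a chromosome")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        mp = None
        if self.map_positions is not None:
            mp = self.map_positions.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(
            self.dosages[:, idx], self.locus_ids[idx], self.individual_ids, mp
        )


@dataclass
class TrainingData:
    """Phenotypes plus mean-model and variance-model design matrices.

    ``y`` (n,) phenotypes; ``X`` (n, f) fixed-effect design; ``W`` (n, s)
    design for the log fixed variance multipliers ``tau`` (column 0 is the
    all-ones baseline under the set-to-zero parameterization); ``M`` (n, t)
    0/1 incidence for the cluster relative variances ``v``; ``cluster_ids``
    optional mean-model random-cluster labels (e.g. slaughter dates);
    ``pedigree`` optional (id, sire, dam) DataFrame.
    """

    y: np.ndarray
    X: np.ndarray
    W: Optional[np.ndarray] = None
    M: Optional[np.ndarray] = None
    cluster_ids: Optional[np.ndarray] = None
    pedigree: Optional[pd.DataFrame] = None
    individual_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise IntegrityError("X row count != n")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise IntegrityError("X is rank deficient after constraints")
        if self.W is not None:
            self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
            if self.W.shape[0] != n:
                raise IntegrityError("W row count != n")
        if self.M is not None:
            self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
            if self.M.shape[0] != n:
                raise IntegrityError("M row count != n")
            if not np.allclose(self.M.sum(axis=1), 1.0):
                raise IntegrityError("rows of M must each sum to 1")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class AMatrix:
    """Pedigree-based additive (numerator) relationship matrix."""

    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise IntegrityError("A matrix must be symmetric")
        if np.any(np.diag(self.values) < 1.0 - 1e-12):
            raise IntegrityError("A matrix diagonal must be >= 1")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


@dataclass
class ModelSpec:
    """Which marker-prior family to fit and how the priors are configured.

    ``marker_prior`` is one of ``rrblup``, ``bayesa``, ``bayesb``,
    ``bayescpi``.  ``heteroskedastic`` switches on the log-linear residual
    variance model.  ``fixed_hyperparams`` may pin ``s_g2``, ``nu_g`` or
    ``sigma_u2`` to known constants (the identifiability workaround used
    for variable-selection families and polygenic fits).  Defaults follow
    the reference prior set: Beta(10, 1) on the null probability pi,
    density ``(1 + alpha_v)**-2`` on the inverted-gamma shape and
    ``(1 + nu_g)**-2`` on the Student-t degrees of freedom.
    """

    marker_prior: str = "rrblup"
    heteroskedastic: bool = False
    fixed_hyperparams: Mapping[str, float] = field(default_factory=dict)
    pi_prior: tuple[float, float] = (10.0, 1.0)

    def __post_init__(self) -> None:
        key = self.marker_prior.lower().replace("-", "").replace("_", "")
        aliases = {"rrblup": "rrblup", "bayesa": "bayesa", "bayesb": "bayesb",
                   "bayescpi": "bayescpi", "bayesc": "bayescpi"}
        if key not in aliases:
            raise ValueError(f"unknown marker prior {self.marker_prior!r}")
        self.marker_prior = aliases[key]
        for k, val in self.fixed_hyperparams.items():
            if val <= 0:
                raise ValueError(f"fixed hyperparameter {k} must be positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(
    path,
    dialect: str = "dosage",
    loci_as_rows: bool = False,
    recode_to_minor: bool = False,
    missing: str = "error",
) -> GenotypeMatrix:
    """Read a delimited-text dosage matrix.

    ``dialect='dosage'`` expects a header row of locus IDs and a first
    column of individual IDs; ``dialect='plink-raw'`` expects the PLINK
    ``.raw`` layout (FID IID PAT MAT SEX PHENOTYPE then dosage columns).
    ``recode_to_minor`` flips any column coded on the major allele so that
    every stored column counts the minor allele (mean dose/2 <= 0.5).
    Missing dosages raise by default; ``missing='mean'`` imputes the
    column rounded mean.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if dialect == "plink-raw":
        ind = df.iloc[:, 1].astype(str).to_numpy()
        dose = df.iloc[:, 6:]
    elif dialect == "dosage":
        ind = df.iloc[:, 0].astype(str).to_numpy()
        dose = df.iloc[:, 1:]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    loci = dose.columns.to_numpy(dtype=object)
    mat = dose.to_numpy(dtype=float)
    if loci_as_rows:
        mat = mat.T
        ind, loci = loci, ind
    if len(set(ind)) != len(ind):
        raise IntegrityError(f"duplicated individual ID in {path}")
    if np.isnan(mat).any():
        if missing == "error":
            bad = np.argwhere(np.isnan(mat))[0]
            raise IntegrityError(
                f"missing genotype at row {bad[0] + 1}, locus {loci[bad[1]]}"
            )
        elif missing == "mean":
            col_mean = np.nanmean(mat, axis=0)
            idx = np.where(np.isnan(mat))
            mat[idx] = np.rint(col_mean[idx[1]])
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    bad = ~np.isin(mat, [0.0, 1.0, 2.0])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise IntegrityError(
            f"dosage outside {{0,1,2}} at line {i + 2} (locus {loci[j]})"
        )
    mat = mat.astype(np.int8)
    if recode_to_minor:
        freq = mat.mean(axis=0) / 2.0
        flip = freq > 0.5
        mat[:, flip] = 2 - mat[:, flip]
    return GenotypeMatrix(mat, loci, ind)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the dosage matrix in the header + ID-column dialect."""
    pd.DataFrame(g.dosages, index=g.individual_ids, columns=g.locus_ids).to_csv(
        path, index_label="id"
    )


def read_pedigree(path) -> pd.DataFrame:
    """Read a 3-column (id, sire, dam) CSV; 0/NA mean unknown parent."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = ["id", "sire", "dam"]
    for col in ("sire", "dam"):
        df[col] = df[col].replace({"0": None, "NA": None, "nan": None})
        df[col] = df[col].where(df[col].notna(), None)
    return df


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def compute_maf(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-locus minor allele frequency ``min(f, 1-f)`` with ``f = sum(dose)/2n``."""
    dos = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    n = dos.shape[0]
    if n == 0:
        raise ValueError("cannot compute allele frequencies with zero individuals")
    f = dos.sum(axis=0) / (2.0 * n)
    return np.minimum(f, 1.0 - f)


# ---------------------------------------------------------------------------
# additive relationship matrix (tabular method)
# ---------------------------------------------------------------------------

def _toposort(ped: pd.DataFrame) -> list[int]:
    ids = list(ped["id"])
    index = {v: k for k, v in enumerate(ids)}
    state = np.zeros(len(ids), dtype=int)  # 0 unvisited, 1 in stack, 2 done
    order: list[int] = []

    def visit(i: int, stack: list[int]) -> None:
        if state[i] == 2:
            return
        if state[i] == 1:
            raise ValueError(f"cyclic pedigree involving individual {ids[i]}")
        state[i] = 1
        for parent in (ped.iloc[i]["sire"], ped.iloc[i]["dam"]):
            if parent is not None and parent in index:
                visit(index[parent], stack)
        state[i] = 2
        order.append(i)

    for i in range(len(ids)):
        visit(i, [])
    return order


def build_a_matrix(pedigree: pd.DataFrame | Sequence[tuple]) -> AMatrix:
    """Additive relationship matrix by the tabular (recursive) method.

    ``a_ii = 1 + 0.5 a(sire, dam)`` and ``a_ij = 0.5 (a(j, sire_i) +
    a(j, dam_i))``; unknown parents contribute 0.  The pedigree is
    topologically sorted internally so parents precede offspring; a cycle
    raises.  Parents referenced but never listed are treated as unknown
    founders.
    """
    if not isinstance(pedigree, pd.DataFrame):
        pedigree = pd.DataFrame(pedigree, columns=["id", "sire", "dam"])
    ped = pedigree.copy()
    ped["id"] = ped["id"].astype(object)
    if ped["id"].duplicated().any():
        raise ValueError("duplicate individual in pedigree")
    known = set(ped["id"])
    for col in ("sire", "dam"):
        ped[col] = [
            par if (par is not None and not pd.isna(par) and par in known) else None
            for par in ped[col]
        ]
    order = _toposort(ped)
    ids = ped["id"].to_numpy(dtype=object)
    index = {v: k for k, v in enumerate(ids)}
    m = len(ids)
    a = np.zeros((m, m))
    for i in order:
        s, d = ped.iloc[i]["sire"], ped.iloc[i]["dam"]
        si = index[s] if s is not None else -1
        di = index[d] if d is not None else -1
        a[i, i] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
        for j in order:
            if j == i:
                break
            val = 0.0
            if si >= 0:
                val += 0.5 * a[j, si]
            if di >= 0:
                val += 0.5 * a[j, di]
            a[i, j] = a[j, i] = val
    return AMatrix(a, ids)


# ---------------------------------------------------------------------------
# variance-model design matrices
# ---------------------------------------------------------------------------

def build_variance_designs(
    fixed_labels: Optional[Sequence] = None,
    cluster_labels: Optional[Sequence] = None,
    reference: Optional[object] = None,
    n: Optional[int] = None,
):
    """Build ``(W, M, w_levels, m_levels)`` for the log-linear variance model.

    ``W`` uses the set-to-zero parameterization: column 0 is the all-ones
    baseline (the reference level's variance), and one indicator column per
    non-reference level of ``fixed_labels``, so the corresponding tau
    component is interpretable as a variance ratio (e.g. female-to-male).
    The reference level is the first in sorted order unless ``reference``
    is given.  ``M`` is the full 0/1 incidence of ``cluster_labels`` with
    unit row sums.  Either argument may be ``None``; ``n`` is then
    required to size the all-ones baseline.
    """
    import warnings

    if fixed_labels is not None:
        fixed_labels = np.asarray(fixed_labels, dtype=object)
        n = len(fixed_labels)
    elif cluster_labels is not None:
        n = len(cluster_labels)
    elif n is None:
        raise ValueError("provide labels or n")

    w_levels: list = ["baseline"]
    W = np.ones((n, 1))
    if fixed_labels is not None:
        levels = sorted(set(fixed_labels))
        ref = levels[0] if reference is None else reference
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among labels")
        others = [lv for lv in levels if lv != ref]
        if not others and cluster_labels is None:
            warnings.warn(
                "single-level variance fixed factor and no random clusters: "
                "model reduces to homoskedastic",
                stacklevel=2,
            )
        cols = [(fixed_labels == lv).astype(float)[:, None] for lv in others]
        if cols:
            W = np.hstack([W] + cols)
        w_levels += others

    M = None
    m_levels: list = []
    if cluster_labels is not None:
        cluster_labels = np.asarray(cluster_labels, dtype=object)
        if len(cluster_labels) != n:
            raise ValueError("label length mismatch")
        m_levels = sorted(set(cluster_labels))
        M = np.zeros((n, len(m_levels)))
        for k, lv in enumerate(m_levels):
            M[cluster_labels == lv, k] = 1.0
    return W, M, w_levels, m_levels
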