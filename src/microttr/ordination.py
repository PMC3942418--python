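"""Canonical correspondence analysis, forward selection, variance partitioning.

CCA relates a community count table to environmental covariates. The count
matrix is turned into its chi-square residual form

    Qbar_ij = (p_ij - r_i * c_j) / sqrt(r_i * c_j),   P = Y / grand_total,

whose squared Frobenius norm is the table's total inertia (the chi-square
statistic divided by the grand total). Covariates are centred with row-mass
weights and the weighted covariate space is used to project Qbar; the SVD of
the projection yields the constrained eigenvalues (squared singular values)
and ordination scores. Partial CCA residualizes the covariates on a set of
conditioning variables first, measuring what they explain *beyond* the
condition.

Forward selection adds covariates greedily by additional constrained inertia,
testing each addition with a seeded residual-permutation Monte Carlo test
using the (b+1)/(m+1) p-value estimator. Variance partitioning runs the full
set of marginal and joint CCAs for three covariate groups (wastewater W,
operational O, scale S) and solves the inclusion-exclusion system for the
seven Venn fractions of explained inertia. Fractions are raw inertia ratios
(no adjusted-R2 correction); shared fractions can be slightly negative and
are reported as computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_io import CommunityTable, ValidationError

GROUP_LABELS = ("W", "O", "S")

_RANK_TOL = 1e-9


@dataclass
class CovariateTable:
    """Per-sample covariates with a W/O/S group label per variable."""

    sample_ids: list[str]
    data: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if list(self.data.index) != list(self.sample_ids):
            self.data = self.data.loc[self.sample_ids]
        if self.data.isna().any().any():
            raise ValidationError("covariate table contains missing values")
        for var in self.data.columns:
            grp = self.groups.get(var)
            if grp not in GROUP_LABELS:
                raise ValidationError(
                    f"variable {var!r} must be assigned to one of {GROUP_LABELS}"
                )

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, variables: list[str]) -> "CovariateTable":
        return CovariateTable(
            sample_ids=list(self.sample_ids),
            data=self.data[variables].copy(),
            groups={v: self.groups[v] for v in variables},
        )

    def group_variables(self, label: str) -> list[str]:
        return [v for v in self.data.columns if self.groups[v] == label]


@dataclass
class CCAResult:
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores: np.ndarray
    species_scores: np.ndarray
    biplot_scores: np.ndarray
    explained_fraction: float


@dataclass
class ForwardSelectionResult:
    selected: list[tuple[str, float]]
    rejected: list[tuple[str, float]]
    n_permutations: int
    threshold: float


@dataclass
class VPAResult:
    """Venn fractions of explained inertia for groups W, O, S.

    Keys: "W", "O", "S" (pure), "W&O", "W&S", "O&S", "W&O&S" (shared),
    "unexplained". The eight values sum to 1.
    """

    fractions: dict[str, float]


def transform_covariates(cov: CovariateTable) -> CovariateTable:
    """log2(x + 1) transform of every covariate value (standardization)."""
    if (cov.data.to_numpy() < 0).any():
        raise ValidationError("log2(x+1) transform requires non-negative values")
    return CovariateTable(
        sample_ids=list(cov.sample_ids),
        data=np.log2(cov.data + 1.0),
        groups=dict(cov.groups),
    )


def _chi_square_residuals(table: CommunityTable):
    """Qbar, row masses r, column masses c; all-zero taxa are dropped."""
    totals = table.sample_totals()
    for sid, t in zip(table.sample_ids, totals):
        if t == 0:
            raise ValidationError(f"sample {sid!r} has zero total count")
    counts = table.counts.astype(float)
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    grand = counts.sum()
    P = counts / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    qbar = (P - expected) / np.sqrt(expected)
    return qbar, r, c


def total_inertia(table: CommunityTable) -> float:
    """Chi-square statistic of the count table divided by its grand total."""
    qbar, _, _ = _chi_square_residuals(table)
    return float((qbar**2).sum())


def _weighted_design(cov: CovariateTable, r: np.ndarray, n_samples: int) -> np.ndarray:
    """Row-mass-weighted, weighted-centred design matrix sqrt(r) * (X - mean_r X)."""
    X = cov.data.to_numpy(dtype=float)
    if X.shape[1] > n_samples - 1:
        raise ValidationError(
            f"{X.shape[1]} covariates exceed the limit of n_samples - 1 = "
            f"{n_samples - 1}"
        )
    for j, var in enumerate(cov.variables):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"covariate {var!r} is constant across samples")
    means = r @ X  # weights sum to 1
    Xc = X - means
    return np.sqrt(r)[:, None] * Xc


def _orthonormal_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of M (rank-revealing SVD)."""
    if M.size == 0 or M.shape[1] == 0:
        return np.zeros((M.shape[0], 0))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int((s > _RANK_TOL * max(s[0], 1.0)).sum()) if s.size else 0
    return U[:, :rank]


def _constrained_inertia(qbar: np.ndarray, basis: np.ndarray) -> float:
    if basis.shape[1] == 0:
        return 0.0
    return float(((basis.T @ qbar) ** 2).sum())


def _cca_from_basis(
    qbar: np.ndarray, r: np.ndarray, c: np.ndarray, basis: np.ndarray, Xw: np.ndarray
) -> CCAResult:
    tot = float((qbar**2).sum())
    fitted = basis @ (basis.T @ qbar) if basis.shape[1] else np.zeros_like(qbar)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int((s > 1e-12 * max(s[0], 1.0) if s.size else 0).sum()) if s.size else 0
    n_axes = min(n_axes, basis.shape[1])
    U, s, V = U[:, :n_axes], s[:n_axes], Vt[:n_axes].T
    eig = s**2
    # site-focused scaling: sites at U*s in weighted space, back-transformed
    with np.errstate(divide="ignore", invalid="ignore"):
        site = (U * s) / np.sqrt(r)[:, None]
        species = V / np.sqrt(c)[:, None]
    if Xw.shape[1] and n_axes:
        norms = np.linalg.norm(Xw, axis=0)
        biplot = (Xw.T @ U) / norms[:, None]
    else:
        biplot = np.zeros((Xw.shape[1], n_axes))
    constrained = float(eig.sum())
    return CCAResult(
        eigenvalues=eig,
        total_inertia=tot,
        constrained_inertia=constrained,
        site_scores=site,
        species_scores=species,
        biplot_scores=biplot,
        explained_fraction=constrained / tot if tot > 0 else 0.0,
    )


def cca(table: CommunityTable, cov: CovariateTable) -> CCAResult:
    """Canonical correspondence analysis of a count table on covariates."""
    if table.n_samples < 3:
        raise ValidationError("cca needs at least 3 samples")
    if table.n_taxa < 2:
        raise ValidationError("cca needs at least 2 taxa")
    qbar, r, c = _chi_square_residuals(table)
    Xw = _weighted_design(cov, r, table.n_samples)
    basis = _orthonormal_basis(Xw)
    return _cca_from_basis(qbar, r, c, basis, Xw)


def partial_cca(
    table: CommunityTable, cov: CovariateTable, condition: CovariateTable | None
) -> CCAResult:
    """CCA of ``cov`` after residualizing on ``condition`` variables.

    The constrained inertia is what ``cov`` explains beyond the condition.
    An empty condition reduces to plain :func:`cca`.
    """
    if condition is None or not condition.variables:
        return cca(table, cov)
    overlap = set(cov.variables) & set(condition.variables)
    if overlap:
        raise ValidationError(
            f"conditioning variables overlap covariates: {sorted(overlap)}"
        )
    qbar, r, c = _chi_square_residuals(table)
    Xw = _weighted_design(cov, r, table.n_samples)
    Zw = _weighted_design(condition, r, table.n_samples)
    Zb = _orthonormal_basis(Zw)
    X_res = Xw - Zb @ (Zb.T @ Xw)
    basis = _orthonormal_basis(X_res)
    return _cca_from_basis(qbar, r, c, basis, X_res)


def forward_select(
    table: CommunityTable,
    cov: CovariateTable,
    n_permutations: int = 499,
    threshold: float = 0.05,
    seed: int = 0,
) -> ForwardSelectionResult:
    """Greedy forward selection of covariates by permutation test.

    At each step the candidate adding the most constrained inertia beyond the
    already-selected set is tested by permuting its residuals (given the
    selected variables, under row-mass-weighted regression); the p-value is
    (b + 1) / (m + 1) with b the number of permuted statistics >= observed.
    Selection stops when no remaining candidate attains p < threshold.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if not cov.variables:
        raise ValidationError("forward selection needs at least one candidate")
    qbar, r, _ = _chi_square_residuals(table)
    Xw_all = _weighted_design(cov, r, table.n_samples)
    cols = {v: Xw_all[:, j] for j, v in enumerate(cov.variables)}
    rng = np.random.default_rng(seed)

    def extra_inertia(col: np.ndarray, sel_basis: np.ndarray) -> float:
        resid = col - sel_basis @ (sel_basis.T @ col) if sel_basis.shape[1] else col
        norm = np.linalg.norm(resid)
        if norm < _RANK_TOL:
            return 0.0
        return float((((resid / norm) @ qbar) ** 2).sum())

    selected: list[tuple[str, float]] = []
    remaining = list(cov.variables)
    sel_basis = np.zeros((table.n_samples, 0))
    last_pvals: dict[str, float] = {}
    while remaining:
        stats = {v: extra_inertia(cols[v], sel_basis) for v in remaining}
        order = sorted(remaining, key=lambda v: stats[v], reverse=True)
        added = None
        for v in order:
            obs = stats[v]
            col = cols[v]
            fitted = (
                sel_basis @ (sel_basis.T @ col) if sel_basis.shape[1] else np.zeros_like(col)
            )
            resid = col - fitted
            b = 0
            for _ in range(n_permutations):
                perm = fitted + rng.permutation(resid)
                if extra_inertia(perm, sel_basis) >= obs - 1e-15:
                    b += 1
            p = (b + 1) / (n_permutations + 1)
            last_pvals[v] = p
            if p < threshold:
                added = (v, p)
                break
        if added is None:
            break
        v, p = added
        selected.append((v, p))
        remaining.remove(v)
        sel_basis = _orthonormal_basis(
            np.column_stack([cols[name] for name, _ in selected])
        )
    rejected = [(v, last_pvals.get(v, float("nan"))) for v in remaining]
    return ForwardSelectionResult(
        selected=selected,
        rejected=rejected,
        n_permutations=n_permutations,
        threshold=threshold,
    )


def variance_partition(table: CommunityTable, cov: CovariateTable) -> VPAResult:
    """Three-way variance partitioning of explained inertia (W, O, S).

    Runs plain CCAs for every non-empty subset of the three groups and solves
    the inclusion-exclusion system for the seven Venn components; unexplained
    is 1 minus the fraction explained by all groups together.
    """
    groups = {g: cov.group_variables(g) for g in GROUP_LABELS}
    for g, vars_ in groups.items():
        if not vars_:
            raise ValidationError(f"covariate group {g!r} is empty")
    frac: dict[frozenset, float] = {}
    for size in (1, 2, 3):
        for combo in itertools.combinations(GROUP_LABELS, size):
            vars_ = [v for g in combo for v in groups[g]]
            frac[frozenset(combo)] = cca(table, cov.subset(vars_)).explained_fraction

    # unknowns: pure W, pure O, pure S, W&O, W&S, O&S, W&O&S
    comps = [
        frozenset("W"),
        frozenset("O"),
        frozenset("S"),
        frozenset("WO"),
        frozenset("WS"),
        frozenset("OS"),
        frozenset("WOS"),
    ]
    sets = [frozenset(s) for s in (["W"], ["O"], ["S"], "WO", "WS", "OS", "WOS")]
    A = np.zeros((7, 7))
    b = np.zeros(7)
    for i, subset in enumerate(sets):
        for j, comp in enumerate(comps):
            # component j lies inside the union explained by `subset` iff the
            # groups it belongs to intersect the subset
            A[i, j] = 1.0 if comp & subset else 0.0
        b[i] = frac[subset]
    x = np.linalg.solve(A, b)
    labels = ["W", "O", "S", "W&O", "W&S", "O&S", "W&O&S"]
    fractions = {lab: float(v) for lab, v in zip(labels, x)}
    fractions["unexplained"] = float(1.0 - frac[frozenset("WOS")])
    return VPAResult(fractions=fractions)


def write_covariates(path, cov: CovariateTable) -> None:
    """Long-form TSV: header ``sample  variable  group  value``."""
    with open(path, "w") as fh:
        fh.write("sample\tvariable\tgroup\tvalue\n")
        for var in cov.variables:
            for sid in cov.sample_ids:
                fh.write(
                    f"{sid}\t{var}\t{cov.groups[var]}\t{cov.data.loc[sid, var]:.10g}\n"
                )


def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "variable": str})
    expected = ["sample", "variable", "group", "value"]
    if list(df.columns) != expected:
        raise ValidationError(f"covariate header must be {expected}")
    wide = df.pivot(index="sample", columns="variable", values="value")
    sample_ids = list(dict.fromkeys(df["sample"]))
    wide = wide.loc[sample_ids]
    groups = dict(zip(df["variable"], df["group"]))
    return CovariateTable(
        sample_ids=sample_ids, data=wide[list(dict.fromkeys(df["variable"]))],
        groups=groups,
    )
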