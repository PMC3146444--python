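"""Principal component analysis of population allele frequencies.

Populations (not individuals) are the observations, in the style of
PCA-GEN: rows of the data matrix are per-population allele-frequency
vectors over all (locus, allele) columns, weighted by gene counts. Each
axis is reported with its share of total inertia, an apportioned per-axis
FST (global multilocus θ × inertia share — a reporting convention, not an
estimator of its own), and a permutation p-value obtained by shuffling
individuals among populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import GenotypeTable, GroupingSpec, allele_frequencies
from .popgen import wc_fst

__all__ = [
    "PcaResult",
    "population_frequency_matrix",
    "pca_of_populations",
    "pca_populations",
    "pca_randomization_test",
]


def population_frequency_matrix(
    table: GenotypeTable, grouping: GroupingSpec = "population"
) -> tuple[pd.DataFrame, pd.Series]:
    """Population × allele frequency matrix and gene-count weights.

    Columns are a MultiIndex of (locus, allele) over every allele in each
    locus registry; each locus block of a row sums to one. A population
    with no data at some locus cannot be placed in the common frequency
    space and raises ``ValueError``.
    """
    gf = allele_frequencies(table, grouping)
    pops = gf.groups
    if len(pops) < 2:
        raise ValueError("population_frequency_matrix requires >= 2 populations")
    bad = [
        (g, name)
        for g in pops
        for name, c in zip(gf.locus_names, gf.gene_counts[g])
        if c == 0
    ]
    if bad:
        raise ValueError(f"populations with an all-missing locus: {bad}")

    cols = [(l.name, a) for l in table.loci for a in l.alleles]
    mat = np.zeros((len(pops), len(cols)))
    for i, g in enumerate(pops):
        j = 0
        for l, freqs in zip(table.loci, gf.freqs[g]):
            for a in l.alleles:
                mat[i, j] = freqs.get(a, 0.0)
                j += 1
    index = pd.Index(pops, name="population")
    columns = pd.MultiIndex.from_tuples(cols, names=["locus", "allele"])
    weights = pd.Series(
        [float(sum(gf.gene_counts[g])) for g in pops], index=index, name="gene_count"
    )
    return pd.DataFrame(mat, index=index, columns=columns), weights


@dataclass
class PcaResult:
    """Weighted PCA of population frequencies with per-axis summaries."""

    scores: pd.DataFrame  # populations × axes
    loadings: pd.DataFrame  # columns × axes
    eigenvalues: np.ndarray
    inertia_fraction: np.ndarray
    axis_fst: np.ndarray | None = None
    axis_p_values: np.ndarray | None = None
    n_randomizations: int = 0
    total_inertia: float = 0.0
    extras: dict = field(default_factory=dict)


def _weighted_eigen(
    mat: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Eigendecomposition of the weight-centered covariance of ``mat``.

    Returns (eigenvalues desc, eigenvectors by column, centered matrix,
    total inertia). Eigenvalues below 1e-12 of the total are dropped.
    """
    wn = w / w.sum()
    center = wn @ mat
    X = mat - center
    cov = (X * wn[:, None]).T @ X
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = float(vals.sum())
    if total <= 0:
        return np.empty(0), np.empty((mat.shape[1], 0)), X, 0.0
    keep = vals > 1e-12 * total
    return vals[keep], vecs[:, keep], X, total


def pca_of_populations(
    freq_matrix: pd.DataFrame,
    population_weights: pd.Series,
    n_axes: int | None = None,
    global_theta: float | None = None,
) -> PcaResult:
    """Weighted PCA of a population frequency matrix.

    ``population_weights`` are gene counts; axes are sign-fixed so the
    largest-magnitude loading on each axis is positive, making plots
    reproducible. When ``global_theta`` is supplied, per-axis FST is
    apportioned as θ × inertia fraction (summing to θ over all axes).
    """
    w = population_weights.reindex(freq_matrix.index).to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("population weights must be positive")
    vals, vecs, X, total = _weighted_eigen(freq_matrix.to_numpy(dtype=float), w)
    n_avail = len(vals)
    if n_axes is not None and n_axes > n_avail:
        import warnings

        warnings.warn(
            f"requested {n_axes} axes but only {n_avail} have positive inertia; "
            "truncating",
            stacklevel=2,
        )
    k = n_avail if n_axes is None else min(n_axes, n_avail)
    vals, vecs = vals[:k], vecs[:, :k]
    # sign convention: largest |loading| positive per axis
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = X @ vecs
    axes = [f"PC{j + 1}" for j in range(vecs.shape[1])]
    frac = vals / total if total > 0 else vals
    return PcaResult(
        scores=pd.DataFrame(scores, index=freq_matrix.index, columns=axes),
        loadings=pd.DataFrame(vecs, index=freq_matrix.columns, columns=axes),
        eigenvalues=vals,
        inertia_fraction=frac,
        axis_fst=None if global_theta is None else global_theta * frac,
        total_inertia=total,
    )


def pca_populations(
    table: GenotypeTable,
    grouping: GroupingSpec = "population",
    n_axes: int | None = None,
) -> PcaResult:
    """Convenience wrapper: frequency matrix, weights and global θ from a
    genotype table, then :func:`pca_of_populations`."""
    mat, w = population_frequency_matrix(table, grouping)
    theta = wc_fst(table, grouping).theta
    return pca_of_populations(mat, w, n_axes=n_axes, global_theta=theta)


def pca_randomization_test(
    table: GenotypeTable,
    grouping: GroupingSpec = "population",
    n_rand: int = 5000,
    n_axes: int = 4,
    seed: int | None = None,
) -> np.ndarray:
    """Per-axis randomization p-values for the population PCA.

    Individuals are permuted among populations (sizes preserved), the
    frequency matrix is rebuilt and the leading eigenvalues recomputed;
    p_j = (1 + #{λ*_j ≥ λ̂_j}) / (n_rand + 1). Seeded and reproducible.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    labels = table.group_labels(grouping)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("randomization test requires >= 2 populations")
    gid = np.array([uniq.index(lab) for lab in labels])
    geno, _ = table.to_arrays()
    n_alleles = [l.n_alleles for l in table.loci]

    def eigenvalues(ids: np.ndarray) -> np.ndarray:
        mat, w = _freq_matrix_arrays(geno, ids, len(uniq), n_alleles)
        vals, _, _, _ = _weighted_eigen(mat, w)
        out = np.zeros(n_axes)
        out[: min(n_axes, len(vals))] = vals[:n_axes]
        return out

    obs = eigenvalues(gid)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_axes, dtype=np.int64)
    for _ in range(n_rand):
        perm = rng.permutation(gid)
        exceed += eigenvalues(perm) >= obs
    return (1 + exceed) / (n_rand + 1)


def _freq_matrix_arrays(
    geno: np.ndarray, gid: np.ndarray, n_groups: int, n_alleles: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency matrix and gene-count weights from coded genotype arrays.

    Fast path shared with the randomization test; assumes every group has
    data at every locus (guaranteed by construction for permuted labels of
    a matrix that already validated).
    """
    n_loci = geno.shape[1]
    blocks = []
    w = np.zeros(n_groups)
    for l in range(n_loci):
        gl = geno[:, l, :]
        valid = gl[:, 0] >= 0
        ids2 = np.repeat(gid[valid], 2)
        alleles = gl[valid].ravel()
        counts = np.zeros((n_groups, n_alleles[l]))
        np.add.at(counts, (ids2, alleles), 1.0)
        totals = counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        blocks.append(counts / totals)
        w += counts.sum(axis=1)
    return np.hstack(blocks), w
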