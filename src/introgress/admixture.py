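"""Bayesian admixture model for multilocus codominant genotypes.

A Gibbs sampler over the classic model-based clustering model for diploid
genotypes: each individual i has an ancestry vector Q_i on the K-simplex,
each gene copy carries a latent cluster-of-origin z drawn from Q_i, and the
allele observed on that copy is drawn from the origin cluster's allele
frequencies P_k at the locus. Priors are Dirichlet(λ) on frequencies and a
symmetric Dirichlet(α, ..., α) on ancestries, with α itself sampled by a
Metropolis random walk.

Two frequency models are provided:

* ``independent`` — cluster frequencies are a priori independent
  Dirichlet(λ) draws per locus;
* ``correlated`` (default) — cluster frequencies drift from a shared
  ancestral frequency vector, P_kl ~ Dirichlet(p_anc,l (1−F_k)/F_k), with
  per-cluster drift parameters F_k under a gamma prior and both F_k and the
  ancestral frequencies updated by Metropolis steps. The correlated model
  retains power to separate closely related clusters, which is why it is
  the default for recently diverged, hybridizing taxa.

Learning samples ("popflag" individuals) are supported by clamping their Q
to the unit vector of their labelled cluster, so the reference pools anchor
cluster identities and the sampler estimates admixture only for the
remaining individuals.

Model choice across K uses the estimator ln P(D) ≈ mean(lnL) − var(lnL)/2
over the sampling period, and the ΔK statistic: the mean absolute second
difference of ln P(D) across K divided by its standard deviation over
replicate runs, whose mode marks the uppermost level of structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import GenotypeTable, GroupingSpec

__all__ = [
    "AdmixtureConfig",
    "AdmixtureRun",
    "run_admixture",
    "posterior_summary",
    "estimate_ln_prob_data",
    "evanno_delta_k",
    "align_columns",
]

_TINY = 1e-300


@dataclass(frozen=True)
class AdmixtureConfig:
    """Sampler configuration.

    Defaults are desk-scale (5 000 burn-in / 20 000 sampling sweeps); the
    field-survey scale of 20 000 / 100 000 is available by overriding
    ``burn_in`` and ``n_sweeps``.
    """

    K: int = 2
    burn_in: int = 5_000
    n_sweeps: int = 20_000
    freq_model: str = "correlated"  # or "independent"
    lambda_: float = 1.0
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_proposal_sd: float = 0.025
    drift_prior_mean: float = 0.01
    drift_prior_sd: float = 0.05
    drift_proposal_sd: float = 0.05
    anc_proposal_sd: float = 0.05
    use_reference_labels: bool = False
    seed: int = 0
    thin: int = 10

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in < 1 or self.n_sweeps < 1:
            raise ValueError("burn_in and n_sweeps must be >= 1")
        if self.alpha_max <= 0:
            raise ValueError("alpha_max must be positive")
        if self.freq_model not in ("correlated", "independent"):
            raise ValueError("freq_model must be 'correlated' or 'independent'")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class AdmixtureRun:
    """Posterior output of one sampler run."""

    q_mean: pd.DataFrame            # individuals × clusters
    q_ci90: pd.DataFrame            # individuals × (cluster, lo/hi)
    p_mean: np.ndarray              # clusters × loci × alleles (padded)
    alpha_trace: np.ndarray
    lnl_trace: np.ndarray
    ln_prob_data: float
    config: AdmixtureConfig
    reference_clusters: dict[str, int] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)

    @property
    def cluster_names(self) -> list[str]:
        return list(self.q_mean.columns)


def default_reference_clusters(table: GenotypeTable) -> dict[str, int]:
    """Cluster labels for reference individuals derived from species.

    Convention for supervised K=2 runs: *I. graellsii* anchors cluster 0
    and *I. elegans* (the non-Spanish reference pool) anchors cluster 1.
    """
    out: dict[str, int] = {}
    for s in table.samples:
        if not s.is_reference:
            continue
        if s.species == "graellsii":
            out[s.id] = 0
        elif s.species == "elegans":
            out[s.id] = 1
        else:
            raise ValueError(
                f"reference sample {s.id!r} has species 'unknown'; cannot "
                "derive its cluster label"
            )
    return out


def _ln_dirichlet(x: np.ndarray, a: np.ndarray) -> float:
    """Log density of Dirichlet(a) at x over the last axis (both 1-D)."""
    return float(
        gammaln(a.sum()) - gammaln(a).sum() + ((a - 1.0) * np.log(x)).sum()
    )


def run_admixture(
    table: GenotypeTable,
    config: AdmixtureConfig,
    reference_clusters: dict[str, int] | None = None,
) -> AdmixtureRun:
    """Run the Gibbs sampler on ``table``.

    When ``config.use_reference_labels`` is set, individuals flagged
    ``is_reference`` have their ancestry clamped to the unit vector of their
    labelled cluster. Labels come from ``reference_clusters`` (sample id →
    cluster index) or, by default, are derived from species via
    :func:`default_reference_clusters`.

    The run is fully reproducible from ``config.seed``.
    """
    if table.n_samples == 0:
        raise ValueError("empty genotype table")
    K = config.K
    geno, _ = table.to_arrays()
    N, L, _ = geno.shape
    n_alleles = np.array([l.n_alleles for l in table.loci])
    if np.any(n_alleles == 0):
        empty = [l.name for l in table.loci if l.n_alleles == 0]
        raise ValueError(f"loci with no observed alleles: {empty}")
    A = int(n_alleles.max())
    valid_slot = np.arange(A)[None, :] < n_alleles[:, None]  # (L, A)
    miss = geno[:, :, 0] < 0  # (N, L); both-or-neither missing
    geno_safe = np.where(geno >= 0, geno, 0)
    copy_valid = ~np.repeat(miss[:, :, None], 2, axis=2)  # (N, L, 2)
    n_valid_copies = int(copy_valid.sum())

    clamp_cluster = np.full(N, -1, dtype=np.int64)
    if config.use_reference_labels:
        if reference_clusters is None:
            reference_clusters = default_reference_clusters(table)
        if not reference_clusters:
            raise ValueError("use_reference_labels set but no reference samples found")
        ids = {s.id: i for i, s in enumerate(table.samples)}
        for sid, k in reference_clusters.items():
            if sid not in ids:
                raise ValueError(f"reference id {sid!r} not in table")
            if not (0 <= k < K):
                raise ValueError(f"reference cluster {k} out of range for K={K}")
            clamp_cluster[ids[sid]] = k
    else:
        reference_clusters = {}
    clamped = clamp_cluster >= 0
    free = ~clamped
    n_free = int(free.sum())

    rng = np.random.default_rng(config.seed)
    lam = config.lambda_

    # --- initial state ----------------------------------------------------
    q = np.full((N, K), 1.0 / K)
    if K == 1:
        q[:] = 1.0
    q[clamped] = 0.0
    q[clamped, clamp_cluster[clamped]] = 1.0

    # ancestral frequencies: smoothed observed sample frequencies
    panc = np.zeros((L, A))
    lidx = np.broadcast_to(np.arange(L)[None, :, None], geno.shape)
    flat_l = lidx[copy_valid]
    flat_a = geno_safe[copy_valid]
    np.add.at(panc, (flat_l, flat_a), 1.0)
    panc += lam * valid_slot
    panc /= panc.sum(axis=1, keepdims=True)

    p = np.where(valid_slot[None, :, :], panc[None, :, :], 0.0).repeat(K, axis=0)
    p = np.ascontiguousarray(p.reshape(K, L, A))
    F = np.full(K, config.drift_prior_mean)
    alpha = float(config.alpha_init)

    # gamma prior on drift parameters, parameterised by mean and sd
    f_shape = (config.drift_prior_mean / config.drift_prior_sd) ** 2
    f_scale = config.drift_prior_sd**2 / config.drift_prior_mean
    correlated = config.freq_model == "correlated"

    n_rec = config.n_sweeps // config.thin
    q_samples = np.empty((n_rec, N, K))
    lnl_trace = np.empty(n_rec)
    alpha_trace = np.empty(n_rec)
    p_sum = np.zeros((K, L, A))
    rec = 0

    L_idx = np.arange(L)[None, :, None]  # for p gather
    total_sweeps = config.burn_in + config.n_sweeps

    for sweep in range(total_sweeps):
        # -- z: latent cluster of origin per gene copy ---------------------
        pg = p[:, L_idx, geno_safe]                # (K, N, L, 2)
        w = pg * q.T[:, :, None, None]
        wsum = w.sum(axis=0)
        cdf = np.cumsum(w, axis=0)
        u = rng.random((N, L, 2)) * wsum
        z = (cdf < u[None]).sum(axis=0)            # (N, L, 2) in [0, K)

        zc = z[copy_valid]
        # -- allele counts per (cluster, locus, allele) --------------------
        counts = np.bincount(
            (zc * L + flat_l) * A + flat_a, minlength=K * L * A
        ).reshape(K, L, A).astype(float)

        # -- P: Dirichlet conjugate update ---------------------------------
        if correlated:
            prior = panc[None, :, :] * ((1.0 - F) / F)[:, None, None]
        else:
            prior = np.full((1, L, A), lam)
        shape = np.where(valid_slot[None, :, :], prior + counts, 0.0)
        g = rng.gamma(np.maximum(shape, 0.0))
        gsum = g.sum(axis=2, keepdims=True)
        gsum[gsum == 0] = 1.0
        p = g / gsum
        np.maximum(p, _TINY, where=valid_slot[None, :, :], out=p)

        # -- Q: Dirichlet conjugate update for free individuals ------------
        icopy = np.broadcast_to(np.arange(N)[:, None, None], geno.shape)[copy_valid]
        m = np.bincount(icopy * K + zc, minlength=N * K).reshape(N, K).astype(float)
        gq = rng.gamma(alpha + m)
        gq = np.clip(gq, _TINY, None)
        qnew = gq / gq.sum(axis=1, keepdims=True)
        q[free] = qnew[free]
        # clamped rows stay unit vectors

        # -- alpha: Metropolis random walk ---------------------------------
        if K > 1 and n_free > 0 and config.alpha_proposal_sd > 0:
            prop = alpha + rng.normal(0.0, config.alpha_proposal_sd)
            if 0.0 < prop <= config.alpha_max:
                s_lnq = float(np.log(np.clip(q[free], _TINY, None)).sum())
                delta = (
                    n_free * (gammaln(K * prop) - K * gammaln(prop)
                              - gammaln(K * alpha) + K * gammaln(alpha))
                    + (prop - alpha) * s_lnq
                )
                if np.log(rng.random()) < delta:
                    alpha = prop
            else:
                rng.random()  # keep stream aligned on rejection at bounds

        # -- correlated model: drift F_k and ancestral frequencies ---------
        if correlated:
            for k in range(K):
                prop = F[k] + rng.normal(0.0, config.drift_proposal_sd)
                if not (0.0 < prop < 1.0):
                    continue
                delta = (f_shape - 1.0) * (np.log(prop) - np.log(F[k])) - (
                    prop - F[k]
                ) / f_scale
                for l in range(L):
                    v = valid_slot[l]
                    a_old = panc[l, v] * (1.0 - F[k]) / F[k]
                    a_new = panc[l, v] * (1.0 - prop) / prop
                    delta += _ln_dirichlet(p[k, l, v], a_new) - _ln_dirichlet(
                        p[k, l, v], a_old
                    )
                if np.log(rng.random()) < delta:
                    F[k] = prop

            c_k = (1.0 - F) / F  # (K,)
            for l in range(L):
                nal = int(n_alleles[l])
                if nal < 2:
                    continue
                i, j = rng.choice(nal, size=2, replace=False)
                d = rng.normal(0.0, config.anc_proposal_sd)
                pi_new, pj_new = panc[l, i] + d, panc[l, j] - d
                if pi_new <= 0.0 or pj_new <= 0.0:
                    continue
                delta = (lam - 1.0) * (
                    np.log(pi_new) + np.log(pj_new)
                    - np.log(panc[l, i]) - np.log(panc[l, j])
                )
                delta += float(
                    (
                        -gammaln(c_k * pi_new) - gammaln(c_k * pj_new)
                        + gammaln(c_k * panc[l, i]) + gammaln(c_k * panc[l, j])
                        + c_k * (pi_new - panc[l, i]) * np.log(p[:, l, i])
                        + c_k * (pj_new - panc[l, j]) * np.log(p[:, l, j])
                    ).sum()
                )
                if np.log(rng.random()) < delta:
                    panc[l, i], panc[l, j] = pi_new, pj_new

        # -- record --------------------------------------------------------
        s_post = sweep - config.burn_in
        if s_post >= 0 and (s_post % config.thin) == 0 and rec < n_rec:
            pg = p[:, L_idx, geno_safe]
            mix = np.einsum("nk,knlc->nlc", q, pg)
            lnl_trace[rec] = float(np.log(np.clip(mix, _TINY, None))[copy_valid].sum())
            alpha_trace[rec] = alpha
            q_samples[rec] = q
            p_sum += p
            rec += 1

    q_mean = q_samples.mean(axis=0)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    lo = np.percentile(q_samples, 5.0, axis=0)
    hi = np.percentile(q_samples, 95.0, axis=0)
    # credible bounds always bracket the posterior mean (empirical-percentile
    # intervals can exclude it in extremely skewed cases)
    lo = np.minimum(lo, q_mean)
    hi = np.maximum(hi, q_mean)

    ids = [s.id for s in table.samples]
    cluster_names = [f"cluster_{k}" for k in range(K)]
    q_mean_df = pd.DataFrame(q_mean, index=pd.Index(ids, name="id"), columns=cluster_names)
    ci_cols = pd.MultiIndex.from_product([cluster_names, ["lo", "hi"]])
    ci = np.empty((N, 2 * K))
    ci[:, 0::2] = lo
    ci[:, 1::2] = hi
    q_ci_df = pd.DataFrame(ci, index=q_mean_df.index, columns=ci_cols)

    run_warnings: list[str] = []
    if K > 1 and n_free > 0 and config.alpha_proposal_sd > 0:
        if np.ptp(alpha_trace) < 1e-12:
            msg = "alpha trace is flat; the sampler may not be mixing"
            run_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)

    return AdmixtureRun(
        q_mean=q_mean_df,
        q_ci90=q_ci_df,
        p_mean=p_sum / max(rec, 1),
        alpha_trace=alpha_trace,
        lnl_trace=lnl_trace,
        ln_prob_data=estimate_ln_prob_data(lnl_trace),
        config=config,
        reference_clusters=dict(reference_clusters),
        sample_ids=ids,
        warnings_=run_warnings,
    )


def posterior_summary(
    run: AdmixtureRun, table: GenotypeTable, grouping: GroupingSpec = "population"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean ancestry and the per-individual ancestry table.

    Returns ``(group_means, individual_table)``; the individual table joins
    posterior means with 90% credible bounds and the group label, ready for
    hybrid-class binning.
    """
    labels = table.group_labels(grouping)
    indiv = run.q_mean.copy()
    indiv["group"] = labels
    group_means = indiv.groupby("group", sort=False)[run.cluster_names].mean()
    ci = run.q_ci90.copy()
    ci.columns = [f"{k}_{bound}" for k, bound in ci.columns]
    full = indiv.join(ci)
    return group_means, full


def estimate_ln_prob_data(lnl_trace: np.ndarray) -> float:
    """The model-choice estimate ln P(D) ≈ mean(lnL) − var(lnL)/2.

    ``var`` is the sample variance (ddof=1) of the post-burn-in likelihood
    trace; requires at least two recorded values.
    """
    trace = np.asarray(lnl_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("lnL trace must have length >= 2")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def evanno_delta_k(ln_prob_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """ΔK model-selection table from replicate ln P(D) values per K.

    ΔK(K) = mean_r |L_r(K−1) − 2 L_r(K) + L_r(K+1)| / sd_r L(K), pairing
    replicate runs by index (runs are truncated to the smallest replicate
    count if K values differ). Defined only at interior K with sd > 0;
    undefined entries are NaN. Requires at least three consecutive K values
    and two runs per K.
    """
    ks = sorted(ln_prob_by_k)
    if len(ks) < 3:
        raise ValueError("Evanno's method needs >= 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError(f"K values must be consecutive, got {ks}")
    n_runs = min(len(ln_prob_by_k[k]) for k in ks)
    if n_runs < 2:
        raise ValueError("Evanno's method needs >= 2 runs per K")
    arr = np.array([ln_prob_by_k[k][:n_runs] for k in ks], dtype=float)  # (nk, r)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    delta = np.full(len(ks), np.nan)
    for idx in range(1, len(ks) - 1):
        if sd[idx] > 0:
            second = arr[idx - 1] - 2.0 * arr[idx] + arr[idx + 1]
            delta[idx] = np.abs(second).mean() / sd[idx]
    out = pd.DataFrame(
        {"K": ks, "mean_lnP": mean, "sd_lnP": sd, "delta_K": delta}
    ).set_index("K")
    return out


def align_columns(reference: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Greedy cluster-column matching of ``other`` onto ``reference``.

    For plotting multiple unsupervised runs with consistent colours only;
    supervised runs are already anchored by their reference labels.
    """
    ref = reference.to_numpy()
    oth = other.to_numpy()
    K = ref.shape[1]
    remaining = list(range(K))
    order: list[int] = []
    for j in range(K):
        sims = [float(ref[:, j] @ oth[:, c]) for c in remaining]
        best = remaining.pop(int(np.argmax(sims)))
        order.append(best)
    return other.iloc[:, order].set_axis(list(reference.columns), axis=1)
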