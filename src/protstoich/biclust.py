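"""Nonparametric Bayesian Local Clustering (NoB-LoC) of proteins.

The model partitions proteins into *biclusters* — sets of proteins that
share a local partition of the samples — while allowing both proteins and
samples to opt out as "invariant"/"inactive".  Priors are zero-enriched
Pólya urns: a protein is variant with probability ``pi0`` (default 0.01)
and variant proteins follow a Dirichlet-process urn with concentration
``alpha_protein``; within each bicluster, a sample is active with
probability ``pi0_sample`` and active samples follow their own urn.

The sampling model is conjugate: for protein ``g`` in bicluster ``k``,
the (standardized log) abundances of the samples in subcluster ``j`` are
i.i.d. Normal with a Normal–Inverse-Gamma (m0, k0, a0, b0) prior on their
mean and variance, integrated analytically; invariant proteins and
inactive samples follow a fixed Normal(base_mean, base_sd²) baseline.
Inference is collapsed Gibbs sampling (Neal 2000, Alg. 8 with one
auxiliary component for the new-bicluster move, so the chain targets the
exact joint posterior).  The posterior point estimate is Dahl's
least-squares partition over visited states under the pairwise
co-clustering L1 distance

    H(ω, ω′) = Σ_{g<g′} |I(ω_g = ω_{g′}) − I(ω′_g = ω′_{g′})| .
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln, logsumexp

LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# settings and partition containers


@dataclass
class PriorSettings:
    """Hyperparameters of the zero-enriched NoB-LoC model.

    pi0
        Prior probability that a protein is *variant* (participates in a
        bicluster); 0.01 reflects that most biological responses involve
        a small subset of proteins.
    pi0_sample
        Prior probability that a sample is active within a bicluster.
    alpha_protein, alpha_sample
        Dirichlet-process concentrations of the protein and sample urns.
    m0, k0, a0, b0
        Normal–Inverse-Gamma base measure for block means/variances.
    base_mean, base_sd
        Fixed Normal baseline for invariant proteins and inactive samples
        (rows are standardized before sampling, so N(0, 1) is natural).
    """

    pi0: float = 0.01
    pi0_sample: float = 0.5
    alpha_protein: float = 1.0
    alpha_sample: float = 1.0
    m0: float = 0.0
    k0: float = 0.1
    a0: float = 1.0
    b0: float = 1.0
    base_mean: float = 0.0
    base_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi0 <= 1.0 or not 0.0 < self.pi0_sample <= 1.0:
            raise ValueError("pi0 and pi0_sample must lie in (0, 1]")
        if min(self.alpha_protein, self.alpha_sample) <= 0:
            raise ValueError("DP concentrations must be positive")
        if min(self.k0, self.a0, self.b0, self.base_sd) <= 0:
            raise ValueError("k0, a0, b0, base_sd must be positive")


@dataclass
class BiclusterPartition:
    """Protein membership ``omega`` plus per-bicluster local sample partitions.

    ``omega[g] = 0`` marks protein ``g`` invariant; bicluster labels are
    contiguous ``1..K``.  ``sample_partitions[k][s] = 0`` marks sample
    ``s`` inactive in bicluster ``k``; subcluster labels are ``1..J_k``.
    """

    omega: np.ndarray
    sample_partitions: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=int)
        labels = np.unique(self.omega[self.omega > 0])
        K = self.n_biclusters
        if labels.size and (labels.min() < 1 or labels.max() != labels.size):
            raise ValueError("bicluster labels must be contiguous 1..K")
        for k in range(1, K + 1):
            if k not in self.sample_partitions:
                raise ValueError(f"missing sample partition for bicluster {k}")
            part = np.asarray(self.sample_partitions[k], dtype=int)
            self.sample_partitions[k] = part
            active = np.unique(part[part > 0])
            if active.size and active.max() != active.size:
                raise ValueError(f"subcluster labels of bicluster {k} not contiguous")

    @property
    def n_proteins(self) -> int:
        return self.omega.size

    @property
    def n_biclusters(self) -> int:
        return int(self.omega.max(initial=0))

    @property
    def n_invariant(self) -> int:
        return int((self.omega == 0).sum())

    def copy(self) -> "BiclusterPartition":
        return BiclusterPartition(
            self.omega.copy(), {k: v.copy() for k, v in self.sample_partitions.items()}
        )


@dataclass
class MCMCTrace:
    """Post burn-in partition samples with bookkeeping."""

    partitions: list[BiclusterPartition]
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    loglik_trace: list[float]


def summarize_partition(p: BiclusterPartition) -> dict:
    """Headline counts: biclusters, invariant proteins, sizes, subclusters."""
    K = p.n_biclusters
    sizes = {k: int((p.omega == k).sum()) for k in range(1, K + 1)}
    subclusters = {
        k: int(p.sample_partitions[k].max(initial=0)) for k in range(1, K + 1)
    }
    return {
        "n_biclusters": K,
        "n_invariant": p.n_invariant,
        "bicluster_sizes": sizes,
        "sample_subclusters": subclusters,
    }


# ---------------------------------------------------------------------------
# marginal likelihoods


def _nig_logml(n, s1, s2, m0: float, k0: float, a0: float, b0: float):
    """Log marginal likelihood of n i.i.d. Normal values with an NIG prior,
    from sufficient statistics (count, sum, sum of squares). Vectorized."""
    scalar = np.isscalar(n) or np.ndim(n) == 0
    n = np.atleast_1d(np.asarray(n, dtype=float))
    s1 = np.broadcast_to(np.asarray(s1, dtype=float), n.shape)
    s2 = np.broadcast_to(np.asarray(s2, dtype=float), n.shape)
    out = np.zeros(n.shape)
    pos = n > 0
    if np.any(pos):
        npos, s1p, s2p = n[pos], s1[pos], s2[pos]
        kn = k0 + npos
        an = a0 + npos / 2.0
        ybar = s1p / npos
        ssd = np.maximum(s2p - npos * ybar**2, 0.0)
        bn = b0 + 0.5 * (ssd + k0 * npos * (ybar - m0) ** 2 / kn)
        out[pos] = (
            -0.5 * npos * LOG_2PI
            + 0.5 * (math.log(k0) - np.log(kn))
            + a0 * math.log(b0)
            - an * np.log(bn)
            + gammaln(an)
            - gammaln(a0)
        )
    return float(out[0]) if scalar else out


def block_marginal_loglik(values, priors: PriorSettings | None = None) -> float:
    """Log marginal likelihood of a block of values under the NIG model.

    The block mean and variance are integrated analytically; an empty
    block has marginal likelihood 1 (log 0).
    """
    priors = priors or PriorSettings()
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)] if v.size else v
    if v.size == 0:
        return 0.0
    if not np.all(np.isfinite(v)):
        raise ValueError("block values must be finite")
    return float(
        _nig_logml(v.size, v.sum(), (v**2).sum(), priors.m0, priors.k0, priors.a0, priors.b0)
    )


def _baseline_loglik(values: np.ndarray, priors: PriorSettings) -> float:
    """Fixed-Normal baseline log density for invariant/inactive cells."""
    v = values[np.isfinite(values)]
    if v.size == 0:
        return 0.0
    z = (v - priors.base_mean) / priors.base_sd
    return float(-0.5 * (z**2).sum() - v.size * (math.log(priors.base_sd) + 0.5 * LOG_2PI))


# ---------------------------------------------------------------------------
# Gibbs sampler state


class GibbsState:
    """Mutable sampler state over a fixed (standardized) data matrix.

    ``Y`` holds standardized log abundances with NaN for missing cells.
    """

    def __init__(self, Y: np.ndarray, partition: BiclusterPartition):
        self.Y = np.asarray(Y, dtype=float)
        self.obs = np.isfinite(self.Y)
        self.Yf = np.where(self.obs, self.Y, 0.0)
        self.Y2 = self.Yf**2
        self.G, self.S = self.Y.shape
        self.omega = partition.omega.copy()
        self.parts: list[np.ndarray] = [
            partition.sample_partitions[k].copy() for k in range(1, partition.n_biclusters + 1)
        ]
        if self.omega.size != self.G:
            raise ValueError("partition length does not match data")

    @property
    def n_biclusters(self) -> int:
        return len(self.parts)

    def partition(self) -> BiclusterPartition:
        return BiclusterPartition(
            self.omega.copy(), {k + 1: p.copy() for k, p in enumerate(self.parts)}
        )

    # -- likelihood pieces ---------------------------------------------------

    def row_loglik(self, g: int, labels: np.ndarray, priors: PriorSettings) -> float:
        """Marginal log likelihood of row g under a sample partition."""
        o = self.obs[g]
        ll = _baseline_loglik(np.where((labels == 0) & o, self.Y[g], np.nan), priors)
        for j in range(1, int(labels.max(initial=0)) + 1):
            m = (labels == j) & o
            n = int(m.sum())
            if n:
                ll += float(
                    _nig_logml(
                        n, self.Yf[g, m].sum(), self.Y2[g, m].sum(),
                        priors.m0, priors.k0, priors.a0, priors.b0,
                    )
                )
        return ll

    def loglik(self, priors: PriorSettings) -> float:
        """Collapsed data log likelihood of the current partition."""
        ll = 0.0
        for g in range(self.G):
            k = self.omega[g]
            if k == 0:
                ll += _baseline_loglik(np.where(self.obs[g], self.Y[g], np.nan), priors)
            else:
                ll += self.row_loglik(g, self.parts[k - 1], priors)
        return ll

    def log_prior(self, priors: PriorSettings) -> float:
        """Zero-enriched urn log prior of the current partition."""

        def urn(labels: np.ndarray, pi_in: float, alpha: float) -> float:
            active = labels[labels > 0]
            n_in, n_out = active.size, labels.size - active.size
            lp = n_out * math.log1p(-pi_in) if pi_in < 1 else (0.0 if n_out == 0 else -math.inf)
            lp += n_in * math.log(pi_in)
            if n_in:
                sizes = np.bincount(active)[1:]
                sizes = sizes[sizes > 0]
                lp += sizes.size * math.log(alpha) + float(gammaln(sizes).sum())
                lp -= float(gammaln(alpha + n_in) - gammaln(alpha))
            return lp

        lp = urn(self.omega, priors.pi0, priors.alpha_protein)
        for part in self.parts:
            lp += urn(part, priors.pi0_sample, priors.alpha_sample)
        return lp


def _draw_prior_sample_partition(S: int, priors: PriorSettings, rng: np.random.Generator) -> np.ndarray:
    """Draw a local sample partition from the zero-enriched urn prior."""
    labels = np.zeros(S, dtype=int)
    sizes: list[int] = []
    for s in range(S):
        if rng.random() >= priors.pi0_sample:
            continue
        n_act = sum(sizes)
        probs = np.array(sizes + [priors.alpha_sample], dtype=float) / (n_act + priors.alpha_sample)
        j = rng.choice(probs.size, p=probs)
        if j == len(sizes):
            sizes.append(1)
        else:
            sizes[j] += 1
        labels[s] = j + 1
    return labels


def _log_choice(logw: np.ndarray, rng: np.random.Generator) -> int:
    w = np.exp(logw - logw.max())
    return int(rng.choice(w.size, p=w / w.sum()))


def gibbs_update_protein(
    g: int, state: GibbsState, priors: PriorSettings, rng: np.random.Generator
) -> GibbsState:
    """Resample protein g's membership among invariant / existing / new.

    Weights follow the zero-enriched urn conditional: (1−π₀)·L_base for
    invariant; π₀·n_k/(G_v−1+α)·L_k for bicluster k; π₀·α/(G_v−1+α)·L_new
    for a fresh bicluster whose sample partition is an auxiliary draw from
    the prior (Neal Alg. 8, m=1), keeping the collapsed chain exact.
    """
    k_old = state.omega[g]
    state.omega[g] = 0
    aux_part: np.ndarray
    if k_old > 0 and not np.any(state.omega == k_old):
        # g was a singleton: its old partition is the auxiliary component
        aux_part = state.parts.pop(k_old - 1)
        state.omega[state.omega > k_old] -= 1
    else:
        aux_part = _draw_prior_sample_partition(state.S, priors, rng)

    n_variant = int((state.omega > 0).sum())
    denom = math.log(n_variant + priors.alpha_protein)
    row_all = np.where(state.obs[g], state.Y[g], np.nan)
    logw = [math.log1p(-priors.pi0) + _baseline_loglik(row_all, priors)] if priors.pi0 < 1 else [-math.inf]
    lpi0 = math.log(priors.pi0)
    for k, part in enumerate(state.parts, start=1):
        n_k = int((state.omega == k).sum())
        logw.append(lpi0 + math.log(n_k) - denom + state.row_loglik(g, part, priors))
    logw.append(
        lpi0 + math.log(priors.alpha_protein) - denom + state.row_loglik(g, aux_part, priors)
    )
    choice = _log_choice(np.array(logw), rng)
    if choice == 0:
        pass  # invariant
    elif choice <= len(state.parts):
        state.omega[g] = choice
    else:
        state.parts.append(aux_part)
        state.omega[g] = len(state.parts)
    return state


def gibbs_update_samples(
    k: int, state: GibbsState, priors: PriorSettings, rng: np.random.Generator
) -> GibbsState:
    """Resample every sample's subcluster label within bicluster k (1-based).

    Each sample moves among {inactive} ∪ {existing subclusters} ∪ {new}
    by the zero-enriched urn with pi0_sample/alpha_sample; likelihoods are
    products over the bicluster's proteins of NIG marginal ratios.
    """
    part = state.parts[k - 1]
    rows = np.flatnonzero(state.omega == k)
    if rows.size == 0:
        raise ValueError(f"bicluster {k} is empty")
    m0, k0, a0, b0 = priors.m0, priors.k0, priors.a0, priors.b0
    for s in range(state.S):
        old = part[s]
        part[s] = 0
        if old > 0 and not np.any(part == old):
            part[part > old] -= 1
        J = int(part.max(initial=0))
        n_act = int((part > 0).sum())
        denom = math.log(n_act + priors.alpha_sample)
        o_s = state.obs[rows, s]
        y_s = state.Yf[rows, s]
        base = _baseline_loglik(np.where(o_s, state.Y[rows, s], np.nan), priors)
        logw = [math.log1p(-priors.pi0_sample) + base] if priors.pi0_sample < 1 else [-math.inf]
        lpi = math.log(priors.pi0_sample)
        single = _nig_logml(o_s.astype(float), y_s, y_s**2, m0, k0, a0, b0)
        for j in range(1, J + 1):
            m = part == j
            n_j = state.obs[np.ix_(rows, np.flatnonzero(m))].sum(axis=1).astype(float)
            s1 = state.Yf[np.ix_(rows, np.flatnonzero(m))].sum(axis=1)
            s2 = state.Y2[np.ix_(rows, np.flatnonzero(m))].sum(axis=1)
            before = _nig_logml(n_j, s1, s2, m0, k0, a0, b0)
            after = _nig_logml(n_j + o_s, s1 + y_s, s2 + y_s**2, m0, k0, a0, b0)
            logw.append(lpi + math.log(int(m.sum())) - denom + float(np.sum(after - before)))
        logw.append(lpi + math.log(priors.alpha_sample) - denom + float(np.sum(single)))
        choice = _log_choice(np.array(logw), rng)
        part[s] = 0 if choice == 0 else (choice if choice <= J else J + 1)
    return state


# ---------------------------------------------------------------------------
# initialization and the full chain


def init_partition(
    data: np.ndarray,
    n_variant_sets: int = 20,
    invariant_rule: str = "singletons",
) -> BiclusterPartition:
    """Initialize ω from agglomerative clustering of protein rows.

    Rows (mean-imputed where missing) are clustered with Euclidean
    distance and average linkage, the tree is cut into ``n_variant_sets``
    groups, and — under the default ``singletons`` rule — size-1 groups
    are designated invariant.  Each surviving bicluster starts with all
    samples in a single subcluster.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two proteins to initialize")
    if np.isnan(X).any():
        row_mean = np.nanmean(X, axis=1, keepdims=True)
        X = np.where(np.isnan(X), row_mean, X)
    Z = linkage(X, method="average", metric="euclidean")
    raw = fcluster(Z, t=min(n_variant_sets, X.shape[0]), criterion="maxclust")
    omega = np.zeros(X.shape[0], dtype=int)
    next_label = 1
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        if invariant_rule == "singletons" and members.size == 1:
            continue
        omega[members] = next_label
        next_label += 1
    S = X.shape[1]
    parts = {k: np.ones(S, dtype=int) for k in range(1, next_label)}
    return BiclusterPartition(omega, parts)


def _init_sample_partition(
    rows: np.ndarray, priors: PriorSettings, max_subclusters: int = 6
) -> np.ndarray:
    """Data-informed starting sample partition for one bicluster.

    Samples (columns of ``rows``) are average-linkage clustered and the
    tree is cut at each J ≤ ``max_subclusters``; the cut maximizing the
    collapsed likelihood plus the urn prior wins.  All samples start
    active.  This only sets the chain's starting point — the stationary
    distribution is untouched — but one-at-a-time Gibbs moves cannot
    cheaply nucleate a subcluster split inside a large bicluster, so a
    sensible start matters for mixing.
    """
    S = rows.shape[1]
    X = rows.T
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0, keepdims=True)
        X = np.where(np.isnan(X), np.where(np.isfinite(col_mean), col_mean, 0.0), X)
    Z = linkage(X, method="average", metric="euclidean")
    helper = GibbsState(rows, BiclusterPartition(np.zeros(rows.shape[0], dtype=int), {}))
    best_labels = np.ones(S, dtype=int)
    best_score = -math.inf
    for J in range(1, min(max_subclusters, S) + 1):
        labels = fcluster(Z, t=J, criterion="maxclust").astype(int)
        score = sum(helper.row_loglik(g, labels, priors) for g in range(rows.shape[0]))
        sizes = np.bincount(labels)[1:]
        score += float(
            len(sizes) * math.log(priors.alpha_sample)
            + gammaln(sizes).sum()
            - (gammaln(priors.alpha_sample + S) - gammaln(priors.alpha_sample))
        )
        if score > best_score:
            best_score, best_labels = score, labels
    return best_labels


def _standardize_rows(Y: np.ndarray) -> np.ndarray:
    mean = np.nanmean(Y, axis=1, keepdims=True)
    sd = np.nanstd(Y, axis=1, ddof=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (Y - mean) / sd


def run_mcmc(
    data,
    priors: PriorSettings | None = None,
    n_iter: int = 35_000,
    burn_in: int = 5_000,
    thin: int = 1,
    seed: int = 0,
    init: str | BiclusterPartition = "hclust",
    n_init_sets: int | None = None,
    sample_init: str = "hclust",
    standardize: bool = True,
    log_scale: bool = False,
) -> MCMCTrace:
    """Run the collapsed Gibbs sampler and return post burn-in partitions.

    ``data`` is a protein×sample matrix (an :class:`AbundanceMatrix`'s
    peak areas, log-transformed unless ``log_scale`` says they already
    are; NaN marks missing) or a plain ndarray of log abundances.  One
    iteration is a full protein sweep followed by a sample sweep over
    every bicluster.  Rows are standardized by default so clustering is
    by response pattern, not mean abundance.
    """
    from .abundance import AbundanceMatrix

    priors = priors or PriorSettings()
    if isinstance(data, AbundanceMatrix):
        vals = np.where(data.missing_mask, np.nan, data.values)
        obs = ~data.missing_mask
        if np.any(vals[obs] <= 0):
            raise ValueError("peak areas must be positive for log transform")
        Y = np.log(vals) if not log_scale else vals
    else:
        Y = np.asarray(data, dtype=float)
    if np.isinf(Y).any():
        raise ValueError("data must be finite (NaN marks missing)")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if standardize:
        Y = _standardize_rows(Y)
    if isinstance(init, BiclusterPartition):
        start = init
    elif init == "hclust":
        # over-splitting at init is the safe bias: same-partition sets merge
        # during sampling, while splitting a merged set mixes poorly
        if n_init_sets is None:
            n_init_sets = max(20, Y.shape[0] // 5)
        start = init_partition(Y, n_variant_sets=n_init_sets)
    elif init == "all_invariant":
        start = BiclusterPartition(np.zeros(Y.shape[0], dtype=int), {})
    else:
        raise ValueError(f"unknown init: {init}")
    if sample_init == "hclust":
        for k in range(1, start.n_biclusters + 1):
            rows = Y[start.omega == k]
            start.sample_partitions[k] = _init_sample_partition(rows, priors)
    elif sample_init != "single":
        raise ValueError(f"unknown sample_init: {sample_init}")
    rng = np.random.default_rng(seed)
    state = GibbsState(Y, start)
    partitions: list[BiclusterPartition] = []
    loglik: list[float] = []
    for it in range(n_iter):
        # sample pass first: a freshly initialized bicluster carries a
        # single all-sample subcluster, and its local partition must adapt
        # before the protein pass judges memberships against it
        for k in range(1, state.n_biclusters + 1):
            gibbs_update_samples(k, state, priors, rng)
        for g in range(state.G):
            gibbs_update_protein(g, state, priors, rng)
        if it >= burn_in and (it - burn_in) % thin == 0:
            partitions.append(state.partition())
            loglik.append(state.loglik(priors) + state.log_prior(priors))
    return MCMCTrace(partitions, n_iter, burn_in, thin, seed, loglik)


# ---------------------------------------------------------------------------
# partition summaries and distances


def coclustering_indicator(omega: np.ndarray) -> np.ndarray:
    """G×G binary matrix with entry 1 iff ω_g = ω_{g'} (literal equality:
    two invariant proteins count as co-clustered)."""
    om = np.asarray(omega)
    return (om[:, None] == om[None, :]).astype(np.uint8)


def partition_distance(omega: np.ndarray, omega_prime: np.ndarray) -> int:
    """H(ω, ω′): L1 distance between co-clustering indicators over
    unordered protein pairs."""
    a = np.asarray(omega)
    b = np.asarray(omega_prime)
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    da = a[:, None] == a[None, :]
    db = b[:, None] == b[None, :]
    return int((da != db).sum() // 2)


def posterior_coclustering(trace: MCMCTrace) -> np.ndarray:
    """Mean co-clustering indicator across the trace."""
    if not trace.partitions:
        raise ValueError("empty trace")
    G = trace.partitions[0].n_proteins
    acc = np.zeros((G, G))
    for p in trace.partitions:
        acc += coclustering_indicator(p.omega)
    return acc / len(trace.partitions)


def least_squares_partition(trace: MCMCTrace) -> tuple[BiclusterPartition, np.ndarray]:
    """Dahl's least-squares point estimate restricted to visited partitions.

    Returns the sampled partition minimizing the summed pairwise
    co-clustering distance to all trace samples (earliest minimizer on
    ties) and the distribution of H(ω_t, ω^LS) scaled by the number of
    protein pairs, as an uncertainty diagnostic.
    """
    if not trace.partitions:
        raise ValueError("empty trace")
    omegas = [p.omega for p in trace.partitions]
    T, G = len(omegas), omegas[0].size
    iu = np.triu_indices(G, 1)
    counts = np.zeros(iu[0].size, dtype=np.int64)
    for om in omegas:
        counts += (om[:, None] == om[None, :])[iu]
    base = counts.sum()
    costs = np.empty(T, dtype=np.int64)
    for t, om in enumerate(omegas):
        d = (om[:, None] == om[None, :])[iu]
        costs[t] = base + int(d @ (T - 2 * counts))
    best = int(np.argmin(costs))
    d_best = (omegas[best][:, None] == omegas[best][None, :])[iu]
    n_pairs = G * (G - 1) // 2
    scaled = np.array(
        [int(((om[:, None] == om[None, :])[iu] != d_best).sum()) / n_pairs for om in omegas]
    )
    return trace.partitions[best].copy(), scaled


def recovery_ari(truth: np.ndarray, omega: np.ndarray) -> float:
    """Adjusted Rand index between a planted membership and an estimate
    (label 0 = invariant is treated as its own class)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(np.asarray(truth), np.asarray(omega)))


# ---------------------------------------------------------------------------
# exact enumeration oracle (tiny instances)


def _set_partitions(items: list[int]):
    """Yield all set partitions of ``items`` as lists of lists."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _zero_enriched_partitions(n: int):
    """Yield (inactive_set, blocks) over all zero-enriched partitions of
    range(n)."""
    idx = list(range(n))
    for r in range(n + 1):
        for active in itertools.combinations(idx, r):
            inactive = [i for i in idx if i not in active]
            for blocks in _set_partitions(list(active)):
                yield inactive, blocks


def _urn_log_prior(n_total: int, blocks: list[list[int]], pi_in: float, alpha: float) -> float:
    n_in = sum(len(b) for b in blocks)
    n_out = n_total - n_in
    if pi_in < 1:
        lp = n_out * math.log1p(-pi_in)
    elif n_out:
        return -math.inf
    else:
        lp = 0.0
    lp += n_in * math.log(pi_in) if n_in else 0.0
    if blocks:
        lp += len(blocks) * math.log(alpha)
        lp += sum(math.lgamma(len(b)) for b in blocks)
        lp -= math.lgamma(alpha + n_in) - math.lgamma(alpha)
    return lp


def _bicluster_evidence(Y: np.ndarray, rows: tuple[int, ...], priors: PriorSettings) -> float:
    """log Σ over local sample partitions of prior × likelihood for a
    fixed protein block (samples marginalized out)."""
    S = Y.shape[1]
    terms = []
    for inactive, blocks in _zero_enriched_partitions(S):
        lp = _urn_log_prior(S, blocks, priors.pi0_sample, priors.alpha_sample)
        for g in rows:
            lp += _baseline_loglik(Y[g, inactive], priors)
            for b in blocks:
                lp += block_marginal_loglik(Y[g, b][np.isfinite(Y[g, b])], priors)
        terms.append(lp)
    return float(logsumexp(terms))


def enumerate_posterior(Y: np.ndarray, priors: PriorSettings | None = None) -> dict:
    """Exact posterior over zero-enriched protein biclusterings (G ≤ ~4).

    Enumerates every protein partition with an invariant set, marginalizes
    each bicluster's local sample partition by enumeration, and returns
    the G×G posterior co-clustering probability matrix (literal ω-equality
    convention), the log evidence, and the per-partition posterior.
    """
    priors = priors or PriorSettings()
    Y = np.asarray(Y, dtype=float)
    G = Y.shape[0]
    cache: dict[tuple[int, ...], float] = {}

    def evidence(rows: tuple[int, ...]) -> float:
        if rows not in cache:
            cache[rows] = _bicluster_evidence(Y, rows, priors)
        return cache[rows]

    log_weights = []
    configs = []
    for inactive, blocks in _zero_enriched_partitions(G):
        lp = _urn_log_prior(G, blocks, priors.pi0, priors.alpha_protein)
        for g in inactive:
            lp += _baseline_loglik(Y[g][np.isfinite(Y[g])], priors)
        for b in blocks:
            lp += evidence(tuple(sorted(b)))
        log_weights.append(lp)
        configs.append((inactive, blocks))
    log_weights = np.array(log_weights)
    log_evidence = float(logsumexp(log_weights))
    probs = np.exp(log_weights - log_evidence)
    cocluster = np.zeros((G, G))
    posterior = []
    for p, (inactive, blocks) in zip(probs, configs):
        omega = np.zeros(G, dtype=int)
        for k, b in enumerate(blocks, start=1):
            omega[b] = k
        cocluster += p * coclustering_indicator(omega)
        posterior.append((omega, float(p)))
    return {
        "coclustering": cocluster,
        "log_evidence": log_evidence,
        "partitions": posterior,
    }


def enumerate_sample_coassignment(Yk: np.ndarray, priors: PriorSettings | None = None) -> np.ndarray:
    """Exact S×S posterior co-assignment matrix for the samples of a single
    bicluster containing all rows of ``Yk`` (S ≤ ~4); entry (s, s′) is the
    probability the two samples carry equal labels (inactive included)."""
    priors = priors or PriorSettings()
    Yk = np.asarray(Yk, dtype=float)
    S = Yk.shape[1]
    terms, configs = [], []
    for inactive, blocks in _zero_enriched_partitions(S):
        lp = _urn_log_prior(S, blocks, priors.pi0_sample, priors.alpha_sample)
        for g in range(Yk.shape[0]):
            lp += _baseline_loglik(Yk[g, inactive], priors)
            for b in blocks:
                lp += block_marginal_loglik(Yk[g, b][np.isfinite(Yk[g, b])], priors)
        terms.append(lp)
        configs.append((inactive, blocks))
    terms = np.array(terms)
    probs = np.exp(terms - logsumexp(terms))
    co = np.zeros((S, S))
    for p, (inactive, blocks) in zip(probs, configs):
        labels = np.zeros(S, dtype=int)
        for j, b in enumerate(blocks, start=1):
            labels[b] = j
        co += p * (labels[:, None] == labels[None, :])
    return co
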