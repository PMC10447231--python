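"""Dirichlet-process mixture clustering of mutations in CCF space.

Mutations are clustered by their per-sample cancer-cell fractions using a
truncated stick-breaking Gibbs sampler with binomial emissions
``v ~ Binom(d, expected_vaf(ccf, purity, CN, m))``.  Cluster CCFs live on
a discrete grid over [0, 1.2] (slack above 1 absorbs noise), which makes
the per-cluster CCF update an exact categorical draw and keeps the whole
sweep vectorized.

The sampler is deterministic given the seed.  A short greedy "annealed"
initialization phase (data-seeded centers, hard assignments) precedes the
Gibbs chain; its objective is monotonically non-decreasing by
construction.  Post-burn-in partitions are summarized through the
posterior-similarity matrix and an average-linkage cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from .core_io import CountMatrix, SampleMeta, SegmentIndex

logger = logging.getLogger(__name__)

_CCF_MAX = 1.2
_GRID_STEP = 0.01
CCF_GRID = np.round(np.arange(0.0, _CCF_MAX + 1e-9, _GRID_STEP), 10)


class DegenerateInputError(ValueError):
    """Raised for observations that cannot be clustered (e.g. zero depth)."""


@dataclass
class MutationObservation:
    """One mutation's counts and copy-number context across samples."""

    site_index: int
    v: np.ndarray  # (S,)
    d: np.ndarray  # (S,)
    n_major: np.ndarray  # (S,)
    n_minor: np.ndarray  # (S,)
    multiplicity: np.ndarray  # (S,) mutant-allele copies, >= 1
    excluded: bool = False
    exclude_reason: str = ""

    def __post_init__(self) -> None:
        for name in ("v", "d", "n_major", "n_minor", "multiplicity"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if (self.multiplicity < 1).any():
            raise ValueError("multiplicity must be >= 1")
        if (self.multiplicity > np.maximum(self.n_major, 1)).any():
            raise ValueError("multiplicity must be <= n_major")


@dataclass
class Cluster:
    cluster_id: int
    ccf: np.ndarray  # (S,) cancer-cell fraction per sample
    n_assigned: int
    assign_prob: np.ndarray | None = None  # (N,) membership posterior


@dataclass
class ClusterConfig:
    n_iter: int = 2000
    burn_in: int = 1000
    conc_shape: float = 1.0
    conc_rate: float = 1.0
    max_clusters: int = 30
    seed: int = 0
    thin: int = 5
    init_iters: int = 20
    min_cluster_frac: float = 0.01  # smaller clusters merged into neighbors
    err_floor: float = 1e-3  # emission-model sequencing-error floor
    consensus_bandwidth: float = 0.08  # mean-shift bandwidth on posterior means

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")


@dataclass
class ClusteringResult:
    clusters: list[Cluster]
    assignments: np.ndarray  # (N,) index into clusters
    sample_ids: list[str]
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    init_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    psm: np.ndarray | None = None

    @property
    def ccf_matrix(self) -> np.ndarray:
        return np.array([c.ccf for c in self.clusters])


def expected_vaf(ccf: float, purity: float, n_major: int, n_minor: int,
                 m: int = 1) -> float:
    """Expected VAF of a mutation at cancer-cell fraction ``ccf``.

    xi = purity*ccf*m / (purity*(n_major+n_minor) + (1-purity)*2),
    clipped to [0, 1).
    """
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if ccf < 0:
        raise ValueError(f"ccf must be >= 0, got {ccf}")
    denom = purity * (n_major + n_minor) + (1.0 - purity) * 2.0
    return float(np.clip(purity * ccf * m / denom, 0.0, 1.0 - 1e-12))


def estimate_multiplicity(v: int, d: int, purity: float, n_major: int,
                          n_minor: int) -> int:
    """Integer mutant multiplicity estimate, in [1, max(n_major, 1)].

    Defaults to 1; bumped only when the observed VAF clearly exceeds the
    single-copy clonal expectation (factor 1.5).
    """
    if d == 0 or n_major <= 1:
        return 1
    xi1 = expected_vaf(1.0, purity, n_major, n_minor, 1)
    vaf = v / d
    if vaf <= 1.5 * xi1:
        return 1
    denom = purity * (n_major + n_minor) + (1.0 - purity) * 2.0
    m = int(round(vaf * denom / purity))
    return max(1, min(m, n_major))


def observations_from_counts(
    counts: CountMatrix,
    segments: SegmentIndex | None = None,
    estimate_m: bool = True,
    exclude_chroms: tuple[str, ...] = ("X", "Y", "chrX", "chrY"),
) -> list[MutationObservation]:
    """Build clustering observations from a count matrix plus CN segments.

    Sex-chromosome mutations are flagged ``excluded`` (clustered post hoc
    by maximum likelihood rather than sampled).
    """
    n_sites, n_samples = counts.var_reads.shape
    obs = []
    for i in range(n_sites):
        site = counts.sites[i]
        nmaj = np.ones(n_samples, dtype=np.int64)
        nmin = np.ones(n_samples, dtype=np.int64)
        if segments is not None:
            for s, meta in enumerate(counts.samples):
                nmaj[s], nmin[s] = segments.lookup(meta.sample_id, site.chrom, site.pos)
        mult = np.ones(n_samples, dtype=np.int64)
        if estimate_m:
            for s, meta in enumerate(counts.samples):
                mult[s] = estimate_multiplicity(
                    int(counts.var_reads[i, s]), int(counts.depth[i, s]),
                    meta.purity, int(nmaj[s]), int(nmin[s]),
                )
        excluded = site.chrom in exclude_chroms
        obs.append(
            MutationObservation(
                site_index=i, v=counts.var_reads[i], d=counts.depth[i],
                n_major=nmaj, n_minor=nmin, multiplicity=mult,
                excluded=excluded,
                exclude_reason="sex_chromosome" if excluded else "",
            )
        )
    return obs


# ---------------------------------------------------------------------------
# Gibbs machinery
# ---------------------------------------------------------------------------

def _emission_table(v: np.ndarray, d: np.ndarray, coef: np.ndarray,
                    err_floor: float = 1e-3) -> np.ndarray:
    """Per-(mutation, sample, grid) binomial log-likelihood table.

    coef[i, s] maps CCF to expected VAF: xi = clip(coef * ccf).  The lower
    clip (``err_floor``) models the sequencing-error floor: without it a
    single background-error read would dominate the likelihood and pin
    mutations to spurious near-zero-CCF components.  Constant binomial
    coefficients are dropped (they cancel in every conditional the
    sampler uses).
    """
    xi = np.clip(coef[:, :, None] * CCF_GRID[None, None, :], err_floor, 1.0 - 1e-9)
    return (
        v[:, :, None] * np.log(xi)
        + (d - v)[:, :, None] * np.log1p(-xi)
    )


def _sample_alpha(alpha: float, n: int, k: int, shape: float, rate: float,
                  rng: np.random.Generator) -> float:
    """Escobar-West auxiliary-variable update of the DP concentration."""
    eta = rng.beta(alpha + 1.0, n)
    odds = (shape + k - 1.0) / (n * (rate - np.log(eta)))
    pi_eta = odds / (1.0 + odds)
    if rng.random() < pi_eta:
        return rng.gamma(shape + k, 1.0 / (rate - np.log(eta)))
    return rng.gamma(shape + k - 1.0, 1.0 / (rate - np.log(eta)))


def _categorical_rows(logp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one index per row of a (N, K) log-probability matrix."""
    g = rng.gumbel(size=logp.shape)
    return np.argmax(logp + g, axis=1)


def geweke_z(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke-style z-score comparing early vs late chain means.

    Standard errors come from batch means, which absorbs the
    autocorrelation of an MCMC trace (an iid variance estimate would
    inflate the score).
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    a = trace[: max(int(first * n), 4)]
    b = trace[-max(int(last * n), 4):]

    def batch_se(x: np.ndarray) -> float:
        n_batches = max(min(10, x.size // 4), 2)
        batches = np.array_split(x, n_batches)
        means = np.array([bb.mean() for bb in batches])
        return float(np.sqrt(means.var(ddof=1) / n_batches))

    denom = np.hypot(batch_se(a), batch_se(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def gibbs_cluster(
    observations: list[MutationObservation],
    samples: list[SampleMeta],
    cfg: ClusterConfig,
) -> ClusteringResult:
    """Cluster mutations in per-sample CCF space under a DP mixture.

    Returns the consensus partition (posterior-similarity average-linkage
    cut), per-cluster grid-MAP CCFs, and chain diagnostics.  Excluded
    observations are assigned post hoc by maximum likelihood.
    """
    active = [o for o in observations if not o.excluded]
    if not active:
        raise DegenerateInputError("no clusterable observations")
    zero_depth = [o.site_index for o in active if o.d.sum() == 0]
    if zero_depth:
        raise DegenerateInputError(
            f"mutations with zero depth in every sample: {zero_depth[:10]}"
        )
    rng = np.random.default_rng(cfg.seed)
    S = len(samples)
    purity = np.array([m.purity for m in samples])

    v = np.array([o.v for o in active], dtype=float)
    d = np.array([o.d for o in active], dtype=float)
    nmaj = np.array([o.n_major for o in active], dtype=float)
    nmin = np.array([o.n_minor for o in active], dtype=float)
    mult = np.array([o.multiplicity for o in active], dtype=float)
    N = v.shape[0]
    K = min(cfg.max_clusters, N)
    G = CCF_GRID.size

    denom = purity[None, :] * (nmaj + nmin) + (1.0 - purity[None, :]) * 2.0
    coef = purity[None, :] * mult / denom  # xi = coef * ccf
    L = _emission_table(v, d, coef, err_floor=cfg.err_floor)  # (N, S, G)

    # --- data-seeded greedy initialization (monotone objective) ---
    with np.errstate(divide="ignore", invalid="ignore"):
        naive_ccf = np.clip(np.where(d > 0, v / np.maximum(d, 1), 0.0) / coef,
                            0.0, _CCF_MAX)
    seed_idx = rng.choice(N, size=K, replace=N < K)
    gidx = np.clip(
        np.round(naive_ccf[seed_idx] / _GRID_STEP).astype(int), 0, G - 1
    )  # (K, S) grid indices of cluster CCFs

    def loglik_at(gidx_: np.ndarray) -> np.ndarray:
        ll = np.zeros((N, K))
        for s in range(S):
            ll += L[:, s, :][:, gidx_[:, s]]
        return ll

    init_trace = []
    z = np.argmax(loglik_at(gidx), axis=1)
    for _ in range(cfg.init_iters):
        # M-step: grid-MAP CCF per occupied cluster
        for k in np.unique(z):
            gidx[k] = np.argmax(L[z == k].sum(axis=0), axis=1)
        ll = loglik_at(gidx)
        z = np.argmax(ll, axis=1)
        init_trace.append(float(ll[np.arange(N), z].sum()))

    # --- Gibbs chain ---
    alpha = 1.0
    psm = np.zeros((N, N))
    mean_ccf = np.zeros((N, S))  # posterior mean CCF per mutation
    n_saved = 0
    trace = []
    L_flat = L.reshape(N, S * G)
    for it in range(cfg.n_iter):
        counts_k = np.bincount(z, minlength=K)
        # cluster CCFs: exact categorical draw on the grid per sample,
        # vectorized over (cluster, sample) via a one-hot scatter-sum
        onehot = np.zeros((K, N))
        onehot[z, np.arange(N)] = 1.0
        M = (onehot @ L_flat).reshape(K, S, G)
        M -= M.max(axis=2, keepdims=True)
        P = np.exp(M)
        P /= P.sum(axis=2, keepdims=True)
        cum = P.cumsum(axis=2)
        u = rng.random((K, S, 1))
        gidx = (cum < u).sum(axis=2)
        # stick-breaking weights
        remaining = counts_k[::-1].cumsum()[::-1]
        tail = np.concatenate([remaining[1:], [0]])
        sticks = rng.beta(1.0 + counts_k, alpha + tail)
        sticks[-1] = 1.0
        log_sticks = np.log(np.clip(sticks, 1e-300, 1.0))
        log1m = np.log(np.clip(1.0 - sticks, 1e-300, 1.0))
        log_w = log_sticks + np.concatenate([[0.0], np.cumsum(log1m[:-1])])
        # assignments
        ll = loglik_at(gidx)
        z = _categorical_rows(ll + log_w[None, :], rng)
        # concentration
        k_occ = int((np.bincount(z, minlength=K) > 0).sum())
        alpha = _sample_alpha(alpha, N, k_occ, cfg.conc_shape, cfg.conc_rate, rng)
        trace.append(float(ll[np.arange(N), z].sum()))
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            psm += z[:, None] == z[None, :]
            mean_ccf += CCF_GRID[gidx][z]
            n_saved += 1
    psm /= max(n_saved, 1)
    mean_ccf /= max(n_saved, 1)

    # --- consensus partition ---
    # Mutations of one clone share a posterior-mean CCF even when the
    # chain keeps several interchangeable components alive for it.
    # Cluster centers are the density peaks of the posterior-mean
    # vectors (mean shift); mutations that sit between two peaks
    # (genuinely ambiguous counts) are pulled to one of them instead of
    # forming phantom intermediate clusters.  The PSM is kept as a
    # diagnostic.
    if N > 1:
        from sklearn.cluster import MeanShift

        ms = MeanShift(bandwidth=cfg.consensus_bandwidth, bin_seeding=True,
                       min_bin_freq=max(2, int(0.005 * N)))
        labels = ms.fit_predict(mean_ccf)
    else:
        labels = np.zeros(1, dtype=int)

    labels, cluster_ccf = _finalize_clusters(L, labels, cfg.min_cluster_frac)
    n_clusters = cluster_ccf.shape[0]

    # responsibilities under the final clusters (for reporting)
    sizes = np.bincount(labels, minlength=n_clusters).astype(float)
    ll_final = np.zeros((N, n_clusters))
    gi = np.clip(np.round(cluster_ccf / _GRID_STEP).astype(int), 0, G - 1)
    for s in range(S):
        ll_final += L[:, s, :][:, gi[:, s]]
    lw = ll_final + np.log(sizes / sizes.sum())[None, :]
    lw -= lw.max(axis=1, keepdims=True)
    resp = np.exp(lw)
    resp /= resp.sum(axis=1, keepdims=True)

    # map back to full observation list; ML-assign excluded observations
    full_n = len(observations)
    full_assign = np.full(full_n, -1, dtype=int)
    active_pos = [j for j, o in enumerate(observations) if not o.excluded]
    for row, j in enumerate(active_pos):
        full_assign[j] = labels[row]
    for j, o in enumerate(observations):
        if o.excluded:
            full_assign[j] = _ml_assign(o, samples, cluster_ccf)

    clusters = []
    full_sizes = np.bincount(full_assign, minlength=n_clusters)
    for k in range(n_clusters):
        prob = np.zeros(full_n)
        for row, j in enumerate(active_pos):
            prob[j] = resp[row, k]
        for j, o in enumerate(observations):
            if o.excluded and full_assign[j] == k:
                prob[j] = 1.0
        clusters.append(
            Cluster(
                cluster_id=k, ccf=cluster_ccf[k],
                n_assigned=int(full_sizes[k]), assign_prob=prob,
            )
        )
    return ClusteringResult(
        clusters=clusters,
        assignments=full_assign,
        sample_ids=[m.sample_id for m in samples],
        loglik_trace=np.array(trace),
        init_trace=np.array(init_trace),
        psm=psm,
    )


def _finalize_clusters(L: np.ndarray, labels: np.ndarray,
                       min_frac: float, merge_tol: float = 0.05,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Refine the consensus partition and compute grid-MAP CCFs.

    Hard-EM refinement (grid-MAP CCF update + ML reassignment) dissolves
    phantom consensus clusters; clusters whose CCFs end up within
    ``merge_tol`` in every sample are merged; clusters below the
    ``min_frac`` size threshold are merged into their nearest neighbor.
    """
    N, S, G = L.shape

    def map_ccf(lab: np.ndarray) -> np.ndarray:
        ks = np.unique(lab)
        ccf = np.zeros((ks.size, S))
        for j, k in enumerate(ks):
            ccf[j] = CCF_GRID[np.argmax(L[lab == k].sum(axis=0), axis=1)]
        return ccf

    def reassign(lab: np.ndarray, ccf: np.ndarray) -> np.ndarray:
        gi = np.clip(np.round(ccf / _GRID_STEP).astype(int), 0, G - 1)
        ll = np.zeros((N, ccf.shape[0]))
        for s in range(S):
            ll += L[:, s, :][:, gi[:, s]]
        return np.argmax(ll, axis=1)

    def soft_em(ccf0: np.ndarray, w0: np.ndarray, n_iter: int = 200,
                tol: float = 1e-7):
        """Finite-mixture EM on the CCF grid from given centers/weights.

        Returns (marginal loglik, centers, weights, responsibilities).
        """
        ccf_c = ccf0.copy()
        w = w0.copy()
        ll_prev = -np.inf
        resp = None
        for _ in range(n_iter):
            gi = np.clip(np.round(ccf_c / _GRID_STEP).astype(int), 0, G - 1)
            ll = np.zeros((N, ccf_c.shape[0]))
            for s in range(S):
                ll += L[:, s, :][:, gi[:, s]]
            lw = ll + np.log(np.maximum(w, 1e-300))[None, :]
            m = lw.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(lw - m).sum(axis=1))
            marg = float(lse.sum())
            resp = np.exp(lw - lse[:, None])
            w = resp.mean(axis=0)
            # M-step: responsibility-weighted grid MAP per component/sample
            for k in range(ccf_c.shape[0]):
                wk = resp[:, k]
                if wk.sum() < 1e-9:
                    continue
                score = np.einsum("i,isg->sg", wk, L)
                ccf_c[k] = CCF_GRID[np.argmax(score, axis=1)]
            if marg - ll_prev < tol * max(abs(marg), 1.0):
                ll_prev = marg
                break
            ll_prev = marg
        return ll_prev, ccf_c, w, resp

    # compact labels from the consensus partition
    _, labels = np.unique(labels, return_inverse=True)
    ccf = map_ccf(labels)
    w = np.bincount(labels, minlength=ccf.shape[0]).astype(float) / N
    ll_best, ccf, w, resp = soft_em(ccf, w)
    # backward selection: drop components while BIC improves.  A phantom
    # component sitting between two real clones barely raises the
    # marginal likelihood and is removed here.
    while ccf.shape[0] > 1:
        penalty = 0.5 * (S + 1) * np.log(N)
        candidates = np.argsort(w)[: min(3, ccf.shape[0])]
        best_drop = None
        for k in candidates:
            keep = [j for j in range(ccf.shape[0]) if j != k]
            ll_k, ccf_k, w_k, resp_k = soft_em(
                ccf[keep].copy(), w[keep] / w[keep].sum()
            )
            if ll_k - ll_best >= -penalty and (
                best_drop is None or ll_k > best_drop[0]
            ):
                best_drop = (ll_k, ccf_k, w_k, resp_k)
        if best_drop is None:
            break
        ll_best, ccf, w, resp = best_drop
    labels = np.argmax(resp, axis=1)
    _, labels = np.unique(labels, return_inverse=True)
    ccf = map_ccf(labels)
    # iteratively merge clusters below the size threshold
    while True:
        sizes = np.bincount(labels)
        small = [k for k in range(sizes.size) if sizes[k] < min_frac * N]
        if not small or sizes.size <= 1:
            break
        k = min(small, key=lambda k: sizes[k])
        others = [j for j in range(sizes.size) if j != k]
        nearest = min(
            others, key=lambda j: float(np.sum((ccf[j] - ccf[k]) ** 2))
        )
        labels[labels == k] = nearest
        _, labels = np.unique(labels, return_inverse=True)
        ccf = map_ccf(labels)
    # deterministic ordering: by descending total CCF, then lexicographic
    order = sorted(
        range(ccf.shape[0]),
        key=lambda k: (-float(ccf[k].sum()), tuple(-ccf[k])),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[k] for k in labels])
    return labels, ccf[order]


def _ml_assign(o: MutationObservation, samples: list[SampleMeta],
               cluster_ccf: np.ndarray) -> int:
    """Maximum-likelihood cluster for a single held-out observation."""
    best_k, best_ll = 0, -np.inf
    for k in range(cluster_ccf.shape[0]):
        ll = 0.0
        for s, meta in enumerate(samples):
            xi = expected_vaf(
                float(cluster_ccf[k, s]), meta.purity,
                int(o.n_major[s]), int(o.n_minor[s]), int(o.multiplicity[s]),
            )
            xi = min(max(xi, 1e-3), 1 - 1e-9)
            ll += o.v[s] * np.log(xi) + (o.d[s] - o.v[s]) * np.log1p(-xi)
        if ll > best_ll:
            best_k, best_ll = k, ll
    return best_k


def cluster_1d(
    observations: list[MutationObservation],
    samples: list[SampleMeta],
    sample_id: str,
    cfg: ClusterConfig,
) -> ClusteringResult:
    """Single-sample clustering: the n-dimensional sampler restricted to one
    sample (identical code path and seed schedule)."""
    s = [m.sample_id for m in samples].index(sample_id)
    obs1 = [
        MutationObservation(
            site_index=o.site_index, v=o.v[s : s + 1], d=o.d[s : s + 1],
            n_major=o.n_major[s : s + 1], n_minor=o.n_minor[s : s + 1],
            multiplicity=o.multiplicity[s : s + 1],
            excluded=o.excluded, exclude_reason=o.exclude_reason,
        )
        for o in observations
    ]
    return gibbs_cluster(obs1, [samples[s]], cfg)


# ---------------------------------------------------------------------------
# Consensus across runs
# ---------------------------------------------------------------------------

def consensus_clustering(
    runs: list[ClusteringResult],
    split_threshold: float = 0.1,
    min_split_frac: float = 0.05,
) -> ClusteringResult:
    """Merge a core clustering with enrichment runs over sample subsets.

    The first run defines the skeleton.  An enrichment run may split a
    core cluster only when it partitions the cluster's mutations into
    groups whose CCF centroids (in the enrichment run's own samples)
    differ by more than ``split_threshold`` in at least one sample, each
    group holding at least ``min_split_frac`` of the cluster.
    """
    if not runs:
        raise ValueError("need at least one clustering run")
    core = runs[0]
    n = core.assignments.size
    for r in runs[1:]:
        if r.assignments.size != n:
            raise ValueError("runs do not share a mutation universe")
    labels = core.assignments.copy()
    next_label = labels.max() + 1
    for run in runs[1:]:
        for k in np.unique(labels):
            members = np.flatnonzero(labels == k)
            if members.size < 2:
                continue
            sub = run.assignments[members]
            groups = np.unique(sub)
            if groups.size < 2:
                continue
            sizeable = [
                g for g in groups
                if (sub == g).sum() >= max(1, min_split_frac * members.size)
            ]
            if len(sizeable) < 2:
                continue
            cents = {
                g: np.array([
                    run.clusters[g].ccf
                ]).ravel()
                for g in sizeable
            }
            separated = any(
                np.max(np.abs(cents[a] - cents[b])) > split_threshold
                for ai, a in enumerate(sizeable)
                for b in sizeable[ai + 1:]
            )
            if not separated:
                continue
            # adopt the enrichment split; small leftovers stay with the
            # largest sizeable group
            largest = max(sizeable, key=lambda g: (sub == g).sum())
            for g in sizeable:
                if g == largest:
                    continue
                labels[members[sub == g]] = next_label
                next_label += 1
    _, labels = np.unique(labels, return_inverse=True)
    clusters = []
    for k in np.unique(labels):
        members = labels == k
        # centroid in core-run CCF space (mean of member cluster CCFs)
        core_ccfs = np.array(
            [core.clusters[c].ccf for c in core.assignments[members]]
        )
        clusters.append(
            Cluster(cluster_id=int(k), ccf=core_ccfs.mean(axis=0),
                    n_assigned=int(members.sum()))
        )
    return ClusteringResult(
        clusters=clusters, assignments=labels, sample_ids=core.sample_ids,
    )
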