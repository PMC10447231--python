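"""Post-calling quality filters, germline removal, and presence calling.

Three layers, applied to a force-called count matrix:

1. annotation filters (median alignment score, clipping metric) on the
   caller's per-variant quality fields;
2. a one-sided exact binomial test against heterozygous-germline
   expectation (p = 0.5) on counts aggregated across largely diploid
   samples, Benjamini-Hochberg corrected;
3. a site-specific beta-binomial error model, fitted on designated
   negative samples, used to separate true variant presence from noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .core_io import CountMatrix, VariantSite

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    asmd_min: float = 140.0
    clpm_max: float = 0.0
    germline_q_cutoff: float = 1e-5
    presence_alpha: float = 1e-3
    missing_annotation_policy: str = "retain"  # retain | reject

    def __post_init__(self) -> None:
        if not (0.0 < self.germline_q_cutoff < 1.0):
            raise ValueError("germline_q_cutoff must be in (0,1)")
        if self.missing_annotation_policy not in ("retain", "reject"):
            raise ValueError("missing_annotation_policy must be retain|reject")


@dataclass
class ErrorModel:
    """Per-site error rate and overdispersion for the beta-binomial null.

    ``rho == 0`` reduces the model to a plain binomial.
    """

    epsilon: np.ndarray  # (n_sites,)
    rho: np.ndarray  # (n_sites,)
    loglik: np.ndarray = None
    low_confidence: np.ndarray = None
    samples_used: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if (self.epsilon >= 0.5).any() or (self.epsilon < 0).any():
            raise ValueError("epsilon must lie in [0, 0.5)")
        if (self.rho < 0).any() or (self.rho >= 1).any():
            raise ValueError("rho must lie in [0, 1)")
        if self.loglik is None:
            self.loglik = np.full(self.epsilon.shape, np.nan)
        if self.low_confidence is None:
            self.low_confidence = np.zeros(self.epsilon.shape, dtype=bool)


@dataclass
class PresenceCall:
    site_index: int
    sample_index: int
    p_value: float
    q_value: float
    present: bool


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------

def apply_quality_filters(
    sites: list[VariantSite], cfg: FilterConfig
) -> tuple[list[VariantSite], list[tuple[VariantSite, str]]]:
    """Partition sites into (retained, rejected-with-reason).

    A site is retained iff ASMD >= ``asmd_min`` and CLPM <= ``clpm_max``.
    Sites missing either annotation follow ``missing_annotation_policy``.
    """
    retained: list[VariantSite] = []
    rejected: list[tuple[VariantSite, str]] = []
    for site in sites:
        asmd = site.annotations.get("ASMD")
        clpm = site.annotations.get("CLPM")
        if asmd is None or clpm is None:
            if cfg.missing_annotation_policy == "retain":
                logger.warning(
                    "site %s:%d missing ASMD/CLPM annotation; retained",
                    site.chrom, site.pos,
                )
                retained.append(site)
            else:
                rejected.append((site, "missing_annotation"))
            continue
        if asmd < cfg.asmd_min:
            rejected.append((site, "ASMD"))
        elif clpm > cfg.clpm_max:
            rejected.append((site, "CLPM"))
        else:
            retained.append(site)
    return retained, rejected


# ---------------------------------------------------------------------------
# Germline test
# ---------------------------------------------------------------------------

def germline_test(v_agg: int, d_agg: int) -> float:
    """One-sided exact binomial test against heterozygous germline.

    Returns p = P(X <= v_agg) for X ~ Binomial(d_agg, 0.5).  Small p means
    too few variant reads to be a heterozygous germline variant, i.e.
    evidence for somatic origin.
    """
    if d_agg == 0:
        logger.warning("germline_test with zero depth; returning p = 1")
        return 1.0
    if not (0 <= v_agg <= d_agg):
        raise ValueError(f"need 0 <= v ({v_agg}) <= d ({d_agg})")
    return float(stats.binom.cdf(v_agg, d_agg, 0.5))


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    q_(k) = min_{j >= k} m * p_(j) / j over the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_germline(
    counts: CountMatrix,
    diploid_samples: list[str],
    cfg: FilterConfig | None = None,
) -> "pd.DataFrame":
    """Label each site somatic/germline via the aggregated binomial test.

    Counts are summed over ``diploid_samples`` (one test per site), BH
    corrected over all sites; a site is somatic iff q < germline_q_cutoff.
    """
    import pandas as pd

    cfg = cfg or FilterConfig()
    if not diploid_samples:
        raise ValueError("diploid_samples must be nonempty")
    sub = counts.subset_samples(diploid_samples)
    v_agg = sub.var_reads.sum(axis=1)
    d_agg = sub.depth.sum(axis=1)
    with np.errstate(divide="ignore"):
        p = stats.binom.cdf(v_agg, np.maximum(d_agg, 1), 0.5)
    p = np.where(d_agg == 0, 1.0, p)
    q = bh_qvalues(p)
    label = np.where(q < cfg.germline_q_cutoff, "somatic", "germline")
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in counts.sites],
            "pos": [s.pos for s in counts.sites],
            "ref": [s.ref for s in counts.sites],
            "alt": [s.alt for s in counts.sites],
            "v_agg": v_agg,
            "d_agg": d_agg,
            "p_value": p,
            "q_value": q,
            "label": label,
        }
    )


def designate_diploid_samples(
    counts: CountMatrix, lo: float = 1.8, hi: float = 2.2
) -> list[str]:
    """Default largely-diploid subset: tumor samples with ploidy in [lo, hi]."""
    return [
        s.sample_id
        for s in counts.samples
        if s.role == "tumor" and lo <= s.ploidy <= hi
    ]


# ---------------------------------------------------------------------------
# Beta-binomial error model
# ---------------------------------------------------------------------------

def betabinom_logpmf(v, d, eps: float, rho: float):
    """log P(V = v | d) under BetaBin with mean eps and overdispersion rho.

    Parameterization: alpha = eps * (1 - rho) / rho, beta = (1 - eps) *
    (1 - rho) / rho; rho = 0 falls back to Binomial(d, eps).
    """
    if rho <= 0:
        return stats.binom.logpmf(v, d, eps)
    a = eps * (1.0 - rho) / rho
    b = (1.0 - eps) * (1.0 - rho) / rho
    return stats.betabinom.logpmf(v, d, a, b)


def betabinom_sf(v, d, eps: float, rho: float):
    """P(V >= v) under the beta-binomial null (one-sided upper tail)."""
    if rho <= 0:
        return stats.binom.sf(np.asarray(v) - 1, d, eps)
    a = eps * (1.0 - rho) / rho
    b = (1.0 - eps) * (1.0 - rho) / rho
    return stats.betabinom.sf(np.asarray(v) - 1, d, a, b)


_RHO_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 0.5, 25)])


def _profile_eps(v: np.ndarray, d: np.ndarray, rho: float,
                 eps_floor: float) -> tuple[float, float]:
    """Maximize the (beta-)binomial log-likelihood in eps for fixed rho."""
    if rho <= 0:
        tot_d = int(d.sum())
        eps = max(float(v.sum()) / tot_d if tot_d else 0.0, eps_floor)
        eps = min(eps, 0.4999)
        return eps, float(np.sum(stats.binom.logpmf(v, d, eps)))

    def nll(eps: float) -> float:
        return -float(np.sum(betabinom_logpmf(v, d, eps, rho)))

    res = optimize.minimize_scalar(
        nll, bounds=(eps_floor, 0.4999), method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x), -float(res.fun)


def fit_error_model(
    counts: CountMatrix,
    negative_samples: list[str],
    lr_tol: float = 1e-3,
    rho_grid: np.ndarray = _RHO_GRID,
) -> ErrorModel:
    """Fit per-site (epsilon, rho) on presumed-negative samples.

    Profile likelihood over a fixed rho grid with a bounded 1-D epsilon
    optimization at each grid point, followed by golden-section refinement
    of rho around the grid optimum.  rho collapses to 0 whenever the
    binomial fits within ``lr_tol`` log-likelihood units of the best
    beta-binomial.
    """
    sub = counts.subset_samples(negative_samples)
    n_sites = len(counts.sites)
    eps_out = np.zeros(n_sites)
    rho_out = np.zeros(n_sites)
    ll_out = np.zeros(n_sites)
    lowconf = np.zeros(n_sites, dtype=bool)
    few_negatives = len(negative_samples) < 2

    for i in range(n_sites):
        v = sub.var_reads[i].astype(float)
        d = sub.depth[i].astype(float)
        tot_d = d.sum()
        eps_floor = 0.5 / (tot_d + 1.0) if tot_d > 0 else 1e-6
        if few_negatives or tot_d == 0:
            eps = max(float(v.sum()) / tot_d if tot_d else 0.0, eps_floor)
            eps_out[i] = min(eps, 0.4999)
            rho_out[i] = 0.0
            ll_out[i] = float(np.sum(stats.binom.logpmf(v, d, eps_out[i])))
            lowconf[i] = True
            continue
        if v.sum() == 0:
            # no variant reads anywhere: no overdispersion evidence;
            # epsilon sits at the pseudocount floor
            eps_out[i], rho_out[i] = eps_floor, 0.0
            ll_out[i] = float(np.sum(stats.binom.logpmf(v, d, eps_floor)))
            continue
        best = None
        ll_binom = None
        for rho in rho_grid:
            eps, ll = _profile_eps(v, d, float(rho), eps_floor)
            if rho == 0.0:
                ll_binom = ll
            if best is None or ll > best[2]:
                best = (float(rho), eps, ll)
        rho_hat, eps_hat, ll_hat = best
        if rho_hat > 0:
            # golden-section refine rho between neighbouring grid points
            k = int(np.searchsorted(rho_grid, rho_hat))
            lo = rho_grid[max(k - 1, 1)]
            hi = rho_grid[min(k + 1, len(rho_grid) - 1)]
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda r: -_profile_eps(v, d, r, eps_floor)[1],
                    bounds=(float(lo), float(hi)), method="bounded",
                    options={"xatol": 1e-6},
                )
                if -res.fun > ll_hat:
                    rho_hat = float(res.x)
                    eps_hat, ll_hat = _profile_eps(v, d, rho_hat, eps_floor)
        if ll_hat - ll_binom <= lr_tol:
            rho_hat = 0.0
            eps_hat, ll_hat = _profile_eps(v, d, 0.0, eps_floor)
        eps_out[i], rho_out[i], ll_out[i] = eps_hat, rho_hat, ll_hat

    return ErrorModel(
        epsilon=eps_out, rho=rho_out, loglik=ll_out,
        low_confidence=lowconf, samples_used=list(negative_samples),
    )


def call_presence(
    counts: CountMatrix, model: ErrorModel, cfg: FilterConfig | None = None
) -> list[PresenceCall]:
    """Per-(site, sample) one-sided presence test under the error model.

    p = P(X >= v) under BetaBin(d, eps_i, rho_i); BH within each sample;
    present iff v > 0 and q < presence_alpha.
    """
    cfg = cfg or FilterConfig()
    n_sites, n_samples = counts.var_reads.shape
    if model.epsilon.shape[0] != n_sites:
        raise ValueError("error model not fitted for all sites")
    calls: list[PresenceCall] = []
    for s in range(n_samples):
        p = np.ones(n_sites)
        for i in range(n_sites):
            v, d = counts.var_reads[i, s], counts.depth[i, s]
            if v == 0 or d == 0:
                p[i] = 1.0
            else:
                p[i] = float(
                    betabinom_sf(v, d, float(model.epsilon[i]), float(model.rho[i]))
                )
        q = bh_qvalues(p)
        for i in range(n_sites):
            present = bool(
                counts.var_reads[i, s] > 0 and q[i] < cfg.presence_alpha
            )
            calls.append(
                PresenceCall(
                    site_index=i, sample_index=s,
                    p_value=float(p[i]), q_value=float(q[i]), present=present,
                )
            )
    return calls


def presence_matrix(calls: list[PresenceCall], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for c in calls:
        out[c.site_index, c.sample_index] = c.present
    return out
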