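"""Aggregated-site detection of a rare lineage and clone-size estimation.

A branch of the clone tree defines a set of diploid SNV sites.  For each
queried sample, variant reads and depth are summed over the whole site
set and tested one-sided against a background error rate estimated from
a panel of unrelated samples:

    p = P(X >= V),  X ~ Binomial(D, epsilon)

Clone size is twice the aggregated VAF maximum-likelihood estimate
(diploid heterozygous sites), capped at 1, with an exact Clopper-Pearson
95% interval transformed the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import CountMatrix, SegmentIndex
from .phylogeny import CloneTree

logger = logging.getLogger(__name__)


@dataclass
class LineageSiteSet:
    branch_id: int
    site_indices: list[int]
    excluded: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.site_indices) & set(self.excluded)
        if overlap:
            raise ValueError(f"sites both included and excluded: {sorted(overlap)}")

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)


@dataclass
class BackgroundErrorModel:
    epsilon: float
    per_sample_rates: np.ndarray
    n_panel: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 0.01):
            raise ValueError(
                f"background rate {self.epsilon} outside [0, 0.01]; "
                "panel is unlikely to be lineage-free"
            )


@dataclass
class LineageTestResult:
    sample_id: str
    V: int
    D: int
    epsilon: float
    p_value: float
    vaf_mle: float
    ci_low: float
    ci_high: float
    clone_size: float
    clone_ci_low: float
    clone_ci_high: float
    log10_p: float = np.nan
    stars: str = ""


def define_site_set(
    tree: CloneTree,
    branch_id: int,
    segments: SegmentIndex,
    query_samples: list[str],
    counts: CountMatrix,
) -> LineageSiteSet:
    """Branch SNVs lying in (1,1) copy-number regions in all query samples.

    Sites on CNV-affected segments (e.g. a 17p loss) are excluded with an
    itemized reason; an empty resulting set is an error.
    """
    if branch_id not in tree.nodes():
        raise KeyError(f"branch {branch_id} not in tree")
    included: list[int] = []
    excluded: dict[int, str] = {}
    for idx in tree.branch_mutations.get(branch_id, []):
        site = counts.sites[idx]
        if site.var_class != "SNV":
            excluded[idx] = "not_snv"
            continue
        bad = None
        for sid in query_samples:
            cn = segments.lookup(sid, site.chrom, site.pos)
            if cn != (1, 1):
                bad = f"cn_{cn[0]}_{cn[1]}_in_{sid}"
                break
        if bad:
            excluded[idx] = bad
        else:
            included.append(idx)
    if not included:
        raise ValueError(
            f"no usable sites remain for branch {branch_id} "
            f"({len(excluded)} excluded)"
        )
    return LineageSiteSet(branch_id=branch_id, site_indices=included,
                          excluded=excluded)


def estimate_background(
    site_set: LineageSiteSet, panel_counts: CountMatrix
) -> BackgroundErrorModel:
    """Mean per-panel-sample aggregate error rate over the site set.

    Each panel sample contributes rate = sum(V)/sum(D) over the sites;
    epsilon is the mean of these rates (samples with zero depth dropped).
    """
    idx = site_set.site_indices
    v = panel_counts.var_reads[idx]
    d = panel_counts.depth[idx]
    rates = []
    for s in range(len(panel_counts.samples)):
        D = int(d[:, s].sum())
        if D == 0:
            logger.warning(
                "panel sample %s has zero aggregate depth; dropped",
                panel_counts.samples[s].sample_id,
            )
            continue
        rates.append(v[:, s].sum() / D)
    if not rates:
        raise ValueError("every panel sample has zero aggregate depth")
    rates = np.array(rates)
    eps = float(rates.mean())
    if eps == 0.0:
        logger.warning(
            "background rate is exactly 0; downstream tests degenerate"
        )
    return BackgroundErrorModel(
        epsilon=eps, per_sample_rates=rates, n_panel=rates.size
    )


def clopper_pearson(V: int, D: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval on V/D."""
    alpha = 1.0 - conf
    lo = 0.0 if V == 0 else float(stats.beta.ppf(alpha / 2, V, D - V + 1))
    hi = 1.0 if V == D else float(stats.beta.ppf(1 - alpha / 2, V + 1, D - V))
    return lo, hi


def detect_lineage(
    V: int, D: int, model: BackgroundErrorModel, sample_id: str = ""
) -> LineageTestResult:
    """One-sided binomial test of aggregated counts against background."""
    if D <= 0:
        raise ValueError("aggregate depth must be positive")
    if not (0 <= V <= D):
        raise ValueError(f"need 0 <= V ({V}) <= D ({D})")
    eps = model.epsilon
    if eps == 0.0:
        if V > 0:
            logger.warning(
                "degenerate null (epsilon = 0) with V > 0: p reported as 0"
            )
            p, log10p = 0.0, -np.inf
        else:
            p, log10p = 1.0, 0.0
    elif V == 0:
        p, log10p = 1.0, 0.0
    else:
        logp = float(stats.binom.logsf(V - 1, D, eps))
        p = float(np.exp(logp))
        log10p = logp / np.log(10.0)
    vaf = V / D
    lo, hi = clopper_pearson(V, D)
    return LineageTestResult(
        sample_id=sample_id, V=int(V), D=int(D), epsilon=eps,
        p_value=p, vaf_mle=vaf, ci_low=lo, ci_high=hi,
        clone_size=min(1.0, 2.0 * vaf),
        clone_ci_low=min(1.0, 2.0 * lo),
        clone_ci_high=min(1.0, 2.0 * hi),
        log10_p=log10p,
        stars="***" if p < 1e-3 else "",
    )


def track_lineage_timecourse(
    site_set: LineageSiteSet,
    counts: CountMatrix,
    model: BackgroundErrorModel,
) -> list[LineageTestResult]:
    """One aggregated detection result per sample, in input sample order."""
    idx = site_set.site_indices
    missing = [i for i in idx if i >= len(counts.sites)]
    if missing:
        raise ValueError(f"count matrix is missing site indices {missing[:10]}")
    results = []
    for s, meta in enumerate(counts.samples):
        V = int(counts.var_reads[idx, s].sum())
        D = int(counts.depth[idx, s].sum())
        results.append(detect_lineage(V, D, model, sample_id=meta.sample_id))
    return results


def site_outlier_report(
    site_set: LineageSiteSet, counts: CountMatrix, max_frac: float = 0.05
) -> "pd.DataFrame":
    """Per-site contribution diagnostics: flags any site carrying more than
    ``max_frac`` of a sample's aggregate variant reads."""
    import pandas as pd

    idx = np.array(site_set.site_indices)
    rows = []
    for s, meta in enumerate(counts.samples):
        v = counts.var_reads[idx, s]
        V = v.sum()
        if V == 0:
            continue
        frac = v / V
        for j in np.flatnonzero(frac > max_frac):
            site = counts.sites[idx[j]]
            rows.append(
                {
                    "sample": meta.sample_id,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "var_reads": int(v[j]),
                    "fraction_of_evidence": float(frac[j]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "var_reads", "fraction_of_evidence"],
    )


def results_table(results: list[LineageTestResult]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample": r.sample_id, "V": r.V, "D": r.D,
                "epsilon": r.epsilon, "p_value": r.p_value,
                "log10_p": r.log10_p, "vaf_mle": r.vaf_mle,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "clone_size": r.clone_size,
                "clone_ci_low": r.clone_ci_low,
                "clone_ci_high": r.clone_ci_high,
                "stars": r.stars,
            }
            for r in results
        ]
    )
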