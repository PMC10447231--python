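"""Per-branch 96-channel spectra, signature extraction and exposure fitting.

Extraction is a non-negative factorization of the branch x channel count
matrix under the multinomial (generalized KL) objective, by multiplicative
updates with multiple seeded restarts.  Exposure refitting against a fixed
catalog is the EM algorithm for multinomial mixture weights; both routes
keep signatures and exposures on the probability simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import CHANNELS, SignatureCatalog

logger = logging.getLogger(__name__)

#: Branches with fewer SNVs than this are excluded from de-novo
#: extraction (they are still refitted against the catalog).
MIN_BRANCH_SNVS = 100


@dataclass
class ContextSpectrum:
    branch_id: int
    counts: np.ndarray  # (96,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"spectrum must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExposureMatrix:
    branch_ids: list[int]
    signature_names: list[str]
    exposures: np.ndarray  # (n_branches, n_signatures), rows on simplex
    totals: np.ndarray  # per-branch SNV totals

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if (self.exposures < 0).any():
            raise ValueError("exposures must be non-negative")
        sums = self.exposures.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"exposure rows must sum to 1, got {sums}")


def branch_spectra(
    tree, contexts: dict[int, int] | list[int | None]
) -> list[ContextSpectrum]:
    """One 96-channel spectrum per branch of a clone tree.

    ``contexts`` maps mutation index -> channel index (non-SNVs / N-context
    sites absent or None are skipped).  Branches under ``MIN_BRANCH_SNVS``
    are computed but flagged via a log message.
    """
    if not isinstance(contexts, dict):
        contexts = {i: c for i, c in enumerate(contexts) if c is not None}
    spectra = []
    for branch in tree.nodes():
        counts = np.zeros(96, dtype=np.int64)
        for mut in tree.branch_mutations.get(branch, []):
            ch = contexts.get(mut)
            if ch is not None:
                counts[ch] += 1
        if counts.sum() < MIN_BRANCH_SNVS:
            logger.info(
                "branch %s has %d SNVs (< %d): excluded from de-novo "
                "extraction, exposures still fitted",
                branch, int(counts.sum()), MIN_BRANCH_SNVS,
            )
        spectra.append(ContextSpectrum(branch_id=branch, counts=counts))
    return spectra


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(X || WH)."""
    mask = X > 0
    return float(
        np.sum(X[mask] * np.log(X[mask] / WH[mask])) - X.sum() + WH.sum()
    )


def _nmf_kl(X: np.ndarray, K: int, rng: np.random.Generator,
            n_iter: int = 3000, tol: float = 1e-11,
            ) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Multiplicative-update NMF under generalized KL.

    Returns (W, H, obj, trace) with X ~ W @ H; the objective trace is
    non-increasing by the standard majorization argument.
    """
    n, p = X.shape
    W = rng.random((n, K)) + 0.1
    H = rng.random((K, p)) + 0.1
    eps = 1e-12
    prev = np.inf
    trace: list[float] = []
    for _ in range(n_iter):
        WH = W @ H + eps
        H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = W @ H + eps
        W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(X, W @ H + eps)
        trace.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0):
            prev = obj
            break
        prev = obj
    return W, H, prev, trace


def extract_signatures(
    spectra: list[ContextSpectrum],
    K: int,
    seed: int = 0,
    n_restarts: int = 20,
    min_branch_snvs: int = MIN_BRANCH_SNVS,
) -> tuple[np.ndarray, ExposureMatrix]:
    """De-novo extraction of K signatures from branch spectra.

    Uses only branches with at least ``min_branch_snvs`` SNVs.  Returns
    (signatures (K x 96) on the simplex, ExposureMatrix over those
    branches).  Deterministic for a given seed; best of ``n_restarts``
    restarts by KL objective.
    """
    used = [s for s in spectra if s.total >= min_branch_snvs]
    if K > len(used):
        raise ValueError(
            f"K={K} exceeds the {len(used)} branches with >= "
            f"{min_branch_snvs} SNVs"
        )
    X = np.array([s.counts for s in used], dtype=float)
    if X.sum() < 50 * K:
        raise ValueError("too few mutations for the requested K")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        W, H, obj, _trace = _nmf_kl(X, K, rng)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H, _ = best
    sig_scale = H.sum(axis=1)
    signatures = H / sig_scale[:, None]
    expo = W * sig_scale[None, :]
    expo = expo / expo.sum(axis=1, keepdims=True)
    # deterministic signature ordering: by descending total attribution
    order = np.argsort(-(expo * X.sum(axis=1)[:, None]).sum(axis=0), kind="stable")
    signatures = signatures[order]
    expo = expo[:, order]
    exposures = ExposureMatrix(
        branch_ids=[s.branch_id for s in used],
        signature_names=[f"signature_{chr(ord('A') + j)}" for j in range(K)],
        exposures=expo,
        totals=np.array([s.total for s in used]),
    )
    return signatures, exposures


def fit_exposures(
    spectrum: ContextSpectrum,
    catalog: SignatureCatalog,
    n_iter: int = 2000,
    tol: float = 1e-12,
) -> np.ndarray:
    """ML multinomial-mixture weights of catalog signatures for one spectrum.

    EM: w_j <- w_j * sum_c x_c S_jc / sum_k w_k S_kc, normalized.  Returns
    the weight vector (sums to 1).
    """
    x = spectrum.counts.astype(float)
    if x.sum() == 0:
        raise ValueError("cannot fit exposures for an empty spectrum")
    S = catalog.probs  # (J, 96)
    J = S.shape[0]
    w = np.full(J, 1.0 / J)
    for _ in range(n_iter):
        mix = w @ S  # (96,)
        mix = np.maximum(mix, 1e-300)
        w_new = w * (S @ (x / mix))
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return w


def exposure_loglik(spectrum: ContextSpectrum, catalog: SignatureCatalog,
                    weights: np.ndarray) -> float:
    """Multinomial log-likelihood (up to the constant term) of weights."""
    x = spectrum.counts.astype(float)
    mix = np.maximum(weights @ catalog.probs, 1e-300)
    return float(np.sum(x * np.log(mix)))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_catalog(
    signature: np.ndarray, catalog: SignatureCatalog,
    ambiguity_margin: float = 0.02,
) -> tuple[str, float, bool]:
    """Best cosine match of a signature against a catalog.

    Returns (name, cosine, ambiguous) where ``ambiguous`` flags a runner-up
    within ``ambiguity_margin`` of the best.
    """
    sims = np.array([cosine_similarity(signature, row) for row in catalog.probs])
    order = np.argsort(-sims)
    best = int(order[0])
    ambiguous = sims.size > 1 and sims[best] - sims[int(order[1])] < ambiguity_margin
    return catalog.names[best], float(sims[best]), ambiguous


def spectra_table(spectra: list[ContextSpectrum]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {f"branch_{s.branch_id}": s.counts for s in spectra},
        index=list(CHANNELS),
    )
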