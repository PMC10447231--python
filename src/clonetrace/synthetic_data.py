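"""Synthetic serially-sampled leukemia studies with machine-readable truth.

Generates the full set of inputs the pipeline consumes — clone trees with
pigeonhole-valid per-sample CCFs, branch mutations drawn from mixtures of
three synthetic signature generators, binomial/beta-binomial read counts
at configurable depth, copy-number segments (including a 17p-style loss),
panel-of-normals counts, reference sequence with planted RSS-flanked
deletions — plus a TruthSet recording every generating parameter.

The three shipped signature generators qualitatively resemble SBS1
(C>T at CpG), SBS5 (flat) and SBS87 (thiopurine; T>G/T>A enriched) but
are synthetic stand-ins, not COSMIC data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    CHANNELS,
    BreakpointPair,
    CopyNumberSegment,
    CountMatrix,
    SampleMeta,
    SignatureCatalog,
    VariantSite,
    revcomp,
)
from .rss_motif import RSS_HEPTAMER, RSS_NONAMER

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Synthetic signature generators
# ---------------------------------------------------------------------------

def synthetic_signatures() -> SignatureCatalog:
    """Three synthetic 96-channel generators: clock-CpG, flat, thiopurine-like."""
    probs = np.zeros((3, 96))
    # syn-SBS1-like: C>T at NpCpG contexts dominates
    for i, ch in enumerate(CHANNELS):
        sub = ch[2:5]
        left, right = ch[0], ch[6]
        if sub == "C>T" and right == "G":
            probs[0, i] = 20.0
        elif sub == "C>T":
            probs[0, i] = 1.0
        else:
            probs[0, i] = 0.05
    # syn-SBS5-like: near-flat with mild tilt
    probs[1] = 1.0
    for i, ch in enumerate(CHANNELS):
        if ch[2:5] in ("T>C", "C>T"):
            probs[1, i] = 1.6
    # syn-SBS87-like: T>G and T>A in specific contexts
    for i, ch in enumerate(CHANNELS):
        sub = ch[2:5]
        left, right = ch[0], ch[6]
        if sub == "T>G" and left in "CG":
            probs[2, i] = 14.0
        elif sub == "T>G":
            probs[2, i] = 4.0
        elif sub == "T>A" and right == "T":
            probs[2, i] = 8.0
        elif sub == "T>A":
            probs[2, i] = 2.0
        else:
            probs[2, i] = 0.05
    probs /= probs.sum(axis=1, keepdims=True)
    return SignatureCatalog(
        names=["syn-SBS1", "syn-SBS5", "syn-SBS87"], probs=probs
    )


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedDeletion:
    chrom: str
    bp_low: int
    bp_high: int
    spacer_len: int  # 12 or 23
    offset: int  # bp downstream of the 3' (high) breakpoint
    strand: str = "+"


@dataclass
class SimulationConfig:
    samples: list[SampleMeta]
    parent: list[int | None]  # clone tree, one entry per clone
    ccf: np.ndarray  # (n_clones, n_samples) clade CCFs
    branch_n_snvs: list[int]
    branch_sig_weights: np.ndarray  # (n_clones, 3)
    depth: float = 100.0
    eps: float = 1.6e-4
    rho: float = 0.0
    n_panel: int = 32
    panel_depth: float = 100.0
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    cn_segments: list[CopyNumberSegment] = field(default_factory=list)
    branch_n_on_lost_segment: dict[int, int] = field(default_factory=dict)
    lost_segment: tuple[str, int, int] | None = None  # (chrom, start, end)
    deletions: list[PlantedDeletion] = field(default_factory=list)
    spike: dict[str, dict[int, float]] = field(default_factory=dict)
    site_spacing: int = 40
    generate_sequences: bool = True  # skip FASTA/RSS planting when False

    def __post_init__(self) -> None:
        self.ccf = np.asarray(self.ccf, dtype=float)
        self.branch_sig_weights = np.asarray(self.branch_sig_weights, dtype=float)
        n = len(self.parent)
        if self.ccf.shape != (n, len(self.samples)):
            raise ValueError(
                f"ccf shape {self.ccf.shape} != ({n}, {len(self.samples)})"
            )
        if len(self.branch_n_snvs) != n:
            raise ValueError("branch_n_snvs must have one entry per clone")
        if not self.chrom_lengths:
            self.chrom_lengths = {
                "1": 150_000, "2": 150_000, "3": 150_000,
                "9": 20_000, "17": 30_000,
            }
        self.validate_pigeonhole()

    def validate_pigeonhole(self) -> None:
        """Reject infeasible clone-fraction configurations before sampling."""
        n = len(self.parent)
        roots = [i for i in range(n) if self.parent[i] is None]
        if len(roots) != 1:
            raise ValueError(f"config must have one root clone, got {roots}")
        if (self.ccf < 0).any() or (self.ccf > 1).any():
            raise ValueError("clade CCFs must lie in [0, 1]")
        sums = {}
        for i, p in enumerate(self.parent):
            if p is None:
                continue
            if np.any(self.ccf[i] > self.ccf[p] + 1e-9):
                raise ValueError(f"clone {i} CCF exceeds parent {p}")
            sums.setdefault(p, np.zeros(self.ccf.shape[1]))
            sums[p] = sums[p] + self.ccf[i]
        for p, s in sums.items():
            if np.any(s > self.ccf[p] + 1e-9):
                raise ValueError(
                    f"children of clone {p} sum to {s} > parent CCF {self.ccf[p]}"
                )


@dataclass
class TruthSet:
    """Everything the simulator decided, for parameter-recovery tests."""

    seed: int
    parent: list[int | None]
    ccf: np.ndarray
    sample_ids: list[str]
    purity: list[float]
    branch_of_site: np.ndarray  # (n_sites,)
    channel_of_site: np.ndarray  # (n_sites,) -1 for non-SNV
    signature_of_site: np.ndarray  # (n_sites,) generator index, -1 non-SNV
    eps: float
    rho: float
    spike: dict[str, dict[int, float]]
    deletions: list[PlantedDeletion]
    planted_window_offsets: list[int]
    lost_segment: tuple[str, int, int] | None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "seed": self.seed,
            "parent": self.parent,
            "ccf": self.ccf.tolist(),
            "sample_ids": self.sample_ids,
            "purity": self.purity,
            "branch_of_site": self.branch_of_site.tolist(),
            "channel_of_site": self.channel_of_site.tolist(),
            "signature_of_site": self.signature_of_site.tolist(),
            "eps": self.eps,
            "rho": self.rho,
            "spike": {k: {str(c): v for c, v in d.items()}
                      for k, d in self.spike.items()},
            "deletions": [vars(d) for d in self.deletions],
            "planted_window_offsets": self.planted_window_offsets,
            "lost_segment": self.lost_segment,
        }
        Path(path).write_text(json.dumps(obj, indent=2))


@dataclass
class SimulatedStudy:
    counts: CountMatrix
    panel_counts: CountMatrix
    cn_segments: list[CopyNumberSegment]
    sequences: dict[str, str]
    breakpoints: list[BreakpointPair]
    truth: TruthSet


# ---------------------------------------------------------------------------
# Random clone trees
# ---------------------------------------------------------------------------

def random_clone_tree(
    n_clones: int,
    n_samples: int,
    rng: np.random.Generator,
    min_sep: float = 0.1,
    require_unique: bool = False,
    max_tries: int = 500,
) -> tuple[list[int | None], np.ndarray]:
    """Random pigeonhole-valid (parent, ccf) with pairwise CCF separation.

    Children nearly saturate their parent's CCF so trees are informative.
    With ``require_unique``, resamples until exhaustive enumeration admits
    exactly one feasible tree (used by oracle tests; n_clones <= ~7).
    """
    from .clonal_clustering import Cluster
    from .phylogeny import enumerate_all_trees

    for _ in range(max_tries):
        parent: list[int | None] = [None]
        for i in range(1, n_clones):
            parent.append(int(rng.integers(0, i)))
        ccf = np.zeros((n_clones, n_samples))
        ccf[0] = 1.0
        kids: dict[int, list[int]] = {}
        for i, p in enumerate(parent):
            if p is not None:
                kids.setdefault(p, []).append(i)
        ok = True
        for p in sorted(kids):
            group = kids[p]
            for s in range(n_samples):
                budget = ccf[p, s] * rng.uniform(0.85, 0.99)
                w = rng.dirichlet(np.ones(len(group)))
                for j, c in enumerate(group):
                    ccf[c, s] = budget * w[j]
        ccf = np.round(ccf, 3)
        # pairwise separation in at least one sample
        for a in range(n_clones):
            for b in range(a + 1, n_clones):
                if np.max(np.abs(ccf[a] - ccf[b])) < min_sep:
                    ok = False
            if ccf[a].max() < min_sep and a != 0:
                ok = False
        if not ok:
            continue
        # rounding must not break feasibility
        try:
            SimulationConfig(
                samples=[SampleMeta(sample_id=f"s{i}") for i in range(n_samples)],
                parent=parent, ccf=ccf,
                branch_n_snvs=[1] * n_clones,
                branch_sig_weights=np.full((n_clones, 3), 1 / 3),
            )
        except ValueError:
            continue
        if require_unique:
            clusters = [Cluster(cluster_id=i, ccf=ccf[i], n_assigned=1)
                        for i in range(n_clones)]
            if len(enumerate_all_trees(clusters, tol=0.0)) != 1:
                continue
        return parent, ccf
    raise RuntimeError("could not generate a valid clone tree")


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

def _place_sites(cfg: SimulationConfig, rng: np.random.Generator
                 ) -> list[tuple[str, int]]:
    """Deterministically allocate spaced site positions per branch.

    Sites earmarked for the lost segment go there; the rest are spread over
    the non-CNV chromosomes.
    """
    avoid = {cfg.lost_segment[0]} if cfg.lost_segment else set()
    avoid |= {d.chrom for d in cfg.deletions}
    normal_chroms = [c for c in cfg.chrom_lengths if c not in avoid]
    slots: list[tuple[str, int]] = []
    for c in normal_chroms:
        length = cfg.chrom_lengths[c]
        for pos in range(cfg.site_spacing, length - cfg.site_spacing,
                         cfg.site_spacing):
            slots.append((c, pos))
    rng.shuffle(slots)
    n_normal = sum(cfg.branch_n_snvs) - sum(cfg.branch_n_on_lost_segment.values())
    if n_normal > len(slots):
        raise ValueError("not enough genome for the requested mutation count")
    lost_slots: list[tuple[str, int]] = []
    if cfg.lost_segment:
        chrom, start, end = cfg.lost_segment
        for pos in range(start + cfg.site_spacing, end - cfg.site_spacing,
                         cfg.site_spacing):
            lost_slots.append((chrom, pos))
        rng.shuffle(lost_slots)
    out = []
    i_norm = i_lost = 0
    for b, n in enumerate(cfg.branch_n_snvs):
        n_lost = cfg.branch_n_on_lost_segment.get(b, 0)
        for _ in range(n - n_lost):
            out.append(slots[i_norm]); i_norm += 1
        for _ in range(n_lost):
            out.append(lost_slots[i_lost]); i_lost += 1
    return out


def simulate_study(cfg: SimulationConfig, seed: int) -> SimulatedStudy:
    """Generate a full synthetic study (counts, CN, FASTA, breakpoints, truth)."""
    rng = np.random.default_rng(seed)
    sigs = synthetic_signatures().probs
    n_clones = len(cfg.parent)
    n_samples = len(cfg.samples)

    # effective clade CCFs, with spikes folded in
    ccf = cfg.ccf.copy()
    sample_ids = [s.sample_id for s in cfg.samples]
    for sid, spikes in cfg.spike.items():
        s = sample_ids.index(sid)
        for clone, size in spikes.items():
            ccf[clone, s] = max(ccf[clone, s], size)

    # reference sequences
    seq_arrays: dict[str, list[str]] = {}
    if cfg.generate_sequences:
        base_arr = np.array(list(_BASES))
        seq_arrays = {
            c: list(base_arr[rng.integers(0, 4, size=n)])
            for c, n in cfg.chrom_lengths.items()
        }

    # per-branch mutations: channel draws from the signature mixture
    positions = _place_sites(cfg, rng)
    sites: list[VariantSite] = []
    branch_of_site = []
    channel_of_site = []
    signature_of_site = []
    k = 0
    for b in range(n_clones):
        w = cfg.branch_sig_weights[b] / cfg.branch_sig_weights[b].sum()
        for _ in range(cfg.branch_n_snvs[b]):
            chrom, pos = positions[k]
            k += 1
            g = int(rng.choice(3, p=w))
            ch = int(rng.choice(96, p=sigs[g]))
            label = CHANNELS[ch]  # e.g. A[C>T]G
            trinuc, alt = label[0] + label[2] + label[6], label[4]
            if rng.random() < 0.5:  # represent on the purine strand
                trinuc, alt = revcomp(trinuc), _COMP[alt]
            if cfg.generate_sequences:
                seq_arrays[chrom][pos - 2 : pos + 1] = list(trinuc)
            sites.append(
                VariantSite(chrom=chrom, pos=pos, ref=trinuc[1], alt=alt,
                            var_class="SNV")
            )
            branch_of_site.append(b)
            channel_of_site.append(ch)
            signature_of_site.append(g)

    # planted RSS deletions
    breakpoints: list[BreakpointPair] = []
    planted_offsets: list[int] = []
    window = 50
    if cfg.generate_sequences:
        for d in cfg.deletions:
            seq_arr = seq_arrays[d.chrom]
            bp, off = plant_rss_deletion(
                seq_arr, d.chrom, d.bp_low, d.bp_high, d.spacer_len, d.offset,
                strand=d.strand, rng=rng, window=window,
            )
            breakpoints.append(bp)
            planted_offsets.append(off)

    sequences = {c: "".join(a) for c, a in seq_arrays.items()}
    # flank sequences reflect the final (post-planting) reference
    for bp in breakpoints:
        seq = sequences[bp.chrom]
        bp.flank_low_seq = seq[max(bp.bp_low - 1 - window, 0): bp.bp_low + window]
        bp.flank_high_seq = seq[max(bp.bp_high - 1 - window, 0): bp.bp_high + window]

    # copy-number segments
    cn_segments = list(cfg.cn_segments)
    cn_by_sample: dict[str, list[CopyNumberSegment]] = {}
    for seg in cn_segments:
        cn_by_sample.setdefault(seg.sample_id, []).append(seg)

    # read counts (vectorized over the site x sample grid)
    n_sites = len(sites)
    dmat = rng.poisson(cfg.depth, size=(n_sites, n_samples)).astype(np.int64)
    branch_arr = np.array(branch_of_site)
    C = ccf[branch_arr, :]  # (n_sites, n_samples) carrier CCF
    nmaj = np.ones((n_sites, n_samples), dtype=np.int64)
    nmin = np.ones((n_sites, n_samples), dtype=np.int64)
    for s, sid in enumerate(sample_ids):
        for seg in cn_by_sample.get(sid, []):
            mask = np.array([
                st.chrom == seg.chrom and seg.start <= st.pos <= seg.end
                for st in sites
            ])
            nmaj[mask, s] = seg.n_major
            nmin[mask, s] = seg.n_minor
    purity_arr = np.array([m.purity for m in cfg.samples])
    denom = purity_arr[None, :] * (nmaj + nmin) + (1 - purity_arr[None, :]) * 2.0
    xi = np.clip(purity_arr[None, :] * C / denom, 0.0, 1.0 - 1e-12)
    carrier = C > 0
    v = rng.binomial(dmat, cfg.eps)  # background error everywhere
    if cfg.rho <= 0:
        v_carrier = rng.binomial(dmat, xi)
    else:
        a = xi * (1 - cfg.rho) / cfg.rho
        b_par = (1 - xi) * (1 - cfg.rho) / cfg.rho
        p = rng.beta(np.maximum(a, 1e-12), np.maximum(b_par, 1e-12))
        v_carrier = rng.binomial(dmat, p)
    v = np.where(carrier, v_carrier, v)
    counts = CountMatrix(
        sites=sites, samples=list(cfg.samples), var_reads=v, depth=dmat,
    )

    # panel of normals
    panel_meta = [
        SampleMeta(sample_id=f"PANEL{j:02d}", role="panel")
        for j in range(cfg.n_panel)
    ]
    pd_depth = rng.poisson(
        cfg.panel_depth, size=(n_sites, cfg.n_panel)
    ).astype(np.int64)
    pv = rng.binomial(pd_depth, cfg.eps)
    panel_counts = CountMatrix(
        sites=sites, samples=panel_meta, var_reads=pv, depth=pd_depth,
    )

    truth = TruthSet(
        seed=seed,
        parent=list(cfg.parent),
        ccf=ccf,
        sample_ids=sample_ids,
        purity=[s.purity for s in cfg.samples],
        branch_of_site=np.array(branch_of_site),
        channel_of_site=np.array(channel_of_site),
        signature_of_site=np.array(signature_of_site),
        eps=cfg.eps,
        rho=cfg.rho,
        spike=cfg.spike,
        deletions=list(cfg.deletions),
        planted_window_offsets=planted_offsets,
        lost_segment=cfg.lost_segment,
    )
    return SimulatedStudy(
        counts=counts, panel_counts=panel_counts, cn_segments=cn_segments,
        sequences=sequences, breakpoints=breakpoints, truth=truth,
    )


def plant_rss_deletion(
    seq_arr: list[str],
    chrom: str,
    bp_low: int,
    bp_high: int,
    spacer_len: int,
    offset: int,
    strand: str = "+",
    rng: np.random.Generator | None = None,
    window: int = 50,
) -> tuple[BreakpointPair, int]:
    """Write a consensus RSS ``offset`` bp downstream of the 3' breakpoint.

    Returns the BreakpointPair (flanks filled in later, once all edits are
    applied) and the planted motif's start index within the high-side scan
    window.  Errors when the motif would overlap the breakpoint or fall
    outside the window.
    """
    rng = rng or np.random.default_rng(0)
    motif_len = 7 + spacer_len + 9
    if offset < 0:
        raise ValueError("motif would overlap the breakpoint (offset < 0)")
    if offset + motif_len > window:
        raise ValueError(
            f"offset {offset} + motif length {motif_len} exceeds window {window}"
        )
    spacer = "".join(rng.choice(list(_BASES), size=spacer_len))
    motif = RSS_HEPTAMER + spacer + RSS_NONAMER
    if strand == "-":
        motif = revcomp(motif)
    start0 = (bp_high - 1) + offset  # 0-based genome start of the motif
    if start0 + motif_len > len(seq_arr):
        raise ValueError("motif falls outside the reference sequence")
    seq_arr[start0 : start0 + motif_len] = list(motif)
    window_start0 = max(bp_high - 1 - window, 0)
    in_window_offset = start0 - window_start0
    bp = BreakpointPair(
        chrom=chrom, bp_low=bp_low, bp_high=bp_high, sv_type="deletion"
    )
    return bp, in_window_offset


# ---------------------------------------------------------------------------
# The template study
# ---------------------------------------------------------------------------

#: AML-root diploid site count in the template configuration
TEMPLATE_AML_ROOT_DIPLOID_SITES = 2318
TEMPLATE_SPIKE_VAF = 0.0013
TEMPLATE_AML_ROOT_CLONE = 5


def paper_template_config() -> SimulationConfig:
    """An 8-sample / 6-timepoint study mirroring the case structure.

    Clones: 0 truncal, 1 a 17p-loss diagnostic subclone (20% of the first
    diagnostic sample), 2 the progression clone (75% / 88% of the two
    diagnostic samples), 3 the relapse root carrying thiopurine-type
    mutations shared by both descendant lineages, 4 the ALL-relapse
    precursor, 5 the AML root (2,318 diploid sites after excluding 82 on
    the lost 17p-like segment; spiked into the second-relapse sample at
    VAF 0.0013), 6/7 the two ALL relapse clones, 8 an AML subclone.
    """
    samples = [
        SampleMeta("DX1", "diagnosis", 1.0, 2.0, "tumor"),
        SampleMeta("DX2", "diagnosis", 1.0, 2.0, "tumor"),
        SampleMeta("R1a", "relapse1", 1.0, 2.0, "tumor"),
        SampleMeta("R1b", "relapse1", 1.0, 2.0, "tumor"),
        SampleMeta("R2", "relapse2", 1.0, 2.0, "tumor"),
        SampleMeta("MDS", "post-CAR-T", 1.0, 2.0, "tumor"),
        SampleMeta("AML1", "aml", 1.0, 2.0, "tumor"),
        SampleMeta("AML2", "aml+3mo", 1.0, 2.0, "tumor"),
    ]
    parent = [None, 0, 0, 2, 3, 3, 4, 4, 5]
    #          DX1   DX2   R1a   R1b   R2      MDS   AML1  AML2
    ccf = np.array([
        [1.00, 1.00, 1.00, 1.00, 1.00, 0.30, 0.98, 0.98],  # 0 truncal
        [0.20, 0.10, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],  # 1 17p clone
        [0.75, 0.88, 1.00, 1.00, 1.00, 0.30, 0.98, 0.98],  # 2 progression
        [0.00, 0.00, 0.98, 0.98, 0.95, 0.28, 0.96, 0.96],  # 3 relapse root
        [0.00, 0.00, 0.95, 0.95, 0.90, 0.00, 0.00, 0.00],  # 4 ALL precursor
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.26, 0.94, 0.94],  # 5 AML root
        [0.00, 0.00, 0.90, 0.85, 0.00, 0.00, 0.00, 0.00],  # 6 relapse 1
        [0.00, 0.00, 0.00, 0.00, 0.85, 0.00, 0.00, 0.00],  # 7 relapse 2
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.30, 0.70],  # 8 AML subclone
    ])
    # thiopurine-like signature (index 2) appears only after treatment start
    sig_w = np.array([
        [0.45, 0.55, 0.00],  # truncal: clock-like only
        [0.35, 0.65, 0.00],
        [0.30, 0.60, 0.10],
        [0.10, 0.30, 0.60],  # shared thiopurine branch
        [0.15, 0.35, 0.50],
        [0.10, 0.30, 0.60],  # AML root: thiopurine-heavy
        [0.15, 0.40, 0.45],  # private thiopurine in relapse 1
        [0.15, 0.40, 0.45],
        [0.20, 0.50, 0.30],
    ])
    branch_n = [500, 300, 400, 250, 200,
                TEMPLATE_AML_ROOT_DIPLOID_SITES + 82, 400, 350, 300]
    lost = ("17", 1, 10_000)
    cn_segments = [
        CopyNumberSegment(sid, "17", 1, 10_000, 1, 0)
        for sid in ("AML1", "AML2")
    ]
    deletions = [
        PlantedDeletion(chrom="9", bp_low=5_000, bp_high=5_231 * 1, spacer_len=23,
                        offset=10, strand="+"),
        PlantedDeletion(chrom="9", bp_low=12_000, bp_high=12_196, spacer_len=12,
                        offset=5, strand="-"),
    ]
    return SimulationConfig(
        samples=samples,
        parent=parent,
        ccf=ccf,
        branch_n_snvs=branch_n,
        branch_sig_weights=sig_w,
        depth=100.0,
        eps=1.6e-4,
        rho=0.0,
        n_panel=32,
        panel_depth=100.0,
        cn_segments=cn_segments,
        branch_n_on_lost_segment={TEMPLATE_AML_ROOT_CLONE: 82},
        lost_segment=lost,
        deletions=deletions,
        spike={"R2": {TEMPLATE_AML_ROOT_CLONE: 2 * TEMPLATE_SPIKE_VAF}},
    )
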