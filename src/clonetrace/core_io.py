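"""Domain types and readers/writers for the formats the pipeline touches.

Coordinate convention: 1-based inclusive everywhere (VCF style).  Any
BED-style half-open input is converted on read and the conversion logged.

The 96 single-base-substitution channels use the conventional
substitution-major order: the six pyrimidine substitutions
C>A, C>G, C>T, T>A, T>C, T>G, and within each substitution the 16
flanking-base combinations in A, C, G, T order for the 5' then 3' base.
Channel ``i`` is therefore ``sub_index * 16 + left_index * 4 + right_index``.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: All 96 channel labels, e.g. ``A[C>A]A``, in canonical order.
CHANNELS: tuple[str, ...] = tuple(
    f"{l}[{sub}]{r}" for sub in _SUBSTITUTIONS for l in _BASES for r in _BASES
)
_CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


class CountsUnavailableError(ValueError):
    """Raised when a VCF record carries no recoverable read counts."""


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantSite:
    """A single somatic variant locus.

    ``annotations`` carries caller quality metrics (ASMD, CLPM, ...)
    when present; ``context`` is the pyrimidine-normalized trinucleotide
    context label for SNVs (e.g. ``A[C>T]A``), or ``None``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_class: str = "SNV"  # SNV | insertion | deletion
    context: str | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.var_class == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValidationError(
                f"SNV must have single-base alleles, got {self.ref}>{self.alt}"
            )
        if self.context is not None and self.context[2:5][0:1] not in ("C", "T"):
            # context label looks like X[C>T]Y; central ref base is position 2
            raise ValidationError(f"context {self.context} lacks pyrimidine center")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleMeta:
    """Per-sample metadata: identity, timepoint, purity/ploidy, role."""

    sample_id: str
    timepoint_label: str = ""
    purity: float = 1.0
    ploidy: float = 2.0
    role: str = "tumor"  # tumor | normal | panel

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(f"purity must be in (0,1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValidationError(f"ploidy must be > 0, got {self.ploidy}")


@dataclass
class CountMatrix:
    """Variant-read and depth integers per (site, sample).

    ``min_baseq`` / ``min_mapq`` record the extraction thresholds used to
    produce the counts; they are provenance, not re-applied here.
    """

    sites: list[VariantSite]
    samples: list[SampleMeta]
    var_reads: np.ndarray  # (n_sites, n_samples) int
    depth: np.ndarray  # (n_sites, n_samples) int
    min_baseq: int = 25
    min_mapq: int = 40

    def __post_init__(self) -> None:
        self.var_reads = np.asarray(self.var_reads, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        n_i, n_s = len(self.sites), len(self.samples)
        if self.var_reads.shape != (n_i, n_s) or self.depth.shape != (n_i, n_s):
            raise ValidationError(
                f"count matrix shape mismatch: {self.var_reads.shape} vs "
                f"({n_i}, {n_s})"
            )
        self.validate()

    def validate(self) -> None:
        bad = np.argwhere((self.var_reads > self.depth) | (self.var_reads < 0))
        if bad.size:
            i, s = bad[0]
            site = self.sites[i]
            raise ValidationError(
                f"var_reads > depth at {site.chrom}:{site.pos} "
                f"sample {self.samples[s].sample_id} "
                f"(v={self.var_reads[i, s]}, d={self.depth[i, s]})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountMatrix(
            sites=self.sites,
            samples=[self.samples[j] for j in idx],
            var_reads=self.var_reads[:, idx],
            depth=self.depth[:, idx],
            min_baseq=self.min_baseq,
            min_mapq=self.min_mapq,
        )


@dataclass
class CopyNumberSegment:
    """Allele-specific copy number over a 1-based inclusive interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.n_major < self.n_minor:
            raise ValidationError(
                f"n_major {self.n_major} < n_minor {self.n_minor}"
            )
        if self.n_minor < 0:
            raise ValidationError("copy numbers must be >= 0")


@dataclass
class BreakpointPair:
    """A structural-variant breakpoint pair with +/-50 bp flank sequences."""

    chrom: str
    bp_low: int
    bp_high: int
    sv_type: str = "deletion"  # deletion | other
    flank_low_seq: str = ""
    flank_high_seq: str = ""

    def __post_init__(self) -> None:
        if self.bp_low >= self.bp_high:
            raise ValidationError(
                f"bp_low {self.bp_low} must be < bp_high {self.bp_high}"
            )
        for seq in (self.flank_low_seq, self.flank_high_seq):
            if set(seq.upper()) - set("ACGTN"):
                raise ValidationError(f"flank sequence has non-ACGTN characters: {seq}")


@dataclass
class SignatureCatalog:
    """Reference signatures: one simplex row per signature over 96 channels."""

    names: list[str]
    probs: np.ndarray  # (n_signatures, 96)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape != (len(self.names), 96):
            raise ValidationError(
                f"catalog shape {self.probs.shape} != ({len(self.names)}, 96)"
            )
        if (self.probs < 0).any():
            raise ValidationError("catalog probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError(f"catalog rows must sum to 1, got {sums}")

    def row(self, name: str) -> np.ndarray:
        return self.probs[self.names.index(name)]


# ---------------------------------------------------------------------------
# Trinucleotide context
# ---------------------------------------------------------------------------

def context_label(trinuc: str, alt: str) -> str | None:
    """Pyrimidine-normalized channel label for a ref trinucleotide + alt base.

    Returns ``None`` when the context contains N.
    """
    trinuc = trinuc.upper()
    alt = alt.upper()
    if len(trinuc) != 3 or "N" in trinuc or alt == "N":
        return None
    if trinuc[1] in "AG":  # purine center: flip to the pyrimidine strand
        trinuc = revcomp(trinuc)
        alt = _COMPLEMENT[alt]
    return f"{trinuc[0]}[{trinuc[1]}>{alt}]{trinuc[2]}"


def channel_index(label: str) -> int:
    """Index 0-95 of a channel label in canonical order."""
    try:
        return _CHANNEL_INDEX[label]
    except KeyError:
        raise KeyError(f"not a valid channel label: {label!r}") from None


def trinucleotide_context(fasta, site: VariantSite) -> int | None:
    """96-channel index for an SNV from an indexed FASTA-like object.

    ``fasta`` must support ``fasta[chrom][start:end]`` with 0-based slices
    returning a sequence whose ``str()`` is the bases (pyfaidx semantics).
    Returns ``None`` (with a warning) when the context contains N.
    """
    if site.var_class != "SNV":
        raise ValueError(f"context is defined for SNVs only, got {site.var_class}")
    # site.pos is 1-based; fetch [pos-2, pos+1) 0-based
    trinuc = str(fasta[site.chrom][site.pos - 2 : site.pos + 1]).upper()
    if len(trinuc) != 3:
        raise ValueError(
            f"cannot fetch trinucleotide at {site.chrom}:{site.pos} (contig edge?)"
        )
    if trinuc[1] != site.ref.upper():
        raise ValidationError(
            f"reference mismatch at {site.chrom}:{site.pos}: "
            f"FASTA has {trinuc[1]}, site.ref is {site.ref}"
        )
    label = context_label(trinuc, site.alt)
    if label is None:
        logger.warning(
            "site %s:%d excluded from context assignment (N in context %s)",
            site.chrom, site.pos, trinuc,
        )
        return None
    return channel_index(label)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_id: str) -> tuple[list[VariantSite], np.ndarray, np.ndarray]:
    """Read a VCF and return (sites, var_reads, depth) for one sample.

    Counts are taken from the sample's AD/DP FORMAT fields.  Multi-allelic
    records are split into one site per alt; depth is the record DP for
    every split.  ASMD/CLPM INFO fields are captured as annotations.
    """
    import pysam

    path = Path(path)
    vcf = pysam.VariantFile(str(path))
    if sample_id not in list(vcf.header.samples):
        raise KeyError(f"sample {sample_id!r} not in VCF {path}")
    sites: list[VariantSite] = []
    vs: list[int] = []
    ds: list[int] = []
    for rec in vcf:
        call = rec.samples[sample_id]
        ad = call.get("AD")
        dp = call.get("DP")
        if ad is None or dp is None or dp is False:
            raise CountsUnavailableError(
                f"counts unavailable (AD/DP missing) at {rec.chrom}:{rec.pos}"
            )
        annotations = {}
        for key in ("ASMD", "CLPM"):
            if key in rec.info:
                annotations[key] = float(rec.info[key])
        alts = rec.alts or ()
        for ai, alt in enumerate(alts):
            if len(rec.ref) == 1 and len(alt) == 1:
                var_class = "SNV"
            elif len(alt) > len(rec.ref):
                var_class = "insertion"
            else:
                var_class = "deletion"
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    var_class=var_class,
                    annotations=dict(annotations),
                )
            )
            vs.append(int(ad[ai + 1]))
            ds.append(int(dp))
    v = np.array(vs, dtype=np.int64)
    d = np.array(ds, dtype=np.int64)
    if ((v > d) | (v < 0)).any():
        i = int(np.argwhere((v > d) | (v < 0))[0][0])
        raise ValidationError(
            f"var reads exceed depth at {sites[i].chrom}:{sites[i].pos}"
        )
    return sites, v, d


def write_vcf(path: str | Path, sites: Sequence[VariantSite], var_reads: np.ndarray,
              depth: np.ndarray, sample_id: str,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write sites with per-sample counts to an uncompressed VCF 4.2 file."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "clonetrace")
    if contigs is None:
        contigs = {}
        for s in sites:
            contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos + 1000)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("ASMD", 1, "Float", "Median alignment score of supporting reads")
    header.info.add("CLPM", 1, "Float", "Clipping metric of supporting reads")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample_id)
    out = pysam.VariantFile(str(path), "w", header=header)
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    for i in order:
        s = sites[i]
        v, d = int(var_reads[i]), int(depth[i])
        rec = out.new_record(
            contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt)
        )
        for key in ("ASMD", "CLPM"):
            if key in s.annotations:
                rec.info[key] = float(s.annotations[key])
        rec.samples[sample_id]["AD"] = (d - v, v)
        rec.samples[sample_id]["DP"] = d
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# Count matrix TSV
# ---------------------------------------------------------------------------

_META_PREFIX = "##sample="


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    """Serialize a CountMatrix to TSV.

    Layout: ``##`` metadata lines (sample metadata, extraction thresholds),
    then a header ``chrom pos ref alt var_class`` followed by
    ``<sample>_var`` / ``<sample>_depth`` column pairs.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"##min_baseq={cm.min_baseq}\n")
        fh.write(f"##min_mapq={cm.min_mapq}\n")
        for s in cm.samples:
            fh.write(
                f"{_META_PREFIX}<id={s.sample_id},timepoint={s.timepoint_label},"
                f"purity={s.purity!r},ploidy={s.ploidy!r},role={s.role}>\n"
            )
        cols = ["chrom", "pos", "ref", "alt", "var_class"]
        for s in cm.samples:
            cols += [f"{s.sample_id}_var", f"{s.sample_id}_depth"]
        fh.write("\t".join(cols) + "\n")
        for i, site in enumerate(cm.sites):
            row = [site.chrom, str(site.pos), site.ref, site.alt, site.var_class]
            for j in range(len(cm.samples)):
                row += [str(cm.var_reads[i, j]), str(cm.depth[i, j])]
            fh.write("\t".join(row) + "\n")


def _parse_sample_meta(line: str) -> SampleMeta:
    inner = line[len(_META_PREFIX):].strip().strip("<>")
    kv = dict(item.split("=", 1) for item in inner.split(","))
    return SampleMeta(
        sample_id=kv["id"],
        timepoint_label=kv.get("timepoint", ""),
        purity=float(kv.get("purity", 1.0)),
        ploidy=float(kv.get("ploidy", 2.0)),
        role=kv.get("role", "tumor"),
    )


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Read a count-matrix TSV written by :func:`write_counts_tsv`.

    Also accepts bare tables (no ``##`` metadata); sample metadata then
    defaults to purity 1, ploidy 2, role tumor.
    """
    path = Path(path)
    metas: dict[str, SampleMeta] = {}
    min_baseq, min_mapq = 25, 40
    header_line = None
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for k, line in enumerate(lines):
        if line.startswith("##min_baseq="):
            min_baseq = int(line.strip().split("=", 1)[1])
        elif line.startswith("##min_mapq="):
            min_mapq = int(line.strip().split("=", 1)[1])
        elif line.startswith(_META_PREFIX):
            m = _parse_sample_meta(line)
            metas[m.sample_id] = m
        elif line.startswith("##"):
            continue
        else:
            header_line = line.rstrip("\n").split("\t")
            data_start = k + 1
            break
    if header_line is None:
        raise ValidationError(f"{path}: no header row found")
    df = pd.read_csv(
        path, sep="\t", skiprows=data_start - 1, comment=None, dtype={"chrom": str}
    )
    sample_ids = []
    for col in df.columns:
        if col.endswith("_var"):
            sid = col[: -len("_var")]
            if f"{sid}_depth" not in df.columns:
                raise ValidationError(f"column {sid}_depth missing for {col}")
            sample_ids.append(sid)
    if not sample_ids:
        raise ValidationError(f"{path}: no <sample>_var/<sample>_depth column pairs")
    sites = [
        VariantSite(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            var_class=str(getattr(r, "var_class", "SNV")),
        )
        for r in df.itertuples(index=False)
    ]
    v = df[[f"{s}_var" for s in sample_ids]].to_numpy(dtype=np.int64)
    d = df[[f"{s}_depth" for s in sample_ids]].to_numpy(dtype=np.int64)
    samples = [metas.get(s, SampleMeta(sample_id=s)) for s in sample_ids]
    return CountMatrix(
        sites=sites, samples=samples, var_reads=v, depth=d,
        min_baseq=min_baseq, min_mapq=min_mapq,
    )


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------

def read_cn_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read a CN-segment TSV (sample, chrom, start, end, n_major, n_minor).

    Coordinates are 1-based inclusive.  Overlapping segments within a
    (sample, chrom) pair are a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "start", "end", "n_major", "n_minor"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    segs = [
        CopyNumberSegment(
            sample_id=str(r["sample"]), chrom=str(r["chrom"]),
            start=int(r["start"]), end=int(r["end"]),
            n_major=int(r["n_major"]), n_minor=int(r["n_minor"]),
        )
        for _, r in df.iterrows()
    ]
    validate_segments(segs)
    return segs


def validate_segments(segs: Iterable[CopyNumberSegment]) -> None:
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for seg in segs:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sid, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments in {sid} {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_cn_segments(segs: Sequence[CopyNumberSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_major\tn_minor\n")
        for s in segs:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t"
                f"{s.n_major}\t{s.n_minor}\n"
            )


class SegmentIndex:
    """Sorted-interval index for per-(sample, chrom) CN lookup."""

    def __init__(self, segments: Iterable[CopyNumberSegment],
                 default: tuple[int, int] = (1, 1)):
        validate_segments(list(segments) if not isinstance(segments, list) else segments)
        self.default = default
        self._by_key: dict[tuple[str, str], tuple[list[int], list[CopyNumberSegment]]] = {}
        grouped: dict[tuple[str, str], list[CopyNumberSegment]] = {}
        for seg in segments:
            grouped.setdefault((seg.sample_id, seg.chrom), []).append(seg)
        for key, group in grouped.items():
            group = sorted(group, key=lambda s: s.start)
            self._by_key[key] = ([s.start for s in group], group)

    def lookup(self, sample_id: str, chrom: str, pos: int) -> tuple[int, int]:
        entry = self._by_key.get((sample_id, chrom))
        if entry is None:
            return self.default
        starts, group = entry
        k = bisect_right(starts, pos) - 1
        if k >= 0 and group[k].start <= pos <= group[k].end:
            return (group[k].n_major, group[k].n_minor)
        return self.default


def lookup_cn(segments: Sequence[CopyNumberSegment], sample_id: str, chrom: str,
              pos: int, default: tuple[int, int] = (1, 1)) -> tuple[int, int]:
    """Convenience single-query CN lookup (builds a transient index)."""
    return SegmentIndex(segments, default=default).lookup(sample_id, chrom, pos)


# ---------------------------------------------------------------------------
# Signature catalog
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-style SBS catalog TSV.

    Accepts either a single channel column (``Type`` entries like
    ``A[C>A]A``) or the two-column form (``Type`` = substitution,
    ``SubType`` = trinucleotide).  Rows are reordered to canonical
    channel order; every signature column becomes one catalog row.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "Type" in cols and df["Type"].astype(str).str.contains(r"\[").all():
        labels = df["Type"].astype(str)
        sig_cols = [c for c in cols if c != "Type"]
    elif "Type" in cols and "SubType" in cols:
        labels = df.apply(
            lambda r: f"{r['SubType'][0]}[{r['Type']}]{r['SubType'][2]}", axis=1
        )
        sig_cols = [c for c in cols if c not in ("Type", "SubType")]
    else:
        raise ValidationError(
            f"{path}: expected 'Type' channel column or 'Type'+'SubType' columns"
        )
    if sorted(labels) != sorted(CHANNELS):
        raise ValidationError(f"{path}: catalog does not cover the 96 channels")
    order = [int(np.argwhere(labels.values == c)[0][0]) for c in CHANNELS]
    probs = df[sig_cols].to_numpy(dtype=float)[order].T
    probs = probs / probs.sum(axis=1, keepdims=True)
    return SignatureCatalog(names=[str(c) for c in sig_cols], probs=probs)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        {"Type": CHANNELS}
        | {name: catalog.probs[i] for i, name in enumerate(catalog.names)}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------

def read_breakpoints(path: str | Path) -> list[BreakpointPair]:
    """Read a breakpoint TSV: chrom, bp_low, bp_high, sv_type[, flank seqs]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "bp_low", "bp_high", "sv_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            BreakpointPair(
                chrom=str(r["chrom"]), bp_low=int(r["bp_low"]),
                bp_high=int(r["bp_high"]), sv_type=str(r["sv_type"]),
                flank_low_seq=str(r.get("flank_low_seq", "") or ""),
                flank_high_seq=str(r.get("flank_high_seq", "") or ""),
            )
        )
    return out


def write_breakpoints(bps: Sequence[BreakpointPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbp_low\tbp_high\tsv_type\tflank_low_seq\tflank_high_seq\n")
        for b in bps:
            fh.write(
                f"{b.chrom}\t{b.bp_low}\t{b.bp_high}\t{b.sv_type}\t"
                f"{b.flank_low_seq}\t{b.flank_high_seq}\n"
            )


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
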