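"""Gene/transcript models and variant classification.

A single transcript model per gene carries exon structure, CDS limits,
strand and functional protein domains.  Variants (already annotated with a
consequence and, for missense, a REVEL score) are classified into the three
analysis classes used throughout the burden framework:

* ``PTV`` — protein-truncating: stop-gain, frameshift, splice-site;
* ``DAMAGING_MISSENSE`` — missense with REVEL strictly above a cutoff
  (default 0.7);
* ``SYNONYMOUS`` — the calibration class.

PTVs are additionally annotated for predicted escape from nonsense-mediated
decay (NMD): a truncation in the last coding exon, within the final 50
coding bases of the penultimate coding exon, or anywhere in a single-exon
gene, is expected to escape NMD and produce a truncated protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

logger = logging.getLogger("modyburden")

#: consequences counted as protein-truncating
PTV_CONSEQUENCES = frozenset({"stop_gain", "frameshift", "splice_site"})

VALID_CONSEQUENCES = frozenset(
    {"stop_gain", "frameshift", "splice_site", "missense", "synonymous", "other"}
)

#: length of the NMD-escape window at the 3' end of the penultimate exon (bp)
NMD_PENULTIMATE_WINDOW = 50


class VariantClass(Enum):
    """Analysis class of a variant; classes are pairwise disjoint."""

    PTV = "PTV"
    DAMAGING_MISSENSE = "DAMAGING_MISSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    NONE = "NONE"


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exons, CDS limits, strand and protein domains.

    Coordinates are genomic, 1-based and closed.  ``exons`` are given in
    transcription order (for a ``-`` strand gene, descending genomic
    position).  ``domains`` are named amino-acid intervals, 1-based closed.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end) genomic intervals, transcription order
    cds_start: int  # genomic coordinate, cds_start <= cds_end
    cds_end: int
    domains: tuple = ()  # of (name, aa_start, aa_end)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(
            self, "domains", tuple(tuple(d) for d in self.domains)
        )
        if not exons:
            raise ValueError("gene model needs at least one exon")
        for s, e in exons:
            if s > e:
                raise ValueError(f"malformed exon interval ({s}, {e})")
        genomic_sorted = sorted(exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if exons != tuple(expected):
            raise ValueError("exons not in transcription order for strand")
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start > cds_end")
        span = (min(s for s, _ in exons), max(e for _, e in exons))
        if not (span[0] <= self.cds_start and self.cds_end <= span[1]):
            raise ValueError("CDS outside exon span")
        plen = self.protein_length
        for name, a, b in self.domains:
            if not (1 <= a <= b <= plen):
                raise ValueError(f"domain {name} outside protein length {plen}")

    @property
    def coding_exons(self) -> tuple:
        """Exon intervals intersected with the CDS, transcription order."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return tuple(out)

    @property
    def single_exon(self) -> bool:
        return len(self.coding_exons) == 1

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_exons)

    @property
    def protein_length(self) -> int:
        # stop codon excluded when CDS length is a multiple of 3
        return max(1, self.cds_length // 3 - 1) if self.cds_length >= 6 else 1

    def coding_exon_index(self, pos: int) -> Optional[int]:
        """0-based index (transcription order) of the coding exon holding
        genomic position ``pos``; ``None`` if intronic/UTR."""
        for i, (s, e) in enumerate(self.coding_exons):
            if s <= pos <= e:
                return i
        return None

    def cds_position(self, pos: int) -> int:
        """1-based coding-sequence position of genomic position ``pos``."""
        idx = self.coding_exon_index(pos)
        if idx is None:
            raise ValueError(f"position {pos} not in a coding exon of {self.gene_id}")
        offset = sum(e - s + 1 for s, e in self.coding_exons[:idx])
        s, e = self.coding_exons[idx]
        within = (pos - s + 1) if self.strand == "+" else (e - pos + 1)
        return offset + within


@dataclass
class VariantRecord:
    """One variant with annotations, site QC metrics and population counts.

    ``site_metrics`` holds the caller-level site statistics (FS, QD,
    ReadPosRankSum, MQRankSum, MQ, AAscore) where available; ``flags`` marks
    low-complexity and low-coverage regions.  ``pop_ac``/``pop_an`` are
    per-population allele counts from an external reference.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    gene: Optional[str] = None
    revel: Optional[float] = None
    protein_pos: Optional[int] = None
    cds_offset_from_transcript_end: Optional[int] = None
    site_metrics: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    pop_ac: dict = field(default_factory=dict)
    pop_an: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.consequence not in VALID_CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.revel is not None and self.consequence != "missense":
            raise ValueError("revel only meaningful for missense variants")
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError("revel outside [0, 1]")
        for p, ac in self.pop_ac.items():
            an = self.pop_an.get(p, 0)
            if ac < 0 or an < 0 or ac > an:
                raise ValueError(f"pop_ac/pop_an inconsistent for {p}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def classify_variant(v: VariantRecord, revel_cutoff: float = 0.7) -> VariantClass:
    """Assign the analysis class of a variant.

    Stop-gain, frameshift and splice-site consequences are PTVs; missense
    variants with REVEL strictly above ``revel_cutoff`` are damaging
    missense (REVEL exactly at the cutoff does not qualify); synonymous
    variants form the calibration class.  A missense variant without a
    REVEL score cannot be assessed and falls to ``NONE`` with a warning.
    """
    if not (0.0 < revel_cutoff < 1.0):
        raise ValueError("revel_cutoff must be in (0, 1)")
    if v.consequence in PTV_CONSEQUENCES:
        return VariantClass.PTV
    if v.consequence == "missense":
        if v.revel is None:
            logger.warning(
                "missense variant %s:%d %s>%s lacks a REVEL score; class NONE",
                v.chrom, v.pos, v.ref, v.alt,
            )
            return VariantClass.NONE
        return (
            VariantClass.DAMAGING_MISSENSE
            if v.revel > revel_cutoff
            else VariantClass.NONE
        )
    if v.consequence == "synonymous":
        return VariantClass.SYNONYMOUS
    return VariantClass.NONE


def _truncation_exon(v: VariantRecord, g: GeneModel) -> int:
    """Coding-exon index (transcription order) where the truncation acts.

    Splice-site variants fall in introns; by convention they take the NMD
    status of the downstream (3' in transcript orientation) coding exon they
    disrupt.
    """
    idx = g.coding_exon_index(v.pos)
    if idx is not None:
        return idx
    if v.consequence != "splice_site":
        raise ValueError(
            f"PTV at {v.chrom}:{v.pos} not mappable to the CDS of {g.gene_id}"
        )
    # nearest downstream coding exon in transcript orientation
    for i, (s, e) in enumerate(g.coding_exons):
        if (g.strand == "+" and v.pos < s) or (g.strand == "-" and v.pos > e):
            return i
    raise ValueError(
        f"splice-site variant at {v.chrom}:{v.pos} downstream of all coding "
        f"exons of {g.gene_id}"
    )


def is_nmd_escape(v: VariantRecord, g: GeneModel) -> bool:
    """Predict whether a PTV escapes nonsense-mediated decay.

    True when the truncation lies in the last coding exon, within the final
    50 coding bases of the penultimate coding exon (inclusive window,
    measured along the transcript), or when the gene has a single coding
    exon (no exon junction downstream of any stop, so NMD never engages).
    """
    if classify_variant(v) is not VariantClass.PTV:
        raise ValueError("is_nmd_escape applies to PTVs only")
    if g.single_exon:
        return True
    n = len(g.coding_exons)
    idx = _truncation_exon(v, g)
    if idx == n - 1:
        return True
    if idx == n - 2:
        if g.coding_exon_index(v.pos) is None:
            # splice variant assigned to the penultimate exon boundary:
            # treat as disrupting the whole exon, i.e. not inside the window
            return False
        s, e = g.coding_exons[idx]
        dist_from_3prime = (e - v.pos + 1) if g.strand == "+" else (v.pos - s + 1)
        return dist_from_3prime <= NMD_PENULTIMATE_WINDOW
    return False


def in_functional_domain(v: VariantRecord, g: GeneModel) -> bool:
    """True iff the variant's amino-acid position falls inside any annotated
    functional domain (closed endpoints)."""
    if v.protein_pos is None:
        raise ValueError(
            f"variant {v.chrom}:{v.pos} has no protein position; cannot test "
            "domain membership"
        )
    return any(a <= v.protein_pos <= b for _, a, b in g.domains)
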