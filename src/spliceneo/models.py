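"""Core domain types shared across the pipeline.

Coordinate convention: everything in memory is 0-based, half-open
``(start, end)`` on the genome forward strand; GTF I/O converts to and from
the 1-based inclusive convention at the boundary.  Exon lists are stored in
genomic (left-to-right) order regardless of strand; transcript orientation
is recovered from ``strand`` when sequences are assembled.
"""
from __future__ import annotations

from dataclasses import dataclass, field

EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "MXE")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one annotated transcript.

    ``cds_start``/``cds_end`` are genomic coordinates (0-based half-open
    like exons); the CDS of the reference isoform is a multiple of 3 by
    construction and translation starts in frame 0 at the CDS 5' end
    (transcript orientation).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        for (s, e) in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval ({s}, {e})")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be in genomic order")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    Coordinate fields follow the rMATS layout generalised over event
    classes: ``exon`` is the class-defining interval (SE cassette exon, RI
    retained intron, A3SS/A5SS extended region, MXE first exon),
    ``upstream``/``downstream`` are the flanking exons, and ``exon2`` is
    only used by MXE (second mutually exclusive exon).
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    exon: tuple[int, int]
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    exon2: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if self.event_type == "MXE" and self.exon2 is None:
            raise ValueError("MXE events need exon2")

    @property
    def key(self) -> tuple:
        """Annotation-independent identity for cross-sample comparison."""
        return (
            self.chrom,
            self.strand,
            self.event_type,
            self.exon,
            self.upstream,
            self.downstream,
            self.exon2,
        )


@dataclass
class JunctionCounts:
    """Per-sample inclusion/skipping junction read counts for one event.

    ``ijc``/``sjc`` map sample name -> count; ``samples`` maps sample name
    -> (condition, replicate).
    """

    event_id: str
    ijc: dict[str, int]
    sjc: dict[str, int]
    inc_form_len: int
    skip_form_len: int
    samples: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if self.inc_form_len < 1 or self.skip_form_len < 1:
            raise ValueError("effective lengths must be >= 1")
        for d in (self.ijc, self.sjc):
            for v in d.values():
                if v < 0:
                    raise ValueError("junction counts must be >= 0")

    def by_condition(self, condition: str) -> list[tuple[int, int]]:
        """(ijc, sjc) pairs of every sample in `condition`, replicate order."""
        names = sorted(
            (s for s, (c, _) in self.samples.items() if c == condition),
            key=lambda s: self.samples[s][1],
        )
        return [(self.ijc[s], self.sjc[s]) for s in names]


@dataclass
class VariantProtein:
    """Protein-level consequence of applying one splice event to a transcript.

    ``junction_residue`` is the index of the first residue whose codon spans
    or follows the novel junction; ``novel_region`` is the half-open residue
    interval that does not match the reference protein (empty when the event
    does not change the coding sequence).
    """

    event_id: str
    transcript_id: str
    sequence: str
    frame_status: str  # "in_frame" | "frameshift"
    junction_residue: int
    novel_region: tuple[int, int]

    @property
    def has_novelty(self) -> bool:
        return self.novel_region[1] > self.novel_region[0]


@dataclass(frozen=True)
class NeopeptideRecord:
    """One unique 8-11-mer with provenance and self-proteome verdict."""

    sequence: str
    event_id: str
    transcript_id: str
    spans_junction: bool
    frame_status: str
    self_hit: bool = False

    def __post_init__(self) -> None:
        if not (8 <= len(self.sequence) <= 11):
            raise ValueError(f"peptide length {len(self.sequence)} outside 8-11")
        if not self.sequence.isupper():
            raise ValueError("peptide must be uppercase")


@dataclass
class CandidateNeoantigen:
    """Final-tier call: an MS-validated or predicted candidate neoantigen."""

    peptide: str
    allele: str
    tier: str  # "ms_validated" | "predicted"
    score: float
    immunogenicity: float | None
    evidence: dict = field(default_factory=dict)
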