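"""From filtered splice events to junction-spanning neopeptides.

Each event is applied to a matching annotated transcript to produce the
spliced mRNA of both isoform forms (inclusion and skipping); the variant
form — the one gaining abundance under treatment, by the sign of dPSI — is
translated from the annotated CDS start to the first stop codon.  A length
change in the coding region that is not a multiple of 3 shifts the reading
frame, so every downstream residue is novel until the new stop.  The novel
residue interval is digested into unique 8-11-mers and any k-mer occurring
verbatim in the self proteome is flagged and removed.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .models import NeopeptideRecord, SpliceEvent, TranscriptModel, VariantProtein


class EventNotRepresentable(ValueError):
    """Event cannot be realised on the given transcript."""


class NoProteinProduct(ValueError):
    """Event destroys the annotated start codon (or CDS start unmappable)."""


# --------------------------------------------------------------------------
# Isoform construction


def isoform_exons(
    event: SpliceEvent, transcript: TranscriptModel
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    """Genomic-order exon lists of the (inclusion, skipping) isoform forms."""
    exons = list(transcript.exons)
    t = event.event_type
    if t == "SE":
        for required in (event.upstream, event.exon, event.downstream):
            if required not in exons:
                raise EventNotRepresentable(
                    f"{event.event_id}: exon {required} not on {transcript.transcript_id}"
                )
        inclusion = tuple(exons)
        exclusion = tuple(e for e in exons if e != event.exon)
    elif t == "RI":
        up, dn = event.upstream, event.downstream
        if up not in exons or dn not in exons:
            raise EventNotRepresentable(
                f"{event.event_id}: flanking exons not on {transcript.transcript_id}"
            )
        if event.exon != (up[1], dn[0]):
            raise EventNotRepresentable(
                f"{event.event_id}: retained interval is not the intron between flanks"
            )
        merged = []
        for e in exons:
            if e == up:
                merged.append((up[0], dn[1]))
            elif e == dn:
                continue
            else:
                merged.append(e)
        inclusion = tuple(merged)
        exclusion = tuple(exons)
    elif t in ("A3SS", "A5SS"):
        short = event.upstream
        region = event.exon
        if short not in exons:
            raise EventNotRepresentable(
                f"{event.event_id}: short exon not on {transcript.transcript_id}"
            )
        if region[1] == short[0]:
            long_exon = (region[0], short[1])
        elif short[1] == region[0]:
            long_exon = (short[0], region[1])
        else:
            raise EventNotRepresentable(
                f"{event.event_id}: region not adjacent to the short exon"
            )
        inclusion = tuple(long_exon if e == short else e for e in exons)
        exclusion = tuple(exons)
    elif t == "MXE":
        if event.exon not in exons:
            raise EventNotRepresentable(
                f"{event.event_id}: first MXE exon not on {transcript.transcript_id}"
            )
        assert event.exon2 is not None
        inclusion = tuple(exons)
        exclusion = tuple(
            sorted((event.exon2 if e == event.exon else e for e in exons))
        )
    else:  # pragma: no cover - guarded by SpliceEvent
        raise EventNotRepresentable(f"unknown event type {t}")
    return inclusion, exclusion


def build_mrna(
    exons: tuple[tuple[int, int], ...], strand: str, chrom_seq: str
) -> str:
    """Spliced mRNA in transcript orientation (reverse-complemented on -)."""
    for (s, e) in exons:
        if e > len(chrom_seq):
            raise ValueError(f"exon ({s}, {e}) beyond sequence end {len(chrom_seq)}")
    forward = "".join(chrom_seq[s:e] for s, e in exons)
    if strand == "-":
        return str(Seq(forward).reverse_complement())
    return forward


def genomic_to_transcript(
    exons: tuple[tuple[int, int], ...], strand: str, pos: int
) -> int | None:
    """Transcript-orientation coordinate of genomic base `pos`; None if intronic."""
    offset = 0
    t_fwd = None
    for (s, e) in exons:
        if s <= pos < e:
            t_fwd = offset + (pos - s)
            break
        offset += e - s
    if t_fwd is None:
        return None
    if strand == "-":
        total = sum(e - s for s, e in exons)
        return total - 1 - t_fwd
    return t_fwd


def cds_offset_on(
    exons: tuple[tuple[int, int], ...], transcript: TranscriptModel
) -> int | None:
    """Transcript coordinate of the first CDS base on the given isoform."""
    first = transcript.cds_start if transcript.strand == "+" else transcript.cds_end - 1
    return genomic_to_transcript(exons, transcript.strand, first)


@dataclass(frozen=True)
class IsoformPair:
    """Both spliced mRNA forms of an event on one transcript."""

    event_id: str
    transcript_id: str
    inclusion_mrna: str
    exclusion_mrna: str
    inclusion_exons: tuple[tuple[int, int], ...]
    exclusion_exons: tuple[tuple[int, int], ...]


def apply_event(
    event: SpliceEvent, transcript: TranscriptModel, genome: dict[str, str]
) -> IsoformPair:
    """Realise both isoform forms of an event as spliced mRNA sequences."""
    if event.gene_id != transcript.gene_id:
        raise EventNotRepresentable(
            f"{event.event_id}: gene {event.gene_id} != {transcript.gene_id}"
        )
    inc_exons, exc_exons = isoform_exons(event, transcript)
    chrom_seq = genome[event.chrom]
    return IsoformPair(
        event_id=event.event_id,
        transcript_id=transcript.transcript_id,
        inclusion_mrna=build_mrna(inc_exons, transcript.strand, chrom_seq),
        exclusion_mrna=build_mrna(exc_exons, transcript.strand, chrom_seq),
        inclusion_exons=inc_exons,
        exclusion_exons=exc_exons,
    )


def reference_form(event_type: str) -> str:
    """Which isoform form the reference annotation encodes.

    The annotated transcript includes the cassette/first-MXE exon and the
    long A3SS/A5SS exon is a gain relative to it, while introns are spliced
    out — so RI's reference is the *exclusion* (spliced) form.
    """
    return "exclusion" if event_type == "RI" else "inclusion"


def select_transcript(
    event: SpliceEvent, transcripts: list[TranscriptModel]
) -> TranscriptModel:
    """Deterministic transcript choice: representable, then longest CDS, then id."""
    viable = []
    for t in transcripts:
        if t.gene_id != event.gene_id:
            continue
        try:
            isoform_exons(event, t)
        except EventNotRepresentable:
            continue
        viable.append(t)
    if not viable:
        raise EventNotRepresentable(
            f"{event.event_id}: no transcript of {event.gene_id} carries the event"
        )
    return max(viable, key=lambda t: (t.cds_end - t.cds_start, t.transcript_id))


# --------------------------------------------------------------------------
# Translation


def _translate_from(mrna: str, offset: int) -> str:
    """Standard-table translation from `offset` to the first stop codon."""
    coding = mrna[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate(to_stop=True))
    return aa


def _coding_length_change(
    pair: IsoformPair, transcript: TranscriptModel, variant_form: str
) -> int:
    """Net exonic-length change within the annotated CDS interval, in nt."""

    def cds_overlap(exons):
        lo, hi = transcript.cds_start, transcript.cds_end
        return sum(max(0, min(e, hi) - max(s, lo)) for s, e in exons)

    variant = pair.inclusion_exons if variant_form == "inclusion" else pair.exclusion_exons
    other = pair.exclusion_exons if variant_form == "inclusion" else pair.inclusion_exons
    return cds_overlap(variant) - cds_overlap(other)


def translate_variant(
    event: SpliceEvent,
    transcript: TranscriptModel,
    genome: dict[str, str],
    variant_form: str | None = None,
) -> tuple[VariantProtein, str]:
    """Translate the variant isoform; returns (variant protein, reference protein).

    ``variant_form`` is "inclusion" or "exclusion"; defaults to the
    non-reference form of the event class.  Frame status is frameshift iff
    the net coding-length change is not a multiple of 3.  The novel region
    is found by longest-common-prefix/suffix trimming against the reference
    protein (prefix-only for frameshifts, whose novelty extends to the new
    C-terminus); an in-frame deletion whose junction falls between intact
    codons leaves no changed residue, so its novel region is the pair of
    residues abutting the new junction (the peptides unique to the variant
    are exactly the k-mers bridging them).
    """
    pair = apply_event(event, transcript, genome)
    ref_form = reference_form(event.event_type)
    if variant_form is None:
        variant_form = "exclusion" if ref_form == "inclusion" else "inclusion"
    if variant_form not in ("inclusion", "exclusion"):
        raise ValueError(f"variant_form must be inclusion/exclusion, got {variant_form}")

    forms = {
        "inclusion": (pair.inclusion_mrna, pair.inclusion_exons),
        "exclusion": (pair.exclusion_mrna, pair.exclusion_exons),
    }
    var_mrna, var_exons = forms[variant_form]
    ref_mrna, ref_exons = forms[ref_form]

    var_off = cds_offset_on(var_exons, transcript)
    ref_off = cds_offset_on(ref_exons, transcript)
    if var_off is None or ref_off is None:
        raise NoProteinProduct(f"{event.event_id}: CDS start lost on variant isoform")

    var_prot = _translate_from(var_mrna, var_off)
    ref_prot = _translate_from(ref_mrna, ref_off)
    if not var_prot.startswith("M"):
        raise NoProteinProduct(f"{event.event_id}: start codon destroyed")

    delta_nt = _coding_length_change(pair, transcript, variant_form)
    frame_status = "frameshift" if delta_nt % 3 != 0 else "in_frame"

    # junction residue: first codon differing from the reference CDS
    var_cds = var_mrna[var_off:]
    ref_cds = ref_mrna[ref_off:]
    lcp_nt = _common_prefix_len(var_cds, ref_cds)
    junction_residue = min(lcp_nt // 3, max(len(var_prot) - 1, 0))

    if variant_form == ref_form or delta_nt == 0 and var_prot == ref_prot:
        novel = (0, 0)
    elif frame_status == "frameshift":
        p = _common_prefix_len(var_prot, ref_prot)
        novel = (p, len(var_prot))
        if novel[0] >= novel[1]:
            novel = (max(0, len(var_prot) - 1), len(var_prot))
    else:
        p = _common_prefix_len(var_prot, ref_prot)
        s = _common_suffix_len(var_prot, ref_prot)
        s = min(s, len(var_prot) - p, len(ref_prot) - p)
        if p < len(var_prot) - s:
            novel = (p, len(var_prot) - s)
        else:
            # clean in-frame deletion: flag the two residues abutting the junction
            j = min(max(p, 1), max(len(var_prot) - 1, 0))
            novel = (max(0, j - 1), min(len(var_prot), j + 1))
    vp = VariantProtein(
        event_id=event.event_id,
        transcript_id=transcript.transcript_id,
        sequence=var_prot,
        frame_status=frame_status,
        junction_residue=junction_residue,
        novel_region=novel,
    )
    return vp, ref_prot


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


# --------------------------------------------------------------------------
# Digestion and self-proteome subtraction

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def digest_kmers(
    variant: VariantProtein, k_range: tuple[int, int] = (8, 11)
) -> list[NeopeptideRecord]:
    """All unique k-mers (k in `k_range`) overlapping the novel region.

    ``spans_junction`` marks windows covering the junction residue.  Windows
    containing a non-standard residue (X from ambiguous codons, U) are
    dropped — binding predictors reject them.  Deduplicated by sequence,
    first (leftmost, smallest-k) provenance kept.
    """
    kmin, kmax = k_range
    seq = variant.sequence
    lo, hi = variant.novel_region
    if hi <= lo or len(seq) < kmin:
        return []
    seen: dict[str, NeopeptideRecord] = {}
    for k in range(kmin, kmax + 1):
        for start in range(0, len(seq) - k + 1):
            end = start + k
            if end <= lo or start >= hi:
                continue
            pep = seq[start:end]
            if pep in seen or not set(pep) <= STANDARD_AA:
                continue
            seen[pep] = NeopeptideRecord(
                sequence=pep,
                event_id=variant.event_id,
                transcript_id=variant.transcript_id,
                spans_junction=start <= variant.junction_residue < end,
                frame_status=variant.frame_status,
            )
    return list(seen.values())


def filter_self(
    kmers: list[NeopeptideRecord], proteome: dict[str, str]
) -> tuple[list[NeopeptideRecord], list[NeopeptideRecord]]:
    """Split k-mers into (novel, self) by exact substring match to the proteome."""
    if not proteome:
        raise ValueError("proteome is empty")
    lengths = {len(r.sequence) for r in kmers}
    universe: set[str] = set()
    for seq in proteome.values():
        for k in lengths:
            for i in range(0, len(seq) - k + 1):
                universe.add(seq[i : i + k])
    novel, hits = [], []
    for rec in kmers:
        if rec.sequence in universe:
            hits.append(
                NeopeptideRecord(
                    sequence=rec.sequence,
                    event_id=rec.event_id,
                    transcript_id=rec.transcript_id,
                    spans_junction=rec.spans_junction,
                    frame_status=rec.frame_status,
                    self_hit=True,
                )
            )
        else:
            novel.append(rec)
    return novel, hits


def neopeptides_for_event(
    event: SpliceEvent,
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    proteome: dict[str, str],
    delta_psi: float,
    k_range: tuple[int, int] = (8, 11),
) -> list[NeopeptideRecord]:
    """Full per-event path: pick transcript, translate the gaining form, digest, subtract self.

    The variant form follows the sign of dPSI (negative = skipping form
    gained under treatment).  Returns only proteome-novel records; raises
    EventNotRepresentable / NoProteinProduct like its parts.
    """
    transcript = select_transcript(event, transcripts)
    if event.event_type == "RI":
        form = "inclusion" if delta_psi > 0 else "exclusion"
    else:
        form = "exclusion" if delta_psi < 0 else "inclusion"
    variant, _ = translate_variant(event, transcript, genome, variant_form=form)
    kmers = digest_kmers(variant, k_range)
    novel, _ = filter_self(kmers, proteome)
    return novel
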