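"""Synthetic study generator: every input the pipeline consumes, seeded.

The generator emulates the design of a small perturbation RNA-seq study —
two conditions (control vs treated) in duplicate — at the junction-count
level: each gene gets one 5-exon transcript with an annotated CDS, the
middle (cassette) exon carries a skipped-exon event, and per-replicate
junction reads are drawn as Binomial splits of Poisson totals at the
planted, length-adjusted true PSI.  Treatment induces exon skipping
(negative dPSI) so the skipping isoform — frameshifted when the cassette
length is not a multiple of 3 — produces the planted neopeptides.  A subset
of those neopeptides is planted as strong binders in both predictor lookup
tables, and a subset of the binders as treatment-exclusive MS detections.

Everything is a pure function of ``SimulationConfig.seed``; each artifact
draws from its own child stream so tables are reproducible independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import translate as tr
from .events import effective_lengths
from .models import JunctionCounts, SpliceEvent, TranscriptModel

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# stop codons in all three frames, to terminate frameshifted read-through
STOP_GUARD = "TAACTAACTAAC"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_genes: int = 40
    n_events: int = 40
    read_length: int = 100
    min_anchor: int = 1
    replicates_per_condition: int = 2
    coverage_mean: float = 200.0
    psi_control: float = 0.75
    psi_treated: float = 0.45
    fraction_differential: float = 0.7
    fraction_frameshift: float = 0.5
    fraction_ri: float = 0.0
    fraction_minus_strand: float = 0.5
    gc_content: float = 0.5
    n_planted_binders: int = 10
    n_planted_ms_exclusive: int = 5
    n_background_ms: int = 40
    n_exclusive_self_ms: int = 10
    alleles: tuple[str, ...] = ("A*11:01", "B*40:01", "C*03:04")

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_events > self.n_genes:
            raise ValueError("n_events cannot exceed n_genes (one event per gene)")
        for name in ("psi_control", "psi_treated", "fraction_differential",
                     "fraction_frameshift", "fraction_ri",
                     "fraction_minus_strand", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read_length must be >= 2*min_anchor")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.n_planted_ms_exclusive > self.n_planted_binders:
            raise ValueError("MS-exclusive peptides are drawn from the planted binders")


@dataclass
class GroundTruth:
    """Planted state of one synthetic study, plus the reference artifacts."""

    config: SimulationConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    proteome: dict[str, str]
    events: list[SpliceEvent]
    # event_id -> dict(psi_control, psi_treated, differential, frameshift, variant_form)
    event_truth: dict[str, dict]
    tpm: dict[str, float]
    # event_id -> planted novel peptides (proteome-absent by construction)
    neopeptides: dict[str, list[str]]
    # rows: peptide, allele, rank_a, rank_b
    binders: pd.DataFrame = field(default_factory=pd.DataFrame)
    ms_exclusive_peptides: tuple[str, ...] = ()

    def truth_dict(self) -> dict:
        """JSON-serialisable planted truth (no sequences)."""
        return {
            "seed": self.config.seed,
            "event_truth": self.event_truth,
            "neopeptides": self.neopeptides,
            "binders": self.binders.to_dict(orient="records"),
            "ms_exclusive_peptides": list(self.ms_exclusive_peptides),
        }


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free random codons (reference frame has no internal stop)."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def _pick_cassette_len(rng: np.random.Generator, frameshift: bool) -> int:
    if frameshift:
        choices = [n for n in range(31, 62) if n % 3 != 0]
    else:
        choices = [n for n in range(30, 63) if n % 3 == 0]
    return int(rng.choice(choices))


@dataclass
class _Gene:
    transcript: TranscriptModel
    event: SpliceEvent
    chrom_seq: str
    frameshift: bool


def _build_gene(
    rng: np.random.Generator, idx: int, cfg: SimulationConfig,
    event_type: str, frameshift: bool,
) -> _Gene:
    gid, tid = f"GENE{idx:04d}", f"GENE{idx:04d}.t1"
    chrom = f"chr{idx + 1}"
    strand = "-" if rng.random() < cfg.fraction_minus_strand else "+"

    if event_type == "SE":
        middle_len = _pick_cassette_len(rng, frameshift)
    else:  # RI: the retained intron sets the frame, the cassette stays in frame
        middle_len = int(rng.choice([n for n in range(30, 63) if n % 3 == 0]))

    utr5 = _random_seq(rng, int(rng.integers(30, 61)), cfg.gc_content)
    parts = [int(rng.integers(60, 121)) for _ in range(4)]  # coding nt in exons 1,2,4,5
    total = sum(parts) + middle_len
    parts[3] += (3 - total % 3) % 3  # reference CDS a multiple of 3 (with stop)
    cds = _random_cds(rng, (sum(parts) + middle_len) // 3)
    c1, c2, c4 = parts[0], parts[1], parts[2]
    cuts = np.cumsum([c1, c2, middle_len, c4])
    exon_coding = [cds[: cuts[0]], cds[cuts[0]:cuts[1]], cds[cuts[1]:cuts[2]],
                   cds[cuts[2]:cuts[3]], cds[cuts[3]:]]
    utr3 = _random_seq(rng, int(rng.integers(40, 81)), cfg.gc_content) + STOP_GUARD

    def intron(length: int | None = None) -> str:
        n = int(rng.integers(80, 301)) if length is None else length
        s = _random_seq(rng, n, cfg.gc_content)
        return "GT" + s[2:-2] + "AG"

    if event_type == "RI":
        ri_len = int(rng.integers(81, 160))
        if frameshift and ri_len % 3 == 0:
            ri_len += 1
        if not frameshift and ri_len % 3 != 0:
            ri_len += 3 - ri_len % 3
        # the retained intron must not introduce an in-frame stop when retained
        while True:
            intron2 = "GT" + "".join(
                SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=ri_len // 3 + 2)
            )[: ri_len - 4] + "AG"
            inc_tail = exon_coding[1] + intron2 + "".join(exon_coding[2:])
            frame_seq = (exon_coding[0] + inc_tail)
            if frameshift or "*" not in str(Seq(frame_seq[: len(frame_seq) - len(frame_seq) % 3]).translate()):
                break
    else:
        intron2 = intron()

    spacer5 = _random_seq(rng, 50, cfg.gc_content)
    spacer3 = _random_seq(rng, 50, cfg.gc_content)
    pieces = [
        spacer5,
        utr5 + exon_coding[0],
        intron(),
        exon_coding[1],
        intron2,
        exon_coding[2],
        intron(),
        exon_coding[3],
        intron(),
        exon_coding[4] + "TAA" + utr3,
        spacer3,
    ]
    # sense-strand coordinates
    bounds, pos = [], 0
    for p in pieces:
        bounds.append((pos, pos + len(p)))
        pos += len(p)
    sense = "".join(pieces)
    exon_ivs = [bounds[1], bounds[3], bounds[5], bounds[7], bounds[9]]
    cds_start_sense = bounds[1][0] + len(utr5)
    cds_end_sense = bounds[9][0] + len(exon_coding[4]) + 3  # stop codon included

    L = len(sense)

    def gmap(iv: tuple[int, int]) -> tuple[int, int]:
        return iv if strand == "+" else (L - iv[1], L - iv[0])

    chrom_seq = sense if strand == "+" else str(Seq(sense).reverse_complement())
    cds_iv = gmap((cds_start_sense, cds_end_sense))
    transcript = TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
        exons=tuple(sorted(gmap(iv) for iv in exon_ivs)),
        cds_start=cds_iv[0], cds_end=cds_iv[1],
    )

    # event coordinates in genomic frame; flanks genomically ordered.  The
    # event always sits on the transcript's 2nd/3rd exons in sense space
    # (the RI intron is the specially built stop-free intron2).
    if event_type == "SE":
        up, dn = sorted([gmap(bounds[3]), gmap(bounds[7])])
        event = SpliceEvent(
            event_id=f"{gid}_SE", event_type="SE", gene_id=gid, chrom=chrom,
            strand=strand, exon=gmap(bounds[5]), upstream=up, downstream=dn,
        )
    else:
        up, dn = sorted([gmap(bounds[3]), gmap(bounds[5])])
        event = SpliceEvent(
            event_id=f"{gid}_RI", event_type="RI", gene_id=gid, chrom=chrom,
            strand=strand, exon=(up[1], dn[0]), upstream=up, downstream=dn,
        )
    return _Gene(transcript=transcript, event=event, chrom_seq=chrom_seq,
                 frameshift=frameshift)


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel], dict[str, str], list[SpliceEvent]]:
    """Genome, transcript models, reference proteome and candidate events.

    Deterministic in ``config.seed``; the proteome is the translation of
    every reference CDS (first stop codon, standard table).
    """
    rng = np.random.default_rng([config.seed, 1])
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    proteome: dict[str, str] = {}
    events: list[SpliceEvent] = []
    n_ri = int(round(config.fraction_ri * config.n_events))
    n_fs = int(round(config.fraction_frameshift * config.n_events))
    for i in range(config.n_genes):
        has_event = i < config.n_events
        etype = "RI" if (has_event and i < n_ri) else "SE"
        frameshift = has_event and i < n_fs
        g = _build_gene(rng, i, config, etype, frameshift)
        genome[g.transcript.chrom] = g.chrom_seq
        transcripts.append(g.transcript)
        mrna = tr.build_mrna(g.transcript.exons, g.transcript.strand, g.chrom_seq)
        off = tr.cds_offset_on(g.transcript.exons, g.transcript)
        assert off is not None
        prot = tr._translate_from(mrna, off)
        proteome[g.transcript.gene_id] = prot
        if has_event:
            events.append(g.event)
    return genome, transcripts, proteome, events


def _planted_psi(cfg: SimulationConfig, event: SpliceEvent, differential: bool) -> tuple[float, float]:
    if not differential:
        return cfg.psi_control, cfg.psi_control
    if event.event_type == "RI":
        # treatment induces retention: inclusion (retained) form gains
        return cfg.psi_treated, cfg.psi_control
    return cfg.psi_control, cfg.psi_treated


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Full planted state: annotation, PSI per event, neopeptides, binders.

    Planted neopeptides are computed by running the event-to-peptide path
    on the planted variant form, so they are guaranteed consistent with the
    emitted annotation and absent from the emitted proteome.
    """
    genome, transcripts, proteome, events = simulate_annotation(config)
    rng = np.random.default_rng([config.seed, 2])

    n_diff = int(round(config.fraction_differential * len(events)))
    diff_idx = set(rng.choice(len(events), size=n_diff, replace=False).tolist())

    event_truth: dict[str, dict] = {}
    neopeptides: dict[str, list[str]] = {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    for i, ev in enumerate(events):
        differential = i in diff_idx
        psi_c, psi_t = _planted_psi(config, ev, differential)
        delta = psi_t - psi_c
        truth = {
            "event_type": ev.event_type,
            "psi_control": psi_c,
            "psi_treated": psi_t,
            "differential": differential and psi_c != psi_t,
            "variant_form": None,
        }
        if truth["differential"]:
            form = ("inclusion" if delta > 0 else "exclusion") if ev.event_type == "RI" \
                else ("exclusion" if delta < 0 else "inclusion")
            truth["variant_form"] = form
            peps = tr.neopeptides_for_event(
                ev, by_gene[ev.gene_id], genome, proteome, delta_psi=delta,
            )
            neopeptides[ev.event_id] = sorted(r.sequence for r in peps)
        event_truth[ev.event_id] = truth

    # expression: differential event genes clearly expressed; background spans the TPM gate
    tpm: dict[str, float] = {}
    diff_genes = {
        ev.gene_id for i, ev in enumerate(events) if event_truth[ev.event_id]["differential"]
    }
    for t in transcripts:
        if t.gene_id in diff_genes:
            tpm[t.gene_id] = float(np.round(rng.uniform(5.0, 100.0), 3))
        else:
            tpm[t.gene_id] = float(np.round(rng.uniform(0.5, 50.0), 3))

    # planted binders: distinct novel peptides drawn across events
    pool = sorted({p for peps in neopeptides.values() for p in peps})
    n_bind = min(config.n_planted_binders, len(pool))
    chosen = sorted(rng.choice(len(pool), size=n_bind, replace=False).tolist()) if n_bind else []
    ab_alleles = [a for a in config.alleles if a[0] in "AB"] or list(config.alleles)
    rows = []
    for j in chosen:
        pep = pool[j]
        allele = ab_alleles[int(rng.integers(len(ab_alleles)))]
        rows.append({
            "peptide": pep,
            "allele": allele,
            "rank_a": float(np.round(rng.uniform(0.05, 1.95), 3)),
            "rank_b": float(np.round(rng.uniform(0.05, 1.95), 3)),
        })
    binders = pd.DataFrame(rows, columns=["peptide", "allele", "rank_a", "rank_b"])

    n_excl = min(config.n_planted_ms_exclusive, len(binders))
    excl_idx = sorted(rng.choice(len(binders), size=n_excl, replace=False).tolist()) if n_excl else []
    ms_excl = tuple(binders["peptide"].iloc[excl_idx]) if n_excl else ()

    return GroundTruth(
        config=config, genome=genome, transcripts=transcripts, proteome=proteome,
        events=events, event_truth=event_truth, tpm=tpm, neopeptides=neopeptides,
        binders=binders, ms_exclusive_peptides=ms_excl,
    )


def length_adjusted_theta(psi: float, inc_len: int, skip_len: int) -> float:
    """Probability that a junction read comes from the inclusion form."""
    num = psi * inc_len
    den = num + (1 - psi) * skip_len
    return num / den if den > 0 else 0.0


def simulate_junction_counts(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> dict[str, JunctionCounts]:
    """Per-replicate (IJC, SJC): Binomial split of Poisson totals at planted PSI."""
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 3])
    out: dict[str, JunctionCounts] = {}
    for ev in truth.events:
        inc_len, skip_len = effective_lengths(ev, cfg.read_length, cfg.min_anchor)
        t = truth.event_truth[ev.event_id]
        ijc, sjc, samples = {}, {}, {}
        for cond, psi in (("control", t["psi_control"]), ("treated", t["psi_treated"])):
            theta = length_adjusted_theta(psi, inc_len, skip_len)
            for r in range(1, cfg.replicates_per_condition + 1):
                total = int(rng.poisson(cfg.coverage_mean))
                i = int(rng.binomial(total, theta)) if total > 0 else 0
                name = f"{cond}_{r}"
                ijc[name], sjc[name] = i, total - i
                samples[name] = (cond, r)
        out[ev.event_id] = JunctionCounts(
            event_id=ev.event_id, ijc=ijc, sjc=sjc,
            inc_form_len=inc_len, skip_form_len=skip_len, samples=samples,
        )
    return out


def simulate_predictor_tables(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lookup tables for the two predictors with the planted binders <= 2 %Rank.

    Non-planted (peptide, allele) pairs get explicit weak ranks so both
    predictors cover the same universe.
    """
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 4])
    planted = {
        (row["peptide"], row["allele"]): (row["rank_a"], row["rank_b"])
        for _, row in truth.binders.iterrows()
    }
    peptides = sorted({p for peps in truth.neopeptides.values() for p in peps})
    rows_a, rows_b = [], []
    for pep in peptides:
        for allele in cfg.alleles:
            if (pep, allele) in planted:
                ra, rb = planted[(pep, allele)]
            else:
                ra = float(np.round(rng.uniform(5.0, 90.0), 3))
                rb = float(np.round(rng.uniform(5.0, 90.0), 3))
            rows_a.append({"peptide": pep, "allele": allele,
                           "predictor_id": "predA", "percent_rank": ra})
            rows_b.append({"peptide": pep, "allele": allele,
                           "predictor_id": "predB", "percent_rank": rb})
    cols = ["peptide", "allele", "predictor_id", "percent_rank"]
    return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)


def simulate_ms_table(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """MHC IP-MS peptide table: planted treatment-exclusive peptides + background.

    Planted exclusive peptides appear in >=1 treated replicate at FDR < 0.05
    and never in control; background peptides are proteome 9-mers seen in
    both conditions, plus a slab of treated-only *self* peptides that are
    exclusive but explained by the proteome (exercising the cross-check).
    """
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 5])
    rows = []
    reps = range(1, cfg.replicates_per_condition + 1)

    for pep in truth.ms_exclusive_peptides:
        n_hit = int(rng.integers(1, cfg.replicates_per_condition + 1))
        hit_reps = sorted(rng.choice(list(reps), size=n_hit, replace=False).tolist())
        for r in hit_reps:
            rows.append({"peptide": pep, "condition": "treated", "replicate": r,
                         "fdr": float(np.round(rng.uniform(0.001, 0.04), 4))})

    prots = sorted(truth.proteome.values())
    def self_peptide() -> str:
        while True:
            seq = prots[int(rng.integers(len(prots)))]
            if len(seq) >= 9:
                i = int(rng.integers(len(seq) - 8))
                return seq[i : i + 9]

    seen = set(truth.ms_exclusive_peptides)
    for _ in range(cfg.n_background_ms):
        pep = self_peptide()
        if pep in seen:
            continue
        seen.add(pep)
        for cond in ("control", "treated"):
            for r in reps:
                rows.append({"peptide": pep, "condition": cond, "replicate": r,
                             "fdr": float(np.round(rng.uniform(0.001, 0.04), 4))})
    for _ in range(cfg.n_exclusive_self_ms):
        pep = self_peptide()
        if pep in seen:
            continue
        seen.add(pep)
        for r in reps:
            rows.append({"peptide": pep, "condition": "treated", "replicate": r,
                         "fdr": float(np.round(rng.uniform(0.001, 0.04), 4))})
    return pd.DataFrame(rows, columns=["peptide", "condition", "replicate", "fdr"])


def simulate_immunogenicity(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Immunogenicity lookup: planted binders immunogenic (> 0.5), rest weak."""
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 6])
    rows = []
    planted = set()
    for _, row in truth.binders.iterrows():
        planted.add(row["peptide"])
        rows.append({"peptide": row["peptide"], "allele": row["allele"],
                     "immunogenicity": float(np.round(rng.uniform(0.55, 0.95), 3))})
    peptides = sorted({p for peps in truth.neopeptides.values() for p in peps})
    for pep in peptides:
        if pep in planted:
            continue
        for allele in cfg.alleles:
            rows.append({"peptide": pep, "allele": allele,
                         "immunogenicity": float(np.round(rng.uniform(0.0, 0.5), 3))})
    return pd.DataFrame(rows, columns=["peptide", "allele", "immunogenicity"])


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Same study with no planted differential signal (PSI equal across conditions)."""
    return replace(config, psi_treated=config.psi_control,
                   n_planted_binders=0, n_planted_ms_exclusive=0)
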