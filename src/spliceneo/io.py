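"""Readers and writers for the file dialects the pipeline exchanges.

GTF is 1-based inclusive on disk and 0-based half-open in memory; the
conversion happens here and nowhere else.  The JCEC table follows the
rMATS junction-count layout: one row per event, replicate counts joined
with commas inside ``IJC_SAMPLE_1``/``SJC_SAMPLE_1`` (control) and
``*_SAMPLE_2`` (treated).
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import JunctionCounts, SpliceEvent, TranscriptModel

JCEC_COLUMNS = [
    "event_id", "gene_id", "event_type", "chrom", "strand",
    "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "exon2Start_0base", "exon2End",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen",
]


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# GTF

def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Emit exon + CDS features, converting to 1-based inclusive coordinates."""
    lines = []
    for t in transcripts:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        for (s, e) in t.exons:
            lines.append(
                f"{t.chrom}\tspliceneo\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}"
            )
        lines.append(
            f"{t.chrom}\tspliceneo\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t{t.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip('"')
    return out


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon/CDS features into TranscriptModel objects (0-based half-open)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
        chrom, _, feature, start, end, _, strand, _, attr_field = fields
        if feature not in ("exon", "CDS"):
            continue
        attrs = _parse_attrs(attr_field)
        try:
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: missing attribute {exc}") from exc
        iv = (int(start) - 1, int(end))
        meta[tid] = (gid, chrom, strand)
        (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    out = []
    for tid, (gid, chrom, strand) in meta.items():
        cds_ivs = cds.get(tid, [])
        cds_start = min(s for s, _ in cds_ivs) if cds_ivs else 0
        cds_end = max(e for _, e in cds_ivs) if cds_ivs else 0
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return sorted(out, key=lambda t: t.transcript_id)


# --------------------------------------------------------------------------
# JCEC

def _join(values: list[int]) -> str:
    return ",".join(str(v) for v in values)


def _split_counts(field: str) -> list[int]:
    return [int(x) for x in str(field).split(",")]


def write_jcec(
    events: list[SpliceEvent],
    counts: dict[str, JunctionCounts],
    path: str | Path,
) -> None:
    rows = []
    for ev in events:
        jc = counts[ev.event_id]
        ctrl = jc.by_condition("control")
        trt = jc.by_condition("treated")
        e2 = ev.exon2 if ev.exon2 is not None else (-1, -1)
        rows.append({
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "exonStart_0base": ev.exon[0], "exonEnd": ev.exon[1],
            "upstreamES": ev.upstream[0], "upstreamEE": ev.upstream[1],
            "downstreamES": ev.downstream[0], "downstreamEE": ev.downstream[1],
            "exon2Start_0base": e2[0], "exon2End": e2[1],
            "IJC_SAMPLE_1": _join([i for i, _ in ctrl]),
            "SJC_SAMPLE_1": _join([s for _, s in ctrl]),
            "IJC_SAMPLE_2": _join([i for i, _ in trt]),
            "SJC_SAMPLE_2": _join([s for _, s in trt]),
            "IncFormLen": jc.inc_form_len,
            "SkipFormLen": jc.skip_form_len,
        })
    pd.DataFrame(rows, columns=JCEC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_jcec(path: str | Path) -> tuple[list[SpliceEvent], dict[str, JunctionCounts]]:
    df = pd.read_csv(path, sep="\t")
    events, counts = [], {}
    for _, row in df.iterrows():
        e2 = (int(row["exon2Start_0base"]), int(row["exon2End"]))
        ev = SpliceEvent(
            event_id=str(row["event_id"]),
            event_type=str(row["event_type"]),
            gene_id=str(row["gene_id"]),
            chrom=str(row["chrom"]),
            strand=str(row["strand"]),
            exon=(int(row["exonStart_0base"]), int(row["exonEnd"])),
            upstream=(int(row["upstreamES"]), int(row["upstreamEE"])),
            downstream=(int(row["downstreamES"]), int(row["downstreamEE"])),
            exon2=None if e2 == (-1, -1) else e2,
        )
        ijc_c = _split_counts(row["IJC_SAMPLE_1"])
        sjc_c = _split_counts(row["SJC_SAMPLE_1"])
        ijc_t = _split_counts(row["IJC_SAMPLE_2"])
        sjc_t = _split_counts(row["SJC_SAMPLE_2"])
        if len(ijc_c) != len(sjc_c) or len(ijc_t) != len(sjc_t):
            raise ValueError(f"{path}: ragged replicate counts for {ev.event_id}")
        ijc, sjc, samples = {}, {}, {}
        for r, (i, s) in enumerate(zip(ijc_c, sjc_c), start=1):
            name = f"control_{r}"
            ijc[name], sjc[name] = i, s
            samples[name] = ("control", r)
        for r, (i, s) in enumerate(zip(ijc_t, sjc_t), start=1):
            name = f"treated_{r}"
            ijc[name], sjc[name] = i, s
            samples[name] = ("treated", r)
        events.append(ev)
        counts[ev.event_id] = JunctionCounts(
            event_id=ev.event_id,
            ijc=ijc,
            sjc=sjc,
            inc_form_len=int(row["IncFormLen"]),
            skip_form_len=int(row["SkipFormLen"]),
            samples=samples,
        )
    return events, counts


# --------------------------------------------------------------------------
# Plain TSV tables

def read_tpm(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"], df["tpm"].astype(float)))


def write_tpm(tpm: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(tpm), "tpm": [tpm[g] for g in tpm]}
    ).to_csv(path, sep="\t", index=False)


def read_predictor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "predictor_id", "percent_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing predictor columns {sorted(missing)}")
    return df


def read_ms_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "condition", "replicate", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing MS columns {sorted(missing)}")
    return df


def read_immunogenicity(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {
        (row["peptide"], row["allele"]): float(row["immunogenicity"])
        for _, row in df.iterrows()
    }


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
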