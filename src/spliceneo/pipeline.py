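"""End-to-end orchestration and the run manifest.

``run_synthetic_pipeline`` executes the whole chain on generated inputs:

    simulate -> differential events -> filters -> variant translation ->
    k-mer digestion -> self-proteome subtraction -> dual-predictor
    consensus -> composite ranking -> MS exclusivity -> tier calls

The manifest accounts for every event (tested / skipped) and records
per-stage counts, thresholds and the seed, so two runs with the same
config produce byte-identical output bundles.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import candidates as cand
from . import io as sio
from . import synthdata as sd
from .binding import (LookupPredictor, consensus_binders, peptide_metadata,
                      predict, rank_candidates)
from .events import apply_filters, differential_table, test_all_events
from .models import NeopeptideRecord
from .translate import (EventNotRepresentable, NoProteinProduct,
                        neopeptides_for_event)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds; defaults are the conventional gating values."""

    max_q: float = 0.05
    min_abs_dpsi: float = 0.1
    min_tpm: float = 3.0
    tpm_log2: bool = False
    min_reads: int = 20
    rank_threshold: float = 2.0
    ms_fdr: float = 0.05
    immuno_threshold: float = 0.5
    top_n: int = 2
    k_min: int = 8
    k_max: int = 11
    literal_product: bool = False


@dataclass
class PipelineResult:
    truth: sd.GroundTruth
    counts: dict
    diff_events: list
    skipped: list
    filtered: list
    neopeptides: list[NeopeptideRecord]
    consensus: pd.DataFrame
    ranked: pd.DataFrame
    exclusive: set[str]
    candidates: list
    cross_check: dict
    manifest: dict = field(default_factory=dict)

    @property
    def ms_validated(self) -> list:
        return [c for c in self.candidates if c.tier == "ms_validated"]

    @property
    def predicted(self) -> list:
        return [c for c in self.candidates if c.tier == "predicted"]


def collect_neopeptides(
    filtered, truth: sd.GroundTruth, k_range: tuple[int, int]
) -> tuple[list[NeopeptideRecord], list[tuple[str, str]]]:
    """Variant translation + digestion + self subtraction over filtered events.

    Deduplicated by sequence across events (first event in id order wins),
    so the output is invariant to input order.
    """
    by_gene: dict[str, list] = {}
    for t in truth.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    records: dict[str, NeopeptideRecord] = {}
    dropped: list[tuple[str, str]] = []
    for de in sorted(filtered, key=lambda d: d.event.event_id):
        ev = de.event
        try:
            novel = neopeptides_for_event(
                ev, by_gene.get(ev.gene_id, []), truth.genome, truth.proteome,
                delta_psi=de.delta_psi, k_range=k_range,
            )
        except (EventNotRepresentable, NoProteinProduct) as exc:
            dropped.append((ev.event_id, str(exc)))
            continue
        for rec in novel:
            records.setdefault(rec.sequence, rec)
    return list(records.values()), dropped


def run_synthetic_pipeline(
    sim_config: sd.SimulationConfig,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic study; optionally write the output bundle."""
    cfg = config or PipelineConfig()

    truth = sd.simulate_truth(sim_config)
    counts = sd.simulate_junction_counts(truth)

    tested, skipped = test_all_events(truth.events, counts)
    filtered = apply_filters(
        tested, counts, truth.tpm,
        max_q=cfg.max_q, min_abs_dpsi=cfg.min_abs_dpsi,
        min_tpm=cfg.min_tpm, tpm_log2=cfg.tpm_log2, min_reads=cfg.min_reads,
    )

    neopeptides, dropped = collect_neopeptides(
        filtered, truth, (cfg.k_min, cfg.k_max)
    )

    tab_a, tab_b = sd.simulate_predictor_tables(truth)
    pred_a = LookupPredictor.from_frame(tab_a)
    pred_b = LookupPredictor.from_frame(tab_b)
    peptides = sorted(r.sequence for r in neopeptides)
    alleles = list(sim_config.alleles)
    df_a = predict(peptides, alleles, pred_a)
    df_b = predict(peptides, alleles, pred_b)
    consensus = consensus_binders(df_a, df_b, threshold=cfg.rank_threshold)

    diff_by_event = {de.event.event_id: de for de in tested}
    meta = peptide_metadata(neopeptides, diff_by_event, counts)
    ranked = rank_candidates(consensus, meta, literal_product=cfg.literal_product)

    ms = sd.simulate_ms_table(truth)
    exclusive = cand.ms_exclusive(ms, max_fdr=cfg.ms_fdr)
    immuno_df = sd.simulate_immunogenicity(truth)
    immuno = {
        (row["peptide"], row["allele"]): float(row["immunogenicity"])
        for _, row in immuno_df.iterrows()
    }
    called, call_log = cand.call_candidates(
        ranked, exclusive, immuno,
        top_n=cfg.top_n, immuno_threshold=cfg.immuno_threshold,
    )
    cross = cand.proteome_cross_check(
        exclusive, truth.proteome, {r.sequence for r in neopeptides}
    )

    manifest = {
        "seed": sim_config.seed,
        "simulation": asdict(sim_config),
        "thresholds": asdict(cfg),
        "counts": {
            "events_input": len(truth.events),
            "events_tested": len(tested),
            "events_skipped": len(skipped),
            "events_passed_filters": len(filtered),
            "events_unrepresentable": len(dropped),
            "neopeptides": len(neopeptides),
            "consensus_binders": int(len(consensus)),
            "ranked_candidates": int(len(ranked)),
            "ms_exclusive": len(exclusive),
            "candidates_ms_validated": sum(1 for c in called if c.tier == "ms_validated"),
            "candidates_predicted": sum(1 for c in called if c.tier == "predicted"),
            "cross_check_missed": len(cross["missed"]),
        },
        "call_log": call_log,
        "skipped_events": skipped,
        "dropped_events": dropped,
    }
    result = PipelineResult(
        truth=truth, counts=counts, diff_events=tested, skipped=skipped,
        filtered=filtered, neopeptides=neopeptides, consensus=consensus,
        ranked=ranked, exclusive=exclusive, candidates=called,
        cross_check=cross, manifest=manifest,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Write the full output bundle (plain text) to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = result.truth
    sio.write_fasta(truth.genome, out / "genome.fa")
    sio.write_fasta(truth.proteome, out / "proteome.fa")
    sio.write_gtf(truth.transcripts, out / "annotation.gtf")
    sio.write_jcec(truth.events, result.counts, out / "junction_counts.jcec.tsv")
    sio.write_tpm(truth.tpm, out / "expression.tpm.tsv")
    differential_table(result.diff_events).to_csv(
        out / "differential_events.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "sequence": r.sequence, "event_id": r.event_id,
                "transcript_id": r.transcript_id, "k": len(r.sequence),
                "spans_junction": r.spans_junction, "frame_status": r.frame_status,
            }
            for r in sorted(result.neopeptides, key=lambda r: r.sequence)
        ],
        columns=["sequence", "event_id", "transcript_id", "k",
                 "spans_junction", "frame_status"],
    ).to_csv(out / "neopeptides.tsv", sep="\t", index=False)
    result.ranked.to_csv(out / "ranked_candidates.tsv", sep="\t", index=False)
    cand.candidates_table(result.candidates).to_csv(
        out / "candidate_neoantigens.tsv", sep="\t", index=False
    )
    sio.write_json(result.cross_check, out / "cross_check.json")
    sio.write_json(truth.truth_dict(), out / "ground_truth.json")
    sio.write_json(result.manifest, out / "manifest.json")
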