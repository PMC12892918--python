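#!/usr/bin/env python
"""Translate filter-passing events into proteome-novel 8-11-mer neopeptides.

For each significant event the treatment-gaining isoform (skipping form for
negative dPSI) is spliced and translated from the annotated CDS start; the
novel residue stretch — the frameshifted tail, or the junction-bridging
residues for in-frame skips — is digested into unique 8-11-mers and every
k-mer found verbatim in the reference proteome is removed.
"""
from pathlib import Path

import pandas as pd

from spliceneo import io as sio
from spliceneo.models import NeopeptideRecord
from spliceneo.translate import (EventNotRepresentable, NoProteinProduct,
                                 neopeptides_for_event)

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE / "synthetic_inputs"


def main() -> None:
    diff = pd.read_csv(BASE / "differential_events.tsv", sep="\t")
    events, _ = sio.read_jcec(INP / "junction_counts.jcec.tsv")
    by_id = {e.event_id: e for e in events}
    transcripts = sio.read_gtf(INP / "annotation.gtf")
    by_gene: dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genome = sio.read_fasta(INP / "genome.fa")
    proteome = sio.read_fasta(INP / "proteome.fa")

    records: dict[str, NeopeptideRecord] = {}
    for _, row in diff[diff["passes_filters"].astype(bool)].iterrows():
        ev = by_id[str(row["event_id"])]
        try:
            novel = neopeptides_for_event(
                ev, by_gene[ev.gene_id], genome, proteome,
                delta_psi=float(row["delta_psi"]),
            )
        except (EventNotRepresentable, NoProteinProduct) as exc:
            print(f"  skipped {ev.event_id}: {exc}")
            continue
        for rec in novel:
            records.setdefault(rec.sequence, rec)

    out = pd.DataFrame(
        [{"sequence": r.sequence, "event_id": r.event_id,
          "transcript_id": r.transcript_id, "k": len(r.sequence),
          "spans_junction": r.spans_junction, "frame_status": r.frame_status}
         for r in sorted(records.values(), key=lambda r: r.sequence)]
    )
    out.to_csv(BASE / "neopeptides.tsv", sep="\t", index=False)
    sio.write_fasta(
        {f"np{i:05d}": s for i, s in enumerate(sorted(records))},
        BASE / "neopeptides.fa",
    )
    n_fs = int((out["frame_status"] == "frameshift").sum())
    print(f"{len(out)} unique proteome-novel neopeptides "
          f"({n_fs} from frameshifted isoforms, "
          f"{int(out['spans_junction'].sum())} spanning the novel junction)")


if __name__ == "__main__":
    main()
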