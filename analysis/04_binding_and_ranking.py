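#!/usr/bin/env python
"""Dual-predictor MHC binding consensus and composite candidate ranking.

Scores every neopeptide against the study HLA alleles with both lookup
predictors, keeps peptide-allele pairs called binders (%Rank <= 2) by BOTH,
and orders them by score = junction_count x |dPSI| / %Rank.
"""
from pathlib import Path

import pandas as pd

from spliceneo import io as sio
from spliceneo.binding import (LookupPredictor, consensus_binders,
                               peptide_metadata, predict, rank_candidates)
from spliceneo.models import NeopeptideRecord

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE / "synthetic_inputs"
ALLELES = ["A*11:01", "B*40:01", "C*03:04"]


def main() -> None:
    peps_df = pd.read_csv(BASE / "neopeptides.tsv", sep="\t")
    pred_a = LookupPredictor.from_frame(sio.read_predictor_table(INP / "predictor_A.tsv"))
    pred_b = LookupPredictor.from_frame(sio.read_predictor_table(INP / "predictor_B.tsv"))
    peptides = sorted(peps_df["sequence"])
    df_a = predict(peptides, ALLELES, pred_a)
    df_b = predict(peptides, ALLELES, pred_b)
    consensus = consensus_binders(df_a, df_b, threshold=2.0)
    print(f"{len(df_a)} peptide-allele pairs scored per predictor; "
          f"{len(consensus)} consensus binders (%Rank <= 2 under both)")

    diff = pd.read_csv(BASE / "differential_events.tsv", sep="\t")

    class _DE:
        def __init__(self, delta): self.delta_psi = delta

    diff_by_event = {str(r["event_id"]): _DE(float(r["delta_psi"]))
                     for _, r in diff.iterrows()}
    _, counts = sio.read_jcec(INP / "junction_counts.jcec.tsv")
    records = [
        NeopeptideRecord(
            sequence=r["sequence"], event_id=str(r["event_id"]),
            transcript_id=str(r["transcript_id"]),
            spans_junction=bool(r["spans_junction"]),
            frame_status=r["frame_status"],
        )
        for _, r in peps_df.iterrows()
    ]
    meta = peptide_metadata(records, diff_by_event, counts)
    ranked = rank_candidates(consensus, meta)
    ranked.to_csv(BASE / "ranked_candidates.tsv", sep="\t", index=False)
    print("top ranked candidates:")
    for _, row in ranked.head(5).iterrows():
        print(f"  {row['peptide']:>12} {row['allele']}  "
              f"ranks ({row['rank_a']:.2f}, {row['rank_b']:.2f})  "
              f"JC {row['junction_count']:.0f}  |dPSI| {row['abs_delta_psi']:.2f}  "
              f"score {row['score']:.1f}")


if __name__ == "__main__":
    main()
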