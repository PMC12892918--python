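#!/usr/bin/env python
"""Final candidate-neoantigen calls from MS exclusivity and immunogenicity.

Tier ms_validated: ranked consensus binders detected in >= 1 treated MS
replicate (FDR < 0.05) and never in control.  Tier predicted: top-2 remaining
binders by immunogenicity (> 0.5, HLA-A/-B only).  The cross-check partitions
all treatment-exclusive MS peptides into proteome-matching vs novel and flags
any novel peptide the pipeline failed to predict.
"""
from pathlib import Path

import pandas as pd

from spliceneo import io as sio
from spliceneo.candidates import (call_candidates, candidates_table,
                                  ms_exclusive, proteome_cross_check)

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE / "synthetic_inputs"


def main() -> None:
    ms = sio.read_ms_table(INP / "ms_peptides.tsv")
    ranked = pd.read_csv(BASE / "ranked_candidates.tsv", sep="\t")
    exclusive = ms_exclusive(ms, max_fdr=0.05)
    immuno = sio.read_immunogenicity(INP / "immunogenicity.tsv")
    called, log = call_candidates(ranked, exclusive, immuno, top_n=2)
    candidates_table(called).to_csv(
        BASE / "candidate_neoantigens.tsv", sep="\t", index=False
    )
    proteome = sio.read_fasta(INP / "proteome.fa")
    cross = proteome_cross_check(exclusive, proteome, set(ranked["peptide"]))
    sio.write_json(cross, BASE / "cross_check.json")

    n_ms = sum(c.tier == "ms_validated" for c in called)
    n_pr = sum(c.tier == "predicted" for c in called)
    print(f"{len(exclusive)} treatment-exclusive MS peptides "
          f"({len(cross['proteome_matching'])} explained by the proteome, "
          f"{len(cross['non_matching'])} novel)")
    print(f"{n_ms} MS-validated + {n_pr} predicted candidate neoantigens:")
    for c in called:
        imm = f"{c.immunogenicity:.2f}" if c.immunogenicity is not None else "-"
        print(f"  [{c.tier:>12}] {c.peptide:>12} {c.allele}  "
              f"score {c.score:.1f}  immunogenicity {imm}")
    print(f"missed novel exclusive peptides: {len(cross['missed'])}")


if __name__ == "__main__":
    main()
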