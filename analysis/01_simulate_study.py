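#!/usr/bin/env python
"""Generate the synthetic perturbation study all downstream steps analyse.

Two conditions (control vs treated) in duplicate, 40 genes each carrying one
cassette-exon event; treatment induces exon skipping (planted dPSI = -0.3) in
~70% of events, half of the cassettes frameshift when skipped.  Writes every
pipeline input (genome, GTF, proteome, JCEC junction counts, TPM, predictor
lookup tables, MHC IP-MS peptide table, immunogenicity table, ground truth)
under results/synthetic_inputs/.
"""
from pathlib import Path

from spliceneo import SimulationConfig
from spliceneo import io as sio
from spliceneo import synthdata as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_inputs"
SEED = 11


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    truth = sd.simulate_truth(cfg)
    counts = sd.simulate_junction_counts(truth)
    OUT.mkdir(parents=True, exist_ok=True)
    sio.write_fasta(truth.genome, OUT / "genome.fa")
    sio.write_fasta(truth.proteome, OUT / "proteome.fa")
    sio.write_gtf(truth.transcripts, OUT / "annotation.gtf")
    sio.write_jcec(truth.events, counts, OUT / "junction_counts.jcec.tsv")
    sio.write_tpm(truth.tpm, OUT / "expression.tpm.tsv")
    tab_a, tab_b = sd.simulate_predictor_tables(truth)
    tab_a.to_csv(OUT / "predictor_A.tsv", sep="\t", index=False)
    tab_b.to_csv(OUT / "predictor_B.tsv", sep="\t", index=False)
    sd.simulate_ms_table(truth).to_csv(OUT / "ms_peptides.tsv", sep="\t", index=False)
    sd.simulate_immunogenicity(truth).to_csv(
        OUT / "immunogenicity.tsv", sep="\t", index=False
    )
    sio.write_json(truth.truth_dict(), OUT / "ground_truth.json")

    n_diff = sum(t["differential"] for t in truth.event_truth.values())
    n_pep = sum(len(v) for v in truth.neopeptides.values())
    print(f"simulated {cfg.n_genes} genes / {cfg.n_events} events "
          f"({n_diff} with planted differential splicing)")
    print(f"planted {n_pep} candidate neopeptides across differential events, "
          f"{len(truth.binders)} strong binders, "
          f"{len(truth.ms_exclusive_peptides)} treatment-exclusive in MS")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
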