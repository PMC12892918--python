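"""Immunopeptidome gating: from ranked binders to candidate neoantigens.

Two tiers are called.  Tier ``ms_validated``: a ranked consensus binder that
is treatment-exclusive in the MHC IP-MS tables — identified in at least one
treated replicate at FDR < 0.05 and in no control replicate.  Tier
``predicted``: among the remaining ranked binders, the top-n by
immunogenicity with score > 0.5, restricted to HLA-A/-B alleles (HLA-C
immunogenicity predictions are not trusted for lack of training data).
"""
from __future__ import annotations

import pandas as pd

from .binding import allele_gene
from .models import CandidateNeoantigen


def ms_exclusive(
    ms_table: pd.DataFrame,
    max_fdr: float = 0.05,
    control_fdr_gate: float | None = None,
) -> set[str]:
    """Peptides detected in >=1 treated replicate (FDR < max_fdr) and never in control.

    By default ANY control-replicate record disqualifies, regardless of its
    FDR (conservative reading of treatment exclusivity);
    ``control_fdr_gate`` restricts disqualification to control records with
    fdr < gate.
    """
    bad = {"control", "treated"} - set(ms_table["condition"].unique())
    if bad == {"control", "treated"}:
        raise ValueError("MS table has neither condition")
    treated_hits = set(
        ms_table.loc[
            (ms_table["condition"] == "treated") & (ms_table["fdr"] < max_fdr),
            "peptide",
        ]
    )
    control = ms_table[ms_table["condition"] == "control"]
    if control_fdr_gate is not None:
        control = control[control["fdr"] < control_fdr_gate]
    control_seen = set(control["peptide"])
    return treated_hits - control_seen


def call_candidates(
    ranked: pd.DataFrame,
    exclusive: set[str],
    immunogenicity: dict[tuple[str, str], float],
    top_n: int = 2,
    immuno_threshold: float = 0.5,
) -> tuple[list[CandidateNeoantigen], list[str]]:
    """Assign tiers over the ranked candidate table.

    Returns (candidates, log).  ``ms_validated`` takes precedence and is
    deduplicated per peptide (best-scoring allele kept); ``predicted`` takes
    the top_n remaining unique peptides ordered by immunogenicity (then
    score), requires immunogenicity > threshold and an HLA-A/-B allele, and
    skips peptide-allele pairs without an immunogenicity score (logged).
    """
    log: list[str] = []
    out: list[CandidateNeoantigen] = []
    if ranked.empty:
        return out, log

    seen: set[str] = set()
    for _, row in ranked.iterrows():  # already score-ordered
        pep = row["peptide"]
        if pep in exclusive and pep not in seen:
            seen.add(pep)
            out.append(
                CandidateNeoantigen(
                    peptide=pep,
                    allele=row["allele"],
                    tier="ms_validated",
                    score=float(row["score"]),
                    immunogenicity=immunogenicity.get((pep, row["allele"])),
                    evidence={
                        "event_id": row["event_id"],
                        "rank_a": float(row["rank_a"]),
                        "rank_b": float(row["rank_b"]),
                        "abs_delta_psi": float(row["abs_delta_psi"]),
                        "junction_count": float(row["junction_count"]),
                    },
                )
            )

    eligible = []
    for _, row in ranked.iterrows():
        pep = row["peptide"]
        if pep in seen:
            continue
        if allele_gene(row["allele"]) not in ("A", "B"):
            log.append(f"{pep}/{row['allele']}: HLA-C excluded from predicted tier")
            continue
        score = immunogenicity.get((pep, row["allele"]))
        if score is None:
            log.append(f"{pep}/{row['allele']}: no immunogenicity score")
            continue
        eligible.append((row, float(score)))

    eligible.sort(key=lambda t: (-t[1], -float(t[0]["score"]), t[0]["peptide"]))
    n_called = 0
    for row, immuno in eligible:
        if n_called >= top_n:
            break
        pep = row["peptide"]
        if pep in seen:
            continue
        if immuno <= immuno_threshold:
            log.append(f"{pep}/{row['allele']}: immunogenicity {immuno} <= {immuno_threshold}")
            continue
        seen.add(pep)
        n_called += 1
        out.append(
            CandidateNeoantigen(
                peptide=pep,
                allele=row["allele"],
                tier="predicted",
                score=float(row["score"]),
                immunogenicity=immuno,
                evidence={
                    "event_id": row["event_id"],
                    "rank_a": float(row["rank_a"]),
                    "rank_b": float(row["rank_b"]),
                    "abs_delta_psi": float(row["abs_delta_psi"]),
                    "junction_count": float(row["junction_count"]),
                },
            )
        )
    return out, log


def proteome_cross_check(
    exclusive: set[str],
    proteome: dict[str, str],
    predicted_peptides: set[str],
) -> dict[str, list[str]]:
    """Partition treatment-exclusive MS peptides and flag unexplained ones.

    Peptides matching the self proteome are presentation changes of
    annotated protein; non-matching peptides should be explained by the
    predicted neopeptide set — any that are not are reported as missed
    candidates.
    """
    matching, non_matching = [], []
    for pep in sorted(exclusive):
        if any(pep in seq for seq in proteome.values()):
            matching.append(pep)
        else:
            non_matching.append(pep)
    missed = [p for p in non_matching if p not in predicted_peptides]
    return {
        "proteome_matching": matching,
        "non_matching": non_matching,
        "missed": missed,
    }


def candidates_table(cands: list[CandidateNeoantigen]) -> pd.DataFrame:
    rows = [
        {
            "peptide": c.peptide,
            "allele": c.allele,
            "tier": c.tier,
            "score": c.score,
            "immunogenicity": c.immunogenicity,
            **{f"evidence_{k}": v for k, v in c.evidence.items()},
        }
        for c in cands
    ]
    cols = ["peptide", "allele", "tier", "score", "immunogenicity",
            "evidence_event_id", "evidence_rank_a", "evidence_rank_b",
            "evidence_abs_delta_psi", "evidence_junction_count"]
    return pd.DataFrame(rows, columns=cols)
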