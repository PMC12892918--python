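"""MHC class I binding consensus and candidate ranking.

Predictors are pluggable: anything that returns a percentile rank (%Rank,
lower = stronger binder, in (0, 100]) per peptide-allele pair.  A
deterministic table-backed predictor and a keyed-hash pseudo-rank predictor
ship for testing; adapters around external tools can implement the same
protocol.  The consensus keeps peptide-allele pairs called binders
(%Rank <= 2 by default) by BOTH predictors, per allele.  Candidates are
ordered by a composite score combining binding rank, junction support and
splicing effect size:

    score = junction_count * |dPSI| / %Rank

so a stronger binder (smaller rank), deeper junction support, or a larger
splicing shift each strictly improve the score.  The literal signed product
-(%Rank) * JC * |dPSI| is available behind ``literal_product=True`` for
auditability; it orders strong binders in the wrong direction, which is why
it is not the default.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Protocol

import pandas as pd

from .models import NeopeptideRecord

_ALLELE_RE = re.compile(
    r"^(?:HLA-?)?([ABC])\*?(\d{2}):?(\d{2})$"
)


def normalize_allele(allele: str) -> str:
    """Normalise HLA allele spellings ("HLA-A11:01", "A1101", ...) to "A*11:01"."""
    m = _ALLELE_RE.match(allele.strip())
    if not m:
        raise ValueError(f"unrecognised HLA allele {allele!r}")
    gene, group, protein = m.groups()
    return f"{gene}*{group}:{protein}"


def allele_gene(allele: str) -> str:
    return normalize_allele(allele)[0]


class Predictor(Protocol):
    predictor_id: str

    def percent_rank(self, peptide: str, allele: str) -> float: ...


@dataclass
class LookupPredictor:
    """Table-backed predictor: returns the stored %Rank or a configured default."""

    predictor_id: str
    table: dict[tuple[str, str], float]
    default_rank: float = 50.0

    @classmethod
    def from_frame(cls, df: pd.DataFrame, predictor_id: str | None = None,
                   default_rank: float = 50.0) -> "LookupPredictor":
        if predictor_id is None:
            if df.empty:
                return cls(predictor_id="lookup", table={}, default_rank=default_rank)
            ids = df["predictor_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"ambiguous predictor_id in table: {sorted(ids)}")
            predictor_id = str(ids[0])
        sub = df[df["predictor_id"] == predictor_id]
        table = {
            (row["peptide"], normalize_allele(row["allele"])): float(row["percent_rank"])
            for _, row in sub.iterrows()
        }
        return cls(predictor_id=predictor_id, table=table, default_rank=default_rank)

    def percent_rank(self, peptide: str, allele: str) -> float:
        return self.table.get((peptide, normalize_allele(allele)), self.default_rank)


@dataclass
class KeyedHashPredictor:
    """Deterministic pseudo-rank from a keyed hash of (peptide, allele).

    Ranks are uniform on (0, 100]; useful as a structureless null predictor
    in tests.
    """

    predictor_id: str
    key: str = "0"

    def percent_rank(self, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(
            f"{self.key}|{peptide}|{normalize_allele(allele)}".encode()
        ).digest()
        frac = int.from_bytes(digest[:8], "big") / 2**64
        return 100.0 * (1.0 - frac) if frac < 1 else 100.0


def predict(
    peptides: list[str], alleles: list[str], predictor: Predictor
) -> pd.DataFrame:
    """One %Rank per (peptide, allele); peptides with non-standard residues rejected."""
    rows, rejected = [], []
    alleles = [normalize_allele(a) for a in alleles]
    for pep in peptides:
        if not (8 <= len(pep) <= 11) or not set(pep) <= set("ACDEFGHIKLMNPQRSTVWY"):
            rejected.append(pep)
            continue
        for allele in alleles:
            rank = predictor.percent_rank(pep, allele)
            if rank <= 0:
                raise ValueError(
                    f"{predictor.predictor_id} returned %Rank {rank} <= 0 for {pep}/{allele}"
                )
            rows.append({
                "peptide": pep,
                "allele": allele,
                "predictor_id": predictor.predictor_id,
                "percent_rank": rank,
            })
    df = pd.DataFrame(rows, columns=["peptide", "allele", "predictor_id", "percent_rank"])
    df.attrs["rejected"] = rejected
    return df


def consensus_binders(
    pred_a: pd.DataFrame, pred_b: pd.DataFrame, threshold: float = 2.0
) -> pd.DataFrame:
    """Peptide-allele pairs with %Rank <= threshold under both predictors.

    Pairs covered by only one predictor are excluded and counted in
    ``df.attrs["uncovered"]``.
    """
    a = pred_a[["peptide", "allele", "percent_rank"]].rename(
        columns={"percent_rank": "rank_a"}
    )
    b = pred_b[["peptide", "allele", "percent_rank"]].rename(
        columns={"percent_rank": "rank_b"}
    )
    merged = a.merge(b, on=["peptide", "allele"], how="outer", indicator=True)
    uncovered = int((merged["_merge"] != "both").sum())
    both = merged[merged["_merge"] == "both"].drop(columns="_merge")
    hits = both[(both["rank_a"] <= threshold) & (both["rank_b"] <= threshold)].copy()
    hits["best_rank"] = hits[["rank_a", "rank_b"]].max(axis=1)
    hits = hits.sort_values(["peptide", "allele"]).reset_index(drop=True)
    hits.attrs["uncovered"] = uncovered
    return hits


def rank_score(
    percent_rank: float,
    junction_count: float,
    abs_delta_psi: float,
    literal_product: bool = False,
) -> float:
    """Composite candidate score from binding rank, junction reads and |dPSI|."""
    if percent_rank <= 0:
        raise ValueError("percent_rank must be > 0")
    if junction_count <= 0 or not (0 < abs_delta_psi <= 1):
        raise ValueError("junction_count and |dPSI| must be positive (|dPSI| <= 1)")
    if literal_product:
        return -percent_rank * junction_count * abs_delta_psi
    return junction_count * abs_delta_psi / percent_rank


def rank_candidates(
    consensus: pd.DataFrame,
    peptide_meta: dict[str, dict],
    literal_product: bool = False,
) -> pd.DataFrame:
    """Score and order consensus binders.

    ``peptide_meta`` maps peptide -> {"junction_count", "abs_delta_psi",
    "event_id", ...} taken from the differential-event table (junction
    count = mean treated-replicate read count of the isoform-private
    junction).  Ordering: score desc, then lower worst-predictor rank,
    then higher junction count, then peptide lexicographic — a total
    order, so output is invariant to input permutation.
    """
    rows = []
    for _, row in consensus.iterrows():
        meta = peptide_meta.get(row["peptide"])
        if meta is None:
            continue
        score = rank_score(
            float(row["best_rank"]),
            float(meta["junction_count"]),
            float(meta["abs_delta_psi"]),
            literal_product=literal_product,
        )
        rows.append({
            "peptide": row["peptide"],
            "allele": row["allele"],
            "rank_a": float(row["rank_a"]),
            "rank_b": float(row["rank_b"]),
            "best_rank": float(row["best_rank"]),
            "junction_count": float(meta["junction_count"]),
            "abs_delta_psi": float(meta["abs_delta_psi"]),
            "event_id": meta.get("event_id"),
            "score": score,
        })
    df = pd.DataFrame(
        rows,
        columns=[
            "peptide", "allele", "rank_a", "rank_b", "best_rank",
            "junction_count", "abs_delta_psi", "event_id", "score",
        ],
    )
    if df.empty:
        return df
    df = df.sort_values(
        by=["score", "best_rank", "junction_count", "peptide", "allele"],
        ascending=[False, True, False, True, True],
    ).reset_index(drop=True)
    return df


def junction_count_for_event(counts, delta_psi: float) -> float:
    """Mean treated-replicate read count of the variant-private junction(s).

    Inclusion-gaining events (dPSI > 0) are supported by IJC, skipping-
    gaining events by SJC; the treated condition is used because that is
    where the neopeptide-encoding isoform is expressed.
    """
    pairs = counts.by_condition("treated")
    if delta_psi >= 0:
        vals = [i for i, _ in pairs]
    else:
        vals = [s for _, s in pairs]
    return float(sum(vals) / len(vals))


def peptide_metadata(
    neopeptides: list[NeopeptideRecord],
    diff_by_event: dict[str, "object"],
    counts: dict[str, "object"],
) -> dict[str, dict]:
    """Join each peptide to its event's junction support and |dPSI|."""
    meta = {}
    for rec in neopeptides:
        de = diff_by_event[rec.event_id]
        jc = junction_count_for_event(counts[rec.event_id], de.delta_psi)
        meta[rec.sequence] = {
            "event_id": rec.event_id,
            "junction_count": jc,
            "abs_delta_psi": abs(de.delta_psi),
            "frame_status": rec.frame_status,
        }
    return meta
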