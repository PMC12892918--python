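"""PSI estimation and differential splicing calls from junction counts.

The percent-spliced-in (PSI) estimator is the standard length-normalised
junction-count ratio:

    PSI = (IJC / L_inc) / (IJC / L_inc + SJC / L_skip)

where the effective form lengths count the read placements that can produce
an inclusion- or skipping-form junction read.  The between-condition test is
a pooled two-proportion likelihood-ratio (G) test on the inclusion fraction,
referred to chi-square(1), with Benjamini-Hochberg correction across events.
Significance and expression filters follow the conventional splice-neoantigen
gating: q < 0.05, |dPSI| >= 0.1, gene TPM >= 3 and IJC+SJC >= 20 in every
sample.  dPSI is signed treated - control, so a treatment that induces exon
skipping produces negative dPSI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import JunctionCounts, SpliceEvent


def effective_lengths(
    event: SpliceEvent, read_length: int, min_anchor: int = 1
) -> tuple[int, int]:
    """Effective (inclusion, skipping) form lengths in read placements.

    Each splice junction admits ``read_length - 2*min_anchor + 1`` distinct
    read start positions; region-type inclusion forms (RI, A3SS, A5SS) add
    the region length to that placement count.
    """
    if read_length < 2 * min_anchor:
        raise ValueError(
            f"read_length {read_length} < 2*min_anchor {2 * min_anchor}"
        )
    j = read_length - 2 * min_anchor + 1
    if event.event_type == "SE":
        return 2 * j, j
    if event.event_type == "RI":
        intron_len = event.exon[1] - event.exon[0]
        return intron_len + j, j
    if event.event_type in ("A3SS", "A5SS"):
        region = event.exon[1] - event.exon[0]
        return region + j, j
    if event.event_type == "MXE":
        return 2 * j, 2 * j
    raise ValueError(f"unknown event type {event.event_type!r}")


def compute_psi(
    ijc: int, sjc: int, inc_form_len: int, skip_form_len: int
) -> float | None:
    """Length-normalised PSI; ``None`` when the event is unquantifiable (0/0)."""
    if ijc < 0 or sjc < 0:
        raise ValueError("counts must be non-negative")
    if inc_form_len < 1 or skip_form_len < 1:
        raise ValueError("effective lengths must be >= 1")
    if ijc == 0 and sjc == 0:
        return None
    inc = ijc / inc_form_len
    skip = sjc / skip_form_len
    return inc / (inc + skip)


def _pooled_theta(pairs: list[tuple[int, int]]) -> tuple[int, int]:
    return sum(i for i, _ in pairs), sum(s for _, s in pairs)


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def differential_test(counts: JunctionCounts) -> tuple[float, float, dict]:
    """LR test of one shared vs two condition-specific inclusion fractions.

    Returns (delta_psi, p_value, detail).  delta_psi is the difference of
    mean per-replicate PSI (treated - control), with unquantifiable
    replicates excluded from the mean.  The p-value comes from a G-test on
    the pooled (IJC, SJC) 2x2 table against chi-square(1).

    Raises ``ValueError`` when a whole condition is unquantifiable or has
    fewer than 2 replicates.
    """
    ctrl = counts.by_condition("control")
    trt = counts.by_condition("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError(f"{counts.event_id}: need >=2 replicates per condition")

    psis = {}
    for cond, pairs in (("control", ctrl), ("treated", trt)):
        vals = [
            compute_psi(i, s, counts.inc_form_len, counts.skip_form_len)
            for i, s in pairs
        ]
        vals = [v for v in vals if v is not None]
        if not vals:
            raise ValueError(f"{counts.event_id}: unquantifiable in {cond}")
        psis[cond] = vals

    delta = float(np.mean(psis["treated"]) - np.mean(psis["control"]))

    table = np.array([_pooled_theta(ctrl), _pooled_theta(trt)], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0 or (row == 0).any():
        raise ValueError(f"{counts.event_id}: no reads in one condition")
    # G = 2 * sum obs*log(obs/exp) with expected from the shared-proportion fit
    g = 2.0 * float(
        _xlogx(table).sum() - _xlogx(row).sum() - _xlogx(col).sum() + _xlogx(np.array([total])).sum()
    )
    g = max(g, 0.0)
    p = float(stats.chi2.sf(g, df=1)) if g > 0 else 1.0
    detail = {
        "psi_control": psis["control"],
        "psi_treated": psis["treated"],
        "g_statistic": g,
    }
    return delta, p, detail


FILTER_COLUMNS = ["pass_q", "pass_dpsi", "pass_tpm", "pass_reads"]


@dataclass
class DifferentialEvent:
    """Differential call and filter verdicts for one splice event."""

    event: SpliceEvent
    psi_control: list[float]
    psi_treated: list[float]
    delta_psi: float
    p_value: float
    q_value: float = float("nan")
    gene_tpm: float = float("nan")
    verdicts: dict = field(default_factory=dict)
    skipped_reason: str | None = None

    @property
    def passes_filters(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


def test_all_events(
    events: list[SpliceEvent], counts: dict[str, JunctionCounts]
) -> tuple[list[DifferentialEvent], list[tuple[str, str]]]:
    """Run the differential test on every event; BH-adjust across the tested set.

    Returns (tested events, skipped (event_id, reason) pairs).  q-values are
    Benjamini-Hochberg over all events that could be tested; ranking ties
    are broken by event_id via a stable pre-sort so output is
    order-invariant.
    """
    order = sorted(events, key=lambda e: e.event_id)
    tested, skipped = [], []
    for ev in order:
        jc = counts[ev.event_id]
        try:
            delta, p, detail = differential_test(jc)
        except ValueError as exc:
            skipped.append((ev.event_id, str(exc)))
            continue
        tested.append(
            DifferentialEvent(
                event=ev,
                psi_control=detail["psi_control"],
                psi_treated=detail["psi_treated"],
                delta_psi=delta,
                p_value=p,
            )
        )
    if tested:
        idx = sorted(range(len(tested)), key=lambda i: (tested[i].p_value, tested[i].event.event_id))
        pvals = [tested[i].p_value for i in idx]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for i, q in zip(idx, qvals):
            tested[i].q_value = float(q)
    return tested, skipped


def apply_filters(
    diff_events: list[DifferentialEvent],
    counts: dict[str, JunctionCounts],
    tpm: dict[str, float],
    *,
    max_q: float = 0.05,
    min_abs_dpsi: float = 0.1,
    min_tpm: float = 3.0,
    tpm_log2: bool = False,
    min_reads: int = 20,
) -> list[DifferentialEvent]:
    """Annotate per-filter verdicts; return the events passing all filters.

    ``min_reads`` requires pooled IJC+SJC >= threshold in *every* sample.
    ``tpm_log2`` switches the expression filter to log2(TPM) >= min_tpm.
    Events whose gene has no TPM entry are dropped with an explicit reason.
    """
    passed = []
    for de in diff_events:
        gid = de.event.gene_id
        if gid not in tpm:
            de.skipped_reason = f"no TPM for gene {gid}"
            de.verdicts = {}
            continue
        de.gene_tpm = float(tpm[gid])
        expr = np.log2(de.gene_tpm) if tpm_log2 else de.gene_tpm
        jc = counts[de.event.event_id]
        depth_ok = all(
            jc.ijc[s] + jc.sjc[s] >= min_reads for s in jc.samples
        )
        de.verdicts = {
            "pass_q": bool(de.q_value < max_q),
            "pass_dpsi": bool(abs(de.delta_psi) >= min_abs_dpsi),
            "pass_tpm": bool(expr >= min_tpm),
            "pass_reads": bool(depth_ok),
        }
        if de.passes_filters:
            passed.append(de)
    return passed


def psi_shift_test(
    diff_events: list[DifferentialEvent], n_comparisons: int = 1
) -> tuple[float, float]:
    """Two-sample t test on pooled PSI distributions, control vs treated.

    Mirrors the per-cell-line comparison of PSI values over significant
    events; ``n_comparisons`` applies a Bonferroni factor (capped at 1).
    Returns (t_statistic, adjusted p).  Degenerate variance yields p = 1.
    """
    if len(diff_events) < 2:
        raise ValueError("need >= 2 events for the PSI shift test")
    ctrl = np.concatenate([de.psi_control for de in diff_events])
    trt = np.concatenate([de.psi_treated for de in diff_events])
    if np.ptp(ctrl) == 0 and np.ptp(trt) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(trt, ctrl, equal_var=False)
    if np.isnan(p):
        return float(t), 1.0
    return float(t), float(min(1.0, p * n_comparisons))


def gc_content(seq: str) -> float:
    """Fraction of G/C over A/C/G/T (case-insensitive)."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no ACGT bases")
    return (s.count("G") + s.count("C")) / acgt


def exon_architecture(
    event: SpliceEvent, genome: dict[str, str]
) -> dict[str, float]:
    """Cassette-exon length, flanking intron lengths and local GC content."""
    if event.event_type != "SE":
        raise ValueError("exon architecture is defined for SE events")
    up, ex, dn = event.upstream, event.exon, event.downstream
    if not (up[1] < ex[0] and ex[1] < dn[0]):
        raise ValueError(f"{event.event_id}: exons not separated by introns")
    seq = genome[event.chrom][ex[0]:ex[1]]
    return {
        "exon_length": float(ex[1] - ex[0]),
        "upstream_intron_length": float(ex[0] - up[1]),
        "downstream_intron_length": float(dn[0] - ex[1]),
        "gc": gc_content(seq),
    }


def exon_architecture_stats(
    group_a: list[SpliceEvent],
    group_b: list[SpliceEvent],
    genome: dict[str, str],
) -> pd.DataFrame:
    """Mann-Whitney U comparison of exon-architecture features between groups.

    Returns one row per feature with group medians and the two-sided p.
    Events that are not SE or lack flanking introns are excluded (counted
    in the ``excluded_*`` attributes of the frame).
    """
    feats, excluded = {}, {"a": 0, "b": 0}
    for label, group in (("a", group_a), ("b", group_b)):
        rows = []
        for ev in group:
            try:
                rows.append(exon_architecture(ev, genome))
            except (ValueError, KeyError):
                excluded[label] += 1
        feats[label] = pd.DataFrame(rows)
    if feats["a"].empty or feats["b"].empty:
        raise ValueError("both groups must contain comparable SE events")
    out = []
    for col in ["exon_length", "upstream_intron_length", "downstream_intron_length", "gc"]:
        u, p = stats.mannwhitneyu(feats["a"][col], feats["b"][col], alternative="two-sided")
        out.append({
            "feature": col,
            "median_a": float(feats["a"][col].median()),
            "median_b": float(feats["b"][col].median()),
            "u_statistic": float(u),
            "p_value": float(p),
        })
    df = pd.DataFrame(out)
    df.attrs["excluded_a"] = excluded["a"]
    df.attrs["excluded_b"] = excluded["b"]
    return df


def differential_table(diff_events: list[DifferentialEvent]) -> pd.DataFrame:
    """Long-form results table (one row per event) for the TSV interface."""
    rows = []
    for de in diff_events:
        row = {
            "event_id": de.event.event_id,
            "gene_id": de.event.gene_id,
            "event_type": de.event.event_type,
            "chrom": de.event.chrom,
            "strand": de.event.strand,
            "psi_control": ",".join(f"{v:.6g}" for v in de.psi_control),
            "psi_treated": ",".join(f"{v:.6g}" for v in de.psi_treated),
            "delta_psi": de.delta_psi,
            "p_value": de.p_value,
            "q_value": de.q_value,
            "gene_tpm": de.gene_tpm,
            "passes_filters": de.passes_filters,
        }
        for c in FILTER_COLUMNS:
            row[c] = de.verdicts.get(c)
        rows.append(row)
    return pd.DataFrame(rows)
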