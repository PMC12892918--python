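"""PSI estimation, differential testing, filters and architecture statistics."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceneo.events import (apply_filters, compute_psi, differential_test,
                              effective_lengths, exon_architecture,
                              exon_architecture_stats, gc_content,
                              psi_shift_test, test_all_events as run_differential_tests)
from spliceneo.models import JunctionCounts, SpliceEvent

from _oracles import oracle_psi


def _se_event(eid="ev1"):
    return SpliceEvent(
        event_id=eid, event_type="SE", gene_id="G1", chrom="chr1", strand="+",
        exon=(300, 345), upstream=(100, 200), downstream=(500, 600),
    )


def _jc(ctrl, trt, inc_len=198, skip_len=99, eid="ev1"):
    ijc, sjc, samples = {}, {}, {}
    for cond, pairs in (("control", ctrl), ("treated", trt)):
        for r, (i, s) in enumerate(pairs, start=1):
            name = f"{cond}_{r}"
            ijc[name], sjc[name] = i, s
            samples[name] = (cond, r)
    return JunctionCounts(
        event_id=eid, ijc=ijc, sjc=sjc,
        inc_form_len=inc_len, skip_form_len=skip_len, samples=samples,
    )


class TestEffectiveLengths:
    def test_se_default_read_length(self):
        assert effective_lengths(_se_event(), 100, 1) == (198, 99)

    def test_se_minimal_read(self):
        assert effective_lengths(_se_event(), 2, 1) == (2, 1)

    def test_se_ratio_invariant_in_placements(self):
        # inclusion/skipping ratio is 2 for SE whatever the placement count
        for rl in (10, 50, 100, 151):
            inc, skip = effective_lengths(_se_event(), rl, 1)
            assert inc == 2 * skip == 2 * (rl - 2 + 1)

    def test_ri_adds_region_length(self):
        ev = SpliceEvent(
            event_id="ri", event_type="RI", gene_id="G", chrom="c", strand="+",
            exon=(200, 290), upstream=(100, 200), downstream=(290, 400),
        )
        inc, skip = effective_lengths(ev, 100, 1)
        assert inc == 90 + 99 and skip == 99

    def test_rejects_too_short_reads(self):
        with pytest.raises(ValueError):
            effective_lengths(_se_event(), 3, 2)


class TestComputePsi:
    @pytest.mark.parametrize(
        "ijc,sjc,expected", [(0, 5, 0.0), (5, 0, 1.0)]
    )
    def test_degenerate_counts(self, ijc, sjc, expected):
        assert compute_psi(ijc, sjc, 198, 99) == expected

    def test_hand_normalisation(self):
        # ijc=sjc=10, lengths (2u, u): 10/2=5 inclusion density; 5/(5+10)
        assert compute_psi(10, 10, 200, 100) == pytest.approx(1 / 3)

    def test_unquantifiable_is_none_not_zero(self):
        assert compute_psi(0, 0, 198, 99) is None

    def test_exhaustive_against_oracle(self):
        lengths = [(198, 99), (2, 1), (150, 75), (189, 99)]
        for inc_len, skip_len in lengths:
            for ijc in range(51):
                for sjc in range(51):
                    got = compute_psi(ijc, sjc, inc_len, skip_len)
                    want = oracle_psi(ijc, sjc, inc_len, skip_len)
                    if want is None:
                        assert got is None
                    else:
                        assert got == pytest.approx(want, abs=1e-12)
                        assert 0.0 <= got <= 1.0

    @given(ijc=st.integers(1, 500), sjc=st.integers(1, 500))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_counts(self, ijc, sjc):
        base = compute_psi(ijc, sjc, 198, 99)
        assert compute_psi(ijc + 1, sjc, 198, 99) > base
        assert compute_psi(ijc, sjc + 1, 198, 99) < base


class TestDifferentialTest:
    def test_null_identity(self):
        jc = _jc([(500, 500), (500, 500)], [(500, 500), (500, 500)])
        delta, p, _ = differential_test(jc)
        assert delta == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_binomial_lrt(self):
        # pooled control (1000, 1000), treated (200, 1800), lengths (2u, u)
        jc = _jc([(500, 500), (500, 500)], [(100, 900), (100, 900)],
                 inc_len=200, skip_len=100)
        delta, p, detail = differential_test(jc)
        # per-formula PSI: control (500/2)/(250+500)=1/3, treated (100/2)/(50+900)=1/19
        assert delta == pytest.approx(1 / 19 - 1 / 3)
        assert p < 1e-6
        # LR statistic equals the closed-form G over the pooled 2x2 table
        table = np.array([[1000, 1000], [200, 1800]], dtype=float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        g_ref = 2 * (table * np.log(table / exp)).sum()
        assert detail["g_statistic"] == pytest.approx(g_ref, rel=1e-10)

    def test_requires_two_replicates(self):
        jc = _jc([(10, 10)], [(10, 10), (10, 10)])
        with pytest.raises(ValueError):
            differential_test(jc)

    def test_unquantifiable_condition_rejected(self):
        jc = _jc([(0, 0), (0, 0)], [(10, 10), (10, 10)])
        with pytest.raises(ValueError):
            differential_test(jc)


class TestBHAndFilters:
    def test_bh_on_constant_pvector(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.001] * 100, method="fdr_bh")[1]
        assert np.allclose(q, 0.001)

    def test_qvalues_permutation_invariant(self):
        events = [_se_event(f"e{i}") for i in range(6)]
        counts = {}
        for i, ev in enumerate(events):
            shift = 50 * i
            counts[ev.event_id] = _jc(
                [(500, 500), (480, 520)],
                [(500 - shift, 500 + shift), (480 - shift, 520 + shift)],
                eid=ev.event_id,
            )
        fwd, _ = run_differential_tests(events, counts)
        rev, _ = run_differential_tests(events[::-1], counts)
        q_fwd = {d.event.event_id: d.q_value for d in fwd}
        q_rev = {d.event.event_id: d.q_value for d in rev}
        assert q_fwd == q_rev
        assert all(0 <= q <= 1 for q in q_fwd.values())

    def _fixture_events(self):
        """10 events; exactly 4 satisfy all four predicates by construction."""
        specs = []
        # (strong delta?, tpm, depth_ok?) -> pass iff strong & tpm>=3 & depth
        plan = [
            (True, 50.0, True),   # pass
            (True, 10.0, True),   # pass
            (True, 5.0, True),    # pass
            (True, 3.0, True),    # pass (TPM boundary inclusive)
            (False, 50.0, True),  # fails dpsi/q
            (False, 8.0, True),
            (True, 1.0, True),    # fails TPM
            (True, 2.9, True),    # fails TPM
            (True, 50.0, False),  # fails depth
            (False, 0.5, True),
        ]
        events, counts, tpm = [], {}, {}
        for i, (strong, t, depth_ok) in enumerate(plan):
            eid = f"fx{i}"
            ev = SpliceEvent(
                event_id=eid, event_type="SE", gene_id=f"GF{i}", chrom="chr1",
                strand="+", exon=(300, 345), upstream=(100, 200),
                downstream=(500, 600),
            )
            events.append(ev)
            tpm[ev.gene_id] = t
            if strong:
                ctrl, trt = [(800, 200), (800, 200)], [(300, 700), (300, 700)]
            else:
                ctrl, trt = [(800, 200), (800, 200)], [(800, 200), (790, 210)]
            if not depth_ok:
                trt = [(10, 9), (300, 700)]  # one sample below 20 pooled reads
            counts[eid] = _jc(ctrl, trt, eid=eid)
        return events, counts, tpm

    def test_filter_fixture_retains_exactly_four(self):
        events, counts, tpm = self._fixture_events()
        tested, _ = run_differential_tests(events, counts)
        passed = apply_filters(tested, counts, tpm)
        assert {d.event.event_id for d in passed} == {"fx0", "fx1", "fx2", "fx3"}
        for d in tested:
            if d.event.event_id == "fx8":
                assert d.verdicts["pass_reads"] is False

    def test_dpsi_boundary_inclusive(self):
        # unit lengths and power-of-two denominators make delta exactly -0.125;
        # with the threshold set to that value the >= comparison must retain it
        ev = _se_event("b")
        counts = {"b": _jc([(600, 200), (600, 200)], [(500, 300), (500, 300)],
                           inc_len=1, skip_len=1, eid="b")}
        tested, _ = run_differential_tests([ev], counts)
        assert tested[0].delta_psi == -0.125
        passed = apply_filters(tested, counts, {"G1": 10.0}, min_abs_dpsi=0.125)
        assert passed and passed[0].verdicts["pass_dpsi"] is True

    def test_reads_boundary_19_drops(self):
        ev = _se_event("r")
        counts = {"r": _jc([(10, 9), (800, 200)], [(300, 700), (300, 700)], eid="r")}
        tested, _ = run_differential_tests([ev], counts)
        passed = apply_filters(tested, counts, {"G1": 10.0})
        assert passed == []
        assert tested[0].verdicts["pass_reads"] is False

    def test_missing_tpm_dropped_with_reason(self):
        ev = _se_event("m")
        counts = {"m": _jc([(800, 200), (800, 200)], [(300, 700), (300, 700)], eid="m")}
        tested, _ = run_differential_tests([ev], counts)
        passed = apply_filters(tested, counts, {})
        assert passed == []
        assert "no TPM" in tested[0].skipped_reason


class TestPsiShift:
    def _events_with_shift(self, delta, n=100, seed=0):
        rng = np.random.default_rng(seed)
        events, counts = [], {}
        for i in range(n):
            eid = f"s{i}"
            ev = SpliceEvent(
                event_id=eid, event_type="SE", gene_id=f"GS{i}", chrom="chr1",
                strand="+", exon=(300, 345), upstream=(100, 200),
                downstream=(500, 600),
            )
            psi_c = rng.uniform(0.4, 0.8)
            psi_t = min(1.0, max(0.0, psi_c + delta))
            def draw(p):
                # symmetric lengths: binomial read split at PSI directly
                tot = rng.poisson(400)
                i_ = rng.binomial(tot, p)
                return (int(i_), int(tot - i_))
            counts[eid] = _jc([draw(psi_c), draw(psi_c)], [draw(psi_t), draw(psi_t)],
                              inc_len=99, skip_len=99, eid=eid)
            events.append(ev)
        tested, _ = run_differential_tests(events, counts)
        return tested

    def test_null_shift_not_significant(self):
        tested = self._events_with_shift(0.0)
        t, p = psi_shift_test(tested)
        assert p > 0.05

    def test_planted_global_shift_detected(self):
        tested = self._events_with_shift(-0.3)
        t, p = psi_shift_test(tested, n_comparisons=6)
        assert t < 0
        assert p < 0.001

    def test_bonferroni_multiplies_and_caps(self):
        tested = self._events_with_shift(-0.02, n=20, seed=3)
        _, p1 = psi_shift_test(tested, n_comparisons=1)
        _, p6 = psi_shift_test(tested, n_comparisons=6)
        assert p6 == pytest.approx(min(1.0, p1 * 6))


class TestExonArchitecture:
    def test_gc_of_atgc(self):
        assert gc_content("ATGC") == 0.5

    def _group(self, rng, n, exon_scale, chrom_seqs):
        events = []
        for i in range(n):
            elen = int(rng.integers(30, 60) * exon_scale)
            i1 = int(rng.integers(100, 200))
            i2 = int(rng.integers(100, 200))
            start = 300
            chrom = f"c{len(chrom_seqs)}"
            seq = "".join(rng.choice(list("ACGT"), size=start + elen + i2 + 400))
            chrom_seqs[chrom] = seq
            events.append(SpliceEvent(
                event_id=f"{chrom}_e", event_type="SE", gene_id="G", chrom=chrom,
                strand="+", exon=(start, start + elen),
                upstream=(start - i1 - 50, start - i1),
                downstream=(start + elen + i2, start + elen + i2 + 50),
            ))
        return events

    def test_shifted_length_distributions_detected(self):
        rng = np.random.default_rng(1)
        seqs = {}
        short = self._group(rng, 100, 1, seqs)
        long = self._group(rng, 100, 2, seqs)
        df = exon_architecture_stats(short, long, seqs)
        row = df[df["feature"] == "exon_length"].iloc[0]
        assert row["p_value"] < 0.01
        assert row["median_a"] < row["median_b"]

    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        seqs = {}
        g = self._group(rng, 50, 1, seqs)
        df = exon_architecture_stats(g, g, seqs)
        assert (df["p_value"] > 0.05).all()

    def test_event_without_flanking_introns_excluded(self):
        seqs = {"cx": "ACGT" * 300}
        ok = SpliceEvent(
            event_id="ok", event_type="SE", gene_id="G", chrom="cx", strand="+",
            exon=(300, 345), upstream=(100, 200), downstream=(500, 600),
        )
        bad = SpliceEvent(
            event_id="bad", event_type="SE", gene_id="G", chrom="cx", strand="+",
            exon=(200, 245), upstream=(100, 200), downstream=(500, 600),
        )
        df = exon_architecture_stats([ok, bad], [ok], seqs)
        assert df.attrs["excluded_a"] == 1
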