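"""ΔΔCt quantification, group comparison and correlation."""

import numpy as np
import pandas as pd
import pytest

from mirnome.qpcr_quant import (
    CtTable,
    correlate,
    delta_delta_ct,
    group_compare,
)


def ct_frame(rows):
    return CtTable(pd.DataFrame(rows, columns=["sample", "group", "assay",
                                               "replicate", "ct"]))


def flat_table(samples, target_ct, ref_ct=20.0, n_reps=2):
    rows = []
    for sample, group in samples:
        for rep in range(1, n_reps + 1):
            rows.append((sample, group, "T", rep, target_ct(sample)))
            rows.append((sample, group, "R", rep, ref_ct))
    return ct_frame(rows)


class TestDeltaDeltaCt:
    def test_identical_cts_give_zero_everywhere(self):
        table = flat_table(
            [("t1", "tumour"), ("t2", "tumour"), ("c1", "control")],
            target_ct=lambda s: 25.0,
        )
        calls = delta_delta_ct(table, "T", ["R"])
        assert all(c.log2_ratio == pytest.approx(0.0) for c in calls)

    def test_one_cycle_late_target_is_half_copy(self):
        table = flat_table(
            [("t1", "tumour"), ("c1", "control"), ("c2", "control")],
            target_ct=lambda s: 26.0 if s == "t1" else 25.0,
        )
        calls = {c.sample_id: c for c in delta_delta_ct(table, "T", ["R"])}
        assert calls["t1"].log2_ratio == pytest.approx(-1.0)
        assert calls["c1"].log2_ratio == pytest.approx(0.0)

    def test_location_invariance_under_global_ct_shift(self):
        rng = np.random.default_rng(2)
        samples = [(f"t{i}", "tumour") for i in range(4)] + [
            (f"c{i}", "control") for i in range(3)
        ]
        cts = {s: float(rng.uniform(22, 30)) for s, _ in samples}
        base = flat_table(samples, target_ct=lambda s: cts[s])
        shifted_frame = base.frame.copy()
        shifted_frame["ct"] = shifted_frame["ct"] + 3.7
        shifted = CtTable(shifted_frame)
        a = delta_delta_ct(base, "T", ["R"])
        b = delta_delta_ct(shifted, "T", ["R"])
        for x, y in zip(a, b):
            assert y.log2_ratio == pytest.approx(x.log2_ratio, abs=1e-12)

    def test_target_only_shift_moves_ratio_exactly(self):
        samples = [("t1", "tumour"), ("c1", "control"), ("c2", "control")]
        base = flat_table(samples, target_ct=lambda s: 25.0)
        doubled_frame = base.frame.copy()
        sel = (doubled_frame["sample"] == "t1") & (doubled_frame["assay"] == "T")
        doubled_frame.loc[sel, "ct"] -= 1.0  # doubled template in t1 only
        doubled = CtTable(doubled_frame)
        before = {c.sample_id: c for c in delta_delta_ct(base, "T", ["R"])}
        after = {c.sample_id: c for c in delta_delta_ct(doubled, "T", ["R"])}
        assert after["t1"].log2_ratio - before["t1"].log2_ratio == pytest.approx(1.0)

    def test_two_reference_hand_computed_oracle(self):
        # replicate-mean Cts chosen by hand; two reference assays averaged
        # arithmetically; calibrator = mean control delta-Ct
        rows = []
        hand = {
            # sample: (group, T reps, R1 reps, R2 reps)
            "s1": ("tumour", (26.0, 26.2), (20.0, 20.2), (18.0, 18.2)),
            "s2": ("tumour", (24.5, 24.7), (20.1, 20.3), (18.1, 18.3)),
            "s3": ("control", (25.0, 25.2), (20.0, 20.0), (18.0, 18.0)),
            "s4": ("control", (25.4, 25.6), (20.2, 20.2), (18.2, 18.2)),
        }
        for sample, (group, t, r1, r2) in hand.items():
            for rep, (a, b, c) in enumerate(zip(t, r1, r2), start=1):
                rows += [(sample, group, "T", rep, a),
                         (sample, group, "R1", rep, b),
                         (sample, group, "R2", rep, c)]
        table = ct_frame(rows)
        # spreadsheet: dCt = mean(T) - mean(mean(R1), mean(R2))
        dct = {
            s: (sum(v[1]) / 2) - ((sum(v[2]) / 2 + sum(v[3]) / 2) / 2)
            for s, v in hand.items()
        }
        calib = (dct["s3"] + dct["s4"]) / 2
        expected = {s: -(d - calib) for s, d in dct.items()}
        calls = {c.sample_id: c for c in delta_delta_ct(table, "T", ["R1", "R2"])}
        for s, exp in expected.items():
            assert calls[s].log2_ratio == pytest.approx(exp, abs=1e-9)
            assert calls[s].delta_ct == pytest.approx(dct[s], abs=1e-9)

    def test_geometric_reference_average_option(self):
        from scipy.stats import gmean

        rows = []
        for sample, group, t in [("s1", "tumour", 26.0), ("s2", "control", 25.0),
                                 ("s3", "control", 25.0)]:
            rows += [(sample, group, "T", 1, t),
                     (sample, group, "R1", 1, 20.0),
                     (sample, group, "R2", 1, 30.0)]
        table = ct_frame(rows)
        arith = {c.sample_id: c for c in delta_delta_ct(table, "T", ["R1", "R2"])}
        geo = {c.sample_id: c
               for c in delta_delta_ct(table, "T", ["R1", "R2"],
                                       reference_average="geometric")}
        assert arith["s1"].delta_ct == pytest.approx(26.0 - 25.0)
        assert geo["s1"].delta_ct == pytest.approx(26.0 - gmean([20.0, 30.0]))
        # references are identical across samples, so the ratios coincide
        assert geo["s1"].log2_ratio == pytest.approx(arith["s1"].log2_ratio)

    def test_sample_missing_reference_skipped_with_warning(self, caplog):
        rows = [
            ("t1", "tumour", "T", 1, 25.0), ("t1", "tumour", "R", 1, 20.0),
            ("t2", "tumour", "T", 1, 25.0),  # no reference row
            ("c1", "control", "T", 1, 25.0), ("c1", "control", "R", 1, 20.0),
        ]
        with caplog.at_level("WARNING"):
            calls = delta_delta_ct(ct_frame(rows), "T", ["R"])
        assert {c.sample_id for c in calls} == {"t1", "c1"}
        assert any("t2" in r.message for r in caplog.records)

    def test_missing_assay_and_empty_calibrator_error(self):
        rows = [("t1", "tumour", "T", 1, 25.0), ("t1", "tumour", "R", 1, 20.0)]
        table = ct_frame(rows)
        with pytest.raises(ValueError, match="X"):
            delta_delta_ct(table, "X", ["R"])
        with pytest.raises(ValueError, match="calibrator"):
            delta_delta_ct(table, "T", ["R"], calibrator_group="control")

    def test_zero_noise_single_copy_loss_is_minus_one(self, zero_noise_study):
        calls = delta_delta_ct(zero_noise_study.ct, "MIR-LOCUS", ["REF-LOCUS"])
        carriers = set(zero_noise_study.truth.ct_carriers)
        for c in calls:
            expected = -1.0 if c.sample_id in carriers else 0.0
            assert c.log2_ratio == pytest.approx(expected, abs=1e-9)


class TestGroupCompareCorrelate:
    def test_group_compare_matches_scipy_on_shifted_groups(self):
        table = flat_table(
            [(f"t{i}", "tumour") for i in range(5)]
            + [(f"c{i}", "control") for i in range(5)],
            target_ct=lambda s: 26.0 if s.startswith("t") else 25.0,
        )
        calls = delta_delta_ct(table, "T", ["R"])
        res = group_compare(calls)
        assert res["mean_log2_ratio"][0] == pytest.approx(-1.0)
        assert res["mean_log2_ratio"][1] == pytest.approx(0.0)

    def test_group_compare_needs_two_per_group(self):
        table = flat_table([("t1", "tumour"), ("c1", "control"),
                            ("c2", "control")], target_ct=lambda s: 25.0)
        with pytest.raises(ValueError):
            group_compare(delta_delta_ct(table, "T", ["R"]))

    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = correlate(x, x)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_vector_is_undefined(self):
        assert correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == (None, None)

    def test_null_pairs_dropped_pairwise(self):
        x = [1.0, None, 2.0, 3.0, float("nan")]
        y = [2.0, 5.0, 4.0, 6.0, 1.0]
        r, _ = correlate(x, y)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            correlate([1.0, None], [2.0, 3.0])

    def test_planted_codeletion_recovered_across_seeds(self):
        """σ=0.1 Ct noise over 50 samples: co-deleted loci correlate r > 0.9."""
        from mirnome.synthetic_data import make_ct, make_genome_and_annotation

        n_good = 0
        for s in range(20):
            truth = make_genome_and_annotation(n_chroms=1, n_genes=4,
                                               n_mirnas=2, seed=500 + s)
            ct = make_ct(truth, n_tumour=40, n_control=10, carrier_frac=0.6,
                         sd_ct=0.1, seed=600 + s)
            a = {c.sample_id: c.log2_ratio
                 for c in delta_delta_ct(ct, "MIR-LOCUS", ["REF-LOCUS"])}
            b = {c.sample_id: c.log2_ratio
                 for c in delta_delta_ct(ct, "HOST-LOCUS", ["REF-LOCUS"])}
            shared = sorted(set(a) & set(b))
            r, _ = correlate([a[s_] for s_ in shared], [b[s_] for s_ in shared])
            n_good += r > 0.9
        assert n_good >= 18
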