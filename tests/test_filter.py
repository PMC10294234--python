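"""Filter cascade: worked examples, oracle equivalence, monotonicity, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_cascade, random_trajectory_rows, rows_to_trio
from tkiclone.filtering import (
    ACQUIRED_HIGH,
    FAIL_DELTA,
    FAIL_DEPTH,
    FAIL_INTRONIC,
    FAIL_SENSITIVE,
    LOW_ONLY,
    NONE_CLASS,
    PASS,
    SHARED_CONSTANT,
    SHARED_REDUCED_HIGH,
    FilterConfig,
    burden_table,
    compute_vaf,
    filter_and_classify,
    format_vaf_percent,
)
from tkiclone.model import VariantCall


def _trio_from_vafs(cases):
    """cases: list of (sens, low, high) true VAFs (None = absent), depth 10,000."""
    rows = []
    for vs, vl, vh in cases:
        row = {"consequence": "missense", "distance_to_exon": 0}
        for stage, v in zip(("sensitive", "low", "high"), (vs, vl, vh)):
            row[stage] = None if v is None else (10_000, round(v * 10_000))
        rows.append(row)
    return rows_to_trio(rows)


def test_compute_vaf_and_percentage_rendering():
    call = VariantCall("G", 1, "C", "A", "G", depth=72, alt_depth=24)
    assert compute_vaf(call) == pytest.approx(1 / 3)
    assert format_vaf_percent(compute_vaf(call)) == "33.3%"
    assert compute_vaf(VariantCall("G", 1, "C", "A", "G", depth=60, alt_depth=0)) == 0.0
    # 88/127 = 0.6929..., renders to 69% at integer precision
    assert format_vaf_percent(88 / 127, decimals=0) == "69%"
    assert format_vaf_percent(0.125, decimals=1) == "12.5%"
    assert format_vaf_percent(0.295, decimals=0) == "30%"  # half-up, not banker's


@pytest.mark.parametrize(
    "vafs,verdict,clonal_class",
    [
        ((0.0, None, 0.2927), PASS, ACQUIRED_HIGH),  # acquired at high dose only
        ((0.0, 0.2917, 0.3333), PASS, SHARED_CONSTANT),  # shared low/high
        ((0.0, 0.087, 0.6667), PASS, ACQUIRED_HIGH),  # low stage below threshold
        ((0.04, 0.10, 0.12), FAIL_DELTA, NONE_CLASS),
        ((0.50, 0.55, 0.60), FAIL_SENSITIVE, NONE_CLASS),
        ((0.0, 0.30, None), PASS, LOW_ONLY),
        ((0.0, 0.60, 0.30), PASS, SHARED_REDUCED_HIGH),  # VAF drops >15% at high dose
        ((0.0, 0.15, 0.15), FAIL_DELTA, NONE_CLASS),  # exact threshold fails (strict >)
        ((0.05, 0.40, 0.40), FAIL_SENSITIVE, NONE_CLASS),  # >= 0.05 in parent fails
    ],
)
def test_cascade_worked_examples(vafs, verdict, clonal_class):
    trio = _trio_from_vafs([vafs])
    (trajectory,) = filter_and_classify(trio)
    assert trajectory.verdict == verdict
    assert trajectory.clonal_class == clonal_class


def test_depth_and_intronic_rules():
    rows = [
        {"consequence": "missense", "distance_to_exon": 0,
         "sensitive": (5, 0), "low": (8, 4), "high": (9, 5)},  # under-covered everywhere
        {"consequence": "intronic", "distance_to_exon": 45,
         "sensitive": (60, 0), "low": None, "high": (60, 25)},  # deep intronic
        {"consequence": "intronic", "distance_to_exon": 12,
         "sensitive": (60, 0), "low": None, "high": (60, 25)},  # near-exon intronic kept
    ]
    verdicts = [t.verdict for t in filter_and_classify(rows_to_trio(rows))]
    assert verdicts == [FAIL_DEPTH, FAIL_INTRONIC, PASS]


def test_cascade_matches_bruteforce_oracle():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        rows = random_trajectory_rows(50, rng)
        trio = rows_to_trio(rows)
        got = {
            t.key[0]: (t.verdict, t.clonal_class) for t in filter_and_classify(trio)
        }
        expected = brute_force_cascade(rows)
        for i, exp in enumerate(expected):
            assert got[f"G{i}"] == exp, f"seed {seed}, variant {i}"


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(0, 0.2), st.floats(0, 1), st.floats(0, 1)
        ),
        min_size=1,
        max_size=30,
    ),
    st.floats(0.05, 0.5),
    st.floats(0.01, 0.2),
)
def test_pass_count_monotone_in_thresholds(vaf_triples, delta_min, sens_max):
    """Raising delta_vaf_min or lowering sensitive_vaf_max never adds PASS variants."""
    trio = _trio_from_vafs(vaf_triples)
    base = FilterConfig(delta_vaf_min=delta_min, sensitive_vaf_max=sens_max)
    n_base = sum(t.passed for t in filter_and_classify(trio, base))
    stricter_delta = FilterConfig(delta_vaf_min=min(1.0, delta_min + 0.1), sensitive_vaf_max=sens_max)
    stricter_sens = FilterConfig(delta_vaf_min=delta_min, sensitive_vaf_max=sens_max / 2)
    assert sum(t.passed for t in filter_and_classify(trio, stricter_delta)) <= n_base
    assert sum(t.passed for t in filter_and_classify(trio, stricter_sens)) <= n_base


def test_burden_counts_per_stage_and_unique():
    trio = _trio_from_vafs(
        [(0.0, None, 0.2927), (0.0, 0.2917, 0.3333), (0.0, 0.087, 0.6667)]
    )
    table = burden_table({"IM-R1": filter_and_classify(trio)})
    high = table[table.subline == "highIM-R1"].iloc[0]
    low = table[table.subline == "lowIM-R1"].iloc[0]
    assert high.n_pass == 3  # all three exceed the threshold at high dose
    assert low.n_pass == 1  # only the shared variant does at low dose
    assert high.n_pass_unique_trio == 3


def test_burden_empty_input():
    table = burden_table({"IM-R1": []})
    assert (table.n_pass == 0).all() and len(table) == 2


def _recovery(dataset, kinds):
    cfg = FilterConfig()
    correct = total = 0
    by_trio = {tid: filter_and_classify(dataset.trio_samples(tid), cfg) for tid in dataset.trios}
    truth_by_key = {}
    for tv in dataset.truth.variants:
        truth_by_key[(tv.trio_id, tv.chrom, tv.pos, tv.ref, tv.alt)] = tv
    for trio_id, trajectories in by_trio.items():
        for t in trajectories:
            chrom, pos, ref, alt, _ = t.key
            tv = truth_by_key.get((trio_id, chrom, pos, ref, alt))
            if tv is None or tv.kind not in kinds or tv.true_class == NONE_CLASS:
                continue
            deltas = [v or 0 for v in tv.stage_vafs]
            if max(deltas[1] - deltas[0], deltas[2] - deltas[0]) < 0.25:
                continue
            total += 1
            correct += t.clonal_class == tv.true_class
    return correct, total


def test_class_recovery_exact_at_high_depth(deep_dataset):
    """At 10,000x every planted driver and background variant classifies exactly."""
    correct, total = _recovery(deep_dataset, kinds={"driver", "background"})
    assert total > 200
    assert correct == total


def test_class_recovery_at_study_depth(dataset):
    """At 60x, class accuracy >= 0.9 for variants with a VAF gain of at least 0.25."""
    correct, total = _recovery(dataset, kinds={"driver", "background"})
    assert total > 200
    assert correct / total >= 0.9
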