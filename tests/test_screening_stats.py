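import numpy as np
import pandas as pd
import pytest

from aflpsim.amplification import Combination, PrimerSpec, amplify, parse_combination
from aflpsim.digestion import BUILTIN_ENZYMES, double_digest
from aflpsim.genome_io import GenomeSequence
from aflpsim.profiling import AdaptorModel, build_profile
from aflpsim.screening_stats import (
    ScreenRow,
    compare_to_empirical,
    enumerate_combinations,
    gc_class,
    homoplasy_length_profile,
    pearson_r,
    read_empirical_table,
    rows_to_dataframe,
    screen_combinations,
    summarize_by_group,
)
from aflpsim.synthetic_fixtures import random_genome

E = BUILTIN_ENZYMES["EcoRI"]
M = BUILTIN_ENZYMES["MseI"]

PATTERNS_84 = ["E+0/M+1", "E+1/M+1", "E+1/M+2"]


def test_enumerate_pattern_sizes():
    assert len(enumerate_combinations("E+0/M+1", E, M)) == 4
    assert len(enumerate_combinations("E+1/M+1", E, M)) == 16
    assert len(enumerate_combinations("E+1/M+2", E, M)) == 64
    assert len(enumerate_combinations(PATTERNS_84, E, M)) == 84


def test_enumerate_order_and_dedup():
    combos = enumerate_combinations("E+0/M+1", E, M)
    assert [c.frequent.selective for c in combos] == ["A", "C", "G", "T"]
    again = enumerate_combinations(["E+0/M+1", "E+0/M+1", "EcoRI+/MseI+A"], E, M)
    assert [c.label for c in again] == [c.label for c in combos]


def test_enumerate_rejects_long_selective():
    with pytest.raises(ValueError):
        enumerate_combinations("E+5/M+1", E, M)


def test_enumerate_explicit_combo_enzyme_check():
    with pytest.raises(ValueError):
        enumerate_combinations("PstI+A/MseI+C", E, M)


@pytest.mark.parametrize(
    "rare_sel,freq_sel,expected",
    [
        ("A", "C", "m"),       # 1 G/C of 2: tie
        ("ACG", "CTC", "GC"),  # 4 G/C of 6: majority
        ("ATG", "ATG", "AT"),  # 2 G/C of 6: minority
        ("", "", "m"),         # no selective bases
        ("", "G", "GC"),
        ("", "T", "AT"),
    ],
)
def test_gc_class_majority_rule(rare_sel, freq_sel, expected):
    combo = Combination(PrimerSpec("EcoRI", rare_sel), PrimerSpec("MseI", freq_sel))
    assert gc_class(combo) == expected


def test_gc_class_partition_of_84_combos():
    """The majority rule partitions the 84 one-to-three-base combinations
    into the expected group sizes: 1 sb -> 2/2, 2 sb -> 4/8/4, 3 sb -> 32/0/32."""
    combos = enumerate_combinations(PATTERNS_84, E, M)
    counts = {}
    for c in combos:
        counts[(c.n_sb, gc_class(c))] = counts.get((c.n_sb, gc_class(c)), 0) + 1
    assert counts == {
        (1, "AT"): 2, (1, "GC"): 2,
        (2, "AT"): 4, (2, "m"): 8, (2, "GC"): 4,
        (3, "AT"): 32, (3, "GC"): 32,
    }


def test_screen_matches_per_combo_recomputation():
    g = random_genome(10_000, 0.36, 2)
    combos = enumerate_combinations("E+0/M+1", E, M)
    rows = screen_combinations([g], combos)
    assert len(rows) == 4
    frags = double_digest(g, E, M)
    for row, combo in zip(rows, combos):
        prof = build_profile(amplify(frags, g, combo), combo)
        assert (row.n_fragments, row.n_peaks, row.H, row.max_comigrating) == (
            prof.n_fragments, prof.n_peaks, prof.H, prof.max_comigrating,
        )


def test_screen_empty_inputs():
    g = random_genome(1000, 0.36, 0)
    assert screen_combinations([g], []) == []
    with pytest.raises(ValueError):
        screen_combinations([], enumerate_combinations("E+0/M+1", E, M))


def test_screen_pools_records_and_is_order_invariant():
    g1 = random_genome(8000, 0.36, 4, id="chr")
    g2 = random_genome(3000, 0.36, 5, id="plasmid")
    combos = enumerate_combinations("E+0/M+1", E, M)
    ab = rows_to_dataframe(screen_combinations([g1, g2], combos))
    ba = rows_to_dataframe(screen_combinations([g2, g1], combos))
    pd.testing.assert_frame_equal(ab, ba)
    rev = rows_to_dataframe(screen_combinations([g1, g2], combos[::-1]))
    assert ab.n_fragments.sum() == rev.n_fragments.sum()
    assert ab.n_peaks.sum() == rev.n_peaks.sum()
    # pooling: totals differ from single-record screens only by co-migration
    solo = rows_to_dataframe(screen_combinations([g1], combos))
    assert ab.n_fragments.sum() >= solo.n_fragments.sum()


def test_report_partition_property():
    """Fragment totals of the four one-base extensions sum to the parent's."""
    g = random_genome(20_000, 0.36, 6)
    parent = screen_combinations([g], [parse_combination("EcoRI+/MseI+A")])[0]
    children = screen_combinations(
        [g], [parse_combination(f"EcoRI+/MseI+A{x}") for x in "ACGT"]
    )
    assert sum(c.n_fragments for c in children) == parent.n_fragments


def _row(rare_sel, freq_sel, n_frag, n_peaks, h, max_cf):
    return ScreenRow(
        Combination(PrimerSpec("EcoRI", rare_sel), PrimerSpec("MseI", freq_sel)),
        n_frag, n_peaks, h, max_cf,
    )


def test_summarize_single_row_equals_itself():
    (s,) = summarize_by_group([_row("A", "T", 30, 25, 0.2, 3)])
    assert (s.n_sb, s.gc_class, s.n_tested) == (2, "AT", 1)
    assert s.mean_peaks == 25 and s.range_peaks == (25, 25)
    assert s.mean_H == 20.0 and s.range_H == (20.0, 20.0)
    assert s.max_comigrating == 3


def test_summarize_hand_computed_groups():
    rows = [
        _row("A", "T", 30, 25, 0.2, 3),
        _row("T", "A", 50, 35, 0.4, 6),
        _row("G", "C", 10, 9, 0.0, 1),
    ]
    summaries = summarize_by_group(rows)
    assert [(s.n_sb, s.gc_class) for s in summaries] == [(2, "AT"), (2, "GC")]
    at = summaries[0]
    assert at.mean_peaks == 30 and at.range_peaks == (25, 35)
    assert at.mean_H == 30.0 and at.range_H == (20.0, 40.0)
    assert at.max_comigrating == 6


def test_summarize_empty_report_errors():
    with pytest.raises(ValueError):
        summarize_by_group([])


def test_summarize_class_ordering():
    rows = [_row("G", "C", 5, 5, 0.0, 1), _row("A", "C", 5, 5, 0.0, 1),
            _row("A", "T", 5, 5, 0.0, 1)]
    assert [s.gc_class for s in summarize_by_group(rows)] == ["AT", "m", "GC"]


def test_homoplasy_length_profile_bins(run_pipeline):
    from aflpsim.profiling import Profile, Peak
    from aflpsim.amplification import AmplifiedFragment
    from aflpsim.digestion import RestrictionFragment

    def peak(length, n):
        members = tuple(
            AmplifiedFragment(
                RestrictionFragment("g", 1000 * i + length, 1000 * i + 2 * length, "EcoRI", "MseI", length),
                "rare_left", length,
            )
            for i in range(n)
        )
        return Peak(length, members)

    combo = Combination(PrimerSpec("EcoRI"), PrimerSpec("MseI"))
    prof = Profile(combo, (50, 500), (peak(60, 1), peak(75, 2), peak(200, 1)))
    hist = homoplasy_length_profile([prof], bin_width=20)
    assert hist == {60: 0.5, 200: 0.0}
    assert 100 not in hist  # empty bins absent, not zero
    with pytest.raises(ValueError):
        homoplasy_length_profile([prof], bin_width=0)


def test_pearson_examples():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
    assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)
    assert pearson_r(x, [5.0] * 4) is None
    with pytest.raises(ValueError):
        pearson_r([1, 2], [3, 4])
    with pytest.raises(ValueError):
        pearson_r([1, 2, 3], [1, 2])


def test_compare_to_empirical_exact_match():
    rows = [_row("A", "T", 30, 25, 0.2, 3), _row("T", "A", 50, 35, 0.4, 6),
            _row("G", "C", 10, 9, 0.0, 1)]
    emp = pd.DataFrame({"combo": [r.combo.label for r in rows],
                        "mean_peaks": [r.n_peaks for r in rows]})
    result = compare_to_empirical(rows, emp)
    assert result["n_shared"] == 3
    assert result["pearson_r"] == pytest.approx(1.0)


def test_compare_to_empirical_shuffled_baseline():
    rng = np.random.default_rng(0)
    peaks = rng.integers(5, 260, size=20)
    sels = [(r, f1 + f2) for r in "AC" for f1 in "ACGT" for f2 in "ACG"][:20]
    rows = [
        _row(r, f, int(p) + 5, int(p), 0.1, 2)
        for (r, f), p in zip(sels, peaks)
    ]
    rs = []
    for seed in range(30):
        perm = np.random.default_rng(seed).permutation(peaks)
        emp = pd.DataFrame({"combo": [r.combo.label for r in rows], "mean_peaks": perm})
        rs.append(compare_to_empirical(rows, emp)["pearson_r"])
    assert abs(np.mean(rs)) < 0.15


def test_compare_to_empirical_no_overlap_errors():
    rows = [_row("A", "T", 30, 25, 0.2, 3)]
    emp = pd.DataFrame({"combo": ["PstI+A/MseI+C"], "mean_peaks": [10]})
    with pytest.raises(ValueError, match="no combinations shared"):
        compare_to_empirical(rows, emp)


def test_compare_to_empirical_bin_deficit_flags(run_pipeline):
    g = random_genome(40_000, 0.36, 9)
    combo = Combination(PrimerSpec("EcoRI"), PrimerSpec("MseI"))
    rows = screen_combinations([g], [combo], keep_profiles=True)
    profiles = [rows[0].profile]
    predicted = {}
    for p in profiles[0].peaks:
        b = (p.peak_length // 20) * 20
        predicted[b] = predicted.get(b, 0) + 1
    emp = pd.DataFrame(
        {
            "combo": [combo.label, rows[0].combo.label],
            "mean_peaks": [rows[0].n_peaks] * 2,
        }
    ).iloc[:1]
    # empirical bins: half the predicted small-fragment count
    for b, n in predicted.items():
        emp[f"bin_{b}"] = [n / 2 if b < 100 else n]
    result = compare_to_empirical(rows, emp, profiles=profiles)
    bins = result["bins"]
    deficits = set(bins.loc[bins.deficit, "bin_start"])
    assert deficits == {b for b in predicted if b < 100 and predicted[b] > 0}


def test_read_empirical_table_requires_columns(tmp_path):
    p = tmp_path / "emp.tsv"
    p.write_text("combo\tmean_peaks\nEcoRI+A/MseI+T\t12\n")
    df = read_empirical_table(p)
    assert df.mean_peaks.iloc[0] == 12
    p2 = tmp_path / "bad.tsv"
    p2.write_text("combination\tpeaks\nx\t1\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_empirical_table(p2)
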