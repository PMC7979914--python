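"""Distances and the hierarchical abundance+Hamming clonotyper."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ablib.annotate import Annotation
from ablib.clonotype import (
    ClonotypeTable,
    clonal_dominance,
    cumulative_rank,
    hamming,
    hierarchical_clonotype,
    levenshtein,
    make_key,
    overlap,
)

# ---------------------------------------------------------------- distances


def test_hamming_basic():
    assert hamming("ARDYW", "ARDYW") == 0
    assert hamming("ARDYW", "ARDFW") == 1
    assert hamming("AAAA", "TTTT") == 4


def test_hamming_undefined_across_lengths():
    with pytest.raises(ValueError):
        hamming("ARD", "ARDYW")


def _lev_oracle(a, b):
    """Classic dynamic-programming edit distance."""
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb))
    return dp[-1]


def test_levenshtein_against_dp_oracle(rng):
    assert levenshtein("kitten", "sitting") == 3
    assert levenshtein("", "AB") == 2
    assert levenshtein("XYZ", "XYZ") == 0
    alphabet = np.array(list("ARNDC"))
    for _ in range(50):
        a = "".join(rng.choice(alphabet, size=rng.integers(0, 12)))
        b = "".join(rng.choice(alphabet, size=rng.integers(0, 12)))
        assert levenshtein(a, b) == _lev_oracle(a, b)


# ---------------------------------------------------------------- clonotyper


def brute_force_clonotype(counts, h):
    """Independent absorber: all-pairs scan, same tie-break rules."""
    abundant = sorted((k for k, c in counts.items() if c >= 2))
    singles = sorted(k for k, c in counts.items() if c == 1)
    totals = {k: counts[k] for k in abundant}
    members = {k: [k] for k in abundant}
    for s in singles:
        cands = [
            a for a in abundant
            if len(a) == len(s) and sum(x != y for x, y in zip(a, s)) <= h
        ]
        if h > 0 and cands:
            best = sorted(cands, key=lambda a: (-counts[a], a))[0]
            members[best].append(s)
            totals[best] += 1
        else:
            members[s], totals[s] = [s], 1
    return {k: totals[k] for k in members}


def test_singleton_rescue_example():
    table = {"AAAA": 5, "AAAT": 1, "CCCC": 1}
    ct = hierarchical_clonotype(table, 1)
    assert len(ct) == 2
    assert ct.counts == {"AAAA": 6, "CCCC": 1}
    members = {c.representative: c.members for c in ct.clonotypes}
    assert members["AAAA"] == ("AAAA", "AAAT")


def test_hamming_zero_keeps_unique_keys():
    ct = hierarchical_clonotype({"AAAA": 5, "AAAT": 1}, 0)
    assert len(ct) == 2


def test_abundance_only_drops_singletons():
    ct = hierarchical_clonotype({"AAAA": 5, "CCCC": 1}, "abundance_only")
    assert len(ct) == 1
    assert ct.dropped_singletons == 1


def test_length_mismatch_never_absorbed():
    ct = hierarchical_clonotype({"AAAA": 5, "AAA": 1}, 3)
    assert len(ct) == 2


def test_absorption_tie_break_prefers_higher_count_then_lex():
    ct = hierarchical_clonotype({"AAAA": 5, "AAAC": 5, "AAAG": 2, "AAAT": 1}, 1)
    members = {c.representative: c.members for c in ct.clonotypes}
    assert "AAAT" in members["AAAA"]  # count tie 5=5 -> lexicographically first


def test_invalid_criterion_rejected():
    with pytest.raises(ValueError):
        hierarchical_clonotype({"AAAA": 1}, 4)
    with pytest.raises(ValueError):
        hierarchical_clonotype({"AAAA": 0}, 1)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("h", [1, 2, 3])
def test_equivalence_with_brute_force_oracle(seed, h):
    rng = np.random.default_rng(seed)
    keys = {
        "".join(rng.choice(list("AC"), size=rng.integers(4, 7))): int(c)
        for c in rng.zipf(2.0, size=200)
    }
    keys = {k: min(c, 50) for k, c in keys.items()}
    ours = hierarchical_clonotype(keys, h).counts
    assert ours == brute_force_clonotype(keys, h)


def test_clonotype_count_monotone_in_h(rng):
    keys = {
        "".join(rng.choice(list("ACDE"), size=6)): int(min(c, 30))
        for c in rng.zipf(2.2, size=500)
    }
    sizes = [len(hierarchical_clonotype(keys, h)) for h in (0, 1, 2, 3)]
    assert sizes == sorted(sizes, reverse=True)
    assert len(hierarchical_clonotype(keys, "abundance_only")) <= sizes[3]


def test_read_count_conservation(rng):
    keys = {
        "".join(rng.choice(list("ACDEF"), size=5)): int(min(c, 20))
        for c in rng.zipf(2.0, size=300)
    }
    total = sum(keys.values())
    for h in (0, 1, 2, 3):
        assert hierarchical_clonotype(keys, h).total_reads == total


def test_order_independence(rng):
    items = [
        ("".join(rng.choice(list("ACD"), size=5)), int(min(c, 9)))
        for c in rng.zipf(2.0, size=150)
    ]
    table = {}
    for k, c in items:
        table[k] = table.get(k, 0) + c
    forward = hierarchical_clonotype(table, 2)
    reversed_ = hierarchical_clonotype(dict(reversed(list(table.items()))), 2)
    assert forward.counts == reversed_.counts


# ---------------------------------------------------------------- key schemes


def _ann(cdr1="GFTFS", cdr3="ARDYW", v="IGHV3-23"):
    return Annotation(
        read_id="r", v_gene=v, cdr1_aa=cdr1, cdr3_aa=cdr3,
        productive=True, pass_filter=True,
    )


def test_merged_key_concatenates_cdr1_and_cdr3():
    assert make_key(_ann(), "merged") == "GFTFS|ARDYW"
    assert make_key(_ann(), "cdr3") == "ARDYW"


def test_germline_scheme_separates_same_cdr3_different_v():
    k1 = make_key(_ann(v="IGHV3-23"), "germline")
    k2 = make_key(_ann(v="IGHV1-69"), "germline")
    assert k1 != k2
    ct = hierarchical_clonotype({k1: 5, k2: 5}, 1, "germline")
    assert len(ct) == 2


def test_germline_scheme_rescues_within_same_v():
    keys = {"IGHV3-23|ARDYW": 5, "IGHV3-23|ARDFW": 1, "IGHV1-69|ARDFW": 1}
    ct = hierarchical_clonotype(keys, 1, "germline")
    assert ct.counts == {"IGHV3-23|ARDYW": 6, "IGHV1-69|ARDFW": 1}


# ---------------------------------------------------------------- statistics


def test_clonal_dominance():
    t = hierarchical_clonotype({"A": 8, "B": 2}, 0)
    assert clonal_dominance(t) == pytest.approx(0.8)
    t = hierarchical_clonotype({"A": 4}, 0)
    assert clonal_dominance(t) == 1.0
    t = hierarchical_clonotype({f"K{i:03d}": 2 for i in range(100)}, 0)
    assert clonal_dominance(t) == pytest.approx(1 / 100)


def test_cumulative_rank_and_spectrum():
    t = hierarchical_clonotype({"A": 5, "B": 3, "C": 2}, 0)
    rank = cumulative_rank(t)
    assert rank.clones_to_half == 1
    t = hierarchical_clonotype({f"K{i}": 2 for i in range(10)}, 0)
    assert cumulative_rank(t).clones_to_half == 5
    t = hierarchical_clonotype({"AB": 1, "CD": 1, "EF": 2}, 0)
    assert cumulative_rank(t).copy_number_spectrum[1] == pytest.approx(2 / 3)


def test_overlap_jaccard():
    ta = hierarchical_clonotype({"A": 2, "B": 2}, 0)
    tb = hierarchical_clonotype({"B": 2, "C": 2}, 0)
    rep = overlap(ta, tb)
    assert rep.jaccard == pytest.approx(1 / 3)
    assert overlap(ta, ta).jaccard == 1.0
    tc = hierarchical_clonotype({"X": 2}, 0)
    assert overlap(ta, tc).jaccard == 0.0
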