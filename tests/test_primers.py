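"""IUPAC-aware distances, Ward clustering and amplification specificity."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from ablib.annotate import Annotation
from ablib.primers import (
    distance_matrix,
    iupac_hamming,
    normalize_by_primer,
    on_target_rate,
    primer_match_simulation,
    ward_cluster,
)
from ablib.resources import PrimerRecord, load_primer_panel


def test_iupac_degenerate_matching():
    assert iupac_hamming("K", "G") == 0  # K = {G,T}
    assert iupac_hamming("K", "C") == 1
    assert iupac_hamming("ACGT", "ACGT") == 0
    assert iupac_hamming("NNNN", "ACGT") == 0


def test_iupac_symmetry_and_errors(rng):
    for _ in range(20):
        a = "".join(rng.choice(list("ACGTRYKM"), size=10))
        b = "".join(rng.choice(list("ACGTRYKM"), size=10))
        assert iupac_hamming(a, b) == iupac_hamming(b, a)
    with pytest.raises(ValueError):
        iupac_hamming("AC", "A")
    with pytest.raises(ValueError):
        iupac_hamming("AX", "AC")


def test_distance_matrix_properties(ighv_panel):
    dm = distance_matrix(ighv_panel)
    arr = dm.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0)
    assert arr.max() <= 18


def test_ward_reproduces_three_primer_family_clusters(ighv_panel):
    """The printed IGHV panel splits into the three known cross-family groups."""
    result = ward_cluster(ighv_panel)
    clusters = {frozenset(c) for c in result.clusters()}
    assert result.k == 3
    assert clusters == {
        frozenset({"IGHV1a", "IGHV1b", "IGHV1c", "IGHV1d",
                   "IGHV3a", "IGHV3b", "IGHV3c", "IGHV5a"}),
        frozenset({"IGHV2a", "IGHV2b"}),
        frozenset({"IGHV4", "IGHV6a"}),
    }


def test_ward_identical_sequences_merge_at_zero():
    primers = [
        PrimerRecord("p1", "CAGGTGCAGCTGGTGCAG", "F1"),
        PrimerRecord("p2", "CAGGTGCAGCTGGTGCAG", "F1"),
        PrimerRecord("p3", "TTTTTTTTTTTTTTTTTT", "F2"),
    ]
    result = ward_cluster(primers, k=2)
    assert result.merges[0][1] == 0.0
    assert {"p1", "p2"} in [set(c) for c in result.clusters()]


def test_ward_k_equals_n_gives_singletons(ighv_panel):
    result = ward_cluster(ighv_panel, k=len(ighv_panel))
    assert all(len(c) == 1 for c in result.clusters())


def test_ward_is_input_order_invariant(ighv_panel):
    fwd = ward_cluster(ighv_panel)
    rev = ward_cluster(list(reversed(ighv_panel)))
    assert {frozenset(c) for c in fwd.clusters()} == {frozenset(c) for c in rev.clusters()}


def test_ward_heights_match_scipy_on_tie_free_data(rng):
    """Independent check: on Euclidean data without ties, the Lance-Williams
    criterion heights equal the squares of scipy's ward linkage heights."""
    seqs = set()
    while len(seqs) < 7:
        seqs.add("".join(rng.choice(list("ACGT"), size=18)))
    panel = [PrimerRecord(f"p{i}", s, "F") for i, s in enumerate(sorted(seqs))]
    ours = ward_cluster(panel, k=1)
    dm = distance_matrix(panel).to_numpy()
    Z = sch.linkage(squareform(dm), method="ward")
    ours_heights = sorted(h for _, h in ours.merges)
    scipy_heights = sorted(float(h) ** 2 for h in Z[:, 2])
    assert np.allclose(ours_heights, scipy_heights, rtol=1e-9)


def _pool(intended_frac, n=1000, fam="IGHV1", other="IGHV3"):
    anns = []
    n_in = int(n * intended_frac)
    for i in range(n):
        f = fam if i < n_in else other
        anns.append(Annotation(read_id=f"r{i}", v_gene=f + "-1", v_family=f,
                               pass_filter=True))
    return anns


def test_on_target_rate_recovers_constructed_fraction():
    primer = PrimerRecord("IGHV1a", "CAGGTKCAGCTGGTGCAG", "IGHV1", ("IGHV1-1",))
    rep = on_target_rate(_pool(0.70), primer)
    assert rep.family_level_fraction == pytest.approx(0.70)
    assert rep.gene_level_fraction == pytest.approx(0.70)
    assert sum(rep.off_target_families.values()) == pytest.approx(1.0)
    perfect = on_target_rate(_pool(1.0), primer)
    assert perfect.family_level_fraction == 1.0
    with pytest.raises(ValueError):
        on_target_rate([], primer)


def test_family_fraction_bounds_gene_fraction():
    primer = PrimerRecord("IGHV1a", "CAGGTKCAGCTGGTGCAG", "IGHV1", ("IGHV1-1",))
    anns = _pool(0.7)
    # half the intended-family reads call a different gene in the family
    for a in anns[: len(anns) // 4]:
        a.v_gene = "IGHV1-2"
    rep = on_target_rate(anns, primer)
    assert rep.gene_level_fraction <= rep.family_level_fraction


def test_normalize_by_primer_equalizes_pools():
    combined = normalize_by_primer({
        "p1": {"a": 60, "b": 40},
        "p2": {"b": 900},
    })
    assert combined["b"] == pytest.approx(0.4 * 0.5 + 0.5)
    assert combined["a"] == pytest.approx(0.3)
    assert sum(combined.values()) == pytest.approx(1.0)
    single = normalize_by_primer({"p1": {"a": 6, "b": 4}})
    assert single == pytest.approx({"a": 0.6, "b": 0.4})
    with pytest.raises(ValueError):
        normalize_by_primer({})


def test_match_simulation_exact_primer_dominates(reference, ighv_panel):
    mat = primer_match_simulation(reference, ighv_panel)
    assert np.allclose(mat.sum(axis=1), 1.0)
    # IGHV3c is the exact 5' of IGHV3-23 up to degeneracy
    row = mat.loc["IGHV3c"]
    assert row.idxmax() == "IGHV3-23"


def test_match_simulation_abundance_split():
    """Two genes at equal distance with 9:1 abundance capture 0.9/0.1."""
    from ablib.resources import GermlineGene, GermlineReference

    body = "GCT" * 90 + "TGC"
    bounds = ((0, 78), (78, 99), (99, 150), (150, 174), (174, 288))
    g1 = GermlineGene("IGHV1-1", "IGHV1", "heavy", "V", "CAGGTGCAGCTGGTGCAG" + body, 288, bounds)
    g2 = GermlineGene("IGHV1-2", "IGHV1", "heavy", "V", "CAGGTGCAGCTGGTGCAG" + body, 288, bounds)
    ref = GermlineReference([g1, g2])
    primer = PrimerRecord("p", "CAGGTGCAGCTGGTGCAG", "IGHV1")
    mat = primer_match_simulation(ref, [primer], abundance={"IGHV1-1": 9, "IGHV1-2": 1})
    assert mat.loc["p", "IGHV1-1"] == pytest.approx(0.9)
    assert mat.loc["p", "IGHV1-2"] == pytest.approx(0.1)


def test_match_simulation_three_prime_mismatch_blocks_capture(reference, ighv_panel):
    """A primer mismatched at its 3' terminus captures almost nothing relative
    to a primer matched there (terminal mismatches weighted 3x)."""
    good = PrimerRecord("good", "GAGGTGCAGCTGTTGGAG", "IGHV3")  # exact IGHV3-23 start
    bad = PrimerRecord("bad", "GAGGTGCAGCTGTTGCCC", "IGHV3")  # 3 terminal mismatches
    mat = primer_match_simulation(reference, [good, bad])
    raw_good = np.exp(0.0)
    raw_bad = np.exp(-9.0)  # 3 mismatches x weight 3
    assert raw_bad / raw_good < 1e-3
    # both rows still normalise; the bad primer's best gene keeps most weight
    assert np.allclose(mat.sum(axis=1), 1.0)
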