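"""The long-match query engine, operation by operation and end to end."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sylpbwt.errors import InputError, ThresholdError
from sylpbwt.index import build_index
from sylpbwt.oracle import naive_long_matches
from sylpbwt.panel import HaplotypePanel
from sylpbwt.query import (
    compare_reverse_prefix,
    encode_query,
    match_extent,
    min_full_syllables,
    min_query_length_sites,
    query_long_matches,
    refine_match,
    scan_for_matches,
    virtual_insert,
    window_sizes,
    PotentialMatch,
)
from sylpbwt.synthetic_data import PanelSpec, PlantSpec, generate_panel, generate_query


# --- threshold arithmetic ---------------------------------------------------


@pytest.mark.parametrize("B", [1, 2, 4, 16, 64, 128])
def test_min_full_syllables_at_threshold(B):
    assert min_full_syllables(2 * B - 1, B) == 1
    if B > 1:  # floor((2B+1)/B) = 2 except in the degenerate B=1 case
        assert min_full_syllables(3 * B, B) == 2


def test_min_full_syllables_direct():
    assert min_full_syllables(10, 4) == 1  # floor(7/4)


def test_min_full_syllables_refuses_small_L():
    with pytest.raises(ThresholdError) as exc:
        min_full_syllables(254, 128)
    assert exc.value.min_length == 255
    assert "255" in str(exc.value)


@pytest.mark.parametrize("B,expected", [(1, 1), (64, 127), (128, 255)])
def test_min_query_length_sites(B, expected):
    assert min_query_length_sites(B) == expected


# --- encoding ---------------------------------------------------------------


def _random_index(seed=0, M=12, N=120, B=4, founders=3):
    panel = generate_panel(
        PanelSpec(M=M, N=N, founders=founders, switch_rate=0.02, mut_rate=0.01, seed=seed)
    )
    return panel, build_index(panel, B=B, hash_seed=seed)


def test_encode_query_identical_to_panel_row():
    panel, index = _random_index()
    z = encode_query(panel.alleles[3], index)
    assert (z.z == index.panel.compressed[3]).all()
    assert (z.h == index.h[3]).all()


def test_encode_query_out_of_dictionary_code():
    # Panel of all zeros: each dictionary is [0]; an all-ones query is absent
    # at every syllable and must be coded |r_k| = 1.
    panel = HaplotypePanel(np.zeros((3, 12), dtype=np.uint8))
    index = build_index(panel, B=4)
    z = encode_query(np.ones(12, dtype=np.uint8), index)
    assert (z.z == 1).all()
    z0 = encode_query(np.zeros(12, dtype=np.uint8), index)
    assert (z0.z == index.panel.compressed[0]).all()


def test_encode_query_input_errors():
    _, index = _random_index()
    with pytest.raises(InputError):
        encode_query(np.zeros(5, dtype=np.uint8), index)
    bad = np.zeros(index.N, dtype=np.int64)
    bad[0] = 2
    with pytest.raises(InputError):
        encode_query(bad, index)


# --- reversed-prefix comparison & virtual insertion -------------------------


def _rev(seq, k):
    return tuple(int(v) for v in seq[:k][::-1])


def test_compare_reverse_prefix_agrees_with_direct_comparison():
    panel, index = _random_index(seed=4, M=10, N=80, B=2)
    rng = np.random.default_rng(7)
    q = rng.integers(0, 2, index.N, dtype=np.uint8)
    z = encode_query(q, index)
    comp = index.panel.compressed
    for i in range(index.M):
        for k in range(index.n + 1):
            got, b = compare_reverse_prefix(z, index, i, k)
            zz, xx = _rev(z.z, k), _rev(comp[i], k)
            want = 0 if zz == xx else (-1 if zz < xx else 1)
            assert got == want
            if want != 0:
                diffs = [j for j in range(k) if int(z.z[j]) != int(comp[i, j])]
                assert b == max(diffs)


def brute_t(comp, zcodes, k):
    zz = _rev(zcodes, k)
    return sum(_rev(row, k) <= zz for row in comp)


def test_virtual_insert_tie_convention_at_syllable_zero():
    _, index = _random_index()
    q = np.zeros(index.N, dtype=np.uint8)
    cursor = virtual_insert(encode_query(q, index), index)
    assert cursor.t[0] == index.M  # all empty prefixes tie; z goes below them


def test_virtual_insert_query_equal_to_one_haplotype():
    panel, index = _random_index(seed=9, M=8, N=96, B=4)
    i = 5
    cursor = virtual_insert(encode_query(panel.alleles[i], index), index)
    for k in range(index.n + 1):
        pos = int(np.flatnonzero(index.a[k] == i)[0])
        # z ties with haplotype i and any equal neighbours below it
        assert cursor.t[k] == brute_t(index.panel.compressed, index.panel.compressed[i], k)
        assert cursor.t[k] >= pos + 1


@given(st.integers(0, 10_000))
def test_virtual_insert_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    M, n = int(rng.integers(2, 17)), int(rng.integers(1, 9))
    panel = HaplotypePanel(rng.integers(0, 2, (M, 2 * n), dtype=np.uint8))
    index = build_index(panel, B=2, hash_seed=seed % 97)
    q = rng.integers(0, 2, 2 * n, dtype=np.uint8)
    z = encode_query(q, index)
    cursor = virtual_insert(z, index)
    for k in range(n + 1):
        assert cursor.t[k] == brute_t(index.panel.compressed, z.z, k)
    assert (np.diff(cursor.low_anchor) >= 0).all()  # monotone anchor


# --- window sizes -----------------------------------------------------------


def test_window_sizes_site_mode_constant():
    _, index = _random_index(B=4)
    w = window_sizes(index, 12, "sites")
    assert w[0] is None
    assert all(v == 2 for v in w[1:])  # floor((12-4+1)/4) = 2


def test_window_sizes_cm_uniform_matches_site_mode():
    panel, _ = _random_index(B=4, N=120)
    panel.positions = np.arange(120, dtype=np.float64)  # 1 unit per site
    index = build_index(panel, B=4, hash_seed=0)
    w = window_sizes(index, 2 * 4 - 1, "cm")  # L = 2B-1 units
    interior = w[2 : index.n - 1]
    assert all(v == 1 for v in interior)


def test_window_sizes_cm_gap_collapses_window():
    panel, _ = _random_index(B=4, N=120)
    g = np.arange(120, dtype=np.float64) * 0.001
    g[62:] += 500.0  # huge gap inside syllable 15
    panel.positions = g
    index = build_index(panel, B=4, hash_seed=0)
    w = window_sizes(index, 10.0, "cm")
    assert w[16] == 1  # window spanning the gap needs a single syllable
    assert w[5] is None  # early windows can never reach 10 cM


def test_window_sizes_cm_requires_map():
    _, index = _random_index()
    with pytest.raises(InputError):
        window_sizes(index, 1.0, "cm")
    with pytest.raises(InputError):
        window_sizes(index, 1.0, "parsecs")


# --- scanning, extent, refinement -------------------------------------------


def _planted_run_setup():
    """Two-haplotype panel; query shares exactly syllables [2, 7) with hap 0."""
    rng = np.random.default_rng(31)
    B, n = 4, 10
    hap0 = rng.integers(0, 2, B * n, dtype=np.uint8)
    q = 1 - hap0
    q[2 * B : 7 * B] = hap0[2 * B : 7 * B]
    hap1 = 1 - q  # disagrees with the query at every site
    panel = HaplotypePanel(np.stack([hap0, hap1]))
    index = build_index(panel, B=B, hash_seed=3)
    return panel, index, q


def test_scan_emits_planted_run_exactly_once():
    _, index, q = _planted_run_setup()
    z = encode_query(q, index)
    cursor = virtual_insert(z, index)
    w = window_sizes(index, 12, "sites")  # window of 2 syllables
    found = scan_for_matches(z, cursor, index, w)
    assert found.count(PotentialMatch(hap=0, syl_start=2, syl_end=7)) == 1
    assert [pm for pm in found if pm.hap == 1] == []


def test_scan_no_shared_window_is_empty():
    panel = HaplotypePanel(np.ones((4, 32), dtype=np.uint8))
    index = build_index(panel, B=4)
    q = np.zeros(32, dtype=np.uint8)
    z = encode_query(q, index)
    found = scan_for_matches(z, virtual_insert(z, index), index,
                             window_sizes(index, 7, "sites"))
    assert found == []


def test_scan_full_length_run_for_identical_query():
    panel, index = _random_index(seed=2, M=6, N=64, B=4)
    q = panel.alleles[2]
    z = encode_query(q, index)
    found = scan_for_matches(z, virtual_insert(z, index), index,
                             window_sizes(index, 2 * 4 - 1, "sites"))
    full = [pm for pm in found if pm.hap == 2]
    assert full == [PotentialMatch(hap=2, syl_start=0, syl_end=index.n)]


def test_match_extent_against_naive_scan():
    panel, index = _random_index(seed=13, M=10, N=400, B=4, founders=2)
    rng = np.random.default_rng(5)
    q = panel.alleles[0].copy()
    q[250:] = rng.integers(0, 2, 150)  # long shared head with hap 0 (> 10 syllables)
    z = encode_query(q, index)
    comp = index.panel.compressed
    for i in range(index.M):
        for k in [0, 3, 12, 40]:
            m = k
            while m < index.n and int(z.z[m]) == int(comp[i, m]):
                m += 1
            assert match_extent(z, i, k, index) == m


def test_match_extent_trivial_cases():
    panel, index = _random_index(seed=1, M=4, N=64, B=4)
    z = encode_query(panel.alleles[1], index)
    assert match_extent(z, 1, 0, index) == index.n  # agreement through the end
    other = 1 - panel.alleles[1]
    z2 = encode_query(other, index)
    assert match_extent(z2, 1, 0, index) == 0  # diverge immediately


def test_refine_match_bitwise_boundaries():
    # B=4, run over syllable [1, 2). Left syllables differ at bit 3,
    # right syllables at bit 0 -> sites [4, 8).
    B = 4
    hap = np.zeros(12, dtype=np.uint8)
    q = np.zeros(12, dtype=np.uint8)
    hap[:4] = [0, 1, 0, 0]   # raw 0b0010
    q[:4] = [0, 1, 0, 1]     # raw 0b1010
    hap[4:8] = [1, 0, 1, 1]  # shared syllable
    q[4:8] = [1, 0, 1, 1]
    hap[8:] = [0, 0, 1, 0]   # raw 0b0100
    q[8:] = [1, 0, 1, 0]     # raw 0b0101
    panel = HaplotypePanel(hap[None, :])
    index = build_index(panel, B=B)
    z = encode_query(q, index)
    m = refine_match(PotentialMatch(hap=0, syl_start=1, syl_end=2), z.z_raw, index,
                     L=4, mode="sites")
    assert (m.start, m.end) == (4, 8)
    assert refine_match(PotentialMatch(0, 1, 2), z.z_raw, index, 5, "sites") is None


def test_refine_full_length_match():
    panel, index = _random_index(seed=21, M=5, N=60, B=4)
    z = encode_query(panel.alleles[4], index)
    m = refine_match(PotentialMatch(hap=4, syl_start=0, syl_end=index.n),
                     z.z_raw, index, L=7, mode="sites")
    assert (m.hap, m.start, m.end) == (4, 0, index.N)


# --- end-to-end -------------------------------------------------------------


def test_all_ones_panel_all_zeros_query_empty():
    panel = HaplotypePanel(np.ones((5, 100), dtype=np.uint8))
    index = build_index(panel, B=4)
    assert query_long_matches(index, np.zeros(100, dtype=np.uint8), 20) == []


def test_threshold_error_propagates():
    _, index = _random_index(B=4)
    with pytest.raises(ThresholdError):
        query_long_matches(index, np.zeros(index.N, dtype=np.uint8), 6)


def _oracle_sweep(index, panel, queries, L, mode):
    discrepancies = []
    for qi, q in enumerate(queries):
        eng = {m.key() for m in query_long_matches(index, q, L, mode=mode)}
        orc = {m.key() for m in naive_long_matches(panel, q, L, mode=mode)}
        if eng != orc:
            discrepancies.append((qi, sorted(eng ^ orc)[:3]))
    return discrepancies


def test_query_long_matches_planted_segments_match_oracle():
    panel = generate_panel(
        PanelSpec(M=50, N=2000, founders=5, switch_rate=0.01, mut_rate=0.002, seed=8)
    )
    index = build_index(panel, B=8, hash_seed=8)
    rng = np.random.default_rng(80)
    queries = []
    for qi in range(10):
        segs = [
            (int(rng.integers(50)), 150 + 380 * j, int(rng.integers(32, 200)))
            for j in range(5)
        ]
        q, _ = generate_query(panel, PlantSpec(segments=segs, seed=700 + qi))
        queries.append(q)
    assert _oracle_sweep(index, panel, queries, 32, "sites") == []


def test_query_long_matches_random_sweep_and_scout_equivalence():
    panel = generate_panel(
        PanelSpec(M=40, N=1500, founders=4, switch_rate=0.008, mut_rate=0.002, seed=12)
    )
    index = build_index(panel, B=8, hash_seed=12)
    rng = np.random.default_rng(3)
    queries = [rng.integers(0, 2, 1500, dtype=np.uint8) for _ in range(8)]
    queries += [
        generate_query(panel, PlantSpec(segments=[(7, 300, 500)], seed=s))[0]
        for s in range(4)
    ]
    assert _oracle_sweep(index, panel, queries, 40, "sites") == []
    for q in queries:
        plain = [m.key() for m in query_long_matches(index, q, 40, scout=False)]
        scout = [m.key() for m in query_long_matches(index, q, 40, scout=True)]
        assert plain == scout


def test_query_long_matches_cm_mode_matches_oracle():
    panel = generate_panel(
        PanelSpec(M=40, N=1500, founders=4, switch_rate=0.008, mut_rate=0.002, seed=14)
    )
    rng = np.random.default_rng(44)
    panel.positions = np.cumsum(rng.exponential(0.05, 1500))
    index = build_index(panel, B=8, hash_seed=14)
    queries = [
        generate_query(panel, PlantSpec(segments=[(3, 200, 400)], seed=s))[0]
        for s in range(6)
    ]
    assert _oracle_sweep(index, panel, queries, 2.5, "cm") == []
    for q in queries:
        for m in query_long_matches(index, q, 2.5, mode="cm"):
            assert m.length_cm >= 2.5
            assert m.length_cm == pytest.approx(
                panel.positions[m.end - 1] - panel.positions[m.start]
            )


def test_reported_matches_are_maximal():
    panel = generate_panel(
        PanelSpec(M=30, N=1000, founders=4, switch_rate=0.01, mut_rate=0.002, seed=6)
    )
    index = build_index(panel, B=8, hash_seed=6)
    q, _ = generate_query(panel, PlantSpec(segments=[(11, 100, 300)], seed=5))
    matches = query_long_matches(index, q, 32)
    assert matches  # the plant guarantees at least one
    for m in matches:
        assert m.start == 0 or panel.alleles[m.hap, m.start - 1] != q[m.start - 1]
        assert m.end == panel.N or panel.alleles[m.hap, m.end] != q[m.end]
        assert (panel.alleles[m.hap, m.start : m.end] == q[m.start : m.end]).all()
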