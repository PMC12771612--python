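"""ROH scanner vs. an independent exhaustive oracle, and fROH arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feralmix.genotype_io import MISSING, MarkerInfo
from feralmix.roh_scan import (
    SSCROFA11_AUTOSOME_KB,
    ROHParams,
    ROHProfile,
    ROHSegment,
    compare_groups,
    detect_roh_segments,
    summarize_froh,
)
from feralmix.synthetic_panel import simulate_roh_individual

from conftest import make_markers


# ---------------------------------------------------------------------------
# independent O(n^2) enumeration oracle
# ---------------------------------------------------------------------------

def oracle_segments(dosage, positions, p: ROHParams):
    """Enumerate every (i, j) interval as a full n x n validity matrix,
    applying each constraint directly, keep one-step-maximal candidates,
    then resolve overlaps by repeatedly keeping the longest (ties:
    leftmost).  Structurally unlike the scanner: no per-start frontier, no
    early termination — all n(n+1)/2 intervals are scored."""
    n = len(positions)
    dosage = np.asarray(dosage)
    positions = np.asarray(positions, dtype=np.int64)
    i_idx = np.arange(n)[:, None]  # rows: interval start
    j_idx = np.arange(n)[None, :]  # cols: interval end

    def interval_count(indicator):
        c = np.concatenate([[0], np.cumsum(indicator)])
        return c[None, 1:] - c[:-1, None]  # counts over [i, j]

    het_count = interval_count(dosage == 1)
    mis_count = interval_count(dosage == MISSING)
    # the gap between markers a and a+1 lies inside [i, j] iff i <= a < j
    big = np.diff(positions) > p.max_gap_bp
    B = np.concatenate([[0], np.cumsum(big)])  # B[t] = gaps among first t
    gap_inside = B[j_idx] - B[np.minimum(i_idx, j_idx)]

    n_snps = j_idx - i_idx + 1
    length_kb = (positions[None, :] - positions[:, None] + 1) / 1000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        density_ok = length_kb / n_snps <= p.max_kb_per_snp
    valid = (
        (j_idx >= i_idx)
        & (het_count <= p.max_het)
        & (mis_count <= p.max_missing)
        & (gap_inside <= 0)
        & (n_snps >= p.min_snps)
        & (length_kb >= p.min_kb)
        & density_ok
    )
    ext_right = np.zeros_like(valid)
    ext_right[:, :-1] = valid[:, 1:]
    ext_left = np.zeros_like(valid)
    ext_left[1:, :] = valid[:-1, :]
    maximal = valid & ~ext_right & ~ext_left
    cands = [(int(i), int(j)) for i, j in np.argwhere(maximal)]
    kept = []
    while cands:
        best = max(cands, key=lambda c: (positions[c[1]] - positions[c[0]],
                                         -positions[c[0]]))
        kept.append(best)
        cands = [c for c in cands if c[1] < best[0] or c[0] > best[1]]
    return sorted(kept)


def scanner_intervals(dosage, positions, p):
    markers = [MarkerInfo(f"m{i}", "1", int(pos), "A", "G")
               for i, pos in enumerate(positions)]
    segs = detect_roh_segments(np.asarray(dosage, dtype=np.int8), markers, p)
    pos_to_idx = {int(pos): i for i, pos in enumerate(positions)}
    return sorted((pos_to_idx[s.start_bp], pos_to_idx[s.end_bp]) for s in segs)


def random_chromosome(rng, n=200):
    """Random dosages and spacings straddling every constraint boundary."""
    dosage = rng.choice([0, 1, 2, MISSING], size=n,
                        p=[0.42, 0.12, 0.42, 0.04])
    # long homozygous stretches so candidate segments actually occur
    n_runs = rng.integers(0, 3)
    for _ in range(n_runs):
        start = int(rng.integers(0, max(1, n - 60)))
        length = int(rng.integers(30, 60))
        dosage[start:start + length] = rng.choice([0, 2], size=length)
    gaps = rng.choice(
        [20_000, 50_000, 79_999, 80_000, 80_001, 599_999, 600_000, 600_001],
        size=n - 1, p=[0.35, 0.3, 0.08, 0.08, 0.08, 0.04, 0.04, 0.03],
    )
    positions = np.concatenate([[1], 1 + np.cumsum(gaps)])
    return dosage.astype(np.int8), positions


SCAN_PARAMS = ROHParams(max_het=1, max_missing=2, max_gap_bp=600_000,
                        max_kb_per_snp=80.0, min_snps=25, min_kb=500.0)


def test_scanner_matches_oracle_on_random_chromosomes():
    """1,000 seeded random 200-marker chromosomes spanning the gap, density
    and heterozygote constraint boundaries: scanner output must be identical
    to exhaustive enumeration."""
    rng = np.random.default_rng(80)
    for _ in range(1000):
        dosage, positions = random_chromosome(rng)
        assert (scanner_intervals(dosage, positions, SCAN_PARAMS)
                == oracle_segments(dosage, positions, SCAN_PARAMS))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_scanner_matches_oracle_property(data):
    """Property form of the oracle equivalence on small random instances
    with permissive minimum-size settings (so density/gap logic is hit)."""
    n = data.draw(st.integers(5, 40))
    dosage = np.array(
        [data.draw(st.sampled_from([0, 1, 2, MISSING])) for _ in range(n)],
        dtype=np.int8)
    gaps = [data.draw(st.sampled_from([30_000, 80_001, 600_001]))
            for _ in range(n - 1)]
    positions = np.concatenate([[1], 1 + np.cumsum(gaps)])
    params = ROHParams(max_het=1, max_missing=1, max_gap_bp=600_000,
                       max_kb_per_snp=80.0, min_snps=2, min_kb=0.0)
    assert (scanner_intervals(dosage, positions, params)
            == oracle_segments(dosage, positions, params))


# ---------------------------------------------------------------------------
# constructed cases
# ---------------------------------------------------------------------------

def test_constructed_long_run_single_segment():
    """300 homozygous SNPs at 50 kb spacing (~15 Mb span) with clean
    flanks: exactly one segment covering the run."""
    n = 300
    dosage = np.full(n, 2, dtype=np.int8)
    markers = make_markers(n, spacing=50_000)
    segs = detect_roh_segments(dosage, markers, SCAN_PARAMS)
    assert len(segs) == 1
    s = segs[0]
    assert s.n_snps == 300 and s.n_het == 0
    assert s.length_kb > 10_000


def test_two_hets_split_run():
    """A long run with 2 interior heterozygotes must split: no reported
    segment may contain both (max_het = 1)."""
    n = 300
    dosage = np.full(n, 0, dtype=np.int8)
    dosage[[100, 200]] = 1
    markers = make_markers(n, spacing=50_000)
    segs = detect_roh_segments(dosage, markers, SCAN_PARAMS)
    assert len(segs) >= 1
    for s in segs:
        assert s.n_het <= 1
    het_pos = {markers[100].position_bp, markers[200].position_bp}
    for s in segs:
        inside = [p for p in het_pos if s.start_bp <= p <= s.end_bp]
        assert len(inside) <= 1


def test_gap_over_600kb_breaks_run():
    markers = (make_markers(100, spacing=50_000, prefix="a")
               + [MarkerInfo(f"b{i}", "1", 100 * 50_000 + 600_001 + i * 50_000,
                             "A", "G") for i in range(100)])
    dosage = np.full(200, 2, dtype=np.int8)
    segs = detect_roh_segments(dosage, markers, SCAN_PARAMS)
    assert len(segs) == 2
    boundary = markers[99].position_bp
    assert segs[0].end_bp <= boundary < segs[1].start_bp


def test_density_ceiling_exactly_80kb_per_snp():
    """At exactly 80 kb/SNP density the segment qualifies; just above, not."""
    n = 50
    # span/n = (n-1)*s + 1 over n SNPs; choose s so span/n == 80 kb exactly
    spacing = (80_000 * n - 1) // (n - 1)  # makes span ~= 80kb * n
    markers = make_markers(n, spacing=spacing)
    span_kb = (markers[-1].position_bp - markers[0].position_bp + 1) / 1000
    dosage = np.full(n, 2, dtype=np.int8)
    params = ROHParams(max_het=1, max_missing=2, max_gap_bp=10**9,
                       max_kb_per_snp=80.0, min_snps=2, min_kb=0.0)
    segs = detect_roh_segments(dosage, markers, params)
    if span_kb / n <= 80.0:
        assert any(s.n_snps == n for s in segs)
    tight = ROHParams(max_het=1, max_missing=2, max_gap_bp=10**9,
                      max_kb_per_snp=span_kb / n - 0.001, min_snps=2, min_kb=0.0)
    segs2 = detect_roh_segments(dosage, markers, tight)
    assert not any(s.n_snps == n for s in segs2)


def test_unsorted_markers_rejected():
    markers = make_markers(10, spacing=50_000)
    markers[3], markers[4] = markers[4], markers[3]
    with pytest.raises(ValueError, match="sorted"):
        detect_roh_segments(np.zeros(10, dtype=np.int8), markers)


def test_scanner_deterministic():
    rng = np.random.default_rng(81)
    dosage, positions = random_chromosome(rng)
    a = scanner_intervals(dosage, positions, SCAN_PARAMS)
    b = scanner_intervals(dosage.copy(), positions.copy(), SCAN_PARAMS)
    assert a == b


# ---------------------------------------------------------------------------
# fROH summaries
# ---------------------------------------------------------------------------

def test_froh_zero_without_segments():
    p = summarize_froh([], sample_id="x")
    assert p.froh == 0.0 and p.n_long == 0


def test_froh_exact_arithmetic():
    seg = ROHSegment("x", "1", 1, int(226_577.5e3), n_snps=100, n_het=0,
                     n_missing=0)
    p = summarize_froh([seg])
    assert p.froh == pytest.approx(0.1, abs=1e-12)


def test_fully_homozygous_genome_froh_equals_covered_span():
    """A dense fully homozygous genome yields froh = covered span /
    autosome constant, to 1e-9."""
    layout = [("1", 500, 50_000), ("2", 400, 50_000)]
    g, _ = simulate_roh_individual(
        layout,
        planted=[("1", 1, 1 + 499 * 50_000), ("2", 1, 1 + 399 * 50_000)],
        background_het=0.0, seed=82)
    segs = detect_roh_segments(g.dosage[0], g.markers, SCAN_PARAMS)
    covered_kb = sum(s.length_kb for s in segs)
    expected_kb = (499 * 50_000 + 1) / 1000 + (399 * 50_000 + 1) / 1000
    assert covered_kb == pytest.approx(expected_kb)
    p = summarize_froh(segs)
    assert p.froh == pytest.approx(expected_kb / SSCROFA11_AUTOSOME_KB, abs=1e-9)


def test_froh_monotone_in_planted_length():
    layout = [("1", 1000, 50_000)]
    frohs = []
    for n_mark in (100, 200, 400):
        g, _ = simulate_roh_individual(
            layout, planted=[("1", 1, 1 + (n_mark - 1) * 50_000)],
            background_het=0.5, seed=83)
        segs = detect_roh_segments(g.dosage[0], g.markers, SCAN_PARAMS)
        frohs.append(summarize_froh(segs).froh)
    assert frohs[0] <= frohs[1] <= frohs[2]


def test_long_segment_count_threshold():
    mk = lambda kb: ROHSegment("x", "1", 1, int(kb * 1000), 50, 0, 0)
    p = summarize_froh([mk(9_999), mk(10_000), mk(10_001)])
    assert p.n_long == 1  # strictly greater than 10 Mb


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def prof(sid, froh_kb):
    seg = ROHSegment(sid, "1", 1, int(froh_kb * 1000), 50, 0, 0)
    return ROHProfile(sample_id=sid, segments=[seg])


def test_identical_groups_identical_rows():
    a = [prof("a1", 1000), prof("a2", 2000)]
    b = [prof("b1", 1000), prof("b2", 2000)]
    t = compare_groups({"A": a, "B": b})
    assert np.allclose(t.loc["A"].drop("n").astype(float),
                       t.loc["B"].drop("n").astype(float))


def test_planted_group_has_higher_mean_froh():
    layout = [("1", 600, 50_000)]
    planted, clean = [], []
    for i in range(3):
        g, _ = simulate_roh_individual(
            layout, planted=[("1", 1, 1 + 300 * 50_000)],
            background_het=0.4, seed=90 + i, sample_id=f"p{i}")
        segs = detect_roh_segments(g.dosage[0], g.markers, SCAN_PARAMS)
        planted.append(summarize_froh(segs, sample_id=f"p{i}"))
        g2, _ = simulate_roh_individual(layout, planted=[],
                                        background_het=0.4, seed=95 + i,
                                        sample_id=f"c{i}")
        segs2 = detect_roh_segments(g2.dosage[0], g2.markers, SCAN_PARAMS)
        clean.append(summarize_froh(segs2, sample_id=f"c{i}"))
    t = compare_groups({"planted": planted, "clean": clean})
    assert t.loc["planted", "mean_froh"] > t.loc["clean", "mean_froh"]


def test_single_sample_group_mean_is_its_froh():
    p = prof("solo", 5000)
    t = compare_groups({"solo_group": [p]})
    assert t.loc["solo_group", "mean_froh"] == pytest.approx(p.froh)


def test_empty_group_excluded_with_warning():
    with pytest.warns(UserWarning, match="empty"):
        t = compare_groups({"full": [prof("a", 1000)], "void": []})
    assert list(t.index) == ["full"]
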