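"""Extended loops, orientation-stratified pairing, APA and domain pileups."""

import numpy as np
import pandas as pd
import pytest

import fountainscope as fs

from conftest import brute_force_extended


def _loops(rows):
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )


def test_extended_loops_distance_window():
    # 5' anchor mids {1.005, 2.0} Mb, 3' anchor mids {2.8, 4.4} Mb ->
    # recombination separations {1.795, 3.395, 0.8, 2.4} Mb; the window
    # [1.5, 3.0] Mb keeps exactly the 1.795 and 2.4 Mb pairs
    primary = _loops([
        ("chr1", 1_000_000, 1_010_000, "chr1", 2_795_000, 2_805_000),
        ("chr1", 1_995_000, 2_005_000, "chr1", 4_395_000, 4_405_000),
    ])
    ext = fs.make_extended_loops(primary, min_dist=1.5e6, max_dist=3.0e6)
    seps = sorted(
        ((ext["start2"] + ext["end2"]) / 2 - (ext["start1"] + ext["end1"]) / 2) / 1e6
    )
    assert len(seps) == 2
    assert seps[0] == pytest.approx(1.795, abs=0.01)
    assert seps[1] == pytest.approx(2.4, abs=0.01)


def test_extended_loops_never_cross_chromosomes():
    primary = _loops([
        ("chr1", 1_000_000, 1_010_000, "chr1", 1_500_000, 1_510_000),
        ("chr2", 1_000_000, 1_010_000, "chr2", 1_500_000, 1_510_000),
    ])
    ext = fs.make_extended_loops(primary, min_dist=0, max_dist=1e9)
    assert (ext["chrom1"] == ext["chrom2"]).all()
    assert not ((ext["chrom1"] == "chr1") & (ext["chrom2"] == "chr2")).any()


def test_extended_loops_inverted_limits_warn_empty():
    primary = _loops([("chr1", 0, 10_000, "chr1", 2_000_000, 2_010_000)])
    with pytest.warns(UserWarning, match="min_dist"):
        ext = fs.make_extended_loops(primary, min_dist=3e6, max_dist=1.5e6)
    assert len(ext) == 0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_extended_loops_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(60):
        chrom = rng.choice(["chr1", "chr2"])
        s1 = int(rng.integers(0, 20_000_000))
        s2 = s1 + int(rng.integers(100_000, 3_000_000))
        rows.append((chrom, s1, s1 + 10_000, chrom, s2, s2 + 10_000))
    primary = _loops(rows)
    ext = fs.make_extended_loops(primary, 1.5e6, 3e6, dedup_binsize=1)
    got = {
        (r.chrom1, (r.start1 + r.end1) / 2, (r.start2 + r.end2) / 2)
        for r in ext.itertuples()
    }
    want = brute_force_extended(primary.to_dict("records"), 1.5e6, 3e6)
    assert got == want


def test_orientation_pairing_rules():
    regions = pd.DataFrame({
        "chrom": ["chr1"] * 2, "start": [1_000_000, 2_000_000],
        "end": [1_010_000, 2_010_000],
    })
    motifs = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [1_002_000, 2_002_000], "end": [1_002_019, 2_002_019],
        "strand": ["+", "-"],
    })
    classes = fs.pair_regions_by_orientation(regions, motifs, 0, 1e9)
    assert len(classes["convergent"]) == 1
    assert len(classes["tandem"]) == 0 and len(classes["divergent"]) == 0


def test_region_with_both_orientations_excluded():
    regions = pd.DataFrame({"chrom": ["chr1"] * 2,
                            "start": [1_000_000, 2_000_000],
                            "end": [1_010_000, 2_010_000]})
    motifs = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [1_002_000, 1_005_000, 2_002_000],
        "end": [1_002_019, 1_005_019, 2_002_019],
        "strand": ["+", "-", "-"],
    })
    classes = fs.pair_regions_by_orientation(regions, motifs, 0, 1e9)
    assert all(len(v) == 0 for v in classes.values())


def test_orientation_class_counts_match_enumeration():
    strands = ["+", "-", "+", "+", "-", "-"]
    regions = pd.DataFrame({
        "chrom": "chr1",
        "start": [i * 1_000_000 for i in range(1, 7)],
        "end": [i * 1_000_000 + 10_000 for i in range(1, 7)],
    })
    motifs = pd.DataFrame({
        "chrom": "chr1",
        "start": [i * 1_000_000 + 100 for i in range(1, 7)],
        "end": [i * 1_000_000 + 119 for i in range(1, 7)],
        "strand": strands,
    })
    classes = fs.pair_regions_by_orientation(regions, motifs, 0, 1e9)
    expect = {"convergent": 0, "tandem": 0, "divergent": 0}
    for i in range(6):
        for j in range(i + 1, 6):
            su, sd = strands[i], strands[j]
            key = ("convergent" if (su, sd) == ("+", "-")
                   else "tandem" if su == sd else "divergent")
            expect[key] += 1
    assert {k: len(v) for k, v in classes.items()} == expect


def _flat_map(n=300, res=5000):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return fs.ContactMatrix({"chr1": (1.0 + d) ** -1.0}, res)


def test_apa_on_flat_oe_gives_unit_enrichment():
    cm = _flat_map()
    loops = _loops([("chr1", 200_000, 205_000, "chr1", 900_000, 905_000)])
    pu = fs.aggregate_loop_pileup(cm, loops, pad_bp=100_000)
    assert pu.enrichment == pytest.approx(1.0)
    assert pu.n_loops_used == 1


def test_apa_validation_errors():
    cm = _flat_map()
    with pytest.raises(ValueError, match="empty"):
        fs.aggregate_loop_pileup(cm, _loops([]), pad_bp=100_000)
    near_diag = _loops([("chr1", 200_000, 205_000, "chr1", 260_000, 265_000)])
    with pytest.raises(ValueError, match="dropped"):
        fs.aggregate_loop_pileup(cm, near_diag, pad_bp=100_000)


def test_apa_recovers_injected_fold():
    """Loops injected at fold 4 pile up to enrichment ~4 (Poisson tolerance)."""
    rng = np.random.default_rng(8)
    n_bins, res = 3000, 5000
    size = n_bins * res
    loops = []
    for _ in range(500):
        p1 = int(rng.integers(300_000, size - 3_500_000))
        p2 = p1 + int(rng.integers(500_000, 3_000_000))
        loops.append(("chr1", p1, p2, 4.0))
    spec = fs.SyntheticSpec(
        chrom_sizes={"chr1": size}, binsize=res, loop_list=loops,
        total_counts=2e7, seed=21,
    )
    sm = fs.synthesize_contact_matrix(spec)
    df = _loops([(c, p1, p1 + res, c, p2, p2 + res) for c, p1, p2, _ in loops])
    pu = fs.aggregate_loop_pileup(sm.matrix, df, pad_bp=200_000)
    assert 3.0 <= pu.enrichment <= 5.0


def test_apa_invariant_to_loop_order():
    cm = _flat_map()
    rng = np.random.default_rng(3)
    rows = []
    for _ in range(20):
        p1 = int(rng.integers(150_000, 400_000))
        p2 = p1 + int(rng.integers(400_000, 700_000))
        rows.append(("chr1", p1, p1 + 5000, "chr1", p2, p2 + 5000))
    df = _loops(rows)
    a = fs.aggregate_loop_pileup(cm, df, pad_bp=50_000)
    b = fs.aggregate_loop_pileup(cm, df.sample(frac=1, random_state=0), pad_bp=50_000)
    np.testing.assert_allclose(a.grid, b.grid, equal_nan=True)


def test_rescaled_pileup_flat_and_shape():
    cm = _flat_map(n=400, res=20_000)
    domains = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [1_000_000, 3_000_000, 5_000_000],
        "end": [1_600_000, 3_800_000, 5_500_000],
    })
    pu = fs.rescaled_domain_pileup(cm, domains, out_size_bins=99)
    assert pu.grid.shape == (99, 99)
    np.testing.assert_allclose(pu.grid[np.isfinite(pu.grid)], 1.0, atol=1e-9)
    with pytest.raises(ValueError, match="odd"):
        fs.rescaled_domain_pileup(cm, domains, out_size_bins=98)


def test_rescaled_pileup_recovers_domain_fold():
    # domains cover a small fraction of the chromosome so the expected
    # profile is barely inflated and the O/E fold stays close to 2
    n, res = 1200, 20_000
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = (1.0 + d) ** -1.0
    domains = []
    for start in (150, 500, 900):
        L = 30
        base[start:start + L, start:start + L] *= 2.0
        domains.append(("chr1", start * res, (start + L) * res))
    cm = fs.ContactMatrix({"chr1": base}, res)
    df = pd.DataFrame(domains, columns=["chrom", "start", "end"])
    pu = fs.rescaled_domain_pileup(cm, df, out_size_bins=33)
    assert pu.enrichment == pytest.approx(2.0, rel=0.15)


def test_extended_loop_gain_under_cohesin_stabilisation(preset_maps):
    """Anchor recombinations at long range gain contact when cohesin is
    stabilised (release off), the extended-loop phenotype."""
    prm_u, res_u = preset_maps["untreated"]
    prm_w, res_w = preset_maps["wapl_off"]
    bs = prm_u.binsize
    # primary loops: adjacent convergent barrier pairs
    barrier_bins = sorted(p for p, _o, _s in prm_u.barriers)
    rows = [
        ("chrSim", b1 * bs, (b1 + 1) * bs, "chrSim", b2 * bs, (b2 + 1) * bs)
        for b1, b2 in zip(barrier_bins, barrier_bins[1:])
    ]
    primary = _loops(rows)
    extended = fs.make_extended_loops(primary, min_dist=6e5, max_dist=1.2e6)
    assert len(extended) > 0
    e_u = fs.aggregate_loop_pileup(res_u.matrix, extended, pad_bp=5 * bs).enrichment
    e_w = fs.aggregate_loop_pileup(res_w.matrix, extended, pad_bp=5 * bs).enrichment
    assert e_w > e_u
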