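"""ZAC coverage ratios, reference statistics and karyotype calling."""

import numpy as np
import pytest

from paleokin.io_formats import AUTOSOMES
from paleokin.simulate import default_site_map, simulate_depth_table
from paleokin.zac import (
    DepthTable,
    InsufficientDataError,
    build_reference_stats,
    call_karyotype,
    estimate_ploidy,
    normalize_depth,
    read_depth_table,
    write_depth_table,
    _round_toward,
)

SITES = {str(i): 1000 for i in range(1, 23)} | {"X": 1000, "Y": 1000}


def table(sample="s", rate=0.05, scale=None, sites=SITES):
    """Noiseless depth table: reads = sites * rate * copies/2 per chromosome."""
    scale = scale or {}
    reads = {c: round(sites[c] * rate * scale.get(c, 1.0)) for c in sites}
    return DepthTable(sample, reads, dict(sites))


def jittered_refs(n=10, karyotype="XY", rate=0.05, delta=0.02, include_y=True):
    """Deterministic reference set with symmetric +/-delta jitter: sd > 0
    on every chromosome while each mean ratio stays exactly at the
    noiseless value (n must be even)."""
    x_scale = {"XY": 0.5, "XX": 1.0}[karyotype]
    y_scale = {"XY": 0.5, "XX": 0.0}[karyotype]
    sites = SITES if include_y else {c: v for c, v in SITES.items() if c != "Y"}
    refs, karyos = [], {}
    for i in range(n):
        sign = 1 if i % 2 == 0 else -1
        scale = {"X": x_scale * (1 + sign * delta), "Y": y_scale * (1 + sign * delta)}
        for j, c in enumerate(AUTOSOMES):
            scale[c] = 1 + delta * (1 if (i + j) % 2 == 0 else -1)
        refs.append(table(f"{karyotype}{i}", rate, scale, sites=sites))
        karyos[f"{karyotype}{i}"] = karyotype
    return refs, karyos


# --- normalize_depth -------------------------------------------------------

def test_uniform_coverage_gives_unit_ratios():
    ratios = normalize_depth(table(rate=0.05))
    for c in AUTOSOMES:
        assert ratios[c] == pytest.approx(1.0)


def test_trisomic_chromosome_ratio_is_three_halves_of_diploid():
    ratios = normalize_depth(table(scale={"21": 1.5}))
    assert ratios["21"] / ratios["1"] == pytest.approx(1.5)


def test_zero_y_reads_give_zero_ratio():
    ratios = normalize_depth(table(scale={"Y": 0.0}))
    assert ratios["Y"] == 0.0


def test_zero_autosomal_reads_is_insufficient_data():
    with pytest.raises(InsufficientDataError):
        normalize_depth(table(rate=0.0))


def test_site_weighted_autosomal_mean_is_one(rng):
    """Self-consistency: autosomal ratios average to 1 under site weights."""
    sites = {c: int(rng.integers(500, 5000)) for c in SITES}
    reads = {c: int(rng.integers(1, 500)) for c in SITES}
    t = DepthTable("r", reads, sites)
    ratios = normalize_depth(t)
    w = np.array([sites[c] for c in AUTOSOMES], dtype=float)
    r = np.array([ratios[c] for c in AUTOSOMES])
    assert np.average(r, weights=w) == pytest.approx(1.0, abs=1e-12)


# --- reference statistics --------------------------------------------------

def test_xx_and_xy_references_share_the_per_copy_x_expectation():
    refs_xy, k_xy = jittered_refs(10, "XY")
    refs_xx, k_xx = jittered_refs(10, "XX", include_y=False)
    stats_xy = build_reference_stats(refs_xy, k_xy)
    stats_xx = build_reference_stats(refs_xx, k_xx)
    # one X copy at ratio 0.5 and two X copies at ratio 1.0 both mean 0.5/copy
    assert stats_xy.mean_ratio["X"] == pytest.approx(0.5, rel=1e-9)
    assert stats_xx.mean_ratio["X"] == pytest.approx(0.5, rel=1e-9)
    assert stats_xy.reference_copies["X"] == 1


def test_xx_references_contribute_nothing_to_y():
    refs, karyos = jittered_refs(10, "XX")
    with pytest.raises(ValueError, match="Y"):
        build_reference_stats(refs, karyos)


def test_single_reference_rejected():
    refs, karyos = jittered_refs(1, "XY")
    with pytest.raises(ValueError, match=">= 2"):
        build_reference_stats(refs, karyos)


def test_zero_variance_references_rejected():
    refs = [table(f"r{i}", 0.05, {"X": 0.5, "Y": 0.5}) for i in range(3)]
    with pytest.raises(ValueError, match="zero variance"):
        build_reference_stats(refs, {f"r{i}": "XY" for i in range(3)})


def test_poisson_references_have_positive_spread(rng):
    sites = default_site_map(100_000)
    refs, karyos = [], {}
    for i in range(20):
        k = "XX" if i % 2 else "XY"
        refs.append(simulate_depth_table(k, sites, 0.1, rng=rng, sample=f"r{i}"))
        karyos[f"r{i}"] = k
    stats = build_reference_stats(refs, karyos)
    assert all(sd > 0 for sd in stats.sd_ratio.values())
    assert set(stats.mean_ratio) == set(sites)


# --- ploidy estimation -----------------------------------------------------

def test_noiseless_diploid_sample_is_called_diploid_with_zero_z():
    refs, karyos = jittered_refs(10, "XY")
    stats = build_reference_stats(refs, karyos)
    calls = estimate_ploidy(table(scale={"X": 0.5, "Y": 0.5}), stats)
    by = {c.chromosome: c for c in calls}
    for c in AUTOSOMES:
        assert by[c].copies == 2
        assert by[c].z == pytest.approx(0.0, abs=1e-9)
        assert not by[c].flagged
    assert by["X"].copies == 1 and by["Y"].copies == 1


def test_simulated_trisomy_21_flagged_at_low_coverage(rng):
    sites = default_site_map(1_150_000)
    refs, karyos = [], {}
    for i in range(20):
        k = "XX" if i % 2 else "XY"
        refs.append(simulate_depth_table(k, sites, 0.1, rng=rng, sample=f"r{i}"))
        karyos[f"r{i}"] = k
    stats = build_reference_stats(refs, karyos)
    t = simulate_depth_table("XX+21", sites, 0.05, rng=rng)
    by = {c.chromosome: c for c in estimate_ploidy(t, stats)}
    assert by["21"].copies == 3
    assert by["21"].flagged


def test_per_copy_gonosome_estimates_recover_xyy():
    refs, karyos = jittered_refs(10, "XY")
    stats = build_reference_stats(refs, karyos)
    # X at one per-copy unit, Y at two per-copy units
    calls = estimate_ploidy(table(scale={"X": 0.5, "Y": 1.0}, rate=0.2), stats)
    by = {c.chromosome: c for c in calls}
    assert by["X"].copies == 1 and by["Y"].copies == 2
    kc = call_karyotype(calls)
    assert kc.gonosomal == "XYY" and kc.genetic_sex == "M"


def test_missing_reference_chromosome_is_an_error():
    refs, karyos = jittered_refs(10, "XY")
    stats = build_reference_stats(refs, karyos)
    del stats.mean_ratio["22"]
    with pytest.raises(ValueError, match="22"):
        estimate_ploidy(table(), stats)


def test_scale_invariance_of_calls():
    """Multiplying every read count by a constant changes nothing."""
    refs, karyos = jittered_refs(10, "XY")
    stats = build_reference_stats(refs, karyos)
    t1 = table(scale={"X": 0.5, "Y": 1.0, "21": 1.5})
    t10 = DepthTable("s", {c: r * 10 for c, r in t1.reads.items()}, dict(t1.sites))
    c1 = estimate_ploidy(t1, stats)
    c10 = estimate_ploidy(t10, stats)
    for a, b in zip(c1, c10):
        assert (a.ratio, a.z, a.copies, a.flagged) == pytest.approx(
            (b.ratio, b.z, b.copies, b.flagged)
        )


@pytest.mark.parametrize(
    "x, expected, result",
    [(2.5, 2, 2), (1.5, 2, 2), (4.5, 2, 4), (1.5, 1, 1), (0.5, 1, 1), (2.4, 2, 2),
     (2.6, 2, 3), (-0.4, 2, 0)],
)
def test_half_ties_round_toward_expected_copies(x, expected, result):
    assert _round_toward(x, expected) == result


# --- karyotype calls -------------------------------------------------------

def karyo(scale, rate=0.2):
    refs, karyos = jittered_refs(10, "XY")
    stats = build_reference_stats(refs, karyos)
    return call_karyotype(estimate_ploidy(table(scale=scale, rate=rate), stats))


def test_canonical_female_call():
    kc = karyo({"X": 1.0, "Y": 0.0})
    assert kc.gonosomal == "XX" and kc.genetic_sex == "F"


def test_x0_has_undetermined_sex_by_convention():
    kc = karyo({"X": 0.5, "Y": 0.0})
    assert kc.gonosomal == "X0" and kc.genetic_sex == "undetermined"


def test_below_min_reads_is_undetermined_not_a_crash():
    refs, karyos = jittered_refs(10, "XY")
    stats = build_reference_stats(refs, karyos)
    t = table(scale={"X": 0.02, "Y": 0.0}, rate=0.05)  # 1 X read, 0 Y reads
    kc = call_karyotype(estimate_ploidy(t, stats), min_reads=100)
    assert kc.gonosomal == "undetermined"
    assert kc.genetic_sex == "undetermined"
    assert not kc.min_informative


def test_karyotype_without_gonosomes_is_undetermined():
    auto_sites = {c: 1000 for c in AUTOSOMES}
    t = DepthTable("s", {c: 50 for c in AUTOSOMES}, auto_sites)
    refs, karyos = jittered_refs(10, "XY")
    stats = build_reference_stats(refs, karyos)
    kc = call_karyotype(estimate_ploidy(t, stats))
    assert kc.gonosomal == "undetermined" and not kc.min_informative


# --- end-to-end recovery ---------------------------------------------------

KARYOTYPES = ("XX", "XY", "XYY", "XXY", "X0", "XX+21")


def recovery_rate(karyotype, coverage, n_rep, stats, sites, seed):
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_rep):
        t = simulate_depth_table(karyotype, sites, coverage, rng=rng)
        kc = call_karyotype(estimate_ploidy(t, stats))
        ok += kc.karyotype_label == karyotype
    return ok / n_rep


@pytest.fixture(scope="module")
def ref_stats_1240k():
    rng = np.random.default_rng(424_242)
    sites = default_site_map(1_150_000)
    refs, karyos = [], {}
    for i in range(20):
        k = "XX" if i < 10 else "XY"
        refs.append(simulate_depth_table(k, sites, 0.1, rng=rng, sample=f"r{i}"))
        karyos[f"r{i}"] = k
    return build_reference_stats(refs, karyos), sites


@pytest.mark.parametrize("karyotype", KARYOTYPES)
def test_karyotype_recovery_at_hundredth_x(karyotype, ref_stats_1240k):
    """>=95% correct karyotypes at 0.01x on a 1240k-like site map."""
    stats, sites = ref_stats_1240k
    rate = recovery_rate(
        karyotype, 0.01, 50, stats, sites, seed=1000 + KARYOTYPES.index(karyotype)
    )
    assert rate >= 0.95


def test_recovery_improves_with_coverage(ref_stats_1240k):
    """Correct-call rate is non-decreasing in coverage (binomial slack)."""
    stats, sites = ref_stats_1240k
    rates = [
        recovery_rate("XX+21", cov, 40, stats, sites, seed=99)
        for cov in (0.005, 0.01, 0.05, 0.1)
    ]
    for lo, hi in zip(rates, rates[1:]):
        assert hi >= lo - 0.1
    assert rates[-1] >= 0.95


# --- depth TSV -------------------------------------------------------------

def test_depth_table_round_trip(tmp_path):
    tables = [table("a"), table("b", scale={"X": 0.5, "Y": 0.5})]
    write_depth_table(tables, tmp_path / "d.tsv")
    back = read_depth_table(tmp_path / "d.tsv")
    assert [t.sample for t in back] == ["a", "b"]
    assert back[1].reads == tables[1].reads and back[1].sites == tables[1].sites
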