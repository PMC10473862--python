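"""MPMR: mismatch counting, background normalization, degree classes,
jackknife uncertainty and network construction."""

import math

import numpy as np
import pytest

from paleokin.kinship import (
    DEFAULT_CUTOFFS,
    background_rate,
    build_network,
    classify_degree,
    jackknife_se,
    kin_matrix,
    pairwise_mismatch,
)
from paleokin.simulate import PedigreeSpec, SimulationConfig, pseudohaploidize, simulate_pedigree_genotypes
from conftest import make_matrix


# --- raw mismatch counting -------------------------------------------------

def test_identical_samples_have_zero_pmr():
    calls = np.full((2, 1000), 2, dtype=np.int8)
    calls[:, ::3] = 0
    pc = pairwise_mismatch(make_matrix(calls), "ind0", "ind1")
    assert pc.pmr == 0.0 and pc.overlap == 1000


def test_hand_counted_six_site_example():
    # mismatches at sites 3 and 5 (1-based) -> pmr = 2/6
    a = [0, 2, 2, 0, 0, 2]
    b = [0, 2, 0, 0, 2, 2]
    pc = pairwise_mismatch(make_matrix([a, b]), "ind0", "ind1")
    assert pc.overlap == 6 and pc.mismatches == 2
    assert pc.pmr == pytest.approx(2 / 6)


def test_all_missing_pair_is_insufficient_not_crash():
    pc = pairwise_mismatch(make_matrix([[9, 9, 9], [0, 2, 0]]), "ind0", "ind1")
    assert pc.overlap == 0 and math.isnan(pc.pmr)


def test_missing_in_either_sample_removes_site_from_overlap():
    pc = pairwise_mismatch(make_matrix([[0, 9, 2, 2], [0, 2, 9, 0]]), "ind0", "ind1")
    assert pc.overlap == 2 and pc.mismatches == 1


def test_same_sample_rejected():
    with pytest.raises(ValueError):
        pairwise_mismatch(make_matrix([[0, 2], [2, 0]]), "ind0", "ind0")


# --- background ------------------------------------------------------------

def test_background_median():
    assert background_rate([0.125, 0.24, 0.25, 0.26]) == pytest.approx(0.245)


def test_background_median_of_one():
    assert background_rate([0.25]) == 0.25


def test_background_supplied_passthrough():
    assert background_rate([0.1, 0.9], mode="supplied", supplied=0.248) == 0.248


def test_background_no_eligible_pairs_is_error():
    with pytest.raises(ValueError):
        background_rate([float("nan")])


# --- degree classification -------------------------------------------------

@pytest.mark.parametrize(
    "norm, degree",
    [(0.125 / 0.245, "identical/twin"), (0.5, "identical/twin"),
     (0.75, "first"), (1.0, "unrelated"), (0.875, "second"),
     # boundaries are closed below, open above
     (0.625, "first"), (0.8125, "second"), (0.90625, "unrelated"),
     (float("nan"), "insufficient")],
)
def test_degree_cutoffs(norm, degree):
    assert classify_degree(norm) == degree


def test_cutoffs_bracket_expected_norms():
    # identical/first and first/second bounds are midpoints of the
    # expected scores; the unrelated bound sits at the second/third-degree
    # midpoint (0.90625), keeping third-degree pairs out of "second"
    assert DEFAULT_CUTOFFS[0] == (0.5 + 0.75) / 2
    assert DEFAULT_CUTOFFS[1] == (0.75 + 0.875) / 2
    assert DEFAULT_CUTOFFS[2] == (0.875 + 0.9375) / 2
    for expected, degree in [(0.5, "identical/twin"), (0.75, "first"),
                             (0.875, "second"), (1.0, "unrelated")]:
        assert classify_degree(expected) == degree


# --- jackknife -------------------------------------------------------------

def test_jackknife_zero_when_blocks_identical():
    se = jackknife_se(np.array([10, 10, 10]), np.array([50, 50, 50]), background=0.25)
    assert se == pytest.approx(0.0)


def test_jackknife_two_block_closed_form():
    # blocks with pmr 0.2 and 0.3, equal overlap 100, background 0.25:
    # delete-one estimates are 0.3/0.25 = 1.2 and 0.2/0.25 = 0.8;
    # se = sqrt((g-1)/g * sum((theta - mean)^2)) = sqrt(0.5 * 0.08) = 0.2
    se = jackknife_se(np.array([20, 30]), np.array([100, 100]), background=0.25)
    assert se == pytest.approx(0.2)


def test_jackknife_single_block_is_missing():
    assert math.isnan(jackknife_se(np.array([20]), np.array([100]), 0.25))


def test_jackknife_drops_empty_blocks():
    se = jackknife_se(np.array([20, 0, 30]), np.array([100, 0, 100]), background=0.25)
    assert se == pytest.approx(0.2)


# --- cohort estimation on simulated pedigrees ------------------------------

@pytest.fixture(scope="module")
def family_cohort():
    """Duplicated sample, parent-offspring, full sibs (dizygotic twins),
    half sibs, plus an unrelated background of founders."""
    ped = PedigreeSpec(
        founders=tuple(f"U{i}" for i in range(10)) + ("P1", "P2", "P3"),
        matings=(("P1", "P2", "TWIN1"), ("P1", "P2", "TWIN2"), ("P1", "P3", "HALF")),
        duplicates=(("P1", "P1copy"),),
    )
    cfg = SimulationConfig(n_sites=50_000, coverage=1.0, seed=31)
    matrix = pseudohaploidize(simulate_pedigree_genotypes(ped, cfg), cfg)
    return ped, {e.pair: e for e in kin_matrix(matrix)}


@pytest.mark.parametrize(
    "a, b, expected_norm, expected_degree",
    [
        ("P1", "P1copy", 0.5, "identical/twin"),
        ("P1", "TWIN1", 0.75, "first"),
        ("TWIN1", "TWIN2", 0.75, "first"),
        ("TWIN1", "HALF", 0.875, "second"),
        ("U0", "U1", 1.0, "unrelated"),
    ],
)
def test_norm_matches_one_minus_kinship(family_cohort, a, b, expected_norm, expected_degree):
    """E[norm] = 1 - phi under random-allele pseudohaploidization."""
    ped, est = family_cohort
    assert 1 - ped.kinship_coefficient(a, b) == pytest.approx(expected_norm)
    e = est[tuple(sorted((a, b)))]
    assert e.norm == pytest.approx(expected_norm, abs=0.02)
    assert e.degree == expected_degree


def test_network_contains_only_close_relatives(family_cohort):
    _, est = family_cohort
    net = build_network(est.values())
    assert net.has_edge("P1", "TWIN1")
    assert net.has_edge("TWIN1", "TWIN2")
    assert not net.has_edge("U0", "U1")
    assert not net.has_edge("P1", "P2")
    assert all(d["degree"] in ("identical/twin", "first", "second")
               for _, _, d in net.edges(data=True))


def test_trio_network_edges():
    ped = PedigreeSpec(
        founders=tuple(f"U{i}" for i in range(8)) + ("FATHER", "MOTHER"),
        matings=(("FATHER", "MOTHER", "CHILD"),),
    )
    cfg = SimulationConfig(n_sites=20_000, coverage=1.0, seed=17)
    matrix = pseudohaploidize(simulate_pedigree_genotypes(ped, cfg), cfg)
    net = build_network(kin_matrix(matrix))
    assert net.has_edge("FATHER", "CHILD")
    assert net.has_edge("MOTHER", "CHILD")
    assert not net.has_edge("FATHER", "MOTHER")


def test_zero_overlap_cohort_gives_empty_network():
    calls = np.array([[0, 2, 9, 9], [9, 9, 2, 0]], dtype=np.int8)
    est = kin_matrix(make_matrix(calls), min_overlap=1)
    assert all(e.degree == "insufficient" for e in est)
    assert build_network(est).number_of_edges() == 0


def test_symmetry_and_permutation_invariance():
    rng = np.random.default_rng(5)
    calls = rng.choice([0, 2, 9], size=(4, 2000)).astype(np.int8)
    m = make_matrix(calls)
    est = {e.pair: (e.pmr, e.norm, e.degree) for e in kin_matrix(m, min_overlap=100)}
    # permute samples and SNPs
    sperm = [2, 0, 3, 1]
    jperm = rng.permutation(2000)
    from paleokin.io_formats import PseudohaploidMatrix

    m2 = PseudohaploidMatrix(
        [m.samples[i] for i in sperm],
        [m.snps[j] for j in jperm],
        calls[np.ix_(sperm, jperm)],
    )
    est2 = {e.pair: (e.pmr, e.norm, e.degree) for e in kin_matrix(m2, min_overlap=100)}
    assert est == est2


def test_masking_half_the_calls_leaves_norm_unchanged():
    """Missingness shrinks overlap but not the expected normalized score."""
    ped = PedigreeSpec(
        founders=tuple(f"U{i}" for i in range(10)) + ("P1", "P2"),
        matings=(("P1", "P2", "KID"),),
    )
    diffs = []
    for seed in range(5):
        cfg = SimulationConfig(n_sites=50_000, coverage=1.0, seed=60 + seed)
        matrix = pseudohaploidize(simulate_pedigree_genotypes(ped, cfg), cfg)
        full = {e.pair: e for e in kin_matrix(matrix)}
        rng = np.random.default_rng(90 + seed)
        masked_calls = matrix.calls.copy()
        masked_calls[rng.random(masked_calls.shape) < 0.5] = 9
        from paleokin.io_formats import PseudohaploidMatrix

        masked = {
            e.pair: e
            for e in kin_matrix(PseudohaploidMatrix(matrix.samples, matrix.snps, masked_calls))
        }
        key = ("KID", "P1")
        assert masked[key].overlap < full[key].overlap * 0.6
        diffs.append(masked[key].norm - full[key].norm)
    assert abs(np.mean(diffs)) < 0.01


def test_damage_inflates_pmr_but_not_norm():
    """C->T damage raises raw mismatch rates in every pair, so the
    background absorbs it and the normalized score barely moves."""
    ped = PedigreeSpec(
        founders=tuple(f"U{i}" for i in range(10)) + ("P1", "P2"),
        matings=(("P1", "P2", "KID"),),
    )
    norm_shift, pmr_shift = [], []
    for seed in range(3):
        clean_cfg = SimulationConfig(n_sites=50_000, coverage=1.0, seed=70 + seed)
        dmg_cfg = SimulationConfig(n_sites=50_000, coverage=1.0, damage_rate=0.03, seed=70 + seed)
        diploid = simulate_pedigree_genotypes(ped, clean_cfg)
        clean = {e.pair: e for e in kin_matrix(pseudohaploidize(diploid, clean_cfg))}
        damaged = {e.pair: e for e in kin_matrix(pseudohaploidize(diploid, dmg_cfg))}
        key = ("KID", "P1")
        pmr_shift.append(damaged[key].pmr - clean[key].pmr)
        norm_shift.append(damaged[key].norm - clean[key].norm)
    assert np.mean(pmr_shift) > 0.003
    assert abs(np.mean(norm_shift)) < 0.02


def test_contaminated_background_warns():
    ped = PedigreeSpec(
        founders=("A", "B"),
        matings=(("A", "B", "C"),),
        duplicates=(("A", "A2"), ("B", "B2"), ("C", "C2")),
    )
    cfg = SimulationConfig(n_sites=5_000, coverage=1.0, seed=3)
    matrix = pseudohaploidize(simulate_pedigree_genotypes(ped, cfg), cfg)
    with pytest.warns(UserWarning, match="background"):
        kin_matrix(matrix)
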