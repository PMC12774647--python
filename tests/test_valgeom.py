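"""ProSco, Z', tier classification, support annotation, term enumeration."""

import numpy as np
import pytest

from ntckit.fixtures import (
    build_step_from_torsions,
    make_distribution_set,
    make_reference_distribution,
)
from ntckit.model import extract_na_chains
from ntckit.valgeom import (
    ReferenceDistribution,
    annotate_support,
    classify_tier,
    enumerate_terms,
    load_term_dictionary,
    nearest_reference_cases,
    prosco,
    prosco_interval,
    validate_chain,
    z_prime,
)


def _dist(values, csd_mean=None, csd_sigma=1.0, name="C5-N7"):
    values = np.asarray(values, dtype=float)
    return ReferenceDistribution(
        term_name=name,
        sample=values,
        case_ids=[f"CASE{i:04d}" for i in range(len(values))],
        csd_mean=float(np.mean(values)) if csd_mean is None else csd_mean,
        csd_sigma=csd_sigma,
    )


class TestProsco:
    def test_median_scores_100(self):
        d = _dist(np.linspace(0, 10, 101))
        assert prosco(float(np.median(d.sample)), d) == pytest.approx(100.0)

    def test_hazen_position_hand_computation(self):
        # sample 1..100, x=5: F = (5 - 0.5)/100 = 0.045 -> ProSco 9.0
        d = _dist(np.arange(1, 101))
        assert prosco(5.0, d) == pytest.approx(9.0)

    def test_zero_beyond_extremes(self):
        d = _dist(np.arange(1, 101))
        assert prosco(0.5, d) == 0.0
        assert prosco(101.0, d) == 0.0
        assert prosco(1.0, d) <= 1.0  # at the extreme order statistic

    def test_undersized_sample_rejected(self):
        d = _dist(np.arange(10))
        with pytest.raises(ValueError, match="too small"):
            prosco(1.0, d)

    def test_central_95_percent_on_large_normal_sample(self):
        rng = np.random.default_rng(7)
        d = _dist(rng.normal(size=100_000))
        frac = np.mean(prosco(d.sample, d) >= 5.0)
        assert frac * 100.0 == pytest.approx(95.0, abs=0.3)

    def test_monotone_away_from_median(self):
        rng = np.random.default_rng(3)
        d = _dist(np.sort(rng.normal(size=500)))
        med = float(np.median(d.sample))
        xs = med + np.linspace(0.0, 4.0, 40)
        scores = [prosco(x, d) for x in xs]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


class TestZPrime:
    def test_zero_at_median(self):
        d = _dist([1, 2, 3, 4, 5])
        assert z_prime(3.0, d) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # MAD of {1..5} is 1, so x = median + 2 * 1.4826 gives Z' = 2
        d = _dist([1, 2, 3, 4, 5])
        assert z_prime(3.0 + 2 * 1.4826, d) == pytest.approx(2.0)

    def test_constant_sample_rejected(self):
        d = _dist([2.0] * 30)
        with pytest.raises(ValueError, match="zero spread"):
            z_prime(2.5, d)


class TestTier:
    def test_csd_widens_preferred(self):
        # x sits in the far tail of the empirical sample (ProSco ~2) but
        # inside the wide CSD interval -> Preferred by the union rule
        rng = np.random.default_rng(11)
        d = _dist(np.sort(rng.normal(0.0, 1.0, size=2000)), csd_mean=0.0, csd_sigma=1.5)
        x = float(np.quantile(d.sample, 0.99))
        assert prosco(x, d) < 5.0
        assert x < 3 * 1.5
        assert classify_tier(x, d) == "Preferred"

    def test_outside_preferred_with_small_zprime_is_allowed(self):
        rng = np.random.default_rng(12)
        d = _dist(np.sort(rng.normal(0.0, 1.0, size=2000)), csd_mean=0.0, csd_sigma=0.5)
        lo, hi = prosco_interval(d)
        x = hi + 0.5  # beyond both boundaries but |Z'| ~ 2.5
        assert abs(z_prime(x, d)) <= 5.0
        assert classify_tier(x, d) == "Allowed"

    def test_extreme_value_of_concern(self):
        rng = np.random.default_rng(13)
        d = _dist(np.sort(rng.normal(0.0, 1.0, size=2000)), csd_mean=0.0, csd_sigma=0.5)
        x = 7.0
        assert abs(z_prime(x, d)) > 5.0
        assert classify_tier(x, d) == "OfConcern"

    def test_preferred_interval_contains_both_sources(self, rng):
        for _ in range(20):
            loc = rng.uniform(-2, 2)
            scale = rng.uniform(0.5, 2.0)
            d = _dist(np.sort(rng.normal(loc, scale, size=500)),
                      csd_mean=rng.uniform(-2, 2), csd_sigma=rng.uniform(0.2, 2.0))
            lo_p, hi_p = prosco_interval(d)
            lo_c = d.csd_mean - 3 * d.csd_sigma
            hi_c = d.csd_mean + 3 * d.csd_sigma
            for x in (lo_p, hi_p, lo_c, hi_c, (lo_p + hi_p) / 2, (lo_c + hi_c) / 2):
                assert classify_tier(x, d) == "Preferred"

    def test_tier_and_support_partition(self, rng):
        d = _dist(np.sort(rng.normal(size=300)))
        for x in rng.normal(0, 3, size=50):
            tier = classify_tier(float(x), d)
            assert tier in {"Preferred", "Allowed", "OfConcern"}
            sup = annotate_support(float(x), prosco(float(x), d), d, win=0.05)
            assert sup in {"Common", "Rare", "Ambiguous", "Unique"}


class TestSupport:
    def test_low_prosco_with_neighbours_is_rare(self):
        # the tail point has ProSco ~3.5 but several reference neighbours
        sample = np.sort(np.concatenate([
            np.linspace(1.34, 1.40, 97), [1.371, 1.3712, 1.3708],
        ]))
        d = _dist(sample, name="C5-N7")
        x = float(np.quantile(sample, 0.018))
        p = prosco(x, d)
        assert p < 5.0
        assert annotate_support(x, p, d, win=0.01) == "Rare"

    def test_central_value_is_common(self):
        d = _dist(np.linspace(1.3, 1.45, 100))
        x = 1.375
        assert annotate_support(x, prosco(x, d), d) == "Common"

    def test_isolated_value_is_unique(self):
        d = _dist(np.linspace(1.3, 1.45, 100))
        assert annotate_support(2.5, 0.0, d, win=0.01) == "Unique"

    def test_few_neighbours_is_ambiguous(self):
        sample = np.sort(np.concatenate([np.linspace(0, 1, 99), [5.0]]))
        d = _dist(sample)
        assert annotate_support(5.001, 0.5, d, win=0.01, k_min=3) == "Ambiguous"


class TestNearestCases:
    def test_exact_match_first(self):
        d = _dist([1.0, 2.0, 3.0])
        cases = nearest_reference_cases(2.0, d, 1)
        assert cases == [("CASE0001", 2.0)]

    def test_k_larger_than_sample(self):
        d = _dist([1.0, 2.0, 3.0])
        assert len(nearest_reference_cases(0.0, d, 10)) == 3

    def test_tie_broken_lexically(self):
        d = _dist([1.0, 3.0])  # both at distance 1 from x=2
        cases = nearest_reference_cases(2.0, d, 2)
        assert [c for c, _ in cases] == ["CASE0000", "CASE0001"]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            nearest_reference_cases(1.0, _dist([1, 2, 3]), 0)


class TestEnumerateTerms:
    def test_ideal_adenosine_counts_match_dictionary(self, oligo_factory):
        st = oligo_factory(["BB00"], sequence="AA")
        res = extract_na_chains(st)[0].residues[0]
        dictionary = load_term_dictionary()
        applicable = [t for t in dictionary
                      if t.applies_to in {"all", "ribose", "purine", "A"}]
        measured = enumerate_terms(res, dictionary)
        # 5'-terminal residue lacks the phosphate group (P, OP1, OP2)
        n_missing = sum(1 for t in applicable if any(
            res.atom(a) is None for a in t.atom_names))
        assert len(measured) == len(applicable) - n_missing
        res2 = extract_na_chains(st)[0].residues[1]
        measured2 = enumerate_terms(res2, dictionary)
        assert len(measured2) == len(applicable)

    def test_missing_atom_terms_skipped(self, oligo_factory):
        st = oligo_factory(["BB00"], sequence="AA")
        res = extract_na_chains(st)[0].residues[1]
        n_with_n7 = len(enumerate_terms(res))
        res.atoms = [a for a in res.atoms if a.name != "N7"]
        measured = enumerate_terms(res)
        names = {t.term_name for t, _ in measured}
        assert "C5-N7" not in names and "N7-C8" not in names
        assert len(measured) < n_with_n7

    def test_built_bond_value_measured_exactly(self, monkeypatch):
        # C5-N7 built at 1.371 A must be measured back as 1.371 A
        import ntckit.fixtures as fx

        monkeypatch.setitem(fx._IDEAL, ("bond", "C5-N7"), 1.371)
        _, step, _ = build_step_from_torsions(
            dict(d1=84, e1=-150, z1=-70, a2=-65, b2=170, g2=54, d2=84, ch1=-160, ch2=-160))
        terms = dict(
            (t.term_name, v) for t, v in enumerate_terms(step.residue_1))
        assert terms["C5-N7"] == pytest.approx(1.371, abs=1e-9)

    def test_linkage_terms_need_prev_residue(self, oligo_factory):
        st = oligo_factory(["BB00"], sequence="AA")
        chain = extract_na_chains(st)[0]
        r1, r2 = chain.residues
        without = {t.term_name for t, _ in enumerate_terms(r2)}
        with_prev = {t.term_name for t, _ in enumerate_terms(r2, prev_residue=r1)}
        assert with_prev - without == {"O3'-P", "C3'-O3'-P", "O3'-P-O5'"}


class TestValidateChain:
    def test_ideal_structure_all_preferred(self, oligo_factory):
        st = oligo_factory(["BB00", "BB01"], sequence="GAC")
        dists = make_distribution_set(st, n=200, seed=5)
        verdicts = validate_chain(extract_na_chains(st)[0], dists)
        assert verdicts
        assert all(v.tier == "Preferred" for v in verdicts)

    def test_single_stretched_bond_flagged(self, oligo_factory):
        st = oligo_factory(["BB00", "BB01"], sequence="GAC")
        dists = make_distribution_set(st, n=500, seed=5)
        chain = extract_na_chains(st)[0]
        # stretch the 3'-terminal O3' along its bond: only C3'-O3' changes
        # (the bond direction, hence the C4'-C3'-O3' angle, is preserved)
        res = chain.residues[-1]
        d = dists["C3'-O3'"]
        o3 = res.atom("O3'")
        c3 = res.pos("C3'")
        direction = (o3.position - c3) / np.linalg.norm(o3.position - c3)
        o3.position = c3 + (np.linalg.norm(o3.position - c3) + 12 * d.csd_sigma) * direction
        verdicts = validate_chain(chain, dists)
        concerns = [v for v in verdicts if v.tier == "OfConcern"]
        assert len(concerns) == 1
        assert concerns[0].term_name == "C3'-O3'" and concerns[0].term_type == "bond"
        assert concerns[0].nearest_cases  # inspection aid present

    def test_missing_distribution_skips_term(self, oligo_factory, caplog):
        st = oligo_factory(["BB00"], sequence="GA")
        dists = make_distribution_set(st, n=100, seed=1)
        dists.pop("C5'-C4'")
        with caplog.at_level("WARNING", logger="ntckit"):
            verdicts = validate_chain(extract_na_chains(st)[0], dists)
        assert all(v.term_name != "C5'-C4'" for v in verdicts)
        assert "C5'-C4'" in caplog.text


class TestDistributionFixtures:
    def test_seed_determinism(self):
        a = make_reference_distribution("C5-N7", params={"loc": 1.371, "scale": 0.01}, n=100, seed=9)
        b = make_reference_distribution("C5-N7", params={"loc": 1.371, "scale": 0.01}, n=100, seed=9)
        assert np.array_equal(a.sample, b.sample)

    def test_normal_sample_centered(self):
        d = make_reference_distribution("C5-N7", params={"loc": 1.371, "scale": 0.01}, n=1000, seed=0)
        assert float(np.median(d.sample)) == pytest.approx(1.371, abs=0.001)

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            make_reference_distribution("X", n=10)

    def test_mixture_far_from_csd(self):
        d = make_reference_distribution(
            "X", shape="mixture",
            params={"loc1": 0.0, "loc2": 6.0, "scale1": 0.3, "scale2": 0.3, "w1": 0.5},
            n=400, seed=2, csd_mean=20.0, csd_sigma=0.5,
        )
        lo, hi = prosco_interval(d)
        assert hi < 20.0 - 3 * 0.5  # disjoint sources, union test enabled
        assert classify_tier(19.0, d) in {"Preferred", "OfConcern", "Allowed"}
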