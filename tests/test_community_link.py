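"""Alpha-diversity estimators and ASV-MAG linking."""

import math

import numpy as np
import pandas as pd
import pytest

from pulgate import (
    AsvMagLink,
    CommunityMatrix,
    SimulationSpec,
    ValidationError,
    alpha_diversity_table,
    chao1,
    extend_links_via_ani,
    generate_community_fixture,
    goods_coverage,
    link_asv_to_mags,
    shannon,
    simpson,
    subsample_counts,
)

from _oracles import substring_scan


class TestDiversityClosedForms:
    def test_single_taxon_has_zero_entropy(self):
        assert shannon([0, 17, 0]) == pytest.approx(0.0)

    def test_uniform_four_taxa_is_ln4(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4), abs=1e-12)

    def test_shannon_base_is_configurable(self):
        assert shannon([1, 1, 1, 1], log_base=2) == pytest.approx(2.0)

    def test_simpson_single_taxon(self):
        assert simpson([9]) == pytest.approx(0.0)

    def test_simpson_two_equal_taxa(self):
        assert simpson([4, 4]) == pytest.approx(0.5)

    def test_simpson_dominance_form(self):
        assert simpson([4, 4], form="dominance") == pytest.approx(0.5)
        assert simpson([1, 3], form="dominance") == pytest.approx(10 / 16)

    def test_chao1_no_singletons_reduces_to_richness(self):
        assert chao1([5, 2, 8]) == pytest.approx(3.0)

    def test_chao1_bias_corrected_hand_value(self):
        # S_obs=3, F1=2, F2=1 -> 3 + 2*1/(2*2) = 3.5
        assert chao1([1, 1, 2]) == pytest.approx(3.5)

    def test_chao1_classic_form(self):
        # classic F1^2/(2 F2) = 4/2 = 2 -> 5
        assert chao1([1, 1, 2], bias_corrected=False) == pytest.approx(5.0)

    def test_goods_coverage_hand_values(self):
        assert goods_coverage([1, 1, 2]) == pytest.approx(0.5)
        assert goods_coverage([2, 3, 4]) == pytest.approx(1.0)


class TestDiversityProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_vectors_match_formula_oracles(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=rng.integers(3, 40))
        if counts.sum() == 0:
            counts[0] = 1
        c = counts[counts > 0].astype(float)
        p = c / c.sum()
        f1, f2 = int((c == 1).sum()), int((c == 2).sum())
        assert shannon(counts) == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
        assert simpson(counts) == pytest.approx(1 - (p**2).sum(), abs=1e-12)
        assert chao1(counts) == pytest.approx(
            len(c) + f1 * (f1 - 1) / (2 * (f2 + 1)), abs=1e-12
        )
        assert goods_coverage(counts) == pytest.approx(1 - f1 / c.sum(), abs=1e-12)

    def test_shannon_maximal_for_uniform_vector(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(1, 100, size=8)
            assert shannon(v) <= shannon([10] * 8) + 1e-12

    def test_shannon_permutation_invariant(self):
        assert shannon([3, 1, 7, 2]) == pytest.approx(shannon([7, 2, 3, 1]), abs=1e-15)

    def test_chao1_never_below_observed_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.integers(0, 10, size=20)
            if v.sum() == 0:
                v[0] = 1
            assert chao1(v) >= (v > 0).sum() - 1e-12

    def test_goods_increases_when_singletons_get_a_read(self):
        v = np.array([1, 1, 2, 5])
        bumped = np.array([2, 2, 2, 5])
        assert goods_coverage(bumped) > goods_coverage(v)
        assert goods_coverage(bumped) == pytest.approx(1.0)

    def test_all_zero_vector_rejected(self):
        for fn in (shannon, simpson, chao1, goods_coverage):
            with pytest.raises(ValidationError):
                fn([0, 0, 0])

    def test_chao1_requires_integer_counts(self):
        with pytest.raises(ValidationError):
            chao1([1.5, 2.0])

    def test_subsample_is_seeded_and_sums_to_n(self):
        v = [10, 20, 30, 40]
        a = subsample_counts(v, 50, seed=4)
        b = subsample_counts(v, 50, seed=4)
        assert a.sum() == 50 and (a == b).all() and (a <= np.array(v)).all()
        with pytest.raises(ValidationError):
            subsample_counts(v, 1000, seed=0)

    def test_alpha_diversity_table_per_sample(self):
        counts = pd.DataFrame(
            [[5, 5, 5, 5], [17, 0, 0, 0]], index=["s1", "s2"], columns=list("abcd")
        )
        m = CommunityMatrix(counts=counts, fractions={"s1": "FL", "s2": "PA3"})
        df = alpha_diversity_table(m)
        assert df.loc[df.sample_id == "s1", "shannon"].item() == pytest.approx(math.log(4))
        assert df.loc[df.sample_id == "s2", "shannon"].item() == pytest.approx(0.0)
        assert set(df.columns) == {"sample_id", "fraction", "shannon", "simpson", "chao1", "goods"}

    def test_community_matrix_validation(self):
        counts = pd.DataFrame([[1, -2]], index=["s1"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            CommunityMatrix(counts=counts, fractions={"s1": "FL"})
        ok = pd.DataFrame([[1, 2]], index=["s1"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            CommunityMatrix(counts=ok, fractions={"s1": "XL"})


class TestLinking:
    def test_asv_cut_from_16s_links(self):
        subject = "ACGT" * 200
        asv = subject[340:805]
        links = link_asv_to_mags({"asv1": asv}, {"magA": subject})
        assert links == [AsvMagLink("asv1", "magA", "EXACT_16S")]

    def test_one_substitution_breaks_the_link(self):
        rng = np.random.default_rng(0)
        subject = "".join(rng.choice(list("ACGT"), 1500))
        asv = list(subject[100:500])
        asv[200] = {"A": "C", "C": "A", "G": "T", "T": "G"}[asv[200]]
        assert link_asv_to_mags({"asv1": "".join(asv)}, {"magA": subject}) == []

    def test_reverse_complement_hit_links(self):
        rng = np.random.default_rng(1)
        subject = "".join(rng.choice(list("ACGT"), 1500))
        comp = str.maketrans("ACGT", "TGCA")
        asv = subject[200:600].translate(comp)[::-1]
        assert link_asv_to_mags({"asv1": asv}, {"magA": subject}) == [
            AsvMagLink("asv1", "magA", "EXACT_16S")
        ]

    def test_n_bases_never_match(self):
        subject = "ACGTNACGT" * 60
        asv = subject[0:18]  # contains an N, identical to the subject region
        assert "N" in asv
        assert link_asv_to_mags({"asv1": asv}, {"magA": subject}) == []

    def test_u_normalizes_to_t(self):
        subject = "ACGT" * 100
        asv = subject[10:110].replace("T", "U")
        assert len(link_asv_to_mags({"asv1": asv}, {"magA": subject})) == 1

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValidationError):
            link_asv_to_mags({"asv1": "ACGX"}, {"magA": "ACGT" * 100})

    def test_multi_copy_16s_any_copy_links(self):
        rng = np.random.default_rng(2)
        copy1 = "".join(rng.choice(list("ACGT"), 1500))
        copy2 = "".join(rng.choice(list("ACGT"), 1500))
        asv = copy2[50:450]
        links = link_asv_to_mags({"asv1": asv}, {"magA": [copy1, copy2]})
        assert [(l.asv_id, l.mag_id) for l in links] == [("asv1", "magA")]

    def test_planted_fixture_matches_bruteforce_scan(self):
        fx = generate_community_fixture(SimulationSpec(seed=5))
        links = link_asv_to_mags(fx.asv_sequences, fx.mag_16s_sequences)
        got = {(l.asv_id, l.mag_id) for l in links}
        assert got == set(fx.truth.exact_links)
        # independent naive scan over a subset (full scan is slow in Python)
        planted = dict(fx.truth.exact_links)
        for asv_id in list(planted)[:3]:
            assert substring_scan(
                fx.asv_sequences[asv_id], fx.mag_16s_sequences[planted[asv_id]]
            )
        decoys = [a for a in fx.asv_sequences if a.startswith("asv_decoy")][:3]
        for asv_id in decoys:
            for mag_seq in fx.mag_16s_sequences.values():
                assert not substring_scan(fx.asv_sequences[asv_id], mag_seq)

    def test_linking_invariant_to_global_reverse_complement(self):
        fx = generate_community_fixture(SimulationSpec(seed=6))
        comp = str.maketrans("ACGT", "TGCA")
        flipped = {
            m: s.translate(comp)[::-1] for m, s in fx.mag_16s_sequences.items()
        }
        a = link_asv_to_mags(fx.asv_sequences, fx.mag_16s_sequences)
        b = link_asv_to_mags(fx.asv_sequences, flipped)
        assert a == b


class TestAniExtension:
    def _links(self):
        return [AsvMagLink("asv1", "A", "EXACT_16S")]

    def test_exactly_95_is_inclusive(self):
        ani = pd.DataFrame([{"mag_a": "A", "mag_b": "B", "ani": 95.0}])
        out = extend_links_via_ani(self._links(), ani)
        assert AsvMagLink("asv1", "B", "ANI_EXTENSION", via_mag_id="A") in out

    def test_94_9_is_excluded(self):
        ani = pd.DataFrame([{"mag_a": "A", "mag_b": "B", "ani": 94.9}])
        assert extend_links_via_ani(self._links(), ani) == self._links()

    def test_extensions_do_not_chain(self):
        ani = pd.DataFrame(
            [
                {"mag_a": "A", "mag_b": "B", "ani": 96.0},
                {"mag_a": "B", "mag_b": "C", "ani": 96.0},
            ]
        )
        out = extend_links_via_ani(self._links(), ani)
        mags = {l.mag_id for l in out}
        assert mags == {"A", "B"}  # C is reachable only transitively

    def test_asymmetric_table_rejected(self):
        ani = pd.DataFrame(
            [
                {"mag_a": "A", "mag_b": "B", "ani": 96.0},
                {"mag_a": "B", "mag_b": "A", "ani": 90.0},
            ]
        )
        with pytest.raises(ValidationError):
            extend_links_via_ani(self._links(), ani)

    def test_symmetric_duplicate_rows_accepted(self):
        ani = pd.DataFrame(
            [
                {"mag_a": "A", "mag_b": "B", "ani": 96.0},
                {"mag_a": "B", "mag_b": "A", "ani": 96.0},
            ]
        )
        out = extend_links_via_ani(self._links(), ani)
        assert sum(l.evidence == "ANI_EXTENSION" for l in out) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_one_step_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mags = [f"m{i}" for i in range(8)]
        links = [
            AsvMagLink(f"asv{i}", str(rng.choice(mags)), "EXACT_16S")
            for i in range(5)
        ]
        rows = []
        for i in range(len(mags)):
            for j in range(i + 1, len(mags)):
                if rng.random() < 0.4:
                    rows.append(
                        {"mag_a": mags[i], "mag_b": mags[j],
                         "ani": float(rng.uniform(85, 100))}
                    )
        ani = pd.DataFrame(rows, columns=["mag_a", "mag_b", "ani"])
        out = extend_links_via_ani(links, ani)
        # oracle: direct one-step closure over the symmetric pair list
        expected = {(l.asv_id, l.mag_id) for l in links}
        for l in links:
            for r in rows:
                if r["ani"] < 95.0:
                    continue
                if r["mag_a"] == l.mag_id:
                    expected.add((l.asv_id, r["mag_b"]))
                elif r["mag_b"] == l.mag_id:
                    expected.add((l.asv_id, r["mag_a"]))
        assert {(l.asv_id, l.mag_id) for l in out} == expected
        for l in out:
            if l.evidence == "ANI_EXTENSION":
                assert l.via_mag_id is not None
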