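import numpy as np
import pytest

from dirpred.alignio import Alignment, ReferenceMap, build_reference_map
from dirpred.conservation import ConservationProfile
from dirpred.dirpred_core import (
    ComponentScores,
    combine,
    compute_components,
    cross_tables,
    ortholog_component,
    paralog_component,
    rank_sites,
)
from dirpred.exceptions import ConfigError


def make_profile(scores, flagged=None, method="identity"):
    scores = np.asarray(scores, dtype=float)
    if flagged is None:
        flagged = np.zeros(len(scores), dtype=bool)
    return ConservationProfile(scores, method, np.zeros(len(scores)), np.asarray(flagged))


def identity_map(ref_id, n):
    return ReferenceMap(ref_id, np.arange(n), "A" * n)


class TestOrthologComponent:
    def test_all_conserved(self):
        ref = make_profile([1.0] * 3)
        others = {"p2": make_profile([1.0] * 3)}
        m = identity_map("r", 3)
        assert np.allclose(ortholog_component(ref, m, others, m), 1.0)

    def test_arithmetic_mean_of_two(self):
        ref = make_profile([1.0])
        others = {"p2": make_profile([0.0])}
        m = identity_map("r", 1)
        assert ortholog_component(ref, m, others, m)[0] == 0.5

    def test_gapped_paralog_skipped(self):
        # 5-site fixture, hand-enumerated: paralog p3 flagged at sites 1, 4
        ref = make_profile([1.0, 0.8, 0.6, 0.4, 0.2])
        p2 = make_profile([0.5, 0.5, 0.5, 0.5, 0.5])
        p3 = make_profile(
            [0.0, 1.0, 1.0, 0.0, 1.0], flagged=[True, False, False, True, False]
        )
        m = identity_map("r", 5)
        out = ortholog_component(ref, m, {"p2": p2, "p3": p3}, m)
        expected = [
            (1.0 + 0.5) / 2,
            (0.8 + 0.5 + 1.0) / 3,
            (0.6 + 0.5 + 1.0) / 3,
            (0.4 + 0.5) / 2,
            (0.2 + 0.5 + 1.0) / 3,
        ]
        assert np.allclose(out, expected)

    def test_all_others_gapped_leaves_reference_alone(self):
        ref = make_profile([0.7])
        p2 = make_profile([0.1], flagged=[True])
        m = identity_map("r", 1)
        assert ortholog_component(ref, m, {"p2": p2}, m)[0] == 0.7


class TestParalogComponent:
    def test_complement_identity(self):
        prof = make_profile([1.0, 0.25, 0.0])
        m = identity_map("r", 3)
        x, II = paralog_component(prof, m)
        assert np.allclose(II, [0.0, 0.75, 1.0])
        assert np.allclose(x + II, 1.0)


def make_components(I, II, III, IV, msta=None):
    n = len(I)
    return ComponentScores(
        ref_position=np.arange(1, n + 1),
        ref_residue=["A"] * n,
        I=np.asarray(I, float),
        II_msa=np.asarray(II, float),
        III=np.asarray(III, float),
        IV=np.asarray(IV, float),
        x_paralog_msa=1.0 - np.asarray(II, float),
        II_msta=None if msta is None else np.asarray(msta, float),
        x_paralog_msta=None if msta is None else 1.0 - np.asarray(msta, float),
    )


class TestCombine:
    def test_unit_weights_sum(self):
        c = make_components([1], [1], [1], [1])
        assert combine(c).total_msa[0] == 4.0

    def test_single_component_weight(self):
        c = make_components([0.3], [0.4], [0.5], [0.6])
        r = combine(c, (0, 0, 0, 1))
        assert r.total_msa[0] == 0.6

    def test_arithmetic(self):
        c = make_components([0.5], [0.25], [0.5], [0.75])
        assert combine(c).total_msa[0] == 2.0

    def test_negative_weight_rejected(self):
        c = make_components([1], [1], [1], [1])
        with pytest.raises(ConfigError):
            combine(c, (1, -1, 1, 1))
        with pytest.raises(ConfigError):
            combine(c, (0, 0, 0, 0))

    def test_exact_additivity(self):
        rng = np.random.default_rng(7)
        c = make_components(*(rng.random(20) for _ in range(4)))
        w = (0.5, 1.5, 2.0, 0.25)
        r = combine(c, w)
        recomputed = w[0] * c.I + w[1] * c.II_msa + w[2] * c.III + w[3] * c.IV
        assert np.array_equal(r.total_msa, recomputed)

    def test_msta_totals_when_present(self):
        c = make_components([0.5], [0.2], [0.1], [0.3], msta=[0.9])
        r = combine(c)
        assert r.total_msta[0] == pytest.approx(0.5 + 0.9 + 0.1 + 0.3)


class TestRanking:
    def test_descending_rank(self):
        c = make_components([0, 0, 0], [0, 0, 0], [0, 0, 0], [0.75, 1.0, 0.5])
        r = combine(c)
        assert list(r.rank_msa) == [2, 1, 3]

    def test_tie_broken_by_position(self):
        c = make_components([0, 0], [0, 0], [0, 0], [0.5, 0.5])
        r = combine(c)
        assert list(r.rank_msa) == [1, 2]

    def test_single_site(self):
        c = make_components([1], [1], [1], [1])
        assert combine(c).rank_msa[0] == 1

    def test_rank_is_permutation(self):
        rng = np.random.default_rng(3)
        c = make_components(*(rng.random(30) for _ in range(4)))
        r = rank_sites(combine(c))
        assert sorted(r.rank_msa) == list(range(1, 31))


class TestCrossTables:
    def test_points_and_row_counts(self):
        c = make_components([1.0, 0.5], [0.0, 0.2], [0.8, 0.1], [0.3, 0.9])
        cons, coev = cross_tables(c)
        assert len(cons) == len(coev) == 2
        assert cons["ortholog_conservation"][0] == 1.0
        assert cons["paralog_conservation_msa"][0] == 1.0
        assert coev["ligand_receptor_coevolution"][0] == 0.8
        assert coev["ligand_ligand_coevolution"][0] == pytest.approx(0.7)


class TestComputeComponents:
    def test_components_in_unit_interval(self, small_system):
        s = small_system
        c = compute_components(
            s.master, s.ortholog_msas, s.ref_ids, s.ref_paralog, s.receptor,
            msta=s.msta,
        )
        for arr in (c.I, c.II_msa, c.II_msta, c.III, c.IV):
            assert (arr >= 0).all() and (arr <= 1).all()
        assert c.n_sites == s.master.row(s.ref_id).replace("-", "").__len__()

    def test_msta_identical_to_msa_gives_identical_totals(self, small_system):
        s = small_system
        c = compute_components(
            s.master, s.ortholog_msas, s.ref_ids, s.ref_paralog, s.receptor,
            msta=s.msta,
        )
        r = combine(c)
        assert np.array_equal(r.total_msa, r.total_msta)
        assert np.array_equal(r.rank_msa, r.rank_msta)

    def test_receptor_required(self, small_system):
        s = small_system
        with pytest.raises(ConfigError):
            compute_components(
                s.master, s.ortholog_msas, s.ref_ids, s.ref_paralog, None
            )
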