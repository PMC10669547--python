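"""Corpus statistics: summary tables, CI bands, PCA, KDE, mutant placement."""

import numpy as np
import pytest
from scipy import integrate, stats

from pkalens.ensemble import (
    kde_state,
    pca_profiles,
    place_mutant,
    state_profile,
    summarize,
)
from pkalens.metrics import DistanceRecord
from tests.conftest import make_profiles


def _records(values, state="apo", pair_slot=0, triplet="lobe_closure"):
    """DistanceRecords with given d12 values (other slots missing)."""
    recs = []
    for i, v in enumerate(values):
        slots = {"d12": None, "d13": None, "d23": None}
        slots[("d12", "d13", "d23")[pair_slot]] = v
        recs.append(
            DistanceRecord(
                structure_id=f"S{i:03d}", chain_id="A", triplet_name=triplet,
                state=state, **slots,
            )
        )
    return recs


class TestSummarize:
    def test_order_statistic_oracle(self):
        table = summarize(_records([1.0, 2.0, 3.0, 4.0, 5.0]))
        row = table.iloc[0]
        assert row["median"] == 3.0 and row["q1"] == 2.0 and row["q3"] == 4.0
        assert row["n"] == 5.0
        assert row["average"] == pytest.approx(3.0)
        assert row["std_dev"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))

    def test_singleton_collapses_to_value(self):
        row = summarize(_records([7.3])).iloc[0]
        for col in ("average", "median", "min_value", "q1", "q2", "q3", "max_value"):
            assert row[col] == pytest.approx(7.3)
        assert row["std_dev"] == 0.0 and row["n"] == 1.0

    def test_per_pair_n_differs_with_missingness(self):
        """Missing values drop per pair, as in real apo blocks with unresolved residues."""
        recs = []
        for i in range(9):
            recs.append(
                DistanceRecord(
                    structure_id=f"S{i}", chain_id="A", triplet_name="ctail_gloop",
                    state="apo",
                    d12=None if i < 3 else 10.0 + i,  # 328-52 unresolved in 3 structures
                    d13=None if i < 3 else 11.0 + i,
                    d23=12.0 + i,
                )
            )
        table = summarize(recs)
        n = table["n"].droplevel(["state", "triplet"])
        assert n["328CA-52CA"] == 6.0
        assert n["52CA-127CA"] == 9.0

    def test_ordering_invariants_on_generated_blocks(self, small_corpus):
        from pkalens import pipeline

        states = small_corpus["truth"]
        records = pipeline.corpus_distances(small_corpus["models"], states)
        table = summarize(records)
        assert (table["min_value"] <= table["q1"] + 1e-12).all()
        assert (table["q1"] <= table["q2"] + 1e-12).all()
        assert (table["q2"] <= table["q3"] + 1e-12).all()
        assert (table["q3"] <= table["max_value"] + 1e-12).all()
        assert (table["q2"] == table["median"]).all()

    def test_planted_apo_shift_recovered(self, small_corpus):
        """The +4 A T51-A223 apo displacement appears in the state means."""
        from pkalens import pipeline

        records = pipeline.corpus_distances(
            small_corpus["models"], small_corpus["truth"]
        )
        table = summarize(records)
        col = table.xs(("lobe_closure", "51CA-223CA"), level=["triplet", "pair"])
        shift = col.loc["apo", "average"] - col.loc["substrate_product", "average"]
        assert shift == pytest.approx(4.0, abs=0.6)


class TestStateProfile:
    def test_identical_profiles_zero_width_ci(self):
        base = np.tile(np.linspace(-1, 1, 30), (5, 1))
        band = state_profile(make_profiles(base), seed=0)
        assert np.allclose(band["ci_low"], band["mean"])
        assert np.allclose(band["ci_high"], band["mean"])

    def test_bootstrap_ci_close_to_t_interval(self):
        """Gaussian profiles, n=30: bootstrap width within 25% of the t width."""
        rng = np.random.default_rng(8)
        sigma, n = 0.5, 30
        matrix = rng.normal(0.0, sigma, size=(n, 12))
        band = state_profile(make_profiles(matrix), seed=1, n_boot=2000)
        widths = band["ci_high"] - band["ci_low"]
        for j, width in enumerate(widths):
            sd = matrix[:, j].std(ddof=1)
            t_width = 2 * stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            assert abs(width - t_width) / t_width < 0.25

    def test_same_seed_bit_reproducible(self):
        rng = np.random.default_rng(2)
        matrix = rng.normal(size=(10, 8))
        a = state_profile(make_profiles(matrix), seed=42)
        b = state_profile(make_profiles(matrix), seed=42)
        assert a.equals(b)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        big = rng.normal(size=(80, 5))
        small = big[:20]
        w_small = (lambda b: (b["ci_high"] - b["ci_low"]).mean())(
            state_profile(make_profiles(small), seed=0)
        )
        w_big = (lambda b: (b["ci_high"] - b["ci_low"]).mean())(
            state_profile(make_profiles(big), seed=0)
        )
        assert w_big < w_small

    def test_sparse_residue_keeps_mean_drops_ci(self):
        profiles = make_profiles(np.ones((3, 4)))
        # residue 99 appears in a single profile
        extra = make_profiles(np.array([[2.0]]), structure_ids=["SX"], residue_seqs=[99])
        band = state_profile(profiles + extra, seed=0)
        row = band.xs(99, level="residue_seq").iloc[0]
        assert row["mean"] == 2.0 and np.isnan(row["ci_low"])

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            state_profile(make_profiles(np.ones((1, 4))))


class TestPCAProfiles:
    def test_identical_profiles_no_variance(self):
        prof = make_profiles(np.tile(np.linspace(0, 1, 20), (6, 1)))
        model = pca_profiles(prof)
        assert np.allclose(model.explained_variance, 0.0)

    def test_planted_block_concentrates_pc1(self):
        """A 10-residue block differing between two groups dominates PC1."""
        rng = np.random.default_rng(17)
        n, p = 30, 100
        matrix = rng.normal(0.0, 0.25, size=(n, p))
        block = slice(45, 55)
        matrix[: n // 2, block] += 1.0
        model = pca_profiles(make_profiles(matrix))
        load = model.loadings[0]
        mass = (load[block] ** 2).sum() / (load**2).sum()
        assert mass > 0.8
        pc1 = model.scores[:, 0]
        g1, g2 = pc1[: n // 2], pc1[n // 2:]
        # groups separate cleanly along PC1 (no overlap between score ranges)
        assert g1.min() > g2.max() or g2.min() > g1.max()

    def test_loadings_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(23)
        matrix = rng.normal(size=(12, 15))
        prof = make_profiles(matrix)
        model = pca_profiles(prof, n_components=11)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-10)
        centered = matrix - matrix.mean(axis=0)
        np.testing.assert_allclose(model.scores @ model.loadings, centered, atol=1e-8)

    def test_explained_variance_fractions_monotone_and_bounded(self):
        rng = np.random.default_rng(29)
        model = pca_profiles(make_profiles(rng.normal(size=(20, 30))))
        ev = model.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1.0 + 1e-9

    def test_scores_centered(self):
        rng = np.random.default_rng(31)
        model = pca_profiles(make_profiles(rng.normal(size=(10, 8))))
        np.testing.assert_allclose(model.scores.sum(axis=0), 0.0, atol=1e-9)

    def test_first_profile_per_structure_wins(self):
        a = make_profiles(np.zeros((3, 5)), structure_ids=["X", "Y", "Z"])
        dup = make_profiles(np.ones((1, 5)), structure_ids=["X"])
        model = pca_profiles(a + dup)
        assert model.structure_ids == ["X", "Y", "Z"]

    def test_empty_intersection_is_instructive_error(self):
        a = make_profiles(np.zeros((2, 4)), structure_ids=["A1", "A2"],
                          residue_seqs=[1, 2, 3, 4])
        b = make_profiles(np.zeros((2, 4)), structure_ids=["B1", "B2"],
                          residue_seqs=[10, 11, 12, 13])
        with pytest.raises(ValueError, match="residue"):
            pca_profiles(a + b)


class TestKDE:
    def test_density_integrates_to_one(self):
        model = kde_state([19.0, 21.0])
        total, _ = integrate.quad(lambda x: model.evaluate(x)[0], *model.support)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_mode_recovery(self):
        rng = np.random.default_rng(101)
        model = kde_state(rng.normal(20.0, 1.0, size=500))
        assert abs(model.peak() - 20.0) < 0.2

    def test_negative_support_tail_vanishes(self):
        rng = np.random.default_rng(7)
        model = kde_state(rng.normal(20.0, 1.0, size=100))
        assert model.evaluate(-1.0)[0] < 1e-12

    def test_requires_two_distinct_values(self):
        with pytest.raises(ValueError):
            kde_state([5.0, 5.0, 5.0])

    def test_deterministic_given_data(self):
        data = [18.0, 19.5, 20.1, 21.7]
        assert kde_state(data).peak() == kde_state(data).peak()


class TestPlaceMutant:
    def _densities(self):
        rng = np.random.default_rng(55)
        return {
            "inhibitor": kde_state(rng.normal(21.0, 0.3, 300), state="inhibitor"),
            "substrate_product": kde_state(
                rng.normal(19.0, 0.3, 300), state="substrate_product"
            ),
        }

    def test_value_at_peak_maps_to_that_state(self):
        dens = self._densities()
        peak = dens["inhibitor"].peak()
        placement = place_mutant(peak, dens)
        assert placement.nearest_peak_state == "inhibitor"

    def test_two_state_peak_distance_oracle(self):
        """Peaks near 19 and 21; a 20.9 A distance belongs to the 21 A state."""
        placement = place_mutant(20.9, self._densities())
        assert placement.nearest_peak_state == "inhibitor"
        assert set(placement.density_per_state) == {"inhibitor", "substrate_product"}

    def test_missing_distance_returns_none(self):
        assert place_mutant(None, self._densities()) is None

    def test_requires_two_states(self):
        dens = self._densities()
        with pytest.raises(ValueError):
            place_mutant(20.0, {"inhibitor": dens["inhibitor"]})
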