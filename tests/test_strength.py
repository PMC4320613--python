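"""Maximum-entropy acceptor-strength model: closed forms, exhaustive
normalization, separation on planted data, and group comparison."""

import itertools

import numpy as np
import pytest

from repa.strength import (ConvergenceError, MaxEntAcceptorStrength,
                           StrengthResults, compare_groups,
                           train_strength_model)

ALL4 = ["".join(p) for p in itertools.product("ACGT", repeat=4)]


def _random_seqs(rng, n, L):
    return ["".join("ACGT"[i] for i in rng.integers(0, 4, L)) for _ in range(n)]


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(42)


class TestClosedForms:
    def test_singleton_fit_is_product_of_marginals(self, rng):
        """With singleton constraints the maximum-entropy distribution
        factorizes; verified over all 4^4 sequences."""
        seqs = _random_seqs(rng, 60, 4)
        res = train_strength_model(seqs, seqs, "singletons", window_spec=(4, 0))
        probs = np.exp(res.log_prob(ALL4, "signal"))
        # independent oracle: smoothed per-position counts
        marg = np.zeros((4, 4))
        for i in range(4):
            for j, b in enumerate("ACGT"):
                marg[i, j] = (sum(s[i] == b for s in seqs) + 0.5) / (len(seqs) + 2)
        expected = [
            np.prod([marg[i, "ACGT".index(b)] for i, b in enumerate(s)])
            for s in ALL4
        ]
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    @pytest.mark.parametrize("constraints", ["singletons", "adjacent_pairs"])
    def test_exhaustive_normalization(self, rng, constraints):
        seqs = _random_seqs(rng, 80, 4)
        dec = _random_seqs(rng, 80, 4)
        res = train_strength_model(seqs, dec, constraints, window_spec=(4, 0))
        for which in ("signal", "background"):
            total = np.exp(res.log_prob(ALL4, which)).sum()
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_normalization_length6_pairs(self, rng):
        all6 = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
        seqs = _random_seqs(rng, 100, 6)
        res = train_strength_model(seqs, seqs, "adjacent_pairs", window_spec=(6, 0))
        assert np.exp(res.log_prob(all6, "signal")).sum() == pytest.approx(
            1.0, abs=1e-6
        )

    def test_pair_marginals_reproduced(self, rng):
        """Every constrained marginal matches its empirical target."""
        seqs = _random_seqs(rng, 70, 5)
        all5 = ["".join(p) for p in itertools.product("ACGT", repeat=5)]
        res = train_strength_model(seqs, seqs, "adjacent_pairs", window_spec=(5, 0))
        probs = np.exp(res.log_prob(all5, "signal"))
        for edge in range(4):
            model = np.zeros((4, 4))
            emp = np.zeros((4, 4))
            for s, p in zip(all5, probs):
                model["ACGT".index(s[edge]), "ACGT".index(s[edge + 1])] += p
            for s in seqs:
                emp["ACGT".index(s[edge]), "ACGT".index(s[edge + 1])] += 1
            emp = (emp + 0.5) / (len(seqs) + 8)
            assert np.abs(model - emp).max() < 1e-3


class TestScoring:
    def test_identical_training_sets_score_zero(self, rng):
        seqs = _random_seqs(rng, 50, 4)
        res = train_strength_model(seqs, seqs, window_spec=(4, 0))
        assert np.abs(res.score_many(ALL4)).max() == 0.0

    def test_indistinguishable_classes_center_on_zero(self, rng):
        sig = _random_seqs(rng, 2000, 8)
        dec = _random_seqs(rng, 2000, 8)
        res = train_strength_model(sig, dec, window_spec=(8, 0))
        fresh = _random_seqs(rng, 2000, 8)
        assert abs(res.score_many(fresh).mean()) < 0.2

    def test_wrong_length_and_n_rejected(self, rng):
        res = train_strength_model(_random_seqs(rng, 30, 4),
                                   _random_seqs(rng, 30, 4), window_spec=(4, 0))
        with pytest.raises(ValueError):
            res.score("ACGTA")
        with pytest.raises(ValueError):
            res.score("ACNT")

    def test_min_training_size_at_full_window(self, rng):
        small = _random_seqs(rng, 50, 23)
        with pytest.raises(ValueError, match="200"):
            MaxEntAcceptorStrength(small, small)

    def test_nonuniform_lengths_rejected(self):
        with pytest.raises(ValueError):
            MaxEntAcceptorStrength(["ACGT", "ACG"], ["ACGT", "ACGT"])

    def test_json_roundtrip(self, rng, tmp_path):
        res = train_strength_model(_random_seqs(rng, 40, 4),
                                   _random_seqs(rng, 40, 4), window_spec=(4, 0))
        p = tmp_path / "model.json"
        res.to_json(p)
        loaded = StrengthResults.from_json(p)
        np.testing.assert_allclose(loaded.score_many(ALL4), res.score_many(ALL4))

    def test_summary_mentions_training_sizes(self, rng):
        res = train_strength_model(_random_seqs(rng, 40, 4),
                                   _random_seqs(rng, 41, 4), window_spec=(4, 0))
        text = res.summary()
        assert "40 signal" in text and "41 decoy" in text


class TestPlantedSeparation:
    def test_constitutive_scores_higher(self, trained):
        res, const, repa = trained
        assert res.score_many(const).mean() > res.score_many(repa).mean()

    def test_g_run_insertion_lowers_score(self, trained):
        """Planting a G pentamer at -10..-6 of a pyrimidine-rich window
        strictly lowers its strength."""
        res, const, _ = trained
        for w in const[:25]:
            mutated = w[:10] + "GGGGG" + w[15:]  # intron positions -10..-6
            assert res.score(mutated) < res.score(w)


class TestCompareGroups:
    def test_identical_samples(self):
        df = compare_groups({"ref": [1, 2, 3], "same": [1, 2, 3]})
        row = df.set_index("group").loc["same"]
        assert row.t_vs_reference == pytest.approx(0.0)
        assert row.p_vs_reference == pytest.approx(1.0)

    def test_shifted_samples_vs_permutation_oracle(self):
        """Classic equal-variance t on {1,2,3} vs {11,12,13}: the
        observed |t| tops the exact 20-split permutation distribution."""
        import itertools as it

        from scipy import stats as sps

        x, y = [1, 2, 3], [11, 12, 13]
        df = compare_groups({"ref": x, "shift": y})
        row = df.set_index("group").loc["shift"]
        pooled = x + y
        tstats = []
        for idx in it.combinations(range(6), 3):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(6) if i not in idx]
            tstats.append(abs(sps.ttest_ind(a, b, equal_var=True).statistic))
        assert len(tstats) == 20
        n_extreme = sum(t >= abs(row.t_vs_reference) - 1e-12 for t in tstats)
        assert n_extreme == 2  # only the two perfectly separated splits
        assert row.p_vs_reference < 0.01

    def test_degenerate_groups_flagged(self):
        df = compare_groups({"ref": [1.0, 2.0], "tiny": [5.0]})
        assert bool(df.set_index("group").loc["tiny"].degenerate)

    def test_synthetic_group_ordering(self, big_genome):
        """Purine-rich G-pentamer sites score below pyrimidine-rich
        sites under a model trained on the same generator output."""
        from repa.annotation import derive_introns, extract_windows
        from repa.scan import scan_windows

        windows, _ = extract_windows(big_genome.genome,
                                     derive_introns(big_genome.models))
        truth = big_genome.truth.set_index("site_id")
        known = [w for w in windows
                 if w.site_id in truth.index and len(w.window) == 23]
        const = [w for w in known if not truth.loc[w.site_id].is_repa]
        repa = [w for w in known if truth.loc[w.site_id].is_repa]
        res = train_strength_model([w.window for w in const],
                                   [w.window for w in repa])
        calls = {c.site_id: c for c in scan_windows(known)}
        ggggg = [w.window for w in repa
                 if calls[w.site_id].group_label == "ggggg"]
        scores = {
            "constitutive": res.score_many([w.window for w in const]),
            "ggggg": res.score_many(ggggg),
        }
        df = compare_groups(scores).set_index("group")
        assert df.loc["constitutive", "mean"] > df.loc["ggggg", "mean"]
        assert df.loc["ggggg", "p_vs_reference"] < 0.05
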