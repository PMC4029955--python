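"""Copying-model painting: posterior correctness, assignment, region test."""

import numpy as np
import pandas as pd
import pytest

from _oracles import copying_posterior_brute_force
from coldscan.core import population_index
from coldscan.painting import (
    UNDECIDED,
    assign_ancestry,
    copying_probabilities,
    estimate_rho_em,
    region_ancestry_test,
    select_donors,
)
from coldscan.sim import AdmixtureSpec, SimConfig, simulate_panel


class TestSelectDonors:
    Q = pd.DataFrame(
        {"SIB": [0.995, 0.95, 0.999], "EUR": [0.005, 0.05, 0.001]},
        index=["a", "b", "c"],
    )

    def test_high_q_included(self):
        donors = select_donors(self.Q, {"a": "SIB", "b": "SIB", "c": "SIB"})
        assert "a" in donors["SIB"] and "c" in donors["SIB"]

    def test_low_q_excluded(self):
        donors = select_donors(self.Q, {"a": "SIB", "b": "SIB", "c": "SIB"})
        assert "b" not in donors["SIB"]

    def test_conflicting_cluster_excluded(self):
        donors = select_donors(self.Q, {"a": "EUR", "c": "SIB"})
        assert donors["SIB"] == ["c"]


class TestCopyingProbabilities:
    @pytest.mark.parametrize("n_snps,n_donors", [(2, 2), (5, 4), (8, 6), (8, 3)])
    def test_matches_path_enumeration(self, n_snps, n_donors, rng):
        donors = rng.integers(0, 2, (n_snps, n_donors)).astype(np.uint8)
        rec = rng.integers(0, 2, n_snps).astype(np.uint8)
        gmap = np.sort(rng.random(n_snps)) * 2
        pops = [f"P{j % 2}" for j in range(n_donors)]
        rho, theta = 1.5, 0.05
        bf = copying_posterior_brute_force(rec, donors, gmap, rho, theta)
        table, _ = copying_probabilities(rec, donors, pops, gmap, rho, theta)
        for pop in table.columns:
            cols = [j for j, p in enumerate(pops) if p == pop]
            np.testing.assert_allclose(
                table[pop].to_numpy(), bf[:, cols].sum(axis=1), atol=1e-9
            )

    def test_probabilities_sum_to_one(self, rng):
        donors = rng.integers(0, 2, (50, 10)).astype(np.uint8)
        rec = rng.integers(0, 2, 50).astype(np.uint8)
        gmap = np.linspace(0, 1, 50)
        table, _ = copying_probabilities(
            rec, donors, ["A"] * 5 + ["B"] * 5, gmap
        )
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_donor_dominates(self, rng):
        n = 10
        rec = rng.integers(0, 2, n).astype(np.uint8)
        donors = np.column_stack([rec] + [1 - rec] * 5).astype(np.uint8)
        gmap = np.linspace(0, 0.5, n)
        table, _ = copying_probabilities(
            rec, donors, ["self"] + ["other"] * 5, gmap, rho=1.0, theta=0.01
        )
        assert (table["self"] > 0.99).all()

    def test_invariant_to_donor_order(self, rng):
        donors = rng.integers(0, 2, (30, 6)).astype(np.uint8)
        rec = rng.integers(0, 2, 30).astype(np.uint8)
        gmap = np.linspace(0, 1, 30)
        pops = ["A", "A", "A", "B", "B", "B"]
        t1, _ = copying_probabilities(rec, donors, pops, gmap)
        perm = [2, 0, 1, 5, 3, 4]
        t2, _ = copying_probabilities(
            rec, donors[:, perm], [pops[j] for j in perm], gmap
        )
        np.testing.assert_allclose(t1["A"], t2["A"], atol=1e-12)

    def test_zero_donors_rejected(self):
        with pytest.raises(ValueError, match="donor"):
            copying_probabilities(
                np.array([0, 1], np.uint8),
                np.empty((2, 0), np.uint8),
                [],
                np.array([0.0, 0.1]),
            )

    def test_negative_distance_rejected(self, rng):
        donors = rng.integers(0, 2, (3, 2)).astype(np.uint8)
        with pytest.raises(ValueError, match="non-decreasing"):
            copying_probabilities(
                np.array([0, 1, 0], np.uint8), donors, ["A", "A"],
                np.array([0.0, 0.5, 0.2]),
            )


class TestAssignAncestry:
    def _table(self, rows, cols=("P1", "P2", "P3")):
        return pd.DataFrame(rows, columns=list(cols)[: len(rows[0])])

    def test_clear_majority_assigned(self):
        out = assign_ancestry(self._table([[0.8, 0.15, 0.05]]))
        assert out.iloc[0] == "P1"

    def test_below_threshold_undecided(self):
        out = assign_ancestry(self._table([[0.6, 0.4, 0.0]]))
        assert out.iloc[0] == UNDECIDED

    def test_exact_threshold_undecided(self):
        # strictly-greater rule: 0.7 exactly is undecided
        out = assign_ancestry(self._table([[0.7, 0.3]], cols=("P1", "P2")))
        assert out.iloc[0] == UNDECIDED


class TestEstimateRho:
    def _model_data(self, rng, rho_true, T=5000, nD=8, theta=0.02, n_rec=3):
        gmap = np.cumsum(rng.exponential(0.002, T))
        gmap -= gmap[0]
        donors = rng.integers(0, 2, (T, nD)).astype(np.uint8)
        d = np.diff(gmap)
        r = 1 - np.exp(-rho_true * d)

        def gen():
            state = rng.integers(nD)
            rec = np.empty(T, np.uint8)
            rec[0] = donors[0, state] ^ (rng.random() < theta)
            for t in range(1, T):
                if rng.random() < r[t - 1]:
                    state = rng.integers(nD)
                rec[t] = donors[t, state] ^ (rng.random() < theta)
            return rec

        recs = np.column_stack([gen() for _ in range(n_rec)])
        return recs, donors, gmap, theta

    def test_likelihood_nondecreasing(self, rng):
        recs, donors, gmap, theta = self._model_data(rng, 2.0, T=800)
        _, lls = estimate_rho_em(recs, donors, gmap, rho_init=0.3,
                                 theta=theta, n_steps=10)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_recovers_rho_within_factor_two(self, rng):
        recs, donors, gmap, theta = self._model_data(rng, 2.0, T=5000)
        rho, _ = estimate_rho_em(recs, donors, gmap, rho_init=0.5,
                                 theta=theta, n_steps=10)
        assert 1.0 <= rho <= 4.0

    def test_zero_steps_returns_initial(self, rng):
        recs, donors, gmap, theta = self._model_data(rng, 2.0, T=200)
        rho, lls = estimate_rho_em(recs, donors, gmap, rho_init=0.77,
                                   theta=theta, n_steps=0)
        assert rho == 0.77 and lls == []


class TestRegionTest:
    def test_max_region_smallest_p(self):
        pos = np.arange(1, 1001) * 10_000  # 10 Mb, 10 regions of 1 Mb
        prob = np.full(1000, 0.5)
        prob[200:300] = 0.95  # third 1-Mb region elevated
        obs, p, tail = region_ancestry_test(
            prob, pos, (2_000_000, 3_000_000), chrom_length_bp=10_000_000
        )
        assert obs == pytest.approx(0.95)
        assert p == pytest.approx(1 / 10)

    def test_constant_probability_all_tie(self):
        pos = np.arange(1, 501) * 10_000
        prob = np.ones(500)
        obs, p, tail = region_ancestry_test(
            prob, pos, (1_000_000, 2_000_000), chrom_length_bp=5_000_000
        )
        assert p == 1.0 and tail == 1.0

    def test_uniform_genome_mid_rank(self, rng):
        pos = np.arange(1, 10_001) * 1000
        prob = rng.random(10_000)
        ps = []
        for start in range(0, 10_000_000, 1_000_000):
            _, p, _ = region_ancestry_test(
                prob, pos, (start, start + 1_000_000),
                chrom_length_bp=10_000_000,
            )
            ps.append(p)
        assert np.mean(ps) == pytest.approx(0.55, abs=0.1)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="no SNPs"):
            region_ancestry_test(np.ones(10), np.arange(1, 11) * 100,
                                 (5_000, 6_000))


class TestMosaicRecovery:
    def test_accuracy_on_known_tracts(self):
        cfg = SimConfig(n_pops=2, samples_per_pop=15, n_snps=3000,
                        drift_F=(0.2, 0.2), copying_smoothing=False, seed=7,
                        admixture=AdmixtureSpec(("POP1", "POP2"), 0.5, 5.0, 3))
        panel, _, labels, truth, _ = simulate_panel(cfg)
        g = panel.variants["gmap_cM"].to_numpy()
        pos = panel.variants["pos_bp"].to_numpy()
        donor_cols, donor_pops = [], []
        for pop in ("POP1", "POP2"):
            idx = population_index(labels, panel.sample_ids, pop)
            for h in panel.haplotype_index_for_samples(
                [panel.sample_ids[i] for i in idx]
            ):
                donor_cols.append(h)
                donor_pops.append(pop)
        donor_alleles = panel.alleles[:, donor_cols]
        accuracies, undecided_fracs = [], []
        for hap_id, tracts in list(truth.admixture_tracts.items())[:4]:
            col = panel.haplotype_ids.index(hap_id)
            probs, _ = copying_probabilities(
                panel.alleles[:, col], donor_alleles, donor_pops, g, rho=1.0
            )
            assignment = assign_ancestry(probs).to_numpy()
            true_donor = np.empty(len(pos), dtype=object)
            for s, e, d in tracts:
                true_donor[(pos >= s) & (pos < e)] = d
            decided = assignment != UNDECIDED
            accuracies.append((assignment[decided] == true_donor[decided]).mean())
            undecided_fracs.append(1 - decided.mean())
        assert np.mean(accuracies) >= 0.90
        assert np.mean(undecided_fracs) < 0.5
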