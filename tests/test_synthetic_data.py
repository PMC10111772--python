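"""Forward Wright-Fisher simulator and pedigree inbreeding: determinism,
drift calibration, selection invariants, ancestry tracking, and Wright's F_p
against an independent tabular-method oracle."""

import numpy as np
import pandas as pd
import pytest

from founderpop import diversity as dv
from founderpop import roh as rh
from founderpop import synthetic_data as sd


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex",
                                       "generation", "population"])


class TestPedigreeInbreeding:
    def test_offspring_of_unrelated_parents(self):
        ped = _ped([(1, 0, 0, "M", 0, "p"), (2, 0, 0, "F", 0, "p"),
                    (3, 1, 2, "M", 1, "p")])
        assert sd.pedigree_inbreeding(ped, 3) == 0.0

    def test_full_sib_offspring(self):
        ped = _ped([(1, 0, 0, "M", 0, "p"), (2, 0, 0, "F", 0, "p"),
                    (3, 1, 2, "M", 1, "p"), (4, 1, 2, "F", 1, "p"),
                    (5, 3, 4, "M", 2, "p")])
        assert sd.pedigree_inbreeding(ped, 5) == 0.25

    def test_parent_offspring_mating(self):
        ped = _ped([(1, 0, 0, "M", 0, "p"), (2, 0, 0, "F", 0, "p"),
                    (3, 1, 2, "F", 1, "p"), (4, 1, 3, "M", 2, "p")])
        assert sd.pedigree_inbreeding(ped, 4) == 0.25

    def test_four_generation_pedigree_matches_tabular_oracle(self):
        # sustained sib/backcross mating over 4 generations
        rows = [(1, 0, 0, "M", 0, "p"), (2, 0, 0, "F", 0, "p"),
                (3, 1, 2, "M", 1, "p"), (4, 1, 2, "F", 1, "p"),
                (5, 3, 4, "M", 2, "p"), (6, 3, 4, "F", 2, "p"),
                (7, 5, 6, "M", 3, "p"), (8, 5, 4, "F", 3, "p"),
                (9, 7, 8, "M", 4, "p")]
        ped = _ped(rows)

        # independent oracle: additive-relationship (tabular) method
        ids = [r[0] for r in rows]
        parents = {r[0]: (r[1], r[2]) for r in rows}
        idx = {i: k for k, i in enumerate(ids)}
        a = np.zeros((len(ids), len(ids)))
        for i in ids:  # ids are in generation order
            s, d = parents[i]
            ii = idx[i]
            for j in ids:
                if j == i:
                    break
                jj = idx[j]
                val = 0.0
                if s:
                    val += 0.5 * a[idx[s], jj]
                if d:
                    val += 0.5 * a[idx[d], jj]
                a[ii, jj] = a[jj, ii] = val
            f = 0.5 * a[idx[s], idx[d]] if s and d else 0.0
            a[ii, ii] = 1.0 + f
        for i in ids:
            expected = a[idx[i], idx[i]] - 1.0
            assert sd.pedigree_inbreeding(ped, i) == pytest.approx(expected,
                                                                   abs=1e-12)

    def test_cyclic_pedigree_rejected(self):
        ped = _ped([(1, 2, 3, "M", 0, "p"), (2, 1, 3, "F", 0, "p"),
                    (3, 0, 0, "F", 0, "p")])
        with pytest.raises(ValueError, match="cyclic"):
            sd.pedigree_inbreeding(ped, 1)


class TestSimulator:
    def test_deterministic_given_seed(self):
        cfg = sd.neutral_single_population_config(seed=5, n_diploid=20,
                                                  chromosome_length=20_000,
                                                  n_generations=4)
        a, b = sd.simulate(cfg), sd.simulate(cfg)
        np.testing.assert_array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        pd.testing.assert_frame_equal(a.pedigree, b.pedigree)
        pd.testing.assert_frame_equal(a.truth.sites, b.truth.sites)

    def test_recessive_lethal_homozygotes_absent_in_adults(self):
        cfg = sd.SimulationConfig(
            populations=(sd.PopulationConfig("pop", {0: 20}),),
            n_generations=6, chromosome_lengths=(3_000_000,),
            init_theta=1e-4,
            impact_classes=(sd.ImpactClass("HIGH", 0.5, 1.0, 0.0),),
            mutation_rate=1e-8, seed=3)
        res = sd.simulate(cfg)
        cats = res.truth.sites["category"].to_numpy()
        samples = [s for s in res.genotypes.samples if s.startswith("pop")]
        g = res.genotypes.genotypes[res.genotypes.sample_indices(samples)]
        assert (g[:, cats == "HIGH"] != 2).all()

    def test_drift_variance_matches_wright_fisher_rate(self):
        """Across sites, Var[p_t - p_0] ~ p0(1-p0)(1 - (1-1/2N)^(t+1)) where
        the +1 counts the binomial draw of the founding generation."""
        deltas, expected = [], []
        for seed in range(6):
            cfg = sd.SimulationConfig(
                populations=(sd.PopulationConfig("pop", {0: 50}),),
                n_generations=3, chromosome_lengths=(20_000_000,),
                init_theta=2e-4, impact_classes=(), mutation_rate=0.0,
                seed=seed)
            res = sd.simulate(cfg)
            p0 = res.truth.sites["p_init"].to_numpy()
            samples = [s for s in res.genotypes.samples if s.startswith("pop")]
            pt = res.genotypes.allele_frequency(samples)
            ok = np.isfinite(p0)
            deltas.append(((pt - p0)[ok]) ** 2)
            expected.append(p0[ok] * (1 - p0[ok]))
        factor = 1.0 - (1.0 - 1.0 / 100.0) ** 4
        observed = np.concatenate(deltas).mean()
        predicted = factor * np.concatenate(expected).mean()
        assert observed == pytest.approx(predicted, rel=0.15)

    def test_pulse_ancestry_fraction_recovers_f(self):
        f = 0.3
        fracs = []
        for seed in range(6):
            res = sd.simulate(sd.founder_captive_config(
                seed=seed, pulse_fraction=f, n_generations=10))
            ind = res.truth.individuals
            sub = ind[ind["population"] == "lineage1"]
            fracs.append(sub["ancestry_donor"].mean())
        assert np.mean(fracs) == pytest.approx(f, abs=0.1)
        res0 = sd.simulate(sd.founder_captive_config(seed=0, n_generations=10))
        unadmixed = res0.truth.individuals
        assert (unadmixed.loc[unadmixed["population"] == "lineage1",
                              "ancestry_donor"] == 0).all()

    def test_ancestry_fractions_sum_to_one(self, founder_run):
        ind = founder_run.truth.individuals
        anc = ind[[c for c in ind.columns if c.startswith("ancestry_")]]
        ingroup = ind["population"] != "outgroup"
        np.testing.assert_allclose(anc[ingroup].sum(axis=1), 1.0, atol=1e-12)

    def test_founder_event_inflates_long_roh(self):
        """Paired comparison: lineages founded by 6 animals then grown carry
        more long (>1 Mb) ROH than lineages founded without a bottleneck."""

        def total_long_roh(founded):
            total = 0
            for seed in (0, 1, 2):
                base = sd.founder_captive_config(seed=seed, n_generations=14)
                if not founded:
                    pops = tuple(
                        p if p.source is None else sd.PopulationConfig(
                            p.name, {min(p.sizes): 20, max(p.sizes): 20},
                            source=p.source)
                        for p in base.populations)
                    base = sd.SimulationConfig(
                        populations=pops, n_generations=base.n_generations,
                        chromosome_lengths=base.chromosome_lengths,
                        init_theta=base.init_theta,
                        impact_classes=base.impact_classes,
                        mutation_rate=base.mutation_rate, seed=seed)
                res = sd.simulate(base)
                samples = res.population_spec.samples_in("lineage1")[:5]
                seg = rh.detect_roh_all(res.genotypes, samples=samples)
                total += seg.loc[seg["length"] > 1_000_000, "length"].sum()
            return total

        assert total_long_roh(True) > total_long_roh(False)

    def test_extinction_reported(self):
        cfg = sd.SimulationConfig(
            populations=(sd.PopulationConfig("pop", {0: 30}),),
            n_generations=3, chromosome_lengths=(2_000_000,),
            init_theta=5e-3,  # enormous standing lethal load
            impact_classes=(sd.ImpactClass("HIGH", 1.0, 1.0, 0.5),),
            mutation_rate=0.0, seed=0)
        with pytest.raises(sd.SimulationFailure):
            sd.simulate(cfg)

    def test_founder_preset_respects_sex_counts(self, founder_run):
        """Each captive lineage descends from exactly 1 wild sire and at most
        2 wild dams (the 1M+2F founder draw)."""
        ped = founder_run.pedigree
        sex_of = dict(zip(ped["id"], ped["sex"]))
        for lineage in ("lineage1", "lineage2"):
            rows = ped[ped["population"] == lineage]
            first = rows[rows["generation"] == rows["generation"].min()]
            sires, dams = set(first["sire"]), set(first["dam"])
            assert len(sires) == 1 and len(dams) <= 2
            assert all(sex_of[s] == "M" for s in sires)
            assert all(sex_of[d] == "F" for d in dams)


class TestNeutralCalibration:
    def test_equilibrium_pi_matches_theta_and_msprime(self):
        """Mean pairwise diversity matches the coalescent expectation
        theta = 4*N*mu, cross-checked against an independent coalescent
        simulator at the same parameters."""
        import msprime

        theta, n, L = 0.002, 50, 50_000
        fwd = []
        for seed in range(15):
            res = sd.simulate(sd.neutral_single_population_config(
                seed=seed, n_diploid=n, theta=theta, chromosome_length=L))
            samples = [s for s in res.genotypes.samples if s.startswith("pop")]
            fwd.append(dv.mean_pi(res.genotypes, samples))
        coal = []
        for seed in range(15):
            ts = msprime.sim_ancestry(samples=n, population_size=n,
                                      sequence_length=L,
                                      recombination_rate=1e-8,
                                      random_seed=seed + 1)
            ts = msprime.sim_mutations(ts, rate=theta / (4 * n),
                                       random_seed=seed + 1)
            coal.append(ts.diversity())
        assert np.mean(fwd) == pytest.approx(theta, rel=0.15)
        assert np.mean(fwd) == pytest.approx(np.mean(coal), rel=0.15)


class TestUnlinkedSampler:
    def test_truth_frequencies_match_sampled_genotypes(self):
        pops = [sd.DriftPop("anc", None, 0.0, 0),
                sd.DriftPop("P1", "anc", 0.05, 30)]
        gm, spec, truth = sd.simulate_unlinked(pops, 3000, seed=2)
        obs = gm.allele_frequency(spec.samples_in("P1"))
        resid = obs - truth["P1"].to_numpy()
        assert abs(resid.mean()) < 0.005
        assert np.corrcoef(obs, truth["P1"])[0, 1] > 0.95

    def test_admixture_mixes_frequencies_linearly(self):
        f = 0.25
        pops = [sd.DriftPop("anc", None, 0.0, 0),
                sd.DriftPop("donor", "anc", 0.2, 0),
                sd.DriftPop("target", "anc", 0.0, 0,
                            admixture=("donor", f))]
        _, _, truth = sd.simulate_unlinked(pops, 20_000, seed=3)
        expected = (1 - f) * truth["anc"] + f * truth["donor"]
        np.testing.assert_allclose(truth["target"], expected, atol=1e-12)

    def test_deterministic(self):
        pops = [sd.DriftPop("anc", None, 0.0, 2)]
        a = sd.simulate_unlinked(pops, 500, seed=9)[0]
        b = sd.simulate_unlinked(pops, 500, seed=9)[0]
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
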