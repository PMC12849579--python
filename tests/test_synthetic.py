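import numpy as np
import pytest

from qpmsi import SimulationConfig, compute_grm, simulate_dataset, standardize_and_adjust
from qpmsi.errors import InvalidConfig, NonPSDCorrelation
from qpmsi.synthetic import simulate_markers, simulate_traits


def _corr(p0, rho):
    C = np.full((p0, p0), rho)
    np.fill_diagonal(C, 1.0)
    return C


class TestConfigValidation:
    def test_rejects_non_psd_correlation(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(NonPSDCorrelation):
            SimulationConfig(trait_corr=C)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_families=0), dict(p_markers=0),
         dict(allele_freq_range=(0.0, 0.5)), dict(h2=(2.0, 0.5, 0.5, 0.5))],
    )
    def test_rejects_invalid_settings(self, kwargs):
        with pytest.raises(InvalidConfig):
            SimulationConfig(**kwargs)


class TestSimulateMarkers:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_families=3, family_size=4, p_markers=50, seed=11)
        m1, f1 = simulate_markers(cfg)
        m2, f2 = simulate_markers(cfg)
        np.testing.assert_array_equal(m1.dosages, m2.dosages)
        assert f1 == f2
        m3, _ = simulate_markers(
            SimulationConfig(n_families=3, family_size=4, p_markers=50, seed=12)
        )
        assert not np.array_equal(m1.dosages, m3.dosages)

    def test_valid_dosage_range_and_no_monomorphic(self):
        cfg = SimulationConfig(n_families=4, family_size=5, p_markers=200, seed=2)
        m, _ = simulate_markers(cfg)
        assert m.dosages.min() >= 0 and m.dosages.max() <= 2
        assert (m.dosages.std(axis=0) > 0).all()

    def test_family_blocks_elevate_within_relatedness(self):
        # 5 families x 10 sibs, 500 markers: within-family mean off-diagonal
        # G exceeds between-family mean in nearly all replicates
        wins = 0
        reps = 20
        for seed in range(reps):
            cfg = SimulationConfig(
                n_families=5, family_size=10, p_markers=500, seed=seed
            )
            m, fam = simulate_markers(cfg)
            G = compute_grm(m).G
            fam = np.array(fam)
            same = np.equal.outer(fam, fam)
            off = ~np.eye(len(fam), dtype=bool)
            if G[same & off].mean() > G[~same].mean():
                wins += 1
        assert wins == reps

    def test_singleton_families_have_no_block_structure(self):
        cfg = SimulationConfig(n_families=30, family_size=1, p_markers=300, seed=5)
        m, fam = simulate_markers(cfg)
        assert len(set(fam)) == 30
        G = compute_grm(m).G
        off = G[~np.eye(30, dtype=bool)]
        assert abs(off.mean()) < 0.1  # unrelated individuals hover near zero


class TestSimulateTraits:
    def test_identity_correlation_recovered(self):
        cfg = SimulationConfig(
            n_families=100, family_size=5, p_markers=1500,
            trait_corr=np.eye(3), h2=(1.0, 1.0, 1.0), seed=3,
        )
        ds = simulate_dataset(cfg)
        C = np.corrcoef(ds.traits.values.T)
        assert np.abs(C[np.triu_indices(3, k=1)]).max() < 0.1

    def test_strong_correlation_recovered(self):
        cfg = SimulationConfig(
            n_families=100, family_size=5, p_markers=1500,
            trait_corr=_corr(2, 0.8), h2=(1.0, 1.0), seed=4,
        )
        ds = simulate_dataset(cfg)
        r = np.corrcoef(ds.traits.values.T)[0, 1]
        assert r == pytest.approx(0.8, abs=0.1)

    def test_direction_flag_inverts_polarity(self):
        base = SimulationConfig(
            n_families=20, family_size=5, p_markers=200,
            trait_corr=np.eye(1), h2=(1.0,), seed=6,
        )
        flipped = SimulationConfig(
            n_families=20, family_size=5, p_markers=200,
            trait_corr=np.eye(1), h2=(1.0,),
            directions=("lower_is_better",), seed=6,
        )
        t_hi = simulate_dataset(base).traits
        t_lo = simulate_dataset(flipped).traits
        # same underlying signal, opposite raw polarity
        r = np.corrcoef(t_hi.values[:, 0], t_lo.values[:, 0])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_h2_zero_traits_independent_of_genome(self):
        # permutation test: with pure-noise traits, genotype merit should not
        # predict relatedness structure
        non_sig = 0
        reps = 20
        for seed in range(reps):
            cfg_r = SimulationConfig(
                n_families=10, family_size=10, p_markers=300,
                trait_corr=np.eye(1), h2=(0.0,), seed=seed,
            )
            ds = simulate_dataset(cfg_r)
            fam = np.array(ds.true_family)
            vals = ds.traits.values[:, 0]
            # between-family variance of family means vs permutation null
            obs = np.var([vals[fam == f].mean() for f in np.unique(fam)])
            rng = np.random.default_rng(seed)
            null = []
            for _ in range(200):
                perm = rng.permutation(vals)
                null.append(np.var([perm[fam == f].mean() for f in np.unique(fam)]))
            p = (np.sum(np.asarray(null) >= obs) + 1) / 201
            if p > 0.05:
                non_sig += 1
        assert non_sig >= 0.9 * reps - 2  # alpha = 0.05 false-positive slack

    def test_pipeline_compatibility(self):
        # generated data passes standardization and GRM construction cleanly
        cfg = SimulationConfig(n_families=4, family_size=6, p_markers=150, seed=8)
        ds = simulate_dataset(cfg)
        y = standardize_and_adjust(ds.traits)
        G = compute_grm(ds.markers)
        np.testing.assert_allclose(y.y.mean(axis=0), 0, atol=1e-9)
        assert np.linalg.eigvalsh(G.G)[0] >= -1e-8

    def test_trait_values_deterministic_given_seed(self):
        cfg = SimulationConfig(n_families=3, family_size=4, p_markers=60, seed=9)
        m, _ = simulate_markers(cfg)
        t1 = simulate_traits(m, cfg)
        t2 = simulate_traits(m, cfg)
        np.testing.assert_array_equal(t1.values, t2.values)
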