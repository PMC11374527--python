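"""pcVPC, NPDE and goodness-of-fit tables: calibration and detection power."""

import dataclasses

import numpy as np
import pytest

from vedopk.data import apply_exclusions
from vedopk.diagnostics import gof_tables, npde, pc_vpc
from vedopk.model import VarianceComponents
from vedopk.trial import PopulationSpec, generate_population, simulate_trial


def _doubled_cl(params):
    return dataclasses.replace(
        params,
        theta=dataclasses.replace(params.theta, cl_ref=2 * params.theta.cl_ref),
    )


def _doubled_sigma(params):
    return dataclasses.replace(
        params,
        variance=dataclasses.replace(
            params.variance, sigma_prop=2 * params.variance.sigma_prop
        ),
    )


class TestVpc:
    def test_self_consistency_under_true_model(self, medium_dataset, truth):
        """Simulating and checking with the same model keeps the observed
        median inside the simulated median band in nearly all bins."""
        res = pc_vpc(medium_dataset, truth, n_rep=300, bins=8, seed=61)
        assert res.coverage("p50") >= 0.75  # single-seed smoke bound
        assert res.band_lower["p50"].le(res.band_upper["p50"]).all()

    def test_identity_correction_when_predictions_equal(self, truth):
        """If every prediction in a bin is identical the correction is 1."""
        from vedopk.data import TrialDataset

        pop = generate_population(
            PopulationSpec(n_vedo_1015=0, n_vedo_3035=30, dropout_fraction=0.0),
            seed=62,
        )
        ds, _ = apply_exclusions(simulate_trial(pop, truth, seed=63))
        # identical covariates and a single shared sampling time: every
        # observation in the (single) bin has the same population prediction
        df = ds.df.copy()
        df[["WT", "ALB", "AGE", "LYM"]] = [75.0, 4.0, 53.0, 0.1]
        df[["GVHDL", "GVHDS", "GVHDI"]] = 0
        first_obs = df[df["EVID"] == 0].groupby("ID").head(1).index
        df = df[(df["EVID"] == 1) | df.index.isin(first_obs)]
        ds = TrialDataset(df.reset_index(drop=True))
        raw = pc_vpc(ds, truth, n_rep=40, bins=1, seed=64,
                     prediction_corrected=False)
        pc = pc_vpc(ds, truth, n_rep=40, bins=1, seed=64)
        assert np.allclose(pc.observed["p50"], raw.observed["p50"], rtol=1e-9)
        assert np.allclose(
            pc.band_upper["p95"], raw.band_upper["p95"], rtol=1e-9
        )

    def test_detects_doubled_clearance(self, truth):
        """VPC against a model with doubled CL: the observed median exceeds
        the simulated median band in late bins in >= 8/10 seeds."""
        hits = 0
        for seed in range(10):
            pop = generate_population(
                PopulationSpec(n_vedo_1015=5, n_vedo_3035=25), seed=70 + seed
            )
            ds, _ = apply_exclusions(simulate_trial(pop, truth, seed=80 + seed))
            res = pc_vpc(ds, _doubled_cl(truth), n_rep=100, bins=6, seed=90 + seed)
            late = res.observed["p50"].to_numpy()[-3:] > \
                res.band_upper["p50"].to_numpy()[-3:]
            hits += bool(late.any())
        assert hits >= 8

    def test_bands_widen_with_cl_variance(self, truth):
        """Pointwise simulated band width grows with omega_CL (3 points)."""
        pop = generate_population(
            PopulationSpec(n_vedo_1015=0, n_vedo_3035=30, dropout_fraction=0.0),
            seed=65,
        )
        ds, _ = apply_exclusions(simulate_trial(pop, truth, seed=66))
        widths = []
        for w2 in (0.02, 0.0827, 0.3):
            om = truth.variance.omega.copy()
            scale = np.sqrt(w2 / om[0, 0])
            om[0, :] *= scale
            om[:, 0] *= scale
            var = dataclasses.replace(truth.variance, omega=om)
            params = dataclasses.replace(truth, variance=var)
            res = pc_vpc(ds, params, n_rep=150, bins=6, seed=67)
            widths.append(
                float(np.mean(res.band_upper["p50"] - res.band_lower["p50"]))
            )
        assert widths[0] < widths[1] < widths[2]

    def test_small_bins_are_merged(self, medium_dataset, truth):
        res = pc_vpc(medium_dataset, truth, n_rep=20, bins=40, seed=68,
                     min_bin_size=60)
        assert res.n_per_bin.min() >= 60
        assert len(res.merged_bins) > 0

    def test_rejects_single_replicate(self, medium_dataset, truth):
        with pytest.raises(ValueError):
            pc_vpc(medium_dataset, truth, n_rep=1)


class TestNpde:
    def test_calibrated_under_true_model(self, medium_dataset, truth):
        res = npde(medium_dataset, truth, n_rep=600, seed=71)
        assert abs(res.mean) < 0.12
        assert 0.8 < res.variance < 1.2

    def test_invariant_to_row_order(self, truth):
        """Shuffling subject blocks leaves each observation's NPDE unchanged."""
        from vedopk.data import TrialDataset

        pop = generate_population(
            PopulationSpec(n_vedo_1015=3, n_vedo_3035=10), seed=72
        )
        ds, _ = apply_exclusions(simulate_trial(pop, truth, seed=73))
        a = npde(ds, truth, n_rep=200, seed=74)
        ids = ds.df["ID"].unique()[::-1]
        shuffled = TrialDataset(
            ds.df.set_index("ID").loc[ids].reset_index()[ds.df.columns]
        )
        b = npde(shuffled, truth, n_rep=200, seed=74)
        am = a.table.set_index(["ID", "TIME"])["npde"].sort_index()
        bm = b.table.set_index(["ID", "TIME"])["npde"].sort_index()
        assert np.allclose(am.to_numpy(), bm.to_numpy())

    def test_two_seeds_highly_correlated(self, truth):
        pop = generate_population(
            PopulationSpec(n_vedo_1015=3, n_vedo_3035=12), seed=75
        )
        ds, _ = apply_exclusions(simulate_trial(pop, truth, seed=76))
        a = npde(ds, truth, n_rep=1500, seed=77)
        b = npde(ds, truth, n_rep=1500, seed=78)
        r = np.corrcoef(a.values, b.values)[0, 1]
        assert r > 0.95

    def test_detects_doubled_sigma(self, truth):
        """Data with doubled residual noise against the nominal model gives
        NPDE variance above 1 in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            pop = generate_population(
                PopulationSpec(n_vedo_1015=4, n_vedo_3035=16), seed=100 + seed
            )
            ds, _ = apply_exclusions(
                simulate_trial(pop, _doubled_sigma(truth), seed=110 + seed)
            )
            res = npde(ds, truth, n_rep=300, seed=120 + seed)
            hits += res.variance > 1.0
        assert hits >= 9

    def test_rejects_too_few_replicates(self, medium_dataset, truth):
        with pytest.raises(ValueError):
            npde(medium_dataset, truth, n_rep=50)


class TestGofTables:
    def test_perfect_fit_observed_equals_ipred(self, truth):
        """With sigma -> 0 the individual predictions reproduce the data."""
        var = VarianceComponents(
            omega=truth.variance.omega, omega_iov_cl=truth.variance.omega_iov_cl,
            sigma_prop=1e-10,
        )
        gen = dataclasses.replace(truth, variance=var)
        pop = generate_population(
            PopulationSpec(n_vedo_1015=2, n_vedo_3035=6), seed=81
        )
        ds, _ = apply_exclusions(simulate_trial(pop, gen, seed=82))
        tables = gof_tables(ds, gen)
        obs = tables["observations"]
        assert np.allclose(obs["DV"], obs["IPRED"], rtol=1e-4)

    def test_schema_covers_every_retained_observation(
        self, medium_dataset, truth
    ):
        tables = gof_tables(medium_dataset, truth)
        obs = tables["observations"]
        assert len(obs) == medium_dataset.n_observations
        assert {"ID", "TIME", "TAD", "DV", "PRED", "IPRED", "RES",
                "IWRES"} <= set(obs.columns)
        ebes = tables["ebes"]
        assert {"eta_cl", "eta_vc", "eta_vp", "WT", "ALB", "GVHDS"} <= set(
            ebes.columns
        )

    def test_null_gvhd_effect_leaves_group_means_close(self, truth):
        """Simulated with all GvHD factors at 1, the EBE-vs-GvHD contrast
        shows no systematic difference (means within 0.25 SD)."""
        pop = generate_population(
            PopulationSpec(n_vedo_1015=10, n_vedo_3035=110), seed=83
        )
        ds, _ = apply_exclusions(simulate_trial(pop, truth, seed=84))
        ebes = gof_tables(ds, truth)["ebes"]
        with_gvhd = ebes[ebes["GVHDS"] == 1]["eta_cl"]
        without = ebes[ebes["GVHDS"] == 0]["eta_cl"]
        assert len(with_gvhd) > 10
        pooled_sd = ebes["eta_cl"].std()
        assert abs(with_gvhd.mean() - without.mean()) < 0.25 * pooled_sd
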