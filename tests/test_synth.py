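"""Synthetic cohort generator: determinism, calibration, parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from eestoich.core import ConfigError, Region, RunConfig
from eestoich.drivers import ols, pearson
from eestoich.io import records_to_frame
from eestoich.stoichiometry import cohort_summary
from eestoich.synth import (
    DRIVER_COVARIATES,
    GeneratorConfig,
    generate_cohort,
    generate_communities,
    write_fixture,
)
from eestoich.vectors import limitation_table


def test_default_cohort_shape(default_cohort):
    assert len(default_cohort) == 30
    assert sum(r.region == Region.SXK for r in default_cohort) == 10
    assert len({r.sample_id for r in default_cohort}) == 30


def test_same_seed_identical_cohort():
    a = records_to_frame(generate_cohort(GeneratorConfig(seed=7)))
    b = records_to_frame(generate_cohort(GeneratorConfig(seed=7)))
    pd.testing.assert_frame_equal(a, b)


def test_all_positive_quantities(default_cohort):
    for r in default_cohort:
        assert min(r.enzymes.as_array()) > 0
        for k, v in {**r.water, **r.sediment}.items():
            if k in ("ph", "temp_c"):
                continue
            assert v > 0, (r.sample_id, k)


def test_regional_enzyme_contrasts(default_cohort):
    """BG runs ~3× higher and AP ~4× lower in the small basin, by design."""
    cfg = GeneratorConfig(seed=2, n_sxk=3000, n_lxk=6000)
    rec = generate_cohort(cfg)
    bg = {reg: np.mean([r.enzymes.bg for r in rec if r.region == reg])
          for reg in Region}
    ap = {reg: np.mean([r.enzymes.ap for r in rec if r.region == reg])
          for reg in Region}
    assert bg[Region.SXK] / bg[Region.LXK] == pytest.approx(3.0, rel=0.15)
    assert ap[Region.SXK] / ap[Region.LXK] == pytest.approx(0.25, rel=0.15)


def test_infeasible_stoichiometry_target_rejected():
    with pytest.raises(ConfigError):
        GeneratorConfig(target_cnp=(1.0, -0.5, 1.5))


def test_planted_betas_recovered_by_regression():
    """Regressing log BG on the standardised log covariates in a large
    cohort recovers every planted coefficient within 2 standard errors."""
    cfg = GeneratorConfig(seed=3, n_sxk=2000, n_lxk=4000)
    rec = generate_cohort(cfg)
    std = cfg.standardisation()
    raw = {
        "depth": np.array([r.water["depth_m"] for r in rec]),
        "tds": np.array([r.water["tds_mg_l"] for r in rec]),
        "cond": np.array([r.water["conductivity"] for r in rec]),
        "tc": np.array([r.sediment["tc_g_kg"] for r in rec]),
    }
    X = pd.DataFrame({
        c: (np.log(raw[c]) - std[c][0]) / std[c][1] for c in DRIVER_COVARIATES
    })
    X["sxk"] = [1.0 if r.region == Region.SXK else 0.0 for r in rec]
    y = np.log([r.enzymes.bg for r in rec])
    fit = ols(y, X)
    import statsmodels.api as sm

    ref = sm.OLS(y, sm.add_constant(X)).fit()
    for i, c in enumerate(DRIVER_COVARIATES):
        planted = cfg.betas["bg"][i]
        assert abs(fit.coefficients[c] - planted) < 2 * ref.bse[c]


def test_null_betas_decouple_limitation_from_covariates():
    """With all effect coefficients zeroed (and neutral regional multipliers,
    since a regional enzyme contrast couples VL to any region-structured
    covariate), corr(VL, depth) is centred on 0 across replicate cohorts."""
    enzymes = ("bg", "cbh", "nag", "lap", "ap")
    zero = {e: (0.0, 0.0, 0.0, 0.0) for e in enzymes}
    flat = {e: 1.0 for e in enzymes}
    rs = []
    for seed in range(100):
        cfg = GeneratorConfig(seed=seed, betas=dict(zero), region_mean_ratio=dict(flat))
        rec = generate_cohort(cfg)
        vec = limitation_table(rec, RunConfig(seed=seed))
        depth = [r.water["depth_m"] for r in rec]
        rs.append(pearson(depth, vec["length"])[0])
    assert abs(np.mean(rs)) < 0.08


class TestCommunities:
    def test_phylum_means_near_calibration(self, default_cohort):
        cfg = GeneratorConfig(seed=0)
        bact, fung = generate_communities(cfg, default_cohort)
        pb = bact.phylum_proportions().mean()
        pf = fung.phylum_proportions().mean()
        assert 100 * pb["Proteobacteria"] == pytest.approx(33.03, abs=2.0)
        assert 100 * pf["Ascomycota"] == pytest.approx(53.23, abs=2.0)

    def test_proportions_sum_to_one(self, default_cohort):
        cfg = GeneratorConfig(seed=0)
        bact, _ = generate_communities(cfg, default_cohort)
        sums = bact.phylum_proportions().sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert (bact.sample_depths() == cfg.read_depth).all()

    def test_large_concentration_collapses_to_means(self, default_cohort):
        cfg = GeneratorConfig(seed=1, dirichlet_conc=1e7, coupling=0.0,
                              read_depth=200_000)
        bact, _ = generate_communities(cfg, default_cohort)
        props = bact.phylum_proportions()
        for name, target in cfg.bacterial_phyla.items():
            assert props[name].mean() == pytest.approx(target, abs=0.01)

    def test_zero_coupling_gives_null_mantel(self, default_cohort):
        from eestoich.diversity import distance_matrix
        from eestoich.drivers import mantel
        from eestoich.core import DistanceMatrix

        rs = []
        for seed in range(8):
            cfg = GeneratorConfig(seed=seed, coupling=0.0)
            rec = generate_cohort(cfg)
            bact, _ = generate_communities(cfg, rec)
            dm = distance_matrix(bact)
            vec = limitation_table(rec, RunConfig(seed=seed))
            vl = vec.set_index("sample_id")["length"].loc[dm.ids].to_numpy()
            delta = DistanceMatrix(dm.ids, np.abs(vl[:, None] - vl[None, :]))
            rs.append(mantel(dm, delta, n_perm=99, seed=seed).r_obs)
        assert abs(np.mean(rs)) < 0.12

    def test_default_coupling_links_composition_to_limitation(self, default_cohort):
        from eestoich.diversity import distance_matrix
        from eestoich.drivers import mantel
        from eestoich.core import DistanceMatrix

        cfg = GeneratorConfig(seed=0)
        bact, _ = generate_communities(cfg, default_cohort)
        dm = distance_matrix(bact)
        vec = limitation_table(default_cohort, RunConfig(seed=0))
        vl = vec.set_index("sample_id")["length"].loc[dm.ids].to_numpy()
        delta = DistanceMatrix(dm.ids, np.abs(vl[:, None] - vl[None, :]))
        res = mantel(dm, delta, n_perm=999, seed=0)
        assert res.r_obs > 0
        assert res.p_value < 0.05


class TestWriteFixture:
    def test_fixture_files_and_shapes(self, fixture_dir):
        for f in ("samples.csv", "otu_bacteria.tsv", "otu_fungi.tsv",
                  "taxonomy_bacteria.tsv", "taxonomy_fungi.tsv",
                  "generator_config.yaml", "config.yaml"):
            assert (fixture_dir / f).exists()
        samples = pd.read_csv(fixture_dir / "samples.csv")
        assert len(samples) == 30

    def test_same_seed_byte_identical(self, tmp_path):
        write_fixture(GeneratorConfig(seed=9), tmp_path / "a")
        write_fixture(GeneratorConfig(seed=9), tmp_path / "b")
        for f in ("samples.csv", "otu_bacteria.tsv", "otu_fungi.tsv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_single_region_fixture(self, tmp_path):
        m = write_fixture(GeneratorConfig(seed=1, n_sxk=0, n_lxk=8), tmp_path / "sr")
        assert m["n_samples"] == 8

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=4, n_sxk=5, n_lxk=7, coupling=0.1)
        cfg.to_yaml(tmp_path / "g.yaml")
        back = GeneratorConfig.from_yaml(tmp_path / "g.yaml")
        assert back == cfg
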