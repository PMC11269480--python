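"""Synthetic two-region lake-sediment survey generator.

Emulates a 30-site field survey of a large temperate freshwater lake split
by a dyke into a small eutrophic basin (SXK, 10 sites: shallow, high
dissolved solids and conductivity, carbon-rich sediment) and a large basin
(LXK, 20 sites: deeper, more dilute, carbon-poor sediment), so that every
downstream stage of the pipeline can be exercised without field data.

Model
-----
Strictly positive covariates (depth, TDS, conductivity, sediment TC/TN/TP,
nutrients) are log-normal per region with configured means and a common
coefficient of variation; pH and temperature are normal.  Each enzyme
activity is log-normal with

    ln A_e = ln(base_e) + ln(mult_{e,region}) + Σ_i β_{e,i} · z_i + ε_e

where z_i are the log covariates (depth, TDS, water conductivity, sediment
TC) standardised with *analytic* pooled moments, and ε_e is Gaussian noise.
Because every term is log-normal, the pooled expected activity of each
enzyme has a closed form via E[lognormal] = exp(μ + σ²/2).  The generator
inverts that closed form to solve the base levels and region multipliers so
that, in expectation,

* the pooled C:N:P acquisition stoichiometry equals the configured target
  (default 1 : 0.58 : 1.51),
* the SXK/LXK ratio of mean BG is the configured contrast (default 3×),
  and of mean AP the default ¼×,

exactly — no tuning loop.  Communities are Dirichlet-multinomial at phylum
level with configured mean proportions, within-phylum OTU weights drawn
once by stick-breaking, and an optional tilt that makes composition drift
along the conductivity gradient (coupling biotic beta diversity to the
limitation gradient).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ENZYME_FIELDS,
    CommunityTable,
    ConfigError,
    EnzymeProfile,
    Region,
    RunConfig,
    SampleRecord,
    derived_n_to_p,
)
from .io import save_run_config, write_otu_table, write_sample_table, write_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "generate_cohort", "generate_communities", "write_fixture"]

#: Covariates that enter the enzyme log-mean model, in fixed order.
DRIVER_COVARIATES: tuple[str, ...] = ("depth", "tds", "cond", "tc")

_BACTERIAL_PHYLA = (
    ("Proteobacteria", 0.3303),
    ("Acidobacteria", 0.1132),
    ("Chloroflexi", 0.1045),
    ("Planctomycetes", 0.0918),
    ("Actinobacteria", 0.0754),
)
_FUNGAL_PHYLA = (
    ("Ascomycota", 0.5323),
    ("Basidiomycota", 0.3347),
    ("Chytridiomycota", 0.0606),
    ("Rozellomycota", 0.0172),
    ("Mortierellomycota", 0.002),
)


def _with_other(phyla: tuple) -> dict[str, float]:
    props = dict(phyla)
    rem = 1.0 - sum(props.values())
    if rem < -1e-9:
        raise ConfigError("phylum proportions exceed 1")
    props["Other"] = max(rem, 0.0)
    return props


@dataclass
class GeneratorConfig:
    """All calibration constants of the synthetic cohort.

    Regional means follow the study design the generator emulates; every
    dispersion is a generator choice (survey tables of this kind publish
    only means), defaulting to a 30% coefficient of variation.
    """

    seed: int = 0
    n_sxk: int = 10
    n_lxk: int = 20
    cv: float = 0.30  # CoV of every log-normal covariate and enzyme

    # mean (SXK, LXK) per strictly positive covariate; log-normal draws
    sediment_means: dict = field(default_factory=lambda: {
        "tc_g_kg": (18.06, 5.43),
        "tn_g_kg": (1.78, 0.69),
        "tp_g_kg": (0.73, 0.44),
        "conductivity": (350.0, 200.0),
        "doc": (25.0, 10.0),
        "nh4": (12.0, 6.0),
        "no3": (3.0, 2.0),
        "no2": (0.3, 0.2),
        "po4": (0.8, 0.5),
    })
    water_means: dict = field(default_factory=lambda: {
        "depth_m": (2.0, 5.5),
        "tds_mg_l": (320.0, 160.0),
        "conductivity": (480.0, 250.0),
        "salinity": (0.16, 0.09),
        "tn": (1.2, 0.8),
        "tp": (0.06, 0.05),
        "nh4": (0.25, 0.15),
        "no3": (0.4, 0.3),
        "no2": (0.02, 0.015),
        "po4": (0.03, 0.02),
    })
    # mean (SXK, LXK) and sd for normal covariates
    water_ph: tuple = (8.1, 7.8, 0.25)
    water_temp_c: tuple = (22.0, 21.0, 1.2)
    sediment_ph: tuple = (6.8, 7.2, 0.3)

    # pooled acquisition stoichiometry target, C : N : P
    target_cnp: tuple = (1.0, 0.58, 1.51)
    activity_scale: float = 100.0   # pooled mean C-acquisition, nmol g^-1 h^-1
    bg_frac_of_c: float = 0.6       # BG share of the C pool (CBH the rest)
    nag_frac_of_n: float = 0.5      # NAG share of the N pool (LAP the rest)

    # SXK/LXK ratio of regional mean activity, per enzyme
    region_mean_ratio: dict = field(default_factory=lambda: {
        "bg": 3.0, "cbh": 3.0, "nag": 1.2, "lap": 1.2, "ap": 0.25,
    })
    # effect of each standardised log covariate on log activity,
    # per enzyme, ordered as DRIVER_COVARIATES = (depth, tds, cond, tc)
    betas: dict = field(default_factory=lambda: {
        "bg":  (-0.40, 0.40, 0.30, 0.40),
        "cbh": (-0.40, 0.40, 0.30, 0.40),
        "nag": (0.0, 0.0, 0.0, 0.0),
        "lap": (0.0, 0.0, 0.0, 0.0),
        "ap":  (0.30, -0.30, -0.25, -0.30),
    })

    # community model
    bacterial_phyla: dict = field(default_factory=lambda: _with_other(_BACTERIAL_PHYLA))
    fungal_phyla: dict = field(default_factory=lambda: _with_other(_FUNGAL_PHYLA))
    dirichlet_conc: float = 200.0
    otus_per_phylum_bacteria: int = 30
    otus_per_phylum_fungi: int = 20
    read_depth: int = 10000
    stick_alpha: float = 5.0
    #: strength of the community drift along the conductivity gradient
    coupling: float = 0.25

    def __post_init__(self) -> None:
        if self.n_sxk + self.n_lxk < 4:
            raise ConfigError("need at least 4 samples in total")
        if self.n_sxk < 0 or self.n_lxk < 0:
            raise ConfigError("region sizes must be non-negative")
        if self.cv <= 0:
            raise ConfigError("coefficient of variation must be > 0")
        if any(t <= 0 for t in self.target_cnp):
            raise ConfigError("stoichiometry target components must be positive")
        if any(m <= 0 for m in self.region_mean_ratio.values()):
            raise ConfigError("region mean ratios must be positive")
        if not (0 < self.bg_frac_of_c < 1 and 0 < self.nag_frac_of_n < 1):
            raise ConfigError("pool fractions must lie in (0, 1)")
        if self.read_depth < 1:
            raise ConfigError("read depth must be >= 1")
        if self.dirichlet_conc <= 0:
            raise ConfigError("Dirichlet concentration must be > 0")

    # -- log-normal helpers ------------------------------------------------

    @property
    def sigma_log(self) -> float:
        """Log-scale sd implied by the configured CoV."""
        return math.sqrt(math.log(1.0 + self.cv**2))

    def _mu_log(self, mean: float) -> float:
        return math.log(mean) - 0.5 * self.sigma_log**2

    def region_weights(self) -> tuple[float, float]:
        n = self.n_sxk + self.n_lxk
        return self.n_sxk / n, self.n_lxk / n

    def driver_log_moments(self) -> dict[str, tuple[float, float, float]]:
        """Per driver covariate: (μ_SXK, μ_LXK, σ) of the log draw."""
        out = {}
        means = {
            "depth": self.water_means["depth_m"],
            "tds": self.water_means["tds_mg_l"],
            "cond": self.water_means["conductivity"],
            "tc": self.sediment_means["tc_g_kg"],
        }
        for name, (m_s, m_l) in means.items():
            out[name] = (self._mu_log(m_s), self._mu_log(m_l), self.sigma_log)
        return out

    def standardisation(self) -> dict[str, tuple[float, float]]:
        """Analytic pooled mean and sd of each log driver covariate.

        These fixed constants (not data-derived ones) standardise the
        covariates inside the enzyme model, keeping the stoichiometry
        calibration closed-form.
        """
        w_s, w_l = self.region_weights()
        out = {}
        for name, (mu_s, mu_l, sig) in self.driver_log_moments().items():
            m = w_s * mu_s + w_l * mu_l
            var = sig**2 + w_s * mu_s**2 + w_l * mu_l**2 - m**2
            out[name] = (m, math.sqrt(var))
        return out

    # -- enzyme calibration ------------------------------------------------

    def _region_z_moments(self) -> dict[str, dict[str, tuple[float, float]]]:
        """Mean/sd of each standardised covariate z within each region."""
        std = self.standardisation()
        logm = self.driver_log_moments()
        out: dict[str, dict[str, tuple[float, float]]] = {"SXK": {}, "LXK": {}}
        for name, (m, s) in std.items():
            mu_s, mu_l, sig = logm[name]
            out["SXK"][name] = ((mu_s - m) / s, sig / s)
            out["LXK"][name] = ((mu_l - m) / s, sig / s)
        return out

    def enzyme_parameters(self) -> dict[str, dict]:
        """Solve base levels and SXK multipliers in closed form.

        For each enzyme the regional conditional mean is
        base · mult_r · G_r with
        G_r = exp(Σ β a_r + ½ Σ β² b_r² + ½ σ_e²); the SXK multiplier makes
        the regional mean ratio exact and the base level makes the pooled
        mean hit the stoichiometry target.
        """
        zmom = self._region_z_moments()
        sig_e2 = self.sigma_log**2
        w_s, w_l = self.region_weights()
        c_t, n_t, p_t = self.target_cnp
        pool_target = {
            "bg": self.activity_scale * c_t * self.bg_frac_of_c,
            "cbh": self.activity_scale * c_t * (1 - self.bg_frac_of_c),
            "nag": self.activity_scale * n_t * self.nag_frac_of_n,
            "lap": self.activity_scale * n_t * (1 - self.nag_frac_of_n),
            "ap": self.activity_scale * p_t,
        }
        params: dict[str, dict] = {}
        for e in ENZYME_FIELDS:
            beta = np.asarray(self.betas[e], dtype=float)
            G = {}
            for r in ("SXK", "LXK"):
                a = np.array([zmom[r][c][0] for c in DRIVER_COVARIATES])
                b = np.array([zmom[r][c][1] for c in DRIVER_COVARIATES])
                G[r] = math.exp(float(beta @ a) + 0.5 * float(beta**2 @ b**2)
                                + 0.5 * sig_e2)
            mult_sxk = self.region_mean_ratio[e] * G["LXK"] / G["SXK"]
            k = w_s * mult_sxk * G["SXK"] + w_l * G["LXK"]
            params[e] = {
                "base": pool_target[e] / k,
                "mult": {"SXK": mult_sxk, "LXK": 1.0},
                "beta": beta,
                "sigma": math.sqrt(sig_e2),
            }
        return params

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
            elif isinstance(v, dict):
                d[k] = {kk: (list(vv) if isinstance(vv, tuple) else vv)
                        for kk, vv in v.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("target_cnp", "water_ph", "water_temp_c", "sediment_ph"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("sediment_means", "water_means", "region_mean_ratio", "betas"):
            if key in raw:
                raw[key] = {k: (tuple(v) if isinstance(v, list) else v)
                            for k, v in raw[key].items()}
        return cls(**raw)


def _draw_lognormal(rng, mean: float, sigma: float, n: int) -> np.ndarray:
    return rng.lognormal(math.log(mean) - 0.5 * sigma**2, sigma, size=n)


def generate_cohort(cfg: GeneratorConfig) -> list[SampleRecord]:
    """Draw one synthetic cohort; identical output for identical config."""
    rng = np.random.default_rng([cfg.seed, 11])
    sig = cfg.sigma_log
    n = cfg.n_sxk + cfg.n_lxk
    is_sxk = np.arange(n) < cfg.n_sxk

    def per_region(means: tuple[float, float]) -> np.ndarray:
        vals = np.empty(n)
        for reg_mask, m in ((is_sxk, means[0]), (~is_sxk, means[1])):
            k = int(reg_mask.sum())
            if k:
                vals[reg_mask] = _draw_lognormal(rng, m, sig, k)
        return vals

    water = {k: per_region(v) for k, v in cfg.water_means.items()}
    sediment = {k: per_region(v) for k, v in cfg.sediment_means.items()}
    for spec_, store, key in (
        (cfg.water_ph, water, "ph"),
        (cfg.water_temp_c, water, "temp_c"),
        (cfg.sediment_ph, sediment, "ph"),
    ):
        m_s, m_l, sd = spec_
        vals = np.where(is_sxk, m_s, m_l) + rng.normal(0.0, sd, size=n)
        store[key] = vals

    std = cfg.standardisation()
    z = {}
    raw_driver = {
        "depth": water["depth_m"],
        "tds": water["tds_mg_l"],
        "cond": water["conductivity"],
        "tc": sediment["tc_g_kg"],
    }
    for name in DRIVER_COVARIATES:
        m, s = std[name]
        z[name] = (np.log(raw_driver[name]) - m) / s
    zmat = np.column_stack([z[c] for c in DRIVER_COVARIATES])

    enz_par = cfg.enzyme_parameters()
    activities = {}
    for e in ENZYME_FIELDS:
        p = enz_par[e]
        mult = np.where(is_sxk, p["mult"]["SXK"], p["mult"]["LXK"])
        # ln A = ln base + ln mult + β·z + ε; the calibration's closed form
        # already accounts for E[exp(β·z)] and E[exp(ε)] per region
        log_mean = np.log(p["base"]) + np.log(mult) + zmat @ p["beta"]
        activities[e] = np.exp(log_mean + rng.normal(0.0, p["sigma"], size=n))

    records = []
    for i in range(n):
        reg = Region.SXK if is_sxk[i] else Region.LXK
        sid = f"{'S' if reg == Region.SXK else 'L'}{i + 1:05d}"
        w = {k: float(v[i]) for k, v in water.items()}
        s = {k: float(v[i]) for k, v in sediment.items()}
        w["n_to_p"] = derived_n_to_p(w["tn"], w["tp"])
        s["n_to_p"] = derived_n_to_p(s["tn_g_kg"], s["tp_g_kg"])
        records.append(
            SampleRecord(
                sample_id=sid,
                region=reg,
                water=w,
                sediment=s,
                enzymes=EnzymeProfile(**{e: float(activities[e][i]) for e in ENZYME_FIELDS}),
            )
        )
    return records


def _community(
    cfg: GeneratorConfig,
    records: list[SampleRecord],
    phyla: dict[str, float],
    otus_per_phylum: int,
    prefix: str,
    rng: np.random.Generator,
) -> CommunityTable:
    names = list(phyla.keys())
    base_p = np.array([phyla[p] for p in names], dtype=float)
    base_p = base_p / base_p.sum()
    # tilt loadings: dominant phylum and the "Other" bin stay fixed; the
    # remaining phyla alternate sign so the drift is compositional
    dom = int(np.argmax(base_p))
    loadings = np.zeros(len(names))
    sign = 1.0
    for j in range(len(names)):
        if j == dom or names[j] == "Other":
            continue
        loadings[j] = sign
        sign = -sign

    # within-phylum OTU weights: one stick-breaking draw per cohort
    taxon_ids: list[str] = []
    phylum_of: dict[str, str] = {}
    weights_per_phylum = []
    for name in names:
        v = rng.beta(1.0, cfg.stick_alpha, size=otus_per_phylum)
        remaining = np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
        w = v * remaining
        w = w / w.sum()
        weights_per_phylum.append(w)
        for j in range(otus_per_phylum):
            tid = f"{prefix}_{name}_{j + 1:03d}"
            taxon_ids.append(tid)
            phylum_of[tid] = name

    m_cond, s_cond = cfg.standardisation()["cond"]
    counts = np.zeros((len(records), len(taxon_ids)), dtype=np.int64)
    for i, rec in enumerate(records):
        zc = (math.log(rec.water["conductivity"]) - m_cond) / s_cond
        tilted = base_p * np.exp(cfg.coupling * loadings * zc)
        tilted = tilted / tilted.sum()
        phylum_props = rng.dirichlet(cfg.dirichlet_conc * tilted)
        taxon_props = np.concatenate(
            [phylum_props[j] * weights_per_phylum[j] for j in range(len(names))]
        )
        counts[i] = rng.multinomial(cfg.read_depth, taxon_props / taxon_props.sum())
    return CommunityTable(
        sample_ids=[r.sample_id for r in records],
        taxon_ids=taxon_ids,
        counts=counts,
        phylum_of=phylum_of,
    )


def generate_communities(
    cfg: GeneratorConfig, records: list[SampleRecord]
) -> tuple[CommunityTable, CommunityTable]:
    """Bacterial and fungal OTU tables coupled to the cohort's gradients."""
    if not records:
        raise ConfigError("generate_communities needs a non-empty cohort")
    rng_b = np.random.default_rng([cfg.seed, 21])
    rng_f = np.random.default_rng([cfg.seed, 22])
    bact = _community(cfg, records, cfg.bacterial_phyla,
                      cfg.otus_per_phylum_bacteria, "BOTU", rng_b)
    fung = _community(cfg, records, cfg.fungal_phyla,
                      cfg.otus_per_phylum_fungi, "FOTU", rng_f)
    return bact, fung


def write_fixture(cfg: GeneratorConfig, outdir: str | Path) -> dict:
    """Emit a complete, self-consistent on-disk fixture.

    Writes samples.csv, the two OTU/taxonomy pairs, the generator config,
    and a ready-to-run pipeline config pointing at the written files.
    Returns a manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(cfg)
    bact, fung = generate_communities(cfg, records)
    write_sample_table(records, outdir / "samples.csv")
    write_otu_table(bact, outdir / "otu_bacteria.tsv")
    write_otu_table(fung, outdir / "otu_fungi.tsv")
    write_taxonomy(bact, outdir / "taxonomy_bacteria.tsv")
    write_taxonomy(fung, outdir / "taxonomy_fungi.tsv")
    cfg.to_yaml(outdir / "generator_config.yaml")
    run_cfg = RunConfig(
        samples_path=str(outdir / "samples.csv"),
        otu_bacteria_path=str(outdir / "otu_bacteria.tsv"),
        otu_fungi_path=str(outdir / "otu_fungi.tsv"),
        taxonomy_bacteria_path=str(outdir / "taxonomy_bacteria.tsv"),
        taxonomy_fungi_path=str(outdir / "taxonomy_fungi.tsv"),
        outdir=str(outdir / "results"),
        seed=cfg.seed,
    )
    save_run_config(run_cfg, outdir / "config.yaml")
    if cfg.n_sxk == 0 or cfg.n_lxk == 0:
        logger.info("single-region fixture: between-region comparisons will be skipped")
    files = [
        "samples.csv", "otu_bacteria.tsv", "otu_fungi.tsv",
        "taxonomy_bacteria.tsv", "taxonomy_fungi.tsv",
        "generator_config.yaml", "config.yaml",
    ]
    return {"outdir": str(outdir), "files": files, "n_samples": len(records)}
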