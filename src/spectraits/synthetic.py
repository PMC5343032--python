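"""Synthetic wheat canopy scenes: trait tables and forward-modeled spectra.

The generator emulates the statistical structure the downstream analyses
assume, for a panel of spring bread wheat genotypes grown under two hydric
regimes — fully irrigated (FI) and water-stressed (WS):

* **Traits.**  Each trait × environment gets a scaled-Beta distribution whose
  range, mean and SD default to the field study's published summaries (grain
  yield FI 5.1–12.9 t/ha mean 9.7 ± 1.2; WS 0.9–6.9 mean 3.1 ± 0.9; carbon
  isotope discrimination FI 17.1–20.2 ‰, WS 12.3–16.5 ‰; etc.).  A shared
  per-plot "performance" factor with trait-specific loadings induces the
  realistic positive correlations among yield, Δ¹³C and canopy traits;
  genotype values are correlated across environments (Gaussian copula,
  default r = 0.5); replicates add plot-level noise and values are clipped
  to the stated range (clip rate logged).  Δ¹³C is produced by simulating
  plant δ¹³C and running it through :func:`delta13c` with air δ¹³C = −8.0 ‰
  (the conventional signed value; see docs/methods.md).
* **Spectra.**  One spectrum per plot per assessment stage (AN anthesis, GF
  grain filling) on the full 350–2500 nm 1-nm grid: an LAI/structure-weighted
  mixture of a smooth soil line and a vegetation endmember whose chlorophyll
  well (670 nm) and red-edge position follow the stage-matched chlorophyll
  trait, and whose NIR/SWIR water absorption features (970, 1200, 1450,
  1940 nm) follow canopy water status (tied to grain yield), plus band-wise
  Gaussian noise, clamped to [0, 1].  Setting a coupling strength to zero
  makes the corresponding feature statistically independent of its trait.

These are smooth parametric curves, not a radiative-transfer model: the goal
is controllable statistical structure, not physical fidelity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm as norm_dist

from .spectra_io import SpectraMatrix, TraitTable

logger = logging.getLogger(__name__)

DELTA13C_AIR = -8.0  # ‰, conventional signed atmospheric value

WAVELENGTHS = np.arange(350, 2501)

#: (trait, stage) -> {env: (min, max, mean, sd)}; the field study's summary
#: statistics for 384 genotypes x 2 replicates under each regime.
TABLE_TRAITS: dict[tuple[str, str], dict[str, tuple]] = {
    ("SM2", "m"): {"FI": (320.0, 1125.0, 627.7, 133.7),
                   "WS": (75.0, 625.0, 321.1, 69.3)},
    ("KPS", "m"): {"FI": (15.0, 68.9, 38.6, 6.5),
                   "WS": (9.4, 55.6, 32.3, 6.3)},
    ("TKW", "m"): {"FI": (30.8, 88.6, 49.3, 6.6),
                   "WS": (29.4, 89.4, 44.4, 6.8)},
    ("GY", "m"): {"FI": (5.1, 12.9, 9.7, 1.2),
                  "WS": (0.9, 6.9, 3.1, 0.9)},
    ("Chl", "an"): {"FI": (35.9, 58.2, 49.3, 3.3),
                    "WS": (31.3, 52.0, 41.4, 3.5)},
    ("Chl", "gf"): {"FI": (30.1, 56.0, 47.8, 3.7),
                    "WS": (0.8, 48.8, 34.0, 10.3)},
    ("WSC", "an"): {"FI": (16.1, 610.9, 141.2, 49.2),
                    "WS": (20.6, 708.4, 226.8, 51.7)},
    ("WSC", "m"): {"FI": (5.6, 686.3, 43.4, 33.3),
                   "WS": (5.0, 218.3, 48.0, 23.5)},
    ("WSCC", "an"): {"FI": (19.3, 926.0, 172.1, 86.3),
                     "WS": (32.7, 1271.6, 410.8, 140.9)},
    ("WSCC", "m"): {"FI": (6.1, 926.6, 47.4, 45.1),
                    "WS": (4.9, 262.9, 52.1, 34.4)},
    ("D13C", "m"): {"FI": (17.1, 20.2, 18.8, 0.5),
                    "WS": (12.3, 16.5, 14.9, 0.5)},
    ("LAI", "an"): {"FI": (2.4, 8.4, 5.2, 1.0)},  # not measured under WS
}

#: loading of each trait on the shared per-plot performance factor; the rest
#: of the latent variance is trait-specific.  Positive loadings give the
#: yield / Δ13C / canopy-vigour correlations seen in field panels.
SHARED_LOADINGS: dict[tuple[str, str], float] = {
    ("SM2", "m"): 0.6, ("KPS", "m"): 0.4, ("TKW", "m"): 0.3,
    ("GY", "m"): 0.8, ("Chl", "an"): 0.6, ("Chl", "gf"): 0.6,
    ("WSC", "an"): 0.3, ("WSC", "m"): 0.2, ("WSCC", "an"): 0.4,
    ("WSCC", "m"): 0.2, ("D13C", "m"): 0.7, ("LAI", "an"): 0.6,
}


def delta13c(delta13c_plant: float, delta13c_air: float = DELTA13C_AIR) -> float:
    """Carbon isotope discrimination Δ¹³C (‰) from plant and air δ¹³C.

    Δ¹³C = (δ¹³C_a − δ¹³C_p) / (1 + δ¹³C_p / 1000).
    """
    denom = 1.0 + delta13c_plant / 1000.0
    if denom == 0.0:
        raise ZeroDivisionError("delta13c undefined: 1 + δ13C_p/1000 = 0")
    return (delta13c_air - delta13c_plant) / denom


def _invert_delta13c(disc: np.ndarray, air: float = DELTA13C_AIR) -> np.ndarray:
    """Plant δ¹³C giving a target discrimination (inverse of :func:`delta13c`)."""
    return (air - disc) / (1.0 + disc / 1000.0)


@dataclass
class TraitGenerationParams:
    """Study-scale knobs for :func:`generate_traits`.

    Defaults are the field study's conditions: 384 genotypes, 2 replicates,
    trait distributions from :data:`TABLE_TRAITS`.  ``rep_noise_frac`` is the
    plot-level residual SD as a fraction of the trait SD (the remaining
    variance is between-genotype); ``env_correlation`` is the genotype-level
    copula correlation between a genotype's FI and WS latent values.
    """

    n_genotypes: int = 384
    n_replicates: int = 2
    env_correlation: float = 0.5
    rep_noise_frac: float = 0.25
    table: dict = field(default_factory=lambda: dict(TABLE_TRAITS))
    loadings: dict = field(default_factory=lambda: dict(SHARED_LOADINGS))

    def __post_init__(self):
        if not 0.0 <= self.rep_noise_frac < 1.0:
            raise ValueError("infeasible variance split: rep_noise_frac must be "
                             "in [0, 1)")
        if not -1.0 < self.env_correlation < 1.0:
            raise ValueError("env_correlation must be in (-1, 1)")
        for key, envs in self.table.items():
            for env, (lo, hi, mean, sd) in envs.items():
                if not lo < hi:
                    raise ValueError(f"{key} {env}: min must be < max")
                if not lo < mean < hi:
                    raise ValueError(f"{key} {env}: mean outside (min, max)")


def _beta_params(lo, hi, mean, sd):
    """Beta(a, b) on [0,1] matching the scaled mean and (approximately) SD."""
    mu = (mean - lo) / (hi - lo)
    s = sd / (hi - lo)
    kappa = mu * (1.0 - mu) / max(s * s, 1e-6) - 1.0
    kappa = max(kappa, 2.0)  # keep the density unimodal-ish, tails nontrivial
    return mu * kappa, (1.0 - mu) * kappa


def _correlated_pair(rng, n, rho):
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    return z1, z2


def plot_id(genotype: int, replicate: int, env: str) -> str:
    return f"g{genotype:03d}_r{replicate}_{env}"


def generate_traits(params: TraitGenerationParams | None = None,
                    seed: int = 0) -> TraitTable:
    """Simulate the trait table for a two-regime wheat panel.

    One latent genotype value per trait per environment (shared-factor +
    trait-specific, FI/WS correlated), mapped through a scaled-Beta quantile
    onto the trait's published range, plus replicate noise, clipped to range.
    Fully deterministic given the seed.
    """
    p = params or TraitGenerationParams()
    rng = np.random.default_rng(seed)
    n = p.n_genotypes

    shared = dict(zip(("FI", "WS"), _correlated_pair(rng, n, p.env_correlation)))

    records = []
    n_clipped = n_total = 0
    for (trait, stage), envs in p.table.items():
        lam = p.loadings.get((trait, stage), 0.5)
        spec_fi, spec_ws = _correlated_pair(rng, n, p.env_correlation)
        specific = {"FI": spec_fi, "WS": spec_ws}
        for env, (lo, hi, mean, sd) in envs.items():
            z = lam * shared[env] + np.sqrt(1.0 - lam ** 2) * specific[env]
            u = norm_dist.cdf(z)
            a, b = _beta_params(lo, hi, mean, sd)
            geno_vals = lo + (hi - lo) * beta_dist.ppf(u, a, b)
            for r in range(1, p.n_replicates + 1):
                noise = rng.normal(0.0, p.rep_noise_frac * sd, size=n)
                vals = geno_vals + noise
                clipped = np.clip(vals, lo, hi)
                n_clipped += int((clipped != vals).sum())
                n_total += n
                if trait == "D13C":
                    # route through the discrimination formula: simulate plant
                    # δ13C from the target Δ, then recompute Δ from it
                    plant = _invert_delta13c(clipped)
                    clipped = np.array([delta13c(dp) for dp in plant])
                for g in range(n):
                    records.append((plot_id(g, r, env), trait, stage,
                                    clipped[g]))
    if n_total:
        logger.info("trait clip rate: %.3f%%", 100.0 * n_clipped / n_total)
    df = pd.DataFrame(records, columns=["observation_id", "trait",
                                        "measurement_stage", "value"])
    return TraitTable(df)


# ---------------------------------------------------------------------------
# spectral forward model


@dataclass
class SpectralForwardParams:
    """Couplings and noise for :func:`generate_spectra`.

    ``couplings`` scale how strongly each spectral feature follows its trait
    (0 = feature fixed at its baseline, independent of the trait; 1 = default
    strength).  ``water_jitter`` adds latent canopy-water noise (in units of
    the normalized trait) so the trait–spectrum link is strong but not exact.
    """

    couplings: dict = field(default_factory=lambda: {
        "chlorophyll": 1.0, "water": 1.0, "structure": 1.0})
    noise_sigma: float = 0.004
    water_jitter: float = 0.05
    chl_trait: str = "Chl"          # stage-matched: an for AN, gf for GF
    water_trait: tuple = ("GY", "m")
    structure_trait: tuple = ("LAI", "an")   # falls back to SM2 m where absent


def _soil_line(wl: np.ndarray) -> np.ndarray:
    return 0.12 + 0.00011 * (wl - 350.0)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _norm01(values: pd.Series) -> pd.Series:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return pd.Series(0.5, index=values.index)
    return (values - lo) / (hi - lo)


#: water absorption wells: (center nm, width nm, baseline depth)
WATER_WELLS = ((970, 32, 0.10), (1200, 45, 0.12), (1450, 55, 0.55),
               (1940, 70, 0.75))


def _vegetation_endmember(wl, chl_eff, water_eff, stage):
    """Vegetation reflectance rows for per-observation effect vectors."""
    wl = wl[None, :]
    chl = chl_eff[:, None]
    wat = water_eff[:, None]
    vis = (0.10
           + 0.05 * np.exp(-((wl - 550.0) ** 2) / (2 * 35.0 ** 2)) * (1 - 0.5 * chl)
           - 0.08 * chl * np.exp(-((wl - 670.0) ** 2) / (2 * 55.0 ** 2)))
    vis = np.clip(vis, 0.01, None)
    plateau = 0.45 - (0.02 if stage == "GF" else 0.0)
    edge_pos = 700.0 + 15.0 * (chl - 0.5)   # red edge moves right with Chl
    shape = _logistic((wl - edge_pos) / 18.0)
    visnir = vis + (plateau - vis) * shape
    swir_decline = 1.0 - 0.35 * _logistic((wl - 1300.0) / 200.0)
    wells = np.ones_like(visnir)
    for center, width, depth in WATER_WELLS:
        wells *= 1.0 - depth * wat * np.exp(-((wl - center) ** 2)
                                            / (2 * width ** 2))
    return visnir * swir_decline * wells


def _meta_from_plot_ids(ids):
    """Parse the generator's plot-id convention g###_r#_ENV."""
    genos, envs = [], []
    for pid in ids:
        parts = str(pid).split("_")
        genos.append(parts[0])
        envs.append(parts[-1])
    return genos, envs


def generate_spectra(traits: TraitTable,
                     params: SpectralForwardParams | None = None,
                     seed: int = 0) -> SpectraMatrix:
    """Forward-model one canopy spectrum per plot per assessment stage.

    Feature drivers are min–max normalizations of the plot's traits over the
    whole table (so pooled two-regime tables place FI and WS plots on one
    physiological scale).  Effect = baseline + coupling · (driver − 0.5), so
    zero coupling pins the feature at baseline.
    """
    p = params or SpectralForwardParams()
    rng = np.random.default_rng(seed)
    wl = WAVELENGTHS.astype(float)

    water_raw = traits.get(*p.water_trait)
    plots = list(water_raw.index)
    genos, envs = _meta_from_plot_ids(plots)
    water_norm = _norm01(water_raw)

    struct_raw = traits.get(*p.structure_trait)
    struct_fallback = traits.get("SM2", "m")
    struct_norm = _norm01(struct_raw) if len(struct_raw) else pd.Series(dtype=float)
    fallback_norm = _norm01(struct_fallback) if len(struct_fallback) else None

    c_chl = p.couplings.get("chlorophyll", 1.0)
    c_wat = p.couplings.get("water", 1.0)
    c_str = p.couplings.get("structure", 1.0)

    all_meta, all_refl, all_ids = [], [], []
    n_preclamp = 0
    for stage, chl_stage in (("AN", "an"), ("GF", "gf")):
        chl_norm = _norm01(traits.get(p.chl_trait, chl_stage))

        def driver(series, fallback=0.5):
            return np.array([series.get(pid, fallback) for pid in plots])

        chl_d = driver(chl_norm)
        wat_d = driver(water_norm)
        wat_d = np.clip(wat_d + rng.normal(0, p.water_jitter, len(plots)), 0, 1)
        if fallback_norm is not None:
            str_d = np.array([struct_norm.get(pid,
                                              fallback_norm.get(pid, 0.5))
                              for pid in plots])
        else:
            str_d = driver(struct_norm)

        chl_eff = np.clip(0.5 + c_chl * (chl_d - 0.5), 0.0, 1.0)
        wat_eff = np.clip(0.35 + 0.9 * c_wat * (wat_d - 0.5), 0.02, 1.0)
        frac = np.clip(0.55 + 0.5 * c_str * (str_d - 0.5), 0.05, 0.98)

        veg = _vegetation_endmember(wl, chl_eff, wat_eff, stage)
        soil = _soil_line(wl)[None, :]
        refl = frac[:, None] * veg + (1.0 - frac[:, None]) * soil
        refl += rng.normal(0.0, p.noise_sigma, refl.shape)
        n_preclamp += int(((refl < 0) | (refl > 1)).sum())
        refl = np.clip(refl, 0.0, 1.0)

        all_refl.append(refl)
        all_ids.extend(f"{pid}@{stage}" for pid in plots)
        all_meta.extend(zip(genos, envs, [stage] * len(plots)))

    frac_clamped = n_preclamp / (len(all_ids) * len(wl))
    if frac_clamped > 0.10:
        warnings.warn(f"{100 * frac_clamped:.1f}% of bands clamped to [0, 1]; "
                      "couplings may be too strong", stacklevel=2)

    meta = pd.DataFrame(all_meta, columns=["genotype_id", "environment", "stage"],
                        index=pd.Index(all_ids, name="observation_id"))
    refl = pd.DataFrame(np.vstack(all_refl), index=meta.index,
                        columns=WAVELENGTHS)
    return SpectraMatrix(meta=meta, reflectance=refl)


def make_benchmark_fixture(seed: int = 0, n_genotypes: int = 64,
                           trait_params: TraitGenerationParams | None = None,
                           forward_params: SpectralForwardParams | None = None
                           ) -> tuple[SpectraMatrix, TraitTable]:
    """Small default scene for end-to-end tests: 64 genotypes × 2 replicates ×
    2 environments × 2 assessment stages = 512 spectra."""
    tp = trait_params or TraitGenerationParams(n_genotypes=n_genotypes)
    traits = generate_traits(tp, seed=seed)
    spectra = generate_spectra(traits, forward_params,
                               seed=seed + 1 if seed < 2 ** 31 - 1 else seed - 1)
    return spectra, traits
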