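"""Truth-known virtual sites for end-to-end testing of the pipeline.

The generator emulates the statistical structure of a temperate-forest
Cambisol monitoring site: a five-layer profile (0–5, 5–15, 15–30, 30–45,
45–60 cm), SOC decreasing exponentially with depth, a retained fraction
X_k proportional to SOC (surface ≈ 4.5%, ninefold lower at depth),
retention durations rising from ~20 yr at the surface to ~305 yr at depth,
litterfall carrying 11% of the rainfall isotope input, and a 1952–1972
bomb-pulse ³⁶Cl forcing three orders of magnitude above the cosmogenic
background.  Observation noise uses the stated monitoring uncertainties
(5% bulk density; 10% thickness, litterfall mass and drainage volume;
3% rainfall; 5% default analytical uncertainty on concentrations — the
analytical level is a parameter, not a fixed fact).

"Measured" ³⁶Cl stocks are produced by running the forward model itself
from the pre-bomb steady state to the stock year and adding noise to each
physically measured factor (density, concentrations, carrier amounts), so
inference on a generated site is a genuine parameter-recovery experiment:
the generator's noise draws are entirely separate from the inference
engine's perturbation draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    AnnualFlux,
    FluxComponent,
    Measurement,
    SiteDataset,
    SoilLayer,
    Species,
    ValidationError,
    write_site_tables,
)
from .forcing import (
    DEFAULT_LITTERFALL_FRACTION,
    ForcingScenario,
    PulseShape,
    build_forcing,
    write_forcing_table,
)
from .massbalance import (
    DEFAULT_ROOT_EFOLDING_CM,
    ModelParams,
    SteadyState,
    derive_steady_state,
    simulate,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "gen_site",
    "gen_observations",
    "write_site",
    "load_truth",
    "score_recovery",
]

# Atoms of Cl per gram: N_A / 35.45 — used only to keep default
# concentrations on a realistic scale (µg-per-g chloride in soil).
_AT_PER_G_CL = 6.02214076e23 / 35.453


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the virtual site; defaults are the emulated study design."""

    boundaries_cm: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 45.0, 60.0)
    bulk_density: tuple[float, ...] = (1.05, 1.15, 1.25, 1.35, 1.40)
    #: SOC at z=0 (g C kg⁻¹) and e-folding depth chosen so the surface layer
    #: averages ~30 g kg⁻¹ and the surface/deep SOC (hence X) ratio is ~9.
    soc_surface: float = 33.43
    soc_efolding_cm: float = 50.0 / math.log(9.0)
    #: X_k = x_per_soc · SOC_k; 0.0015 per (g kg⁻¹) puts the surface at 4.5%.
    x_per_soc: float = 0.0015
    #: optional lognormal-free jitter sd on X around the SOC line (X units)
    x_jitter_sd: float = 0.0
    #: true retention durations (yr), surface to deep; T_R = X·T′ follows.
    t_prime_true: tuple[float, ...] = (20.0, 50.0, 110.0, 200.0, 305.0)
    #: modern rainfall fluxes (at m⁻² yr⁻¹): ³⁶Cl background, and stable Cl
    #: equivalent to ~1 mg L⁻¹ chloride in ~900 mm of rain.
    background_cl36: float = 5.0e8
    background_cl: float = 1.5e22
    litterfall_fraction: float = DEFAULT_LITTERFALL_FRACTION
    pulse: PulseShape = field(default_factory=PulseShape)
    start_year: int = 1940
    end_year: int = 2020
    stock_year: int = 2010
    flux_year: int = 2012
    z0_cm: float = DEFAULT_ROOT_EFOLDING_CM
    #: carrier amounts: annual rain water (L m⁻²) and dry litterfall (g m⁻²)
    rain_carrier: float = 900.0
    litter_carrier: float = 300.0
    drainage_carrier: float = 400.0
    # relative 1σ of each measured quantity
    rel_sigma_bd: float = 0.05
    rel_sigma_thickness: float = 0.10
    rel_sigma_rain: float = 0.03
    rel_sigma_litter: float = 0.10
    rel_sigma_drainage: float = 0.10
    #: analytical uncertainty of every Cl/³⁶Cl concentration (parametrized,
    #: not a known constant)
    rel_sigma_conc: float = 0.05


def _layer_mean_exponential(
    surface: float, efold: float, top: float, bottom: float
) -> float:
    """Mean of ``surface·exp(-z/efold)`` over [top, bottom]."""
    return (
        surface
        * efold
        * (math.exp(-top / efold) - math.exp(-bottom / efold))
        / (bottom - top)
    )


@dataclass
class SyntheticTruth:
    """Everything needed to rebuild the site and score recovery."""

    seed: int
    config: SyntheticConfig
    soc: np.ndarray  # g C kg⁻¹ per layer
    x_true: np.ndarray
    t_r_true: np.ndarray  # yr, = X·T′
    t_prime_true: np.ndarray  # yr

    @property
    def n_layers(self) -> int:
        return self.x_true.size

    def scenario(self) -> ForcingScenario:
        cfg = self.config
        return build_forcing(
            {Species.CL36: cfg.background_cl36, Species.CL: cfg.background_cl},
            pulse=cfg.pulse,
            litterfall_fraction=cfg.litterfall_fraction,
            start_year=cfg.start_year,
            end_year=cfg.end_year,
        )

    def steady_state(self) -> SteadyState:
        cfg = self.config
        return derive_steady_state(
            s_cl=self.t_r_true * self._i_cl(),
            rainfall_cl=cfg.background_cl,
            litterfall_cl=cfg.litterfall_fraction * cfg.background_cl,
            boundaries_cm=np.array(cfg.boundaries_cm),
            z0_cm=cfg.z0_cm,
        )

    def _i_cl(self) -> np.ndarray:
        cfg = self.config
        from .massbalance import cl_input_cascade, root_absorption_weights

        w = root_absorption_weights(np.array(cfg.boundaries_cm), cfg.z0_cm)
        litter = cfg.litterfall_fraction * cfg.background_cl
        return cl_input_cascade(cfg.background_cl, litter, w * litter)

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "config": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self.config).items()
                    if k != "pulse"
                },
                "pulse": asdict(self.config.pulse),
            },
            "soc": self.soc.tolist(),
            "x_true": self.x_true.tolist(),
            "t_r_true": self.t_r_true.tolist(),
            "t_prime_true": self.t_prime_true.tolist(),
        }
        return json.dumps(d, indent=2)


def load_truth(path: str | Path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    cfg_d = dict(d["config"])
    pulse = PulseShape(**cfg_d.pop("pulse"))
    for key in ("boundaries_cm", "bulk_density", "t_prime_true"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = SyntheticConfig(pulse=pulse, **cfg_d)
    return SyntheticTruth(
        seed=int(d["seed"]),
        config=cfg,
        soc=np.array(d["soc"]),
        x_true=np.array(d["x_true"]),
        t_r_true=np.array(d["t_r_true"]),
        t_prime_true=np.array(d["t_prime_true"]),
    )


def gen_site(seed: int, config: SyntheticConfig | None = None) -> SyntheticTruth:
    """Draw the true site: SOC profile, X_k = a·SOC_k, timescales.

    Deterministic given (seed, config); the seed matters only when
    ``x_jitter_sd > 0``.
    """
    cfg = config if config is not None else SyntheticConfig()
    b = np.array(cfg.boundaries_cm)
    n_layers = b.size - 1
    if len(cfg.bulk_density) != n_layers or len(cfg.t_prime_true) != n_layers:
        raise ValidationError("config arrays must have one entry per layer")
    soc = np.array(
        [
            _layer_mean_exponential(cfg.soc_surface, cfg.soc_efolding_cm, t, bb)
            for t, bb in zip(b[:-1], b[1:])
        ]
    )
    x = cfg.x_per_soc * soc
    if cfg.x_jitter_sd > 0:
        rng = np.random.default_rng(seed)
        x = np.clip(x + rng.normal(0.0, cfg.x_jitter_sd, size=n_layers), 1e-6, 1 - 1e-6)
    elif np.any(x <= 0) or np.any(x >= 1):
        raise ValidationError(
            f"configured X outside (0, 1): {x}; adjust x_per_soc or enable jitter"
        )
    t_prime = np.array(cfg.t_prime_true, dtype=float)
    t_r = x * t_prime
    z = x / t_r  # = 1/T′
    if np.any(z > 1):
        raise ValidationError("configured truth implies Z > 1")
    return SyntheticTruth(
        seed=seed, config=cfg, soc=soc, x_true=x, t_r_true=t_r, t_prime_true=t_prime
    )


def gen_observations(
    truth: SyntheticTruth, noise_seed: int | None = None, noise_scale: float = 1.0
) -> tuple[SiteDataset, ForcingScenario]:
    """Forward-simulate the truth and emit a noisy "measured" dataset.

    ``noise_scale = 0`` gives exact (noise-free) observations; the stated
    uncertainty percentages are always recorded in the tables either way so
    the inference's perturbation widths do not depend on the realized noise.
    """
    cfg = truth.config
    rng = np.random.default_rng(
        truth.seed + 1_000_003 if noise_seed is None else noise_seed
    )

    def noisy(value: float, rel: float) -> float:
        if noise_scale == 0.0 or rel == 0.0:
            return value
        draw = rng.normal(value, noise_scale * rel * value)
        while draw < 0:
            draw = rng.normal(value, noise_scale * rel * value)
        return draw

    scenario = truth.scenario()
    steady = truth.steady_state()
    state = simulate(
        ModelParams(x=truth.x_true, z0_cm=cfg.z0_cm), steady, scenario
    )
    s36 = state.stock_at(Species.CL36, cfg.stock_year)
    s_cl = steady.s_cl

    b = np.array(cfg.boundaries_cm)
    layers = []
    for k in range(truth.n_layers):
        rho, d = cfg.bulk_density[k], b[k + 1] - b[k]
        conc_cl = s_cl[k] / (rho * d * 1e4)
        conc_36 = s36[k] / (rho * d * 1e4)
        layers.append(
            SoilLayer(
                index=k + 1,
                top_cm=float(b[k]),
                bottom_cm=float(b[k + 1]),
                bulk_density=Measurement(noisy(rho, cfg.rel_sigma_bd), cfg.rel_sigma_bd),
                concentrations={
                    Species.CL: Measurement(
                        noisy(conc_cl, cfg.rel_sigma_conc), cfg.rel_sigma_conc
                    ),
                    Species.CL36: Measurement(
                        noisy(conc_36, cfg.rel_sigma_conc), cfg.rel_sigma_conc
                    ),
                },
                soc_concentration=truth.soc[k],
                thickness_rel_sigma=cfg.rel_sigma_thickness,
            )
        )

    # carrier amounts are shared per component; concentrations per species
    fluxes: list[AnnualFlux] = []

    def add_water_flux(
        comp: FluxComponent, carrier: float, carrier_rel: float,
        flux36: float, flux_cl: float,
    ) -> None:
        carrier_obs = noisy(carrier, carrier_rel)
        for sp, f in ((Species.CL36, flux36), (Species.CL, flux_cl)):
            conc = noisy(f / carrier, cfg.rel_sigma_conc)
            fluxes.append(
                AnnualFlux(
                    component=comp,
                    species=sp,
                    carrier=Measurement(carrier_obs, carrier_rel),
                    concentration=Measurement(conc, cfg.rel_sigma_conc),
                    year=cfg.flux_year,
                )
            )

    add_water_flux(
        FluxComponent.RAINFALL, cfg.rain_carrier, cfg.rel_sigma_rain,
        cfg.background_cl36, cfg.background_cl,
    )
    # throughfall equals rainfall at this kind of site (canopy adds nothing)
    add_water_flux(
        FluxComponent.THROUGHFALL, cfg.rain_carrier, cfg.rel_sigma_rain,
        cfg.background_cl36, cfg.background_cl,
    )
    add_water_flux(
        FluxComponent.LITTERFALL, cfg.litter_carrier, cfg.rel_sigma_litter,
        cfg.litterfall_fraction * cfg.background_cl36,
        cfg.litterfall_fraction * cfg.background_cl,
    )
    d36 = state.drainage[Species.CL36][-1, state.years.tolist().index(cfg.flux_year)]
    dcl = state.drainage[Species.CL][-1, state.years.tolist().index(cfg.flux_year)]
    add_water_flux(
        FluxComponent.DRAINAGE, cfg.drainage_carrier, cfg.rel_sigma_drainage, d36, dcl
    )

    dataset = SiteDataset(
        layers, fluxes, stock_year=cfg.stock_year, flux_year=cfg.flux_year
    )
    return dataset, scenario


def write_site(
    truth: SyntheticTruth,
    out_dir: str | Path,
    noise_seed: int | None = None,
    noise_scale: float = 1.0,
) -> dict[str, Path]:
    """Emit layers.csv, fluxes.csv, forcing.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, scenario = gen_observations(truth, noise_seed, noise_scale)
    paths = {
        "layers": out / "layers.csv",
        "fluxes": out / "fluxes.csv",
        "forcing": out / "forcing.csv",
        "truth": out / "truth.json",
    }
    write_site_tables(dataset, paths["layers"], paths["fluxes"])
    write_forcing_table(scenario, paths["forcing"])
    paths["truth"].write_text(truth.to_json())
    return paths


def score_recovery(truth: SyntheticTruth, summary) -> pd.DataFrame:
    """Per-layer bias/coverage report of a posterior against the truth."""
    table = summary.table if hasattr(summary, "table") else summary
    if len(table) != truth.n_layers:
        raise ValidationError(
            f"posterior has {len(table)} layers, truth has {truth.n_layers}"
        )
    rows = []
    for k in range(truth.n_layers):
        row = table.iloc[k]
        sd = row["x_sd"] if row["x_sd"] > 0 else np.nan
        rows.append(
            {
                "layer": k + 1,
                "x_true": truth.x_true[k],
                "x_mean": row["x_mean"],
                "x_sd": row["x_sd"],
                "z_score": (row["x_mean"] - truth.x_true[k]) / sd,
                "covered_95": bool(
                    row["x_q025"] <= truth.x_true[k] <= row["x_q975"]
                ),
                "tprime_true": truth.t_prime_true[k],
                "tprime_median": row["tprime_median"],
                "tprime_ratio": row["tprime_median"] / truth.t_prime_true[k],
            }
        )
    return pd.DataFrame(rows)
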