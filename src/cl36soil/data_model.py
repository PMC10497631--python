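"""Domain types, tabular I/O, and stock/flux arithmetic with uncertainty.

All quantities follow a fixed unit convention:

========================  =============================
quantity                  unit
========================  =============================
depth                     cm (intervals are [top, bottom), surface = 0)
bulk density              g cm⁻³
soil concentration        atoms per g dry soil
stock                     atoms m⁻²
flux                      atoms m⁻² yr⁻¹
carrier amount            L m⁻² yr⁻¹ (water) or g m⁻² yr⁻¹ (litter)
SOC concentration         g C per kg soil
========================  =============================

A stock is ``S = C · ρ · d · 10⁴`` (the 10⁴ converts cm² to m²); a flux is
``F = C · Φ``.  Uncertainties are stored as relative 1σ and combined in
quadrature for products and quotients (first-order propagation), which covers
every quantity in this model — all are products of measured factors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "FluxComponent",
    "Measurement",
    "SoilLayer",
    "LayerStock",
    "AnnualFlux",
    "SiteDataset",
    "ValidationError",
    "ParseError",
    "propagate_uncertainty",
    "compute_stock",
    "compute_flux",
    "ratio_profile",
    "read_site_tables",
    "write_site_tables",
]


class ValidationError(ValueError):
    """A domain invariant was violated; the message names the offending field."""


class ParseError(ValueError):
    """A table could not be interpreted; the message names the row/column."""


class Species(enum.Enum):
    """The two chlorine species tracked by the model."""

    CL = "Cl"
    CL36 = "Cl36"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FluxComponent(enum.Enum):
    RAINFALL = "rainfall"
    THROUGHFALL = "throughfall"
    LITTERFALL = "litterfall"
    DRAINAGE = "drainage"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def propagate_uncertainty(rel_sigmas: Iterable[float]) -> float:
    """Combine relative 1σ uncertainties of multiplicative factors.

    Classical first-order propagation for a product/quotient: the relative
    variance of the result is the sum of the relative variances of the
    factors, so the relative σ is the root-sum-of-squares.

    Parameters
    ----------
    rel_sigmas
        Relative 1σ values, all ≥ 0.

    Returns
    -------
    float
        ``sqrt(sum(s_i**2))``.
    """
    sigmas = list(rel_sigmas)
    for s in sigmas:
        if s < 0:
            raise ValidationError(f"relative uncertainty must be >= 0, got {s}")
    return math.sqrt(sum(s * s for s in sigmas))


@dataclass(frozen=True)
class Measurement:
    """A non-negative measured value with a relative 1σ uncertainty."""

    value: float
    rel_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(f"measurement value must be >= 0, got {self.value}")
        if self.rel_sigma < 0:
            raise ValidationError(f"rel_sigma must be >= 0, got {self.rel_sigma}")

    @property
    def sigma(self) -> float:
        """Absolute 1σ = value × rel_sigma."""
        return self.value * self.rel_sigma

    def times(self, *others: "Measurement") -> "Measurement":
        """Product with quadrature-combined relative uncertainty."""
        value = self.value
        rels = [self.rel_sigma]
        for m in others:
            value *= m.value
            rels.append(m.rel_sigma)
        return Measurement(value, propagate_uncertainty(rels))

    def scaled(self, factor: float) -> "Measurement":
        """Multiply by an exact (uncertainty-free) factor ≥ 0."""
        return Measurement(self.value * factor, self.rel_sigma)

    def ratio(self, denom: "Measurement") -> "Measurement":
        """Quotient with quadrature-combined relative uncertainty."""
        if denom.value == 0:
            raise ValidationError("ratio undefined: zero denominator")
        return Measurement(
            self.value / denom.value,
            propagate_uncertainty([self.rel_sigma, denom.rel_sigma]),
        )


# Stated measurement-uncertainty percentages for this kind of monitoring data.
DEFAULT_REL_SIGMA = {
    "bulk_density": 0.05,
    "thickness": 0.10,
    "litterfall_mass": 0.10,
    "drainage_volume": 0.10,
    "rainfall": 0.03,
}


@dataclass(frozen=True)
class SoilLayer:
    """One depth interval of the profile with its measured properties.

    ``concentrations`` maps each :class:`Species` to atoms per g of dry soil.
    ``soc_concentration`` is g C per kg soil (diagnostic; not a model input).
    """

    index: int
    top_cm: float
    bottom_cm: float
    bulk_density: Measurement
    concentrations: dict[Species, Measurement]
    soc_concentration: float = float("nan")
    thickness_rel_sigma: float = DEFAULT_REL_SIGMA["thickness"]

    def __post_init__(self) -> None:
        if self.top_cm < 0:
            raise ValidationError(f"layer {self.index}: top_cm must be >= 0")
        if self.bottom_cm <= self.top_cm:
            raise ValidationError(
                f"layer {self.index}: bottom_cm ({self.bottom_cm}) must exceed "
                f"top_cm ({self.top_cm})"
            )
        if self.bulk_density.value <= 0:
            raise ValidationError(f"layer {self.index}: bulk_density must be > 0")

    @property
    def thickness(self) -> Measurement:
        return Measurement(self.bottom_cm - self.top_cm, self.thickness_rel_sigma)

    @property
    def mid_depth_cm(self) -> float:
        return 0.5 * (self.top_cm + self.bottom_cm)

    def concentration(self, species: Species) -> Measurement:
        try:
            return self.concentrations[species]
        except KeyError:
            raise ValidationError(
                f"layer {self.index}: no {species.value} concentration"
            ) from None


@dataclass(frozen=True)
class LayerStock:
    """Per-layer inventory of one species, atoms m⁻²."""

    layer_index: int
    species: Species
    stock: Measurement


@dataclass(frozen=True)
class AnnualFlux:
    """An annual input/output flux: concentration × carrier amount.

    The carrier is litres of water (rainfall, throughfall, drainage) or grams
    of dry litter (litterfall); the concentration is atoms per carrier unit.
    """

    component: FluxComponent
    species: Species
    carrier: Measurement
    concentration: Measurement
    year: int

    @property
    def flux(self) -> Measurement:
        """F = C · Φ, atoms m⁻² yr⁻¹."""
        return compute_flux(self.concentration, self.carrier)


def compute_stock(layer: SoilLayer, species: Species) -> LayerStock:
    """Layer inventory S = C · ρ · d · 10⁴ (atoms m⁻²).

    C is atoms g⁻¹, ρ g cm⁻³, d cm; the 10⁴ converts the per-cm² column to
    per m².  The relative uncertainty combines the concentration, density and
    thickness uncertainties in quadrature.
    """
    conc = layer.concentration(species)
    stock = conc.times(layer.bulk_density, layer.thickness).scaled(1.0e4)
    return LayerStock(layer.index, species, stock)


def compute_flux(concentration: Measurement, carrier: Measurement) -> Measurement:
    """Annual flux F = C · Φ (atoms m⁻² yr⁻¹) with propagated uncertainty."""
    return concentration.times(carrier)


@dataclass
class SiteDataset:
    """One site: an ordered soil profile plus its annual flux measurements."""

    layers: list[SoilLayer]
    fluxes: list[AnnualFlux]
    stock_year: int = 2010
    flux_year: int = 2012

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.layers:
            raise ValidationError("dataset has no soil layers")
        ordered = sorted(self.layers, key=lambda l: l.top_cm)
        for upper, lower in zip(ordered, ordered[1:]):
            if lower.top_cm < upper.bottom_cm:
                raise ValidationError(
                    f"layers {upper.index} and {lower.index} overlap: "
                    f"[{upper.top_cm}, {upper.bottom_cm}) vs "
                    f"[{lower.top_cm}, {lower.bottom_cm})"
                )
            if lower.top_cm > upper.bottom_cm:
                raise ValidationError(
                    f"layers {upper.index} and {lower.index} are not contiguous: "
                    f"gap between {upper.bottom_cm} and {lower.top_cm} cm"
                )
        self.layers = ordered
        for sp in Species:
            for comp in (FluxComponent.RAINFALL, FluxComponent.LITTERFALL):
                if self.get_flux(comp, sp, default=None) is None:
                    raise ValidationError(
                        f"missing {comp.value} flux for species {sp.value}"
                    )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def boundaries_cm(self) -> np.ndarray:
        """Depth boundaries [z_0=top, ..., z_K=bottom] in cm."""
        return np.array(
            [self.layers[0].top_cm] + [l.bottom_cm for l in self.layers]
        )

    def get_flux(
        self,
        component: FluxComponent,
        species: Species,
        default: object = "raise",
    ) -> AnnualFlux | None:
        for f in self.fluxes:
            if f.component == component and f.species == species:
                return f
        if default == "raise":
            raise ValidationError(
                f"no {component.value} flux for species {species.value}"
            )
        return default  # type: ignore[return-value]

    def stocks(self, species: Species) -> list[LayerStock]:
        return [compute_stock(l, species) for l in self.layers]

    def stock_values(self, species: Species) -> np.ndarray:
        return np.array([s.stock.value for s in self.stocks(species)])

    def soc_values(self) -> np.ndarray:
        return np.array([l.soc_concentration for l in self.layers])


def ratio_profile(dataset: SiteDataset) -> pd.DataFrame:
    """³⁶Cl/Cl ratios for every layer stock and every flux component.

    Returns a frame with one row per item (``kind`` is ``stock`` or ``flux``)
    and an ``enrichment`` column: the item's ratio divided by the rainfall
    flux ratio.  Soil enrichment > 1 is the bomb-pulse fingerprint — the
    multi-annual soil pool still carries ³⁶Cl deposited at rates far above
    today's background.
    """
    rain36 = dataset.get_flux(FluxComponent.RAINFALL, Species.CL36).flux
    rain_cl = dataset.get_flux(FluxComponent.RAINFALL, Species.CL).flux
    if rain_cl.value == 0:
        raise ValidationError("rainfall Cl flux is zero: ratios undefined")
    rain_ratio = rain36.ratio(rain_cl)

    rows = []
    for layer in dataset.layers:
        s36 = compute_stock(layer, Species.CL36).stock
        scl = compute_stock(layer, Species.CL).stock
        if scl.value == 0:
            raise ValidationError(
                f"layer {layer.index}: zero Cl stock, ratio undefined"
            )
        r = s36.ratio(scl)
        rows.append(
            {
                "kind": "stock",
                "label": f"layer_{layer.index}",
                "ratio": r.value,
                "rel_sigma": r.rel_sigma,
                "enrichment": r.value / rain_ratio.value,
            }
        )
    seen: set[FluxComponent] = set()
    for f in dataset.fluxes:
        if f.component in seen:
            continue
        pair36 = dataset.get_flux(f.component, Species.CL36, default=None)
        pair_cl = dataset.get_flux(f.component, Species.CL, default=None)
        if pair36 is None or pair_cl is None:
            continue
        seen.add(f.component)
        if pair_cl.flux.value == 0:
            raise ValidationError(
                f"{f.component.value}: zero Cl flux, ratio undefined"
            )
        r = pair36.flux.ratio(pair_cl.flux)
        rows.append(
            {
                "kind": "flux",
                "label": f.component.value,
                "ratio": r.value,
                "rel_sigma": r.rel_sigma,
                "enrichment": r.value / rain_ratio.value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular I/O
#
# Both tables are plain CSV with a mandatory units line (`# units: ...`)
# preceding the header, so a file can never be mis-read in the wrong unit
# system silently.

LAYER_COLUMNS = [
    "k",
    "top_cm",
    "bottom_cm",
    "thickness_rel_sigma",
    "bulk_density",
    "bd_rel_sigma",
    "soc_conc",
    "cl_conc",
    "cl_rel_sigma",
    "cl36_conc",
    "cl36_rel_sigma",
]
LAYER_UNITS = (
    "# units: k=-, top_cm=cm, bottom_cm=cm, thickness_rel_sigma=-, "
    "bulk_density=g.cm-3, bd_rel_sigma=-, soc_conc=gC.kg-1, "
    "cl_conc=at.g-1, cl_rel_sigma=-, cl36_conc=at.g-1, cl36_rel_sigma=-"
)

FLUX_COLUMNS = [
    "component",
    "species",
    "year",
    "carrier_amount",
    "carrier_rel_sigma",
    "concentration",
    "conc_rel_sigma",
]
FLUX_UNITS = (
    "# units: component=-, species=-, year=yr, "
    "carrier_amount=L.m-2.yr-1|g.m-2.yr-1, carrier_rel_sigma=-, "
    "concentration=at.L-1|at.g-1, conc_rel_sigma=-"
)


def _read_units_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    text = path.read_text().splitlines()
    if not any(line.startswith("# units:") for line in text[:2]):
        raise ParseError(f"{path}: missing mandatory '# units:' header line")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def read_site_tables(
    layers_path: str | Path,
    fluxes_path: str | Path,
    stock_year: int = 2010,
) -> SiteDataset:
    """Read ``layers.csv`` and ``fluxes.csv`` into a validated dataset."""
    layers_path, fluxes_path = Path(layers_path), Path(fluxes_path)
    ldf = _read_units_csv(layers_path, LAYER_COLUMNS)
    layers = []
    for i, row in ldf.iterrows():
        try:
            layers.append(
                SoilLayer(
                    index=int(row["k"]),
                    top_cm=float(row["top_cm"]),
                    bottom_cm=float(row["bottom_cm"]),
                    bulk_density=Measurement(
                        float(row["bulk_density"]), float(row["bd_rel_sigma"])
                    ),
                    concentrations={
                        Species.CL: Measurement(
                            float(row["cl_conc"]), float(row["cl_rel_sigma"])
                        ),
                        Species.CL36: Measurement(
                            float(row["cl36_conc"]), float(row["cl36_rel_sigma"])
                        ),
                    },
                    soc_concentration=float(row["soc_conc"]),
                    thickness_rel_sigma=float(row["thickness_rel_sigma"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{layers_path} row {i + 1}: {exc}") from exc

    fdf = _read_units_csv(fluxes_path, FLUX_COLUMNS)
    fluxes = []
    flux_years = set()
    for i, row in fdf.iterrows():
        try:
            comp = FluxComponent(str(row["component"]))
            sp = Species(str(row["species"]))
            fluxes.append(
                AnnualFlux(
                    component=comp,
                    species=sp,
                    carrier=Measurement(
                        float(row["carrier_amount"]),
                        float(row["carrier_rel_sigma"]),
                    ),
                    concentration=Measurement(
                        float(row["concentration"]), float(row["conc_rel_sigma"])
                    ),
                    year=int(row["year"]),
                )
            )
            flux_years.add(int(row["year"]))
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{fluxes_path} row {i + 1}: {exc}") from exc
    flux_year = min(flux_years) if flux_years else stock_year
    try:
        return SiteDataset(layers, fluxes, stock_year=stock_year, flux_year=flux_year)
    except ValidationError as exc:
        raise ParseError(f"{layers_path}/{fluxes_path}: {exc}") from exc


def write_site_tables(
    dataset: SiteDataset,
    layers_path: str | Path,
    fluxes_path: str | Path,
) -> None:
    """Write the dataset back out; ``read_site_tables`` round-trips it."""
    layers_path, fluxes_path = Path(layers_path), Path(fluxes_path)
    lrows = []
    for l in dataset.layers:
        lrows.append(
            {
                "k": l.index,
                "top_cm": l.top_cm,
                "bottom_cm": l.bottom_cm,
                "thickness_rel_sigma": l.thickness_rel_sigma,
                "bulk_density": l.bulk_density.value,
                "bd_rel_sigma": l.bulk_density.rel_sigma,
                "soc_conc": l.soc_concentration,
                "cl_conc": l.concentrations[Species.CL].value,
                "cl_rel_sigma": l.concentrations[Species.CL].rel_sigma,
                "cl36_conc": l.concentrations[Species.CL36].value,
                "cl36_rel_sigma": l.concentrations[Species.CL36].rel_sigma,
            }
        )
    with open(layers_path, "w") as fh:
        fh.write(LAYER_UNITS + "\n")
        pd.DataFrame(lrows, columns=LAYER_COLUMNS).to_csv(
            fh, index=False, float_format="%.12g"
        )

    frows = []
    for f in dataset.fluxes:
        frows.append(
            {
                "component": f.component.value,
                "species": f.species.value,
                "year": f.year,
                "carrier_amount": f.carrier.value,
                "carrier_rel_sigma": f.carrier.rel_sigma,
                "concentration": f.concentration.value,
                "conc_rel_sigma": f.concentration.rel_sigma,
            }
        )
    with open(fluxes_path, "w") as fh:
        fh.write(FLUX_UNITS + "\n")
        pd.DataFrame(frows, columns=FLUX_COLUMNS).to_csv(
            fh, index=False, float_format="%.12g"
        )
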