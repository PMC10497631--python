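"""Monte-Carlo rejection inference of the retained fractions X_k.

The only free parameter of the mass balance is the per-layer retained
fraction X_k.  It is inferred ABC-style: draw X_k from a uniform prior on
[0, 1], perturb every measured quantity (stocks, densities, thicknesses,
concentrations, carrier amounts) with a zero-truncated normal at its stated
1σ, run the forward model from the pre-bomb steady state to the stock
sampling year, and accept the draw when the simulated ³⁶Cl stock falls
within ``m × σ`` of the (perturbed) measured stock — measurement
uncertainty is the acceptance kernel.

Because a layer's input is the drainage of the layer above, layers are
fitted top-down: stage k draws its upstream X's from the accepted
(lowest-branch) sets of earlier stages, so downstream posteriors inherit
upstream uncertainty without the geometric acceptance-rate collapse of
joint rejection.  A ``joint`` mode (accept only when every layer fits
simultaneously) exists for cross-checks on small profiles.

The stock-vs-X response can cross the measured value twice (a small X that
keeps the bomb spike for decades, or a large X that grabs more of it but
flushes it quickly), so accepted sets may be bimodal; the physically
indicated solution — measured input/output fluxes show only a few percent
retained — is the lowest branch, selected by a first-gap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    FluxComponent,
    SiteDataset,
    Species,
    ValidationError,
)
from .forcing import PulseShape, build_forcing
from .massbalance import (
    DEFAULT_ROOT_EFOLDING_CM,
    root_absorption_weights,
    simulate_cl36_ensemble,
)

__all__ = [
    "MCConfig",
    "PosteriorSample",
    "PosteriorSummary",
    "BranchSelection",
    "InferenceError",
    "run_mc",
    "select_lowest_branch",
    "summarize_posteriors",
    "soc_correlation",
    "age_agreement",
]


class InferenceError(RuntimeError):
    """Raised when inference cannot produce a posterior; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class MCConfig:
    """Settings of the rejection run."""

    n_simulations: int = 10_000
    seed: int = 0
    #: acceptance half-width in units of the measured stock's 1σ
    tolerance: float = 1.0
    #: minimum X-gap that splits accepted draws into branches
    gap_threshold: float = 0.05
    #: fewer accepted draws than this flags the summary "insufficient"
    min_draws: int = 30
    mode: str = "sequential"  # or "joint"
    absorption_mode: str = "mobile"  # or "rainfall"
    start_year: int = 1940
    z0_cm: float = DEFAULT_ROOT_EFOLDING_CM

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValidationError("n_simulations must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("tolerance multiplier must be > 0")
        if self.mode not in ("sequential", "joint"):
            raise ValidationError(f"unknown MC mode {self.mode!r}")


@dataclass
class PosteriorSample:
    """Accepted draws per layer, with their per-draw derived quantities.

    ``x[k]``, ``t_r[k]``, ``z[k]`` and ``t_prime[k]`` are aligned arrays for
    layer k (0-based); every stored draw satisfied the acceptance rule, and
    Z = X/T_R, T′ = T_R/X hold exactly per draw.
    """

    x: list[np.ndarray]
    t_r: list[np.ndarray]
    z: list[np.ndarray]
    t_prime: list[np.ndarray]
    n_simulations: int
    acceptance_counts: np.ndarray
    infeasible_counts: np.ndarray
    config: MCConfig

    @property
    def n_layers(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BranchSelection:
    """Result of the lowest-branch rule: a mask plus diagnostics."""

    mask: np.ndarray
    n_branches: int
    gap_positions: tuple[float, ...]

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def select_lowest_branch(
    x_draws: np.ndarray, gap_threshold: float = 0.05
) -> BranchSelection:
    """Keep the lowest contiguous cluster of accepted X draws.

    Draws are sorted and split at every gap wider than ``gap_threshold``
    (in X units); the mask selects members of the lowest cluster.  Unimodal
    sets pass through unchanged.
    """
    x_draws = np.asarray(x_draws, dtype=float)
    if x_draws.size == 0:
        raise ValidationError("cannot select a branch from an empty set")
    order = np.argsort(x_draws)
    xs = x_draws[order]
    gaps = np.diff(xs)
    split_idx = np.nonzero(gaps > gap_threshold)[0]
    n_branches = split_idx.size + 1
    cutoff = xs[split_idx[0]] if split_idx.size else np.inf
    mask = x_draws <= cutoff
    gap_positions = tuple(
        float(0.5 * (xs[i] + xs[i + 1])) for i in split_idx
    )
    return BranchSelection(mask=mask, n_branches=n_branches, gap_positions=gap_positions)


# ---------------------------------------------------------------------------
# Perturbation machinery


def _tn_factors(rng: np.random.Generator, rel, size) -> np.ndarray:
    """Multiplicative factors ~ Normal(1, rel) truncated at zero."""
    rel = np.broadcast_to(np.asarray(rel, dtype=float), size)
    f = rng.normal(1.0, rel)
    bad = f < 0
    while bad.any():
        f = np.where(bad, rng.normal(1.0, rel), f)
        bad = f < 0
    return f


@dataclass
class _ReplicateDraws:
    """Per-replicate perturbed inputs for the ensemble simulator."""

    s36_obs: np.ndarray  # (n, K) perturbed measured 36Cl stocks
    s_cl: np.ndarray  # (n, K) perturbed Cl stocks
    t_r: np.ndarray  # (n, K)
    i_cl: np.ndarray  # (n, K)
    a_cl: np.ndarray  # (n, K)
    rain36: np.ndarray  # (n, T)
    litter36: np.ndarray  # (n, T)
    rain_ratio: np.ndarray  # (n, T) rainfall 36Cl/Cl


def _perturb_replicates(
    dataset: SiteDataset,
    n: int,
    rng: np.random.Generator,
    shape36: np.ndarray,
    weights: np.ndarray,
) -> _ReplicateDraws:
    layers = dataset.layers
    n_layers = len(layers)

    rho = np.array([l.bulk_density.value for l in layers])
    rho_rel = np.array([l.bulk_density.rel_sigma for l in layers])
    d = np.array([l.thickness.value for l in layers])
    d_rel = np.array([l.thickness.rel_sigma for l in layers])
    c_cl = np.array([l.concentrations[Species.CL].value for l in layers])
    c_cl_rel = np.array([l.concentrations[Species.CL].rel_sigma for l in layers])
    c_36 = np.array([l.concentrations[Species.CL36].value for l in layers])
    c_36_rel = np.array([l.concentrations[Species.CL36].rel_sigma for l in layers])

    rho_f = _tn_factors(rng, rho_rel, (n, n_layers))
    d_f = _tn_factors(rng, d_rel, (n, n_layers))
    ccl_f = _tn_factors(rng, c_cl_rel, (n, n_layers))
    c36_f = _tn_factors(rng, c_36_rel, (n, n_layers))

    # the same physical ρ and d perturbations hit both species' stocks
    s_cl = (c_cl * rho * d * 1e4) * rho_f * d_f * ccl_f
    s36_obs = (c_36 * rho * d * 1e4) * rho_f * d_f * c36_f

    def flux_draws(comp: FluxComponent) -> tuple[np.ndarray, np.ndarray]:
        f_cl = dataset.get_flux(comp, Species.CL)
        f_36 = dataset.get_flux(comp, Species.CL36)
        carrier_f = _tn_factors(rng, f_cl.carrier.rel_sigma, (n,))
        cl = f_cl.flux.value * carrier_f * _tn_factors(
            rng, f_cl.concentration.rel_sigma, (n,)
        )
        c36 = f_36.flux.value * carrier_f * _tn_factors(
            rng, f_36.concentration.rel_sigma, (n,)
        )
        return cl, c36

    r_cl, r_36 = flux_draws(FluxComponent.RAINFALL)
    l_cl, l_36 = flux_draws(FluxComponent.LITTERFALL)

    a_cl = weights[None, :] * l_cl[:, None]
    top = (r_cl + l_cl)[:, None]
    a_cum = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(a_cl[:, :-1], axis=1)], axis=1
    )
    i_cl = top - a_cum
    t_r = s_cl / i_cl

    rain36 = r_36[:, None] * shape36[None, :]
    lam36 = (l_36 / r_36)[:, None]
    litter36 = lam36 * rain36
    rain_ratio = rain36 / r_cl[:, None]
    return _ReplicateDraws(
        s36_obs=s36_obs,
        s_cl=s_cl,
        t_r=t_r,
        i_cl=i_cl,
        a_cl=a_cl,
        rain36=rain36,
        litter36=litter36,
        rain_ratio=rain_ratio,
    )


def run_mc(
    dataset: SiteDataset,
    pulse: PulseShape | None = None,
    config: MCConfig | None = None,
) -> PosteriorSample:
    """Rejection-sample the per-layer retained fractions X_k.

    Each replicate re-perturbs every measured quantity, rebuilds the derived
    state (stocks, cascade, residence times, pre-bomb initialization),
    draws X ~ U(0, 1), simulates ³⁶Cl from ``config.start_year`` to the
    stock year, and accepts when the simulated stock is within
    ``tolerance × σ`` of the measured one.  Draws whose implied release
    fraction exceeds 1 (Z = X/T_R > 1) are infeasible and counted, never
    accepted.

    Raises :class:`InferenceError` with nearest-miss diagnostics if a layer
    ends with zero acceptances.
    """
    pulse = pulse if pulse is not None else PulseShape()
    config = config if config is not None else MCConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_simulations
    n_layers = dataset.n_layers

    # unit-background pulse shape, start year -> stock year
    unit = build_forcing(
        {Species.CL36: 1.0, Species.CL: 1.0},
        pulse=pulse,
        start_year=config.start_year,
        end_year=dataset.stock_year,
    )
    shape36 = unit.rainfall[Species.CL36]
    n_years = shape36.size
    weights = root_absorption_weights(dataset.boundaries_cm(), config.z0_cm)

    # acceptance half-width: the measured stock's propagated 1σ (fixed, not
    # re-perturbed, so the kernel width is the measurement uncertainty)
    sigma_obs = np.array(
        [s.stock.sigma for s in dataset.stocks(Species.CL36)]
    )
    if np.any(sigma_obs <= 0):
        raise ValidationError(
            "measured 36Cl stocks need a positive uncertainty for acceptance"
        )

    x_acc: list[np.ndarray] = []
    tr_acc: list[np.ndarray] = []
    z_acc: list[np.ndarray] = []
    tp_acc: list[np.ndarray] = []
    counts = np.zeros(n_layers, dtype=int)
    infeasible = np.zeros(n_layers, dtype=int)

    if config.mode == "joint":
        rep = _perturb_replicates(dataset, n, rng, shape36, weights)
        x = rng.uniform(0.0, 1.0, size=(n, n_layers))
        feasible = np.all(x / rep.t_r <= 1.0, axis=1)
        infeasible[:] = int(np.count_nonzero(~feasible))
        idx = np.nonzero(feasible)[0]
        s_sim = np.full((n, n_layers), np.nan)
        s_sim[idx], _ = simulate_cl36_ensemble(
            x[idx],
            rep.t_r[idx],
            rep.i_cl[idx],
            rep.a_cl[idx],
            rep.rain36[idx],
            rep.litter36[idx],
            absorption_mode=config.absorption_mode,
            rain_ratio=rep.rain_ratio[idx],
        )
        dist = np.abs(s_sim - rep.s36_obs) / sigma_obs[None, :]
        ok = np.all(dist <= config.tolerance, axis=1) & feasible
        if not ok.any():
            worst = dist[idx].max(axis=1) if idx.size else np.array([np.inf])
            raise InferenceError(
                "joint rejection accepted nothing",
                diagnostics={"nearest_miss_sigma": float(worst.min())},
            )
        for k in range(n_layers):
            x_acc.append(x[ok, k])
            tr_acc.append(rep.t_r[ok, k])
            z_acc.append(x[ok, k] / rep.t_r[ok, k])
            tp_acc.append(rep.t_r[ok, k] / x[ok, k])
            counts[k] = int(ok.sum())
        return PosteriorSample(
            x_acc, tr_acc, z_acc, tp_acc, n, counts, infeasible, config
        )

    # sequential top-down: stage k conditions on accepted upstream draws
    upstream: np.ndarray | None = None  # accepted joint rows (n_acc, k)
    for k in range(n_layers):
        rep = _perturb_replicates(dataset, n, rng, shape36, weights)
        x = np.empty((n, k + 1))
        if k > 0:
            pick = rng.integers(0, upstream.shape[0], size=n)
            x[:, :k] = upstream[pick]
        x[:, k] = rng.uniform(0.0, 1.0, size=n)
        t_r = rep.t_r[:, : k + 1]
        feasible = np.all(x / t_r <= 1.0, axis=1)
        infeasible[k] = int(np.count_nonzero(~feasible))
        idx = np.nonzero(feasible)[0]
        if idx.size == 0:
            raise InferenceError(
                f"layer {k + 1}: every draw infeasible (Z > 1); "
                "check Cl stocks vs input fluxes"
            )
        s_sim, _ = simulate_cl36_ensemble(
            x[idx],
            t_r[idx],
            rep.i_cl[idx, : k + 1],
            rep.a_cl[idx, : k + 1],
            rep.rain36[idx],
            rep.litter36[idx],
            absorption_mode=config.absorption_mode,
            rain_ratio=rep.rain_ratio[idx],
        )
        dist = np.abs(s_sim[:, k] - rep.s36_obs[idx, k]) / sigma_obs[k]
        ok = dist <= config.tolerance
        if not ok.any():
            raise InferenceError(
                f"layer {k + 1}: zero acceptances in {n} replicates",
                diagnostics={
                    "layer": k + 1,
                    "nearest_miss_sigma": float(dist.min()),
                    "feasible_fraction": idx.size / n,
                },
            )
        acc = idx[ok]
        counts[k] = int(acc.size)
        x_acc.append(x[acc, k])
        tr_acc.append(rep.t_r[acc, k])
        z_acc.append(x[acc, k] / rep.t_r[acc, k])
        tp_acc.append(rep.t_r[acc, k] / x[acc, k])

        # downstream stages condition on the adopted (lowest-branch) solution
        sel = select_lowest_branch(x[acc, k], config.gap_threshold)
        upstream = x[acc][sel.mask][:, : k + 1]

    return PosteriorSample(x_acc, tr_acc, z_acc, tp_acc, n, counts, infeasible, config)


@dataclass
class PosteriorSummary:
    """Per-layer posterior summaries on the selected (lowest) branch."""

    table: pd.DataFrame

    def __getitem__(self, column: str):
        return self.table[column]


def summarize_posteriors(
    sample: PosteriorSample,
    gap_threshold: float | None = None,
    min_draws: int | None = None,
) -> PosteriorSummary:
    """Normal fit for X, log-normal fit for the retention duration T′.

    X is summarized by its branch mean ± sd; T′ by the log-normal implied
    median ``exp(μ_log)`` and 16–84% interval ``exp(μ_log ± σ_log)``; raw
    quantiles are reported alongside for model-free use.  Layers with fewer
    accepted draws than ``min_draws`` are flagged ``insufficient``.
    """
    gap = sample.config.gap_threshold if gap_threshold is None else gap_threshold
    floor = sample.config.min_draws if min_draws is None else min_draws
    rows = []
    for k in range(sample.n_layers):
        sel = select_lowest_branch(sample.x[k], gap)
        x = sample.x[k][sel.mask]
        tp = sample.t_prime[k][sel.mask]
        logtp = np.log(tp)
        mu = float(np.mean(logtp))
        sd = float(np.std(logtp, ddof=1)) if x.size > 1 else 0.0
        rows.append(
            {
                "layer": k + 1,
                "n_accepted": int(sample.x[k].size),
                "n_branch": int(x.size),
                "n_branches": sel.n_branches,
                "gap_positions": sel.gap_positions,
                "insufficient": bool(x.size < floor),
                "x_mean": float(np.mean(x)),
                "x_sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "x_q025": float(np.quantile(x, 0.025)),
                "x_median": float(np.median(x)),
                "x_q975": float(np.quantile(x, 0.975)),
                "tprime_median": float(np.exp(mu)),
                "tprime_lo16": float(np.exp(mu - sd)),
                "tprime_hi84": float(np.exp(mu + sd)),
                "tprime_raw_median": float(np.median(tp)),
                "tprime_raw_q16": float(np.quantile(tp, 0.16)),
                "tprime_raw_q84": float(np.quantile(tp, 0.84)),
            }
        )
    return PosteriorSummary(pd.DataFrame(rows))


def soc_correlation(x_means: np.ndarray, soc: np.ndarray):
    """OLS of the retained fraction on SOC concentration.

    A tight linear relation is the signature that organically-fixed chlorine
    tracks soil organic matter.  Returns the scipy linregress result
    (slope, intercept, rvalue, pvalue, stderr).
    """
    x_means = np.asarray(x_means, dtype=float)
    soc = np.asarray(soc, dtype=float)
    if x_means.size < 3:
        raise ValidationError("need at least 3 layers for a correlation")
    if np.ptp(soc) == 0:
        raise ValidationError("SOC is constant across layers: correlation undefined")
    return stats.linregress(soc, x_means)


def age_agreement(
    durations: pd.DataFrame, ages: pd.DataFrame
) -> dict[str, float | np.ndarray]:
    """Depth-matched comparison of retention durations with external SOC ages.

    Both frames need ``top_cm``, ``bottom_cm`` and ``value`` columns; rows
    are matched on exact depth intervals.  Purely a reporting utility — the
    external ages come from independent literature methods, not this model.
    """
    required = {"top_cm", "bottom_cm", "value"}
    for name, df in (("durations", durations), ("ages", ages)):
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"{name} table missing columns {sorted(missing)}")
    merged = durations.merge(
        ages, on=["top_cm", "bottom_cm"], suffixes=("_dur", "_age"), how="outer",
        indicator=True,
    )
    unmatched = merged[merged["_merge"] != "both"]
    if not unmatched.empty:
        bad = unmatched[["top_cm", "bottom_cm"]].to_dict("records")
        raise ValidationError(f"unmatched depth intervals: {bad}")
    d = merged["value_dur"].to_numpy(dtype=float)
    a = merged["value_age"].to_numpy(dtype=float)
    ratios = d / a
    out: dict[str, float | np.ndarray] = {
        "n": int(d.size),
        "ratios": ratios,
        "mean_ratio": float(np.mean(ratios)),
    }
    if d.size >= 3 and np.ptp(a) > 0 and np.ptp(d) > 0:
        r, p = stats.pearsonr(a, d)
        out["pearson_r"] = float(r)
        out["pearson_p"] = float(p)
    elif d.size >= 2 and np.allclose(ratios, ratios[0]):
        out["pearson_r"] = 1.0
    return out
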