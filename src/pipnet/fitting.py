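"""Parameter estimation against the multi-genotype time-course panel.

The model is parameterized against all genotype x (+/- inhibitor) time
courses jointly with a genetic algorithm searching log10 parameter space,
optionally followed by a local simplex refinement from the GA best.  The
objective is COPASI-style weighted least squares: shared global rate
constants across the panel, per-genotype enzyme-activity multipliers, and
per-point weights 1/max(SD, floor)^2 with an SD floor of 5% of the
species' panel-wide mean (so near-zero-SD points cannot dominate).

Rate-law model selection (linear-range mass action vs saturable
Michaelis-Menten phosphatases) is done by fitting both variants with
matched budgets and comparing small-sample AICc.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    DEFAULT_PARAMS,
    Genotype,
    ModelSpec,
    Species,
    apply_genotype,
    build_reference_network,
)
from .simulate import (
    IntegrationError,
    Protocol,
    SteadyStateError,
    observe,
    simulate,
    steady_state,
)

__all__ = [
    "ExperimentData",
    "FitConfig",
    "FitResult",
    "objective",
    "fit_genetic_algorithm",
    "compare_rate_law_variants",
    "bootstrap_flux_ratios",
    "build_variant",
    "VARIANT_FREE_PARAMS",
    "MEASURED_SPECIES",
]

#: Species observed by the measurement panel (response-ratio scaled).
MEASURED_SPECIES: tuple[Species, ...] = (
    Species.PIP3,
    Species.PI34P2,
    Species.PI45P2,
)

#: Penalty returned when a candidate parameter set cannot be simulated.
_PENALTY = 1e12

#: Solver tolerances used inside the objective (looser than the analysis
#: tolerances; the objective only needs the sampled observables).
_FIT_RTOL = 1e-6
_FIT_ATOL = 1e-9


@dataclass(frozen=True)
class ExperimentData:
    """One genotype x condition time course.

    ``observations`` columns: species (Species value string), time_s,
    replicate, value; optional sd.  ``scale_species`` lists the species
    whose values are response-ratio scaled (all measured species here).
    """

    genotype: Genotype
    protocol: Protocol
    observations: pd.DataFrame
    scale_species: tuple[Species, ...] = MEASURED_SPECIES

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise ValueError("experiment carries no observations")
        needed = {"species", "time_s", "replicate", "value"}
        missing = needed - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        tmax = float(self.observations["time_s"].max())
        if tmax > self.protocol.t_end + 1e-9:
            raise ValueError("observation times exceed the protocol span")


@dataclass(frozen=True)
class FitConfig:
    """Search-space and GA hyperparameters.

    Bounds are offsets in log10 space around each parameter's prior
    magnitude (the template value).  GA defaults: population 50, 300
    generations, tournament selection, per-gene mutation rate 0.1,
    log-uniform initialization within bounds.  ``reduced_budget`` drops
    the population/generations for quick runs (bootstraps, smoke tests).
    """

    free_params: tuple[str, ...]
    log10_bounds: tuple[float, float] = (-4.0, 2.0)
    population: int = 50
    generations: int = 300
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.25
    tournament_size: int = 3
    elitism: int = 2
    seed: int = 0
    local_refine: bool = True
    local_refine_maxiter: int = 200
    refine_starts: int = 3
    sd_floor_fraction: float = 0.05
    variant: str = "reference"

    def __post_init__(self) -> None:
        lo, hi = self.log10_bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("log10 bounds must be finite with lo < hi")
        if not self.free_params:
            raise ValueError("at least one free parameter is required")

    def reduced(self, population: int = 20, generations: int = 15) -> "FitConfig":
        return replace(self, population=population, generations=generations,
                       local_refine_maxiter=80)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class FitResult:
    """Best parameter set found, with provenance for reproducibility."""

    params: Mapping[str, float]
    objective_value: float
    residuals: pd.DataFrame
    variant: str
    seed: int
    config_hash: str
    history: tuple[float, ...] = ()


# -- model variants ---------------------------------------------------------

#: Free parameters per rate-law variant.  The reference/linear variants fit
#: the route rate constants plus the PI3K catalytic constant; the saturable
#: variant adds a shared phosphatase Km.
VARIANT_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "reference": (
        "k_pi3k_catalysis", "k_pten_pip3", "k_ship2_pip3", "k_x_pip3",
        "k_inpp4b", "k_pten_pi34p2", "vmax_y",
    ),
    "linear": (
        "k_pi3k_catalysis", "k_pten_pip3", "k_ship2_pip3", "k_x_pip3",
        "k_inpp4b", "k_pten_pi34p2", "k_y_linear",
    ),
    "saturable": (
        "k_pi3k_catalysis", "k_pten_pip3", "k_ship2_pip3", "k_x_pip3",
        "k_inpp4b", "k_pten_pi34p2", "k_y_linear", "saturable_km",
    ),
}


def build_variant(variant: str, params: Optional[Mapping[str, float]] = None) -> ModelSpec:
    """Instantiate a model variant from a (possibly partial) parameter map.

    ``reference``: mass-action phosphatases with the saturable Y route (the
    calibrated configuration).  ``linear``: every phosphatase mass-action.
    ``saturable``: every phosphatase Michaelis-Menten with a shared Km
    (parameter ``saturable_km``); in the limit Km >> substrate this variant
    collapses onto the linear one with k = Vmax/Km.
    """
    params = dict(params or {})
    if variant == "reference":
        return build_reference_network(params, y_saturable=True,
                                       provenance="fallback-calibration")
    if variant == "linear":
        return build_reference_network(params, y_saturable=False,
                                       provenance="linear-variant")
    if variant == "saturable":
        km = params.pop("saturable_km", 1000.0)
        return build_reference_network(params, phosphatase_rate_law="michaelis_menten",
                                       saturable_km=km, provenance="saturable-variant")
    raise ValueError(f"unknown variant {variant!r}")


def _prior_value(name: str) -> float:
    if name == "saturable_km":
        return 10.0
    return DEFAULT_PARAMS[name]


# -- objective --------------------------------------------------------------

def _weights(experiments: Sequence[ExperimentData], floor_fraction: float) -> dict:
    """Per-species SD floors from panel-wide means."""
    frames = [e.observations for e in experiments]
    if not frames:
        return {}
    panel = pd.concat(frames, ignore_index=True)
    means = panel.groupby("species")["value"].mean()
    return {sp: max(floor_fraction * abs(m), 1e-12) for sp, m in means.items()}


def predict_experiment(
    model: ModelSpec, experiment: ExperimentData,
    rtol: float = _FIT_RTOL, atol: float = _FIT_ATOL,
    _cache: Optional[dict] = None,
) -> pd.DataFrame:
    """Predicted observables for every observation row of one experiment.

    ``_cache`` (keyed by genotype name) reuses the starved steady state
    across the +/- inhibitor arms of the same genotype.
    """
    # a sparse grid is enough for the sampled objective
    proto = replace(experiment.protocol,
                    dense_grid_dt=max(experiment.protocol.t_end / 16, 1.0))
    key = experiment.genotype.name
    if _cache is not None and key in _cache:
        geno_model, ss = _cache[key]
    else:
        geno_model = apply_genotype(model, experiment.genotype)
        ss = steady_state(geno_model)
        if _cache is not None:
            _cache[key] = (geno_model, ss)
    traj = simulate(geno_model, proto, initial_state=ss, rtol=rtol, atol=atol)
    obs = experiment.observations
    out = obs.copy()
    out["predicted"] = np.nan
    for sp_name, idx in obs.groupby("species").groups.items():
        sp = Species(sp_name)
        times = obs.loc[idx, "time_s"].to_numpy(float)
        out.loc[idx, "predicted"] = observe(traj, sp, times)
    return out


def objective(
    params: Mapping[str, float],
    experiments: Sequence[ExperimentData],
    builder: Callable[[Mapping[str, float]], ModelSpec] | str = "reference",
    sd_floor_fraction: float = 0.05,
) -> float:
    """Weighted least-squares objective over the whole panel.

    Sum over experiments, species, times and replicates of
    w * (observed - predicted)^2 with w = 1/max(SD, floor)^2.  Simulation
    failure at a candidate parameter set yields a large-but-finite penalty
    rather than an exception, so a search can continue past pathological
    candidates.
    """
    if not experiments:
        return 0.0
    if isinstance(builder, str):
        variant = builder
        builder = lambda p: build_variant(variant, p)  # noqa: E731
    r = _weighted_residuals(params, experiments, builder, sd_floor_fraction)
    if r is None:
        return _PENALTY
    return float(np.sum(r**2))


def _weighted_residuals(
    params: Mapping[str, float],
    experiments: Sequence[ExperimentData],
    builder: Callable[[Mapping[str, float]], ModelSpec],
    sd_floor_fraction: float,
) -> Optional[np.ndarray]:
    """sqrt(w)*(obs - pred) over the whole panel; None on simulation failure."""
    floors = _weights(experiments, sd_floor_fraction)
    try:
        model = builder(params)
    except (ValueError, KeyError):
        return None
    chunks = []
    ss_cache: dict = {}
    for exp in experiments:
        try:
            pred = predict_experiment(model, exp, _cache=ss_cache)
        except (SteadyStateError, IntegrationError, ValueError):
            return None
        obs = pred["value"].to_numpy(float)
        mod = pred["predicted"].to_numpy(float)
        if "sd" in pred.columns:
            sd = pred["sd"].to_numpy(float)
        else:
            sd = np.zeros(len(pred))
        floor = pred["species"].map(floors).to_numpy(float)
        chunks.append((obs - mod) / np.maximum(sd, floor))
    return np.concatenate(chunks)


def _residual_table(
    params: Mapping[str, float],
    experiments: Sequence[ExperimentData],
    builder: Callable[[Mapping[str, float]], ModelSpec],
) -> pd.DataFrame:
    model = builder(params)
    rows = []
    ss_cache: dict = {}
    for exp in experiments:
        pred = predict_experiment(model, exp, _cache=ss_cache)
        pred = pred.assign(genotype=exp.genotype.name,
                           inhibitor=exp.protocol.inhibitor is not None,
                           residual=pred["value"] - pred["predicted"])
        rows.append(pred)
    return pd.concat(rows, ignore_index=True)


# -- genetic algorithm ------------------------------------------------------

def fit_genetic_algorithm(
    experiments: Sequence[ExperimentData],
    config: FitConfig,
    builder: Callable[[Mapping[str, float]], ModelSpec] | None = None,
) -> FitResult:
    """GA search in log10 parameter space, deterministic given the seed.

    Tournament selection with elitism; uniform crossover; gaussian
    mutation in log space; optional Nelder-Mead refinement from the GA
    best.  The best-so-far objective is recorded per generation and is
    non-increasing by construction.
    """
    if not experiments:
        raise ValueError("at least one experiment is required")
    if builder is None:
        variant = config.variant
        builder = lambda p: build_variant(variant, p)  # noqa: E731

    names = list(config.free_params)
    priors = np.log10([_prior_value(n) for n in names])
    lo = priors + config.log10_bounds[0]
    hi = priors + config.log10_bounds[1]
    rng = np.random.default_rng(config.seed)

    def decode(x: np.ndarray) -> dict[str, float]:
        return {n: float(10.0 ** v) for n, v in zip(names, x)}

    def evaluate(x: np.ndarray) -> float:
        return objective(decode(x), experiments, builder, config.sd_floor_fraction)

    pop = rng.uniform(lo, hi, size=(config.population, len(names)))
    fitness = np.array([evaluate(x) for x in pop])
    history: list[float] = [float(fitness.min())]

    for _ in range(config.generations):
        order = np.argsort(fitness)
        elite = pop[order[: config.elitism]].copy()
        children = [e for e in elite]
        while len(children) < config.population:
            idx = rng.integers(0, config.population, size=(2, config.tournament_size))
            pa = pop[idx[0][np.argmin(fitness[idx[0]])]]
            pb = pop[idx[1][np.argmin(fitness[idx[1]])]]
            child = pa.copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(len(names)) < 0.5
                child[mask] = pb[mask]
            mut = rng.random(len(names)) < config.mutation_rate
            child = child + mut * rng.normal(0.0, config.mutation_sigma, len(names))
            children.append(np.clip(child, lo, hi))
        pop = np.array(children[: config.population])
        fitness = np.array([evaluate(x) for x in pop])
        history.append(min(history[-1], float(fitness.min())))

    best = pop[int(np.argmin(fitness))]
    best_val = float(fitness.min())
    if history[-1] < best_val:  # elite preserved: recover best-so-far
        best_val = history[-1]

    if config.local_refine:
        n_res = int(sum(len(e.observations) for e in experiments))

        def res_vec(x: np.ndarray) -> np.ndarray:
            r = _weighted_residuals(decode(x), experiments, builder,
                                    config.sd_floor_fraction)
            if r is None:
                return np.full(n_res, math.sqrt(_PENALTY / n_res))
            return r

        # refine from the best few distinct GA individuals: local minima in
        # the noisy objective make a single start unreliable
        order = np.argsort(fitness)
        starts, seen = [np.clip(best, lo, hi)], [best]
        for i in order:
            if len(starts) >= config.refine_starts:
                break
            cand = pop[i]
            if all(np.abs(cand - s).max() > 0.2 for s in seen):
                starts.append(np.clip(cand, lo, hi))
                seen.append(cand)
        for x0 in starts:
            res = least_squares(
                res_vec, x0, bounds=(lo, hi), method="trf",
                diff_step=1e-3, xtol=1e-12, ftol=1e-12, gtol=1e-10,
                max_nfev=config.local_refine_maxiter,
            )
            refined_val = float(2 * res.cost)  # cost = 0.5 * sum(r^2)
            if refined_val <= best_val:
                best, best_val = res.x, refined_val
        history.append(best_val)

    params = decode(best)
    residuals = _residual_table(params, experiments, builder)
    return FitResult(
        params=params,
        objective_value=best_val,
        residuals=residuals,
        variant=config.variant,
        seed=config.seed,
        config_hash=config.config_hash(),
        history=tuple(history),
    )


# -- model selection --------------------------------------------------------

def _aicc(wrss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC for a least-squares fit."""
    wrss = max(wrss, 1e-300)
    aic = n * math.log(wrss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def compare_rate_law_variants(
    experiments: Sequence[ExperimentData],
    config: FitConfig,
    variants: tuple[str, str] = ("linear", "saturable"),
) -> dict:
    """Fit each rate-law variant with a matched budget and select by AICc.

    Returns a report with per-variant objective, parameter count, AICc and
    the selected variant (smallest AICc; parameter count breaks ties when
    objectives are within the noise floor).
    """
    if not experiments:
        raise ValueError("at least one experiment is required")
    n = int(sum(len(e.observations) for e in experiments))
    report: dict = {"n_points": n, "variants": {}}
    best_variant, best_aicc = None, math.inf
    for variant in variants:
        cfg = replace(config, variant=variant,
                      free_params=VARIANT_FREE_PARAMS[variant])
        fit = fit_genetic_algorithm(experiments, cfg)
        k = len(cfg.free_params)
        aicc = _aicc(fit.objective_value, n, k)
        report["variants"][variant] = {
            "objective": fit.objective_value,
            "n_params": k,
            "aicc": aicc,
            "params": dict(fit.params),
        }
        if aicc < best_aicc - 1e-12 or (
            math.isclose(aicc, best_aicc, abs_tol=1e-12) and best_variant is None
        ):
            best_variant, best_aicc = variant, aicc
    report["selected"] = best_variant
    return report


# -- bootstrap --------------------------------------------------------------

def bootstrap_flux_ratios(
    fit: FitResult,
    experiments: Sequence[ExperimentData],
    n_boot: int,
    seed: int,
    config: Optional[FitConfig] = None,
    ratio_fn: Optional[Callable[[Mapping[str, float]], Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Residual-resampling bootstrap intervals for the headline ratios.

    Residuals of the fitted model are resampled with replacement within
    each species and added back to the predictions to form synthetic
    panels; each panel is refit with a reduced budget and the ratio set
    recomputed.  Returns a table of percentile (2.5/50/97.5) intervals.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if config is None:
        config = FitConfig(free_params=VARIANT_FREE_PARAMS[fit.variant],
                           variant=fit.variant, seed=seed).reduced()
    if ratio_fn is None:
        from .synth import headline_ratios_from_params
        ratio_fn = lambda p: headline_ratios_from_params(p, fit.variant)  # noqa: E731

    rng = np.random.default_rng(seed)
    res = fit.residuals
    samples: dict[str, list[float]] = {}
    for b in range(n_boot):
        boot_frames = []
        cursor = 0
        for exp in experiments:
            n_rows = len(exp.observations)
            block = res.iloc[cursor: cursor + n_rows]
            cursor += n_rows
            new_obs = exp.observations.copy()
            resampled = np.empty(n_rows)
            for sp_name, idx in block.groupby("species").groups.items():
                pos = block.index.get_indexer(idx)
                r = block.loc[idx, "residual"].to_numpy(float)
                resampled[pos] = rng.choice(r, size=len(r), replace=True)
            new_obs["value"] = np.maximum(
                block["predicted"].to_numpy(float) + resampled, 0.0
            )
            boot_frames.append(replace(exp, observations=new_obs))
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        boot_fit = fit_genetic_algorithm(boot_frames, cfg)
        for name, value in ratio_fn(boot_fit.params).items():
            samples.setdefault(name, []).append(float(value))

    rows = []
    for name, vals in samples.items():
        arr = np.asarray(vals)
        rows.append({
            "quantity": name,
            "lo_2.5": float(np.percentile(arr, 2.5)),
            "median": float(np.percentile(arr, 50)),
            "hi_97.5": float(np.percentile(arr, 97.5)),
            "n_boot": n_boot,
        })
    return pd.DataFrame(rows)
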