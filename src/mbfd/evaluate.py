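"""Monte Carlo evaluation of MBFD analysis strategies.

Runs scenario grids crossing sample size, intraclass correlation, effect
pattern, mean model and estimator, and summarizes bias, type I error and
power with Monte Carlo standard errors. Hypothesis tests are two-sided Wald
t-tests at Bonferroni-adjusted levels: 0.05/2 for the additive model (two
tested coefficients), 0.05/3 for the interaction and multi-arm models.

Each replicate simulates one trial from the random-intercept generator and
analyzes the same dataset with every requested estimator (common random
numbers), so estimator contrasts are paired. Replicate substreams are
spawned deterministically from the master seed, making any replicate
reproducible in isolation and parallel execution identical to serial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import Allocation, Design, build_standard_design, randomize
from .gee import fit_gee, gee_test
from .lmm import FitResult, ModelSpec, design_matrix, fit_reml
from .simulate import EffectParameters, VarianceComponents, simulate_trial

__all__ = [
    "HypothesisSet",
    "ScenarioConfig",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "combined_effect",
    "reproduce_tables",
    "EFFECT_SCENARIOS",
]

ESTIMATORS = ("LMM", "GEE", "GEE-MD")

#: the three canonical effect patterns (beta_a, beta_b, beta_c)
EFFECT_SCENARIOS = {
    "null": (0.0, 0.0, 0.0),
    "additive": (0.8, 0.8, 1.6),
    "interaction": (0.8, 0.8, 2.0),
}


@dataclass(frozen=True)
class HypothesisSet:
    """Coefficients tested for a model, with the Bonferroni-adjusted level."""

    model_id: int
    coefficients: tuple[str, ...] = field(init=False)
    adjusted_level: float = field(init=False)

    def __post_init__(self) -> None:
        coeffs = {
            1: ("beta_a", "beta_b"),
            2: ("beta_a", "beta_b", "beta_i"),
            3: ("beta_a", "beta_b", "beta_c"),
        }[self.model_id]
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "adjusted_level", 0.05 / len(coeffs))


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid."""

    n_participants: int
    icc: float
    effects: tuple[float, float, float]  # (beta_a, beta_b, beta_c)
    model_id: int
    estimators: tuple[str, ...] = ESTIMATORS
    n_sim: int = 5000
    seed: int = 0
    sigma: float = 1.0
    beta_t: float = 1.0
    design: Design | None = None  # standard 6x5 design when None

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must be in [0, 1)")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")

    def get_design(self) -> Design:
        return self.design if self.design is not None else build_standard_design()

    def effect_parameters(self) -> EffectParameters:
        ba, bb, bc = self.effects
        return EffectParameters(
            u=0.0, beta_t=self.beta_t, beta_a=ba, beta_b=bb, beta_c=bc
        )

    def variance_components(self) -> VarianceComponents:
        return VarianceComponents.from_icc(self.icc, self.sigma)


@dataclass
class ScenarioResult:
    """Aggregated Monte Carlo summaries of one scenario."""

    config: ScenarioConfig
    summary: pd.DataFrame  # rows: estimator x coefficient
    disjunctive: pd.DataFrame  # per-estimator "at least one rejected" rate
    n_completed: int
    n_excluded: int
    n_df_fallback: int
    warnings: list[str] = field(default_factory=list)


def _true_values(config: ScenarioConfig) -> dict[str, float]:
    eff = config.effect_parameters()
    return {
        "intercept": eff.u,
        "period": eff.beta_t,
        "beta_a": eff.beta_a,
        "beta_b": eff.beta_b,
        "beta_i": eff.beta_i,
        "beta_c": eff.beta_c,
    }


def _replicate_seed(master_seed: int, replicate_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(replicate_index,))


def run_replicate(config: ScenarioConfig, replicate_index: int) -> dict:
    """Simulate one trial and analyze it with every requested estimator.

    Returns a mapping ``estimator -> {coefficient -> (estimate, p, reject)}``
    plus convergence metadata; deterministic in
    ``(config.seed, replicate_index)``.
    """
    ss = _replicate_seed(config.seed, replicate_index)
    alloc_seed, data_ss = ss.spawn(2)
    design = config.get_design()
    allocation = randomize(
        design, config.n_participants, alloc_seed.generate_state(1)[0] % 2**31
    )
    data = simulate_trial(
        design,
        allocation,
        config.effect_parameters(),
        config.variance_components(),
        np.random.default_rng(data_ss),
    )
    spec = ModelSpec(config.model_id)
    hyp = HypothesisSet(config.model_id)
    level = hyp.adjusted_level
    idx = {name: k for k, name in enumerate(spec.coef_names)}

    out: dict = {"estimators": {}, "excluded": [], "df_fallback": []}
    need_lmm = "LMM" in config.estimators
    need_gee = "GEE" in config.estimators or "GEE-MD" in config.estimators

    if need_lmm:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_reml(data, spec)
            if not fit.converged:
                raise RuntimeError("REML did not converge")
            pvals = fit.pvalues()
            out["estimators"]["LMM"] = {
                name: (float(fit.coef[idx[name]]), float(pvals[idx[name]]),
                       bool(pvals[idx[name]] < level))
                for name in hyp.coefficients
            }
            if fit.df_fallback:
                out["df_fallback"].append("LMM")
        except Exception as exc:  # pragma: no cover - rare numeric failure
            out["excluded"].append(("LMM", str(exc)))

    if need_gee:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_gee(data, spec)
            if not fit.converged:
                raise RuntimeError("GEE did not converge")
            # Standard GEE is tested against the large-sample normal
            # reference (the default Wald test of GEE software); the
            # Mancl-DeRouen variant pairs the corrected variance with the
            # small-sample t reference, df = N - p.
            for tag, kind, df in (
                ("GEE", "robust", np.inf),
                ("GEE-MD", "md", None),
            ):
                if tag not in config.estimators:
                    continue
                res = {}
                for name in hyp.coefficients:
                    e = np.zeros(spec.n_params)
                    e[idx[name]] = 1.0
                    _, _, p = gee_test(fit, e, kind, df=df)
                    res[name] = (
                        float(fit.coef[idx[name]]), p, bool(p < level)
                    )
                out["estimators"][tag] = res
        except Exception as exc:  # pragma: no cover - rare numeric failure
            for tag in ("GEE", "GEE-MD"):
                if tag in config.estimators:
                    out["excluded"].append((tag, str(exc)))
    return out


def run_scenario(config: ScenarioConfig, n_jobs: int = 1) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate performance measures.

    Parallel execution (``n_jobs``) gives results identical to serial
    because every replicate owns a seed substream.
    """
    if n_jobs == 1:
        reps = [run_replicate(config, r) for r in range(config.n_sim)]
    else:
        reps = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(config, r) for r in range(config.n_sim)
        )

    hyp = HypothesisSet(config.model_id)
    truth = _true_values(config)
    rows = []
    disj_rows = []
    n_excluded = 0
    n_fallback = sum(len(r["df_fallback"]) for r in reps)
    warn_msgs: list[str] = []
    for est in config.estimators:
        done = [r["estimators"][est] for r in reps if est in r["estimators"]]
        n_exc = config.n_sim - len(done)
        n_excluded = max(n_excluded, n_exc)
        if n_exc > 0.05 * config.n_sim:
            warn_msgs.append(
                f"{est}: {n_exc}/{config.n_sim} replicates excluded (>5%)"
            )
        m = len(done)
        any_reject = np.zeros(m, dtype=bool)
        for name in hyp.coefficients:
            est_vals = np.array([d[name][0] for d in done])
            rejects = np.array([d[name][2] for d in done])
            any_reject |= rejects
            rate = float(rejects.mean()) if m else np.nan
            rows.append(
                {
                    "estimator": est,
                    "coefficient": name,
                    "true_value": truth[name],
                    "mean_estimate": float(est_vals.mean()) if m else np.nan,
                    "bias": float(est_vals.mean() - truth[name]) if m else np.nan,
                    "mc_se_bias": float(est_vals.std(ddof=1) / np.sqrt(m))
                    if m > 1
                    else np.nan,
                    "rejection_rate": rate,
                    "mc_se_rate": float(np.sqrt(rate * (1 - rate) / m))
                    if m
                    else np.nan,
                    "n_replicates": m,
                }
            )
        disj = float(any_reject.mean()) if m else np.nan
        disj_rows.append(
            {
                "estimator": est,
                "disjunctive_rate": disj,
                "mc_se": float(np.sqrt(disj * (1 - disj) / m)) if m else np.nan,
                "n_replicates": m,
            }
        )
    return ScenarioResult(
        config=config,
        summary=pd.DataFrame(rows),
        disjunctive=pd.DataFrame(disj_rows),
        n_completed=config.n_sim - n_excluded,
        n_excluded=n_excluded,
        n_df_fallback=n_fallback,
        warnings=warn_msgs,
    )


def combined_effect(fit: FitResult, spec: ModelSpec) -> tuple[float, float]:
    """Estimate and SE of the combined (AB vs control) effect.

    Additive model: ``beta_a + beta_b``; interaction model:
    ``beta_a + beta_b + beta_i``; multi-arm model: ``beta_c`` directly.
    """
    names = spec.coef_names
    c = np.zeros(len(names))
    if spec.model_id == 1:
        picks = ("beta_a", "beta_b")
    elif spec.model_id == 2:
        picks = ("beta_a", "beta_b", "beta_i")
    else:
        picks = ("beta_c",)
    for name in picks:
        c[names.index(name)] = 1.0
    est = float(c @ fit.coef)
    se = float(np.sqrt(c @ fit.vcov @ c))
    return est, se


_TABLE_SCENARIOS = {
    3: ("null", "rejection_rate"),
    4: ("additive", "rejection_rate"),
    5: ("interaction", "mean_estimate"),
    6: ("interaction", "rejection_rate"),
}


def reproduce_tables(
    table_id: int,
    n_sim: int = 5000,
    seed: int = 0,
    iccs: tuple[float, ...] = (0.05, 0.10, 0.30),
    sample_sizes: tuple[int, ...] = (30, 60, 120),
    model_ids: tuple[int, ...] = (1, 2, 3),
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Recompute one of the headline simulation grids.

    Table 3-style: type I error under the null; 4: power under additive
    effects; 5: mean estimates under an interaction; 6: power under an
    interaction. Output is tidy (one row per ICC, model, N, estimator and
    coefficient) with a 3-decimal ``value`` column.
    """
    if table_id not in _TABLE_SCENARIOS:
        raise ValueError(f"table_id must be one of {sorted(_TABLE_SCENARIOS)}")
    scenario, measure = _TABLE_SCENARIOS[table_id]
    estimators = ("LMM", "GEE") if table_id == 5 else ESTIMATORS
    frames = []
    for icc_i, icc in enumerate(iccs):
        for mid in model_ids:
            for n_i, n in enumerate(sample_sizes):
                # distinct, reproducible master seed per cell
                cell_seed = (
                    seed + 1_000_003 * (icc_i * 100 + mid * 10 + n_i)
                ) % 2**31
                cfg = ScenarioConfig(
                    n_participants=n,
                    icc=icc,
                    effects=EFFECT_SCENARIOS[scenario],
                    model_id=mid,
                    estimators=estimators,
                    n_sim=n_sim,
                    seed=cell_seed,
                )
                res = run_scenario(cfg, n_jobs=n_jobs)
                block = res.summary.copy()
                block.insert(0, "icc", icc)
                block.insert(1, "model", mid)
                block.insert(2, "n", n)
                frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out["value"] = out[measure].round(3)
    return out
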