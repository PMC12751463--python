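"""Monte Carlo probabilistic sensitivity analysis (PSA).

Model parameters are declared as named distributions (fixed, lognormal,
gamma, beta or uniform). Each replicate draws one value per parameter —
in alphabetical order of parameter name, so a fixed seed yields a
bit-identical draw stream — rebuilds the scenario tree, and records the
expected cost, expected QALY and their ratio. Summaries report mean,
median, min, max, the n-1 standard deviation and the 95% confidence
interval of the mean (mean +/- 1.96*sd/sqrt(n)).

Scenario comparisons default to common random numbers: every scenario is
evaluated on the same parameter draws, which removes draw-to-draw noise
from between-scenario contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .effectiveness import (
    CeaConfig,
    PerformanceLike,
    UtilityWeights,
    cost_per_qaly,
    evaluate,
)
from .errors import ConfigError, ModelingError
from .tree import DiagnosticTree

__all__ = [
    "ParameterSpec",
    "PsaSummary",
    "PsaResult",
    "Scenario",
    "sample_parameters",
    "run_psa",
    "summarize",
    "sweep",
    "compare",
    "load_parameter_specs",
]

_FAMILIES = ("fixed", "lognormal", "gamma", "beta", "uniform")

#: Parameter names that, when present in a draw, refresh the replicate's
#: utility weights and prevalence before evaluation.
_UTILITY_KEYS = ("u_tp", "u_tn", "u_fp", "u_fn")


@dataclass(frozen=True)
class ParameterSpec:
    """Named sampling distribution for one model parameter.

    families and parameters:

    * ``fixed(value)`` — degenerate;
    * ``lognormal(meanlog, sdlog)`` — log-scale mean and SD;
    * ``gamma(shape, scale)`` — mean = shape*scale;
    * ``beta(a, b)`` — mean = a/(a+b);
    * ``uniform(lo, hi)``.
    """

    name: str
    family: str
    params: tuple[float, ...]
    unit: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(
                f"parameter {self.name!r}: unknown family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        n_expected = 1 if self.family == "fixed" else 2
        if len(self.params) != n_expected:
            raise ConfigError(
                f"parameter {self.name!r}: family {self.family!r} takes "
                f"{n_expected} parameter(s), got {len(self.params)}"
            )
        a, b = (self.params + (None,))[:2]
        if self.family == "lognormal" and b <= 0:
            raise ConfigError(f"parameter {self.name!r}: sdlog must be > 0")
        if self.family == "gamma" and (a <= 0 or b <= 0):
            raise ConfigError(f"parameter {self.name!r}: shape and scale must be > 0")
        if self.family == "beta" and (a <= 0 or b <= 0):
            raise ConfigError(f"parameter {self.name!r}: a and b must be > 0")
        if self.family == "uniform" and not a < b:
            raise ConfigError(f"parameter {self.name!r}: requires lo < hi")

    @classmethod
    def fixed(cls, name: str, value: float, unit: str = "") -> "ParameterSpec":
        return cls(name, "fixed", (value,), unit)

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        p = self.params
        if self.family == "fixed":
            return p[0]
        if self.family == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if self.family == "gamma":
            return p[0] * p[1]
        if self.family == "beta":
            return p[0] / (p[0] + p[1])
        return (p[0] + p[1]) / 2.0  # uniform

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "fixed":
            return p[0]
        if self.family == "lognormal":
            return float(rng.lognormal(p[0], p[1]))
        if self.family == "gamma":
            return float(rng.gamma(p[0], p[1]))
        if self.family == "beta":
            return float(rng.beta(p[0], p[1]))
        return float(rng.uniform(p[0], p[1]))


def sample_parameters(
    specs: Sequence[ParameterSpec], rng: np.random.Generator
) -> dict[str, float]:
    """One draw per spec, consumed in alphabetical order of name.

    The documented sampling order makes draw streams reproducible across
    machines and independent of the order specs are listed in.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate parameter names: {dupes}")
    return {s.name: s.sample(rng) for s in sorted(specs, key=lambda s: s.name)}


class Scenario(Protocol):
    """A buildable scenario: parameters in, (tree, registry, overrides) out."""

    scenario_id: str

    def model(
        self, params: Mapping[str, float]
    ) -> tuple[DiagnosticTree, Mapping[str, PerformanceLike], Mapping[str, float]]:
        ...


@dataclass(frozen=True)
class PsaSummary:
    """Summary statistics of cost per QALY across PSA replicates."""

    scenario: str
    n_replicates: int
    mean: float
    median: float
    min: float
    max: float
    sd: float
    ci95_low: float
    ci95_high: float
    seed: int | None = None
    ratio_mode: str = "per_replicate"
    n_invalid: int = 0

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_replicates": self.n_replicates,
            "mean": self.mean,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "sd": self.sd,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "seed": self.seed,
            "ratio_mode": self.ratio_mode,
            "n_invalid": self.n_invalid,
        }


@dataclass(frozen=True)
class PsaResult:
    """Per-replicate table plus its summary."""

    summary: PsaSummary
    table: pd.DataFrame


def summarize(
    values: Sequence[float],
    *,
    scenario: str = "",
    seed: int | None = None,
    ratio_mode: str = "per_replicate",
    n_invalid: int = 0,
    mean_override: float | None = None,
) -> PsaSummary:
    """Mean/median/min/max/SD and the 95% CI of the mean.

    SD uses the n-1 denominator; the interval is mean +/- 1.96*sd/sqrt(n).
    ``mean_override`` substitutes a ratio-of-expectations mean while the
    distributional statistics stay those of the per-replicate ratios.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("summarize needs at least one finite value")
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / math.sqrt(n)
    reported = mean if mean_override is None else float(mean_override)
    return PsaSummary(
        scenario=scenario,
        n_replicates=n,
        mean=reported,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        sd=sd,
        ci95_low=mean - half if mean_override is None else reported - half,
        ci95_high=mean + half if mean_override is None else reported + half,
        seed=seed,
        ratio_mode=ratio_mode,
        n_invalid=n_invalid,
    )


def _replicate_config(base: CeaConfig, params: Mapping[str, float]) -> CeaConfig:
    """Refresh utilities/prevalence from a parameter draw where sampled."""
    u = base.utilities
    if any(k in params for k in _UTILITY_KEYS):
        u = UtilityWeights(
            u_tp=params.get("u_tp", u.u_tp),
            u_tn=params.get("u_tn", u.u_tn),
            u_fp=params.get("u_fp", u.u_fp),
            u_fn=params.get("u_fn", u.u_fn),
            u_undiagnosed=u.u_undiagnosed,
        )
    prevalence = params.get("prevalence", base.prevalence)
    if u is base.utilities and prevalence == base.prevalence:
        return base
    return replace(base, utilities=u, prevalence=prevalence)


def _evaluate_draws(
    scenario: Scenario,
    draws: Sequence[Mapping[str, float]],
    config: CeaConfig,
) -> pd.DataFrame:
    """Evaluate a scenario on precomputed parameter draws.

    The first replicate's tree is validated in full; later replicates skip
    structural validation (only probabilities change between draws).
    """
    rows: list[dict] = []
    validate = True
    for i, params in enumerate(draws):
        tree, registry, overrides = scenario.model(params)
        rep_config = _replicate_config(config, params)
        row = {"replicate": i, **params}
        try:
            res = evaluate(
                tree, registry, config=rep_config, overrides=overrides,
                validate=validate,
            )
        except ModelingError:
            row.update(
                expected_cost=np.nan, expected_qaly=np.nan,
                cost_per_qaly=np.nan, valid=False,
            )
        else:
            row.update(
                expected_cost=res.expected_cost,
                expected_qaly=res.expected_qaly,
                cost_per_qaly=res.cost_per_qaly,
                valid=True,
            )
        validate = False
        rows.append(row)
    return pd.DataFrame(rows)


def _summarize_table(
    table: pd.DataFrame,
    *,
    scenario: str,
    seed: int | None,
    config: CeaConfig,
) -> PsaSummary:
    valid = table[table["valid"]]
    n_invalid = int((~table["valid"]).sum())
    ratios = valid["cost_per_qaly"].to_numpy()
    mean_override = None
    if config.ratio_mode == "of_expectations":
        mean_override = float(
            cost_per_qaly(valid["expected_cost"].mean(), valid["expected_qaly"].mean())
        )
    return summarize(
        ratios,
        scenario=scenario,
        seed=seed,
        ratio_mode=config.ratio_mode,
        n_invalid=n_invalid,
        mean_override=mean_override,
    )


def run_psa(
    scenario: Scenario,
    specs: Sequence[ParameterSpec],
    n_sims: int,
    seed: int,
    config: CeaConfig,
) -> PsaResult:
    """Monte Carlo PSA of one scenario.

    Per replicate: sample all parameters, rebuild the scenario tree,
    compute expected cost and expected QALY, record the ratio. Replicates
    whose expected QALY is non-positive are recorded as invalid and
    excluded from the summary (counted in ``n_invalid``); they still
    consume their draws, so the stream stays seed-stable.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    draws = [sample_parameters(specs, rng) for _ in range(n_sims)]
    table = _evaluate_draws(scenario, draws, config)
    summary = _summarize_table(
        table, scenario=scenario.scenario_id, seed=seed, config=config
    )
    return PsaResult(summary=summary, table=table)


def compare(
    scenarios: Sequence[Scenario],
    specs: Sequence[ParameterSpec],
    n_sims: int,
    seed: int,
    config: CeaConfig,
    *,
    common_draws: bool = True,
) -> dict[str, PsaResult]:
    """Run several scenarios side by side.

    With ``common_draws`` (default) every scenario is evaluated on the same
    parameter draws (common random numbers), which sharpens between-scenario
    contrasts; otherwise each scenario gets an independent stream derived
    from ``seed`` and its position.
    """
    results: dict[str, PsaResult] = {}
    if common_draws:
        rng = np.random.default_rng(seed)
        draws = [sample_parameters(specs, rng) for _ in range(n_sims)]
        for sc in scenarios:
            table = _evaluate_draws(sc, draws, config)
            summary = _summarize_table(
                table, scenario=sc.scenario_id, seed=seed, config=config
            )
            results[sc.scenario_id] = PsaResult(summary=summary, table=table)
    else:
        for k, sc in enumerate(scenarios):
            results[sc.scenario_id] = run_psa(
                sc, specs, n_sims, seed + k, config
            )
    return results


def sweep(
    scenarios: Sequence[Scenario],
    specs: Sequence[ParameterSpec],
    parameter: str,
    *,
    n_sims: int,
    seed: int,
    config: CeaConfig,
    bins: Sequence[float] | None = None,
    values: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Cost-per-QALY summaries across a parameter grid.

    Two modes, chosen by which argument is given:

    * ``bins`` — run each scenario once (common draws across scenarios) and
      bin replicates by the *sampled* value of ``parameter`` (the natural
      reading of a cost sweep when the cost is itself a PSA distribution);
    * ``values`` — fix ``parameter`` to each grid value in turn and rerun
      the PSA per cell (for parameters held constant within a cell).

    Returns one summary row per (scenario, cell).
    """
    spec_names = {s.name for s in specs}
    if parameter not in spec_names:
        raise ConfigError(f"unknown parameter {parameter!r}; specs define {sorted(spec_names)}")
    if (bins is None) == (values is None):
        raise ValueError("give exactly one of bins= or values=")

    rows: list[dict] = []
    if bins is not None:
        results = compare(scenarios, specs, n_sims, seed, config)
        intervals = pd.IntervalIndex.from_breaks(list(bins), closed="left")
        for sid, res in results.items():
            table = res.table[res.table["valid"]]
            cells = pd.cut(table[parameter], intervals)
            for interval, group in table.groupby(cells, observed=False):
                if group.empty:
                    continue
                s = summarize(
                    group["cost_per_qaly"].to_numpy(),
                    scenario=sid, seed=seed, ratio_mode=config.ratio_mode,
                )
                rows.append(
                    {
                        "scenario": sid,
                        "parameter": parameter,
                        "cell_low": float(interval.left),
                        "cell_high": float(interval.right),
                        "cell_mid": float(interval.mid),
                        **{
                            k: getattr(s, k)
                            for k in (
                                "n_replicates", "mean", "median", "min",
                                "max", "sd", "ci95_low", "ci95_high",
                            )
                        },
                    }
                )
    else:
        base = [s for s in specs if s.name != parameter]
        for v in values:
            cell_specs = base + [ParameterSpec.fixed(parameter, float(v))]
            results = compare(scenarios, cell_specs, n_sims, seed, config)
            for sid, res in results.items():
                s = res.summary
                rows.append(
                    {
                        "scenario": sid,
                        "parameter": parameter,
                        "cell_low": float(v),
                        "cell_high": float(v),
                        "cell_mid": float(v),
                        **{
                            k: getattr(s, k)
                            for k in (
                                "n_replicates", "mean", "median", "min",
                                "max", "sd", "ci95_low", "ci95_high",
                            )
                        },
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------


def load_parameter_specs(text: str) -> list[ParameterSpec]:
    """Parse a YAML/JSON mapping of parameter names to distributions.

    Format: ``{name: {family: gamma, params: [4, 1211.8675], unit: USD}}``;
    a bare number is shorthand for a fixed parameter.
    """
    import yaml

    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("parameter file must be a mapping of name -> spec")
    specs: list[ParameterSpec] = []
    for name, raw in doc.items():
        if isinstance(raw, (int, float)) and not isinstance(raw, bool):
            specs.append(ParameterSpec.fixed(str(name), float(raw)))
            continue
        if not isinstance(raw, dict):
            raise ConfigError(f"parameter {name!r}: expected a mapping or number")
        family = raw.get("family")
        params = raw.get("params", [])
        unit = raw.get("unit", "")
        if family == "fixed" and isinstance(params, (int, float)):
            params = [params]
        specs.append(ParameterSpec(str(name), str(family), tuple(params), str(unit)))
    return specs


def dump_parameter_specs(specs: Sequence[ParameterSpec]) -> str:
    """Serialize specs to YAML (inverse of :func:`load_parameter_specs`)."""
    import yaml

    doc = {
        s.name: {
            "family": s.family,
            "params": list(s.params),
            **({"unit": s.unit} if s.unit else {}),
        }
        for s in specs
    }
    return yaml.safe_dump(doc, sort_keys=True)
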