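"""Synthetic floras with known selection bias, and detection metrics.

The generator emulates the structure of a real flora: many families with
heavy-tailed sizes, a small baseline use proportion, and a minority of
families whose per-family proportion is inflated or suppressed by a
multiplicative effect.  Used counts are binomial draws, so the detection
pipeline can be scored against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.special import betaincinv

from .counts import FamilyCount, FloraTable, ModelConfig, ValidationError
from .classify import FamilyResult, analyze_flora

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "DetectionMetrics",
    "simulate_flora",
    "detection_metrics",
    "run_detection_experiment",
    "coverage_experiment",
    "read_sim_config",
]

LABELS = ("over", "under", "neutral")


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 200
    size_dist: str = "zipf"
    zipf_exponent: float = 1.5
    lognormal_mu: float = 2.0
    lognormal_sigma: float = 1.5
    size_min: int = 1
    size_max: int = 3000
    theta_base: float = 0.008
    frac_over: float = 0.0
    frac_under: float = 0.0
    effect_over: float = 10.0
    effect_under: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        if self.size_dist not in ("zipf", "lognormal"):
            raise ValidationError(f"unknown size_dist {self.size_dist!r}")
        if self.size_dist == "zipf" and self.zipf_exponent <= 1.0:
            raise ValidationError("zipf_exponent must be > 1")
        if not 1 <= self.size_min <= self.size_max:
            raise ValidationError("require 1 <= size_min <= size_max")
        if not 0.0 < self.theta_base < 1.0:
            raise ValidationError("theta_base must be in (0, 1)")
        if self.frac_over < 0 or self.frac_under < 0 or self.frac_over + self.frac_under > 1:
            raise ValidationError("require frac_over, frac_under >= 0 and sum <= 1")
        if self.effect_over < 1.0:
            raise ValidationError("effect_over must be >= 1")
        if not 0.0 <= self.effect_under <= 1.0:
            raise ValidationError("effect_under must be in [0, 1]")
        if self.theta_base * self.effect_over > 1.0:
            raise ValidationError("theta_base * effect_over must not exceed 1")


@dataclass(frozen=True)
class FamilyTruth:
    family: str
    theta: float
    label: str


@dataclass(frozen=True)
class SimulationTruth:
    families: tuple[FamilyTruth, ...]

    def __iter__(self):
        return iter(self.families)

    def __len__(self) -> int:
        return len(self.families)

    def label_of(self) -> dict[str, str]:
        return {t.family: t.label for t in self.families}


@dataclass(frozen=True)
class ModelMetrics:
    sensitivity_over: float | None
    sensitivity_under: float | None
    false_positive_rate: float | None
    n_over: int
    n_under: int
    n_neutral: int
    detected_over: int
    detected_under: int
    false_flags: int


@dataclass(frozen=True)
class DetectionMetrics:
    bayes: ModelMetrics
    idm: ModelMetrics

    def for_model(self, model: str) -> ModelMetrics:
        if model == "bayes":
            return self.bayes
        if model == "idm":
            return self.idm
        raise ValueError(f"unknown model {model!r}")


def _draw_size(rng: np.random.Generator, config: SimulationConfig) -> int:
    if config.size_dist == "zipf":
        size = int(rng.zipf(config.zipf_exponent))
    else:
        size = int(round(float(rng.lognormal(config.lognormal_mu, config.lognormal_sigma))))
    return int(min(max(size, config.size_min), config.size_max))


def simulate_flora(config: SimulationConfig) -> tuple[FloraTable, SimulationTruth]:
    """Generate one synthetic flora and its ground-truth labels.

    Each family uses its own child stream of the master seed, so
    extending ``n_families`` leaves earlier families' draws unchanged.
    Labels are derived from the realized per-family proportion: a family
    is labelled ``over``/``under`` only when its proportion actually
    differs from the baseline.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_families)
    width = max(4, len(str(config.n_families)))
    counts, truths = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        n = _draw_size(rng, config)
        u = rng.uniform()
        if u < config.frac_over:
            theta = config.theta_base * config.effect_over
        elif u < config.frac_over + config.frac_under:
            theta = config.theta_base * config.effect_under
        else:
            theta = config.theta_base
        if theta > config.theta_base:
            label = "over"
        elif theta < config.theta_base:
            label = "under"
        else:
            label = "neutral"
        x = int(rng.binomial(n, theta))
        name = f"Fam{i + 1:0{width}d}"
        counts.append(FamilyCount(family=name, n_total=n, x_used=x))
        truths.append(FamilyTruth(family=name, theta=theta, label=label))
    return FloraTable.from_counts(counts), SimulationTruth(families=tuple(truths))


def _model_metrics(status: dict[str, str], label: dict[str, str]) -> ModelMetrics:
    n_over = sum(1 for v in label.values() if v == "over")
    n_under = sum(1 for v in label.values() if v == "under")
    n_neutral = sum(1 for v in label.values() if v == "neutral")
    det_over = sum(1 for f, v in label.items() if v == "over" and status[f] == "overused")
    det_under = sum(
        1 for f, v in label.items() if v == "under" and status[f] == "underused"
    )
    false_flags = sum(
        1 for f, v in label.items() if v == "neutral" and status[f] != "ns"
    )
    return ModelMetrics(
        sensitivity_over=det_over / n_over if n_over else None,
        sensitivity_under=det_under / n_under if n_under else None,
        false_positive_rate=false_flags / n_neutral if n_neutral else None,
        n_over=n_over,
        n_under=n_under,
        n_neutral=n_neutral,
        detected_over=det_over,
        detected_under=det_under,
        false_flags=false_flags,
    )


def detection_metrics(
    results: Iterable[FamilyResult], truth: SimulationTruth
) -> DetectionMetrics:
    """Cross-tabulate classification statuses against ground-truth labels."""
    results = list(results)
    label = truth.label_of()
    if {r.family for r in results} != set(label):
        raise ValidationError("result and truth family sets differ")
    status_b = {r.family: r.status_bayes for r in results}
    status_i = {r.family: r.status_idm for r in results}
    return DetectionMetrics(
        bayes=_model_metrics(status_b, label),
        idm=_model_metrics(status_i, label),
    )


def run_detection_experiment(
    config: SimulationConfig,
    reps: int,
    model_config: ModelConfig | None = None,
) -> DetectionMetrics:
    """Pooled detection metrics over ``reps`` independent floras.

    Replicate r uses seed ``config.seed + r``; counts are pooled across
    replicates before rates are formed.
    """
    model_config = model_config or ModelConfig()
    totals = {
        m: dict(n_over=0, n_under=0, n_neutral=0, detected_over=0,
                detected_under=0, false_flags=0)
        for m in ("bayes", "idm")
    }
    for r in range(reps):
        table, truth = simulate_flora(replace(config, seed=config.seed + r))
        results, _ = analyze_flora(table, model_config)
        metrics = detection_metrics(results, truth)
        for m in ("bayes", "idm"):
            mm = metrics.for_model(m)
            for key in totals[m]:
                totals[m][key] += getattr(mm, key)

    def pooled(t: dict) -> ModelMetrics:
        return ModelMetrics(
            sensitivity_over=t["detected_over"] / t["n_over"] if t["n_over"] else None,
            sensitivity_under=(
                t["detected_under"] / t["n_under"] if t["n_under"] else None
            ),
            false_positive_rate=(
                t["false_flags"] / t["n_neutral"] if t["n_neutral"] else None
            ),
            **t,
        )

    return DetectionMetrics(bayes=pooled(totals["bayes"]), idm=pooled(totals["idm"]))


def coverage_experiment(
    n: int,
    theta: float,
    reps: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    idm_s: int = 4,
) -> dict[str, float]:
    """Empirical coverage of both interval constructions.

    Draws ``reps`` binomial counts X ~ Bin(n, theta) and returns, per
    model, the fraction of replicates whose interval contains theta.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    xs = rng.binomial(n, theta, size=reps)
    alpha = 1.0 - level

    def pair_coverage(s: int) -> float:
        lo = np.where(xs == 0, 0.0, betaincinv(np.maximum(xs, 1), n - xs + s, alpha / 2))
        hi = np.where(
            xs == n, 1.0, betaincinv(xs + s, np.maximum(n - xs, 1), 1 - alpha / 2)
        )
        return float(np.mean((lo <= theta) & (theta <= hi)))

    return {"bayes": pair_coverage(1), "idm": pair_coverage(idm_s)}


_SIM_FIELDS = {
    "n_families": int,
    "size_dist": str,
    "zipf_exponent": float,
    "lognormal_mu": float,
    "lognormal_sigma": float,
    "size_min": int,
    "size_max": int,
    "theta_base": float,
    "frac_over": float,
    "frac_under": float,
    "effect_over": float,
    "effect_under": float,
    "seed": int,
}


def read_sim_config(path) -> SimulationConfig:
    """Read a ``key = value`` simulation config file ('#' starts a comment)."""
    kwargs = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}, line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in _SIM_FIELDS:
                raise ValidationError(f"{path}, line {lineno}: unknown key {key!r}")
            kwargs[key] = _SIM_FIELDS[key](value)
    return SimulationConfig(**kwargs)
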