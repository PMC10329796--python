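"""Two-sided interval estimates for use proportions.

Two constructions are provided for a binomial count x out of n:

* the Bayesian exceedance pair — lower bound from Beta(x, n-x+1), upper
  from Beta(x+1, n-x), i.e. the exact Clopper-Pearson interval;
* the Imprecise Dirichlet Model (IDM) — the same pair widened by an
  imprecision parameter s: Beta(x, n-x+s) / Beta(x+s, n-x).

The two coincide at s = 1, and the IDM interval contains the Bayesian
one for every s >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import betaincinv

from .counts import FloraTable, ModelConfig

__all__ = [
    "ProportionInterval",
    "beta_quantile",
    "bayes_interval",
    "idm_interval",
    "global_interval",
]

MODELS = ("bayes", "idm")


@dataclass(frozen=True)
class ProportionInterval:
    """A two-sided (lower, upper) range for a proportion."""

    lower: float
    upper: float
    level: float
    model: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(
                f"require 0 <= lower <= upper <= 1, got ({self.lower}, {self.upper})"
            )
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, theta: float) -> bool:
        return self.lower <= theta <= self.upper


def beta_quantile(p: float, a: float, b: float) -> float:
    """Quantile of the Beta(a, b) distribution.

    Degenerate shape conventions represent point masses: a = 0 returns
    0, b = 0 returns 1.  Both zero is an error, as is p outside (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if a < 0 or b < 0:
        raise ValueError(f"shape parameters must be non-negative, got a={a}, b={b}")
    if a == 0 and b == 0:
        raise ValueError("a and b cannot both be zero")
    if a == 0:
        return 0.0
    if b == 0:
        return 1.0
    return float(betaincinv(a, b, p))


def _check_counts(x: int, n: int) -> None:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")


def bayes_interval(
    x: int, n: int, level: float = 0.95, variant: str = "exceedance"
) -> ProportionInterval:
    """Bayesian interval for the use proportion of a single group.

    The default ``exceedance`` variant is the pair-of-beta (exact
    Clopper-Pearson) construction; ``posterior`` uses equal-tailed
    quantiles of the single Beta(x+1, n-x+1) posterior.
    """
    _check_counts(x, n)
    alpha = 1.0 - level
    if variant == "exceedance":
        lower = beta_quantile(alpha / 2.0, x, n - x + 1)
        upper = beta_quantile(1.0 - alpha / 2.0, x + 1, n - x)
    elif variant == "posterior":
        lower = beta_quantile(alpha / 2.0, x + 1, n - x + 1)
        upper = beta_quantile(1.0 - alpha / 2.0, x + 1, n - x + 1)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ProportionInterval(lower=lower, upper=upper, level=level, model="bayes")


def idm_interval(x: int, n: int, s: int = 4, level: float = 0.95) -> ProportionInterval:
    """Imprecise Dirichlet Model interval with imprecision parameter s."""
    _check_counts(x, n)
    if s < 1:
        raise ValueError(f"s must be >= 1, got {s}")
    alpha = 1.0 - level
    lower = beta_quantile(alpha / 2.0, x, n - x + s)
    upper = beta_quantile(1.0 - alpha / 2.0, x + s, n - x)
    return ProportionInterval(lower=lower, upper=upper, level=level, model="idm")


def global_interval(
    table: FloraTable, model: str, config: ModelConfig | None = None
) -> ProportionInterval:
    """Interval for the overall-flora use proportion (X_total / N_total).

    Under ``paper_compat`` (default) the IDM form with s = config.idm_s
    is applied to the totals for BOTH requested models, reproducing the
    published total row where the two columns are identical.  Under
    ``per_model`` each model's own construction is used.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    config = config or ModelConfig()
    X, N = table.X_total, table.N_total
    if config.global_convention == "paper_compat" or model == "idm":
        iv = idm_interval(X, N, s=config.idm_s, level=config.level)
        return ProportionInterval(
            lower=iv.lower, upper=iv.upper, level=iv.level, model=model
        )
    return bayes_interval(X, N, level=config.level, variant=config.bayes_variant)
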