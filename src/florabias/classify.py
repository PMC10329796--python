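"""Classification of families against the overall-flora interval."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .counts import FloraTable, ModelConfig
from .intervals import ProportionInterval, bayes_interval, global_interval, idm_interval

__all__ = [
    "STATUSES",
    "FamilyResult",
    "AnalysisSummary",
    "classify_family",
    "analyze_flora",
    "compare_models",
    "results_to_frame",
    "format_bound",
]

STATUSES = ("overused", "underused", "ns")


@dataclass(frozen=True)
class FamilyResult:
    family: str
    n_total: int
    x_used: int
    bayes: ProportionInterval
    idm: ProportionInterval
    status_bayes: str
    status_idm: str


@dataclass(frozen=True)
class AnalysisSummary:
    """Per-model status counts plus the global intervals and config used."""

    n_families: int
    counts_bayes: dict
    counts_idm: dict
    global_bayes: ProportionInterval
    global_idm: ProportionInterval
    config: ModelConfig

    def counts(self, model: str) -> dict:
        if model == "bayes":
            return self.counts_bayes
        if model == "idm":
            return self.counts_idm
        raise ValueError(f"unknown model {model!r}")


def classify_family(
    family_iv: ProportionInterval, global_iv: ProportionInterval
) -> str:
    """Compare a family interval to the overall-flora interval.

    Strict inequalities: overused iff the family lower bound exceeds the
    global upper bound, underused iff the family upper bound falls below
    the global lower bound; any overlap (including ties) is ``ns``.
    """
    if family_iv.level != global_iv.level:
        raise ValueError(
            f"interval levels differ: {family_iv.level} vs {global_iv.level}"
        )
    if family_iv.lower > global_iv.upper:
        return "overused"
    if family_iv.upper < global_iv.lower:
        return "underused"
    return "ns"


def analyze_flora(
    table: FloraTable, config: ModelConfig | None = None
) -> tuple[list[FamilyResult], AnalysisSummary]:
    """Compute both models' intervals and statuses for every family."""
    config = config or ModelConfig()
    g_bayes = global_interval(table, "bayes", config)
    g_idm = global_interval(table, "idm", config)

    results = []
    for fam in table:
        iv_b = bayes_interval(
            fam.x_used, fam.n_total, level=config.level, variant=config.bayes_variant
        )
        iv_i = idm_interval(fam.x_used, fam.n_total, s=config.idm_s, level=config.level)
        results.append(
            FamilyResult(
                family=fam.family,
                n_total=fam.n_total,
                x_used=fam.x_used,
                bayes=iv_b,
                idm=iv_i,
                status_bayes=classify_family(iv_b, g_bayes),
                status_idm=classify_family(iv_i, g_idm),
            )
        )

    counts_b = {s: sum(r.status_bayes == s for r in results) for s in STATUSES}
    counts_i = {s: sum(r.status_idm == s for r in results) for s in STATUSES}
    summary = AnalysisSummary(
        n_families=len(results),
        counts_bayes=counts_b,
        counts_idm=counts_i,
        global_bayes=g_bayes,
        global_idm=g_idm,
        config=config,
    )
    return results, summary


def compare_models(results: list[FamilyResult]) -> dict[str, tuple[str, str]]:
    """Families whose two model statuses disagree, as
    {family: (status_bayes, status_idm)}."""
    return {
        r.family: (r.status_bayes, r.status_idm)
        for r in results
        if r.status_bayes != r.status_idm
    }


def format_bound(value: float, decimals: int = 7) -> str:
    """Round-half-up fixed-point rendering, e.g. 0.0068357."""
    q = Decimal(1).scaleb(-decimals)
    return f"{Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP):.{decimals}f}"


def results_to_frame(results: list[FamilyResult]) -> pd.DataFrame:
    """Results as a DataFrame with 7-decimal string bounds (table layout)."""
    return pd.DataFrame(
        {
            "family": [r.family for r in results],
            "n_total": [r.n_total for r in results],
            "x_used": [r.x_used for r in results],
            "bayes_lower": [format_bound(r.bayes.lower) for r in results],
            "bayes_upper": [format_bound(r.bayes.upper) for r in results],
            "status_bayes": [r.status_bayes for r in results],
            "idm_lower": [format_bound(r.idm.lower) for r in results],
            "idm_upper": [format_bound(r.idm.upper) for r in results],
            "status_idm": [r.status_idm for r in results],
        }
    )
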