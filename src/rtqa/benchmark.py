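"""Practice-level aggregation of scorecards and outlier flagging.

Pass rates per practice and measure exclude NOT_APPLICABLE and
NOT_EVALUABLE results from the denominator. A practice is flagged on a
measure when its pass count falls in either tail of the exact binomial
distribution at the pooled national rate for its own n (tail probability
below alpha/2) — the simplest defensible surveillance baseline, stated in
the output metadata. No multiple-testing correction is applied by default;
an optional Bonferroni switch is surfaced, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .cqm import Result, ScoreCard
from .errors import WiringError


@dataclass
class MeasureStats:
    n_evaluable: int = 0
    n_pass: int = 0

    @property
    def pass_rate(self) -> Optional[float]:
        if self.n_evaluable == 0:
            return None
        return self.n_pass / self.n_evaluable


@dataclass
class PracticeSummary:
    practice_id: str
    measures: dict = field(default_factory=dict)  # measure_id -> MeasureStats

    @property
    def overall_pass_rate(self) -> Optional[float]:
        n = sum(m.n_evaluable for m in self.measures.values())
        if n == 0:
            return None
        return sum(m.n_pass for m in self.measures.values()) / n


@dataclass(frozen=True)
class OutlierFlag:
    practice_id: str
    measure_id: str
    direction: str  # BELOW | ABOVE
    practice_rate: float
    national_rate: float
    interval: tuple  # central acceptance interval on the rate scale


def summarize(scorecards: list, practice_of: dict) -> list:
    """Aggregate per-patient scorecards into per-practice pass rates.

    ``practice_of`` maps patient_key -> practice label; an unmapped patient
    is a wiring error. Only PASS/FAIL results enter the denominator.
    """
    by_practice: dict = {}
    for card in scorecards:
        if card.patient_key not in practice_of:
            raise WiringError(f"patient '{card.patient_key}' has no practice mapping")
        practice = practice_of[card.patient_key]
        summary = by_practice.setdefault(practice, PracticeSummary(practice))
        for mid, res in card.results.items():
            stats_ = summary.measures.setdefault(mid, MeasureStats())
            if res.result == Result.PASS:
                stats_.n_evaluable += 1
                stats_.n_pass += 1
            elif res.result == Result.FAIL:
                stats_.n_evaluable += 1
    return [by_practice[k] for k in sorted(by_practice)]


def national_rates(summaries: list) -> dict:
    """Pooled rate per measure: sum of passes over sum of evaluable."""
    totals: dict = {}
    for s in summaries:
        for mid, m in s.measures.items():
            t = totals.setdefault(mid, MeasureStats())
            t.n_evaluable += m.n_evaluable
            t.n_pass += m.n_pass
    return totals


def flag_outliers(summaries: list, alpha: float = 0.05,
                  bonferroni: bool = False) -> dict:
    """Flag practice-measure cells outside the exact binomial central
    interval at the pooled national rate.

    Returns ``{"flags": [OutlierFlag...], "method": metadata}``. A cell with
    pass count k out of n is flagged BELOW when P(X <= k) < alpha/2 and
    ABOVE when P(X >= k) < alpha/2 under X ~ Binomial(n, national rate).
    Cells with n = 0 are never flagged.
    """
    pooled = national_rates(summaries)
    n_tests = sum(
        1 for s in summaries for mid, m in s.measures.items()
        if m.n_evaluable > 0 and pooled[mid].pass_rate is not None
    )
    eff_alpha = alpha / n_tests if (bonferroni and n_tests) else alpha

    flags = []
    for s in summaries:
        for mid, m in s.measures.items():
            if m.n_evaluable == 0:
                continue
            p = pooled[mid].pass_rate
            if p is None:
                continue
            n, k = m.n_evaluable, m.n_pass
            lo_p = stats.binom.cdf(k, n, p)
            hi_p = stats.binom.sf(k - 1, n, p)
            lo_k = stats.binom.ppf(eff_alpha / 2, n, p)
            hi_k = stats.binom.ppf(1 - eff_alpha / 2, n, p)
            interval = (float(lo_k) / n, float(hi_k) / n)
            if lo_p < eff_alpha / 2:
                flags.append(OutlierFlag(
                    s.practice_id, mid, "BELOW", m.pass_rate, p, interval
                ))
            elif hi_p < eff_alpha / 2:
                flags.append(OutlierFlag(
                    s.practice_id, mid, "ABOVE", m.pass_rate, p, interval
                ))
    return {
        "flags": flags,
        "method": {
            "rule": "exact binomial two-tailed at pooled national rate",
            "alpha": alpha,
            "bonferroni": bonferroni,
            "effective_alpha": eff_alpha,
            "n_tests": n_tests,
        },
    }


def summaries_to_rows(summaries: list):
    """Yield flat (practice, measure, n_evaluable, n_pass, pass_rate) rows
    for CSV/DataFrame export."""
    for s in summaries:
        for mid in sorted(s.measures):
            m = s.measures[mid]
            yield {
                "practice_id": s.practice_id,
                "measure_id": mid,
                "n_evaluable": m.n_evaluable,
                "n_pass": m.n_pass,
                "pass_rate": m.pass_rate,
            }
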