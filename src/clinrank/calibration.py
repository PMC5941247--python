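"""Calibration of the predicted-significance score ranges.

The raw score of a variant is mapped to a predicted significance (CTPS) by
locating it within seven contiguous intervals on the score axis.  The
intervals come from non-parametric prediction intervals (PIs) of control
distributions: the raw scores of all two-star records of unambiguous
Mendelian significance (B, LB, US, LP, P) having at least two valid
assertions.

For each bounded class the interval endpoint nearer zero is not estimated
but fixed analytically at ``2 * weight * 0.7 * 1.0`` — the minimum score a
variant can carry while still meeting the two-star criterion with both
assertions at most five years old.  That gives +/-8.4 for P/B and +/-4.2
for LP/LB.  The PI confidence per class is then chosen as the highest level
on a grid whose zero-side PI endpoint stays outside that fixed bound, and
the zero-side endpoint is clamped to the fixed bound.  The uncertain class
has no fixed bound: its region is simply the open interval between the LB
and LP fixed bounds.

The seven output ranges partition the real line: the B/LB and LP/P PIs
overlap, and those overlaps become the combined BLB and PLP categories.
Scores beyond the extreme PI endpoints still classify as B or P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .model import AssertionSignificance, OverallSignificance, VariationRecord
from .scoring import (
    DEFAULT_CONSTANTS,
    EvaluationContext,
    ScoringConstants,
    assertion_weight,
    compute_ctrs,
    count_valid,
)

#: Maximum age factor compatible with two-star status (both assertions <= 5 y).
TWO_STAR_MAX_AGE_FACTOR = 0.7

#: Confidence levels scanned during calibration, highest first.
DEFAULT_CONFIDENCE_GRID = (0.999, 0.998, 0.995, 0.99, 0.98, 0.96, 0.95, 0.90)

_BENIGN_CLASSES = (AssertionSignificance.B, AssertionSignificance.LB)
_BOUNDED_CLASSES = (
    AssertionSignificance.B,
    AssertionSignificance.LB,
    AssertionSignificance.LP,
    AssertionSignificance.P,
)


def fixed_lower_bound(
    sig: AssertionSignificance, constants: ScoringConstants = DEFAULT_CONSTANTS
) -> float:
    """Analytic zero-side bound of a class range: 2 * w * 0.7 * 1.0.

    "Lower" means nearer zero: +4.2/+8.4 for LP/P, -4.2/-8.4 for LB/B.
    The uncertain class has no such bound.
    """
    if sig not in _BOUNDED_CLASSES:
        raise ValueError("the uncertain class has no fixed lower bound")
    return 2.0 * assertion_weight(sig, constants) * TWO_STAR_MAX_AGE_FACTOR * 1.0


def nonparametric_pi(values: Sequence[float], alpha: float) -> tuple[float, float]:
    """Distribution-free prediction interval from order statistics.

    Returns the c-th and r-th values (1-based ranks) of the ascending
    sample, with ``c = trunc(alpha/2 * (n + 1))`` and ``r = n - c + 1``.
    A fresh draw from the same distribution falls inside the interval with
    probability about ``1 - alpha``.
    """
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if any(values[i] > values[i + 1] for i in range(n - 1)):
        raise ValueError("values must be sorted ascending")
    c = math.trunc(alpha / 2.0 * (n + 1))
    if c < 1:
        raise ValueError(f"sample of {n} too small for alpha={alpha}")
    r = n - c + 1
    return float(values[c - 1]), float(values[r - 1])


@dataclass(frozen=True)
class CalibrationClassStats:
    """Control-distribution summary for one significance class."""

    significance: AssertionSignificance
    n: int
    median: float
    pi_low: float
    pi_high: float
    confidence_pct: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("control sample must have n >= 2")
        if not self.pi_low <= self.pi_high:
            raise ValueError("pi_low must not exceed pi_high")


@dataclass(frozen=True)
class _Interval:
    label: OverallSignificance
    low: float  # -inf allowed
    low_inclusive: bool
    high: float  # +inf allowed
    high_inclusive: bool

    def contains(self, x: float) -> bool:
        if x < self.low or (x == self.low and not self.low_inclusive):
            return False
        if x > self.high or (x == self.high and not self.high_inclusive):
            return False
        return True


class CtpsRangeSet:
    """Seven labelled score intervals partitioning the real line."""

    def __init__(self, intervals: Sequence[_Interval]):
        if len(intervals) != 7:
            raise ValueError("expected exactly seven intervals")
        self.intervals = tuple(intervals)
        self._validate()

    def _validate(self) -> None:
        order = [iv.label for iv in self.intervals]
        expected = [
            OverallSignificance.B,
            OverallSignificance.BLB,
            OverallSignificance.LB,
            OverallSignificance.US,
            OverallSignificance.LP,
            OverallSignificance.PLP,
            OverallSignificance.P,
        ]
        if order != expected:
            raise ValueError("intervals must run B..P in scale order")
        for left, right in zip(self.intervals, self.intervals[1:]):
            if left.high != right.low:
                raise ValueError("intervals must be contiguous")
            if left.high_inclusive == right.low_inclusive:
                raise ValueError("shared endpoints must belong to exactly one side")
        if not math.isinf(self.intervals[0].low) or not math.isinf(self.intervals[-1].high):
            raise ValueError("extreme intervals must be unbounded")

    def classify(self, score: float) -> OverallSignificance:
        """Label of the unique interval containing the score."""
        for iv in self.intervals:
            if iv.contains(score):
                return iv.label
        raise AssertionError("partition violated")  # unreachable by construction

    def boundaries(self) -> list[float]:
        """The six finite interval endpoints, ascending."""
        return [iv.high for iv in self.intervals[:-1]]


def build_calibration_set(
    records: Iterable[VariationRecord], ctx: EvaluationContext
) -> dict[AssertionSignificance, list[float]]:
    """Per-class raw-score control lists for calibration.

    Keeps records that (i) carry two stars, (ii) have an unambiguous
    Mendelian overall significance (B, LB, US, LP, P — combined and
    conflicted categories cannot anchor a single class), and (iii) have at
    least two valid assertions.  Scores are returned sorted ascending.
    """
    pure = {
        OverallSignificance.B: AssertionSignificance.B,
        OverallSignificance.LB: AssertionSignificance.LB,
        OverallSignificance.US: AssertionSignificance.US,
        OverallSignificance.LP: AssertionSignificance.LP,
        OverallSignificance.P: AssertionSignificance.P,
    }
    out: dict[AssertionSignificance, list[float]] = {s: [] for s in AssertionSignificance}
    for rec in records:
        if rec.stars != 2:
            continue
        cls = pure.get(rec.cvcs) if isinstance(rec.cvcs, OverallSignificance) else None
        if cls is None:
            continue
        if count_valid(rec.assertions) < 2:
            continue
        out[cls].append(compute_ctrs(rec.assertions, ctx))
    for values in out.values():
        values.sort()
    return out


def select_confidence(
    values: Sequence[float],
    sig: AssertionSignificance,
    grid: Sequence[float] = DEFAULT_CONFIDENCE_GRID,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> CalibrationClassStats:
    """Pick the highest grid confidence aligned to the class's fixed bound.

    Scans the confidence grid from the highest level downward and returns
    the first whose PI endpoint nearer zero does not cross the fixed
    analytic bound toward zero; that endpoint is then clamped to the fixed
    bound (widening the interval, so coverage is preserved).  The uncertain
    class, having no fixed bound, takes the highest computable confidence.
    """
    if not grid:
        raise ValueError("empty confidence grid")
    values = sorted(values)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two control scores")
    med = _median(values)
    bound = None if sig == AssertionSignificance.US else fixed_lower_bound(sig, constants)
    for conf in sorted(grid, reverse=True):
        alpha = 1.0 - conf
        try:
            lo, hi = nonparametric_pi(values, alpha)
        except ValueError:
            continue  # grid level not computable at this n
        if bound is None:
            return CalibrationClassStats(sig, n, med, lo, hi, conf * 100.0)
        if sig in _BENIGN_CLASSES:
            if hi <= bound:  # zero-side endpoint stays below the fixed bound
                return CalibrationClassStats(sig, n, med, lo, bound, conf * 100.0)
        else:
            if lo >= bound:
                return CalibrationClassStats(sig, n, med, bound, hi, conf * 100.0)
    raise ValueError(
        f"no confidence level in the grid aligns with the fixed bound for {sig.value}"
    )


def build_ctps_ranges(
    stats: Mapping[AssertionSignificance, CalibrationClassStats]
) -> CtpsRangeSet:
    """Assemble the seven score ranges from the four bounded-class PIs.

    With the B, LB, LP, P prediction intervals (zero-side endpoints already
    clamped to the fixed bounds), the ranges are::

        B    (-inf, LB.pi_low)
        BLB  [LB.pi_low, B.pi_high]      overlap of B and LB PIs
        LB   (B.pi_high, LB.pi_high]
        US   (LB.pi_high, LP.pi_low)     between the fixed bounds, open
        LP   [LP.pi_low, P.pi_low)
        PLP  [P.pi_low, LP.pi_high]      overlap of LP and P PIs
        P    (LP.pi_high, +inf)
    """
    try:
        b = stats[AssertionSignificance.B]
        lb = stats[AssertionSignificance.LB]
        lp = stats[AssertionSignificance.LP]
        p = stats[AssertionSignificance.P]
    except KeyError as e:
        raise ValueError(f"missing calibration stats for class {e}") from None
    ordered = [lb.pi_low, b.pi_high, lb.pi_high, lp.pi_low, p.pi_low, lp.pi_high]
    if any(x >= y for x, y in zip(ordered, ordered[1:])):
        raise ValueError(
            "prediction intervals do not nest into seven ordered ranges: "
            f"{ordered}"
        )
    if b.pi_low > lb.pi_low or p.pi_high < lp.pi_high:
        raise ValueError("extreme-class PI must extend beyond its neighbour's")
    O = OverallSignificance
    return CtpsRangeSet(
        [
            _Interval(O.B, -math.inf, False, lb.pi_low, False),
            _Interval(O.BLB, lb.pi_low, True, b.pi_high, True),
            _Interval(O.LB, b.pi_high, False, lb.pi_high, True),
            _Interval(O.US, lb.pi_high, False, lp.pi_low, False),
            _Interval(O.LP, lp.pi_low, True, p.pi_low, False),
            _Interval(O.PLP, p.pi_low, True, lp.pi_high, True),
            _Interval(O.P, lp.pi_high, False, math.inf, False),
        ]
    )


def calibrate(
    records: Iterable[VariationRecord],
    ctx: EvaluationContext,
    grid: Sequence[float] = DEFAULT_CONFIDENCE_GRID,
) -> tuple[dict[AssertionSignificance, CalibrationClassStats], CtpsRangeSet]:
    """Full recalibration: filter controls, select PIs, assemble ranges."""
    scores = build_calibration_set(records, ctx)
    stats = {
        sig: select_confidence(scores[sig], sig, grid, ctx.constants)
        for sig in AssertionSignificance
        if scores[sig]
    }
    return stats, build_ctps_ranges(stats)


def load_calibration_stats(path=None) -> dict[AssertionSignificance, CalibrationClassStats]:
    """Load per-class calibration constants from a TSV resource.

    Columns: significance, n, median, pi_low, pi_high, confidence_pct.
    Defaults to the packaged constants derived from the shipped two-star
    control summary.
    """
    if path is None:
        text = (
            resources.files("clinrank").joinpath("data/calibration_default.tsv").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    stats: dict[AssertionSignificance, CalibrationClassStats] = {}
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        sig = AssertionSignificance(row["significance"])
        stats[sig] = CalibrationClassStats(
            significance=sig,
            n=int(row["n"]),
            median=float(row["median"]),
            pi_low=float(row["pi_low"]),
            pi_high=float(row["pi_high"]),
            confidence_pct=float(row["confidence_pct"]),
        )
    return stats


def save_calibration_stats(
    stats: Mapping[AssertionSignificance, CalibrationClassStats], path
) -> None:
    """Write calibration constants in the same TSV resource format."""
    cols = ("significance", "n", "median", "pi_low", "pi_high", "confidence_pct")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for sig in AssertionSignificance:
            if sig not in stats:
                continue
            s = stats[sig]
            fh.write(
                "\t".join(
                    [
                        sig.value,
                        str(s.n),
                        repr(s.median),
                        repr(s.pi_low),
                        repr(s.pi_high),
                        repr(s.confidence_pct),
                    ]
                )
                + "\n"
            )


_DEFAULT_RANGES: Optional[CtpsRangeSet] = None


def default_ranges() -> CtpsRangeSet:
    """The shipped score ranges, built from the packaged calibration TSV."""
    global _DEFAULT_RANGES
    if _DEFAULT_RANGES is None:
        _DEFAULT_RANGES = build_ctps_ranges(load_calibration_stats())
    return _DEFAULT_RANGES


def _median(sorted_values: Sequence[float]) -> float:
    n = len(sorted_values)
    mid = n // 2
    if n % 2:
        return float(sorted_values[mid])
    return (sorted_values[mid - 1] + sorted_values[mid]) / 2.0
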