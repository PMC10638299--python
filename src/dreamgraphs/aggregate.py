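"""Per-dreamer "average graphs" and the MAD outlier screen.

Dreamers contribute unequal numbers of dreams, so per-dream attributes are
collapsed to one row per (dreamer, condition): the arithmetic mean of each
attribute, the dream count n, and the model weight ln(n + 1) used by the
downstream weighted linear models.

Outliers are screened per condition group on the mean node and edge counts:
a row is dropped when either mean lies more than ``threshold`` MADs from the
group median, with MAD = 1.4826 × median(|x − median(x)|) by default (the
consistency constant for normal data). The screen is a single pass; a zero
MAD or a group smaller than three rows disables it for that group with a
warning rather than flagging everything.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import ATTRIBUTE_COLUMNS, RunConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DreamerAverage:
    dreamer_id: str
    condition: str
    n_dreams: int
    means: dict = field(compare=False)
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.n_dreams < 1:
            raise ValueError("n_dreams must be positive")
        if self.weight == 0.0:
            object.__setattr__(self, "weight", math.log(self.n_dreams + 1))

    def as_dict(self) -> dict:
        row = {"dreamer_id": self.dreamer_id, "condition": self.condition,
               "n_dreams": self.n_dreams, "weight": self.weight}
        row.update(self.means)
        return row


@dataclass(frozen=True)
class ExclusionReport:
    attribute: str
    group: str
    median: float
    mad: float
    excluded: tuple[str, ...]


def average_attributes(per_dream_rows: list[dict],
                       weight_rule: str = "log_n_plus_1") -> list[DreamerAverage]:
    """Collapse per-dream attribute rows to one mean row per
    (dreamer, condition), ordered by first appearance."""
    if not per_dream_rows:
        raise ValueError("no per-dream rows to aggregate")
    groups: dict[tuple[str, str], list[dict]] = {}
    for row in per_dream_rows:
        groups.setdefault((str(row["dreamer_id"]), str(row["condition"])),
                          []).append(row)
    out = []
    for (dreamer, cond), rows in groups.items():
        attrs = [c for c in ATTRIBUTE_COLUMNS if c in rows[0]]
        means = {c: float(np.mean([r[c] for r in rows])) for c in attrs}
        n = len(rows)
        weight = math.log(n + 1) if weight_rule == "log_n_plus_1" else 1.0
        out.append(DreamerAverage(dreamer_id=dreamer, condition=cond,
                                  n_dreams=n, means=means, weight=weight))
    return out


def mad_outliers(values, threshold: float = 3.0,
                 constant: float = 1.4826) -> np.ndarray:
    """Boolean mask of points more than ``threshold`` MADs from the median.

    Degenerate cases never flag: fewer than 3 values, or MAD exactly 0
    (constant vectors), both warn and return an all-False mask.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in MAD screen")
    if x.size < 3:
        logger.warning("MAD screen skipped: only %d value(s)", x.size)
        return np.zeros(x.size, dtype=bool)
    med = float(np.median(x))
    mad = constant * float(np.median(np.abs(x - med)))
    if mad == 0.0:
        logger.warning("MAD screen skipped: zero MAD (constant values)")
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - med) > threshold * mad


def apply_exclusion(averages: list[DreamerAverage],
                    config: RunConfig | None = None
                    ) -> tuple[list[DreamerAverage], list[ExclusionReport]]:
    """Single-pass MAD screen on mean N and mean E within each condition.

    A dreamer-condition row flagged on either attribute is removed; a
    dreamer excluded under one condition keeps their rows in other
    conditions (the screen is per participant *and* dream type).
    """
    if not averages:
        raise ValueError("no dreamer averages to screen")
    cfg = config or RunConfig()
    reports: list[ExclusionReport] = []
    drop: set[tuple[str, str]] = set()
    conditions = sorted({a.condition for a in averages})
    for cond in conditions:
        rows = [a for a in averages if a.condition == cond]
        for attr in ("N", "E"):
            vals = np.array([a.means[attr] for a in rows], dtype=float)
            mask = mad_outliers(vals, cfg.mad_threshold, cfg.mad_constant)
            med = float(np.median(vals)) if vals.size else float("nan")
            mad = (cfg.mad_constant *
                   float(np.median(np.abs(vals - med)))) if vals.size else float("nan")
            excluded = tuple(a.dreamer_id for a, m in zip(rows, mask) if m)
            reports.append(ExclusionReport(attribute=f"mean {attr}",
                                           group=cond, median=med, mad=mad,
                                           excluded=excluded))
            for a, m in zip(rows, mask):
                if m:
                    drop.add((a.dreamer_id, a.condition))
                    logger.info("excluding dreamer %s in %s on mean %s",
                                a.dreamer_id, cond, attr)
    kept = [a for a in averages if (a.dreamer_id, a.condition) not in drop]
    return kept, reports
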