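"""End-to-end convenience wrappers: corpus in, per-dreamer table out."""

from __future__ import annotations

import logging

import pandas as pd

from .aggregate import average_attributes, apply_exclusion
from .annotation import Annotator, annotate_report, build_lexicon_annotator
from .corpus import DreamReport, RunConfig
from .graph import attributes_from_sequences

logger = logging.getLogger(__name__)


def per_dream_attributes(reports: list[DreamReport],
                         annotator: Annotator | None = None) -> list[dict]:
    """Annotate every report and compute its graph attribute row.

    Reports with no content lemmas are skipped with a warning.
    """
    annotator = annotator or build_lexicon_annotator()
    seqs = [annotate_report(r.text, annotator, r.report_id) for r in reports]
    meta = {r.report_id: r for r in reports}
    rows = attributes_from_sequences(
        seqs, on_skip=lambda rid: logger.warning("skipping %s: empty", rid))
    for row in rows:
        r = meta[row["report_id"]]
        row["dreamer_id"] = r.dreamer_id
        row["condition"] = r.condition
    return rows


def dreamer_table(reports: list[DreamReport],
                  annotator: Annotator | None = None,
                  config: RunConfig | None = None,
                  exclude_outliers: bool = True) -> pd.DataFrame:
    """Corpus → screened per-dreamer average-attribute table."""
    cfg = config or RunConfig()
    rows = per_dream_attributes(reports, annotator)
    averages = average_attributes(rows, weight_rule=cfg.weight_rule)
    if exclude_outliers:
        averages, _reports = apply_exclusion(averages, cfg)
    return pd.DataFrame([a.as_dict() for a in averages])
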