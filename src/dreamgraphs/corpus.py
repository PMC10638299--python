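"""Corpus records, run configuration, and file I/O.

A corpus is a flat list of dream reports. Each report carries the dreamer's
group (their history: never lucid, lucid dreamer, or out-of-body experiencer)
and the type of the individual dream, from which a five-level condition code
is derived:

====  =======================  ============
code  dreamer group            dream type
====  =======================  ============
NN    non-lucid dreamer        non-lucid
NL    lucid dreamer            non-lucid
LL    lucid dreamer            lucid
NO    OBE dreamer              non-lucid
OO    OBE dreamer              OBE
====  =======================  ============

Non-lucid dreamers by definition contribute only non-lucid dreams; any other
(group, type) pairing is rejected at read time.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger(__name__)

DREAMER_GROUPS = ("non_lucid_dreamer", "lucid_dreamer", "obe_dreamer")
DREAM_TYPES = ("non_lucid", "lucid", "obe")

#: Valid (dreamer_group, dream_type) -> condition code.
CONDITION_MAP = {
    ("non_lucid_dreamer", "non_lucid"): "NN",
    ("lucid_dreamer", "non_lucid"): "NL",
    ("lucid_dreamer", "lucid"): "LL",
    ("obe_dreamer", "non_lucid"): "NO",
    ("obe_dreamer", "obe"): "OO",
}

CONDITIONS = ("NN", "NL", "NO", "LL", "OO")

#: Canonical attribute column order for tables (ids first, then attributes).
ATTRIBUTE_COLUMNS = [
    "N", "E", "PE", "L1", "L2", "L3", "LSC", "ATD",
    "density", "diameter", "CC", "ASP",
    "mean_betweenness", "avg_neighbor_degree",
]


class CorpusError(ValueError):
    """Raised for schema or validation failures while reading a corpus."""


def derive_condition(dreamer_group: str, dream_type: str) -> str:
    """Map (dreamer_group, dream_type) to the condition code.

    Raises :class:`CorpusError` on a forbidden combination (e.g. a lucid
    dream attributed to a non-lucid dreamer).
    """
    try:
        return CONDITION_MAP[(dreamer_group, dream_type)]
    except KeyError:
        raise CorpusError(
            f"forbidden combination: dreamer_group={dreamer_group!r} "
            f"with dream_type={dream_type!r}"
        ) from None


@dataclass(frozen=True)
class DreamReport:
    """One dream report: free text plus dreamer identity and condition."""

    report_id: str
    dreamer_id: str
    dreamer_group: str
    dream_type: str
    text: str
    condition: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.dreamer_group not in DREAMER_GROUPS:
            raise CorpusError(f"unknown dreamer_group {self.dreamer_group!r}")
        if self.dream_type not in DREAM_TYPES:
            raise CorpusError(f"unknown dream_type {self.dream_type!r}")
        if not self.text or not self.text.strip():
            raise CorpusError(f"report {self.report_id!r}: empty text")
        expected = derive_condition(self.dreamer_group, self.dream_type)
        if self.condition and self.condition != expected:
            raise CorpusError(
                f"report {self.report_id!r}: condition {self.condition!r} "
                f"inconsistent with group/type (expected {expected!r})"
            )
        object.__setattr__(self, "condition", expected)


_REQUIRED = ("dreamer_id", "dreamer_group", "dream_type", "text")


def _record_from_mapping(row: dict, index: int) -> DreamReport:
    missing = [k for k in _REQUIRED if k not in row or row[k] is None]
    if missing:
        raise CorpusError(f"row {index}: missing column(s)/key(s) {missing}")
    try:
        return DreamReport(
            report_id=str(row.get("report_id") or f"r{index:05d}"),
            dreamer_id=str(row["dreamer_id"]),
            dreamer_group=str(row["dreamer_group"]),
            dream_type=str(row["dream_type"]),
            text=str(row["text"]),
        )
    except CorpusError as exc:
        raise CorpusError(f"row {index}: {exc}") from exc


def read_corpus(path: str | Path, format: str | None = None) -> list[DreamReport]:
    """Read a corpus from CSV or JSONL.

    The format is inferred from the suffix when not given. ``report_id`` is
    synthesized from the row index (``r00000`` ...) when absent, so reruns on
    the same file are stable. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such file: {path}")
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    if format not in ("csv", "jsonl"):
        raise CorpusError(f"unknown corpus format {format!r}")

    records: list[DreamReport] = []
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CorpusError(f"empty corpus file: {path}")
            for k in _REQUIRED:
                if k not in reader.fieldnames:
                    raise CorpusError(f"missing column {k!r} in {path}")
            for i, row in enumerate(reader):
                records.append(_record_from_mapping(row, i))
    else:
        with path.open(encoding="utf-8") as fh:
            i = 0
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                records.append(_record_from_mapping(json.loads(line), i))
                i += 1
    if not records:
        raise CorpusError(f"empty corpus: {path}")
    return records


def write_corpus(records: Sequence[DreamReport], path: str | Path,
                 format: str | None = None) -> None:
    """Write a corpus to CSV or JSONL (UTF-8; diacritics preserved)."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    cols = ["report_id", "dreamer_id", "dreamer_group", "dream_type",
            "condition", "text"]
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for r in records:
                w.writerow({c: getattr(r, c) for c in cols})
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps({c: getattr(r, c) for c in cols},
                                    ensure_ascii=False) + "\n")
    else:
        raise CorpusError(f"unknown corpus format {format!r}")


def write_attribute_table(records: Sequence[dict], path: str | Path) -> None:
    """Write attribute rows as CSV with a stable column order.

    Identifier columns come first, then the attributes in canonical order,
    then any extra columns. Floats are written with :func:`repr` precision so
    a read-back reproduces the values.
    """
    path = Path(path)
    if not records:
        id_cols: list[str] = ["report_id", "dreamer_id", "condition"]
        header = id_cols + ATTRIBUTE_COLUMNS
        with path.open("w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerow(header)
        return
    schema = set(records[0])
    for i, rec in enumerate(records):
        if set(rec) != schema:
            raise CorpusError(f"row {i} has a different schema than row 0")
    known_ids = [c for c in ("report_id", "dreamer_id", "dreamer_group",
                             "dream_type", "condition", "n_dreams", "weight",
                             "n_raw_tokens") if c in schema]
    attr_cols = [c for c in ATTRIBUTE_COLUMNS if c in schema]
    rest = sorted(schema - set(known_ids) - set(attr_cols))
    header = known_ids + attr_cols + rest
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for rec in records:
            w.writerow([_fmt(rec[c]) for c in header])


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def read_attribute_table(path: str | Path) -> list[dict]:
    """Read an attribute CSV back, restoring numeric types where possible."""
    out: list[dict] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            parsed: dict = {}
            for k, v in row.items():
                try:
                    parsed[k] = int(v)
                except (TypeError, ValueError):
                    try:
                        parsed[k] = float(v)
                    except (TypeError, ValueError):
                        parsed[k] = v
            out.append(parsed)
    return out


@dataclass
class RunConfig:
    """Pipeline configuration with the documented defaults.

    mad_threshold / mad_constant
        Outlier screen: flag dreamer-condition means more than
        ``threshold × constant × median(|x − median|)`` from the group median.
        1.4826 is the consistency constant that makes the MAD estimate the
        standard deviation under normality.
    weight_rule
        Per-dreamer model weight: ``log_n_plus_1`` gives ln(n_dreams + 1),
        ``uniform`` gives 1.
    sum_of_squares_type
        Type of ANOVA sums of squares for fixed-effect F tests (II or III).
    """

    annotator_name: str = "lexicon"
    mad_threshold: float = 3.0
    mad_constant: float = 1.4826
    weight_rule: str = "log_n_plus_1"
    cooccur_top_k: int = 50
    random_seed: int = 0
    sum_of_squares_type: str = "II"
    p_adjust: str = "none"

    def __post_init__(self) -> None:
        if self.mad_threshold <= 0 or self.mad_constant <= 0:
            raise ValueError("mad_threshold and mad_constant must be positive")
        if self.weight_rule not in ("log_n_plus_1", "uniform"):
            raise ValueError(f"unknown weight_rule {self.weight_rule!r}")
        if self.cooccur_top_k < 2:
            raise ValueError("cooccur_top_k must be >= 2")
        if self.sum_of_squares_type not in ("II", "III"):
            raise ValueError("sum_of_squares_type must be 'II' or 'III'")
        if self.p_adjust not in ("none", "bonferroni", "holm"):
            raise ValueError(f"unknown p_adjust {self.p_adjust!r}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are an error (no typo tolerance)."""
    if path is None:
        cfg = RunConfig()
        logger.info("config: %s", cfg)
        return cfg
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    valid = {f.name for f in dc_fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    numeric = {"mad_threshold", "mad_constant", "cooccur_top_k", "random_seed"}
    for k in numeric & set(data):
        if isinstance(data[k], bool) or not isinstance(data[k], (int, float)):
            raise ValueError(f"config key {k!r} must be numeric, got {data[k]!r}")
    cfg = RunConfig(**data)
    logger.info("config: %s", cfg)
    return cfg


def split_by_condition(records: Iterable[DreamReport]) -> dict[str, list[DreamReport]]:
    """Group reports by condition code, preserving order within groups."""
    out: dict[str, list[DreamReport]] = {}
    for r in records:
        out.setdefault(r.condition, []).append(r)
    return out
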