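"""Batch runs: ID lists or VCFs in, metric table (and annotated VCF) out.

This is the programmatic equivalent of a command-line front end: a
:class:`RunConfig` names the input kind (``vid``, ``rsid`` or ``vcf``),
the input paths, and an output prefix; :func:`run` writes
``<prefix>.tsv`` (tab-delimited, the 14 metric columns, ``.`` for missing
values), one ``<prefix>.anno.vcf`` per input VCF, and — when logging is
enabled — ``<prefix>.log`` in append mode so consecutive runs accumulate.

Records come from a local fixture file (``records_path``); wiring a remote
fetch is the caller's responsibility via :func:`clinrank.io.fetch_adapter`.
Runs with a pinned ``evaluation_date`` are byte-reproducible.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .calibration import default_ranges, load_calibration_stats, build_ctps_ranges
from .classify import annotate_record
from .io import expand_rsid, read_fixture_records, read_id_list
from .model import VariantMetrics, VariationRecord
from .scoring import EvaluationContext
from .vcf import annotate_vcf

logger = logging.getLogger("clinrank")


@dataclass
class RunConfig:
    input_kind: str  # "vid" | "rsid" | "vcf"
    input_paths: Sequence[str]
    records_path: str
    output_prefix: str = "clinrank"
    output_dir: str = "."
    log_mode: str = "none"  # "none" | "log" | "long_log"
    evaluation_date: datetime.date = field(default_factory=datetime.date.today)
    calibration_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.input_kind not in ("vid", "rsid", "vcf"):
            raise ValueError(f"unknown input kind {self.input_kind!r}")
        if not self.input_paths:
            raise ValueError("at least one input path is required")
        if self.log_mode not in ("none", "log", "long_log"):
            raise ValueError(f"unknown log mode {self.log_mode!r}")


def _select_records(
    config: RunConfig, records: Sequence[VariationRecord]
) -> list[VariationRecord]:
    by_vid = {rec.vid: rec for rec in records}
    selected: list[VariationRecord] = []
    for path in config.input_paths:
        id_list = read_id_list(path, config.input_kind)
        for ident in id_list.ids:
            if config.input_kind == "vid":
                rec = by_vid.get(ident)
                if rec is None:
                    logger.warning("Variation ID %s not found in records", ident)
                else:
                    selected.append(rec)
            else:
                selected.extend(expand_rsid(ident, records))
    return selected


def _vcf_rsids(path) -> list[str]:
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            site_id = line.split("\t")[2]
            for token in site_id.split(";"):
                if token and token != ".":
                    ids.append(token[2:] if token.lower().startswith("rs") else token)
    return ids


def write_table(metrics: Sequence[VariantMetrics], path) -> None:
    """Tab-delimited table, UTF-8, LF; header is the 14 field names."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(VariantMetrics.FIELDS) + "\n")
        for m in metrics:
            fh.write("\t".join(m.to_row()) + "\n")


def run(config: RunConfig) -> int:
    """Execute a batch run; returns 0 on success, 1 on fatal error."""
    handler: Optional[logging.Handler] = None
    root = logging.getLogger("clinrank")
    if config.log_mode in ("log", "long_log"):
        log_path = Path(config.output_dir) / f"{config.output_prefix}.log"
        handler = logging.FileHandler(log_path, mode="a", encoding="utf-8")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        root.addHandler(handler)
        root.setLevel(
            logging.DEBUG if config.log_mode == "long_log" else logging.WARNING
        )
        root.propagate = False  # log file supersedes terminal warnings
    try:
        records = read_fixture_records(config.records_path)
        if config.calibration_path:
            ranges = build_ctps_ranges(load_calibration_stats(config.calibration_path))
        else:
            ranges = default_ranges()
        ctx = EvaluationContext(evaluation_date=config.evaluation_date)
        if config.input_kind == "vcf":
            selected: list[VariationRecord] = []
            for path in config.input_paths:
                for rsid in _vcf_rsids(path):
                    selected.extend(expand_rsid(rsid, records))
        else:
            selected = _select_records(config, records)
        metrics = [annotate_record(rec, ranges, ctx) for rec in selected]
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(metrics, out_dir / f"{config.output_prefix}.tsv")
        if config.input_kind == "vcf":
            for path in config.input_paths:
                stem = Path(path).stem if len(config.input_paths) > 1 else config.output_prefix
                out_vcf = out_dir / f"{stem}.anno.vcf"
                n = annotate_vcf(path, out_vcf, records, ranges, ctx)
                logger.info("annotated %d site(s) in %s", n, path)
        if config.log_mode == "long_log":
            logger.debug("run complete: %d record(s) tabulated", len(metrics))
        return 0
    except (OSError, ValueError) as e:
        logger.error("run failed: %s", e)
        return 1
    finally:
        if handler is not None:
            root.removeHandler(handler)
            handler.close()
            root.propagate = True
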