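"""End-to-end orchestration: simulate -> filter -> score -> correlate ->
compare-stx -> samplesize, with deterministic, manifest-stamped outputs.

Every table is written as UTF-8 TSV with "NA" for unavailable values; a
JSON manifest records package version, seed, and a hash of the semantic
configuration, so identical config + seed yields an identical bundle.
Input files are never mutated; all outputs live under the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import esmeasure
from esmeasure.data_model import (
    Dataset,
    filter_analysis_visits,
    filter_subjects_with_followup,
    read_dataset,
    write_dataset,
)
from esmeasure.power import PowerSpec, sample_size_table
from esmeasure.scoring import (
    ESConfig,
    endorsed_count_table,
    es_frequency_table,
    frequency_dataframe,
    heatmap_matrix,
)
from esmeasure.simulate import GeneratorConfig, generate_cohort
from esmeasure.stats import correlation_dataframe, correlation_table, stx_comparison_tables

log = logging.getLogger("esmeasure")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``generator`` (simulate a cohort) or ``data_dir``
    (read ``scores.csv`` / ``subjects.csv``) provides the data.
    """

    out_dir: Path
    seed: int = 0
    generator: GeneratorConfig | None = None
    data_dir: Path | None = None
    thresholds: tuple[int, ...] = (1, 2, 3)
    item_sets: tuple[str, ...] = ("IB_plus_II", "IB", "II")
    stability_rule: str = "none"
    heatmap_items: tuple[str, ...] = ("2.11",)
    stx_cutoff_months: float = 12.0
    power: PowerSpec = field(
        default_factory=lambda: PowerSpec(p1=0.751, reduction=0.30)
    )
    log_level: str = "INFO"

    def semantic_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "thresholds": list(self.thresholds),
            "item_sets": list(self.item_sets),
            "stability_rule": self.stability_rule,
            "heatmap_items": list(self.heatmap_items),
            "stx_cutoff_months": self.stx_cutoff_months,
            "power": {
                "p1": self.power.p1,
                "p2": self.power.p2,
                "reduction": self.power.reduction,
                "alpha": self.power.alpha,
                "target_power": self.power.target_power,
                "dropout_rates": list(self.power.dropout_rates),
            },
            "generator": self.generator.to_dict() if self.generator else None,
            "data_dir": str(self.data_dir) if self.data_dir else None,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(level.upper())
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    return handler


def load_or_simulate(cfg: RunConfig) -> Dataset:
    if (cfg.generator is None) == (cfg.data_dir is None):
        raise ValueError("RunConfig needs exactly one of generator or data_dir")
    if cfg.generator is not None:
        gen = GeneratorConfig.from_dict({**cfg.generator.to_dict(), "seed": cfg.seed})
        ds = generate_cohort(gen)
        log.info("simulate: %d subjects, %d records", ds.n_subjects, ds.n_records)
    else:
        ds = read_dataset(
            Path(cfg.data_dir) / "scores.csv", Path(cfg.data_dir) / "subjects.csv"
        )
        log.info("load: %d subjects, %d records", ds.n_subjects, ds.n_records)
    return ds


def prepare(ds: Dataset) -> Dataset:
    """Analysis-population filters: scheduled visits only, then subjects
    with at least one scored post-baseline visit."""
    ds = filter_analysis_visits(ds)
    ds = filter_subjects_with_followup(ds)
    log.info("filter: %d subjects, %d records remain", ds.n_subjects, ds.n_records)
    return ds


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write the full table bundle; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, cfg.log_level)
    written: list[str] = []
    try:
        ds = load_or_simulate(cfg)
        if cfg.generator is not None:
            write_dataset(ds, out / "scores.csv", out / "subjects.csv")
            written += ["scores.csv", "subjects.csv"]
        ds = prepare(ds)

        freq = frequency_dataframe(
            es_frequency_table(
                ds, thresholds=cfg.thresholds, item_sets=cfg.item_sets,
                stability_rule=cfg.stability_rule,
            )
        )
        _write_tsv(freq, out / "es_frequency.tsv")
        written.append("es_frequency.tsv")
        log.info("score: es_frequency.tsv (%d rows)", len(freq))

        endorsed = endorsed_count_table(ds)
        _write_tsv(endorsed, out / "endorsed_counts.tsv")
        written.append("endorsed_counts.tsv")
        log.info("score: endorsed_counts.tsv (%d rows)", len(endorsed))

        for item in cfg.heatmap_items:
            hm = heatmap_matrix(ds, item).to_codes()
            name = f"heatmap_{item.replace('.', '_')}.tsv"
            hm.to_csv(out / name, sep="\t", na_rep="NA")
            written.append(name)
            log.info("score: %s (%d subjects)", name, len(hm))

        for measure in ("events_per_patient", "es_indicator"):
            frames = []
            for tau in cfg.thresholds:
                cells = correlation_table(
                    ds, ESConfig(threshold=tau, stability_rule=cfg.stability_rule),
                    measure=measure,
                )
                frame = correlation_dataframe(cells)
                frame.insert(0, "threshold", tau)
                frames.append(frame)
            name = f"correlations_{'events' if measure == 'events_per_patient' else 'indicator'}.tsv"
            _write_tsv(pd.concat(frames, ignore_index=True), out / name)
            written.append(name)
            log.info("correlate: %s", name)

        for tau in cfg.thresholds:
            tables = stx_comparison_tables(
                ds, ESConfig(threshold=tau, stability_rule=cfg.stability_rule),
                cutoff_months=cfg.stx_cutoff_months,
            )
            _write_tsv(tables.proportions, out / f"stx_proportions_t{tau}.tsv")
            _write_tsv(tables.events, out / f"stx_events_t{tau}.tsv")
            written += [f"stx_proportions_t{tau}.tsv", f"stx_events_t{tau}.tsv"]
            log.info("compare-stx: threshold %d", tau)

        table5 = sample_size_table(cfg.power).to_frame()
        _write_tsv(table5, out / "table5.tsv")
        written.append("table5.tsv")
        log.info("samplesize: table5.tsv")

        manifest = {
            "package": "esmeasure",
            "version": esmeasure.__version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.semantic_dict(),
            "outputs": sorted(written),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
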