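"""End-to-end orchestration: simulate (or load) -> differential expression
-> over-representation -> concordance, with every intermediate table
written, a markdown report, and a versioned JSON summary. Reruns with the
same configuration and seed produce byte-identical outputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import concordance as conc
from . import diffexp, enrichment, io, simulate
from .datamodel import PROTEIN, TRANSCRIPT

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and paths for one pipeline run.

    Defaults are the analysis constants: significance at q <= 0.05, a
    2-fold transcript fold-change requirement, 1.1/0.9 abundance-class cuts,
    a 5-per-cohort detection filter, and Jaccard 0.5 term merging.
    """

    out_dir: str = "concordia_run"
    alpha: float = 0.05
    fc_min: float = 2.0
    up_cut: float = 1.1
    down_cut: float = 0.9
    min_detect: int = 5
    jaccard: float = 0.5
    seed: int = 0
    counts_path: str | None = None
    proteins_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    scenario: dict | None = None

    def __post_init__(self) -> None:
        if min(self.alpha, self.fc_min, self.jaccard) <= 0 or self.min_detect < 0:
            raise ValueError("thresholds must be positive")
        if not self.up_cut > 1 > self.down_cut > 0:
            raise ValueError("need up_cut > 1 > down_cut > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        scenario = simulate.scenario_from_dict({**config.scenario,
                                                "seed": config.seed})
        log.info("simulating cohort (seed=%d)", config.seed)
        return simulate.generate_cohort(scenario)
    for name, path in (("counts", config.counts_path),
                       ("proteins", config.proteins_path),
                       ("design", config.design_path),
                       ("gmt", config.gmt_path)):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing {name} input: {path}")
    transcripts = io.read_expression_matrix(config.counts_path, TRANSCRIPT)
    proteins = io.read_expression_matrix(config.proteins_path, PROTEIN)
    design = io.read_design(config.design_path)
    sets = io.read_gmt(config.gmt_path)
    return transcripts, proteins, design, sets


@_stage("diffexp")
def _diffexp(transcripts, proteins, design, config):
    de_t = diffexp.transcript_de(transcripts, design, alpha=config.alpha,
                                 fc_min=config.fc_min)
    de_p = diffexp.protein_de(proteins, design, alpha=config.alpha)
    log.info("diffexp: %d transcripts (%d significant), %d proteins (%d significant)",
             len(de_t), int(de_t["significant"].sum()),
             len(de_p), int(de_p["significant"].sum()))
    return de_t, de_p


@_stage("enrichment")
def _enrich(de, sets, config, label):
    reference = list(de.index)
    out = {}
    for direction in ("up", "down"):
        hits = list(de.index[de["direction"] == direction])
        rows = enrichment.binomial_ora(hits, reference, sets, correct_fdr=True) \
            if hits else enrichment.binomial_ora([], reference, sets)
        merged = enrichment.merge_redundant_terms(rows, jaccard_min=config.jaccard)
        out[f"enrichment_{label}_{direction}"] = rows.drop(columns=["members"])
        out[f"enrichment_{label}_{direction}_merged"] = \
            merged.drop(columns=["members"]).assign(
                member_terms=merged["member_terms"].map(",".join))
        log.info("enrichment %s/%s: %d hit features, %d sets tested",
                 label, direction, len(hits), len(rows))
    return out


@_stage("concordance")
def _concordance(de_t, de_p, sets, config):
    return conc.build_summary(de_t, de_p, sets, alpha=config.alpha,
                              min_detect=config.min_detect,
                              up_cut=config.up_cut, down_cut=config.down_cut)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the full report bundle to
    ``config.out_dir``. Returns the in-memory bundle (summary dict plus all
    tables)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    transcripts, proteins, design, sets = _load_inputs(config)

    if config.scenario is not None:
        io.write_expression_matrix(transcripts, out_dir / "counts.tsv")
        io.write_expression_matrix(proteins, out_dir / "proteins.tsv")
        io.write_design(design, out_dir / "design.tsv")
        io.write_gmt(sets, out_dir / "gene_sets.gmt")

    de_t, de_p = _diffexp(transcripts, proteins, design, config)
    tables = {
        "de_transcript": de_t.reset_index(),
        "de_protein": de_p.reset_index(),
    }
    tables.update(_enrich(de_t, sets, config, "transcript"))
    tables.update(_enrich(de_p, sets, config, "protein"))

    bundle = _concordance(de_t, de_p, sets, config)
    tables["concordance_transcript"] = bundle["concordance_transcript"]
    tables["concordance_protein"] = bundle["concordance_protein"]
    tables["coupling"] = bundle["coupling"]

    summary = {
        "config": {k: v for k, v in vars(config).items() if k != "scenario"},
        "thresholds": bundle["thresholds"],
        "seed": config.seed,
        "transcript": bundle["transcript"],
        "protein": bundle["protein"],
        "set_union_transcript": bundle["set_union_transcript"],
        "set_union_protein": bundle["set_union_protein"],
        "coupling": bundle["coupling"].to_dict(orient="records"),
    }
    io.write_results_tables(tables, out_dir, summary=summary)
    _write_report(out_dir / "report.md", summary, bundle)
    log.info("wrote %d tables to %s", len(tables), out_dir)
    return {"summary": summary, **tables}


def _write_report(path: Path, summary: dict, bundle: dict) -> None:
    lines = ["# Transcriptome-proteome concordance report", ""]
    for ome in ("transcript", "protein"):
        s = summary[ome]
        lines += [
            f"## Global {ome} changes",
            "",
            f"- detected features: {s['n_detected']}",
            f"- significantly up: {s['n_significant_up']} ({s['pct_up']}%)",
            f"- significantly down: {s['n_significant_down']} ({s['pct_down']}%)",
            f"- up-vs-down proportion test p: {s['global_prop_p']:.3g}",
            "",
        ]
    for key, title in (("concordance_protein", "Per-set protein statistics"),
                       ("concordance_transcript", "Per-set transcript statistics"),
                       ("coupling", "Transcript-protein coupling")):
        lines += [f"## {title}", "", bundle[key].to_markdown(index=False), ""]
    path.write_text("\n".join(lines))
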