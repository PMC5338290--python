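"""End-to-end orchestration: network assembly through enrichment screen.

The pipeline mirrors the analysis chain the statistics modules implement:
build the bipartite network, restrict it to compound-annotated plants,
score family-level interaction Z-scores, run the feed-on-family (evenness)
and feed-on-compound (food-pairing) tests, tabulate per-plant compound
contributions, and screen each insect clade for common-specific compound
candidates.  Every stage persists a TSV so it can be audited or re-run
independently; a summary JSON collects the headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import compound_stats as cs
from . import family_networks as fn
from . import io as pio
from .model import PlantHerbivoreNetwork, restrict_to_compound_annotated
from .null_models import NullModelConfig

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "validate_inputs", "run_all"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    interactions: str = ""
    insect_taxonomy: str = ""
    plant_taxonomy: str = ""
    compounds: str = ""
    out_dir: str = "phytophagnet_out"
    levels: Sequence[str] = ("family", "subfamily")
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    enrichment_unit: str = "relationship"
    p_threshold: float = 1e-6
    v_threshold: float = 0.0
    bh_correction: bool = False

    def __post_init__(self) -> None:
        self.levels = tuple(self.levels)
        for lv in self.levels:
            if lv not in ("family", "subfamily"):
                raise ValueError(f"unsupported analysis level {lv!r}")
        if self.enrichment_unit not in ("relationship", "plant"):
            raise ValueError(f"unsupported enrichment unit {self.enrichment_unit!r}")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        nm = raw.pop("null_model", None)
        cfg = cls(**raw)
        if nm is not None:
            cfg.null_model = NullModelConfig(**nm)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d


def validate_inputs(config: PipelineConfig) -> dict:
    """Cross-reference species across tables; orphans reported, not fatal."""
    net = pio.read_interaction_table(config.interactions)
    insect_tax = pio.read_taxonomy_table(config.insect_taxonomy, side="insect")
    plant_tax = pio.read_taxonomy_table(config.plant_taxonomy, side="plant")
    cat = pio.read_compound_table(config.compounds)
    report = {
        "n_edges": net.n_edges,
        "n_insects": len(net.insects),
        "n_plants": len(net.plants),
        "insects_without_taxonomy": sorted(s for s in net.insects if s not in insect_tax),
        "plants_without_taxonomy": sorted(s for s in net.plants if s not in plant_tax),
        "compound_plants_not_in_network": sorted(cat.plants - net.plants),
        "network_plants_without_compounds": sorted(
            p for p in net.plants if not cat.compounds_of(p)
        ),
    }
    report["n_orphans"] = (
        len(report["insects_without_taxonomy"]) + len(report["plants_without_taxonomy"])
    )
    return report


def _fmt_z(result) -> str:
    return "NA" if result.degenerate else f"{result.z:.3f}"


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis chain; returns the summary dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}
    stage = "read_inputs"
    try:
        net_raw = pio.read_interaction_table(config.interactions)
        insect_tax = pio.read_taxonomy_table(config.insect_taxonomy, side="insect")
        plant_tax = pio.read_taxonomy_table(config.plant_taxonomy, side="plant")
        cat = pio.read_compound_table(config.compounds)

        stage = "compound_filter"
        net = restrict_to_compound_annotated(net_raw, cat)
        if net.n_edges == 0:
            raise ValueError("no edge survives the compound-annotation filter")
        summary["network"] = {
            "raw_edges": net_raw.n_edges,
            "raw_insects": len(net_raw.insects),
            "raw_plants": len(net_raw.plants),
            "filtered_edges": net.n_edges,
            "filtered_insects": len(net.insects),
            "filtered_plants": len(net.plants),
        }
        log.info(
            "compound filter: %d -> %d edges, %d insects, %d plants",
            net_raw.n_edges, net.n_edges, len(net.insects), len(net.plants),
        )
        pio.write_interaction_table(net, out / "network_filtered.tsv")

        stage = "family_zscores"
        for level in config.levels:
            results = fn.family_zscores(
                net, insect_tax, plant_tax, config.null_model, insect_level=level
            )
            fn.zscore_matrix_to_table(results).to_csv(
                out / f"family_z_{level}.tsv", sep="\t", index=False, na_rep="NA"
            )

        stage = "evenness_test"
        ev_global, ev_cats = fn.evenness_test(
            net, plant_tax, config.null_model, insect_tax, levels=config.levels
        )
        ev_rows = [
            {
                "category": taxon, "level": level,
                "E": r.observed, "null_mean": r.null_mean, "null_sd": r.null_sd,
                "z": r.z_or_nan(), "degenerate": r.degenerate,
            }
            for (level, taxon), r in sorted(ev_cats.items())
        ]
        pd.DataFrame(ev_rows).to_csv(out / "evenness.tsv", sep="\t", index=False, na_rep="NA")
        summary["evenness"] = {
            "mean_E_real": ev_global.observed,
            "mean_E_null": ev_global.null_mean,
            "z": None if ev_global.degenerate else ev_global.z,
            "z_printed": _fmt_z(ev_global),
        }

        stage = "food_pairing_test"
        ns_global, ns_clades = cs.feed_on_compound_test(
            net, cat, config.null_model, insect_tax, levels=config.levels
        )
        ns_table, n_excluded = cs.food_pairing_table(net, cat)
        ns_table.to_csv(out / "ns.tsv", sep="\t", index=False)
        ns_rows = [
            {
                "clade": taxon, "level": level,
                "mean_ns": r.observed, "null_mean": r.null_mean, "null_sd": r.null_sd,
                "z": r.z_or_nan(), "degenerate": r.degenerate,
            }
            for (level, taxon), r in sorted(ns_clades.items())
        ]
        pd.DataFrame(ns_rows).to_csv(out / "ns_clades.tsv", sep="\t", index=False, na_rep="NA")
        summary["food_pairing"] = {
            "mean_ns_real": ns_global.observed,
            "mean_ns_null": ns_global.null_mean,
            "z": None if ns_global.degenerate else ns_global.z,
            "z_printed": _fmt_z(ns_global),
            "excluded_species": n_excluded,
        }

        stage = "compound_contribution"
        chi_table, rho, rho_p = cs.chi_degree_profile(net, cat, plant_tax)
        chi_table.to_csv(out / "chi.tsv", sep="\t", index=False, na_rep="NA")
        summary["chi"] = {
            "mean_chi": float(chi_table["chi"].mean()) if len(chi_table) else None,
            "spearman_chi_degree": rho,
            "spearman_p": rho_p,
        }

        stage = "enrichment"
        clades = sorted({
            t for s in net.insects if (t := insect_tax.level(s, "family")) is not None
        })
        all_rows = []
        candidates: dict[str, list[str]] = {}
        for clade in clades:
            try:
                rows = cs.enrichment(
                    net, cat, insect_tax, clade, level="family",
                    unit=config.enrichment_unit,
                    p_threshold=config.p_threshold, v_threshold=config.v_threshold,
                    bh_correction=config.bh_correction,
                )
            except ValueError as exc:
                log.info("enrichment skipped for clade %s: %s", clade, exc)
                continue
            all_rows.extend(rows)
            candidates[clade] = [
                r.compound for r in rows if r.passes and r.direction == "enriched"
            ]
        pd.DataFrame([dataclasses.asdict(r) for r in all_rows]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        summary["enrichment"] = {
            "unit": config.enrichment_unit,
            "p_threshold": config.p_threshold,
            "candidates": candidates,
        }
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_report(out / "report.txt", summary)
    return summary


def _write_report(path: Path, summary: dict) -> None:
    lines = ["phytophagnet pipeline report", "=" * 29, ""]
    n = summary["network"]
    lines += [
        f"raw network: {n['raw_edges']} edges, {n['raw_insects']} insects, {n['raw_plants']} plants",
        f"compound-annotated network: {n['filtered_edges']} edges, "
        f"{n['filtered_insects']} insects, {n['filtered_plants']} plants",
        "",
        f"feed-on-family:   <E>_real = {summary['evenness']['mean_E_real']:.4f}, "
        f"<E>_null = {summary['evenness']['mean_E_null']:.4f}, Z = {summary['evenness']['z_printed']}",
        f"feed-on-compound: <Ns>_real = {summary['food_pairing']['mean_ns_real']:.4f}, "
        f"<Ns>_null = {summary['food_pairing']['mean_ns_null']:.4f}, "
        f"Z = {summary['food_pairing']['z_printed']}",
        f"chi vs degree: Spearman r = {summary['chi']['spearman_chi_degree']}",
        "",
        "common-specific candidates per clade:",
    ]
    for clade, comps in sorted(summary["enrichment"]["candidates"].items()):
        lines.append(f"  {clade}: {', '.join(comps) if comps else '(none)'}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
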