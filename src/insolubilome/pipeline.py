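"""Full-pipeline orchestration from a single TOML config.

Runs the seven analysis stages in order — differential insolubility,
total-insoluble comparison, CIP set algebra, gene-set enrichment,
disease-sharing statistics, biophysical score comparisons, and aging
expression trends — writing every stage's output as plain TSV (so any stage
can be re-run standalone) plus a JSON manifest recording input checksums,
the seed, thresholds and package version. A rerun with the same config and
seed reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .card_share import (
    category_breadth_distribution,
    compare_share_distributions,
    disease_proportion_enrichment,
    random_background,
    set_bp_union,
    share_counts,
)
from .differential import (
    SignificanceThresholds,
    add_qvalues,
    call_significant,
    paired_log_fold_change,
    total_insoluble_compare,
)
from .enrichment import hypergeom_enrich
from .scores_trends import aging_trend, compare_scores, supersaturation_fold
from .setops import DEFAULT_UNIVERSE_SIZE, ProteinSet, build_cip, map_orthologs
from .tables_io import (
    SCORE_COLUMNS,
    read_disease_catalog,
    read_expression,
    read_gmt,
    read_orthology,
    read_protein_list,
    read_quant_matrix,
    read_score_table,
    write_protein_list,
)

__all__ = ["RunConfig", "PipelineStageError", "load_run_config", "run_pipeline", "STAGES"]

STAGES = (
    "differential",
    "total_insoluble",
    "cip",
    "enrichment",
    "card_share",
    "scores",
    "trends",
)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    quant: Path
    gene_sets: Path
    orthology: Path
    disease_catalog: Path
    scores: Path
    expression: Path
    aging_set_1: Path
    aging_set_2: Path
    out_dir: Path
    q_max: float = 0.01
    lfc_min: float = 0.58
    min_peptides: int = 2
    fdr_max: float = 0.05
    p_adj_max: float = 0.05
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    seed: int = 0
    random_background_n: int = 1600
    day_window: tuple[int, int] = (2, 10)
    input_fields: tuple[str, ...] = field(
        default=(
            "quant",
            "gene_sets",
            "orthology",
            "disease_catalog",
            "scores",
            "expression",
            "aging_set_1",
            "aging_set_2",
        ),
        repr=False,
    )

    def validate(self) -> None:
        for name in self.input_fields:
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name!r} does not exist: {path}")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a TOML run config (sections: inputs, thresholds, params, output)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = Path(path).parent
    inputs = raw.get("inputs", {})
    thresholds = raw.get("thresholds", {})
    params = raw.get("params", {})
    output = raw.get("output", {})

    def _p(key: str) -> Path:
        if key not in inputs:
            raise KeyError(f"config missing inputs.{key}")
        return (base / inputs[key]).resolve()

    return RunConfig(
        quant=_p("quant"),
        gene_sets=_p("gene_sets"),
        orthology=_p("orthology"),
        disease_catalog=_p("disease_catalog"),
        scores=_p("scores"),
        expression=_p("expression"),
        aging_set_1=_p("aging_set_1"),
        aging_set_2=_p("aging_set_2"),
        out_dir=(base / output.get("dir", "run_out")).resolve(),
        q_max=float(thresholds.get("q", 0.01)),
        lfc_min=float(thresholds.get("lfc", 0.58)),
        min_peptides=int(thresholds.get("min_peptides", 2)),
        fdr_max=float(thresholds.get("fdr", 0.05)),
        p_adj_max=float(thresholds.get("p_adj", 0.05)),
        universe_size=int(params.get("universe_size", DEFAULT_UNIVERSE_SIZE)),
        seed=int(params.get("seed", 0)),
        random_background_n=int(params.get("random_background_n", 1600)),
        day_window=tuple(params.get("day_window", (2, 10))),  # type: ignore[arg-type]
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(c: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    c.validate()
    out = Path(c.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = SignificanceThresholds(
        min_peptides=c.min_peptides, q_max=c.q_max, lfc_min=c.lfc_min
    )
    manifest: dict = {
        "version": __version__,
        "seed": c.seed,
        "thresholds": asdict(thresholds) | {"fdr": c.fdr_max, "p_adj": c.p_adj_max},
        "universe_size": c.universe_size,
        "inputs": {
            name: {"path": str(getattr(c, name)), "sha256": _sha256(Path(getattr(c, name)))}
            for name in c.input_fields
        },
        "stages": [],
    }

    # --- stage 1: differential insolubility -------------------------------
    stage = "differential"
    try:
        quant = read_quant_matrix(c.quant)
        table = paired_log_fold_change(quant)
        table, qmodel = add_qvalues(table)
        increased = call_significant(table, thresholds, direction="up", name="abeta_increased")
        table.index.name = "protein_id"
        table.to_csv(out / "differential.tsv", sep="\t", na_rep="")
        write_protein_list(increased.members, out / "abeta_increased.txt")
        tested_ids = frozenset(table.index[table["tested"]])
        manifest["stages"].append(
            {
                "name": stage,
                "n_quantified": int(table["tested"].sum()),
                "n_significant_increased": len(increased),
                "pi0": qmodel.pi0,
            }
        )
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage 2: total insoluble protein ---------------------------------
    stage = "total_insoluble"
    try:
        total = total_insoluble_compare(quant)
        total.totals.to_csv(out / "total_insoluble.tsv", sep="\t", index=False)
        manifest["stages"].append({"name": stage, "p": total.p, "method": total.method})
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage 3: CIP construction ----------------------------------------
    stage = "cip"
    try:
        aging1 = ProteinSet("aging_1", frozenset(read_protein_list(c.aging_set_1)))
        aging2 = ProteinSet("aging_2", frozenset(read_protein_list(c.aging_set_2)))
        cip_res = build_cip(aging1, aging2, increased, universe=c.universe_size)
        write_protein_list(cip_res.aging_core.members, out / "aging_core.txt")
        write_protein_list(cip_res.cip.members, out / "cip.txt")
        pd.DataFrame(
            [
                {"test": "aging1_vs_aging2", **asdict(cip_res.test_aging_overlap)},
                {"test": "aging_core_vs_abeta", **asdict(cip_res.test_cip_overlap)},
            ]
        ).to_csv(out / "overlap_tests.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {
                "name": stage,
                "aging_core_size": len(cip_res.aging_core),
                "cip_size": len(cip_res.cip),
                "cip_fraction": cip_res.cip_fraction,
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage 4: gene-set enrichment of the CIP (human orthologs) --------
    stage = "enrichment"
    try:
        collection = read_gmt(c.gene_sets)
        orthology = read_orthology(c.orthology)
        query_h = map_orthologs(cip_res.cip, orthology).mapped
        background_h = map_orthologs(
            ProteinSet("tested", tested_ids), orthology
        ).mapped
        enr = hypergeom_enrich(query_h, collection, background_h)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"name": stage, "n_terms_tested": len(enr), "n_terms_fdr": int((enr["fdr"] < c.fdr_max).sum())}
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage 5: disease sharing (CARD statistic) ------------------------
    stage = "card_share"
    try:
        catalog = read_disease_catalog(c.disease_catalog)
        background_set = ProteinSet("background_insoluble", tested_ids)
        random_set = random_background(
            quant.protein_ids, n=min(c.random_background_n, len(quant.protein_ids)), seed=c.seed
        )
        profiles = {
            "cip": share_counts(cip_res.cip, catalog, collection, orthology),
            "background_insoluble": share_counts(background_set, catalog, collection, orthology),
            "random_proteome": share_counts(random_set, catalog, collection, orthology),
        }
        combined = pd.concat(profiles, names=["set", "protein_id"])
        combined.to_csv(out / "share_profiles.tsv", sep="\t")
        category_breadth_distribution(profiles).to_csv(out / "category_breadth.tsv", sep="\t")
        comparison = compare_share_distributions(profiles)
        comparison.pairwise.to_csv(out / "share_comparison.tsv", sep="\t", index=False)
        proportions = disease_proportion_enrichment(
            set_bp_union(cip_res.cip, collection, orthology), catalog
        )
        pd.DataFrame([asdict(proportions)]).to_csv(out / "disease_proportions.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {
                "name": stage,
                "H": comparison.H,
                "omnibus_p": comparison.p,
                "median_shared_ard": {g: float(np.median(t["shared_ard"])) for g, t in profiles.items()},
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage 6: biophysical score comparisons ---------------------------
    stage = "scores"
    try:
        score_table = read_score_table(c.scores)
        score_sets = {
            "cip": cip_res.cip,
            "background_insoluble": background_set,
            "random_proteome": random_set,
        }
        rows = []
        for score_name in (*SCORE_COLUMNS[:3], "sigma_f_log10"):
            cmp_res = compare_scores(score_table, score_sets, score_name)
            for _, pw in cmp_res.pairwise.iterrows():
                rows.append({"score": score_name, "H": cmp_res.H, "omnibus_p": cmp_res.omnibus_p, **pw})
        pd.DataFrame(rows).to_csv(out / "score_comparisons.tsv", sep="\t", index=False)
        fold = supersaturation_fold(score_table, cip_res.cip, random_set)
        pd.DataFrame([asdict(fold)]).to_csv(out / "supersaturation.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"name": stage, "supersaturation_fold": fold.fold_linear}
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage 7: aging expression trends ---------------------------------
    stage = "trends"
    try:
        expr = read_expression(c.expression)
        trend_table, summary = aging_trend(expr, day_window=c.day_window, alpha=c.p_adj_max)
        trend_table.to_csv(out / "trends.tsv", sep="\t", na_rep="")
        manifest["stages"].append(
            {
                "name": stage,
                "n_tested": summary.n_tested,
                "n_up": summary.n_up,
                "n_down": summary.n_down,
                "n_unchanged": summary.n_unchanged,
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
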