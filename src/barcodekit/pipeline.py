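"""End-to-end orchestration of the barcoding analysis.

One call runs the whole study design: simulate (or ingest) per-locus
reference libraries, build distance matrices, summarise the barcode gap,
optimise per-locus thresholds, score the three identification estimators,
run the market-query matching, and place queries on a bootstrapped NJ tree.
Outputs are the familiar report tables: a per-locus distance summary
(table1.tsv), an identification-efficacy table (table2.tsv), a market
report (table3.tsv), the per-individual gap table (gaps.tsv), the query
tree (tree.nwk) and placements, plus a machine-readable summary.json and
the resolved run configuration.

The run is a pure function of (inputs, config, seed): re-running with the
same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gap_analysis, identification, query_match, synthetic_data, tree as tree_mod
from .core_io import ReferenceLibrary, concatenate, write_alignment
from .distances import DEFAULT_MIN_OVERLAP, build_distance_matrix
from .synthetic_data import Degradation, SyntheticConfig, TruthTable

logger = logging.getLogger("barcodekit")

#: Per-locus simulation defaults emulating the study's two plastid barcodes
#: (alignment length, mean inter- and intraspecific K2P divergence).
DEFAULT_LOCI: dict[str, dict] = {
    "rbcLa": {"seq_length": 552, "inter_target": 0.080, "intra_target": 0.0002},
    "matK": {"seq_length": 915, "inter_target": 0.220, "intra_target": 0.0008},
}


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run (JSON-serialisable)."""

    seed: int = 0
    n_species: int = 108
    individuals_per_species: tuple[int, int] | int = (1, 3)
    loci: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOCI.items()})
    kappa: float = 2.0
    model: str = "k2p"
    min_overlap: int = DEFAULT_MIN_OVERLAP
    n_queries: int = 18
    n_failures: int = 2
    mislabel_rate: float = 5 / 18
    truncate_frac: float = 0.3
    n_mask_frac: float = 0.02
    bold_threshold: float = 0.01
    bootstrap_reps: int = 100
    query_locus: str = "matK"
    min_identity: float = 90.0

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if isinstance(d.get("individuals_per_species"), list):
            d["individuals_per_species"] = tuple(d["individuals_per_species"])
        return cls(**d)


def simulate_panel(cfg: RunConfig) -> tuple[dict[str, ReferenceLibrary], TruthTable]:
    """Simulate every configured locus over one shared specimen panel."""
    base = SyntheticConfig(
        n_species=cfg.n_species,
        individuals_per_species=cfg.individuals_per_species,
        seed=cfg.seed,
        kappa=cfg.kappa,
    )
    structure = synthetic_data.species_structure(base)
    libs: dict[str, ReferenceLibrary] = {}
    truth = None
    for i, (locus, params) in enumerate(sorted(cfg.loci.items())):
        loc_cfg = dataclasses.replace(
            base, locus=locus, seed=cfg.seed + 7919 * (i + 1), **params
        )
        libs[locus], truth = synthetic_data.generate_library(loc_cfg, structure)
    if len(libs) > 1:
        names = sorted(libs)
        combined = concatenate(libs[names[0]], libs[names[1]])
        for extra in names[2:]:
            combined = concatenate(combined, libs[extra])
        libs["combined"] = combined
    return libs, truth


def analyze_locus(
    lib: ReferenceLibrary, cfg: RunConfig
) -> tuple[gap_analysis.GapSummary, pd.DataFrame, pd.DataFrame, float]:
    """Distance, gap, threshold and efficacy analysis for one library.

    Returns (gap summary, efficacy table, individual-gap table, optimised
    threshold).
    """
    m = build_distance_matrix(lib, model=cfg.model, min_overlap=cfg.min_overlap)
    species_of = lib.species_of()
    t_opt, _profile = identification.optimize_threshold(m, species_of)
    summary = gap_analysis.summarize_locus(lib, m, optimized_threshold=t_opt)
    eff = identification.efficacy_table(
        lib, m, bcm_threshold=t_opt, bold_threshold=cfg.bold_threshold
    )
    gaps = gap_analysis.gaps_table(gap_analysis.individual_gaps(m, species_of))
    gaps.insert(0, "locus", lib.locus)
    return summary, eff, gaps, t_opt


def run_market(
    lib: ReferenceLibrary, cfg: RunConfig
) -> tuple[pd.DataFrame, dict, list, pd.DataFrame]:
    """Degrade queries from the reference panel and adjudicate them."""
    degradation = Degradation(
        truncate_frac=cfg.truncate_frac,
        n_mask_frac=cfg.n_mask_frac,
        mislabel_rate=cfg.mislabel_rate,
    )
    queries, qtruth = synthetic_data.make_queries(
        lib,
        n_queries=cfg.n_queries,
        degradation=degradation,
        seed=cfg.seed + 104729,
        n_failures=cfg.n_failures,
    )
    lookup, vernaculars, qtruth = synthetic_data.generate_lookup(
        qtruth,
        [r.species for r in lib.reference_records()],
        mislabel_rate=cfg.mislabel_rate,
        seed=cfg.seed + 224737,
    )
    queries = synthetic_data.attach_vernaculars(queries, vernaculars)
    report = query_match.market_report(
        queries, lib, lookup, min_identity=cfg.min_identity
    )
    return report, query_match.market_summary(report), queries, qtruth


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write all artifacts into ``outdir``.

    Returns the machine-readable summary dictionary that is also written
    to summary.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cfg.to_json(outdir / "config.json")
        logger.info("stage: simulate")
        libs, truth = simulate_panel(cfg)

        logger.info("stage: per-locus analysis")
        table1_rows, eff_frames, gap_frames, thresholds = [], [], [], {}
        for locus in sorted(libs):
            summary, eff, gaps, t_opt = analyze_locus(libs[locus], cfg)
            table1_rows.append(summary.to_row())
            eff_frames.append(eff)
            gap_frames.append(gaps)
            thresholds[locus] = t_opt
        table1 = pd.DataFrame(table1_rows)
        table2 = pd.concat(eff_frames, ignore_index=True)
        gaps_all = pd.concat(gap_frames, ignore_index=True)
        table1.to_csv(outdir / "table1.tsv", sep="\t", index=False, na_rep="NA")
        table2.to_csv(outdir / "table2.tsv", sep="\t", index=False, na_rep="NA")
        gaps_all.to_csv(outdir / "gaps.tsv", sep="\t", index=False, na_rep="NA")

        logger.info("stage: market queries (%s)", cfg.query_locus)
        qlib = libs[cfg.query_locus]
        table3, market, queries, qtruth = run_market(qlib, cfg)
        table3.to_csv(outdir / "table3.tsv", sep="\t", index=False, na_rep="NA")
        qtruth.to_csv(outdir / "query_truth.tsv", sep="\t", index=False)

        logger.info("stage: tree placement")
        amplified = [q for q in queries if q.sequence.replace("-", "")]
        placed_lib = ReferenceLibrary(
            locus=qlib.locus, records=qlib.records + tuple(amplified)
        )
        boot_tree = tree_mod.bootstrap_support(
            placed_lib,
            n_reps=cfg.bootstrap_reps,
            seed=cfg.seed + 331777,
            model=cfg.model,
            min_overlap=cfg.min_overlap,
        )
        tree_mod.write_newick(boot_tree, outdir / "tree.nwk")
        species_of = {r.id: r.species for r in qlib.records}
        placements = tree_mod.annotate_queries(
            boot_tree, [q.id for q in amplified], species_of
        )
        placements.to_csv(outdir / "placements.tsv", sep="\t", index=False, na_rep="NA")

        write_alignment(
            qlib, outdir / "reference.fasta", outdir / "reference_metadata.tsv"
        )

        summary = {
            "seed": cfg.seed,
            "thresholds_pct": {k: 100.0 * v for k, v in thresholds.items()},
            "table1": table1.to_dict(orient="records"),
            "table2": table2.to_dict(orient="records"),
            "market": market,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        logger.info("run complete: %s", outdir)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    return obj
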