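"""End-to-end analysis pipeline and reproducible report bundle.

``run_pipeline`` takes either a finished contingency table (with sample
metadata and a target reference) or a simulation model, and regenerates the
full replicate-reproducibility result set: rank-abundance and
observed/expected proportions, detection-frequency records, per-class
dissimilarity summaries and the rare-OTU threshold sweep, PERMANOVA tables
for both metrics, UPGMA trees with jackknife support, PCoA coordinates with
OTU scores, and the between-run richness t-test.  Every output file carries
the configuration hash and seed so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diversity, design as design_mod, multivariate
from .simulate import MockModel, simulate_table
from .table import (
    OTUTable,
    annotate_targets,
    read_otu_table,
    read_sample_metadata,
    read_target_reference,
    write_otu_table,
)

__all__ = ["RunConfig", "run_pipeline", "compare_runs_summary"]

PAPER_MODE = {
    "rarefaction_depth": 45_609,
    "n_rarefaction_draws": 5,
    "sweep_thresholds": list(range(2, 31)),
    "n_perm": 10_000,
    "jackknife_reps": 100,
    "jackknife_fraction": 0.75,
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run; exactly one input mode.

    Table mode: ``table_path`` (+ optional ``sample_meta_path`` /
    ``target_list_path``).  Simulation mode: ``model``.
    """

    table_path: str | None = None
    sample_meta_path: str | None = None
    target_list_path: str | None = None
    model: MockModel | None = None

    rarefaction_depth: int | None = None  # None -> min sample total
    n_rarefaction_draws: int = 1
    sweep_thresholds: tuple[int, ...] = tuple(range(2, 31))
    metrics: tuple[str, ...] = ("jaccard", "bray_curtis")
    n_perm: int = 10_000
    jackknife_reps: int = 100
    jackknife_fraction: float = 0.75
    seed: int = 0
    out_dir: str = "mockrep_report"

    def __post_init__(self) -> None:
        table_mode = self.table_path is not None
        sim_mode = self.model is not None
        if table_mode == sim_mode:
            raise ValueError("exactly one of table_path / model must be set")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # destination does not change the analysis
        if self.model is not None:
            payload["model"] = dataclasses.asdict(self.model)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "model" in raw and raw["model"] is not None:
            model = raw["model"]
            if "depth_range" in model:
                model["depth_range"] = tuple(model["depth_range"])
            raw["model"] = MockModel(**model)
        if "sweep_thresholds" in raw:
            raw["sweep_thresholds"] = tuple(raw["sweep_thresholds"])
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)


def _load_table(config: RunConfig) -> OTUTable:
    if config.model is not None:
        table, _ = simulate_table(config.model, seed=config.seed)
        return table
    meta = (
        read_sample_metadata(config.sample_meta_path)
        if config.sample_meta_path
        else None
    )
    table = read_otu_table(config.table_path, sample_meta=meta)
    if config.target_list_path:
        table = annotate_targets(table, read_target_reference(config.target_list_path))
    return table


def _write_tsv(df: pd.DataFrame, path: pathlib.Path, header_lines: list[str],
               index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def compare_runs_summary(table: OTUTable) -> dict:
    """Run-level reproducibility summary.

    Per run: per-sample richness and mean +/- SD non-target richness.
    Dataset level: OTUs present in exactly one run (run-exclusive) and the
    histogram of their total read counts.  Single-run tables get an empty
    run-exclusive section with a notice.
    """
    runs = sorted(table.sample_meta["run"].unique())
    rich_all = design_mod.richness_per_sample(table, "all")
    rich_nt = design_mod.richness_per_sample(table, "non_target")
    per_run = {}
    run_presence = {}
    for r in runs:
        samples = table.sample_meta.index[table.sample_meta["run"] == r]
        sub = table.counts.loc[samples]
        run_presence[r] = sub.sum(axis=0) > 0
        nt = rich_nt[samples]
        per_run[int(r)] = {
            "samples": list(samples),
            "richness": {s: int(rich_all[s]) for s in samples},
            "nontarget_richness_mean": float(nt.mean()),
            "nontarget_richness_sd": float(nt.std(ddof=1)) if len(nt) > 1 else 0.0,
        }
    out = {"per_run": per_run, "notice": None}
    if len(runs) < 2:
        out["run_exclusive"] = []
        out["notice"] = "single-run table: run-exclusive section is empty"
        return out
    presence = pd.DataFrame(run_presence)
    exclusive = presence.index[(presence.sum(axis=1) == 1) & presence.any(axis=1)]
    nontarget = set(table.nontarget_ids())
    excl_nt = [o for o in exclusive if o in nontarget]
    totals = table.otu_totals()
    out["run_exclusive"] = list(exclusive)
    out["run_exclusive_nontarget"] = excl_nt
    out["run_exclusive_read_histogram"] = (
        totals[exclusive].value_counts().sort_index().to_dict()
    )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; writes the report bundle and returns the
    in-memory results keyed by output name."""
    out_dir = pathlib.Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = [f"config_hash={chash}", f"seed={config.seed}"]
    results: dict = {"config_hash": chash, "seed": config.seed}

    table = _load_table(config)
    write_otu_table(table, out_dir / "otu_table.tsv")
    repl = design_mod.ReplicateDesign.from_table(table)
    results["table"] = table

    # -- rarefaction ----------------------------------------------------
    depth = config.rarefaction_depth or int(table.sample_totals().min())
    draw_seeds = np.random.SeedSequence(config.seed).spawn(
        config.n_rarefaction_draws + 2
    )
    rarefied_draws = [
        diversity.rarefy(table, depth, np.random.default_rng(s))
        for s in draw_seeds[: config.n_rarefaction_draws]
    ]
    rarefied = rarefied_draws[0]
    results["rarefied"] = rarefied
    results["rarefaction_depth"] = depth

    # -- abundance summaries -------------------------------------------
    rank = diversity.rank_abundance(table)
    _write_tsv(rank, out_dir / "rank_abundance.tsv", header)
    results["rank_abundance"] = rank

    targets = table.target_ids()
    if targets:
        expected = pd.Series(1.0 / len(targets), index=targets)
        obs_exp, _ = diversity.observed_vs_expected(table, expected)
        _write_tsv(obs_exp, out_dir / "observed_vs_expected.tsv", header)
        results["observed_vs_expected"] = obs_exp

    det = diversity.detection_frequency(table)
    det_df = pd.DataFrame([dataclasses.asdict(r) for r in det])
    _write_tsv(det_df, out_dir / "detection_frequency.tsv", header)
    results["detection_frequency"] = det_df

    summary = compare_runs_summary(table)
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump({"config_hash": chash, "seed": config.seed, **summary}, fh,
                  indent=2, default=str)
    results["run_summary"] = summary

    # -- dissimilarity, sweep, multivariate per metric ------------------
    perm_seed_root = np.random.SeedSequence(config.seed).spawn(1)[0]
    factors = pd.DataFrame(
        {
            "run": table.sample_meta["run"].astype(str),
            "primer": table.sample_meta["primer_index"].astype(str),
        },
        index=table.sample_meta.index,
    )
    for metric in config.metrics:
        dm = diversity.pairwise_distances(rarefied, metric)
        dm.to_tsv(out_dir / f"distance_{metric}.tsv")
        results[f"distance_{metric}"] = dm

        summaries = design_mod.summarize_by_class(dm, repl)
        cls_df = pd.DataFrame(
            [
                {
                    "pair_class": s.pair_class.value,
                    "n_pairs": s.n_pairs,
                    "min": s.min,
                    "mean": s.mean,
                    "max": s.max,
                    "sd": s.sd,
                }
                for s in summaries
            ]
        )
        _write_tsv(cls_df, out_dir / f"class_summary_{metric}.tsv", header)
        results[f"class_summary_{metric}"] = summaries

        sweep = diversity.threshold_sweep(
            rarefied, config.sweep_thresholds, metric, repl
        )
        _write_tsv(sweep.summary(), out_dir / f"sweep_{metric}.tsv", header)
        results[f"sweep_{metric}"] = sweep

        perm = multivariate.permanova(
            dm, factors[["run", "primer"]], n_perm=config.n_perm,
            seed=np.random.default_rng(perm_seed_root),
        )
        _write_tsv(perm.to_dataframe(), out_dir / f"permanova_{metric}.tsv", header)
        results[f"permanova_{metric}"] = perm

        tree = multivariate.upgma(dm)
        jk_depth = int(round(config.jackknife_fraction * depth))
        tree = multivariate.jackknife_support(
            rarefied, metric, tree,
            n_reps=config.jackknife_reps,
            subsample_depth=jk_depth,
            seed=np.random.SeedSequence(config.seed + 1),
        )
        with open(out_dir / f"upgma_{metric}.nwk", "w") as fh:
            fh.write(f"# config_hash={chash} seed={config.seed}\n")
            fh.write(tree.newick() + "\n")
        results[f"upgma_{metric}"] = tree

    dm_bc = results.get("distance_bray_curtis") or diversity.pairwise_distances(
        rarefied, "bray_curtis"
    )
    pc = multivariate.pcoa(dm_bc)
    coords = pc.coordinates.copy()
    coords.index.name = "sample_id"
    _write_tsv(coords, out_dir / "pcoa_coordinates.tsv", header, index=True)
    scores = multivariate.otu_scores(rarefied, pc, n_axes=2)
    scores.index.name = "otu_id"
    _write_tsv(scores, out_dir / "pcoa_otu_scores.tsv", header, index=True)
    results["pcoa"] = pc
    results["pcoa_otu_scores"] = scores

    # -- richness t-test between runs ----------------------------------
    runs = sorted(table.sample_meta["run"].unique())
    if len(runs) == 2:
        rich = design_mod.richness_per_sample(table, "all")
        groups = [
            rich[table.sample_meta.index[table.sample_meta["run"] == r]] for r in runs
        ]
        t, df_w, p = design_mod.welch_t(groups[0], groups[1])
        ttest = {"t": t, "df": df_w, "p": p,
                 "group_means": [float(g.mean()) for g in groups]}
        with open(out_dir / "richness_ttest.json", "w") as fh:
            json.dump({"config_hash": chash, "seed": config.seed, **ttest}, fh, indent=2)
        results["richness_ttest"] = ttest

    return results
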