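"""End-to-end orchestration of the four standard analyses.

From one config (YAML/JSON-compatible dict) the pipeline produces, under an
output directory: the simulated or loaded cohort, the normalized matrix,
ranked lists (.rnk) for every comparison, the top/bottom-k set library
(.gmt), per-list enrichment tables, a cross-enrichment NES matrix, volcano
tables, and a run manifest with content hashes so deterministic stages can
be verified bit-for-bit on rerun.

Analyses, mirroring the study's structure:
1. baseline tumor-vs-brain signature (ranked list + volcano);
2. 72 h vs baseline per animal, aggregated per (tissue, treatment) arm;
3. post-treatment tumor-vs-brain at 72 h per arm;
4. all-vs-all signature enrichment against the cohort's top/bottom-k sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import PeakAreaMatrix, RankedList
from .diffstats import volcano_frame, volcano_table
from .enrichment import EnrichmentParams, cross_enrichment_matrix, enrich, results_table
from .io_formats import read_peak_matrix, write_gmt, write_peak_matrix, write_rnk
from .preprocess import preprocess
from .ranking import (
    build_set_library,
    group_fc_ranked_list,
    mean_rank_aggregate,
    paired_fc_ranked_list,
)
from .synthetic_data import SimulationConfig, simulate_cohort

log = logging.getLogger("mdxmet.pipeline")

DECISION_LOG = {
    "tie_policy": "lexicographic by metabolite id",
    "normalization": "per-sample median over detected metabolites = 1",
    "missing_in_group_means": "contributes 0",
    "longitudinal_blocks": "t1-only by raw t1 peak area on top; "
                           "t0-only by raw t0 peak area at the bottom",
    "enrichment_weight": "|score|^w, w=1; rank-only lists scored N+1-rank",
    "volcano_thresholds": "strict fc > cut and p < cut; down at fc < 1/cut",
}


def derive_seed(seed: int, counter: int) -> int:
    """Counter-based child seed so adding stages never perturbs earlier
    stages' draws; always < 2^31."""
    return int(np.random.default_rng([abs(int(seed)), counter]).integers(2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {detail}")


def run_analysis(config: dict, out_dir: str | Path) -> Path:
    """Run the configured analyses; returns the output directory.

    Config keys (all optional except one of ``simulation`` / ``input``):
    ``seed`` (global, fanned out per stage), ``simulation`` (overrides for
    the cohort generator), ``input`` (``matrix``/``metadata`` paths),
    ``preprocess`` (``threshold``, ``mode``, ``filter_before_normalization``),
    ``enrichment`` (``weight_exponent``, ``n_permutations``, ``log2_scores``),
    ``set_k`` (library set size), ``volcano`` (``fc_cut``, ``p_cut``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    outputs: dict[str, str] = {}

    def save(path: Path) -> None:
        outputs[str(path.relative_to(out))] = _sha256(path)

    # -- stage: cohort ------------------------------------------------------
    truth = None
    if "simulation" in config:
        sim_kwargs = dict(config["simulation"] or {})
        for key in ("tumor_fc_range", "injury_fc_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_kwargs.setdefault("seed", derive_seed(seed, 0))
        sim_config = SimulationConfig(**sim_kwargs)
        matrix, truth = simulate_cohort(sim_config)
        write_peak_matrix(matrix, out / "matrix.csv", out / "metadata.csv")
        truth.to_json(out / "ground_truth.json")
        for f in ("matrix.csv", "metadata.csv", "ground_truth.json"):
            save(out / f)
    elif "input" in config:
        matrix = read_peak_matrix(config["input"]["matrix"],
                                  config["input"]["metadata"],
                                  config["input"].get("dialect"))
    else:
        raise PipelineError("cohort", "config needs a 'simulation' or 'input' block")

    # -- stage: preprocess --------------------------------------------------
    pp = config.get("preprocess", {})
    try:
        processed, report = preprocess(
            matrix, threshold=float(pp.get("threshold", 0.90)),
            mode=pp.get("mode", "per_sample_median"),
            filter_before_normalization=bool(
                pp.get("filter_before_normalization", True)))
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError("preprocess", str(e)) from e
    write_peak_matrix(processed, out / "normalized_matrix.tsv")
    save(out / "normalized_matrix.tsv")
    log.info("preprocess: %d -> %d metabolites (threshold %.2f)",
             report.n_metabolites_in, report.n_metabolites_out,
             report.detection_threshold or float("nan"))

    en = config.get("enrichment", {})
    params = EnrichmentParams(
        weight_exponent=float(en.get("weight_exponent", 1.0)),
        n_permutations=int(en.get("n_permutations", 1000)),
        seed=en.get("seed", derive_seed(seed, 1)),
        log2_scores=bool(en.get("log2_scores", False)))
    k = int(config.get("set_k", 35))
    vk = config.get("volcano", {})
    fc_cut = float(vk.get("fc_cut", 1.5))
    p_cut = float(vk.get("p_cut", 0.05))

    lists: dict[str, RankedList] = {}
    rnk_dir = out / "ranked_lists"
    rnk_dir.mkdir(exist_ok=True)

    def emit_list(name: str, rl: RankedList) -> None:
        lists[name] = rl
        write_rnk(rl, rnk_dir / f"{name}.rnk")
        (rnk_dir / f"{name}.provenance.json").write_text(
            json.dumps(rl.provenance, indent=1, default=str), encoding="utf-8")
        save(rnk_dir / f"{name}.rnk")
        save(rnk_dir / f"{name}.provenance.json")

    meta = processed.samples.loc[list(processed.values.columns)]

    # -- stage: baseline signature + volcano --------------------------------
    tum = processed.select_samples(tissue="tumor", timepoint="baseline")
    brn = processed.select_samples(tissue="brain", timepoint="baseline")
    if tum and brn:
        try:
            baseline = group_fc_ranked_list(
                processed, {"tissue": "tumor", "timepoint": "baseline"},
                {"tissue": "brain", "timepoint": "baseline"})
            emit_list("tumor_vs_brain_baseline", baseline)
            rows, counts = volcano_table(
                processed, {"tissue": "tumor", "timepoint": "baseline"},
                {"tissue": "brain", "timepoint": "baseline"},
                fc_cut=fc_cut, p_cut=p_cut)
            vf = volcano_frame(rows)
            vf.to_csv(out / "volcano_tumor_vs_brain_baseline.tsv",
                      sep="\t", index=False)
            save(out / "volcano_tumor_vs_brain_baseline.tsv")
            (out / "volcano_counts.json").write_text(
                json.dumps(counts), encoding="utf-8")
            save(out / "volcano_counts.json")
            log.info("volcano: %s", counts)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("baseline_signature", str(e)) from e

    # -- stage: longitudinal per-animal lists + per-arm aggregates ----------
    for tissue in ("tumor", "brain"):
        for arm in ("vehicle", "TMZ"):
            ids = processed.select_samples(tissue=tissue, timepoint="h72",
                                           treatment=arm)
            animals = sorted(meta.loc[ids, "animal_id"].unique())
            if not animals:
                continue
            try:
                per_animal = []
                for a in animals:
                    rl = paired_fc_ranked_list(processed, a)
                    emit_list(f"h72_vs_baseline_{tissue}_{arm}_{a}", rl)
                    per_animal.append(rl)
                if len(per_animal) >= 2:
                    emit_list(f"h72_vs_baseline_{tissue}_{arm}_mean_rank",
                              mean_rank_aggregate(per_animal))
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"longitudinal_{tissue}_{arm}", str(e)) from e

    # -- stage: post-treatment tumor-vs-brain per arm ------------------------
    for arm in ("vehicle", "TMZ"):
        tum72 = processed.select_samples(tissue="tumor", timepoint="h72",
                                         treatment=arm)
        brn72 = processed.select_samples(tissue="brain", timepoint="h72",
                                         treatment=arm)
        if tum72 and brn72:
            try:
                emit_list(f"tumor_vs_brain_h72_{arm}", group_fc_ranked_list(
                    processed, tum72, brn72))
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"post_treatment_{arm}", str(e)) from e

    # -- stage: set library + cross-enrichment ------------------------------
    try:
        eligible = {n: rl for n, rl in lists.items() if len(rl) >= 2 * k}
        library = build_set_library(eligible, k=k)
        write_gmt(library, out / "set_library.gmt")
        save(out / "set_library.gmt")
        cross = cross_enrichment_matrix(lists, library, params)
        cross.nes.to_csv(out / "cross_enrichment_nes.tsv", sep="\t")
        cross.fdr.to_csv(out / "cross_enrichment_fdr.tsv", sep="\t")
        cross.significant().to_csv(out / "cross_enrichment_significant.tsv",
                                   sep="\t")
        for f in ("cross_enrichment_nes.tsv", "cross_enrichment_fdr.tsv",
                  "cross_enrichment_significant.tsv"):
            save(out / f)
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        for ln, per_set in cross.results.items():
            results_table(per_set).to_csv(enr_dir / f"{ln}.tsv", sep="\t",
                                          index=False)
            save(enr_dir / f"{ln}.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("enrichment", str(e)) from e

    # -- manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "library_versions": {"numpy": np.__version__,
                             "pandas": pd.__version__},
        "config": config,
        "seed": seed,
        "derived_seeds": {"simulation": derive_seed(seed, 0),
                          "enrichment": params.seed},
        "decision_log": DECISION_LOG,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str),
                                       encoding="utf-8")
    return out
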