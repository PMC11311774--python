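"""Synthetic longitudinal microdialysate cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
metabolite × sample peak-area table with ~log-normal abundances spanning
orders of magnitude, multiplicative per-sample scaling (what median
normalization removes), detection-limit missingness, and three planted
effect layers —

* a tumor-vs-brain signature (default 38 up / 33 down metabolites, fold
  changes 1.5–4×, plus one oncometabolite-like marker at 20×, echoing the
  elevated 2-hydroxyglutarate of an IDH-mutant xenograft);
* an injury response in brain samples at 72 h after catheter placement,
  overlapping the tumor-up signature by a configurable fraction ``rho``
  (the injury-resembles-tumor structure the enrichment analysis detects);
* multiplicative attenuation of the injury log-effects by ``alpha`` under
  TMZ treatment.

The default cohort mirrors the study design: 9 tumor + 12 brain animals
sampled at baseline, of which 3 per (tissue × treatment) arm are resampled
at 72 h — 33 samples in total. Baseline and 72 h samples of one animal
share an animal-level random effect, so within-animal fold changes are
less noisy than between-animal ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PeakAreaMatrix, ValidationError
from .enrichment import EnrichmentParams, enrich
from .preprocess import preprocess
from .ranking import (
    build_set_library,
    group_fc_ranked_list,
    mean_rank_aggregate,
    paired_fc_ranked_list,
)

LN10 = float(np.log(10.0))


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the study conditions.

    Effect sizes are fold changes (drawn log-uniformly within the stated
    ranges); noise parameters are standard deviations of the underlying
    normal in natural-log space.
    """

    n_metabolites: int = 226
    n_tumor_baseline: int = 9
    n_brain_baseline: int = 12
    n_per_arm_72h: int = 3
    log10_abundance_mean: float = 5.3
    log10_abundance_sd: float = 0.6
    sample_scale_sd: float = 0.3
    residual_sd: float = 0.25
    n_tumor_up: int = 38
    n_tumor_down: int = 33
    tumor_fc_range: tuple[float, float] = (1.5, 4.0)
    oncometabolite_fc: float = 20.0
    injury_overlap_rho: float = 0.5
    n_injury: int = 40
    injury_fc_range: tuple[float, float] = (1.5, 3.0)
    tmz_attenuation_alpha: float = 0.3
    detection_limit_quantile: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in ("injury_overlap_rho", "tmz_attenuation_alpha",
                     "detection_limit_quantile"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        n_overlap = round(self.injury_overlap_rho * self.n_injury)
        if n_overlap > self.n_tumor_up:
            raise ValidationError(
                f"injury overlap ({n_overlap}) exceeds the tumor-up set "
                f"({self.n_tumor_up})")
        n_neutral = (self.n_metabolites - self.n_tumor_up - self.n_tumor_down)
        if self.n_injury - n_overlap > n_neutral:
            raise ValidationError("not enough neutral metabolites for the "
                                  "non-overlapping injury set")
        if self.n_tumor_up + self.n_tumor_down > self.n_metabolites:
            raise ValidationError("planted tumor sets exceed the metabolome")
        if self.n_per_arm_72h > min(self.n_tumor_baseline // 2,
                                    self.n_brain_baseline // 2):
            raise ValidationError("not enough baseline animals to fill both "
                                  "72 h treatment arms")


def noise_controlled_config(seed: int = 0) -> SimulationConfig:
    """Low-noise recovery conditions: planted effects kept off the 1.5×
    decision boundary and no detection dropout, so the volcano classifier
    can in principle recover the planting record exactly."""
    return dataclasses.replace(SimulationConfig(), seed=seed,
                               residual_sd=0.05,
                               tumor_fc_range=(2.0, 4.0),
                               detection_limit_quantile=0.0)


@dataclass
class GroundTruth:
    """The planting record serialized beside every simulated cohort."""

    tumor_up_ids: list[str]
    tumor_down_ids: list[str]
    injury_ids: list[str]
    oncometabolite_id: str
    tumor_log_fc: dict[str, float]   # ln fold change, tumor vs brain (signed)
    injury_log_fc: dict[str, float]  # ln fold change, 72 h vs baseline brain
    config: SimulationConfig | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tumor_up_ids": self.tumor_up_ids,
            "tumor_down_ids": self.tumor_down_ids,
            "injury_ids": self.injury_ids,
            "oncometabolite_id": self.oncometabolite_id,
            "tumor_log_fc": self.tumor_log_fc,
            "injury_log_fc": self.injury_log_fc,
            "config": dataclasses.asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        cfg = payload.pop("config", None)
        if cfg is not None:
            cfg["tumor_fc_range"] = tuple(cfg["tumor_fc_range"])
            cfg["injury_fc_range"] = tuple(cfg["injury_fc_range"])
            cfg = SimulationConfig(**cfg)
        return cls(config=cfg, **payload)


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    tumor_animals = [f"T{i + 1:02d}" for i in range(config.n_tumor_baseline)]
    brain_animals = [f"B{i + 1:02d}" for i in range(config.n_brain_baseline)]
    k = config.n_per_arm_72h
    for animals, tissue in ((tumor_animals, "tumor"), (brain_animals, "brain")):
        for i, animal in enumerate(animals):
            if i < k:
                arm = "vehicle"
            elif i < 2 * k:
                arm = "TMZ"
            else:
                arm = "none"
            rows.append({"sample_id": f"{animal}_baseline", "animal_id": animal,
                         "tissue": tissue, "timepoint": "baseline",
                         "treatment": arm})
            if arm != "none":
                rows.append({"sample_id": f"{animal}_h72", "animal_id": animal,
                             "tissue": tissue, "timepoint": "h72",
                             "treatment": arm})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_cohort(config: SimulationConfig | None = None,
                    ) -> tuple[PeakAreaMatrix, GroundTruth]:
    """Generate one cohort: raw peak-area matrix + metadata + planting record.

    value(m, j) = 10^μ_m · s_j · a_{m,animal(j)} · effect(m, cell(j)) · ε_mj
    in multiplicative (log-normal) structure; values below the global
    detection-limit quantile become MISSING. Reproducible given the seed.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    mets = [f"M{i + 1:04d}" for i in range(config.n_metabolites)]
    samples = _sample_table(config)
    n_met, n_samp = len(mets), len(samples)

    # planted identities
    order = rng.permutation(n_met)
    up_idx = order[:config.n_tumor_up]
    down_idx = order[config.n_tumor_up:config.n_tumor_up + config.n_tumor_down]
    neutral_idx = order[config.n_tumor_up + config.n_tumor_down:]
    n_overlap = round(config.injury_overlap_rho * config.n_injury)
    inj_from_up = rng.choice(up_idx, size=n_overlap, replace=False)
    inj_from_neutral = rng.choice(neutral_idx,
                                  size=config.n_injury - n_overlap,
                                  replace=False)
    injury_idx = np.concatenate([inj_from_up, inj_from_neutral])

    def draw_log_fc(size: int, fc_range: tuple[float, float]) -> np.ndarray:
        lo, hi = np.log(fc_range[0]), np.log(fc_range[1])
        return rng.uniform(lo, hi, size)

    tumor_log_fc = np.zeros(n_met)
    tumor_log_fc[up_idx] = draw_log_fc(len(up_idx), config.tumor_fc_range)
    tumor_log_fc[down_idx] = -draw_log_fc(len(down_idx), config.tumor_fc_range)
    onco = int(up_idx[0])
    tumor_log_fc[onco] = np.log(config.oncometabolite_fc)
    injury_log_fc = np.zeros(n_met)
    injury_log_fc[injury_idx] = draw_log_fc(len(injury_idx),
                                            config.injury_fc_range)

    # log-normal layers; the oncometabolite-like marker is planted at the
    # center of the abundance distribution: a 20× marker is only a marker
    # if it is quantifiable across the cohort, not hugging the detection limit
    mu = LN10 * rng.normal(config.log10_abundance_mean,
                           config.log10_abundance_sd, n_met)
    mu[onco] = LN10 * config.log10_abundance_mean
    log_s = rng.normal(0.0, config.sample_scale_sd, n_samp)
    animals = sorted(samples["animal_id"].unique())
    animal_ix = {a: i for i, a in enumerate(animals)}
    animal_eff = rng.normal(0.0, config.residual_sd / 2.0,
                            (n_met, len(animals)))
    eps = rng.normal(0.0, config.residual_sd, (n_met, n_samp))

    log_vals = mu[:, None] + log_s[None, :] + eps
    for j, (sid, meta) in enumerate(samples.iterrows()):
        log_vals[:, j] += animal_eff[:, animal_ix[meta["animal_id"]]]
        if meta["tissue"] == "tumor":
            log_vals[:, j] += tumor_log_fc
        if meta["tissue"] == "brain" and meta["timepoint"] == "h72":
            scale = (config.tmz_attenuation_alpha
                     if meta["treatment"] == "TMZ" else 1.0)
            log_vals[:, j] += scale * injury_log_fc

    values = np.exp(log_vals)
    if config.detection_limit_quantile > 0:
        limit = np.quantile(values, config.detection_limit_quantile)
        values = np.where(values < limit, np.nan, values)
    matrix = PeakAreaMatrix(
        values=pd.DataFrame(values, index=mets, columns=list(samples.index)),
        samples=samples, scale="raw")
    truth = GroundTruth(
        tumor_up_ids=[mets[i] for i in up_idx],
        tumor_down_ids=[mets[i] for i in down_idx],
        injury_ids=[mets[i] for i in injury_idx],
        oncometabolite_id=mets[onco],
        tumor_log_fc={mets[i]: float(tumor_log_fc[i]) for i in range(n_met)
                      if tumor_log_fc[i] != 0},
        injury_log_fc={mets[i]: float(injury_log_fc[i]) for i in range(n_met)
                       if injury_log_fc[i] != 0},
        config=config)
    return matrix, truth


@dataclass
class ArmEnrichment:
    arm: str
    nes: float
    fdr_q: float
    es: float
    p_nominal: float


@dataclass
class RecoveryReport:
    """What the full pipeline recovered of the planting record."""

    oncometabolite_rank: int | None
    jaccard_top35_tumor_up: float
    n_metabolites_retained: int
    arm_enrichment: dict[str, ArmEnrichment] = field(default_factory=dict)


def recover_signatures(matrix: PeakAreaMatrix, truth: GroundTruth,
                       params: EnrichmentParams | None = None,
                       k: int = 35, threshold: float = 0.90,
                       ) -> RecoveryReport:
    """Run the full pipeline on a simulated cohort and score it against the
    planting record.

    Stages: detection filter → median normalization → baseline tumor/brain
    fold-change list → top/bottom-k library → per-animal 72 h vs baseline
    brain lists per arm → mean-rank aggregation → enrichment of each arm's
    aggregate against the baseline tumor top-k set.
    """
    if params is None:
        seed = truth.config.seed if truth.config else 0
        params = EnrichmentParams(seed=seed)
    processed, _ = preprocess(matrix, threshold=threshold)
    baseline_list = group_fc_ranked_list(
        processed,
        numerator={"tissue": "tumor", "timepoint": "baseline"},
        denominator={"tissue": "brain", "timepoint": "baseline"})
    library = build_set_library({"tumor_vs_brain_baseline": baseline_list}, k=k)
    top_name = f"tumor_vs_brain_baseline_top{k}"

    try:
        onco_rank = baseline_list.rank_of(truth.oncometabolite_id)
    except KeyError:  # fell below the detection filter in this cohort
        onco_rank = None
    top_set = set(library[top_name].members)
    up = set(truth.tumor_up_ids)
    jaccard = len(top_set & up) / len(top_set | up)

    report = RecoveryReport(
        oncometabolite_rank=onco_rank,
        jaccard_top35_tumor_up=jaccard,
        n_metabolites_retained=len(processed.metabolite_ids))
    for arm in ("vehicle", "TMZ"):
        ids = processed.select_samples(tissue="brain", timepoint="h72",
                                       treatment=arm)
        animals = sorted(processed.samples.loc[ids, "animal_id"].unique())
        if not animals:
            continue
        per_animal = [paired_fc_ranked_list(processed, a) for a in animals]
        aggregate = mean_rank_aggregate(per_animal)
        results = enrich(aggregate, library, params)
        r = results[top_name]
        report.arm_enrichment[arm] = ArmEnrichment(
            arm=arm, nes=float(r.nes), fdr_q=float(r.fdr_q),
            es=float(r.es), p_nominal=float(r.p_nominal))
    return report
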