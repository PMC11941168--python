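"""End-to-end pipeline: simulate (or ingest) -> detect -> rank -> filter
-> intervene, with typed configuration and a reproducible run report.

Output directory layout::

    <out>/
      stages/      per-stage expression TSVs + samples.tsv + ground_truth.json
      detect/      dnb_result.json, stage_index.tsv
      rank/        ranking.tsv (gene_id, index, rank, selected), filtered.json
      intervene/   intervention.json
      report.json  config echo + all headline results + seeds + wall clock
      FAILED       only present when a stage aborted (names the stage)
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .detection import DNBDetector
from .errors import DNBKitError, InvalidConfigurationError
from .intervention import (
    compare_to_random,
    filter_by_biotype,
    ranking_from_expression,
    select_largest_gap,
    select_top,
    simulate_intervention,
)
from .io import read_annotation_tsv, read_stage_series
from .model import build_network
from .synthetic import (
    DEFAULT_MEAS_NOISE_SD,
    DEFAULT_N_SAMPLES,
    ExpressionMatrix,
    generate_stage_series,
    write_stage_series,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "PipelineError"]

log = logging.getLogger("dnbkit")


class PipelineError(DNBKitError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SimulateConfig:
    n_genes: int = 500
    dnb_size: int = 10
    intra_coupling: float = 1.0
    schedule: list[float] = field(default_factory=lambda: [0.1, 0.3, 0.5, 0.7, 0.95])
    n_samples: int = DEFAULT_N_SAMPLES
    meas_noise_sd: float = DEFAULT_MEAS_NOISE_SD
    seed: int = 42
    destabilize: str = "block"
    input_dir: str | None = None  # ingest instead of simulate when set


@dataclass
class DetectConfig:
    sd_fold_min: float = 1.5
    corr_link_min: float = 0.6
    eps: float = 1e-6
    peak_ratio_min: float = 2.0
    log2: bool = False


@dataclass
class RankConfig:
    k: int = 10
    select: str = "topk"
    restrict_to_dnb: bool = False
    excluded_biotypes: list[str] = field(default_factory=lambda: ["lncRNA"])
    annotation: str | None = None  # path to gene_id/biotype TSV


@dataclass
class InterveneConfig:
    strength: float = 0.5
    n_draws: int = 100
    seed: int = 7


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    rank: RankConfig = field(default_factory=RankConfig)
    intervene: InterveneConfig = field(default_factory=InterveneConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every block against its module's preconditions before any
        computation runs."""
        s = self.simulate
        if s.input_dir is None:
            if not (1 <= s.dnb_size < s.n_genes):
                raise InvalidConfigurationError("simulate: need 1 <= dnb_size < n_genes")
            if s.intra_coupling < 0:
                raise InvalidConfigurationError("simulate: intra_coupling must be >= 0")
            if not s.schedule:
                raise InvalidConfigurationError("simulate: schedule must be nonempty")
            if any(not (0.0 <= p < 1.0) for p in s.schedule):
                raise InvalidConfigurationError("simulate: schedule values must be in [0, 1)")
            if s.n_samples < 1:
                raise InvalidConfigurationError("simulate: n_samples must be >= 1")
            if s.meas_noise_sd < 0:
                raise InvalidConfigurationError("simulate: meas_noise_sd must be >= 0")
        d = self.detect
        if d.sd_fold_min <= 0 or d.eps <= 0 or d.peak_ratio_min <= 0:
            raise InvalidConfigurationError("detect: thresholds must be positive")
        if not (0.0 <= d.corr_link_min <= 1.0):
            raise InvalidConfigurationError("detect: corr_link_min must be in [0, 1]")
        r = self.rank
        if r.k < 1:
            raise InvalidConfigurationError("rank: k must be >= 1")
        if r.select not in ("topk", "gap"):
            raise InvalidConfigurationError("rank: select must be 'topk' or 'gap'")
        i = self.intervene
        if i.strength < 0:
            raise InvalidConfigurationError("intervene: strength must be >= 0")
        if i.n_draws < 1:
            raise InvalidConfigurationError("intervene: n_draws must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(block_cls, key):
            block = data.get(key, {}) or {}
            allowed = {f.name for f in dataclasses.fields(block_cls)}
            unknown = set(block) - allowed
            if unknown:
                raise InvalidConfigurationError(
                    f"{key}: unknown config keys {sorted(unknown)}"
                )
            return block_cls(**block)

        unknown = set(data) - {"simulate", "detect", "rank", "intervene"}
        if unknown:
            raise InvalidConfigurationError(f"unknown config sections {sorted(unknown)}")
        return cls(
            simulate=build(SimulateConfig, "simulate"),
            detect=build(DetectConfig, "detect"),
            rank=build(RankConfig, "rank"),
            intervene=build(InterveneConfig, "intervene"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: dict
    detected_stage: str
    is_significant: bool
    composite_index_by_stage: dict[str, float]
    dnb_members: list[str]
    ranking_top: list[dict]
    selected: list[str]
    filtered: list[str]
    intervention: dict | None
    superiority_fraction: float | None
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_ranking_tsv(ranking, path: Path) -> None:
    rows = []
    chosen = set(ranking.selected)
    for rank, g in enumerate(ranking.ranking, start=1):
        rows.append(
            {
                "gene_id": g,
                "index": ranking.index_of(g),
                "rank": rank,
                "selected": int(g in chosen),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunReport:
    """Execute the full workflow and write all artifacts under ``out_dir``.

    ``seed`` overrides the simulate-block seed.  Any stage failure raises
    :class:`PipelineError`; partial outputs are kept and a ``FAILED`` marker
    naming the stage is written.
    """
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # -- simulate or ingest ---------------------------------------------
        stage = "simulate"
        s = config.simulate
        sim_seed = s.seed if seed is None else int(seed)
        model = None
        if s.input_dir is not None:
            log.info("[simulate] ingesting stage series from %s", s.input_dir)
            series = read_stage_series(directory=s.input_dir)
        else:
            log.info(
                "[simulate] %d genes, %d-gene DNB, %d stages, %d samples/stage, seed %d",
                s.n_genes, s.dnb_size, len(s.schedule), s.n_samples, sim_seed,
            )
            model = build_network(
                s.n_genes,
                s.dnb_size,
                s.intra_coupling,
                seed=sim_seed,
                control_schedule=tuple(s.schedule),
                destabilize=s.destabilize,
            )
            series = generate_stage_series(
                model, s.n_samples, s.meas_noise_sd, seed=sim_seed
            )
            write_stage_series(series, out / "stages")

        # -- detect ----------------------------------------------------------
        stage = "detect"
        d = config.detect
        det = DNBDetector(
            sd_fold_min=d.sd_fold_min,
            corr_link_min=d.corr_link_min,
            eps=d.eps,
            peak_ratio_min=d.peak_ratio_min,
            log2=d.log2,
        )
        det.fit(None, series=series)
        result = det.result_
        log.info(
            "[detect] pre-disease stage %s (index %.3g, significant=%s, %d members)",
            result.predisease_stage,
            result.composite_index_by_stage[result.predisease_stage],
            result.is_significant,
            len(result.members),
        )
        ddir = out / "detect"
        ddir.mkdir(exist_ok=True)
        (ddir / "dnb_result.json").write_text(
            json.dumps(result.to_dict(), indent=2) + "\n"
        )
        pd.DataFrame(
            {
                "stage": list(result.composite_index_by_stage),
                "composite_index": list(result.composite_index_by_stage.values()),
            }
        ).to_csv(ddir / "stage_index.tsv", sep="\t", index=False, float_format="%.12g")

        # -- rank ------------------------------------------------------------
        stage = "rank"
        r = config.rank
        pre = series.stages[result.predisease_stage_index]
        if r.restrict_to_dnb and result.members:
            keep = {g: i for i, g in enumerate(pre.gene_ids)}
            rows = [keep[g] for g in result.members]
            pre = ExpressionMatrix(
                gene_ids=[pre.gene_ids[i] for i in rows],
                sample_ids=pre.sample_ids,
                values=pre.values[rows],
                stage_label=pre.stage_label,
            )
        ranking = ranking_from_expression(pre)
        if r.select == "gap":
            ranking = select_largest_gap(ranking, k_max=r.k * 5)
        else:
            ranking = select_top(ranking, k=min(r.k, len(ranking.gene_ids)))
        log.info(
            "[rank] top gene %s (index %.3g); %d selected",
            ranking.ranking[0], ranking.index_of(ranking.ranking[0]),
            len(ranking.selected),
        )
        rdir = out / "rank"
        rdir.mkdir(exist_ok=True)
        _write_ranking_tsv(ranking, rdir / "ranking.tsv")

        # -- filter ----------------------------------------------------------
        stage = "filter"
        if r.annotation is not None:
            annotation = read_annotation_tsv(r.annotation)
            filtered = filter_by_biotype(
                list(ranking.selected), annotation, set(r.excluded_biotypes)
            )
        else:
            filtered = list(ranking.selected)
        (rdir / "filtered.json").write_text(
            json.dumps({"selected": list(ranking.selected), "filtered": filtered}, indent=2)
            + "\n"
        )

        # -- intervene (needs the generative model) --------------------------
        stage = "intervene"
        intervention = None
        superiority = None
        if model is not None:
            i = config.intervene
            p_star = model.control_schedule[result.predisease_stage_index]
            targets = filtered if filtered else list(ranking.selected)
            outcome = simulate_intervention(model, p_star, targets, i.strength)
            superiority = compare_to_random(
                model,
                p_star,
                ranking,
                k=len(targets),
                strength=i.strength,
                n_draws=i.n_draws,
                seed=i.seed,
            )
            intervention = dataclasses.asdict(outcome)
            log.info(
                "[intervene] total variance %.4g -> %.4g; beats %.0f%% of random sets",
                outcome.total_var_before, outcome.total_var_after, 100 * superiority,
            )
            idir = out / "intervene"
            idir.mkdir(exist_ok=True)
            (idir / "intervention.json").write_text(
                json.dumps(
                    {"outcome": intervention, "superiority_fraction": superiority},
                    indent=2,
                )
                + "\n"
            )
        else:
            log.info("[intervene] skipped: no generative model for ingested data")

        stage = "report"
        report = RunReport(
            config=config.to_dict(),
            detected_stage=result.predisease_stage,
            is_significant=result.is_significant,
            composite_index_by_stage={
                k: float(v) for k, v in result.composite_index_by_stage.items()
            },
            dnb_members=list(result.members),
            ranking_top=[
                {"gene_id": g, "index": ranking.index_of(g)}
                for g in ranking.ranking[: len(ranking.selected)]
            ],
            selected=list(ranking.selected),
            filtered=filtered,
            intervention=intervention,
            superiority_fraction=superiority,
            seeds={"simulate": sim_seed, "intervene": config.intervene.seed},
            wall_clock_s=time.perf_counter() - t0,
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        return report
    except Exception as e:
        (out / "FAILED").write_text(f"{stage}: {e}\n")
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, str(e)) from e
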