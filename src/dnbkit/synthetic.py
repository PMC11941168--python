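"""Stage-wise synthetic expression data with planted ground truth.

Each stage is sampled i.i.d. from the exact stationary law of the network
model at that stage's control value: ``x ~ N(mu, Sigma(p))`` plus optional
i.i.d. Gaussian measurement noise.  Sampling from the stationary
distribution directly (via an eigendecomposition square root of ``Sigma``)
is exact and orders of magnitude faster than trajectory integration; the
Euler--Maruyama integrator in :mod:`dnbkit.model` survives as a test oracle.

The default configuration is deliberately HDLSS (high-dimensional
low-sample-size): hundreds of genes, single-digit samples per stage, the
regime of multi-age expression cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .model import NetworkModel, build_network, stationary_covariance

__all__ = [
    "ExpressionMatrix",
    "StageSeries",
    "sample_stage",
    "generate_stage_series",
    "default_demo_model",
    "write_stage_series",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_MEAS_NOISE_SD",
]

#: Default samples per stage (HDLSS: n_genes >> n_samples).
DEFAULT_N_SAMPLES = 8
#: Default i.i.d. Gaussian measurement-noise standard deviation.
DEFAULT_MEAS_NOISE_SD = 0.1


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix for one stage.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``; units are arbitrary continuous intensities.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    stage_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidConfigurationError("values must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidConfigurationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidConfigurationError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidConfigurationError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigurationError("values must be finite (no NaN/inf)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Genes-as-rows DataFrame with a ``gene_id`` index."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )


@dataclass
class StageSeries:
    """Ordered stages sharing one gene universe."""

    stages: list[ExpressionMatrix]
    stage_order: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise InvalidConfigurationError("StageSeries needs at least one stage")
        ref = self.stages[0].gene_ids
        for m in self.stages[1:]:
            if m.gene_ids != ref:
                raise InvalidConfigurationError(
                    f"stage {m.stage_label!r} has a different gene_id list"
                )
        if not self.stage_order:
            self.stage_order = [m.stage_label for m in self.stages]
        if [m.stage_label for m in self.stages] != self.stage_order:
            raise InvalidConfigurationError("stage_order inconsistent with stages")

    @property
    def gene_ids(self) -> list[str]:
        return self.stages[0].gene_ids

    @property
    def n_stages(self) -> int:
        return len(self.stages)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _child_seed(master_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed: ``(seed * 1_000_003 + index) mod 2^31``."""
    return (int(master_seed) * 1_000_003 + int(stage_index)) % (2**31)


def sample_stage(
    model: NetworkModel,
    p: float,
    n_samples: int,
    meas_noise_sd: float = DEFAULT_MEAS_NOISE_SD,
    seed: int = 0,
    *,
    stage_label: str = "stage",
    sigma: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Draw ``n_samples`` i.i.d. observations from the stage's stationary law.

    Each column is ``mu + L z + eps`` with ``L`` an eigendecomposition
    square root of ``Sigma(p)``, ``z`` standard normal and ``eps`` i.i.d.
    ``N(0, meas_noise_sd^2)`` per gene.  Identical arguments give
    byte-identical output.  ``sigma`` may carry a precomputed ``Sigma(p)``
    (the caller's cache); it is trusted as-is.
    """
    if n_samples < 1:
        raise InvalidConfigurationError("n_samples must be >= 1")
    if meas_noise_sd < 0:
        raise InvalidConfigurationError("meas_noise_sd must be >= 0")
    if sigma is None:
        sigma = stationary_covariance(model, p)
    evals, evecs = np.linalg.eigh(sigma)
    evals = np.clip(evals, 0.0, None)  # PSD up to round-off
    L = evecs * np.sqrt(evals)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((model.n_genes, n_samples))
    values = model.baseline_expression[:, None] + L @ z
    if meas_noise_sd > 0:
        values = values + meas_noise_sd * rng.standard_normal(values.shape)
    return ExpressionMatrix(
        gene_ids=_gene_ids(model.n_genes),
        sample_ids=[f"{stage_label}_s{j}" for j in range(n_samples)],
        values=values,
        stage_label=stage_label,
    )


def generate_stage_series(
    model: NetworkModel,
    n_samples_per_stage: int = DEFAULT_N_SAMPLES,
    meas_noise_sd: float = DEFAULT_MEAS_NOISE_SD,
    seed: int = 0,
) -> StageSeries:
    """One :class:`ExpressionMatrix` per entry of ``model.control_schedule``.

    Stage ``t`` uses the derived seed ``(seed * 1_000_003 + t) mod 2^31`` so
    the whole series is a pure function of the master seed.
    """
    if len(model.control_schedule) == 0:
        raise InvalidConfigurationError("model.control_schedule is empty")
    stages = []
    for t, p in enumerate(model.control_schedule):
        stages.append(
            sample_stage(
                model,
                p,
                n_samples_per_stage,
                meas_noise_sd,
                seed=_child_seed(seed, t),
                stage_label=f"stage{t}",
            )
        )
    return StageSeries(
        stages=stages,
        provenance={
            "generator": "dnbkit.synthetic.generate_stage_series",
            "seed": int(seed),
            "n_samples_per_stage": int(n_samples_per_stage),
            "meas_noise_sd": float(meas_noise_sd),
            "control_schedule": list(model.control_schedule),
            "critical_stage": int(model.critical_stage),
            "dnb_genes": [_gene_ids(model.n_genes)[i] for i in model.dnb_genes],
        },
    )


def default_demo_model(seed: int = 42, **overrides) -> NetworkModel:
    """The demo configuration: 500 genes, 10-gene DNB, schedule
    (0.1, 0.3, 0.5, 0.7, 0.95)."""
    params = dict(n_genes=500, dnb_size=10, seed=seed)
    params.update(overrides)
    return build_network(**params)


def write_stage_series(series: StageSeries, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per stage plus sample metadata and ground-truth JSON.

    Layout: ``<out_dir>/<stage_label>.tsv`` (first column ``gene_id``),
    ``<out_dir>/samples.tsv`` (``sample_id``, ``stage``, ``stage_order``)
    and ``<out_dir>/ground_truth.json`` (provenance dict).
    """
    from .io import write_expression_tsv  # local import avoids a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta_rows = []
    for order, m in enumerate(series.stages):
        path = out_dir / f"{m.stage_label}.tsv"
        write_expression_tsv(m, path)
        paths[m.stage_label] = path
        for s in m.sample_ids:
            meta_rows.append({"sample_id": s, "stage": m.stage_label, "stage_order": order})
    meta = out_dir / "samples.tsv"
    pd.DataFrame(meta_rows).to_csv(meta, sep="\t", index=False)
    paths["samples"] = meta
    truth = out_dir / "ground_truth.json"
    truth.write_text(json.dumps(series.provenance, indent=2, sort_keys=True) + "\n")
    paths["ground_truth"] = truth
    return paths
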