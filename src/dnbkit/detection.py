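"""Pre-disease-stage detection from stage-wise fluctuation and correlation.

DNB theory predicts that just before a critical transition a small module of
interacting genes shows (i) rising expression variance, (ii) rising
intra-module correlation and (iii) falling correlation with the rest of the
network.  The detector scores candidate modules per stage with the composite
early-warning index

    I = sd_in * r_in / max(r_out, eps)

where ``sd_in`` is the members' mean standard deviation, ``r_in`` the mean
absolute Pearson correlation over member pairs and ``r_out`` the mean
absolute correlation between members and non-members.  The stage whose best
module maximizes ``I`` is called pre-disease; the peak is flagged
significant when it exceeds ``peak_ratio_min`` times the median of the other
stages' best indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance
from sklearn.base import BaseEstimator

from .errors import (
    InsufficientSamplesError,
    InsufficientStagesError,
    InvalidConfigurationError,
    UndefinedIndexError,
)
from .synthetic import ExpressionMatrix, StageSeries

__all__ = [
    "StageStats",
    "DNBResult",
    "DNBDetector",
    "compute_stage_stats",
    "prefilter_candidates",
    "cluster_members",
    "composite_index",
    "detect_predisease",
]


@dataclass
class StageStats:
    """Per-stage fluctuation/correlation summary.

    ``abs_corr[i, j] = |Pearson r|`` where defined; entries involving a
    constant (zero-sd) gene are stored as 0 and flagged ``False`` in
    ``defined``.  The diagonal is 1 for non-constant genes.
    """

    stage_label: str
    gene_sd: np.ndarray
    abs_corr: np.ndarray
    defined: np.ndarray  # bool mask, True where the correlation exists


@dataclass
class DNBResult:
    """Outcome of pre-disease detection over a stage series."""

    members: list[str]
    predisease_stage: str
    predisease_stage_index: int
    composite_index_by_stage: dict[str, float]
    components_by_stage: dict[str, tuple[float, float, float]]  # (sd_in, r_in, r_out)
    members_by_stage: dict[str, list[str]] = field(default_factory=dict)
    candidate_pool: list[str] = field(default_factory=list)
    is_significant: bool = False
    eps: float = 1e-6

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "predisease_stage": self.predisease_stage,
            "predisease_stage_index": self.predisease_stage_index,
            "composite_index_by_stage": {
                k: float(v) for k, v in self.composite_index_by_stage.items()
            },
            "components_by_stage": {
                k: {"sd_in": float(a), "r_in": float(b), "r_out": float(c)}
                for k, (a, b, c) in self.components_by_stage.items()
            },
            "members_by_stage": {k: list(v) for k, v in self.members_by_stage.items()},
            "candidate_pool": list(self.candidate_pool),
            "is_significant": bool(self.is_significant),
            "eps": float(self.eps),
        }


def compute_stage_stats(matrix: ExpressionMatrix) -> StageStats:
    """Per-gene sample sd (``ddof=1``) and pairwise ``|Pearson r|``.

    Correlation is computed on the values exactly as given (any log
    transform is the caller's preprocessing).  Constant genes are masked,
    not dropped, so gene indexing stays aligned across stages.
    """
    if matrix.n_samples < 3:
        raise InsufficientSamplesError(
            f"stage {matrix.stage_label!r} has {matrix.n_samples} samples; "
            "need >= 3 for correlation"
        )
    X = matrix.values
    sd = X.std(axis=1, ddof=1)
    # a truly constant gene can pick up float dust through the mean; detect
    # constancy by range and force its sd to exactly zero
    constant = (X.max(axis=1) - X.min(axis=1)) == 0
    sd[constant] = 0.0
    ok = ~constant & (sd > 0)
    n = matrix.n_genes
    abs_corr = np.zeros((n, n))
    defined = np.outer(ok, ok)
    if ok.sum() >= 1:
        sub = X[ok]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(sub)
        r = np.atleast_2d(r)
        block = np.abs(r)
        np.clip(block, 0.0, 1.0, out=block)  # round-off can exceed 1
        abs_corr[np.ix_(ok, ok)] = block
    return StageStats(
        stage_label=matrix.stage_label, gene_sd=sd, abs_corr=abs_corr, defined=defined
    )


def prefilter_candidates(
    series: StageSeries,
    stats: list[StageStats],
    sd_fold_min: float = 1.5,
) -> list[str]:
    """Keep genes whose max-over-stages sd is >= ``sd_fold_min`` x their sd
    at the first (reference) stage; zero-reference genes are kept whenever
    their max sd is positive."""
    if len(stats) < 2:
        raise InsufficientStagesError("prefiltering needs >= 2 stages")
    sds = np.vstack([s.gene_sd for s in stats])
    ref = sds[0]
    peak = sds.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = np.where(ref > 0, peak >= sd_fold_min * ref, peak > 0)
    return [g for g, k in zip(series.gene_ids, keep) if k]


def cluster_members(
    stats: StageStats,
    candidates: list[str],
    gene_ids: list[str],
    corr_link_min: float = 0.6,
) -> list[list[str]]:
    """Average-linkage clustering of candidates on distance ``1 - |r|``.

    The dendrogram is cut at distance ``1 - corr_link_min``; singletons are
    dropped; clusters are returned largest-first (ties broken by the
    smallest member gene index, so output is deterministic).  Candidates
    with fully masked correlations are excluded; with fewer than two
    clusterable candidates the result is empty.
    """
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = [pos[g] for g in candidates]
    # keep only candidates whose correlations are defined (non-constant)
    idx = [i for i in idx if stats.defined[i, i]]
    if len(idx) < 2:
        return []
    sub = stats.abs_corr[np.ix_(idx, idx)]
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    labels = scipy.cluster.hierarchy.fcluster(
        Z, t=1.0 - corr_link_min, criterion="distance"
    )
    clusters: dict[int, list[int]] = {}
    for lab, i in zip(labels, idx):
        clusters.setdefault(int(lab), []).append(i)
    keep = [sorted(c) for c in clusters.values() if len(c) >= 2]
    keep.sort(key=lambda c: (-len(c), c[0]))
    return [[gene_ids[i] for i in c] for c in keep]


def composite_index(
    stats: StageStats,
    members: list[str],
    gene_ids: list[str],
    eps: float = 1e-6,
) -> tuple[float, tuple[float, float, float]]:
    """Composite early-warning index and its (sd_in, r_in, r_out) parts.

    Masked (undefined) correlations are excluded from the pair averages.
    All-constant member sets short-circuit to index 0; member sets whose
    within-pair correlations are *all* masked (but not all constant) raise
    :class:`UndefinedIndexError`.
    """
    if len(members) < 2:
        raise InvalidConfigurationError("composite index needs >= 2 members")
    if eps <= 0:
        raise InvalidConfigurationError("eps must be positive")
    pos = {g: i for i, g in enumerate(gene_ids)}
    try:
        m = np.array([pos[g] for g in members])
    except KeyError as e:
        raise InvalidConfigurationError(f"unknown member gene {e.args[0]!r}") from None
    sd_in = float(stats.gene_sd[m].mean())
    if sd_in == 0.0:
        return 0.0, (0.0, 0.0, 0.0)

    inside = np.zeros(len(gene_ids), dtype=bool)
    inside[m] = True
    corr, defined = stats.abs_corr, stats.defined

    in_block = np.ix_(m, m)
    pair_mask = defined[in_block] & ~np.eye(len(m), dtype=bool)
    if not pair_mask.any():
        raise UndefinedIndexError(
            "all within-member correlations are masked; index undefined"
        )
    r_in = float(corr[in_block][pair_mask].mean())

    out = np.where(~inside)[0]
    if len(out):
        cross = np.ix_(m, out)
        cross_mask = defined[cross]
        r_out = float(corr[cross][cross_mask].mean()) if cross_mask.any() else 0.0
    else:
        r_out = 0.0
    return sd_in * r_in / max(r_out, eps), (sd_in, r_in, r_out)


class DNBDetector(BaseEstimator):
    """Detect the pre-disease stage and DNB members from staged samples.

    scikit-learn-style estimator: ``fit(X, y)`` takes ``X`` of shape
    ``(n_samples, n_genes)`` (samples are rows, as everywhere in sklearn)
    and ``y`` giving each sample's stage label; stages are analyzed in
    ``stage_order`` (default: order of first appearance in ``y``).

    Parameters
    ----------
    sd_fold_min : float, default 1.5
        Candidate prefilter: minimum fold increase of a gene's sd at any
        stage relative to the first stage.
    corr_link_min : float, default 0.6
        Minimum absolute correlation for cluster linkage (dendrogram cut at
        distance ``1 - corr_link_min``).
    eps : float, default 1e-6
        Floor for ``r_out`` in the composite index.
    peak_ratio_min : float, default 2.0
        Significance rule: the peak index must be at least this multiple of
        the median best index over the other stages.
    log2 : bool, default False
        Apply ``log2(x + 1)`` to the values before analysis.
    stage_order : sequence of str or None
        Explicit stage ordering; the first entry is the reference stage.

    Attributes
    ----------
    members_ : list of str
        DNB member genes at the detected stage.
    predisease_stage_ : str
        Detected stage label (argmax of the composite index; ties go to the
        earlier stage).
    composite_index_by_stage_ : dict
        Best composite index per stage.
    is_significant_ : bool
        Whether the peak passed the ratio rule.
    result_ : DNBResult
        Full structured result.
    """

    def __init__(
        self,
        sd_fold_min: float = 1.5,
        corr_link_min: float = 0.6,
        eps: float = 1e-6,
        peak_ratio_min: float = 2.0,
        log2: bool = False,
        stage_order: list[str] | None = None,
    ):
        self.sd_fold_min = sd_fold_min
        self.corr_link_min = corr_link_min
        self.eps = eps
        self.peak_ratio_min = peak_ratio_min
        self.log2 = log2
        self.stage_order = stage_order

    # -- construction helpers -------------------------------------------------
    def _series_from_xy(self, X, y) -> StageSeries:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            gene_ids = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
            sample_ids = [str(i) for i in X.index]
        else:
            values = np.asarray(X, dtype=float)
            gene_ids = [f"x{i}" for i in range(values.shape[1])]
            sample_ids = [f"s{i}" for i in range(values.shape[0])]
        y = np.asarray(y)
        if len(y) != values.shape[0]:
            raise InvalidConfigurationError("y must give one stage label per sample")
        order = (
            list(self.stage_order)
            if self.stage_order is not None
            else list(dict.fromkeys(str(v) for v in y))
        )
        stages = []
        ylab = np.array([str(v) for v in y])
        for lab in order:
            cols = np.where(ylab == lab)[0]
            if len(cols) == 0:
                raise InvalidConfigurationError(f"stage {lab!r} has no samples")
            stages.append(
                ExpressionMatrix(
                    gene_ids=gene_ids,
                    sample_ids=[sample_ids[c] for c in cols],
                    values=values[cols].T,
                    stage_label=lab,
                )
            )
        return StageSeries(stages=stages)

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y=None, *, series: StageSeries | None = None):
        """Fit on samples x genes ``X`` with stage labels ``y`` (or a
        prebuilt ``series``)."""
        if series is None:
            if y is None:
                raise InvalidConfigurationError("y (stage labels) is required")
            series = self._series_from_xy(X, y)
        self.result_ = self._detect(series)
        self.feature_names_in_ = np.asarray(series.gene_ids, dtype=object)
        self.n_features_in_ = len(series.gene_ids)
        self.members_ = self.result_.members
        self.predisease_stage_ = self.result_.predisease_stage
        self.composite_index_by_stage_ = self.result_.composite_index_by_stage
        self.components_by_stage_ = self.result_.components_by_stage
        self.candidate_pool_ = self.result_.candidate_pool
        self.is_significant_ = self.result_.is_significant
        return self

    def get_support(self) -> np.ndarray:
        """Boolean mask over genes marking the detected DNB members."""
        members = set(self.members_)
        return np.array([g in members for g in self.feature_names_in_])

    # -- core algorithm -------------------------------------------------------
    def _detect(self, series: StageSeries) -> DNBResult:
        if series.n_stages < 2:
            raise InsufficientStagesError(
                f"detection needs >= 2 stages, got {series.n_stages}"
            )
        if self.log2:
            series = StageSeries(
                stages=[
                    ExpressionMatrix(
                        m.gene_ids,
                        m.sample_ids,
                        np.log2(m.values + 1.0),
                        m.stage_label,
                    )
                    for m in series.stages
                ]
            )
        stats = [compute_stage_stats(m) for m in series.stages]
        candidates = prefilter_candidates(series, stats, self.sd_fold_min)
        gene_ids = series.gene_ids

        best_idx: dict[str, float] = {}
        best_comp: dict[str, tuple[float, float, float]] = {}
        best_members: dict[str, list[str]] = {}
        for st in stats:
            clusters = cluster_members(st, candidates, gene_ids, self.corr_link_min)
            stage_best, comp, mem = 0.0, (0.0, 0.0, 0.0), []
            for c in clusters:
                try:
                    val, parts = composite_index(st, c, gene_ids, self.eps)
                except UndefinedIndexError:
                    continue
                if val > stage_best:
                    stage_best, comp, mem = val, parts, c
            best_idx[st.stage_label] = stage_best
            best_comp[st.stage_label] = comp
            best_members[st.stage_label] = mem

        labels = [st.stage_label for st in stats]
        values = np.array([best_idx[lab] for lab in labels])
        peak_pos = int(np.argmax(values))  # argmax takes the earliest tie
        peak_lab = labels[peak_pos]
        others = np.delete(values, peak_pos)
        med = float(np.median(others)) if len(others) else 0.0
        if med > 0:
            significant = values[peak_pos] >= self.peak_ratio_min * med
        else:
            significant = values[peak_pos] > 0
        significant = bool(significant and best_members[peak_lab])
        return DNBResult(
            members=best_members[peak_lab],
            predisease_stage=peak_lab,
            predisease_stage_index=peak_pos,
            composite_index_by_stage=best_idx,
            components_by_stage=best_comp,
            members_by_stage=best_members,
            candidate_pool=candidates,
            is_significant=significant,
            eps=self.eps,
        )


def detect_predisease(series: StageSeries, **params) -> DNBResult:
    """Functional wrapper over :class:`DNBDetector` for a prebuilt series."""
    det = DNBDetector(**params)
    det.fit(None, series=series)
    return det.result_
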