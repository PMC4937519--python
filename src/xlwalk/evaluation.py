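"""Assessment of crosslink scoring functions against model quality.

A scoring function is judged by how well it recovers near-native models from
an ensemble: the Pearson correlation between the (normalized) score and the
Cα-RMSD to the reference structure, and the precision TP/(TP+FP) of the
top-20 ranked models with TP defined as Cα-RMSD ≤ 4 Å.  When several models
tie at the top-20 boundary, the remaining slots are filled by uniform
sampling from the tie cluster, repeated (default 1000×) to average out the
arbitrary ranking.  Bootstrap recovery curves measure how performance
depends on the fraction of theoretically possible crosslinks observed, and
the cutoff scan locates the maximum bound that optimizes correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .sasd_search import MEASURED, SASDResult, canonical_pair, compute_sasd
from .scoring import (CrosslinkClassification, ScoringConfig,
                      classify_crosslinks, normalize_ensemble, score_matched,
                      score_mnxl, score_nov, score_nov_nonacc, score_sovd)
from .structures_io import (CrosslinkDataset, CrosslinkRecord, NormalParams,
                            StructureModel, fit_sasd_distribution)
from .voxel_grid import build_grid, find_accessible_residues

__all__ = [
    "calpha_rmsd", "pearson", "precision_top_k", "make_theoretical_dataset",
    "compute_model_distances", "EnsembleEvaluation", "evaluate_ensemble",
    "RecoveryCurve", "bootstrap_recovery", "cutoff_scan", "ScoreMatrix",
    "build_score_matrix",
]

TIE_TOL = 1e-9


def calpha_rmsd(model: StructureModel, reference: StructureModel) -> float:
    """Cα root-mean-square deviation after optimal rigid superposition.

    Uses the Cα atoms of residues shared (by chain and number) between the
    two structures; requires at least three.
    """
    shared = sorted(set(model.residues()) & set(reference.residues()))
    xs, ys = [], []
    for key in shared:
        a, b = model.ca(key), reference.ca(key)
        if a is not None and b is not None:
            xs.append(a)
            ys.append(b)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 shared CA atoms, found {len(xs)}")
    x = np.asarray(xs) - np.mean(xs, axis=0)
    y = np.asarray(ys) - np.mean(ys, axis=0)
    _, rssd = Rotation.align_vectors(y, x)
    return float(rssd / np.sqrt(len(xs)))


def pearson(scores: Sequence[float], rmsds: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN when either axis is constant."""
    scores = np.asarray(scores, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    if scores.size < 3:
        raise ValueError("need >= 3 models for a correlation")
    if np.ptp(scores) == 0 or np.ptp(rmsds) == 0:
        return float("nan")
    return float(stats.pearsonr(scores, rmsds).statistic)


def precision_top_k(normalized_scores: Sequence[float],
                    rmsds: Sequence[float], k: int = 20,
                    rmsd_cut: float = 4.0, resamples: int = 1000,
                    seed: int | np.random.Generator | None = 0) -> float:
    """Precision TP/(TP+FP) of the top-``k`` models ranked by score.

    Models are ranked ascending by normalized score (0 = best).  A true
    positive is a top-``k`` model with Cα-RMSD ≤ ``rmsd_cut``.  If the ``k``-th
    boundary falls inside a cluster of tied scores, the remaining slots are
    drawn uniformly without replacement from the cluster, ``resamples`` times,
    and the mean precision returned; without boundary ties the result is
    deterministic.
    """
    scores = np.asarray(normalized_scores, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    n = scores.size
    if n < k:
        raise ValueError(f"need >= {k} models, got {n}")
    order = np.argsort(scores, kind="stable")
    boundary = scores[order[k - 1]]
    definite = order[scores[order] < boundary - TIE_TOL]
    cluster = np.flatnonzero(np.abs(scores - boundary) <= TIE_TOL)
    slots = k - definite.size
    tp_definite = int(np.sum(rmsds[definite] <= rmsd_cut))
    if slots >= cluster.size:
        # no boundary tie: the cluster fits entirely
        chosen = np.concatenate([definite, cluster])[:k]
        return float(np.sum(rmsds[chosen] <= rmsd_cut)) / k
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    total = 0.0
    for _ in range(resamples):
        pick = rng.choice(cluster, size=slots, replace=False)
        total += (tp_definite + np.sum(rmsds[pick] <= rmsd_cut)) / k
    return float(total / resamples)


# ---------------------------------------------------------------------------
# Theoretical datasets and per-model distances


def make_theoretical_dataset(reference: StructureModel, cutoff: float = 33.0,
                             voxel_size: float = 1.0,
                             reference_sasd: SASDResult | None = None
                             ) -> CrosslinkDataset:
    """All lysine/N-terminus pairs whose SASD on the reference is < cutoff.

    This is the full set of theoretically possible crosslinks used as the
    100%-recovery dataset for bootstrap analysis.  ``reference_sasd`` may be
    supplied to reuse an existing computation.
    """
    if reference_sasd is None:
        reference_sasd = compute_model_distances(reference, voxel_size=voxel_size)
    records = []
    for pair, res in sorted(reference_sasd.pairs.items()):
        if res.status == MEASURED and res.distance < cutoff:
            (ca, ra), (cb, rb) = pair
            records.append(CrosslinkRecord(ca, ra, cb, rb))
    return CrosslinkDataset(records, provenance="theoretical")


def compute_model_distances(model: StructureModel, voxel_size: float = 1.0,
                            connectivity: int = 26,
                            keep_paths: bool = False) -> SASDResult:
    """Full SASD pipeline for one model: grid, accessibility, search."""
    grid = build_grid(model, voxel_size=voxel_size)
    access = find_accessible_residues(grid, model)
    return compute_sasd(grid, access, model, pairs="all",
                        connectivity=connectivity, keep_paths=keep_paths)


# ---------------------------------------------------------------------------
# Ensemble evaluation


@dataclass
class EnsembleEvaluation:
    names: list[str]
    normalized_scores: np.ndarray
    rmsds: np.ndarray
    correlation: float
    precision: float
    best_separated: bool = False   # best model > 2 sigma from the ensemble mean


def evaluate_ensemble(model_distances: Mapping[str, SASDResult],
                      rmsds: Mapping[str, float],
                      ms_dataset: CrosslinkDataset, config: ScoringConfig,
                      score: str = "mnxl", k: int = 20, rmsd_cut: float = 4.0,
                      resamples: int = 1000, seed: int = 0
                      ) -> EnsembleEvaluation:
    """Score an ensemble and assess correlation and top-k precision.

    ``score`` selects mnxl / nov / sovd / nov_nonacc.  The correlation is
    computed on the normalized score (0 = best), so an effective scoring
    function yields a positive r against Cα-RMSD.
    """
    names = sorted(model_distances)
    raws, orientation = _raw_scores(
        [model_distances[n] for n in names], ms_dataset, config, score)
    normalized = normalize_ensemble(raws, orientation)
    rmsd_arr = np.array([rmsds[n] for n in names], dtype=float)
    r = pearson(normalized, rmsd_arr)
    prec = precision_top_k(normalized, rmsd_arr, k=k, rmsd_cut=rmsd_cut,
                           resamples=resamples, seed=seed)
    raw = np.asarray(raws)
    separated = bool(raw.std() > 0 and
                     (raw.max() - raw.mean()) > 2 * raw.std()) \
        if orientation == "higher_better" else \
        bool(raw.std() > 0 and (raw.mean() - raw.min()) > 2 * raw.std())
    return EnsembleEvaluation(names, normalized, rmsd_arr, r, prec, separated)


def _raw_scores(distance_list: Sequence[SASDResult],
                ms_dataset: CrosslinkDataset, config: ScoringConfig,
                score: str) -> tuple[list[float], str]:
    raws = []
    for dist in distance_list:
        cls = classify_crosslinks(ms_dataset, dist, config)
        if score == "mnxl":
            raws.append(score_mnxl(cls, config))
        elif score == "nov":
            raws.append(float(score_nov(cls)))
        elif score == "sovd":
            raws.append(score_sovd(cls, config))
        elif score == "nov_nonacc":
            raws.append(float(score_nov_nonacc(cls)))
        else:
            raise ValueError(f"unknown score {score!r}")
    orientation = "higher_better" if score == "mnxl" else "lower_better"
    return raws, orientation


# ---------------------------------------------------------------------------
# Bootstrap recovery analysis

#: Default recovery ladder (% of the theoretical crosslink set).
RECOVERY_LADDER = (90, 80, 70, 60, 50, 40, 30, 20, 10, 5, 1)


@dataclass
class ScoreMatrix:
    """Per-(model, crosslink) score contributions enabling fast subset scoring.

    ``mnxl[m, j]`` is crosslink j's additive MNXL contribution on model m
    (density, violation penalty or non-accessible penalty); ``nov`` and
    ``nonacc`` are 0/1 indicators and ``sovd`` the per-crosslink excess
    distance, so any subset's raw scores are column sums.
    """

    names: list[str]
    mnxl: np.ndarray
    nov: np.ndarray
    sovd: np.ndarray
    nonacc: np.ndarray

    def subset_raw(self, score: str, idx: np.ndarray) -> np.ndarray:
        if score == "mnxl":
            return self.mnxl[:, idx].sum(axis=1)
        if score == "nov":
            return self.nov[:, idx].sum(axis=1)
        if score == "sovd":
            return self.sovd[:, idx].sum(axis=1)
        if score == "nov_nonacc":
            return (self.nov[:, idx] + self.nonacc[:, idx]).sum(axis=1)
        raise ValueError(f"unknown score {score!r}")


def build_score_matrix(model_distances: Mapping[str, SASDResult],
                       ms_dataset: CrosslinkDataset,
                       config: ScoringConfig) -> ScoreMatrix:
    names = sorted(model_distances)
    n_m, n_x = len(names), len(ms_dataset)
    mnxl = np.zeros((n_m, n_x))
    nov = np.zeros((n_m, n_x))
    sovd = np.zeros((n_m, n_x))
    nonacc = np.zeros((n_m, n_x))
    for i, name in enumerate(names):
        dist = model_distances[name]
        for j, rec in enumerate(ms_dataset):
            res = dist.pairs.get(canonical_pair(rec.a, rec.b))
            if res is None:
                raise KeyError(f"crosslink {rec.pair} missing on model {name}")
            if res.status == MEASURED:
                if res.distance <= config.cutoff:
                    mnxl[i, j] = score_matched(res.distance, config)
                else:
                    mnxl[i, j] = config.penalty_violating
                    nov[i, j] = 1.0
                    sovd[i, j] = res.distance - config.cutoff
            else:
                mnxl[i, j] = config.penalty_nonaccessible
                nonacc[i, j] = 1.0
    return ScoreMatrix(names, mnxl, nov, sovd, nonacc)


def subset_size(percent: float, n: int) -> int:
    """Bootstrap subset size: round-half-up of p·N/100, floor of 1."""
    return max(1, int(np.floor(percent * n / 100.0 + 0.5)))


@dataclass
class RecoveryCurve:
    percentages: list[float]
    mean_correlation: list[float]
    mean_precision: list[float]
    n_boot: int
    subset_sizes: list[int] = field(default_factory=list)


def bootstrap_recovery(theoretical: CrosslinkDataset,
                       model_distances: Mapping[str, SASDResult],
                       rmsds: Mapping[str, float], config: ScoringConfig,
                       percent_ladder: Sequence[float] = RECOVERY_LADDER,
                       n_boot: int = 1000, seed: int = 0,
                       score: str = "mnxl", k: int = 20,
                       rmsd_cut: float = 4.0, tie_resamples: int = 100
                       ) -> RecoveryCurve:
    """Score recovery curve: mean correlation/precision vs crosslink coverage.

    For each percentage, ``n_boot`` uniform subsets of the theoretical
    crosslink set are drawn without replacement, every model is scored
    against each subset, and the per-subset correlation and top-``k``
    precision are averaged.  Fully reproducible from ``seed``.
    """
    n = len(theoretical)
    if n == 0:
        raise ValueError("theoretical crosslink set is empty")
    matrix = build_score_matrix(model_distances, theoretical, config)
    rmsd_arr = np.array([rmsds[name] for name in matrix.names], dtype=float)
    orientation = "higher_better" if score == "mnxl" else "lower_better"
    rng = np.random.default_rng(seed)
    mean_r, mean_p, sizes = [], [], []
    for pct in percent_ladder:
        m = subset_size(pct, n)
        sizes.append(m)
        rs = np.empty(n_boot)
        ps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(n, size=m, replace=False)
            raw = matrix.subset_raw(score, idx)
            normalized = normalize_ensemble(raw, orientation)
            rs[b] = pearson(normalized, rmsd_arr)
            ps[b] = precision_top_k(normalized, rmsd_arr, k=k,
                                    rmsd_cut=rmsd_cut,
                                    resamples=tie_resamples, seed=rng)
        mean_r.append(float(np.nanmean(rs)))
        mean_p.append(float(np.mean(ps)))
    return RecoveryCurve(list(percent_ladder), mean_r, mean_p, n_boot, sizes)


# ---------------------------------------------------------------------------
# Maximum-bound scan


def cutoff_scan(model_distances: Mapping[str, SASDResult],
                rmsds: Mapping[str, float], ms_dataset: CrosslinkDataset,
                cutoffs: Sequence[float] = tuple(range(20, 81)),
                config: ScoringConfig | None = None, score: str = "mnxl",
                refit_from: Sequence[float] | None = None,
                k: int = 20, rmsd_cut: float = 4.0, resamples: int = 1000,
                seed: int = 0) -> list[dict]:
    """Re-score the ensemble at each maximum-bound value.

    ``refit_from`` optionally supplies reference SASD values from which the
    matched-score distribution is refitted at each cutoff; otherwise the
    distribution in ``config`` is held fixed and only the classification
    boundary moves.  Returns one record per cutoff with correlation and
    precision.
    """
    if config is None:
        config = ScoringConfig()
    rows = []
    for cut in cutoffs:
        cfg = config.with_cutoff(float(cut))
        if refit_from is not None:
            cfg = ScoringConfig(
                cutoff=float(cut),
                penalty_violating=config.penalty_violating,
                penalty_nonaccessible=config.penalty_nonaccessible,
                distribution=fit_sasd_distribution(refit_from, fit_cutoff=float(cut)),
                distance_mode=config.distance_mode,
                density=config.density)
        ev = evaluate_ensemble(model_distances, rmsds, ms_dataset, cfg,
                               score=score, k=k, rmsd_cut=rmsd_cut,
                               resamples=resamples, seed=seed)
        rows.append({"cutoff": float(cut), "correlation": ev.correlation,
                     "precision": ev.precision})
    return rows
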