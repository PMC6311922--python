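"""Cross-validation protocols and ROC/AUC computation.

Evaluation is *local*: the score of a held-out association is compared only
against candidate miRNAs of the same disease, never across diseases.  Each
test sample therefore reduces to a (rank, pool size) pair -- the average
rank of the held-out miRNA within its candidate pool under descending
score.  Pools are pooled into one ROC curve through the normalised rank

    u = (rank - 1) / (pool_size - 1)

as the decision statistic: at threshold fraction ``x`` the true-positive
rate is the fraction of test samples with ``u <= x`` while the false-
positive rate is ``x`` itself.  The trapezoidal area under that curve
equals ``mean(1 - u)``, which per pool is exactly the Wilcoxon--Mann--
Whitney probability that the positive outscores a random candidate
(ties counted half).

Both protocols recompute the interaction-profile kernels -- and hence the
integrated similarities -- on the training split of every fold, so held-out
associations never leak into the similarity inputs or the training set.
Per-fold training seeds are derived from the evaluation seed and the
held-out pair set, making a k-fold run with singleton folds reproduce
leave-one-out exactly.
"""

from __future__ import annotations

import hashlib
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .datasets import AssociationDataset, ExpressionProfiles, MeshForest, SimilarityMatrix
from .model import FMSM, FmsmParams
from . import similarity as sim_mod

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "CvReport",
    "roc_from_rank_pairs",
    "null_roc",
    "evaluate_fold",
    "make_folds",
    "local_loocv",
    "kfold_cv",
    "ablation",
    "SimilarityInputs",
]


@dataclass
class RocResult:
    """Pooled local ROC curve.

    ``fpr``/``tpr`` trace the curve from (0, 0) to (1, 1); ``auc`` is its
    trapezoidal area; ``n_test`` counts pooled test samples and ``skipped``
    the test samples that could not be ranked (for example the sole
    association of a disease, which leaves no trained neighbourhood).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_test: int
    skipped: int = 0

    def plot(self, ax=None, **kwargs):
        """Draw the ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, **kwargs)
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"Local ROC (AUC = {self.auc:.4f}, n = {self.n_test})")
        return ax


@dataclass
class CvReport:
    """Repeated k-fold cross-validation summary.

    ``per_repeat_auc`` holds one pooled AUC per repeat (the k folds of a
    repeat are pooled into a single curve before averaging over repeats).
    """

    per_repeat_auc: list[float]
    repeats: int
    k: int
    seed: int
    n_test: int = 0
    skipped: int = 0
    mean_auc: float = field(init=False)
    sd_auc: float = field(init=False)

    def __post_init__(self) -> None:
        aucs = np.asarray(self.per_repeat_auc, dtype=float)
        self.mean_auc = float(aucs.mean())
        self.sd_auc = float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0


def roc_from_rank_pairs(
    rank_pairs: Iterable[tuple[float, int]], skipped: int = 0
) -> RocResult:
    """Pool (rank, pool size) pairs into one ROC curve.

    ``rank`` is the (average, tie-aware) rank of the held-out positive under
    descending score, ``1 <= rank <= pool_size``; pools must contain at
    least one other candidate.
    """
    pairs = list(rank_pairs)
    if not pairs:
        raise ValueError("no rank pairs to pool")
    ranks = np.array([r for r, _ in pairs], dtype=float)
    sizes = np.array([n for _, n in pairs], dtype=float)
    if (sizes < 2).any():
        raise ValueError("every candidate pool must contain >= 2 entries")
    if (ranks < 1).any() or (ranks > sizes).any():
        raise ValueError("ranks must lie in [1, pool_size]")
    u = (ranks - 1.0) / (sizes - 1.0)
    n = u.size
    order = np.sort(u)
    # step curve: TPR(x) = fraction of samples with u <= x, FPR(x) = x
    values, counts = np.unique(order, return_counts=True)
    cum = np.cumsum(counts) / n
    fpr = [0.0]
    tpr = [0.0]
    prev = 0.0
    for v, c in zip(values, cum):
        fpr += [v, v]
        tpr += [prev, c]
        prev = c
    fpr.append(1.0)
    tpr.append(1.0)
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocResult(fpr=fpr_arr, tpr=tpr_arr, auc=auc, n_test=n, skipped=skipped)


def null_roc(
    n_samples: int = 500, pool_size: int = 100, seed: int = 0
) -> RocResult:
    """Calibration control: pools scored by pure noise.

    Replaces the model's scores with seeded uniform random values and ranks
    one designated positive per pool; the pooled AUC should hover around
    0.5.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_samples):
        scores = rng.random(pool_size)
        ranks = rankdata(-scores, method="average")
        pairs.append((float(ranks[0]), pool_size))
    return roc_from_rank_pairs(pairs)


@dataclass
class SimilarityInputs:
    """Fold-invariant similarity inputs plus their configuration.

    Expression similarity and semantic similarity do not depend on the
    association matrix, so they are computed once and reused across folds;
    the interaction-profile kernels are recomputed per fold from the
    training split.
    """

    expression_sim: SimilarityMatrix | None = None
    semantic_sim: SimilarityMatrix | None = None
    gamma_prime_d: float = 1.0
    gamma_prime_m: float = 1.0

    @classmethod
    def from_data(
        cls,
        dataset: AssociationDataset,
        expression: ExpressionProfiles | None = None,
        mesh: MeshForest | None = None,
        *,
        delta: float = 0.5,
        gamma_prime_d: float = 1.0,
        gamma_prime_m: float = 1.0,
        es_negative_policy: str = "clip",
    ) -> "SimilarityInputs":
        es = (
            sim_mod.expression_similarity(
                expression, dataset.mirnas, negative_policy=es_negative_policy
            )
            if expression is not None
            else None
        )
        ss = (
            sim_mod.disease_semantic_similarity(mesh, dataset.diseases, delta)
            if mesh is not None
            else None
        )
        return cls(
            expression_sim=es,
            semantic_sim=ss,
            gamma_prime_d=gamma_prime_d,
            gamma_prime_m=gamma_prime_m,
        )


def make_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle ``range(n)`` and split it into ``k`` disjoint folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer associations than folds")
    return np.array_split(rng.permutation(n), k)


def _fold_seed(seed: int, test_pairs: Sequence[tuple[int, int]]) -> int:
    """Deterministic per-fold training seed from the held-out pair set."""
    payload = repr(sorted(test_pairs)).encode() + seed.to_bytes(8, "little", signed=True)
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def evaluate_fold(
    dataset: AssociationDataset,
    test_pairs: Sequence[tuple[int, int]],
    sims: SimilarityInputs,
    params: FmsmParams | None = None,
    *,
    mode: str = "expression_plus_gip",
    seed: int = 0,
) -> tuple[list[tuple[float, int]], int]:
    """Train on ``R`` minus ``test_pairs`` and rank each held-out pair.

    The training matrix and both kernels are rebuilt from the surviving
    association set, so the fold's outputs depend on the held-out entries
    only through their identities, never their stored values.  Each held-out
    (d, m) is ranked among ``{m}`` plus the miRNAs with no known association
    to ``d`` (training or held-out); ties receive average ranks.  Held-out
    pairs whose disease loses its last training association -- the model
    cannot score a disease with an empty neighbourhood -- are skipped and
    counted.

    Returns the list of (rank, pool size) pairs and the skipped count.
    """
    params = params or FmsmParams()
    test = set((int(d), int(m)) for d, m in test_pairs)
    train_ds = dataset.without(test)
    s_m = FMSM.build_mirna_similarity(
        train_ds, None, mode=mode,
        gamma_prime_m=sims.gamma_prime_m, es=sims.expression_sim,
    )
    s_d = FMSM.build_disease_similarity(
        train_ds, None, gamma_prime_d=sims.gamma_prime_d, ss=sims.semantic_sim
    )
    model = FMSM(train_ds, s_m, s_d, params)
    results = model.fit(seed=_fold_seed(seed, sorted(test)))
    scores = results.score_matrix()

    by_disease: dict[int, list[int]] = defaultdict(list)
    for d, m in sorted(test):
        by_disease[d].append(m)
    train_pos = train_ds.positives_by_disease()
    rank_pairs: list[tuple[float, int]] = []
    skipped = 0
    for d, test_ms in sorted(by_disease.items()):
        if train_pos[d].size == 0:
            skipped += len(test_ms)
            continue
        excluded = set(train_pos[d].tolist()) | set(test_ms)
        negatives = [m for m in range(dataset.nm) if m not in excluded]
        if not negatives:
            skipped += len(test_ms)
            continue
        for m in test_ms:
            pool = negatives + [m]
            pool_scores = scores[d, pool]
            ranks = rankdata(-pool_scores, method="average")
            rank_pairs.append((float(ranks[-1]), len(pool)))
    return rank_pairs, skipped


def local_loocv(
    dataset: AssociationDataset,
    sims: SimilarityInputs,
    params: FmsmParams | None = None,
    *,
    mode: str = "expression_plus_gip",
    seed: int = 0,
) -> RocResult:
    """Local leave-one-out cross-validation over all known associations.

    Each association in turn is removed from training; kernels, integrated
    similarities and the model are recomputed on the reduced network; the
    held-out miRNA is ranked among its disease's candidates.  All (rank,
    pool) pairs pool into one ROC curve.
    """
    if dataset.n_associations < 2:
        raise ValueError("leave-one-out needs at least two associations")
    rank_pairs: list[tuple[float, int]] = []
    skipped = 0
    for pair in sorted(dataset.R):
        pairs, s = evaluate_fold(
            dataset, [pair], sims, params, mode=mode, seed=seed
        )
        rank_pairs.extend(pairs)
        skipped += s
    if skipped:
        logger.info("local LOOCV skipped %d unrankable test samples", skipped)
    return roc_from_rank_pairs(rank_pairs, skipped=skipped)


def kfold_cv(
    dataset: AssociationDataset,
    sims: SimilarityInputs,
    params: FmsmParams | None = None,
    *,
    k: int = 5,
    repeats: int = 20,
    mode: str = "expression_plus_gip",
    seed: int = 0,
) -> CvReport:
    """Repeated k-fold cross-validation over the known associations.

    Per repeat the associations are shuffled and split into ``k`` disjoint
    folds; each fold is held out in turn, ranked by :func:`evaluate_fold`,
    and the repeat's folds pool into one AUC.  The report averages the
    per-repeat AUCs.
    """
    R = np.array(sorted(dataset.R), dtype=np.int64)
    rng = np.random.default_rng(seed)
    per_repeat: list[float] = []
    n_test = 0
    skipped_total = 0
    for rep in range(repeats):
        folds = make_folds(len(R), k, rng)
        rank_pairs: list[tuple[float, int]] = []
        for fold in folds:
            test_pairs = [tuple(R[i]) for i in fold]
            pairs, s = evaluate_fold(
                dataset, test_pairs, sims, params, mode=mode, seed=seed
            )
            rank_pairs.extend(pairs)
            skipped_total += s
        roc = roc_from_rank_pairs(rank_pairs)
        per_repeat.append(roc.auc)
        n_test += roc.n_test
        logger.info("repeat %d/%d pooled AUC %.4f", rep + 1, repeats, roc.auc)
    return CvReport(
        per_repeat_auc=per_repeat,
        repeats=repeats,
        k=k,
        seed=seed,
        n_test=n_test,
        skipped=skipped_total,
    )


def ablation(
    dataset: AssociationDataset,
    sims: SimilarityInputs,
    params: FmsmParams | None = None,
    *,
    k: int = 5,
    repeats: int = 2,
    seed: int = 0,
    modes: Sequence[str] = ("none", "expression_only", "expression_plus_gip"),
) -> dict[str, CvReport]:
    """Compare miRNA-similarity configurations under identical CV splits.

    Modes: ``none`` (identity miRNA similarity; network topology only),
    ``expression_only`` (Pearson expression similarity) and
    ``expression_plus_gip`` (expression averaged with the interaction-
    profile kernel -- the default pipeline).  The disease-side inputs are
    identical across modes.
    """
    reports = {}
    for mode in modes:
        reports[mode] = kfold_cv(
            dataset, sims, params, k=k, repeats=repeats, mode=mode, seed=seed
        )
        logger.info(
            "ablation mode %s: mean AUC %.4f +/- %.4f",
            mode, reports[mode].mean_auc, reports[mode].sd_auc,
        )
    return reports
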