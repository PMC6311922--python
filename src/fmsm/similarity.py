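"""Pairwise similarity sources and their integration.

Three independent sources feed the model:

* **Expression similarity (ES)** -- Pearson correlation between the tissue
  expression vectors of two miRNAs.  Correlation lives in ``[-1, 1]``; the
  default policy clips negatives to 0 so that "anti-correlated" and
  "unrelated" both read as no similarity (an ``affine`` alternative maps
  ``r`` to ``(r + 1) / 2``).

* **Disease semantic similarity (SS)** -- overlap of the MeSH ancestor DAGs
  of two diseases, weighted by per-node semantic contributions that decay by
  a factor ``delta`` per generation away from the disease itself.

* **Gaussian interaction-profile (GIP) kernel (KD/KM)** -- an RBF kernel on
  the rows (diseases) or columns (miRNAs) of the binary association matrix,
  with bandwidth normalised by the mean squared profile norm.  Because it is
  derived from the network itself, it covers every entity and is recomputed
  on the training split of every cross-validation fold.

Integration fills coverage gaps: the miRNA similarity averages ES with the
kernel where expression covers both miRNAs and falls back to the kernel
alone otherwise; the disease similarity uses the semantic score where both
diseases carry MeSH annotations and the kernel otherwise.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import (
    AssociationDataset,
    ExpressionProfiles,
    MeshForest,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SemanticContribution",
    "expression_similarity",
    "semantic_contributions",
    "disease_semantic_similarity",
    "gip_kernel",
    "integrate_mirna_similarity",
    "integrate_disease_similarity",
    "identity_similarity",
]


def expression_similarity(
    profiles: ExpressionProfiles,
    mirnas: Sequence[str],
    negative_policy: str = "clip",
) -> SimilarityMatrix:
    """Pearson correlation of expression vectors, mapped into ``[0, 1]``.

    Parameters
    ----------
    profiles
        Expression matrix; may cover only a subset of ``mirnas``.
    mirnas
        Full miRNA universe of the association dataset; the output matrix is
        indexed by this list.
    negative_policy
        ``"clip"`` (default) sets negative correlations to 0; ``"affine"``
        maps ``r`` to ``(r + 1) / 2``.

    miRNAs without a profile, or with a zero-variance profile (correlation
    undefined), are marked uncovered and their rows/columns left at zero.
    """
    if negative_policy not in ("clip", "affine"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    n = len(mirnas)
    S = np.zeros((n, n))
    covered = np.zeros(n, dtype=bool)
    rows = np.full(n, -1)
    for i, name in enumerate(mirnas):
        r = profiles.row_for(name)
        if r is not None and not profiles.zero_variance[r]:
            covered[i] = True
            rows[i] = r
    n_zero_var = sum(
        1 for name in mirnas
        if (r := profiles.row_for(name)) is not None and profiles.zero_variance[r]
    )
    if n_zero_var:
        logger.warning(
            "%d miRNAs have zero-variance expression; treated as uncovered",
            n_zero_var,
        )
    idx = np.flatnonzero(covered)
    if idx.size >= 2:
        X = profiles.E[rows[idx]]
        corr = np.corrcoef(X)
        if negative_policy == "clip":
            corr = np.clip(corr, 0.0, 1.0)
        else:
            corr = np.clip((corr + 1.0) / 2.0, 0.0, 1.0)
        S[np.ix_(idx, idx)] = corr
    S[idx, idx] = 1.0
    sim = SimilarityMatrix(list(mirnas), S, covered)
    sim.validate()
    return sim


@dataclass
class SemanticContribution:
    """Per-node semantic contributions within one disease's MeSH DAG.

    ``contributions[t]`` is the decayed weight ``C_D(t)`` of DAG node ``t``
    to the semantic value of disease ``D``: 1 on the disease's own codes,
    and ``max(delta * C_D(child))`` over the node's children otherwise.
    ``aggregate`` is the sum over all nodes.
    """

    disease: str
    contributions: dict[str, float]
    aggregate: float


def semantic_contributions(
    forest: MeshForest, disease: str, delta: float = 0.5
) -> SemanticContribution:
    """Decayed contribution of every DAG node to a disease's semantic value.

    ``delta`` is the per-generation decay in ``(0, 1)``.  When a node is
    reachable through several child paths the maximum (shortest-path) decay
    wins; a node that is itself one of the disease's codes contributes 1.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    own = forest.codes(disease)
    nodes, _ = forest.dag(disease)
    children: dict[str, list[str]] = defaultdict(list)
    for node in nodes:
        parent = MeshForest.parent(node)
        if parent is not None and parent in nodes:
            children[parent].append(node)
    contributions: dict[str, float] = {}
    # deepest-first so every child is resolved before its parent
    for node in sorted(nodes, key=lambda c: -c.count(".")):
        if node in own:
            contributions[node] = 1.0
        else:
            contributions[node] = max(
                delta * contributions[child] for child in children[node]
            )
    return SemanticContribution(
        disease=disease,
        contributions=contributions,
        aggregate=sum(contributions.values()),
    )


def disease_semantic_similarity(
    forest: MeshForest, diseases: Sequence[str], delta: float = 0.5
) -> SimilarityMatrix:
    """MeSH-based semantic similarity over a disease list.

    For two annotated diseases the score is the summed contribution of their
    shared DAG nodes, from both sides, normalised by the two aggregate
    semantic values.  Diseases absent from the forest are uncovered.
    """
    n = len(diseases)
    S = np.zeros((n, n))
    covered = np.array([d in forest for d in diseases], dtype=bool)
    contribs: dict[int, SemanticContribution] = {
        i: semantic_contributions(forest, diseases[i], delta)
        for i in np.flatnonzero(covered)
    }
    idx = sorted(contribs)
    for a, i in enumerate(idx):
        ci = contribs[i].contributions
        S[i, i] = 1.0
        for j in idx[a + 1:]:
            cj = contribs[j].contributions
            shared = ci.keys() & cj.keys()
            if not shared:
                continue
            num = sum(ci[t] + cj[t] for t in shared)
            S[i, j] = S[j, i] = num / (contribs[i].aggregate + contribs[j].aggregate)
    sim = SimilarityMatrix(list(diseases), S, covered)
    sim.validate()
    return sim


def gip_kernel(
    dataset: AssociationDataset,
    axis: str = "disease",
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel on one side of the network.

    For ``axis="disease"`` the interaction profiles are the rows of ``U``;
    for ``axis="mirna"`` the columns.  The kernel is
    ``exp(-gamma * ||IP_i - IP_j||^2)`` with
    ``gamma = gamma_prime / mean_i ||IP_i||^2``.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    if axis == "disease":
        X = dataset.U.astype(float)
        names = dataset.diseases
    elif axis == "mirna":
        X = dataset.U.T.astype(float)
        names = dataset.mirnas
    else:
        raise ValueError(f"axis must be 'disease' or 'mirna', got {axis!r}")
    sq = (X * X).sum(axis=1)
    mean_sq = sq.mean()
    if mean_sq == 0:
        raise ValueError("kernel bandwidth undefined: all interaction profiles are zero")
    gamma = gamma_prime / mean_sq
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    sim = SimilarityMatrix(list(names), K, np.ones(len(names), dtype=bool))
    sim.validate()
    return sim


def _check_same_names(a: SimilarityMatrix, b: SimilarityMatrix, what: str) -> None:
    from .datasets import canonical_key

    if [canonical_key(n) for n in a.names] != [canonical_key(n) for n in b.names]:
        raise ValueError(f"{what} similarity matrices do not share an index")


def integrate_mirna_similarity(
    es: SimilarityMatrix, km: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated miRNA similarity: mean of expression similarity and the
    interaction-profile kernel where expression covers both miRNAs, kernel
    alone elsewhere."""
    _check_same_names(es, km, "miRNA")
    both = np.outer(es.covered, es.covered)
    S = np.where(both, (es.S + km.S) / 2.0, km.S)
    np.fill_diagonal(S, 1.0)
    sim = SimilarityMatrix(list(km.names), S, np.ones(km.n, dtype=bool))
    sim.validate()
    return sim


def integrate_disease_similarity(
    ss: SimilarityMatrix, kd: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated disease similarity: semantic similarity where both diseases
    carry MeSH annotations, interaction-profile kernel otherwise."""
    _check_same_names(ss, kd, "disease")
    both = np.outer(ss.covered, ss.covered)
    S = np.where(both, ss.S, kd.S)
    np.fill_diagonal(S, 1.0)
    sim = SimilarityMatrix(list(kd.names), S, np.ones(kd.n, dtype=bool))
    sim.validate()
    return sim


def identity_similarity(names: Sequence[str]) -> SimilarityMatrix:
    """Zero-information similarity (identity matrix); used by the ablation
    mode that withholds any extra miRNA similarity."""
    n = len(names)
    return SimilarityMatrix(list(names), np.eye(n), np.ones(n, dtype=bool))
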