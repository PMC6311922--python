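"""Factored miRNA-similarity model (FMSM).

The model treats miRNA-biomarker prioritisation as sparse implicit-feedback
matrix completion.  A learned miRNA-miRNA similarity is factored as
``P @ Q.T`` (both ``nm x d``); the raw score of a (disease, miRNA) pair is

    r_hat(d, m) = b_d + b_m + k^(-alpha) * sum_{j in Rd+ \\ {m}} p_j . q_m

where ``Rd+`` is the set of miRNAs associated with disease ``d`` in the
training split, ``k = |Rd+ \\ {m}|`` is the number of summed neighbours,
``alpha`` damps the neighbourhood size, and ``b_d``, ``b_m`` are scalar
biases.  Excluding ``m`` from its own neighbourhood keeps the rule a proper
regression (the score of a pair never reads its own label, so toggling
``U[d, m]`` leaves ``r_hat(d, m)`` unchanged).

Parameters minimise the squared-error objective over the known associations
``R`` (labelled 1) plus a per-epoch uniform sample ``A`` of unknown pairs
(labelled 0, ``|A| = rho * |R|``), with Frobenius/L2 ridge penalties
``beta`` on P and Q, ``lambda`` on disease biases and ``gamma`` on miRNA
biases, fitted by per-sample stochastic gradient descent.

Final candidate scores add disease- and miRNA-neighbourhood averages of the
integrated similarity matrices to the raw score:

    score(d_i, m_j) = r_hat + W_d * mean_{d': (d', m_j) in R} S_d(d_i, d')
                            + W_m * mean_{m': (d_i, m') in R} S_m(m_j, m')

with an empty neighbourhood contributing 0.

The public surface follows the model/results idiom: build an :class:`FMSM`
from an association dataset plus similarity inputs, call :meth:`FMSM.fit`,
and read estimates and rankings off the returned :class:`FMSMResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .datasets import AssociationDataset, ExpressionProfiles, MeshForest, SimilarityMatrix
from . import similarity as sim_mod

logger = logging.getLogger(__name__)

__all__ = ["FmsmParams", "FmsmState", "FMSM", "FMSMResults", "DivergenceError"]

MIRNA_SIMILARITY_MODES = ("none", "expression_only", "expression_plus_gip")


class DivergenceError(RuntimeError):
    """SGD produced non-finite parameters; retry with a smaller step size."""


@dataclass(frozen=True)
class FmsmParams:
    """Hyperparameters of the factored similarity model.

    Attributes
    ----------
    latent_dim
        Dimension ``d`` of the latent factors (``None`` means full rank,
        ``d = nm``, the default since runtime is not a constraint at these
        problem sizes).
    alpha
        Neighbourhood-size damping exponent in ``[0, 1]``.
    beta, lam, gamma
        Ridge weights for the factor matrices, disease biases and miRNA
        biases respectively.
    eta
        SGD learning rate.
    max_iters
        Number of SGD epochs.
    rho
        Negative-sample factor: ``rho * |R|`` unknown pairs are drawn per
        epoch.
    w_d, w_m
        Aggregation weights of the disease- and miRNA-neighbourhood terms in
        the final score.
    """

    latent_dim: int | None = None
    alpha: float = 0.5
    beta: float = 0.1
    lam: float = 0.1
    gamma: float = 0.1
    eta: float = 0.01
    max_iters: int = 100
    rho: float = 3.0
    w_d: float = 1.0
    w_m: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_dim is not None and self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("beta", "lam", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")


class FmsmState(NamedTuple):
    """Trainable parameters: latent factors and biases."""

    P: np.ndarray
    Q: np.ndarray
    b_d: np.ndarray
    b_m: np.ndarray

    def copy(self) -> "FmsmState":
        return FmsmState(*(a.copy() for a in self))

    def is_finite(self) -> bool:
        return all(np.isfinite(a).all() for a in self)


class FMSM:
    """Factored miRNA-similarity model bound to an association dataset.

    Parameters
    ----------
    dataset
        Binary association network; defines the training positives.
    mirna_similarity
        Integrated miRNA similarity ``S_m`` (initialises the factors and
        feeds the miRNA-neighbourhood score term).
    disease_similarity
        Integrated disease similarity ``S_d`` (feeds the disease-
        neighbourhood score term).
    params
        Hyperparameters; defaults follow the reference configuration.
    """

    def __init__(
        self,
        dataset: AssociationDataset,
        mirna_similarity: SimilarityMatrix,
        disease_similarity: SimilarityMatrix | None = None,
        params: FmsmParams | None = None,
    ) -> None:
        if mirna_similarity.n != dataset.nm:
            raise ValueError("miRNA similarity does not match dataset miRNAs")
        if disease_similarity is not None and disease_similarity.n != dataset.nd:
            raise ValueError("disease similarity does not match dataset diseases")
        self.dataset = dataset
        self.mirna_similarity = mirna_similarity
        self.disease_similarity = disease_similarity
        self.params = params or FmsmParams()
        if self.params.latent_dim is not None and self.params.latent_dim > dataset.nm:
            raise ValueError("latent_dim cannot exceed the number of miRNAs")
        self._pos = dataset.positives_by_disease()
        self._R = np.array(sorted(dataset.R), dtype=np.int64).reshape(-1, 2)
        self._zero_flat = np.flatnonzero(dataset.U.ravel() == 0)

    # -- construction helpers ---------------------------------------------

    @classmethod
    def from_data(
        cls,
        dataset: AssociationDataset,
        expression: ExpressionProfiles | None = None,
        mesh: MeshForest | None = None,
        params: FmsmParams | None = None,
        *,
        delta: float = 0.5,
        gamma_prime_d: float = 1.0,
        gamma_prime_m: float = 1.0,
        es_negative_policy: str = "clip",
        mirna_similarity_mode: str = "expression_plus_gip",
    ) -> "FMSM":
        """Build the model from raw inputs, computing all similarities.

        ``mirna_similarity_mode`` selects what extra miRNA similarity enters
        the model: ``"none"`` (identity; network topology only),
        ``"expression_only"`` (Pearson expression similarity, identity where
        uncovered), or ``"expression_plus_gip"`` (default: expression
        averaged with the interaction-profile kernel, kernel where
        uncovered).  The disease side always integrates semantic similarity
        with the disease kernel.
        """
        s_m = cls.build_mirna_similarity(
            dataset, expression,
            mode=mirna_similarity_mode,
            gamma_prime_m=gamma_prime_m,
            es_negative_policy=es_negative_policy,
        )
        s_d = cls.build_disease_similarity(
            dataset, mesh, delta=delta, gamma_prime_d=gamma_prime_d
        )
        return cls(dataset, s_m, s_d, params)

    @staticmethod
    def build_mirna_similarity(
        dataset: AssociationDataset,
        expression: ExpressionProfiles | None,
        *,
        mode: str = "expression_plus_gip",
        gamma_prime_m: float = 1.0,
        es_negative_policy: str = "clip",
        es: SimilarityMatrix | None = None,
    ) -> SimilarityMatrix:
        """Integrated miRNA similarity for a (training) dataset.

        ``es`` may carry a precomputed expression similarity to avoid
        recomputing it per cross-validation fold (it does not depend on the
        association matrix).
        """
        if mode not in MIRNA_SIMILARITY_MODES:
            raise ValueError(
                f"unknown miRNA similarity mode {mode!r}; "
                f"expected one of {MIRNA_SIMILARITY_MODES}"
            )
        if mode == "none":
            return sim_mod.identity_similarity(dataset.mirnas)
        if es is None:
            if expression is None:
                es = SimilarityMatrix(
                    list(dataset.mirnas),
                    np.zeros((dataset.nm, dataset.nm)),
                    np.zeros(dataset.nm, dtype=bool),
                )
            else:
                es = sim_mod.expression_similarity(
                    expression, dataset.mirnas, negative_policy=es_negative_policy
                )
        if mode == "expression_only":
            S = es.S.copy()
            np.fill_diagonal(S, 1.0)
            return SimilarityMatrix(list(es.names), S, np.ones(es.n, dtype=bool))
        km = sim_mod.gip_kernel(dataset, axis="mirna", gamma_prime=gamma_prime_m)
        return sim_mod.integrate_mirna_similarity(es, km)

    @staticmethod
    def build_disease_similarity(
        dataset: AssociationDataset,
        mesh: MeshForest | None,
        *,
        delta: float = 0.5,
        gamma_prime_d: float = 1.0,
        ss: SimilarityMatrix | None = None,
    ) -> SimilarityMatrix:
        """Integrated disease similarity (semantic where covered, kernel
        otherwise) for a (training) dataset."""
        kd = sim_mod.gip_kernel(dataset, axis="disease", gamma_prime=gamma_prime_d)
        if ss is None:
            if mesh is None:
                return kd
            ss = sim_mod.disease_semantic_similarity(mesh, dataset.diseases, delta)
        return sim_mod.integrate_disease_similarity(ss, kd)

    # -- parameters --------------------------------------------------------

    @property
    def latent_dim(self) -> int:
        return self.params.latent_dim or self.dataset.nm

    def initialize(self) -> FmsmState:
        """Initial parameter state seeded from the miRNA similarity.

        At full rank both factor matrices start as copies of ``S_m``.  For a
        lower dimension ``d`` they start from the rank-``d`` symmetric
        eigen-factorisation of ``S_m`` (negative eigenvalues clipped at 0),
        the closest PSD factor pair in Frobenius norm.
        """
        nm, nd = self.dataset.nm, self.dataset.nd
        d = self.latent_dim
        S = self.mirna_similarity.S
        if d == nm:
            P = S.copy()
            Q = S.copy()
        else:
            evals, evecs = np.linalg.eigh((S + S.T) / 2.0)
            order = np.argsort(evals)[::-1][:d]
            lam = np.clip(evals[order], 0.0, None)
            F = evecs[:, order] * np.sqrt(lam)[None, :]
            P = F.copy()
            Q = F.copy()
        return FmsmState(P=P, Q=Q, b_d=np.zeros(nd), b_m=np.zeros(nm))

    def _neighbourhood(self, d: int, m: int) -> tuple[np.ndarray, float]:
        """Summed-neighbour index set ``Rd+ \\ {m}`` and its damping weight."""
        js = self._pos[d]
        js = js[js != m]
        if js.size == 0:
            return js, 0.0
        return js, float(js.size) ** (-self.params.alpha)

    def predict_raw(self, state: FmsmState, d: int, m: int) -> float:
        """Raw factored-similarity score of one (disease, miRNA) pair."""
        js, w = self._neighbourhood(d, m)
        score = state.b_d[d] + state.b_m[m]
        if js.size:
            score += w * float(state.P[js].sum(axis=0) @ state.Q[m])
        return float(score)

    # -- objective and gradients -------------------------------------------

    def _labelled_pairs(
        self, negatives: Sequence[tuple[int, int]] | np.ndarray = ()
    ) -> tuple[np.ndarray, np.ndarray]:
        neg = np.asarray(list(negatives), dtype=np.int64).reshape(-1, 2)
        pairs = np.vstack([self._R, neg])
        labels = np.concatenate([np.ones(len(self._R)), np.zeros(len(neg))])
        return pairs, labels

    def objective(
        self,
        state: FmsmState,
        negatives: Sequence[tuple[int, int]] | np.ndarray = (),
    ) -> float:
        """Regularised squared-error objective over ``R`` and ``negatives``."""
        if not state.is_finite():
            raise DivergenceError("model parameters are non-finite")
        pairs, labels = self._labelled_pairs(negatives)
        data = 0.0
        for (d, m), r in zip(pairs, labels):
            err = r - self.predict_raw(state, int(d), int(m))
            data += err * err
        p = self.params
        reg = (
            p.beta / 2.0 * (np.sum(state.P**2) + np.sum(state.Q**2))
            + p.lam / 2.0 * np.sum(state.b_d**2)
            + p.gamma / 2.0 * np.sum(state.b_m**2)
        )
        return 0.5 * data + float(reg)

    def objective_gradients(
        self,
        state: FmsmState,
        negatives: Sequence[tuple[int, int]] | np.ndarray = (),
    ) -> FmsmState:
        """Analytic gradient of :meth:`objective` for every parameter block."""
        pairs, labels = self._labelled_pairs(negatives)
        gP = np.zeros_like(state.P)
        gQ = np.zeros_like(state.Q)
        gbd = np.zeros_like(state.b_d)
        gbm = np.zeros_like(state.b_m)
        for (d, m), r in zip(pairs, labels):
            d, m = int(d), int(m)
            js, w = self._neighbourhood(d, m)
            pred = state.b_d[d] + state.b_m[m]
            if js.size:
                t = state.P[js].sum(axis=0)
                pred += w * (t @ state.Q[m])
            err = float(pred - r)
            gbd[d] += err
            gbm[m] += err
            if js.size:
                gQ[m] += err * w * t
                gP[js] += err * w * state.Q[m]
        p = self.params
        gP += p.beta * state.P
        gQ += p.beta * state.Q
        gbd += p.lam * state.b_d
        gbm += p.gamma * state.b_m
        return FmsmState(gP, gQ, gbd, gbm)

    # -- training -----------------------------------------------------------

    def sample_negatives(
        self, rng: np.random.Generator, rho: float | None = None
    ) -> np.ndarray:
        """Uniform sample without replacement of unknown pairs.

        Returns an ``(n, 2)`` array of (disease, miRNA) index pairs drawn
        from the zero entries of the training matrix, ``n = round(rho*|R|)``
        (capped at the number of zeros, with a warning).
        """
        if rho is None:
            rho = self.params.rho
        if rho < 0:
            raise ValueError("rho must be >= 0")
        n = int(round(rho * len(self._R)))
        if n > self._zero_flat.size:
            logger.warning(
                "requested %d negatives but only %d unknown pairs exist; "
                "using all of them", n, self._zero_flat.size,
            )
            n = self._zero_flat.size
        if n == 0:
            return np.empty((0, 2), dtype=np.int64)
        flat = rng.choice(self._zero_flat, size=n, replace=False)
        return np.column_stack(np.divmod(flat, self.dataset.nm)).astype(np.int64)

    def fit(self, seed: int = 0, start: FmsmState | None = None) -> "FMSMResults":
        """Train by per-sample SGD and return a results object.

        Each epoch resamples the negative set, shuffles the labelled pairs
        and applies one gradient step per sample to the touched parameters
        (``b_d``, ``b_m``, ``q_m`` and every neighbour row ``p_j``), with
        the ridge penalties applied per sample to the same parameters.  The
        full objective on that epoch's training pairs is recorded in
        ``loss_path``.
        """
        if len(self._R) == 0:
            raise ValueError("cannot fit on a dataset without associations")
        p = self.params
        rng = np.random.default_rng(seed)
        state = (start or self.initialize()).copy()
        P, Q, b_d, b_m = state
        alpha, eta = p.alpha, p.eta
        beta, lam, gam = p.beta, p.lam, p.gamma
        pos = self._pos
        loss_path: list[float] = []
        for epoch in range(p.max_iters):
            negatives = self.sample_negatives(rng)
            pairs, labels = self._labelled_pairs(negatives)
            order = rng.permutation(len(pairs))
            # overflow on a divergent trajectory is caught by the finiteness
            # check below rather than spamming runtime warnings
            with np.errstate(over="ignore", invalid="ignore"):
                for k in order:
                    d, m = int(pairs[k, 0]), int(pairs[k, 1])
                    r = labels[k]
                    js = pos[d]
                    js = js[js != m]
                    if js.size:
                        t = P[js].sum(axis=0)
                        w = float(js.size) ** (-alpha)
                        pred = b_d[d] + b_m[m] + w * (t @ Q[m])
                    else:
                        pred = b_d[d] + b_m[m]
                    err = r - pred
                    b_d[d] += eta * (err - lam * b_d[d])
                    b_m[m] += eta * (err - gam * b_m[m])
                    if js.size:
                        q_old = Q[m].copy()
                        Q[m] += eta * (err * w * t - beta * q_old)
                        P[js] += eta * (err * w * q_old - beta * P[js])
            if not state.is_finite():
                raise DivergenceError(
                    f"training diverged at epoch {epoch + 1}; "
                    f"try a smaller learning rate than eta={eta}"
                )
            loss = self.objective(state, negatives)
            loss_path.append(loss)
            logger.debug("epoch %d/%d objective %.6f", epoch + 1, p.max_iters, loss)
        return FMSMResults(self, state, np.array(loss_path), seed)


class FMSMResults:
    """Fitted FMSM parameters plus scoring, ranking and reporting."""

    def __init__(
        self,
        model: FMSM,
        state: FmsmState,
        loss_path: np.ndarray,
        seed: int,
    ) -> None:
        self.model = model
        self.state = state
        self.loss_path = loss_path
        self.seed = seed

    @property
    def P(self) -> np.ndarray:
        return self.state.P

    @property
    def Q(self) -> np.ndarray:
        return self.state.Q

    @property
    def b_d(self) -> np.ndarray:
        return self.state.b_d

    @property
    def b_m(self) -> np.ndarray:
        return self.state.b_m

    def predict_raw(self, d: int, m: int) -> float:
        """Raw factored-similarity score of one pair (no neighbourhood
        aggregation)."""
        return self.model.predict_raw(self.state, d, m)

    def raw_score_matrix(self) -> np.ndarray:
        """Raw scores for every (disease, miRNA) pair, vectorised."""
        model = self.model
        nd, nm = model.dataset.nd, model.dataset.nm
        alpha = model.params.alpha
        S_learn = self.P @ self.Q.T  # (nm, nm); S_learn[j, m] = p_j . q_m
        out = np.empty((nd, nm))
        for d in range(nd):
            js = model._pos[d]
            n = js.size
            base = self.b_d[d] + self.b_m
            if n == 0:
                out[d] = base
                continue
            row = S_learn[js].sum(axis=0)
            is_pos = np.zeros(nm, dtype=bool)
            is_pos[js] = True
            row = row - np.where(is_pos, np.diag(S_learn), 0.0)
            count = np.where(is_pos, n - 1, n).astype(float)
            with np.errstate(divide="ignore"):
                weight = np.where(count > 0, count ** (-alpha), 0.0)
            out[d] = base + weight * row
        return out

    def score_matrix(self) -> np.ndarray:
        """Final scores: raw scores plus similarity-neighbourhood averages.

        The disease term averages ``S_d(d_i, d')`` over training diseases
        associated with the candidate miRNA; the miRNA term averages
        ``S_m(m_j, m')`` over training miRNAs associated with the disease.
        Empty neighbourhoods contribute 0.
        """
        model = self.model
        if model.disease_similarity is None:
            raise ValueError("disease similarity is required for final scoring")
        U = model.dataset.U.astype(float)
        S_d = model.disease_similarity.S
        S_m = model.mirna_similarity.S
        p = model.params
        deg_m = U.sum(axis=0)
        deg_d = U.sum(axis=1)
        with np.errstate(invalid="ignore"):
            disease_term = p.w_d * (S_d @ U) / np.maximum(deg_m, 1.0)[None, :]
            mirna_term = p.w_m * (U @ S_m) / np.maximum(deg_d, 1.0)[:, None]
        disease_term[:, deg_m == 0] = 0.0
        mirna_term[deg_d == 0, :] = 0.0
        return self.raw_score_matrix() + disease_term + mirna_term

    def rankings(
        self, top_n: int | None = None
    ) -> dict[str, list[tuple[str, float]]]:
        """Per-disease ranked candidate lists over unknown pairs only.

        Known associations are masked out.  Candidates are sorted by
        descending score with lexicographic miRNA-name tie-break; diseases
        whose miRNAs are all known are omitted with a warning.
        """
        dataset = self.model.dataset
        scores = self.score_matrix()
        out: dict[str, list[tuple[str, float]]] = {}
        for d, disease in enumerate(dataset.diseases):
            candidates = np.flatnonzero(dataset.U[d] == 0)
            if candidates.size == 0:
                logger.warning(
                    "disease %r has no unknown miRNAs left to rank; omitted",
                    disease,
                )
                continue
            scored = sorted(
                ((dataset.mirnas[m], float(scores[d, m])) for m in candidates),
                key=lambda item: (-item[1], item[0]),
            )
            out[disease] = scored[:top_n] if top_n else scored
        return out

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        model = self.model
        ds = model.dataset
        p = model.params
        lines = [
            "Factored miRNA-Similarity Model Results",
            "=" * 44,
            f"diseases (nd):        {ds.nd}",
            f"miRNAs (nm):          {ds.nm}",
            f"associations |R|:     {ds.n_associations}",
            f"density:              {100 * ds.density():.3f}%",
            f"latent dimension:     {model.latent_dim}",
            f"alpha:                {p.alpha}",
            f"ridge (beta/lam/gam): {p.beta}/{p.lam}/{p.gamma}",
            f"learning rate eta:    {p.eta}",
            f"epochs:               {p.max_iters}",
            f"negative factor rho:  {p.rho}",
            f"aggregation W_d/W_m:  {p.w_d}/{p.w_m}",
            f"seed:                 {self.seed}",
        ]
        if self.loss_path.size:
            lines += [
                f"initial objective:    {self.loss_path[0]:.4f}",
                f"final objective:      {self.loss_path[-1]:.4f}",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<FMSMResults nd={self.model.dataset.nd} nm={self.model.dataset.nm} "
            f"epochs={len(self.loss_path)}>"
        )
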