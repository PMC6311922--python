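"""Data containers and plain-text I/O for miRNA-disease association analysis.

The central objects are:

``AssociationDataset``
    A binary disease x miRNA adjacency matrix ``U`` together with the ordered
    name lists that index it.  A 1-entry records an experimentally supported
    association between a disease and a miRNA; the set of 1-entries is ``R``.

``ExpressionProfiles``
    A miRNA x tissue matrix of expression levels used to derive pairwise
    miRNA expression similarity.  Coverage is typically partial: not every
    miRNA in the association network has a measured profile.

``MeshForest``
    A mapping from disease names to sets of dotted MeSH tree codes (for
    example ``C01.252``).  Each disease expands into a small DAG whose nodes
    are the disease's own codes plus every dotted-prefix ancestor.

``SimilarityMatrix``
    A symmetric square matrix of pairwise similarity scores in ``[0, 1]``
    with a boolean ``covered`` mask marking entities for which the source
    data actually existed.

All file formats are tab-separated UTF-8 text with ``#`` comment lines; the
exact layouts are documented on each reader.  Entity names are matched
case-insensitively after whitespace normalisation, which absorbs the naming
drift between miRNA/disease resources.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationDataset",
    "ExpressionProfiles",
    "MeshForest",
    "SimilarityMatrix",
    "ParseError",
    "read_associations",
    "write_associations",
    "read_expression",
    "read_mesh",
    "write_rankings",
    "read_similarity",
    "write_similarity",
]

MESH_CODE_RE = re.compile(r"^[A-Z][0-9]+(?:\.[0-9]+)*$")


class ParseError(ValueError):
    """Raised when an input file violates its documented layout."""


def canonical_key(name: str) -> str:
    """Matching key for an entity name: trimmed, blank-collapsed, lower-case."""
    return " ".join(name.split()).lower()


def _index_names(names: Sequence[str], what: str) -> dict[str, int]:
    index: dict[str, int] = {}
    for i, name in enumerate(names):
        key = canonical_key(name)
        if key in index:
            raise ValueError(f"duplicate {what} name {name!r}")
        index[key] = i
    return index


@dataclass
class AssociationDataset:
    """Binary miRNA-disease association network.

    Parameters
    ----------
    diseases, mirnas
        Ordered, duplicate-free name lists.  Internal indices are 0-based.
    U
        ``(nd, nm)`` matrix with entries in ``{0, 1}``; ``U[d, m] == 1``
        records a known association.
    """

    diseases: list[str]
    mirnas: list[str]
    U: np.ndarray

    _disease_index: dict[str, int] = field(init=False, repr=False)
    _mirna_index: dict[str, int] = field(init=False, repr=False)
    _R: frozenset[tuple[int, int]] | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U)
        if self.U.shape != (len(self.diseases), len(self.mirnas)):
            raise ValueError(
                f"U has shape {self.U.shape}, expected "
                f"({len(self.diseases)}, {len(self.mirnas)})"
            )
        if not np.isin(self.U, (0, 1)).all():
            raise ValueError("U must be binary")
        self.U = self.U.astype(np.int8)
        self._disease_index = _index_names(self.diseases, "disease")
        self._mirna_index = _index_names(self.mirnas, "miRNA")

    # -- basic geometry ----------------------------------------------------

    @property
    def nd(self) -> int:
        return len(self.diseases)

    @property
    def nm(self) -> int:
        return len(self.mirnas)

    @property
    def R(self) -> frozenset[tuple[int, int]]:
        """Set of ``(disease_index, mirna_index)`` pairs with ``U == 1``."""
        if self._R is None:
            d, m = np.nonzero(self.U)
            self._R = frozenset(zip(d.tolist(), m.tolist()))
        return self._R

    @property
    def n_associations(self) -> int:
        return int(self.U.sum())

    def density(self) -> float:
        """``|R| / (nd * nm)``, the sparsity of the association network."""
        return self.n_associations / (self.nd * self.nm)

    def disease_index(self, name: str) -> int:
        return self._disease_index[canonical_key(name)]

    def mirna_index(self, name: str) -> int:
        return self._mirna_index[canonical_key(name)]

    def positives_by_disease(self) -> list[np.ndarray]:
        """For each disease, the sorted array of associated miRNA indices."""
        return [np.flatnonzero(self.U[d]) for d in range(self.nd)]

    # -- derived datasets --------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        diseases: Sequence[str] | None = None,
        mirnas: Sequence[str] | None = None,
    ) -> "AssociationDataset":
        """Build a dataset from (disease, miRNA) name pairs.

        Duplicate pairs collapse to a single association.  Entity order is
        the order of first appearance unless explicit universes are given
        (which may include entities without any association).
        """
        disease_names: list[str] = list(diseases) if diseases else []
        mirna_names: list[str] = list(mirnas) if mirnas else []
        d_index = _index_names(disease_names, "disease")
        m_index = _index_names(mirna_names, "miRNA")
        edges: set[tuple[int, int]] = set()
        for d_name, m_name in pairs:
            dk, mk = canonical_key(d_name), canonical_key(m_name)
            if dk not in d_index:
                d_index[dk] = len(disease_names)
                disease_names.append(d_name.strip())
            if mk not in m_index:
                m_index[mk] = len(mirna_names)
                mirna_names.append(m_name.strip())
            edges.add((d_index[dk], m_index[mk]))
        U = np.zeros((len(disease_names), len(mirna_names)), dtype=np.int8)
        for d, m in edges:
            U[d, m] = 1
        return cls(disease_names, mirna_names, U)

    def without(self, pairs: Iterable[tuple[int, int]]) -> "AssociationDataset":
        """A copy with the given index pairs removed from the network.

        The returned matrix is rebuilt from the surviving association set, so
        the result depends only on ``R`` minus ``pairs`` -- never on the raw
        values stored at the removed entries.
        """
        drop = set(pairs)
        U = np.zeros_like(self.U)
        for d, m in self.R - drop:
            U[d, m] = 1
        return AssociationDataset(list(self.diseases), list(self.mirnas), U)


@dataclass
class ExpressionProfiles:
    """Per-miRNA expression levels across a panel of tissues/cell lines."""

    mirnas: list[str]
    tissues: list[str]
    E: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (len(self.mirnas), len(self.tissues)):
            raise ValueError("expression matrix shape mismatch")
        if np.isnan(self.E).all(axis=1).any():
            raise ValueError("a miRNA row is entirely missing")
        if self.zero_variance is None:
            self.zero_variance = np.ptp(self.E, axis=1) == 0
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)
        self._index = _index_names(self.mirnas, "miRNA")

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def row_for(self, mirna: str) -> int | None:
        """Row index of a miRNA (case-insensitive), or None if absent."""
        return self._index.get(canonical_key(mirna))


@dataclass
class MeshForest:
    """Disease -> MeSH tree codes, expandable to per-disease ancestor DAGs."""

    disease_codes: dict[str, frozenset[str]]

    _index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        for name, codes in self.disease_codes.items():
            for code in codes:
                if not MESH_CODE_RE.match(code):
                    raise ParseError(f"disease {name!r}: malformed MeSH code {code!r}")
            key = canonical_key(name)
            if key in index:
                raise ValueError(f"duplicate disease {name!r} in MeSH mapping")
            index[key] = name
        self._index = index

    def __contains__(self, disease: str) -> bool:
        return canonical_key(disease) in self._index

    def __len__(self) -> int:
        return len(self.disease_codes)

    def codes(self, disease: str) -> frozenset[str]:
        key = canonical_key(disease)
        if key not in self._index:
            raise KeyError(f"disease {disease!r} has no MeSH codes")
        return self.disease_codes[self._index[key]]

    @staticmethod
    def parent(code: str) -> str | None:
        """Dotted-prefix parent of a code (``C01.252`` -> ``C01``)."""
        head, sep, _ = code.rpartition(".")
        return head if sep else None

    @classmethod
    def ancestor_chain(cls, code: str) -> list[str]:
        """The code itself plus all its prefixes, deepest first."""
        chain = [code]
        parent = cls.parent(code)
        while parent is not None:
            chain.append(parent)
            parent = cls.parent(parent)
        return chain

    def dag(self, disease: str) -> tuple[frozenset[str], frozenset[tuple[str, str]]]:
        """Node and edge sets of the disease's DAG.

        Nodes are the union of the ancestor chains of all the disease's
        codes; edges run parent -> child along dotted-prefix truncation.
        """
        nodes: set[str] = set()
        for code in self.codes(disease):
            nodes.update(self.ancestor_chain(code))
        edges = {
            (p, c) for c in nodes if (p := self.parent(c)) is not None
        }
        return frozenset(nodes), frozenset(edges)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity with a coverage mask.

    Entries lie in ``[0, 1]``; covered entities carry a unit diagonal.  Rows
    and columns of uncovered entities are left at zero by the producers and
    typically replaced by a kernel-based fallback during integration.
    """

    names: list[str]
    S: np.ndarray
    covered: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.covered = np.asarray(self.covered, dtype=bool)
        n = len(self.names)
        if self.S.shape != (n, n) or self.covered.shape != (n,):
            raise ValueError("similarity matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.names)

    def validate(self, atol: float = 1e-9) -> None:
        """Assert symmetry, bounds and unit diagonal on covered entities."""
        if not np.allclose(self.S, self.S.T, atol=atol, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        if self.S.min() < -atol or self.S.max() > 1 + atol:
            raise ValueError("similarity entries outside [0, 1]")
        diag = np.diag(self.S)[self.covered]
        if diag.size and not np.allclose(diag, 1.0, atol=atol, rtol=0):
            raise ValueError("covered diagonal entries must equal 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_associations(path) -> AssociationDataset:
    """Read a two-column TSV of (disease, miRNA) association pairs.

    Layout: one ``disease<TAB>miRNA`` pair per line; ``#`` starts a comment.
    Optional ``#! diseases:`` / ``#! mirnas:`` directives (written by
    :func:`write_associations`) pin the full entity universes and their
    order, preserving entities that have no association.  Duplicate pairs
    collapse to a single entry.
    """
    pairs: list[tuple[str, str]] = []
    diseases: list[str] | None = None
    mirnas: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if stripped.startswith("#!"):
                body = stripped[2:].strip()
                if body.startswith("diseases:"):
                    diseases = body[len("diseases:"):].strip().split("\t")
                elif body.startswith("mirnas:"):
                    mirnas = body[len("mirnas:"):].strip().split("\t")
                continue
            if not stripped or stripped.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 2 or not all(parts):
                raise ParseError(
                    f"{path}: line {lineno}: expected two tab-separated columns"
                )
            pairs.append((parts[0], parts[1]))
    if not pairs and not (diseases and mirnas):
        raise ParseError(f"{path}: no association pairs found")
    dataset = AssociationDataset.from_pairs(pairs, diseases=diseases, mirnas=mirnas)
    logger.info(
        "read %s: nd=%d nm=%d |R|=%d density=%.4f%%",
        path, dataset.nd, dataset.nm, dataset.n_associations,
        100 * dataset.density(),
    )
    return dataset


def write_associations(dataset: AssociationDataset, path) -> None:
    """Write a dataset as a pair TSV, with universe directives for exact
    round-tripping (entities without associations survive)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#! diseases:\t" + "\t".join(dataset.diseases) + "\n")
        fh.write("#! mirnas:\t" + "\t".join(dataset.mirnas) + "\n")
        for d, m in sorted(dataset.R):
            fh.write(f"{dataset.diseases[d]}\t{dataset.mirnas[m]}\n")


def read_expression(path) -> ExpressionProfiles:
    """Read a miRNA x tissue expression matrix.

    Layout: header row of tissue names (first cell is a label for the miRNA
    column), one row per miRNA, numeric body.  Constant rows are flagged as
    zero-variance (Pearson correlation is undefined for them).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: cannot parse expression matrix: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate miRNA rows: {dupes}")
    try:
        E = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    if E.size == 0:
        raise ParseError(f"{path}: empty expression matrix")
    profiles = ExpressionProfiles(
        mirnas=[str(m) for m in df.index],
        tissues=[str(t) for t in df.columns],
        E=E,
    )
    n_flagged = int(profiles.zero_variance.sum())
    if n_flagged:
        logger.warning(
            "%s: %d zero-variance expression rows flagged (Pearson undefined)",
            path, n_flagged,
        )
    return profiles


def read_mesh(path) -> MeshForest:
    """Read a TSV mapping ``disease<TAB>code[;code...]`` to a MeSH forest."""
    mapping: dict[str, frozenset[str]] = {}
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2 or not all(parts):
            raise ParseError(
                f"{path}: line {lineno}: expected 'disease<TAB>codes'"
            )
        name, code_field = parts
        key = canonical_key(name)
        if key in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate disease {name!r}")
        seen.add(key)
        codes = frozenset(c.strip() for c in code_field.split(";") if c.strip())
        if not codes:
            raise ParseError(f"{path}: line {lineno}: no codes for {name!r}")
        for code in codes:
            if not MESH_CODE_RE.match(code):
                raise ParseError(
                    f"{path}: line {lineno}: disease {name!r} has malformed "
                    f"MeSH code {code!r}"
                )
        mapping[name] = codes
    if not mapping:
        raise ParseError(f"{path}: no MeSH entries found")
    return MeshForest(mapping)


def write_rankings(
    rankings: Mapping[str, Iterable[tuple[str, float]]], path
) -> None:
    """Write per-disease candidate rankings as a 4-column TSV.

    Columns: disease, rank (1-based), miRNA, score.  Candidates are ordered
    by descending score with lexicographic miRNA-name tie-break.  Diseases
    with an empty candidate list are omitted with a warning.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease\trank\tmiRNA\tscore\n")
        for disease, scored in rankings.items():
            scored = list(scored)
            if not scored:
                logger.warning("disease %r has no candidates; omitted", disease)
                continue
            if not all(np.isfinite(s) for _, s in scored):
                raise ValueError(f"non-finite score for disease {disease!r}")
            ordered = sorted(scored, key=lambda item: (-item[1], item[0]))
            for rank, (mirna, score) in enumerate(ordered, start=1):
                fh.write(f"{disease}\t{rank}\t{mirna}\t{score:.10g}\n")


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Dump a similarity matrix as a square TSV with name header row/col."""
    df = pd.DataFrame(sim.S, index=sim.names, columns=sim.names)
    df.insert(0, "covered", sim.covered.astype(int))
    df.to_csv(path, sep="\t")


def read_similarity(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    covered = df.pop("covered").to_numpy(dtype=bool)
    return SimilarityMatrix(
        names=[str(n) for n in df.index],
        S=df.to_numpy(dtype=float),
        covered=covered,
    )
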