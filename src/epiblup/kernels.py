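"""Relationship kernels for additive and epistatic genomic prediction.

Three kernels over binary DH panels:

* **GBLUP** — VanRaden additive genomic relationship from 0/2 dosages.
* **ERRBLUP** — epistatic random-regression kernel over *all* pairwise
  marker combinations (unordered pairs including self-pairs, so p markers
  give p(p+1)/2 interaction columns).  The interaction design matrix T has
  a 0/1 column per pair coding presence of the 1/1 combination; the kernel
  is the frequency-centered cross-product T scaled VanRaden-style.
* **sERRBLUP** — the same construction restricted to a selected subset of
  pairs (see :mod:`epiblup.selection`).

The ERRBLUP kernel is computed without ever materializing T: for binary M
with S = M M^T, the uncentered pair cross-product satisfies
(T T^T)_ab = (S_ab^2 + S_ab)/2 — lines a and b share S_ab loci at value 1,
and a pair column is 1 for both lines iff both its loci lie in that shared
set — and every centering/scaling term (row sums of T T^T, sum of squared
column frequencies, the sum f(1-f)) is a function of S alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import PredictorPanel

logger = logging.getLogger("epiblup")

__all__ = [
    "RelationshipKernel",
    "InteractionSet",
    "n_interactions",
    "all_pairs",
    "interaction_design",
    "pair_frequencies",
    "gblup_kernel",
    "errblup_kernel",
    "serrblup_kernel",
]


@dataclass
class RelationshipKernel:
    """Symmetric n x n genomic similarity matrix.

    ``scale_c`` is the denominator used in construction (sum of column
    variances of the centered design); ``n_predictors_or_pairs`` the number
    of design columns behind the kernel.
    """

    line_ids: list[str]
    matrix: np.ndarray
    kind: str
    scale_c: float
    n_predictors_or_pairs: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kernel matrix shape does not match line_ids")
        dev = float(np.abs(self.matrix - self.matrix.T).max()) if n else 0.0
        if dev > 1e-10:
            raise ValueError(f"kernel not symmetric (max deviation {dev:.3g})")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def ridged(self) -> np.ndarray:
        """PSD-guarded copy for REML: K + delta*I with
        delta = max(0, -lambda_min) + 1e-8 * mean(diag)."""
        lam_min = float(np.linalg.eigvalsh(self.matrix)[0])
        delta = max(0.0, -lam_min) + 1e-8 * float(np.mean(np.diag(self.matrix)))
        if lam_min < 0:
            logger.info("kernel %s ridged by %.3g (lambda_min=%.3g)", self.kind, delta, lam_min)
        return self.matrix + delta * np.eye(self.n_lines)

    def index_of(self, lines) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[l] for l in lines], dtype=int)
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} absent from kernel") from None


@dataclass
class InteractionSet:
    """Unordered predictor index pairs (j, k), j <= k, with pair frequencies.

    ``freq[i]`` is the mean over lines of the 0/1 indicator column of pair i
    (computed on the full panel).  Pairs are stored sorted lexicographically.
    """

    pairs: np.ndarray  # (m, 2) int, j <= k
    freq: np.ndarray | None = None
    score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if (self.pairs[:, 0] > self.pairs[:, 1]).any():
            raise ValueError("pairs must satisfy j <= k")
        order = np.lexsort((self.pairs[:, 1], self.pairs[:, 0]))
        self.pairs = self.pairs[order]
        if self.freq is not None:
            self.freq = np.asarray(self.freq, dtype=float)[order]
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)[order]
        keys = self.pairs[:, 0] * (self.pairs[:, 1].max(initial=0) + 1) + self.pairs[:, 1]
        if np.unique(keys).size != len(keys):
            raise ValueError("duplicate pairs")

    def __len__(self) -> int:
        return len(self.pairs)


def n_interactions(p: int) -> int:
    """Number of unordered pairwise marker combinations, self-pairs included.

    p markers give p(p+1)/2 interactions; e.g. 3330 haplotype-block
    variants give 5,546,115.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    return p * (p + 1) // 2


def all_pairs(p: int) -> InteractionSet:
    """Every unordered pair (j, k), j <= k, in lexicographic order."""
    j, k = np.triu_indices(p)
    return InteractionSet(np.column_stack([j, k]))


def pair_frequencies(panel: PredictorPanel, pairs: InteractionSet) -> np.ndarray:
    """Frequency of the 1/1 combination per pair over all lines."""
    m = panel.matrix
    return (m[:, pairs.pairs[:, 0]] & m[:, pairs.pairs[:, 1]]).mean(axis=0)


def interaction_design(panel: PredictorPanel, pairs: InteractionSet | None = None) -> np.ndarray:
    """Materialize the 0/1 interaction design matrix T (n x |pairs|).

    Column for pair (j, k) is the elementwise product of predictor columns
    j and k; the self-pair column (j, j) equals column j.  ``pairs=None``
    means all pairs.  Intended for small panels and as the brute-force
    reference; the kernels below avoid materializing T.
    """
    if pairs is None:
        pairs = all_pairs(panel.n_predictors)
    if len(pairs) and pairs.pairs.max() >= panel.n_predictors:
        raise IndexError("pair index out of range for panel")
    m = panel.matrix
    return (m[:, pairs.pairs[:, 0]] & m[:, pairs.pairs[:, 1]]).astype(np.uint8)


def gblup_kernel(panel: PredictorPanel) -> RelationshipKernel:
    """VanRaden additive genomic relationship matrix.

    DH dosage X = 2*M (in {0, 2}); Z = X - 2*f per column with f the allele
    frequency of the analyzed panel itself; K = Z Z^T / sum_j 2 f_j (1-f_j).
    Fully inbred DH lines give trace(K)/n near 2.
    """
    m = panel.matrix.astype(float)
    f = m.mean(axis=0)
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise ValueError("all predictors monomorphic; GBLUP denominator is zero")
    z = 2.0 * (m - f)
    c = float(np.sum(2.0 * f * (1.0 - f)))
    return RelationshipKernel(
        line_ids=list(panel.line_ids), matrix=(z @ z.T) / c, kind="gblup",
        scale_c=c, n_predictors_or_pairs=panel.n_predictors,
    )


def _errblup_terms(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Centered cross-product terms of the full pair design from S = M M^T.

    Returns (TT^T, v, sum_f2, c) where v_a = sum_k f_k T_ak,
    sum_f2 = sum_k f_k^2 and c = sum_k f_k (1 - f_k).
    """
    n = m.shape[0]
    s = (m.astype(float) @ m.T.astype(float))
    tt = 0.5 * (s * s + s)  # (TT^T)_ab = (S_ab^2 + S_ab)/2
    v = tt.sum(axis=1) / n
    sum_f = float(np.trace(tt)) / n  # row a of T sums to (TT^T)_aa for 0/1 T
    sum_f2 = float(tt.sum()) / (n * n)
    c = sum_f - sum_f2
    return tt, v, sum_f2, c


def errblup_kernel(panel: PredictorPanel) -> RelationshipKernel:
    """Epistatic kernel over all pairwise combinations, via the fast path.

    Equals W W^T / c with W the frequency-centered full interaction design
    and c = sum_k f_k (1 - f_k), but computed from S = M M^T only.
    """
    m = panel.matrix
    tt, v, sum_f2, c = _errblup_terms(m)
    if c <= 0:
        raise ValueError("all interaction columns constant; ERRBLUP scale is zero")
    k = (tt - v[:, None] - v[None, :] + sum_f2) / c
    return RelationshipKernel(
        line_ids=list(panel.line_ids), matrix=k, kind="errblup",
        scale_c=c, n_predictors_or_pairs=n_interactions(panel.n_predictors),
    )


def serrblup_kernel(
    panel: PredictorPanel,
    selected: InteractionSet,
    batch_size: int = 1 << 20,
) -> RelationshipKernel:
    """Epistatic kernel restricted to a selected set of pairs.

    Selected pair columns are materialized in batches of at most
    ``batch_size`` columns (results are batch-size invariant), centered by
    their full-panel frequencies and scaled by c = sum f(1-f) over the
    selected pairs only.
    """
    if len(selected) == 0:
        raise ValueError("empty interaction selection")
    m = panel.matrix
    n = m.shape[0]
    gram = np.zeros((n, n))
    v = np.zeros(n)
    sum_f = 0.0
    sum_f2 = 0.0
    for lo in range(0, len(selected), batch_size):
        pb = selected.pairs[lo : lo + batch_size]
        t = (m[:, pb[:, 0]] & m[:, pb[:, 1]]).astype(float)
        f = t.mean(axis=0)
        gram += t @ t.T
        v += t @ f
        sum_f += float(f.sum())
        sum_f2 += float(f @ f)
    c = sum_f - sum_f2
    if c <= 0:
        raise ValueError("selected interaction columns all constant; sERRBLUP scale is zero")
    k = (gram - v[:, None] - v[None, :] + sum_f2) / c
    return RelationshipKernel(
        line_ids=list(panel.line_ids), matrix=k, kind="serrblup",
        scale_c=c, n_predictors_or_pairs=len(selected),
    )
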