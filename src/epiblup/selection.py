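"""Interaction-effect backsolving and variance-based pair selection.

sERRBLUP keeps only the pairwise marker combinations with the largest
estimated effect variances.  The effects are never fitted directly (the
full pair design has p(p+1)/2 columns); instead they are backsolved from
the genetic values of an ERRBLUP fit using the equivalence of the kernel
and random-regression formulations of BLUP:

    alpha_hat = (1/c) W^T K^+ g_hat,

with W the centered pair design, c the kernel scale, and K^+ the
pseudo-inverse of the (unridged) ERRBLUP kernel.  The variance a centered
0/1 column with frequency f contributes at effect alpha is
alpha^2 f (1 - f), which is the ranking criterion.

Selection is run once on the complete previous-year data of the target
environment, never inside cross-validation folds: the across-year design
deliberately borrows information from the source year, and target-year
test phenotypes are never seen.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .data_io import PredictorPanel
from .kernels import InteractionSet, RelationshipKernel, all_pairs

__all__ = ["EffectVarianceRanking", "backsolve_effects", "effect_variances", "select_top"]

DEFAULT_Q_GRID = (0.10, 0.05, 0.01, 0.001, 0.0001, 0.00001)


@dataclass
class EffectVarianceRanking:
    """Per-pair backsolved effects and estimated effect variances."""

    pairs: InteractionSet
    alpha_hat: np.ndarray | None = None
    var_hat: np.ndarray | None = None
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID


def backsolve_effects(
    panel: PredictorPanel,
    g_hat: np.ndarray,
    kernel: RelationshipKernel,
    batch_size: int = 1 << 20,
    pinv_rtol: float = 1e-10,
) -> EffectVarianceRanking:
    """Backsolve all pairwise interaction effects from ERRBLUP genetic values.

    ``g_hat`` must be the BLUPs (one per kernel line, in kernel line order)
    of a fit that used ``kernel``, and the kernel must have been built from
    ``panel``.  Effects are computed in column batches; the result is
    batch-size invariant and never materializes the full design.
    """
    if kernel.kind != "errblup":
        raise ValueError("backsolve requires an ERRBLUP kernel")
    if list(kernel.line_ids) != list(panel.line_ids):
        raise ValueError("kernel was not built from this panel (line ids differ)")
    g_hat = np.asarray(g_hat, dtype=float)
    if g_hat.shape != (panel.n_lines,):
        raise ValueError("g_hat length does not match panel lines")

    # u = K^+ g_hat via eigendecomposition; small singular values zeroed
    w, v = np.linalg.eigh(kernel.matrix)
    keep = w > pinv_rtol * max(w.max(), 0.0)
    u = v[:, keep] @ ((v[:, keep].T @ g_hat) / w[keep])

    m = panel.matrix
    n = m.shape[0]
    pairs = all_pairs(panel.n_predictors)
    alpha = np.empty(len(pairs))
    freq = np.empty(len(pairs))
    u_sum = float(u.sum())
    for lo in range(0, len(pairs), batch_size):
        pb = pairs.pairs[lo : lo + batch_size]
        t = (m[:, pb[:, 0]] & m[:, pb[:, 1]]).astype(float)
        f = t.mean(axis=0)
        # W^T u with W = T - 1 f^T
        alpha[lo : lo + len(pb)] = (t.T @ u - f * u_sum) / kernel.scale_c
        freq[lo : lo + len(pb)] = f
    pairs.freq = freq
    return EffectVarianceRanking(pairs=pairs, alpha_hat=alpha)


def effect_variances(ranking: EffectVarianceRanking) -> EffectVarianceRanking:
    """Fill ``var_hat`` = alpha^2 f (1 - f) from the backsolved effects."""
    if ranking.alpha_hat is None:
        raise ValueError("alpha_hat not filled; run backsolve_effects first")
    f = ranking.pairs.freq
    if f is None:
        raise ValueError("pair frequencies missing")
    ranking.var_hat = ranking.alpha_hat**2 * f * (1.0 - f)
    return ranking


def select_top(ranking: EffectVarianceRanking, q: float) -> InteractionSet:
    """Top ceil(q * P) pairs by estimated effect variance.

    Ties are broken by lexicographic pair index, so selections are total,
    deterministic and nested across q.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    if ranking.var_hat is None:
        raise ValueError("var_hat not filled; run effect_variances first")
    n_keep = ceil(q * len(ranking.pairs))
    pr = ranking.pairs.pairs
    order = np.lexsort((pr[:, 1], pr[:, 0], -ranking.var_hat))
    top = order[:n_keep]
    return InteractionSet(
        pairs=pr[top],
        freq=None if ranking.pairs.freq is None else ranking.pairs.freq[top],
        score=ranking.var_hat[top],
    )
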