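"""Fine evaluation, importance ordering and significance of selected genes.

After crude filtering the surviving gene set is small enough for greedy
leave-one-gene-out search.  ``fine_evaluate`` runs backward elimination
under 10-fold cross-validated MCC; ``order_importance`` repeats the
leave-one-out sweep to rank genes from most to least dispensable; and
``significance`` rebuilds the paired inclusion/exclusion design over the
final genes — exhaustively when that is affordable — and reports a paired
t-test p-value per gene.

All subsets within one run are cross-validated under a single shared fold
partition, so leave-one-gene-out score differences are paired comparisons:
greedy decisions cannot flap on fold-assignment noise, and identical
subsets always score identically.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .datamodel import ExpressionDataset, GeneSubset
from .filter import fit_surrogate, generate_inclusion_scheme, pair_scores
from .metrics import CVConfig, cv_mcc

ScoreFn = Callable[[tuple[int, ...]], float]

FULL_ENUMERATION_MAX = 9  # 2^9 = 512 rows; beyond this, sample the design


def make_cv_scorer(
    dataset: ExpressionDataset, cfg: CVConfig | None = None, seed: int = 0
) -> ScoreFn:
    """Memoised 10-fold CV MCC scorer with one shared fold partition.

    Every subset is scored under the partition drawn from ``seed``, so
    leave-one-gene-out comparisons are paired: score differences reflect
    the genes, not fold reshuffling, and identical subsets always score
    identically within a run.
    """
    cfg = (cfg or CVConfig(n_folds=10)).with_seed(seed)
    cache: dict[tuple[int, ...], float] = {}

    def score(indices: tuple[int, ...]) -> float:
        key = tuple(sorted(indices))
        if key not in cache:
            cache[key] = cv_mcc(dataset, GeneSubset(key), cfg)
        return cache[key]

    return score


def _resolve_scorer(
    dataset: ExpressionDataset | None,
    cfg: CVConfig | None,
    seed: int,
    score_fn: ScoreFn | None,
) -> ScoreFn:
    if score_fn is not None:
        return score_fn
    if dataset is None:
        raise ValueError("either a dataset or an explicit score_fn is required")
    return make_cv_scorer(dataset, cfg, seed)


def fine_evaluate(
    dataset: ExpressionDataset | None,
    genes: GeneSubset,
    cfg: CVConfig | None = None,
    seed: int = 0,
    score_fn: ScoreFn | None = None,
) -> GeneSubset:
    """Greedy backward elimination of the post-filtering gene set.

    At each step the full candidate set Omega is scored, then every
    leave-one-gene-out subset; if the best leave-one-out score is strictly
    below the full-set score, elimination stops and Omega is reported.
    Otherwise the gene whose removal scores highest is dropped (ties: the
    lowest gene index) and the step repeats.  A single gene is never
    removed, so the result is non-empty.
    """
    if len(genes) < 1:
        raise ValueError("fine evaluation needs at least 1 gene")
    score = _resolve_scorer(dataset, cfg, seed, score_fn)
    omega = sorted(genes.indices)
    while len(omega) > 1:
        phi_full = score(tuple(omega))
        phi_minus = [score(tuple(g for g in omega if g != gi)) for gi in omega]
        best = int(np.argmax(phi_minus))  # first max -> lowest gene index
        if phi_minus[best] < phi_full:
            break
        omega.pop(best)
    return GeneSubset(omega)


@dataclass
class ImportanceOrder:
    """Genes in decreasing order of importance, with the removal trace."""

    ordered_genes: list[int]
    trace: list[tuple[int, float]] = field(default_factory=list)


def order_importance(
    dataset: ExpressionDataset | None,
    final_genes: GeneSubset,
    cfg: CVConfig | None = None,
    seed: int = 0,
    score_fn: ScoreFn | None = None,
) -> ImportanceOrder:
    """Rank final genes by repeated most-dispensable-first elimination.

    The gene whose exclusion gives the highest CV MCC is removed from the
    buffer and prepended to the order; the last gene standing ends up at
    the head, i.e. most important first.
    """
    if len(final_genes) < 1:
        raise ValueError("importance ordering needs at least 1 gene")
    score = _resolve_scorer(dataset, cfg, seed, score_fn)
    buffer = sorted(final_genes.indices)
    ordered: list[int] = []
    trace: list[tuple[int, float]] = []
    while len(buffer) > 1:
        phi_minus = [score(tuple(g for g in buffer if g != gi)) for gi in buffer]
        q = int(np.argmax(phi_minus))
        trace.append((buffer[q], float(phi_minus[q])))
        ordered.insert(0, buffer.pop(q))
    ordered.insert(0, buffer.pop())
    return ImportanceOrder(ordered_genes=ordered, trace=trace)


def significance_design(k0: int, K: int = 300, seed: int = 0) -> np.ndarray:
    """Binary design matrix over the final genes for paired significance.

    With k0 <= 9 genes all 2^k0 inclusion patterns are enumerated (binary
    counting order).  With more genes, a K-row balanced scheme is drawn and
    k0+1 rows are appended: the all-ones row, then the k0 x k0 identity so
    each gene also gets a univariate row.
    """
    if k0 < 1:
        raise ValueError("need at least 1 gene")
    if k0 <= FULL_ENUMERATION_MAX:
        return np.array(list(itertools.product((0, 1), repeat=k0)), dtype=np.int8)
    scheme = generate_inclusion_scheme(K, GeneSubset(range(k0)), seed)
    extra = np.vstack([np.ones((1, k0), dtype=np.int8), np.eye(k0, dtype=np.int8)])
    return np.vstack([scheme.bits, extra])


def significance(
    dataset: ExpressionDataset | None,
    final_genes: GeneSubset,
    K: int = 300,
    seed: int = 0,
    cfg: CVConfig | None = None,
    score_fn: ScoreFn | None = None,
    svr_params: dict | None = None,
    alternative: str = "two-sided",
) -> dict[int, float]:
    """Per-gene paired t-test p-values over the inclusion/exclusion design.

    Every design row's gene subset is scored by CV MCC (the all-zeros row is
    the empty model and scores 0 by convention); a surrogate is fitted on
    the design, each gene's column is flipped to predict the counterfactual
    scores, and the paired excluded/included vectors are compared by a
    paired t-test.  Returns {dataset gene index: p-value}.
    """
    if len(final_genes) < 2:
        raise ValueError("significance needs at least 2 genes")
    score = _resolve_scorer(dataset, cfg or CVConfig(n_folds=10), seed, score_fn)
    genes = sorted(final_genes.indices)
    k0 = len(genes)
    X0 = significance_design(k0, K=K, seed=seed)
    phi0 = np.array(
        [
            score(tuple(genes[c] for c in np.flatnonzero(row))) if row.any() else 0.0
            for row in X0
        ]
    )
    surrogate = fit_surrogate(X0, phi0, svr_params)
    p_values: dict[int, float] = {}
    for col, gene in enumerate(genes):
        flipped = X0.copy()
        flipped[:, col] = 1 - flipped[:, col]
        phi1 = surrogate.predict(flipped.astype(float))
        paired = pair_scores(X0, phi0, phi1, col, gene=gene)
        diffs = paired.Zi - paired.Z0
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(), 0.0):
            warnings.warn(
                f"gene {gene}: zero variance in paired differences; p set to 1"
            )
            p_values[gene] = 1.0
            continue
        result = stats.ttest_rel(paired.Zi, paired.Z0, alternative=alternative)
        p_values[gene] = float(result.pvalue)
    return p_values
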