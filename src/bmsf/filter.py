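"""The BMSF fast-filtering engine.

Each round draws a K x G binary inclusion scheme whose columns are balanced
(exactly K/2 ones), scores every row's gene subset by cross-validated SVM
MCC, fits one support-vector-regression surrogate mapping inclusion patterns
to MCC, and then asks, for every gene, whether flipping its column — i.e.
excluding it wherever it was included and vice versa, holding all other
genes fixed — is predicted to improve performance.  Genes whose exclusion
wins the paired comparison are removed simultaneously at round end.

Rounds continue with a decreasing K schedule while the full-survivor-set
MCC keeps improving; on a drop the previous (better-scoring) gene set is
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.svm import SVR

from .datamodel import ExpressionDataset, GeneSubset
from .metrics import CVConfig, cv_mcc

logger = logging.getLogger(__name__)

DEFAULT_K_START = 500
DEFAULT_K_STEP = 50
DEFAULT_K_FLOOR = 300

# SVR surrogate over binary inclusion rows.  A degree-2 polynomial kernel
# spans main effects and pairwise products of the inclusion indicators, so
# the flip predictions can express one gene's effect depending on another
# gene's inclusion state; epsilon is small relative to the MCC spread.
DEFAULT_SVR_PARAMS = {
    "kernel": "poly",
    "degree": 2,
    "coef0": 1.0,
    "C": 1.0,
    "epsilon": 0.01,
    "gamma": "scale",
}


class AllGenesEliminatedError(RuntimeError):
    """A round removed every gene; the caller should fall back to the
    pre-round gene set (the stopping semantics of the multi-round loop)."""


@dataclass
class TrainingCounter:
    """Instrumented count of models trained, in the filtering budget's units.

    One cross-validated training (all folds of one scheme row, or the
    initial full-set evaluation) counts as one classification model; each
    round's surrogate fit counts as one regression model.  Round-end
    checkpoint evaluations of the survivor set are tracked separately and
    excluded from the budget.
    """

    classification: int = 0
    regression: int = 0
    checkpoint: int = 0

    @property
    def total(self) -> int:
        return self.classification + self.regression


@dataclass(frozen=True)
class InclusionScheme:
    """K x G_cur balanced binary design: rows are candidate gene subsets.

    Every column holds exactly K/2 ones, so over the K rows each surviving
    gene is included and excluded equally often.  ``column_map`` maps scheme
    columns back to dataset gene indices.
    """

    bits: np.ndarray
    column_map: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "column_map", tuple(int(i) for i in self.column_map))
        K, G = bits.shape
        if K % 2 != 0:
            raise ValueError(f"K must be even, got {K}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("scheme entries must be 0/1")
        sums = bits.sum(axis=0)
        if not (sums == K // 2).all():
            raise ValueError("every column must contain exactly K/2 ones")
        if len(self.column_map) != G or len(set(self.column_map)) != G:
            raise ValueError("column_map must be injective with one entry per column")

    @property
    def K(self) -> int:
        return self.bits.shape[0]

    @property
    def n_genes(self) -> int:
        return self.bits.shape[1]

    def row_subset(self, k: int) -> GeneSubset:
        """Dataset gene indices included by row k."""
        cols = np.flatnonzero(self.bits[k])
        return GeneSubset([self.column_map[c] for c in cols])


@dataclass
class RoundRecord:
    """Log of one filtering round."""

    round_index: int
    K_used: int
    phi0: np.ndarray
    eliminated: list[int]
    survivors: list[int]
    mu_before: float
    mu_after: float


def generate_inclusion_scheme(K: int, genes: GeneSubset, seed: int) -> InclusionScheme:
    """Draw a balanced K x |genes| inclusion scheme.

    Each column is an independent seeded permutation of a vector of K/2 ones
    and K/2 zeros.
    """
    if K < 2 or K % 2 != 0:
        raise ValueError(f"K must be an even integer >= 2, got {K}")
    if len(genes) < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    base = np.zeros(K, dtype=np.int8)
    base[: K // 2] = 1
    bits = np.column_stack([rng.permutation(base) for _ in range(len(genes))])
    return InclusionScheme(bits=bits, column_map=tuple(genes.indices), seed=int(seed))


def evaluate_rows(
    dataset: ExpressionDataset,
    scheme: InclusionScheme,
    cfg: CVConfig,
    counter: TrainingCounter | None = None,
) -> np.ndarray:
    """Cross-validated MCC of every scheme row's gene subset (the vector phi0).

    All rows share the fold partition drawn from cfg.seed, so row-to-row
    score differences reflect subset composition, not partition luck, and
    identical rows score identically.  Rows with no ones score 0.
    """
    phi0 = np.empty(scheme.K)
    for k in range(scheme.K):
        phi0[k] = cv_mcc(dataset, scheme.row_subset(k), cfg)
        if counter is not None:
            counter.classification += 1
    return phi0


def fit_surrogate(
    scheme_bits: np.ndarray, phi0: np.ndarray, svr_params: dict | None = None
) -> SVR:
    """Fit the SVR surrogate: binary inclusion rows -> observed row MCC."""
    phi0 = np.asarray(phi0, dtype=float)
    if len(phi0) != scheme_bits.shape[0]:
        raise ValueError("phi0 length must equal the number of scheme rows")
    model = SVR(**(svr_params or DEFAULT_SVR_PARAMS))
    model.fit(np.asarray(scheme_bits, dtype=float), phi0)
    return model


def flip_column(scheme: InclusionScheme, col: int) -> InclusionScheme:
    """Complement one column, leaving every other column bit-identical.

    The balanced-column invariant is preserved: complementing K/2 ones and
    K/2 zeros yields K/2 ones again.
    """
    if not 0 <= col < scheme.n_genes:
        raise ValueError(f"column {col} out of range for {scheme.n_genes} columns")
    bits = scheme.bits.copy()
    bits[:, col] = 1 - bits[:, col]
    return replace(scheme, bits=bits)


@dataclass(frozen=True)
class PairedScores:
    """Paired performance vectors for one gene's conditional assessment.

    ``Z0[k]`` is the (observed or predicted) performance of row k's gene
    combination with the gene excluded; ``Zi[k]`` with it included.  All
    other genes' inclusion states are identical within each pair.
    """

    Z0: np.ndarray
    Zi: np.ndarray
    gene: int

    def __post_init__(self) -> None:
        if self.Z0.shape != self.Zi.shape:
            raise ValueError("Z0 and Zi must have equal length")
        if not (np.isfinite(self.Z0).all() and np.isfinite(self.Zi).all()):
            raise ValueError("paired scores must be finite")


def pair_scores(
    bits: np.ndarray, phi0: np.ndarray, phi1: np.ndarray, col: int, gene: int = -1
) -> PairedScores:
    """Assemble the excluded/included score pairs for one column.

    Where the design has a 0 in the column, the observed score phi0[k] is an
    exclusion score and the flipped prediction phi1[k] an inclusion score;
    where it has a 1, the roles swap.
    """
    phi0 = np.asarray(phi0, dtype=float)
    phi1 = np.asarray(phi1, dtype=float)
    if phi0.shape != phi1.shape or len(phi0) != bits.shape[0]:
        raise ValueError("phi0 and phi1 must both have one entry per design row")
    included = bits[:, col] == 1
    Z0 = np.where(included, phi1, phi0)
    Zi = np.where(included, phi0, phi1)
    return PairedScores(Z0=Z0, Zi=Zi, gene=int(gene))


def filter_round(
    dataset: ExpressionDataset,
    genes: GeneSubset,
    K: int,
    seed: int,
    cfg: CVConfig,
    counter: TrainingCounter | None = None,
    svr_params: dict | None = None,
    round_index: int = 1,
) -> RoundRecord:
    """One round of crude filtering over the current gene set.

    Exactly K cross-validated classifier trainings (one per scheme row) and
    one SVR training are performed; every per-gene comparison reuses the
    surrogate's predictions.  Elimination decisions are evaluated against
    the same scheme and surrogate and applied simultaneously at round end:
    gene i is removed iff mean(Z0) > mean(Zi) strictly (ties keep the gene).
    """
    if len(genes) < 2:
        raise ValueError("filtering needs at least 2 genes")
    scheme = generate_inclusion_scheme(K, genes, seed)
    phi0 = evaluate_rows(dataset, scheme, cfg, counter)
    surrogate = fit_surrogate(scheme.bits, phi0, svr_params)
    if counter is not None:
        counter.regression += 1

    eliminated: list[int] = []
    survivors: list[int] = []
    for col, gene in enumerate(scheme.column_map):
        flipped = flip_column(scheme, col)
        phi1 = surrogate.predict(flipped.bits.astype(float))
        paired = pair_scores(scheme.bits, phi0, phi1, col, gene=gene)
        if paired.Z0.mean() > paired.Zi.mean():
            eliminated.append(gene)
        else:
            survivors.append(gene)
    if not survivors:
        raise AllGenesEliminatedError(
            "every gene was eliminated this round; stop filtering and keep "
            "the pre-round gene set"
        )
    return RoundRecord(
        round_index=round_index,
        K_used=K,
        phi0=phi0,
        eliminated=eliminated,
        survivors=survivors,
        mu_before=float("nan"),
        mu_after=float("nan"),
    )


def make_schedule(
    n_rounds: int,
    start: int = DEFAULT_K_START,
    step: int = DEFAULT_K_STEP,
    floor: int = DEFAULT_K_FLOOR,
) -> list[int]:
    """The decreasing K schedule: start, start-step, ... clipped at floor."""
    return [max(floor, start - step * r) for r in range(n_rounds)]


def _schedule_k(round_index: int, start: int, step: int, floor: int) -> int:
    return max(floor, start - step * (round_index - 1))


def run_filtering(
    dataset: ExpressionDataset,
    genes: GeneSubset | None = None,
    schedule: Sequence[int] | None = None,
    seed: int = 0,
    cfg: CVConfig | None = None,
    k_start: int = DEFAULT_K_START,
    k_step: int = DEFAULT_K_STEP,
    k_floor: int = DEFAULT_K_FLOOR,
    max_rounds: int = 30,
    survivor_floor: int = 2,
    stop_on_no_improvement: bool = True,
    checkpoint_reps: int = 5,
    svr_params: dict | None = None,
    counter: TrainingCounter | None = None,
) -> tuple[GeneSubset, list[RoundRecord]]:
    """Multi-round filtering with the decreasing-K schedule and MCC stopping.

    The initial checkpoint mu_0 is the cross-validated MCC on all input
    genes.  After each round the checkpoint is re-evaluated on the
    survivors; if it fails to improve the loop stops and the gene set that
    achieved the higher checkpoint (the pre-round set) is returned.  Guard
    stops: a round that eliminates nothing, survivors at or below
    ``survivor_floor``, or ``max_rounds``.

    Set ``stop_on_no_improvement=False`` to run the schedule to exhaustion
    regardless of checkpoint movement (useful for budget instrumentation).
    """
    cfg = cfg or CVConfig()
    genes = genes if genes is not None else GeneSubset.all_genes(dataset)
    genes.validate_against(dataset)
    if len(genes) < 2:
        raise ValueError("filtering needs at least 2 genes")
    if counter is None:
        counter = TrainingCounter()
    rng = np.random.default_rng(seed)

    def checkpoint_mu(subset: GeneSubset) -> float:
        seeds = [cfg.seed] + [cfg.seed + 9973 * (r + 1) for r in range(checkpoint_reps - 1)]
        return float(
            np.mean([cv_mcc(dataset, subset, cfg.with_seed(s)) for s in seeds])
        )

    current = genes
    mu_prev = checkpoint_mu(current)
    counter.classification += 1  # the initial full-set evaluation
    counter.checkpoint += max(0, checkpoint_reps - 1)
    records: list[RoundRecord] = []
    n_sched = len(schedule) if schedule is not None else max_rounds

    for r in range(1, n_sched + 1):
        if len(current) <= survivor_floor:
            break
        K = (
            int(schedule[r - 1])
            if schedule is not None
            else _schedule_k(r, k_start, k_step, k_floor)
        )
        round_seed = int(rng.integers(0, 2**31))
        try:
            record = filter_round(
                dataset,
                current,
                K,
                round_seed,
                cfg,
                counter=counter,
                svr_params=svr_params,
                round_index=r,
            )
        except AllGenesEliminatedError:
            logger.info("round %d eliminated all genes; reverting", r)
            break
        survivors = GeneSubset(record.survivors)
        mu_new = checkpoint_mu(survivors)
        counter.checkpoint += checkpoint_reps
        record.mu_before = mu_prev
        record.mu_after = mu_new
        records.append(record)
        logger.info(
            "round %d: K=%d, %d -> %d genes, mu %.4f -> %.4f",
            r, K, len(current), len(survivors), mu_prev, mu_new,
        )
        if stop_on_no_improvement and mu_new < mu_prev:
            # Performance with the reduced set is worse: keep the pre-round
            # set, which achieved the higher checkpoint.  A tie is not worse
            # — the smaller set matches the larger one's performance — so
            # filtering continues from the reduced set.
            return current, records
        if not record.eliminated:
            return survivors, records
        current = survivors
        mu_prev = mu_new
    return current, records


@dataclass(frozen=True)
class TrainingBudget:
    classification: int
    regression: int

    @property
    def total(self) -> int:
        return self.classification + self.regression


def count_trainings(schedule: Sequence[int]) -> TrainingBudget:
    """Model-training budget implied by a K schedule.

    One cross-validated classifier training per scheme row plus the single
    initial full-set evaluation; one regression (surrogate) training per
    round.  Round-end checkpoint evaluations are not counted.
    """
    schedule = list(schedule)
    if any(k % 2 != 0 for k in schedule):
        raise ValueError("schedule entries must be even")
    return TrainingBudget(
        classification=int(sum(schedule)) + 1, regression=len(schedule)
    )
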