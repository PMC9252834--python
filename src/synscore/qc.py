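"""Outlier detection and replacement for combination matrices and
single-agent dose-responses.

Combination cells are checked against a model-based prediction of the whole
response matrix: each cell's prediction is a leave-one-out low-rank
(rank-2) non-negative reconstruction of the shifted response matrix — the
cell is masked out, the factorization refitted (5 refits with fixed seeds,
averaged) and the cell predicted from the factors.  Single-agent axis
points are checked against a leave-one-out Hill refit of the remaining
axis points.  Measurements deviating by more than the threshold
(default 20 %inhibition, strict inequality) are flagged and may optionally
be replaced by their predictions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .blocks import CombinationBlock
from .doseresponse import fit_hill, predict_response
from .errors import ConsistencyError, InsufficientDataError

DEFAULT_THRESHOLD = 20.0  # %inhibition; flags require |deviation| > this
# numerical guard so a deviation of exactly the threshold (up to roundoff)
# is never flagged -- the cutoff is a strict inequality
THRESHOLD_EPS = 1e-9
N_REFITS = 5
NMF_RANK = 2
NMF_ITER = 400


@dataclass(frozen=True)
class OutlierFlag:
    """One flagged measurement."""

    index: tuple[int, ...]  # tensor index in the block
    observed: float
    predicted: float
    kind: str  # "combination" | "single_agent"

    @property
    def deviation(self) -> float:
        return self.observed - self.predicted


@dataclass
class OutlierReport:
    """All flags for one block at a given threshold."""

    block_id: str
    sample_id: Optional[str]
    threshold: float
    flags: list[OutlierFlag] = field(default_factory=list)
    shape: tuple[int, ...] = ()

    def __post_init__(self):
        for f in self.flags:
            assert abs(f.deviation) > self.threshold - 1e-6

    def as_records(self) -> list[dict]:
        return [
            {
                "block_id": self.block_id,
                "sample_id": self.sample_id,
                "index": list(f.index),
                "observed": f.observed,
                "predicted": f.predicted,
                "deviation": f.deviation,
                "kind": f.kind,
            }
            for f in self.flags
        ]


# ---------------------------------------------------------------------------
# masked non-negative factorization

def _masked_nmf_predict(
    A: np.ndarray, mask: np.ndarray, rank: int, seed: int, n_iter: int
) -> np.ndarray:
    """Weighted multiplicative-update NMF; entries with mask 0 are ignored.

    Returns the full reconstruction W @ H.
    """
    rng = np.random.default_rng(seed)
    m, n = A.shape
    scale = np.sqrt(max(A[mask > 0].mean(), 1e-6) / rank)
    W = scale * rng.uniform(0.5, 1.5, size=(m, rank))
    H = scale * rng.uniform(0.5, 1.5, size=(rank, n))
    Am = A * mask
    eps = 1e-9
    for _ in range(n_iter):
        WH = W @ H
        W *= (Am @ H.T) / ((mask * WH) @ H.T + eps)
        WH = W @ H
        H *= (W.T @ Am) / (W.T @ (mask * WH) + eps)
    return W @ H


def _loo_matrix_predictions(matrix: np.ndarray) -> np.ndarray:
    """Leave-one-out rank-2 NMF prediction for every cell of a 2-D matrix.

    The matrix is shifted by its minimum so all entries are non-negative;
    predictions are shifted back, which makes the whole procedure (and the
    deviations) invariant to adding a constant to every response.
    """
    shift = float(np.nanmin(matrix))
    A = matrix - shift
    pred = np.empty_like(A)
    base_mask = np.where(np.isnan(A), 0.0, 1.0)
    A = np.nan_to_num(A)
    for i, j in itertools.product(range(A.shape[0]), range(A.shape[1])):
        mask = base_mask.copy()
        mask[i, j] = 0.0
        vals = [
            _masked_nmf_predict(A, mask, NMF_RANK, seed, NMF_ITER)[i, j]
            for seed in range(N_REFITS)
        ]
        pred[i, j] = np.mean(vals)
    return pred + shift


def reconstruct_block(block: CombinationBlock) -> np.ndarray:
    """Model-based prediction of every response cell of the block.

    Two-drug blocks are reconstructed directly; for higher-order blocks
    each two-drug slice (other doses fixed) is reconstructed and cell
    predictions from overlapping slices are averaged.
    """
    if any(s < 3 for s in block.shape):
        raise InsufficientDataError(
            "outlier reconstruction needs a grid of at least 3x3 incl. axes"
        )
    if block.n_drugs == 2:
        return _loo_matrix_predictions(block.response)

    pred_sum = np.zeros(block.shape)
    pred_cnt = np.zeros(block.shape)
    axes = range(block.n_drugs)
    for a1, a2 in itertools.combinations(axes, 2):
        others = [a for a in axes if a not in (a1, a2)]
        for fixed in itertools.product(*(range(block.shape[a]) for a in others)):
            idx: list = [slice(None)] * block.n_drugs
            for a, v in zip(others, fixed):
                idx[a] = v
            sl = block.response[tuple(idx)]
            p = _loo_matrix_predictions(sl)
            pred_sum[tuple(idx)] += p
            pred_cnt[tuple(idx)] += 1.0
    return pred_sum / pred_cnt


def flag_combination_outliers(
    block: CombinationBlock,
    threshold: float = DEFAULT_THRESHOLD,
    predictions: np.ndarray | None = None,
) -> OutlierReport:
    """Flag all-positive-dose cells deviating > threshold (strict) from the
    low-rank reconstruction."""
    if predictions is None:
        predictions = reconstruct_block(block)
    flags = []
    for idx, _ in block.iter_interior_cells():
        obs = float(block.response[idx])
        pred = float(predictions[idx])
        if abs(obs - pred) > threshold + THRESHOLD_EPS:
            flags.append(OutlierFlag(idx, obs, pred, "combination"))
    return OutlierReport(
        block.block_id, block.sample_id, threshold, flags, block.shape
    )


def flag_single_agent_outliers(
    block: CombinationBlock,
    threshold: float = DEFAULT_THRESHOLD,
) -> OutlierReport:
    """Flag single-agent axis points deviating > threshold (strict) from a
    leave-one-out Hill refit of the remaining points on that axis.

    Axes with fewer than 4 dose points (including 0) are skipped with a
    warning — leaving one out would not leave enough points for a fit.
    """
    flags = []
    for axis, drug in enumerate(block.drugs):
        doses = block.dose_grid[axis]
        resp = block.single_agent_responses(axis)
        valid = ~np.isnan(resp)
        if valid.sum() < 4:
            warnings.warn(
                f"axis {drug!r}: fewer than 4 points, skipping single-agent "
                "outlier check",
                stacklevel=2,
            )
            continue
        # Greedy pass: among the leave-one-out refits, the candidate whose
        # exclusion leaves the best-fitting curve for the *remaining*
        # points is the prime suspect; it is flagged if its own deviation
        # from that curve exceeds the threshold, then dropped from all
        # further fits.  Ranking by raw deviation instead would let a
        # gross outlier contaminate the fits of its clean neighbours.
        active = valid.copy()
        while True:
            best: tuple | None = None
            for k in range(1, doses.size):  # never flag the control cell
                if not active[k]:
                    continue
                keep = active.copy()
                keep[k] = False
                if keep.sum() < 3 or np.unique(doses[keep]).size < 3:
                    continue
                curve = fit_hill(
                    doses[keep], resp[keep], drug=drug, warn_poor_fit=False
                )
                pred = float(predict_response(curve, doses[k]))
                if best is None or curve.fit_rss < best[0]:
                    best = (curve.fit_rss, k, pred)
            if best is None:
                break
            _, k, pred = best
            if abs(float(resp[k]) - pred) <= threshold + THRESHOLD_EPS:
                break
            active[k] = False
            flags.append(
                OutlierFlag(block.axis_index(axis, k), float(resp[k]), pred,
                            "single_agent")
            )
    return OutlierReport(
        block.block_id, block.sample_id, threshold, flags, block.shape
    )


def replace_outliers(
    block: CombinationBlock, report: OutlierReport
) -> CombinationBlock:
    """Return a new block with flagged cells set to their predicted values.

    The input block is left unmodified; replaced cell indices are recorded
    on the returned block.
    """
    if report.shape and report.shape != block.shape:
        raise ConsistencyError("report does not match block shape")
    new = block.copy()
    replaced = list(new.replaced_cells)
    for f in report.flags:
        if any(i >= s for i, s in zip(f.index, block.shape)):
            raise ConsistencyError(f"stale report: index {f.index} out of range")
        new.response[f.index] = f.predicted
        replaced.append(f.index)
    new.replaced_cells = tuple(replaced)
    return new


def apply_qc(
    block: CombinationBlock,
    threshold: float = DEFAULT_THRESHOLD,
    replace: bool = True,
) -> tuple[CombinationBlock, list[OutlierReport]]:
    """Full QC pass: single-agent outliers first (corrections propagate to
    the combination reconstruction), then combination outliers.

    With ``replace=False`` only the reports are produced and the original
    block is returned.
    """
    reports = []
    sa = flag_single_agent_outliers(block, threshold)
    reports.append(sa)
    working = replace_outliers(block, sa) if replace else block
    comb = flag_combination_outliers(working, threshold)
    reports.append(comb)
    if replace:
        working = replace_outliers(working, comb)
    return working, reports
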