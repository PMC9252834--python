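"""Batch scoring of many blocks across samples.

Runs the full per-block pipeline (curve fitting, optional outlier QC,
surfaces, summaries) over a list of blocks, organises the chosen summary
score into a combination x sample table, and exports plot-ready heatmap
(wide + long), per-sample waterfall and cross-sample consistency tables.
Failures of individual blocks become explicit missing cells with recorded
diagnostics; they never abort the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blocks import CombinationBlock
from .doseresponse import fit_block_curves
from .errors import BatchError, DataError, SynscoreError
from .models import summarize_surface, synergy_surface
from .postanalysis import weighted_surface
from .qc import apply_qc

SCORE_TYPES = ("mean", "msa", "weighted")
MISSING_SAMPLE = "(unlabelled)"


@dataclass
class MultiSampleResult:
    """Combination x sample table of one summary synergy score."""

    model: str
    score_type: str
    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    diagnostics: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def combinations(self) -> list[str]:
        return sorted({c for c, _ in self.scores} | {c for c, _ in self.diagnostics})

    @property
    def samples(self) -> list[str]:
        return sorted({s for _, s in self.scores} | {s for _, s in self.diagnostics})

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for combo in self.combinations:
            for sample in self.samples:
                key = (combo, sample)
                if key in self.scores:
                    rows.append(
                        {"combination": combo, "sample": sample,
                         "score": self.scores[key]}
                    )
                elif key in self.diagnostics:
                    rows.append(
                        {"combination": combo, "sample": sample,
                         "score": np.nan}
                    )
        return pd.DataFrame(rows, columns=["combination", "sample", "score"])


def _combo_name(block: CombinationBlock) -> str:
    return " + ".join(block.combination_key)


def score_block(
    block: CombinationBlock,
    model: str,
    score_type: str = "mean",
    qc: bool = False,
    qc_threshold: float = 20.0,
    msa_window: int = 3,
) -> float:
    """One block's summary score under one model (the batch unit)."""
    if score_type not in SCORE_TYPES:
        raise DataError(f"unknown score type {score_type!r}")
    working = block
    if qc:
        working, _ = apply_qc(block, threshold=qc_threshold, replace=True)
    curves = fit_block_curves(working, warn_poor_fit=False)
    surf = synergy_surface(working, model, curves)
    if score_type == "weighted":
        surf = weighted_surface(surf, curves, working)
    summary = summarize_surface(surf, msa_window=msa_window)
    if score_type == "mean":
        return summary.mean_delta
    if score_type == "msa":
        return summary.msa_delta
    return summary.weighted_mean_delta


def score_samples(
    blocks: Sequence[CombinationBlock],
    model: str = "consensus",
    score_type: str = "mean",
    qc: bool = False,
    qc_threshold: float = 20.0,
    msa_window: int = 3,
) -> MultiSampleResult:
    """Score every block independently and tabulate by combination/sample.

    Blocks testing the same drug set (order-ignored) in the same sample are
    averaged with a warning.  A block that cannot be scored leaves an
    explicit missing cell with a diagnostic; if *no* block can be scored a
    :class:`BatchError` carrying all diagnostics is raised.
    """
    if len(blocks) == 0:
        raise BatchError("no blocks to score")
    cells: dict[tuple[str, str], list[float]] = {}
    diagnostics: dict[tuple[str, str], str] = {}
    for block in sorted(
        blocks, key=lambda b: (_combo_name(b), b.sample_id or "", b.block_id)
    ):
        key = (_combo_name(block), block.sample_id or MISSING_SAMPLE)
        try:
            score = score_block(
                block, model, score_type, qc=qc,
                qc_threshold=qc_threshold, msa_window=msa_window,
            )
        except SynscoreError as exc:
            diagnostics[key] = f"{type(exc).__name__}: {exc}"
            continue
        cells.setdefault(key, []).append(score)

    result = MultiSampleResult(model=model, score_type=score_type)
    for key, vals in cells.items():
        if len(vals) > 1:
            warnings.warn(
                f"{len(vals)} blocks for combination {key[0]!r} in sample "
                f"{key[1]!r}; averaging their scores",
                stacklevel=2,
            )
        result.scores[key] = float(np.mean(vals))
    result.diagnostics = {
        k: v for k, v in diagnostics.items() if k not in result.scores
    }
    if not result.scores:
        raise BatchError(
            "no block could be scored", diagnostics=result.diagnostics
        )
    return result


def export_heatmap(
    result: MultiSampleResult,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready heatmap tables: (wide, long).

    Wide rows are combinations sorted by cross-sample mean score
    descending (ties by name); columns are samples sorted by name.
    Missing (combination, sample) pairs stay empty cells, never 0.
    """
    long = result.long_frame()
    if long.empty:
        raise DataError("empty multi-sample result")
    wide = long.pivot(index="combination", columns="sample", values="score")
    order = (
        wide.mean(axis=1, skipna=True)
        .to_frame("mean")
        .assign(name=lambda d: d.index)
        .sort_values(["mean", "name"], ascending=[False, True])
        .index
    )
    wide = wide.loc[order, sorted(wide.columns)]
    wide.index.name = "combination"
    return wide, long


def export_waterfall(result: MultiSampleResult, sample_id: str) -> pd.DataFrame:
    """Descending ranked list of combination scores for one sample."""
    if sample_id not in result.samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    rows = [
        {"combination": combo, "score": score}
        for (combo, sample), score in result.scores.items()
        if sample == sample_id
    ]
    df = pd.DataFrame(rows, columns=["combination", "score"])
    df = df.sort_values(
        ["score", "combination"], ascending=[False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def consistency_summary(result: MultiSampleResult) -> pd.DataFrame:
    """Per-combination cross-sample statistics of the chosen score.

    sd is reported as missing for combinations observed in < 2 samples.
    """
    rows = []
    for combo in result.combinations:
        vals = np.array(
            [
                score
                for (c, _), score in result.scores.items()
                if c == combo
            ]
        )
        if vals.size == 0:
            continue
        rows.append(
            {
                "combination": combo,
                "n_samples": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size >= 2 else np.nan,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "fraction_positive": float((vals > 0).mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["combination", "n_samples", "mean", "sd", "min", "max",
                 "fraction_positive"],
    )
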