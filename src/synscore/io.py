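"""Reading combination-screen tables and writing result tables.

Two long-format input dialects are supported (comma-, tab- or
semicolon-delimited text with a header row):

* ``pairwise`` — columns ``block_id, drug_row, drug_col, conc_r, conc_c,
  response`` (or ``count``), optional ``conc_r_unit, conc_c_unit, sample,
  replicate``.
* ``multi`` — columns ``block_id, drug1..drugN, conc1..concN,
  response``/``count``, optional ``sample, replicate``; N is auto-detected
  from the header.

One :class:`~synscore.blocks.CombinationBlock` is built per
(block_id, sample) pair; replicate rows at identical doses are averaged
into the working tensor (the replicate stack is retained).  Raw counts are
converted to % inhibition against plate controls before blocks are built.
"""

from __future__ import annotations

import csv
import io as _io
import json
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .blocks import CombinationBlock, WellRecord
from .errors import (
    ConflictError,
    DataError,
    DegenerateControlError,
    FormatError,
    MissingDataError,
    NormalizationError,
)

DIALECTS = ("pairwise", "multi")


def _sniff_sep(text: str) -> str:
    header = text.splitlines()[0] if text else ""
    counts = {sep: header.count(sep) for sep in (",", "\t", ";")}
    sep = max(counts, key=counts.get)
    if counts[sep] == 0:
        raise FormatError("could not detect a delimiter (comma/tab/semicolon)")
    return sep


def _read_frame(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    sep = _sniff_sep(text)
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _records_pairwise(df: pd.DataFrame) -> list[WellRecord]:
    required = ["block_id", "drug_row", "drug_col", "conc_r", "conc_c"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    value_col = "response" if "response" in df.columns else (
        "count" if "count" in df.columns else None)
    if value_col is None:
        raise FormatError("missing required column 'response' (or 'count')")
    records = []
    for _, row in df.iterrows():
        kwargs = dict(
            block_id=str(row["block_id"]),
            drug_names=(str(row["drug_row"]), str(row["drug_col"])),
            concentrations=(float(row["conc_r"]), float(row["conc_c"])),
            sample_id=str(row["sample"]) if "sample" in df.columns
            and pd.notna(row.get("sample")) else None,
            replicate=int(row["replicate"]) if "replicate" in df.columns
            and pd.notna(row.get("replicate")) else None,
            conc_units=(
                str(row.get("conc_r_unit", "")) if "conc_r_unit" in df.columns else "",
                str(row.get("conc_c_unit", "")) if "conc_c_unit" in df.columns else "",
            ),
        )
        if value_col == "response":
            kwargs["response"] = float(row[value_col])
        else:
            kwargs["raw_count"] = float(row[value_col])
        records.append(WellRecord(**kwargs))
    return records


def _records_multi(df: pd.DataFrame) -> list[WellRecord]:
    if "block_id" not in df.columns:
        raise FormatError("missing required column 'block_id'")
    drug_cols, conc_cols = [], []
    n = 1
    while f"drug{n}" in df.columns:
        if f"conc{n}" not in df.columns:
            raise FormatError(f"missing required column 'conc{n}'")
        drug_cols.append(f"drug{n}")
        conc_cols.append(f"conc{n}")
        n += 1
    if len(drug_cols) < 2:
        raise FormatError("multi dialect needs columns drug1, drug2, ...")
    value_col = "response" if "response" in df.columns else (
        "count" if "count" in df.columns else None)
    if value_col is None:
        raise FormatError("missing required column 'response' (or 'count')")
    records = []
    for _, row in df.iterrows():
        kwargs = dict(
            block_id=str(row["block_id"]),
            drug_names=tuple(str(row[c]) for c in drug_cols),
            concentrations=tuple(float(row[c]) for c in conc_cols),
            sample_id=str(row["sample"]) if "sample" in df.columns
            and pd.notna(row.get("sample")) else None,
            replicate=int(row["replicate"]) if "replicate" in df.columns
            and pd.notna(row.get("replicate")) else None,
        )
        if value_col == "response":
            kwargs["response"] = float(row[value_col])
        else:
            kwargs["raw_count"] = float(row[value_col])
        records.append(WellRecord(**kwargs))
    return records


def normalize_counts(
    records: Sequence[WellRecord],
    positive_is_low: bool = True,
    positive_control_block: Optional[dict] = None,
) -> list[WellRecord]:
    """Convert raw counts to % inhibition against per-block controls.

    In the default orientation the count is a surviving-signal readout
    (inhibition rises as counts fall):

        response = 100 * (1 - count / mean(negative controls))

    or, when positive-control counts are supplied per block
    (``positive_control_block``: block_id -> mean positive count),

        response = 100 * (mean(neg) - count) / (mean(neg) - mean(pos)).

    With ``positive_is_low=False`` the count rises with inhibition
    (e.g. number of cells killed); this orientation needs positive
    controls to define the 100 % level:

        response = 100 * (count - mean(neg)) / (mean(pos) - mean(neg)).

    Negative controls are the wells with all concentrations 0.
    """
    by_block: dict[str, list[WellRecord]] = defaultdict(list)
    for r in records:
        if r.raw_count is None:
            raise DataError("normalize_counts expects raw_count records")
        by_block[r.block_id].append(r)

    out = []
    for block_id, recs in by_block.items():
        neg = [r.raw_count for r in recs
               if all(c == 0 for c in r.concentrations)]
        if not neg:
            raise NormalizationError(
                f"block {block_id!r} has no negative-control well "
                "(all concentrations 0)"
            )
        neg_mean = float(np.mean(neg))
        pos_mean = None
        if positive_control_block and block_id in positive_control_block:
            pos_mean = float(positive_control_block[block_id])
            if abs(neg_mean - pos_mean) < 1e-12:
                raise DegenerateControlError(
                    f"block {block_id!r}: positive and negative control "
                    "means coincide"
                )
        if not positive_is_low and pos_mean is None:
            raise NormalizationError(
                "killed-signal orientation requires positive controls to "
                "define the 100% inhibition level"
            )
        for r in recs:
            if positive_is_low:
                if pos_mean is None:
                    if neg_mean == 0:
                        raise DegenerateControlError(
                            f"block {block_id!r}: negative-control mean is 0"
                        )
                    resp = 100.0 * (1.0 - r.raw_count / neg_mean)
                else:
                    resp = 100.0 * (neg_mean - r.raw_count) / (neg_mean - pos_mean)
            else:
                resp = 100.0 * (r.raw_count - neg_mean) / (pos_mean - neg_mean)
            out.append(
                WellRecord(
                    block_id=r.block_id,
                    drug_names=r.drug_names,
                    concentrations=r.concentrations,
                    response=resp,
                    sample_id=r.sample_id,
                    replicate=r.replicate,
                    conc_units=r.conc_units,
                )
            )
    return out


def blocks_from_records(
    records: Sequence[WellRecord],
    min_positive_doses: int = 2,
) -> list[CombinationBlock]:
    """Assemble full-grid CombinationBlocks from long-format records."""
    groups: dict[tuple, list[WellRecord]] = defaultdict(list)
    for r in records:
        if r.response is None:
            raise DataError(
                "records still carry raw counts; run normalize_counts first"
            )
        groups[(r.block_id, r.sample_id)].append(r)

    blocks = []
    for (block_id, sample_id), recs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
    ):
        drugs = recs[0].drug_names
        for r in recs:
            if r.drug_names != drugs:
                raise ConflictError(
                    f"block {block_id!r}: inconsistent drug names across rows"
                )
        n = len(drugs)
        dose_sets: list[set] = [set() for _ in range(n)]
        for r in recs:
            for k, c in enumerate(r.concentrations):
                dose_sets[k].add(c)
        dose_grid = []
        for k, s in enumerate(dose_sets):
            doses = np.array(sorted(s | {0.0}))
            dose_grid.append(doses)
        shape = tuple(len(d) for d in dose_grid)
        lookup = [
            {c: i for i, c in enumerate(d)} for d in dose_grid
        ]

        seen: dict[tuple, set] = defaultdict(set)
        per_cell: dict[tuple, list[float]] = defaultdict(list)
        for r in recs:
            idx = tuple(lookup[k][c] for k, c in enumerate(r.concentrations))
            rep = r.replicate
            if rep in seen[idx]:
                raise ConflictError(
                    f"block {block_id!r}: duplicate row for doses "
                    f"{r.concentrations} replicate {rep}"
                )
            seen[idx].add(rep)
            per_cell[idx].append(r.response)

        tensor = np.full(shape, np.nan)
        max_rep = max(len(v) for v in per_cell.values())
        rep_stack = np.full((max_rep,) + shape, np.nan) if max_rep > 1 else None
        for idx, vals in per_cell.items():
            tensor[idx] = float(np.mean(vals))
            if rep_stack is not None:
                for i, v in enumerate(vals):
                    rep_stack[(i,) + idx] = v
        ctrl = tuple(0 for _ in range(n))
        if np.isnan(tensor[ctrl]):
            tensor[ctrl] = 0.0  # control is defined 0 %inh

        interior = tuple(slice(1, None) for _ in range(n))
        if np.any(np.isnan(tensor[interior])):
            missing = [
                tuple(float(dose_grid[k][i + 1]) for k, i in enumerate(idx))
                for idx in zip(*np.nonzero(np.isnan(tensor[interior])))
            ]
            raise MissingDataError(
                f"block {block_id!r}: combination cells without a response "
                f"at doses {missing[:10]}"
            )
        # missing single-agent cells are tolerated if enough points remain
        for k, drug in enumerate(drugs):
            ax = [0] * n
            ax[k] = slice(1, None)
            vals = tensor[tuple(ax)]
            if np.sum(~np.isnan(vals)) < min_positive_doses:
                raise MissingDataError(
                    f"block {block_id!r}: drug {drug!r} has fewer than "
                    f"{min_positive_doses} measured non-zero doses"
                )
        blocks.append(
            CombinationBlock(
                block_id=block_id,
                drugs=drugs,
                dose_grid=tuple(dose_grid),
                response=tensor,
                sample_id=sample_id,
                replicate_tensor=rep_stack,
                dose_units=recs[0].conc_units or (),
            )
        )
    return blocks


def read_long_table(
    source,
    dialect: str = "pairwise",
    counts: bool = False,
    positive_is_low: bool = True,
    positive_control_block: Optional[dict] = None,
) -> list[CombinationBlock]:
    """Read a delimited long-format table into CombinationBlocks.

    ``source`` is a path or an open text handle.  With ``counts=True`` the
    value column holds raw counts which are normalized to % inhibition
    first (see :func:`normalize_counts`).
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; use one of {DIALECTS}")
    df = _read_frame(source)
    records = (_records_pairwise if dialect == "pairwise" else _records_multi)(df)
    if counts or records and records[0].raw_count is not None:
        records = normalize_counts(
            records,
            positive_is_low=positive_is_low,
            positive_control_block=positive_control_block,
        )
    return blocks_from_records(records)


def block_to_table(block: CombinationBlock) -> pd.DataFrame:
    """Long-format table of a block (pairwise or multi dialect columns)."""
    rows = []
    n = block.n_drugs
    for idx in np.ndindex(*block.shape):
        val = block.response[idx]
        if np.isnan(val):
            continue
        row: dict = {"block_id": block.block_id}
        if n == 2:
            row.update(
                drug_row=block.drugs[0],
                drug_col=block.drugs[1],
                conc_r=block.dose_grid[0][idx[0]],
                conc_c=block.dose_grid[1][idx[1]],
            )
        else:
            for k in range(n):
                row[f"drug{k + 1}"] = block.drugs[k]
                row[f"conc{k + 1}"] = block.dose_grid[k][idx[k]]
        row["response"] = val
        if block.sample_id is not None:
            row["sample"] = block.sample_id
        rows.append(row)
    return pd.DataFrame(rows)


def write_block(block: CombinationBlock, path) -> None:
    block_to_table(block).to_csv(path, index=False)


def surface_to_table(surface) -> pd.DataFrame:
    """Long-format export of a synergy surface: one row per dose combo."""
    rows = []
    for idx in np.ndindex(*surface.delta.shape):
        row = {"block_id": surface.block_id, "sample_id": surface.sample_id,
               "model": surface.model}
        for k, drug in enumerate(surface.drugs):
            row[f"conc_{k + 1}"] = surface.doses[k][idx[k]]
            row[f"drug_{k + 1}"] = drug
        row["observed"] = surface.observed[idx]
        row["expected"] = surface.expected[idx]
        row["delta"] = surface.delta[idx]
        row["weight"] = (
            surface.weight[idx] if surface.weight is not None else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results, path, format: str = "csv") -> None:
    """Write a result table (DataFrame or list of dicts) to CSV or JSON.

    Column order is preserved as given; JSON files are records-oriented
    and round-trip numeric values exactly (within 1e-9).
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        path.write_text(
            json.dumps(df.to_dict(orient="records"), indent=1, default=str)
        )
    else:
        raise DataError(f"unknown output format {format!r}")
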