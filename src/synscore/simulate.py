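"""Synthetic combination-screen blocks with known ground truth.

Single agents follow four-parameter log-logistic curves; combination cells
are generated from a chosen no-interaction null (Bliss, Loewe, HSA or a
MuSyC surface with chosen interaction parameters), plus an optional
injected synergy delta on the interior cells, Gaussian read noise, and
optional injected outlier shifts.  Every noiseless intermediate is kept in
the returned ground-truth record so recovery tests can compare against
exact values.  The seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .blocks import CombinationBlock
from .doseresponse import DoseResponseCurve, hill
from .errors import DataError
from .models import expected_bliss, expected_hsa, expected_loewe


@dataclass(frozen=True)
class DrugSpec:
    """Ground-truth single-agent curve for simulation."""

    name: str
    l: float = 0.0
    u: float = 100.0
    ec50: float = 1.0
    h: float = 1.0

    def curve(self) -> DoseResponseCurve:
        return DoseResponseCurve(self.name, self.l, self.u, self.ec50, self.h)


@dataclass
class SimulationSpec:
    """Everything needed to generate one block deterministically."""

    drugs: tuple[DrugSpec, ...]
    dose_grids: tuple[tuple[float, ...], ...]
    null_model: str = "bliss"
    injected_delta: float | np.ndarray = 0.0
    musyc_params: Optional[tuple[float, float, float]] = None  # a12, a21, beta
    noise_sd: float = 0.0
    outliers: tuple[tuple[tuple[int, ...], float], ...] = ()
    seed: int = 0
    block_id: str = "sim"
    sample_id: Optional[str] = None

    def __post_init__(self):
        self.drugs = tuple(self.drugs)
        self.dose_grids = tuple(tuple(float(x) for x in g)
                                for g in self.dose_grids)
        if len(self.drugs) != len(self.dose_grids):
            raise DataError("one dose grid per drug")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if self.null_model == "musyc" and self.musyc_params is None:
            raise DataError("musyc null requires musyc_params")
        if self.null_model == "musyc" and len(self.drugs) != 2:
            raise DataError("musyc null is 2-drug only")
        for g in self.dose_grids:
            if g[0] != 0.0 or any(b <= a for a, b in zip(g, g[1:])):
                raise DataError("dose grids must start at 0, strictly increasing")


def _null_tensor(spec: SimulationSpec, singles: list[np.ndarray]) -> np.ndarray:
    """Noiseless response tensor under the chosen null (all cells)."""
    shape = tuple(len(g) for g in spec.dose_grids)
    out = np.zeros(shape)
    curves = [d.curve() for d in spec.drugs]
    if spec.null_model == "musyc":
        from .postanalysis import musyc_response

        a12, a21, beta = spec.musyc_params
        d1, d2 = (np.asarray(g) for g in spec.dose_grids)
        D1, D2 = np.meshgrid(d1, d2, indexing="ij")
        E1 = spec.drugs[0].u / 100.0
        E2 = spec.drugs[1].u / 100.0
        out = 100.0 * musyc_response(
            D1, D2,
            E0=0.0, E1=E1, E2=E2, E3=max(E1, E2) + beta,
            C1=spec.drugs[0].ec50, C2=spec.drugs[1].ec50,
            h1=spec.drugs[0].h, h2=spec.drugs[1].h,
            alpha_12=a12, alpha_21=a21,
        )
        return out

    for idx in np.ndindex(*shape):
        doses = [spec.dose_grids[k][i] for k, i in enumerate(idx)]
        active = [k for k, d in enumerate(doses) if d > 0]
        if not active:
            out[idx] = 0.0
            continue
        ys = [singles[k][idx[k]] for k in active]
        if len(active) == 1:
            out[idx] = ys[0]
        elif spec.null_model == "bliss":
            out[idx] = expected_bliss(ys)
        elif spec.null_model == "hsa":
            out[idx] = expected_hsa(ys)
        elif spec.null_model == "loewe":
            out[idx] = expected_loewe(
                [curves[k] for k in active], [doses[k] for k in active]
            )
        else:
            raise DataError(f"unknown null model {spec.null_model!r}")
    return out


def simulate_block(spec: SimulationSpec) -> tuple[CombinationBlock, dict]:
    """Generate one block plus its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    singles = [
        hill(np.asarray(g), d.l, d.u, d.ec50, d.h)
        for d, g in zip(spec.drugs, spec.dose_grids)
    ]
    clean = _null_tensor(spec, singles)
    interior = tuple(slice(1, None) for _ in spec.drugs)
    with_delta = clean.copy()
    with_delta[interior] = with_delta[interior] + spec.injected_delta

    noisy = with_delta.copy()
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=clean.shape)
        noise[tuple(0 for _ in spec.drugs)] = 0.0  # control is defined 0
        noisy = noisy + noise
    for idx, shift in spec.outliers:
        noisy[tuple(idx)] += shift

    block = CombinationBlock(
        block_id=spec.block_id,
        drugs=tuple(d.name for d in spec.drugs),
        dose_grid=tuple(np.asarray(g) for g in spec.dose_grids),
        response=noisy,
        sample_id=spec.sample_id,
    )
    truth = {
        "curves": {d.name: d.curve() for d in spec.drugs},
        "singles": singles,
        "null_tensor": clean,
        "noiseless_tensor": with_delta,
        "injected_delta": spec.injected_delta,
        "outliers": spec.outliers,
    }
    return block, truth


def simulate_multisample(
    spec: SimulationSpec,
    n_samples: int,
    jitter: float = 0.0,
    sample_prefix: str = "S",
) -> list[CombinationBlock]:
    """Generate one block per sample with between-sample parameter jitter.

    Per sample, each drug's EC50 is scaled by exp(N(0, jitter)) and its
    upper asymptote shifted by N(0, 10 * jitter) %inh; jitter 0 gives
    identical samples.  Sample seeds derive deterministically from the
    master seed.
    """
    if n_samples < 1:
        raise DataError("n_samples must be >= 1")
    master = np.random.default_rng(spec.seed)
    blocks = []
    for s in range(n_samples):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        drugs = []
        for d in spec.drugs:
            ec50 = d.ec50 * float(np.exp(rng.normal(0.0, jitter)))
            u = d.u + float(rng.normal(0.0, 10.0 * jitter))
            u = max(u, d.l + 1.0)
            drugs.append(replace(d, ec50=ec50, u=u))
        sub = replace(
            spec,
            drugs=tuple(drugs),
            seed=sub_seed,
            block_id=spec.block_id,
            sample_id=f"{sample_prefix}{s + 1}",
        )
        blocks.append(simulate_block(sub)[0])
    return blocks
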