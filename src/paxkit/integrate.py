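"""Greedy weighted integration of multiple abundance datasets.

When several datasets quantify the same organism or tissue, a single
best-estimate dataset is built by iterative weighted averaging guided by
the interaction z-score: datasets are sorted by score, the best one seeds
the merge with weight 100%, and each subsequent dataset is folded in at
the weight (from an equally spaced grid over [0, 100%]) that maximizes the
interaction z-score of the merged candidate.  Because the grid contains
w = 0, a dataset that would only hurt the merge is effectively skipped and
the integrated score never falls below the best single dataset's score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .quality import DEFAULT_N_SHUFFLES, InteractionNetwork, interaction_zscore
from .quantify import PPM_TOTAL, AbundanceDataset, to_ppm

logger = logging.getLogger("paxkit")

DEFAULT_N_WEIGHTS = 11


@dataclass(frozen=True)
class IntegrationStep:
    """One greedy step: the weights tried for a dataset and the winner."""

    dataset_name: str
    tried_weights: tuple[float, ...]
    best_weight: float
    best_z: float


@dataclass
class IntegrationResult:
    integrated: AbundanceDataset
    component_weights: dict[str, float]
    trace: list[IntegrationStep] = field(default_factory=list)


def combine(a: AbundanceDataset, b: AbundanceDataset, w: float) -> AbundanceDataset:
    """Weighted average of two ppm datasets, ``w`` = weight of ``b``.

    Proteins quantified (ppm > 0) in both datasets are blended in log
    space — 10^((1-w)*log10(a) + w*log10(b)), a weighted geometric mean,
    since protein abundances are log-distributed.  Proteins quantified on
    one side only are carried over scaled by that side's weight mass
    ((1-w) or w), so a low-trust dataset contributes its unique proteins
    only faintly.  The result is renormalized to 1e6 ppm.  Boundary
    weights return an exact copy of the corresponding input.
    """
    if not 0 <= w <= 1:
        raise ValueError("weight must be in [0, 1]")
    if w == 0:
        return AbundanceDataset(dict(a.abundances), organism=a.organism,
                                tissue=a.tissue, method=a.method, name=a.name)
    if w == 1:
        return AbundanceDataset(dict(b.abundances), organism=b.organism,
                                tissue=b.tissue, method=b.method, name=b.name)
    raw: dict[str, float] = {}
    for pid in a.abundances.keys() | b.abundances.keys():
        va = a.abundances.get(pid, 0.0)
        vb = b.abundances.get(pid, 0.0)
        if va > 0 and vb > 0:
            raw[pid] = 10 ** ((1 - w) * math.log10(va) + w * math.log10(vb))
        elif va > 0:
            raw[pid] = (1 - w) * va
        elif vb > 0:
            raw[pid] = w * vb
        else:  # explicit zero on both sides stays an explicit zero
            raw[pid] = 0.0
    return to_ppm(
        raw,
        organism=a.organism,
        tissue=a.tissue,
        method=f"integrated ({a.method}+{b.method})" if a.method or b.method
        else "integrated",
    )


def integrate_datasets(
    datasets: Sequence[AbundanceDataset],
    net: InteractionNetwork,
    n_weights: int = DEFAULT_N_WEIGHTS,
    seed: int = 0,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
) -> IntegrationResult:
    """Greedy weighted integration of datasets ranked by interaction z-score.

    Datasets are scored, then sorted by z descending (ties by name); the
    best seeds the merge.  Each remaining dataset d is tried at every
    weight of the ``n_weights``-point grid over [0, 1]; the candidate
    combine(merged, d, w) with the highest z-score (same shuffle seed
    throughout, so candidates are compared like with like) becomes the new
    merged dataset.  Ties on z prefer the smaller weight — the established
    merge.  Deterministic given (datasets, network, seed).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if n_weights < 2:
        raise ValueError("need at least 2 grid points")
    named = []
    for i, ds in enumerate(datasets):
        named.append((ds.name or f"dataset{i}", ds))

    if len(named) == 1:
        name, ds = named[0]
        only = AbundanceDataset(dict(ds.abundances), organism=ds.organism,
                                tissue=ds.tissue, method=ds.method, name=ds.name)
        score = interaction_zscore(only, net, n_shuffles=n_shuffles, seed=seed)
        only.score = score.z
        return IntegrationResult(
            integrated=only,
            component_weights={name: 1.0},
            trace=[IntegrationStep(name, (1.0,), 1.0, score.z)],
        )

    scored = sorted(
        (
            (interaction_zscore(ds, net, n_shuffles=n_shuffles, seed=seed).z,
             name, ds)
            for name, ds in named
        ),
        key=lambda t: (-t[0], t[1]),
    )
    grid = tuple(np.linspace(0.0, 1.0, n_weights).tolist())

    best_z, best_name, merged = scored[0]
    logger.info("integrate: seeding with %s (z=%.3f)", best_name, best_z)
    weights = {best_name: 1.0}
    trace = [IntegrationStep(best_name, (1.0,), 1.0, best_z)]
    current_z = best_z
    for z0, name, ds in scored[1:]:
        best_w, best_cand, best_cand_z = None, None, None
        for w in grid:
            cand = combine(merged, ds, w)
            cz = interaction_zscore(cand, net, n_shuffles=n_shuffles, seed=seed).z
            if best_cand_z is None or cz > best_cand_z:
                best_w, best_cand, best_cand_z = w, cand, cz
        merged, current_z = best_cand, best_cand_z
        weights[name] = best_w
        trace.append(IntegrationStep(name, grid, best_w, best_cand_z))
        logger.info(
            "integrate: %s (solo z=%.3f) merged at w=%.2f -> z=%.3f",
            name, z0, best_w, best_cand_z,
        )

    merged = to_ppm(merged.abundances, organism=merged.organism,
                    tissue=merged.tissue, method="integrated",
                    name="integrated")
    merged.score = current_z
    return IntegrationResult(
        integrated=merged, component_weights=weights, trace=trace
    )
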