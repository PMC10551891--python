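"""Dataset quality scoring against a protein-interaction network.

Interacting proteins tend to be expressed at broadly similar abundances,
so a dataset's internal consistency can be scored without ground truth:
take the median absolute log abundance ratio over all interacting pairs
quantified in the dataset, then compare it with the same statistic after
shuffling the protein labels (500 permutations by default).  The z-score of
the observed median against that null — oriented so that
better-than-random consistency gives a large positive value — is the
"interaction z-score" used to rank and weight datasets.

Also provides the per-gene tissue-specificity z-score used for comparing
expression signatures across tissue panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .quantify import AbundanceDataset

logger = logging.getLogger("paxkit")

DEFAULT_N_SHUFFLES = 500


class InteractionNetwork:
    """Undirected, unweighted protein-interaction network.

    Edges are unordered unique pairs of internal ids; self-loops are
    rejected.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._edges: set[tuple[str, str]] = set()
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        self._edges.add((a, b) if a < b else (b, a))

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a < b else (b, a)) in self._edges


def read_network(path) -> InteractionNetwork:
    """Read a two-column TSV edge list (no header required)."""
    net = InteractionNetwork()
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "protein_a":  # optional header
                continue
            net.add_edge(fields[0], fields[1])
    return net


def write_network(net: InteractionNetwork, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class ConsistencyScore:
    """Result of one interaction z-score computation."""

    z: float
    observed_median: float
    null_medians: tuple[float, ...]
    n_pairs_used: int
    seed: int


def interaction_zscore(
    ds: AbundanceDataset | Mapping[str, float],
    net: InteractionNetwork,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    log_base: float = 10.0,
) -> ConsistencyScore:
    """Interaction z-score of a dataset against a reference network.

    observed = median over quantified edges of |log(ppm_a / ppm_b)|; the
    null repeats this ``n_shuffles`` times with abundance values permuted
    across the quantified proteins (network fixed);
    z = (mean(null) - observed) / sd(null), so a dataset whose interacting
    pairs are more similar than random scores large and positive.

    Zero-ppm proteins are excluded (log undefined).  The result is
    bit-reproducible given (dataset, network, seed) and invariant to
    rescaling all abundances and to the log base.

    Raises
    ------
    ValueError
        If fewer than 2 proteins are quantified, no network edge has both
        endpoints quantified, or the null is degenerate (sd = 0).
    """
    abundances = ds.abundances if isinstance(ds, AbundanceDataset) else ds
    ids = sorted(pid for pid, v in abundances.items() if v > 0)
    if len(ids) < 2:
        raise ValueError("need at least 2 proteins with positive abundance")
    index = {pid: i for i, pid in enumerate(ids)}
    logs = np.array(
        [math.log(abundances[pid], log_base) for pid in ids], dtype=float
    )
    edge_idx = [
        (index[a], index[b])
        for a, b in sorted(net.edges)
        if a in index and b in index
    ]
    if not edge_idx:
        raise ValueError("network does not overlap dataset")
    ia = np.array([e[0] for e in edge_idx])
    ib = np.array([e[1] for e in edge_idx])

    observed = float(np.median(np.abs(logs[ia] - logs[ib])))
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = logs[rng.permutation(len(ids))]
        null[s] = np.median(np.abs(shuffled[ia] - shuffled[ib]))
    sd = float(np.std(null, ddof=1))
    if sd == 0:
        raise ValueError("degenerate null (sd of shuffled medians is zero)")
    z = (float(np.mean(null)) - observed) / sd
    logger.info(
        "interaction_zscore: z=%.3f over %d edges (%d quantified proteins, "
        "%d shuffles, seed %d)", z, len(edge_idx), len(ids), n_shuffles, seed,
    )
    return ConsistencyScore(
        z=z,
        observed_median=observed,
        null_medians=tuple(null.tolist()),
        n_pairs_used=len(edge_idx),
        seed=seed,
    )


def tissue_specificity_zscore(
    matrix: pd.DataFrame, pseudocount: float = 1.0, sd_floor: float = 1e-12
) -> pd.DataFrame:
    """Per-gene tissue-specificity z-scores from a gene x tissue ppm table.

    Each row is standardized on log10(ppm + pseudocount):
    z_t = (x_t - mean_t(x)) / sd_t(x), with the sample (n-1) standard
    deviation.  Genes constant across tissues get a row of zeros (flagged
    in the log) rather than NaNs.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    x = np.log10(matrix.to_numpy(float) + pseudocount)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] < sd_floor
    if flat.any():
        logger.warning(
            "tissue_specificity_zscore: %d gene(s) constant across tissues; "
            "z set to 0", int(flat.sum()),
        )
    sd = np.where(sd < sd_floor, 1.0, sd)
    z = (x - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
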