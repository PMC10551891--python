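"""Normalized ppm protein-abundance quantification.

Two routes from raw quantification tables to a normalized abundance
dataset:

* **protein-centric** (iBAQ-style): a protein's relative abundance is its
  summed precursor-peptide intensity divided by the number of tryptic
  peptides theoretically observable from its sequence;
* **peptide-centric** (length-normalized): the sum of each constituent
  peptide's quantity (peak intensity or spectral count) times its length,
  divided by the total length of the theoretically observable peptides.

Raw relative abundances are then rescaled so the quantified proteome sums
to one million: "parts per million" of the protein molecules in the sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .digest import DEFAULT_WINDOW, observable_stats
from .proteome_io import ProteinGroupRow, ProteinRecord

logger = logging.getLogger("paxkit")

PPM_TOTAL = 1_000_000.0

#: Default peptide-level false discovery rate cutoff.
DEFAULT_FDR_THRESHOLD = 0.01

_EXCLUDED_PREFIXES = ("CON_", "REV_")


@dataclass(frozen=True)
class PeptideMeasurement:
    """One quantified peptide: intensity or spectral count, optional FDR."""

    protein_id: str
    peptide: str
    quantity: float
    fdr_score: float | None = None

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"{self.protein_id}/{self.peptide}: negative quantity")


@dataclass
class AbundanceDataset:
    """Protein -> ppm abundance map with dataset metadata.

    ``abundances`` sums to 1e6 over all entries (zero-ppm proteins are kept
    as explicit zeros: quantified-but-undetected, distinct from absent).
    """

    abundances: dict[str, float]
    organism: int | None = None
    tissue: str = "WHOLE_ORGANISM"
    method: str = ""
    score: float | None = None
    coverage: float | None = None
    name: str = ""

    def metadata(self) -> dict:
        return {
            "name": self.name,
            "organism": self.organism,
            "tissue": self.tissue,
            "method": self.method,
            "score": self.score,
            "coverage": self.coverage,
            "n_proteins": len(self.abundances),
        }


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_protein_groups(rows: Sequence[ProteinGroupRow]) -> list[ProteinGroupRow]:
    """Drop contaminant (CON_) and reversed-decoy (REV_) protein groups.

    A row is removed when its group id or any member id carries either
    prefix; row order is preserved.  Idempotent.
    """
    kept = [
        r for r in rows
        if not r.group_id.startswith(_EXCLUDED_PREFIXES)
        and not any(m.startswith(_EXCLUDED_PREFIXES) for m in r.member_ids)
    ]
    if len(kept) < len(rows):
        logger.info(
            "filter_protein_groups: removed %d of %d rows (CON_/REV_)",
            len(rows) - len(kept), len(rows),
        )
    return kept


def filter_peptides_fdr(
    peps: Sequence[PeptideMeasurement],
    threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[PeptideMeasurement]:
    """Keep peptides at or below the FDR score threshold.

    Peptides without an FDR score are kept (assumed pre-filtered upstream).
    """
    if not 0 < threshold <= 1:
        raise ValueError("FDR threshold must be in (0, 1]")
    kept = [p for p in peps if p.fdr_score is None or p.fdr_score <= threshold]
    if len(kept) < len(peps):
        logger.info(
            "filter_peptides_fdr: removed %d of %d peptides at FDR > %g",
            len(peps) - len(kept), len(peps), threshold,
        )
    return kept


# ---------------------------------------------------------------------------
# Raw abundance
# ---------------------------------------------------------------------------

def protein_centric_abundance(
    groups: Sequence[ProteinGroupRow],
    proteome: Mapping[str, ProteinRecord],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> dict[str, float]:
    """iBAQ-style raw abundance from a filtered protein-group table.

    Each group resolves to its first member id found in the proteome (the
    majority-leader convention); its raw abundance is the group intensity
    divided by the protein's observable tryptic peptide count.  Groups with
    no mappable member, and proteins with zero observable peptides, are
    dropped with a logged count.  Intensities of groups resolving to the
    same protein are summed.
    """
    raw: dict[str, float] = {}
    n_unmapped = n_unobservable = 0
    for row in groups:
        leader = next((m for m in row.member_ids if m in proteome), None)
        if leader is None:
            n_unmapped += 1
            continue
        count, _ = observable_stats(proteome[leader].sequence, *window)
        if count == 0:
            n_unobservable += 1
            continue
        raw[leader] = raw.get(leader, 0.0) + row.intensity / count
    if n_unmapped or n_unobservable:
        logger.warning(
            "protein_centric_abundance: dropped %d unmappable groups and "
            "%d proteins with no observable peptides", n_unmapped, n_unobservable,
        )
    return raw


def peptide_centric_abundance(
    peps: Sequence[PeptideMeasurement],
    proteome: Mapping[str, ProteinRecord],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> dict[str, float]:
    """Length-normalized raw abundance from an FDR-filtered peptide table.

    raw[p] = sum_i(quantity_i * len(peptide_i)) / observable_length(p),
    where observable_length is the summed length of p's theoretically
    observable tryptic peptides.  Works identically for intensities and
    spectral counts.  Peptides of unknown proteins and proteins with zero
    observable length are dropped with a logged count.
    """
    sums: dict[str, float] = {}
    n_unknown = 0
    for p in peps:
        if p.protein_id not in proteome:
            n_unknown += 1
            continue
        sums[p.protein_id] = sums.get(p.protein_id, 0.0) + p.quantity * len(p.peptide)
    raw: dict[str, float] = {}
    n_unobservable = 0
    for pid, total in sums.items():
        _, length = observable_stats(proteome[pid].sequence, *window)
        if length == 0:
            n_unobservable += 1
            continue
        raw[pid] = total / length
    if n_unknown or n_unobservable:
        logger.warning(
            "peptide_centric_abundance: dropped %d peptides of unknown proteins "
            "and %d proteins with no observable length", n_unknown, n_unobservable,
        )
    return raw


# ---------------------------------------------------------------------------
# Normalization / coverage
# ---------------------------------------------------------------------------

def to_ppm(raw: Mapping[str, float], **metadata) -> AbundanceDataset:
    """Rescale raw abundances to parts per million (sum = 1e6).

    Zero raw values are kept as 0 ppm.  Raises on an all-zero input.
    Scale-invariant: multiplying every raw value by a positive constant
    leaves the result unchanged.
    """
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("no quantified proteins (all raw abundances zero)")
    abundances = {pid: PPM_TOTAL * v / total for pid, v in raw.items()}
    return AbundanceDataset(abundances=abundances, **metadata)


def coverage(
    ds: AbundanceDataset, proteome: Mapping[str, ProteinRecord] | Iterable[str]
) -> float:
    """Fraction of the proteome quantified by the dataset."""
    ids = set(proteome.keys()) if isinstance(proteome, Mapping) else set(proteome)
    if not ids:
        raise ValueError("empty proteome")
    return len(ids & ds.abundances.keys()) / len(ids)


# ---------------------------------------------------------------------------
# Dataset I/O: two-column TSV + JSON metadata sidecar
# ---------------------------------------------------------------------------

def write_dataset(ds: AbundanceDataset, path) -> None:
    """Write a dataset as ``internal_id<TAB>ppm`` plus a .meta.json sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("internal_id\tppm\n")
        for pid in sorted(ds.abundances):
            fh.write(f"{pid}\t{ds.abundances[pid]:.10g}\n")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(ds.metadata(), indent=2) + "\n")


def read_dataset(path) -> AbundanceDataset:
    """Read a two-column ppm TSV (and its sidecar metadata if present)."""
    path = Path(path)
    abundances: dict[str, float] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("internal_id"):
            raise ValueError(f"{path}: expected 'internal_id\\tppm' header")
        for line in fh:
            pid, value = line.rstrip("\n").split("\t")
            abundances[pid] = float(value)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        meta.pop("n_proteins", None)
    ds = AbundanceDataset(abundances=abundances, **meta)
    if not ds.name:
        ds.name = path.stem
    return ds
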