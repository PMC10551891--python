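"""Proteome I/O and identifier resolution.

Everything in the toolkit operates on one internal protein namespace,
``taxid.locus`` (STRING-style, e.g. ``9606.ENSP00000354587``).  This module
reads and writes FASTA proteomes in that namespace, resolves external
identifiers onto it through an alias table, and maps proteins across
proteome versions or closely related species by reciprocal best-hit
alignment with a minimum-identity requirement in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evo_usage import alignment_score, global_align, make_aligner

logger = logging.getLogger("paxkit")

#: Minimum identity (both directions) for a reciprocal best hit to count.
DEFAULT_RBH_MIN_IDENTITY = 0.90


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence under a stable internal ``taxid.locus`` id."""

    internal_id: str
    sequence: str
    taxid: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.internal_id}: empty sequence")
        if self.taxid <= 0:
            raise ValueError(f"{self.internal_id}: taxid must be positive")


def _taxid_of(internal_id: str) -> int:
    prefix = internal_id.split(".", 1)[0]
    try:
        taxid = int(prefix)
    except ValueError:
        raise ValueError(
            f"internal id {internal_id!r} does not start with a numeric "
            "taxid ('taxid.locus' expected)"
        ) from None
    if taxid <= 0:
        raise ValueError(f"internal id {internal_id!r}: taxid must be positive")
    return taxid


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA proteome into ProteinRecords.

    The header token before the first whitespace becomes the internal id;
    its numeric prefix (before the first dot) the taxid.  Sequences are
    uppercased.

    Raises
    ------
    ValueError
        On an empty file ("no records") or duplicate ids.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        internal_id = entry.id
        seen[internal_id] = seen.get(internal_id, 0) + 1
        records.append(
            ProteinRecord(internal_id, str(entry.seq).upper(), _taxid_of(internal_id))
        )
    if not records:
        raise ValueError(f"{path}: no records")
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path}: duplicate ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write ProteinRecords as FASTA (id-only headers)."""
    SeqIO.write(
        (
            SeqRecord(Seq(r.sequence), id=r.internal_id, description="")
            for r in records
        ),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Alias tables
# ---------------------------------------------------------------------------

class AliasTable:
    """External-id -> internal-id mapping across identifier namespaces.

    An (external_id, namespace) pair maps to at most one internal id;
    conflicting entries are rejected at construction.
    """

    def __init__(self, entries: Iterable[tuple[str, str, str]] = ()) -> None:
        # (external_id, namespace) -> internal_id
        self._by_key: dict[tuple[str, str], str] = {}
        # external_id -> set of internal ids across all namespaces
        self._by_external: dict[str, set[str]] = {}
        for external_id, namespace, internal_id in entries:
            self.add(external_id, namespace, internal_id)

    def add(self, external_id: str, namespace: str, internal_id: str) -> None:
        key = (external_id, namespace)
        existing = self._by_key.get(key)
        if existing is not None and existing != internal_id:
            raise ValueError(
                f"alias conflict: {key} maps to both {existing} and {internal_id}"
            )
        self._by_key[key] = internal_id
        self._by_external.setdefault(external_id, set()).add(internal_id)

    def lookup(self, external_id: str) -> set[str]:
        """Internal ids matching an external id in any namespace."""
        return set(self._by_external.get(external_id, ()))

    def __len__(self) -> int:
        return len(self._by_key)


def read_alias_table(path) -> AliasTable:
    """Read a TSV alias table with columns internal_id, alias, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AliasTable(
        (r.alias, r.source, r.internal_id) for r in df.itertuples()
    )


def map_identifiers(
    ids: Sequence[str], aliases: AliasTable
) -> tuple[dict[str, str], list[str]]:
    """Resolve external ids onto the internal namespace.

    Lookup is exact-string and case-sensitive across all namespaces.  An id
    resolving to exactly one internal id is mapped; ids with no alias, or
    ambiguous across namespaces, are returned as unmapped.  Every input id
    appears exactly once across the two outputs.
    """
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for external_id in ids:
        hits = aliases.lookup(external_id)
        if len(hits) == 1:
            mapped[external_id] = next(iter(hits))
        else:
            if len(hits) > 1:
                logger.debug(
                    "id %s ambiguous across namespaces (%d internal ids)",
                    external_id, len(hits),
                )
            unmapped.append(external_id)
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Reciprocal best hit
# ---------------------------------------------------------------------------

def reciprocal_best_hit(
    set_a: Sequence[ProteinRecord],
    set_b: Sequence[ProteinRecord],
    min_identity: float = DEFAULT_RBH_MIN_IDENTITY,
) -> dict[str, str]:
    """One-to-one protein mapping by reciprocal best global-alignment hit.

    A pair (a, b) is reported iff b is a's unique best-scoring global
    alignment within ``set_b``, a is b's unique best within ``set_a``, and
    the pair's percent identity (identical columns / alignment length) is
    at least ``min_identity``.  A tied best hit on either side disqualifies
    the protein — no one-to-one claim is made on ambiguous evidence.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if not set_a or not set_b:
        return {}
    aligner = make_aligner()
    # Score matrix once; the scoring model is symmetric so one alignment
    # per pair covers both orientations.
    scores: dict[tuple[str, str], float] = {}
    for a in set_a:
        for b in set_b:
            scores[(a.internal_id, b.internal_id)] = alignment_score(
                a.sequence, b.sequence, aligner=aligner
            )

    def unique_best(query_id: str, candidates: Sequence[ProteinRecord],
                    orient_a: bool) -> str | None:
        best_id, best_score, tied = None, None, False
        for c in candidates:
            key = (query_id, c.internal_id) if orient_a else (c.internal_id, query_id)
            s = scores[key]
            if best_score is None or s > best_score:
                best_id, best_score, tied = c.internal_id, s, False
            elif s == best_score:
                tied = True
        return None if tied else best_id

    seq_a = {r.internal_id: r.sequence for r in set_a}
    seq_b = {r.internal_id: r.sequence for r in set_b}
    best_ab = {a.internal_id: unique_best(a.internal_id, set_b, True) for a in set_a}
    best_ba = {b.internal_id: unique_best(b.internal_id, set_a, False) for b in set_b}

    mapping: dict[str, str] = {}
    for a_id, b_id in best_ab.items():
        if b_id is None or best_ba.get(b_id) != a_id:
            continue
        _, _, _, identity = global_align(seq_a[a_id], seq_b[b_id], aligner=aligner)
        if identity >= min_identity:
            mapping[a_id] = b_id
    logger.info(
        "reciprocal_best_hit: %d/%d proteins mapped at >= %.0f%% identity",
        len(mapping), len(set_a), 100 * min_identity,
    )
    return mapping


# ---------------------------------------------------------------------------
# Quantification-table readers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinGroupRow:
    """One row of a protein-group quantification table."""

    group_id: str
    member_ids: tuple[str, ...]
    intensity: float

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"group {self.group_id!r}: no member ids")
        if self.intensity < 0:
            raise ValueError(f"group {self.group_id!r}: negative intensity")


def read_protein_groups(path) -> list[ProteinGroupRow]:
    """Read a MaxQuant-style proteinGroups TSV.

    Uses the "Majority protein IDs" column (semicolon-separated members)
    and the "Intensity" column; all other columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Majority protein IDs": str})
    for col in ("Majority protein IDs", "Intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    rows = []
    for raw, intensity in zip(df["Majority protein IDs"], df["Intensity"]):
        members = tuple(m for m in str(raw).split(";") if m)
        rows.append(
            ProteinGroupRow(
                group_id=str(raw), member_ids=members, intensity=float(intensity)
            )
        )
    return rows


def proteome_index(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index a proteome by internal id."""
    return {r.internal_id: r for r in records}
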