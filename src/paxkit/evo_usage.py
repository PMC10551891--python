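"""Ortholog-domain alignment and amino-acid usage-ratio analysis.

Comparative pipeline for tracking the evolution of amino-acid composition
(sulfur-containing residues in particular) between species:

1. take strict one-to-one ortholog pairs between a query species and a
   reference species;
2. within each pair, match same-named protein domains and globally align
   them (Needleman-Wunsch, BLOSUM62, affine gaps), keeping only the
   highest-scoring instance pair per domain type at >= 40% identity;
3. count the residues of interest (C, M, or both) on each side of the
   aligned domain sections and form the usage ratio query/reference;
4. rank-correlate the ratios against protein abundance of a designated
   abundance species, and summarise per-species results as a star-annotated
   correlation matrix.

A depletion of sulfur residues that intensifies with expression level shows
up as a negative Spearman rho between usage ratio and abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

logger = logging.getLogger("paxkit")

#: Residues accepted in input sequences: the 20 standard amino acids plus X.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Sulfur-containing amino acids.
SULFUR_AAS = frozenset("CM")

# Alignment defaults follow the EMBOSS needle/needleall convention:
# BLOSUM62, gap open 10, gap extend 0.5.
DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

#: Minimum percent identity for a domain alignment to be retained.
DEFAULT_MIN_IDENTITY = 0.40

#: Significance thresholds for heatmap stars, most stringent first.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (1e-5, "***"),
    (1e-3, "**"),
    (1e-2, "*"),
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain instance, 1-based inclusive coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid domain coordinates [{self.start}, {self.end}] "
                f"on {self.protein_id}"
            )

    def extract(self, sequence: str) -> str:
        if self.end > len(sequence):
            raise ValueError(
                f"domain {self.domain_name} [{self.start}, {self.end}] exceeds "
                f"length {len(sequence)} of {self.protein_id}"
            )
        return sequence[self.start - 1 : self.end]


@dataclass(frozen=True)
class OrthologPair:
    """An orthologous protein pair; only one-to-one pairs are analysed."""

    id_a: str
    id_b: str
    one_to_one: bool = True


@dataclass(frozen=True)
class AlignedDomainPair:
    """A matched domain pair with its global alignment."""

    pair: OrthologPair
    domain_name: str
    aligned_a: str
    aligned_b: str
    identity: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def make_aligner(
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    """Configured global pairwise aligner.

    Affine gap model: the first residue of a gap costs ``gap_open``, each
    further residue ``gap_extend``.  End gaps are penalized (strict global
    alignment).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"{label}: invalid residues {sorted(bad)} (allowed: 20 standard + X)"
        )


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[str, str, float, float]:
    """Optimal global alignment of two amino-acid sequences.

    Returns ``(aligned_a, aligned_b, score, identity)`` where identity is
    the fraction of identical columns over the full alignment length (gap
    columns count in the denominator, the EMBOSS convention).  When several
    alignments are co-optimal the first traceback is reported; its score is
    the unique optimum.
    """
    _check_sequence(seq_a, "seq_a")
    _check_sequence(seq_b, "seq_b")
    if aligner is None:
        aligner = make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    n_ident = sum(x == y for x, y in zip(aligned_a, aligned_b))
    identity = n_ident / len(aligned_a)
    return aligned_a, aligned_b, float(aln.score), identity


def alignment_score(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Optimal global alignment score only (no traceback; used for RBH)."""
    _check_sequence(seq_a, "seq_a")
    _check_sequence(seq_b, "seq_b")
    if aligner is None:
        aligner = make_aligner()
    return float(aligner.score(seq_a, seq_b))


# ---------------------------------------------------------------------------
# Domain matching
# ---------------------------------------------------------------------------

def match_domains(
    pair: OrthologPair,
    doms_a: Sequence[DomainAnnotation],
    doms_b: Sequence[DomainAnnotation],
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    aligner: Align.PairwiseAligner | None = None,
) -> list[AlignedDomainPair]:
    """Align same-named domains of an ortholog pair, best instance pair only.

    For every domain type annotated on both proteins, all cross-products of
    instances are aligned and only the single highest-scoring instance pair
    is kept; it is then dropped if its identity falls below ``min_identity``.
    Ties on score are broken by annotation order (first wins).

    ``proteome_a``/``proteome_b`` map protein id -> full sequence.
    """
    if not pair.one_to_one:
        raise ValueError(f"pair {pair.id_a}/{pair.id_b} is not one-to-one")
    if aligner is None:
        aligner = make_aligner()
    seq_a = proteome_a[pair.id_a]
    seq_b = proteome_b[pair.id_b]
    by_name_a: dict[str, list[DomainAnnotation]] = {}
    for d in doms_a:
        if d.protein_id == pair.id_a:
            by_name_a.setdefault(d.domain_name, []).append(d)
    by_name_b: dict[str, list[DomainAnnotation]] = {}
    for d in doms_b:
        if d.protein_id == pair.id_b:
            by_name_b.setdefault(d.domain_name, []).append(d)

    out: list[AlignedDomainPair] = []
    for name in sorted(set(by_name_a) & set(by_name_b)):
        best: AlignedDomainPair | None = None
        for da in by_name_a[name]:
            for db in by_name_b[name]:
                aa, ab, score, ident = global_align(
                    da.extract(seq_a), db.extract(seq_b), aligner=aligner
                )
                if best is None or score > best.score:
                    best = AlignedDomainPair(
                        pair=pair, domain_name=name,
                        aligned_a=aa, aligned_b=ab,
                        identity=ident, score=score,
                    )
        assert best is not None
        if best.identity >= min_identity:
            out.append(best)
        else:
            logger.debug(
                "domain %s of %s/%s dropped at identity %.3f < %.2f",
                name, pair.id_a, pair.id_b, best.identity, min_identity,
            )
    return out


# ---------------------------------------------------------------------------
# Usage ratios
# ---------------------------------------------------------------------------

#: Sentinel returned when a pair lacks the residue of interest on a side.
EXCLUDED = None


def usage_ratio(
    adp: AlignedDomainPair, aa_set: Iterable[str]
) -> tuple[int, int, float] | None:
    """Residue-usage ratio of one aligned domain pair.

    Counts residues of ``aa_set`` among the ungapped residues of each
    aligned string (gap columns contribute nothing).  Returns
    ``(count_a, count_b, count_a / count_b)``, or ``EXCLUDED`` (None) when
    either side has no residue of interest.
    """
    aas = frozenset(aa_set)
    count_a = sum(c in aas for c in adp.aligned_a if c != "-")
    count_b = sum(c in aas for c in adp.aligned_b if c != "-")
    if count_a == 0 or count_b == 0:
        return EXCLUDED
    return count_a, count_b, count_a / count_b


def usage_ratio_table(
    pairs: Iterable[OrthologPair],
    doms_a: Sequence[DomainAnnotation],
    doms_b: Sequence[DomainAnnotation],
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    abundances: Mapping[str, float],
    aa_set: Iterable[str] = SULFUR_AAS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    abundance_side: str = "a",
    aggregate: bool = False,
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """Build the usage-ratio table for a species pair.

    One row per qualifying aligned domain pair (or per ortholog pair with
    ``aggregate=True``, averaging the ratios of its domains), with columns
    ``id_a, id_b, domain, count_a, count_b, ratio, abundance_ppm``.
    Complex (non one-to-one) pairs, domain pairs below the identity filter,
    pairs lacking the residue of interest on either side, and pairs without
    an abundance value are excluded.

    ``abundances`` maps protein ids of the designated ``abundance_side``
    ("a" = query, "b" = reference) to ppm.
    """
    if abundance_side not in ("a", "b"):
        raise ValueError("abundance_side must be 'a' or 'b'")
    if aligner is None:
        aligner = make_aligner()
    aas = frozenset(aa_set)
    rows: list[dict] = []
    n_complex = n_no_aa = n_no_abundance = 0
    for pair in pairs:
        if not pair.one_to_one:
            n_complex += 1
            continue
        abund_id = pair.id_a if abundance_side == "a" else pair.id_b
        ppm = abundances.get(abund_id)
        if ppm is None or ppm <= 0:
            n_no_abundance += 1
            continue
        for adp in match_domains(
            pair, doms_a, doms_b, proteome_a, proteome_b,
            min_identity=min_identity, aligner=aligner,
        ):
            res = usage_ratio(adp, aas)
            if res is EXCLUDED:
                n_no_aa += 1
                continue
            count_a, count_b, ratio = res
            rows.append({
                "id_a": pair.id_a,
                "id_b": pair.id_b,
                "domain": adp.domain_name,
                "count_a": count_a,
                "count_b": count_b,
                "ratio": ratio,
                "abundance_ppm": ppm,
            })
    logger.info(
        "usage_ratio_table: %d rows (%d complex pairs skipped, %d domain pairs "
        "lacking residue of interest, %d pairs without abundance)",
        len(rows), n_complex, n_no_aa, n_no_abundance,
    )
    table = pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "domain", "count_a", "count_b",
                 "ratio", "abundance_ppm"],
    )
    if aggregate and not table.empty:
        table = (
            table.groupby(["id_a", "id_b"], as_index=False)
            .agg(
                domain=("domain", lambda s: ";".join(s)),
                count_a=("count_a", "sum"),
                count_b=("count_b", "sum"),
                ratio=("ratio", "mean"),
                abundance_ppm=("abundance_ppm", "first"),
            )
        )
    return table


def abundance_usage_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation between usage ratios and abundances.

    Average ranks for ties; two-sided p-value via the t approximation.

    Raises
    ------
    ValueError
        With fewer than 3 rows, or when either variable is constant
        (ranks degenerate, rho undefined).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    ratios = table["ratio"].to_numpy(float)
    abund = table["abundance_ppm"].to_numpy(float)
    if np.ptp(ratios) == 0 or np.ptp(abund) == 0:
        raise ValueError("degenerate ranks: constant ratios or abundances")
    rho, p = stats.spearmanr(ratios, abund)
    return float(rho), float(p)


def bin_for_plot(table: pd.DataFrame, n_bins: int = 6) -> pd.DataFrame:
    """Quantile-bin the table by abundance for violin-style summaries.

    Rows are sorted by abundance and split into ``n_bins`` near-equal groups
    (sizes differing by at most 1); returns per-bin median and quartiles of
    the usage ratio plus the bin's abundance range.
    """
    if len(table) < n_bins:
        raise ValueError(f"need at least {n_bins} rows for {n_bins} bins")
    ordered = table.sort_values(
        "abundance_ppm", kind="mergesort"
    ).reset_index(drop=True)
    rows = []
    for i, idx in enumerate(np.array_split(np.arange(len(ordered)), n_bins)):
        chunk = ordered.iloc[idx]
        r = chunk["ratio"].to_numpy(float)
        rows.append({
            "bin": i,
            "n": len(chunk),
            "abundance_min": float(chunk["abundance_ppm"].min()),
            "abundance_max": float(chunk["abundance_ppm"].max()),
            "ratio_median": float(np.median(r)),
            "ratio_p25": float(np.percentile(r, 25)),
            "ratio_p75": float(np.percentile(r, 75)),
        })
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star annotation for a p-value: *** < 1e-5, ** < 1e-3, * < 1e-2."""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def species_heatmap_table(
    all_species_results: Mapping[tuple[str, str], tuple[float, float]],
) -> pd.DataFrame:
    """Long-form correlation matrix across species comparisons.

    ``all_species_results`` maps (query_species, reference_species) to
    (rho, p).  Returns a DataFrame with one row per comparison and columns
    ``query, reference, rho, p, stars``, ordered by query then reference —
    the table behind a clade-by-reference heatmap.
    """
    rows = [
        {
            "query": q,
            "reference": r,
            "rho": rho,
            "p": p,
            "stars": significance_stars(p),
        }
        for (q, r), (rho, p) in sorted(all_species_results.items())
    ]
    return pd.DataFrame(rows, columns=["query", "reference", "rho", "p", "stars"])


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_domain_table(path) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV: protein_id, domain, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain": str})
    return [
        DomainAnnotation(r.protein_id, r.domain, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def read_ortholog_table(path) -> list[OrthologPair]:
    """Read an ortholog-pair TSV: id_a, id_b, one_to_one (0/1 or bool)."""
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    return [
        OrthologPair(r.id_a, r.id_b, bool(int(r.one_to_one)))
        for r in df.itertuples()
    ]
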