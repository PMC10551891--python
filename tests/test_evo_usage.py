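"""Alignment against a brute-force oracle; domain matching; usage ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

import paxkit as pk
from paxkit.evo_usage import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Brute-force alignment oracle: enumerate every gapped global alignment and
# score each with an affine gap model (first gap residue = open, rest =
# extend, end gaps penalized).
# ---------------------------------------------------------------------------

def enumerate_alignments(a: str, b: str):
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb


def score_alignment(aligned_a: str, aligned_b: str,
                    gap_open=DEFAULT_GAP_OPEN, gap_extend=DEFAULT_GAP_EXTEND):
    score = 0.0
    prev = "M"
    for x, y in zip(aligned_a, aligned_b):
        if x == "-":
            score -= gap_extend if prev == "A" else gap_open
            prev = "A"
        elif y == "-":
            score -= gap_extend if prev == "B" else gap_open
            prev = "B"
        else:
            score += BLOSUM62[x, y]
            prev = "M"
    return score


def brute_force_best(a: str, b: str):
    return max(score_alignment(x, y) for x, y in enumerate_alignments(a, b))


def test_identical_sequences_align_without_gaps():
    aa, ab, score, identity = pk.global_align("MKRACDEF", "MKRACDEF")
    assert aa == ab == "MKRACDEF"
    assert identity == 1.0
    assert score == sum(BLOSUM62[c, c] for c in "MKRACDEF")


def test_single_gap_example():
    aa, ab, score, identity = pk.global_align("ACDEFG", "ACDFG")
    assert (aa, ab) == ("ACDEFG", "ACD-FG")
    assert identity == pytest.approx(5 / 6)
    assert score == brute_force_best("ACDEFG", "ACDFG")


def test_invalid_residue_rejected():
    with pytest.raises(ValueError, match="invalid residues"):
        pk.global_align("ACDB", "ACD")
    with pytest.raises(ValueError):
        pk.global_align("", "ACD")


def test_x_is_tolerated_as_unknown():
    _, _, score, _ = pk.global_align("ACXDE", "ACDE")
    assert math.isfinite(score)


def test_score_matches_brute_force_on_short_pairs():
    """Optimal score equals exhaustive enumeration over all gapped
    alignments, and the reported alignment is a valid alignment achieving
    that score with the reported identity."""
    rng = np.random.default_rng(47)
    pairs = [("ACDEFG", "ACDFG"), ("MK", "MKR"), ("W", "W"), ("A", "W")]
    for _ in range(12):
        la, lb = rng.integers(2, 7, size=2)
        pairs.append((
            "".join(rng.choice(list(AA), size=la)),
            "".join(rng.choice(list(AA), size=lb)),
        ))
    pairs.append(("".join(rng.choice(list(AA), 8)),
                  "".join(rng.choice(list(AA), 8))))
    for a, b in pairs:
        aa, ab, score, identity = pk.global_align(a, b)
        assert score == pytest.approx(brute_force_best(a, b)), (a, b)
        # reported alignment is internally consistent
        assert aa.replace("-", "") == a
        assert ab.replace("-", "") == b
        assert score_alignment(aa, ab) == pytest.approx(score)
        assert identity == pytest.approx(
            sum(x == y for x, y in zip(aa, ab)) / len(aa)
        )


# ---------------------------------------------------------------------------
# Domain matching
# ---------------------------------------------------------------------------

@pytest.fixture()
def domain_fixture():
    dom = "MKWVFFAADDEEGGHHIIKK"
    other = "WWYYPPGGSSTTVVAACCDD"
    seq_a = "AAAA" + dom + "AAAA"
    seq_b = "GGGG" + dom + "GGGGG" + other
    proteome_a = {"1.A": seq_a}
    proteome_b = {"2.B": seq_b}
    doms_a = [pk.DomainAnnotation("1.A", "KIN", 5, 24)]
    doms_b = [
        pk.DomainAnnotation("2.B", "KIN", 5, 24),
        pk.DomainAnnotation("2.B", "KIN", 30, 49),  # unrelated second copy
    ]
    pair = pk.OrthologPair("1.A", "2.B")
    return pair, doms_a, doms_b, proteome_a, proteome_b


def test_single_shared_domain_full_identity(domain_fixture):
    pair, doms_a, doms_b, pa, pb = domain_fixture
    matches = pk.match_domains(pair, doms_a[:1], doms_b[:1], pa, pb)
    assert len(matches) == 1
    assert matches[0].identity == 1.0
    assert matches[0].domain_name == "KIN"


def test_multi_copy_domain_keeps_highest_scoring_pair(domain_fixture):
    pair, doms_a, doms_b, pa, pb = domain_fixture
    matches = pk.match_domains(pair, doms_a, doms_b, pa, pb)
    assert len(matches) == 1
    assert matches[0].identity == 1.0  # the true copy wins over the decoy


def test_low_identity_domain_dropped():
    # 20-mer with 13 substitutions: identity 7/20 = 0.35 < 0.40
    seq = "ACDEFGHIKLMNPQRSTVWY"
    mutated = "ACDEFGH" + "GAGAGAGAGAGAG"
    pa = {"1.A": seq}
    pb = {"2.B": mutated}
    pair = pk.OrthologPair("1.A", "2.B")
    da = [pk.DomainAnnotation("1.A", "D", 1, 20)]
    db = [pk.DomainAnnotation("2.B", "D", 1, 20)]
    assert pk.match_domains(pair, da, db, pa, pb, min_identity=0.40) == []
    kept = pk.match_domains(pair, da, db, pa, pb, min_identity=0.30)
    assert len(kept) == 1


def test_non_one_to_one_pair_rejected():
    pair = pk.OrthologPair("1.A", "2.B", one_to_one=False)
    with pytest.raises(ValueError, match="one-to-one"):
        pk.match_domains(pair, [], [], {"1.A": "MK"}, {"2.B": "MK"})


def test_no_shared_domain_names_empty():
    pa, pb = {"1.A": "MKMKMKMKMK"}, {"2.B": "MKMKMKMKMK"}
    pair = pk.OrthologPair("1.A", "2.B")
    da = [pk.DomainAnnotation("1.A", "X", 1, 10)]
    db = [pk.DomainAnnotation("2.B", "Y", 1, 10)]
    assert pk.match_domains(pair, da, db, pa, pb) == []


# ---------------------------------------------------------------------------
# Usage ratios
# ---------------------------------------------------------------------------

def _adp(aligned_a, aligned_b):
    return pk.AlignedDomainPair(
        pair=pk.OrthologPair("1.A", "2.B"), domain_name="D",
        aligned_a=aligned_a, aligned_b=aligned_b, identity=1.0, score=0.0,
    )


def test_usage_ratio_definition():
    adp = _adp("ACCAAAAA", "CCCCAAAA")  # 2 Cys vs 4 Cys
    assert pk.usage_ratio(adp, {"C"}) == (2, 4, 0.5)


def test_usage_ratio_zero_side_excluded():
    adp = _adp("CCCAAAAA", "AAAAAAAA")  # 3 Cys vs 0 Cys
    assert pk.usage_ratio(adp, {"C"}) is pk.EXCLUDED


def test_usage_ratio_ignores_gap_columns():
    adp = _adp("MC-AM", "M-CAA")
    counts = pk.usage_ratio(adp, {"C", "M"})
    assert counts == (3, 2, 1.5)


def test_usage_ratio_antisymmetry():
    rng = np.random.default_rng(53)
    for _ in range(20):
        sa = "".join(rng.choice(list(AA), 30))
        sb = "".join(rng.choice(list(AA), 30))
        fwd = pk.usage_ratio(_adp(sa, sb), pk.SULFUR_AAS)
        rev = pk.usage_ratio(_adp(sb, sa), pk.SULFUR_AAS)
        if fwd is pk.EXCLUDED:
            assert rev is pk.EXCLUDED
        else:
            assert rev[2] == pytest.approx(1.0 / fwd[2])


# ---------------------------------------------------------------------------
# Correlation, binning, stars
# ---------------------------------------------------------------------------

def _table(ratios, abundances):
    return pd.DataFrame({
        "id_a": [f"1.P{i}" for i in range(len(ratios))],
        "id_b": [f"2.P{i}" for i in range(len(ratios))],
        "domain": "D",
        "count_a": 1, "count_b": 1,
        "ratio": ratios,
        "abundance_ppm": abundances,
    })


def test_perfect_monotone_decrease_gives_rho_minus_one():
    table = _table([1.0, 0.8, 0.6, 0.4, 0.2], [10, 100, 1000, 10000, 100000])
    rho, p = pk.abundance_usage_correlation(table)
    assert rho == pytest.approx(-1.0)
    assert p < 0.05


def test_exact_rank_oracle_10_rows():
    rng = np.random.default_rng(59)
    ratios = rng.uniform(0.3, 2.0, 10)
    abund = 10 ** rng.uniform(0, 4, 10)
    rho, _ = pk.abundance_usage_correlation(_table(ratios, abund))
    # direct rank-based computation: Pearson on average ranks
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        return r
    ra, rb = ranks(ratios), ranks(abund)
    expected = float(np.corrcoef(ra, rb)[0, 1])
    assert rho == pytest.approx(expected, abs=1e-12)


def test_degenerate_ranks_error():
    with pytest.raises(ValueError, match="degenerate"):
        pk.abundance_usage_correlation(_table([1.0] * 5, [1, 2, 3, 4, 5]))
    with pytest.raises(ValueError, match="3 rows"):
        pk.abundance_usage_correlation(_table([1.0, 2.0], [1, 2]))


def test_null_correlation_is_small():
    rng = np.random.default_rng(61)
    hits = 0
    for _ in range(20):
        rho, _ = pk.abundance_usage_correlation(
            _table(rng.uniform(0.5, 1.5, 1000), 10 ** rng.uniform(0, 4, 1000))
        )
        hits += abs(rho) < 0.1
    assert hits >= 19


def test_bins_equal_sizes_600():
    table = _table(np.linspace(2, 1, 600), np.linspace(1, 1000, 600))
    bins = pk.bin_for_plot(table, 6)
    assert list(bins["n"]) == [100] * 6


def test_bins_601_rows_differ_by_at_most_one():
    table = _table(np.linspace(2, 1, 601), np.linspace(1, 1000, 601))
    bins = pk.bin_for_plot(table, 6)
    assert bins["n"].max() - bins["n"].min() <= 1
    assert bins["n"].sum() == 601


def test_bins_monotone_for_planted_trend():
    rng = np.random.default_rng(67)
    abund = 10 ** rng.uniform(0, 4, 300)
    ratio = 1.2 - 0.2 * np.log10(abund) / 4 + rng.normal(0, 0.01, 300)
    bins = pk.bin_for_plot(_table(ratio, abund), 6)
    medians = bins["ratio_median"].to_numpy()
    assert (np.diff(medians) <= 0).all()


@pytest.mark.parametrize("p,stars", [
    (0.5, ""),
    (0.02, ""),
    (0.005, "*"),
    (0.0005, "**"),
    (1e-6, "***"),
])
def test_significance_stars(p, stars):
    assert pk.significance_stars(p) == stars


def test_species_heatmap_table():
    results = {
        ("S. cerevisiae", "H. sapiens"): (-0.52, 1e-8),
        ("S. pombe", "H. sapiens"): (-0.10, 0.04),
    }
    table = pk.species_heatmap_table(results)
    assert list(table.columns) == ["query", "reference", "rho", "p", "stars"]
    row = table.set_index("query").loc["S. cerevisiae"]
    assert row["stars"] == "***"
    assert table.set_index("query").loc["S. pombe", "stars"] == ""
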