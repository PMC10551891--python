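"""Synthetic data generation with controlled statistical structure.

Every input the toolkit consumes — proteomes, abundance datasets, peptide
tables, interaction networks, ortholog/domain tables — can be generated
here as a pure function of a :class:`SimulationConfig` and its seed, with
the statistical structure (abundance spread, network consistency, planted
sulfur depletion) set explicitly.  This makes every pipeline stage testable
end-to-end, with known ground truth, from nothing but a seed.

What the generators emulate — and what they do not: sequences are i.i.d.
draws from a residue frequency vector (no homology, no composition bias
along the chain); abundances are log-normal (the canonical shape of
proteome-wide abundance distributions); peptide quantities carry
multiplicative log-normal noise (no mass-spectrometer physics such as
ionization efficiency or missing-value structure); interaction networks
have no topology beyond tunable abundance-similarity of endpoints.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .digest import DEFAULT_WINDOW, tryptic_peptides
from .evo_usage import DomainAnnotation, OrthologPair
from .proteome_io import ProteinRecord
from .quality import InteractionNetwork
from .quantify import AbundanceDataset, PeptideMeasurement, to_ppm

logger = logging.getLogger("paxkit")

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# Distinct stream tags so each generator draws from its own substream of
# the config seed and adding a call never perturbs another generator.
_TAG_PROTEOME, _TAG_ABUNDANCE, _TAG_NETWORK, _TAG_PEPTIDES, _TAG_ORTHOLOGS = range(5)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all synthetic generators.

    Defaults describe a mid-size single-organism proteomics experiment:
    a few hundred proteins of realistic length, abundances spanning several
    orders of magnitude (log10 ppm ~ N(1.5, 1.0) before renormalization),
    and 20% multiplicative noise on peptide quantities.
    """

    n_proteins: int = 300
    length_mean: float = 350.0
    length_sd: float = 120.0
    min_length: int = 30
    #: Residue sampling frequencies in AMINO_ACIDS order; uniform by default
    #: (the simplest null for composition analyses).
    aa_frequencies: tuple[float, ...] = tuple([0.05] * 20)
    abundance_mu: float = 1.5
    abundance_sigma: float = 1.0
    network_density: float = 0.01
    #: >= 0; how strongly edges prefer abundance-similar endpoints
    #: (0 = uniform random edges).
    edge_consistency: float = 0.0
    #: Planted sulfur-depletion strength: expected log10 usage ratio of the
    #: highest-abundance ortholog pair is -depletion_beta.
    depletion_beta: float = 0.0
    #: sd of the log10 multiplicative noise on peptide quantities.
    peptide_noise_sd: float = 0.2
    #: Background substitution rate applied to the query-side ortholog.
    mutation_rate: float = 0.05
    domain_length: int = 100
    taxid: int = 4932
    partner_taxid: int = 9606
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if abs(sum(self.aa_frequencies) - 1.0) > 1e-9:
            raise ValueError("aa_frequencies must sum to 1")
        if len(self.aa_frequencies) != 20:
            raise ValueError("aa_frequencies must have 20 entries")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(cfg: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def make_proteome(cfg: SimulationConfig) -> list[ProteinRecord]:
    """Random proteome: i.i.d. residues, normal lengths (floored)."""
    rng = _rng(cfg, _TAG_PROTEOME)
    records = []
    freqs = np.asarray(cfg.aa_frequencies)
    for i in range(cfg.n_proteins):
        length = max(cfg.min_length, int(round(rng.normal(cfg.length_mean,
                                                          cfg.length_sd))))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length, p=freqs))
        records.append(
            ProteinRecord(f"{cfg.taxid}.P{i:05d}", seq, cfg.taxid)
        )
    return records


def make_abundances(
    cfg: SimulationConfig, proteome: list[ProteinRecord]
) -> AbundanceDataset:
    """Log-normal abundances over a proteome, renormalized to 1e6 ppm."""
    rng = _rng(cfg, _TAG_ABUNDANCE)
    log_ppm = rng.normal(cfg.abundance_mu, cfg.abundance_sigma, len(proteome))
    raw = {r.internal_id: float(10 ** x) for r, x in zip(proteome, log_ppm)}
    return AbundanceDataset(
        abundances=to_ppm(raw).abundances,
        organism=cfg.taxid,
        method="synthetic",
        name=f"synthetic-{cfg.seed}",
    )


def make_network(
    cfg: SimulationConfig, ds: AbundanceDataset
) -> InteractionNetwork:
    """Interaction network with tunable abundance-consistency of edges.

    The number of edges is ``network_density`` times the number of possible
    pairs.  A candidate pair (a, b) is accepted with probability
    exp(-edge_consistency * |log10(ppm_a / ppm_b)|): at consistency 0 the
    network is uniform random; large values concentrate edges on
    similarly-abundant proteins, emulating the empirical tendency of
    interaction partners to be co-expressed.
    """
    rng = _rng(cfg, _TAG_NETWORK)
    ids = sorted(pid for pid, v in ds.abundances.items() if v > 0)
    n = len(ids)
    n_edges = int(round(cfg.network_density * n * (n - 1) / 2))
    if n < 2 or n_edges == 0:
        return InteractionNetwork()
    logs = np.array([math.log10(ds.abundances[pid]) for pid in ids])
    edges: set[tuple[int, int]] = set()
    max_rounds = 2000
    for _ in range(max_rounds):
        if len(edges) >= n_edges:
            break
        batch = max(4 * (n_edges - len(edges)), 64)
        ia = rng.integers(0, n, batch)
        ib = rng.integers(0, n, batch)
        accept = rng.random(batch) < np.exp(
            -cfg.edge_consistency * np.abs(logs[ia] - logs[ib])
        )
        for a, b in zip(ia[accept], ib[accept]):
            if a == b:
                continue
            edges.add((min(a, b), max(a, b)))
            if len(edges) >= n_edges:
                break
    else:  # pragma: no cover - only at extreme consistency settings
        logger.warning(
            "make_network: reached %d rounds with %d/%d edges",
            max_rounds, len(edges), n_edges,
        )
    return InteractionNetwork((ids[a], ids[b]) for a, b in sorted(edges))


def make_peptide_table(
    cfg: SimulationConfig,
    proteome: list[ProteinRecord],
    ds: AbundanceDataset,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[PeptideMeasurement]:
    """Observable tryptic peptides with ppm-proportional noisy quantities.

    Each protein with positive abundance contributes its theoretically
    observable peptides, each at quantity ppm * 10^eps with
    eps ~ N(0, peptide_noise_sd).  At zero noise the length-normalized
    quantification route recovers the input ppm exactly.
    """
    rng = _rng(cfg, _TAG_PEPTIDES)
    lo, hi = window
    peps: list[PeptideMeasurement] = []
    for record in proteome:
        ppm = ds.abundances.get(record.internal_id, 0.0)
        if ppm <= 0:
            continue
        for pep in tryptic_peptides(record.sequence):
            if not lo <= len(pep) <= hi:
                continue
            noise = 10 ** rng.normal(0.0, cfg.peptide_noise_sd)
            peps.append(
                PeptideMeasurement(record.internal_id, pep, ppm * noise)
            )
    return peps


@dataclass
class OrthologSet:
    """A planted two-species ortholog benchmark.

    ``proteome_a`` is the mutated query-side proteome (sulfur thinned as a
    function of abundance rank), ``proteome_b`` the untouched partner;
    ``planted_ratios`` holds the expected sulfur usage ratio per pair id.
    """

    pairs: list[OrthologPair]
    domains_a: list[DomainAnnotation]
    domains_b: list[DomainAnnotation]
    proteome_a: list[ProteinRecord]
    proteome_b: list[ProteinRecord]
    planted_ratios: dict[str, float] = field(default_factory=dict)


def make_ortholog_set(
    cfg: SimulationConfig,
    proteome: list[ProteinRecord],
    abundances: AbundanceDataset,
) -> OrthologSet:
    """Plant a sulfur-depletion signal across one-to-one ortholog pairs.

    The partner proteome (species B) is a verbatim copy of the input; the
    query side (species A) receives background substitutions at
    ``mutation_rate`` and, inside its central domain, each sulfur residue
    (C/M) is replaced by leucine with probability
    1 - 10^(-depletion_beta * q), where q in [0, 1] is the protein's
    abundance quantile.  The expected log10 usage ratio A/B of the
    highest-abundance pair is therefore -depletion_beta; at beta = 0 ratios
    fluctuate around 1 from the background mutations alone.  One domain per
    protein (length ``domain_length``, centered) is annotated identically
    on both sides.
    """
    rng = _rng(cfg, _TAG_ORTHOLOGS)
    freqs = np.asarray(cfg.aa_frequencies)
    quantified = [
        r for r in proteome if abundances.abundances.get(r.internal_id, 0) > 0
    ]
    order = sorted(quantified, key=lambda r: abundances.abundances[r.internal_id])
    n = len(order)
    pairs, doms_a, doms_b = [], [], []
    mutated_a, copies_b = [], []
    planted = {}
    for rank, record in enumerate(order):
        q = rank / (n - 1) if n > 1 else 0.0
        p_thin = 1.0 - 10 ** (-cfg.depletion_beta * q)
        seq = list(record.sequence)
        length = len(seq)
        dom_len = min(cfg.domain_length, length)
        start = (length - dom_len) // 2 + 1  # 1-based
        end = start + dom_len - 1
        for i in range(length):
            if rng.random() < cfg.mutation_rate:
                seq[i] = str(rng.choice(AMINO_ACIDS, p=freqs))
            if start - 1 <= i < end and seq[i] in "CM" and rng.random() < p_thin:
                seq[i] = "L"
        locus = record.internal_id.split(".", 1)[1]
        id_a = record.internal_id
        id_b = f"{cfg.partner_taxid}.{locus}"
        mutated_a.append(ProteinRecord(id_a, "".join(seq), record.taxid))
        copies_b.append(ProteinRecord(id_b, record.sequence, cfg.partner_taxid))
        pairs.append(OrthologPair(id_a, id_b, one_to_one=True))
        doms_a.append(DomainAnnotation(id_a, f"DOM_{locus}", start, end))
        doms_b.append(DomainAnnotation(id_b, f"DOM_{locus}", start, end))
        planted[id_a] = 10 ** (-cfg.depletion_beta * q)
    return OrthologSet(
        pairs=pairs,
        domains_a=doms_a,
        domains_b=doms_b,
        proteome_a=mutated_a,
        proteome_b=copies_b,
        planted_ratios=planted,
    )
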