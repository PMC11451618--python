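"""Synthetic constructs, libraries and read pools with known ground truth.

Everything the pipeline consumes can be generated here: a random dual-allele
construct, planted "dispensable" domains whose deletions keep full function,
per-replicate library skew and dropout, and multinomial sequencing reads for
the selected (CRISPR-ON, galactose) and unselected (CRISPR-OFF, glucose)
conditions of each replicate.  The generator emulates the statistical
structure of a pooled deletion scan:

* allele abundances are log-normal (pooled cloning is uneven);
* a configurable fraction of deletions is absent per replicate (synthesis
  and cloning dropout; real scans recover ~88-95% of designed deletions);
* under selection an allele's reads scale with its survival probability —
  1.0 for functional deletions, a small escaper floor for nonfunctional
  ones (cells escape the lethal cut by gRNA/Cas9 mutation at low rate);
* optional decoy reads carry a single core substitution and must be
  rejected by exact matching.

It does NOT model quality-dependent sequencing errors, indels, or PCR
chimeras; reads are exact amplicons (plus optional stagger and decoys).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DeletionSpec, DualConstruct, enumerate_deletions
from .match import AlleleIndex, CountsTable, build_allele_index
from .recode import CodingSequence, SC_CODON_USAGE, AA_TO_CODONS, recode_max_divergence

__all__ = [
    "SimConfig",
    "SimResult",
    "DEFAULT_SPACER",
    "make_synthetic_construct",
    "make_decoy_genome",
    "simulate_counts",
    "simulate_experiment",
]

# Constant cut-site spacer: equal base composition, used verbatim in every
# synthetic cassette so the gRNA never varies between constructs.
DEFAULT_SPACER = "ACGTATCGGTACATGCGCAT"

CONDITIONS = ("glucose", "galactose")  # CRISPR-OFF, CRISPR-ON

_SENSE_CODONS = [c for aa, cs in AA_TO_CODONS.items() if aa != "*" for c in cs]

# Body codons for synthetic constructs.  Two deletions (m1, n1) and
# (m1+k, n1+k) produce byte-identical repaired molecules whenever copy-1
# codons m1..m1+k-1 equal copy-2 codons n1+1..n1+k — physically
# indistinguishable alleles that no read matcher can separate.  Restricting
# the synthetic CDS to codons whose maximal-divergence recoding is unique
# AND never reproduces any codon of this set (two-codon amino acids plus
# serine TCT -> AGC) makes every deletion allele distinguishable by
# construction, which is exactly the property a real scan's recoded allele
# pair is chosen to approximate.
_BODY_CODONS = ["AAA", "AAT", "GAT", "TGT", "CAA", "GAA", "CAT", "TTT", "TAT", "TCT"]


@dataclass
class SimConfig:
    """Ground-truth experiment parameters.

    survival probabilities apply under CRISPR-ON only (CRISPR-OFF never
    selects); ``domains`` plant dispensable segments — any deletion wholly
    inside one survives with ``survival_inside``, every other deletion with
    the escaper floor ``survival_outside``.  ``functional_map`` overrides
    per deletion id.  ``reads_per_allele`` sets library depth =
    reads_per_allele * number of deletions.
    """

    protein_length: int = 87
    seed: int = 0
    domains: list[tuple[int, int]] = field(default_factory=list)
    survival_inside: float = 1.0
    survival_outside: float = 0.01
    functional_map: dict[str, float] = field(default_factory=dict)
    dropout: float = 0.10
    library_sigma: float = 1.0
    reads_per_allele: int = 200
    n_replicates: int = 3
    error_rate: float = 0.0
    stagger_max: int = 6

    def __post_init__(self) -> None:
        for p in (
            self.survival_inside,
            self.survival_outside,
            self.dropout,
            self.error_rate,
            *self.functional_map.values(),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.reads_per_allele <= 0 or self.n_replicates < 1:
            raise ValueError("reads_per_allele and n_replicates must be positive")

    def survival(self, d: DeletionSpec) -> float:
        if d.id in self.functional_map:
            return self.functional_map[d.id]
        for a, b in self.domains:
            if a <= d.m and d.n <= b:
                return self.survival_inside
        return self.survival_outside


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_synthetic_construct(
    length: int = 87,
    seed: int = 0,
    flank_len: int = 150,
    spacer: str = DEFAULT_SPACER,
) -> DualConstruct:
    """A random dual-allele construct of ``length`` residues.

    Copy 1 is ATG + random codons from a collision-free alphabet + TAA;
    copy 2 is its maximal-divergence synonymous recoding under yeast codon
    usage (deterministic for this alphabet, so every deletion allele has a
    unique DNA sequence).  The
    cassette between them carries the constant 20-nt spacer followed by AGG
    (the cut site) and a random marker placeholder.  Deterministic per seed.
    """
    if length < 10:
        raise ValueError("need at least 10 codons for a meaningful construct")
    rng = np.random.default_rng(seed)
    body = rng.choice(_BODY_CODONS, size=length - 1)
    allele_up = CodingSequence("ATG" + "".join(body) + "TAA")
    allele_down = recode_max_divergence(
        allele_up, SC_CODON_USAGE, seed=int(rng.integers(0, 2**31))
    )
    cassette = (
        _random_dna(rng, 15) + spacer + "AGG" + _random_dna(rng, 60)
    )
    construct = DualConstruct(
        promoter=_random_dna(rng, flank_len),
        allele_up=allele_up,
        cassette=cassette,
        allele_down=allele_down,
        terminator_flank=_random_dna(rng, flank_len),
        spacer=spacer,
    )
    return construct


def make_decoy_genome(
    spacer: str = DEFAULT_SPACER,
    n_sites: int = 50,
    min_mismatches: int = 6,
    seed: int = 0,
    site_spacing: int = 30,
) -> str:
    """A genome whose nearest PAM-adjacent site is exactly ``min_mismatches`` away.

    Builds PAM (NGG) sites whose protospacers differ from ``spacer`` at at
    least ``min_mismatches`` positions, with exactly one site at exactly
    that distance, separated by A/C-only filler (which can form no PAM and,
    on the reverse strand, no CC dinucleotide either).
    """
    rng = np.random.default_rng(seed)
    swap = {"A": "G", "C": "T", "G": "A", "T": "C"}  # never the identity

    def mutated(k: int) -> str:
        pos = rng.choice(20, size=k, replace=False)
        s = list(spacer)
        for p in pos:
            s[p] = swap[s[p]]
        return "".join(s)

    filler = lambda: "".join(np.array(list("AC"))[rng.integers(0, 2, site_spacing)])
    parts = [filler()]
    parts += [mutated(min_mismatches), "AGG", filler()]
    for _ in range(n_sites - 1):
        k = int(rng.integers(min_mismatches, 15))
        parts += [mutated(k), "AGG", filler()]
    return "".join(parts)


@dataclass
class SimResult:
    """Simulated experiment: counts (and optionally FASTQ paths) + truth ledger."""

    construct: DualConstruct
    config: SimConfig
    index: AlleleIndex
    counts: CountsTable  # observed-style counts assembled from the truth draws
    ledger: pd.DataFrame  # id, m, n, survival, functional + true counts per library
    fastq: dict[str, Path] = field(default_factory=dict)


def _draw_counts(
    config: SimConfig, deletions: list[DeletionSpec], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial true counts per library; returns (counts, abundances)."""
    ids = [d.id for d in deletions]
    survival = np.array([config.survival(d) for d in deletions])
    depth = config.reads_per_allele * len(deletions)
    cols: dict[str, np.ndarray] = {}
    abund_cols: dict[str, np.ndarray] = {}
    for rep in range(1, config.n_replicates + 1):
        abund = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=len(deletions))
        dropped = rng.random(len(deletions)) < config.dropout
        abund[dropped] = 0.0
        if abund.sum() == 0:
            raise ValueError("dropout removed every allele; lower SimConfig.dropout")
        abund_cols[f"rep{rep}"] = abund
        for cond in CONDITIONS:
            w = abund if cond == "glucose" else abund * survival
            total = w.sum()
            if total == 0:
                counts = np.zeros(len(deletions), dtype=int)
            else:
                counts = rng.multinomial(depth, w / total)
            cols[f"rep{rep}_{cond}"] = counts
    return (
        pd.DataFrame(cols, index=pd.Index(ids, name="deletion_id")),
        pd.DataFrame(abund_cols, index=pd.Index(ids, name="deletion_id")),
    )


def _make_ledger(
    config: SimConfig, deletions: list[DeletionSpec], true_counts: pd.DataFrame
) -> pd.DataFrame:
    ledger = pd.DataFrame(
        {
            "deletion_id": [d.id for d in deletions],
            "m": [d.m for d in deletions],
            "n": [d.n for d in deletions],
            "survival": [config.survival(d) for d in deletions],
        }
    ).set_index("deletion_id")
    ledger["functional"] = ledger["survival"] >= 0.5
    return ledger.join(true_counts)


def simulate_counts(
    construct: DualConstruct, config: SimConfig
) -> SimResult:
    """Simulate at the count level (no reads): fast path for statistical tests.

    The returned :class:`CountsTable` holds exactly the multinomial truth
    draws — identical to what exact matching of an error-free read pool
    would recover.
    """
    deletions = enumerate_deletions(construct.n_codons)
    rng = np.random.default_rng(config.seed)
    true_counts, _ = _draw_counts(config, deletions, rng)
    index = build_allele_index(construct, deletions, kind="genomic")
    counts = CountsTable.empty(index)
    for lib in true_counts.columns:
        counts.add_column(lib, true_counts[lib], unmatched=0, skipped=0)
    return SimResult(
        construct=construct,
        config=config,
        index=index,
        counts=counts,
        ledger=_make_ledger(config, deletions, true_counts),
    )


def simulate_experiment(
    construct: DualConstruct,
    config: SimConfig,
    outdir: str | Path | None = None,
) -> SimResult:
    """Full read-level simulation: FASTQ per (replicate, condition) + truth ledger.

    Reads are the exact genomic amplicon (anchor5 + chimeric core + anchor3)
    preceded by a random 0..stagger_max-nt prefix; with probability
    ``error_rate`` a read instead carries one random core substitution
    (a decoy that exact matching must reject).  The ledger records the intact
    (matchable) count per allele and library; emitted reads per library
    always equal the configured depth.  Byte-identical output per seed.
    """
    deletions = enumerate_deletions(construct.n_codons)
    rng = np.random.default_rng(config.seed)
    true_counts, _ = _draw_counts(config, deletions, rng)
    index = build_allele_index(construct, deletions, kind="genomic")
    id_to_core = {aid: core for core, aid in index.cores.items()}

    fastq: dict[str, Path] = {}
    intact = pd.DataFrame(0, index=true_counts.index, columns=true_counts.columns)
    decoyed: dict[str, int] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    bases = np.array(list("ACGT"))
    for lib in true_counts.columns:
        records: list[tuple[str, str]] = []
        n_decoy = 0
        for aid, count in true_counts[lib].items():
            if count == 0:
                continue
            core = id_to_core[aid]
            n_err = int(rng.binomial(count, config.error_rate)) if config.error_rate else 0
            intact.loc[aid, lib] = count - n_err
            for r in range(count):
                this_core = core
                if r < n_err:
                    pos = int(rng.integers(0, len(core)))
                    old = core[pos]
                    new = bases[bases != old][int(rng.integers(0, 3))]
                    this_core = core[:pos] + new + core[pos + 1 :]
                    n_decoy += 1
                stagger = _random_dna(rng, int(rng.integers(0, config.stagger_max + 1)))
                records.append((aid, stagger + index.anchor5 + this_core + index.anchor3))
        rng.shuffle(records)  # reads arrive in no particular order
        decoyed[lib] = n_decoy
        if outdir is not None:
            path = outdir / f"{lib}.fastq"
            with open(path, "w") as fh:
                for i, (aid, seq) in enumerate(records):
                    fh.write(f"@{lib}:{i}:{aid}\n{seq}\n+\n{'I' * len(seq)}\n")
            fastq[lib] = path

    counts = CountsTable.empty(index)
    for lib in intact.columns:
        counts.add_column(lib, intact[lib], unmatched=decoyed[lib], skipped=0)
    ledger = _make_ledger(config, deletions, intact)
    return SimResult(
        construct=construct,
        config=config,
        index=index,
        counts=counts,
        ledger=ledger,
        fastq=fastq,
    )
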