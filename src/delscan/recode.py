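"""Synonymous recoding of a coding sequence for maximal DNA divergence.

A deletion scan built on homology-directed repair between two tandem gene
copies needs the two copies to be as different as possible at the DNA level
(while encoding the same protein), so that repair-template homology arms and
sequencing reads can be assigned unambiguously to one copy.  This module
generates such a second allele: for every codon it keeps only the synonymous
codons sharing the fewest position-wise bases with the reference codon, then
draws among ties with probabilities proportional to host codon-usage weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "CodingSequence",
    "CodonUsageTable",
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "SC_CODON_USAGE",
    "translate",
    "recode_max_divergence",
    "pairwise_identity",
    "codon_base_matches",
    "min_sharing_codons",
]

_DNA = set("ACGT")

# Standard genetic code, codon -> one-letter amino acid ('*' for stop),
# taken from Biopython's standard table.
_STD = _BioCodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    CODON_TO_AA[_stop] = "*"

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], []).append(_codon)


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence read in frame 0.

    The length must be a multiple of 3 and the sequence must contain no
    internal stop codons; a single trailing stop codon is allowed (and is
    how the constructs built elsewhere in this package carry their stop).
    """

    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if len(seq) % 3 != 0:
            raise ValueError(f"length {len(seq)} is not divisible by 3")
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
        aa = [CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq), 3)]
        if "*" in aa[:-1]:
            pos = aa.index("*") + 1
            raise ValueError(f"internal stop codon at codon {pos}")

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CodonUsageTable:
    """Per-amino-acid codon weights (normalized to sum to 1 within each AA).

    ``weights`` maps amino acid (one-letter, '*' for stop) to a dict
    codon -> weight.  Weights must be non-negative; each codon must be a
    synonymous codon of its amino acid under the standard genetic code.
    """

    weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, dict[str, float]] = {}
        for aa, codons in self.weights.items():
            for codon, w in codons.items():
                if codon not in CODON_TO_AA or CODON_TO_AA[codon] != aa:
                    raise ValueError(f"codon {codon} does not encode {aa}")
                if w < 0:
                    raise ValueError(f"negative weight for {codon}")
            total = sum(codons.values())
            if total > 0:
                norm[aa] = {c: w / total for c, w in codons.items()}
            else:
                norm[aa] = dict(codons)
        self.weights = norm

    def weight(self, codon: str) -> float:
        aa = CODON_TO_AA[codon]
        return self.weights.get(aa, {}).get(codon, 0.0)

    def covers(self, aa: str) -> bool:
        return aa in self.weights

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        """Read a TSV with columns amino_acid, codon, weight (header required)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"amino_acid", "codon", "weight"}
        if not required.issubset(df.columns):
            raise ValueError(f"codon usage TSV needs columns {sorted(required)}")
        weights: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            weights.setdefault(str(row["amino_acid"]), {})[
                str(row["codon"]).upper()
            ] = float(row["weight"])
        return cls(weights)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("amino_acid\tcodon\tweight\n")
            for aa in sorted(self.weights):
                for codon, w in sorted(self.weights[aa].items()):
                    fh.write(f"{aa}\t{codon}\t{w:.4f}\n")


# Codon usage fractions for the S. cerevisiae nuclear genome (per amino
# acid, normalized).  Values are the commonly tabulated genome-wide codon
# fractions rounded to two decimals; only the relative weights within each
# amino acid matter here.
SC_CODON_USAGE = CodonUsageTable(
    {
        "A": {"GCT": 0.38, "GCC": 0.22, "GCA": 0.29, "GCG": 0.11},
        "R": {"CGT": 0.14, "CGC": 0.06, "CGA": 0.07, "CGG": 0.04, "AGA": 0.48, "AGG": 0.21},
        "N": {"AAT": 0.59, "AAC": 0.41},
        "D": {"GAT": 0.65, "GAC": 0.35},
        "C": {"TGT": 0.63, "TGC": 0.37},
        "Q": {"CAA": 0.69, "CAG": 0.31},
        "E": {"GAA": 0.70, "GAG": 0.30},
        "G": {"GGT": 0.47, "GGC": 0.19, "GGA": 0.22, "GGG": 0.12},
        "H": {"CAT": 0.64, "CAC": 0.36},
        "I": {"ATT": 0.46, "ATC": 0.26, "ATA": 0.27},
        "L": {"TTA": 0.28, "TTG": 0.29, "CTT": 0.13, "CTC": 0.06, "CTA": 0.14, "CTG": 0.11},
        "K": {"AAA": 0.58, "AAG": 0.42},
        "M": {"ATG": 1.0},
        "F": {"TTT": 0.59, "TTC": 0.41},
        "P": {"CCT": 0.31, "CCC": 0.15, "CCA": 0.42, "CCG": 0.12},
        "S": {"TCT": 0.26, "TCC": 0.16, "TCA": 0.21, "TCG": 0.10, "AGT": 0.16, "AGC": 0.11},
        "T": {"ACT": 0.35, "ACC": 0.22, "ACA": 0.30, "ACG": 0.14},
        "W": {"TGG": 1.0},
        "Y": {"TAT": 0.56, "TAC": 0.44},
        "V": {"GTT": 0.39, "GTC": 0.21, "GTA": 0.21, "GTG": 0.19},
        "*": {"TAA": 0.47, "TAG": 0.23, "TGA": 0.30},
    }
)


def translate(cds: CodingSequence | str) -> str:
    """Translate under the standard genetic code; a trailing stop becomes '*'."""
    if not isinstance(cds, CodingSequence):
        cds = CodingSequence(cds)
    return "".join(CODON_TO_AA[c] for c in cds.codons())


def codon_base_matches(a: str, b: str) -> int:
    """Number of positions (of 3) at which two codons carry the same base."""
    return sum(x == y for x, y in zip(a, b))


def min_sharing_codons(reference_codon: str) -> list[str]:
    """Synonymous codons of ``reference_codon`` sharing the fewest bases with it.

    Brute force over the full synonymous set; used both by the recoder and
    as its own oracle in tests.
    """
    aa = CODON_TO_AA[reference_codon]
    synonyms = AA_TO_CODONS[aa]
    scores = {c: codon_base_matches(c, reference_codon) for c in synonyms}
    best = min(scores.values())
    return [c for c in synonyms if scores[c] == best]


def recode_max_divergence(
    reference: CodingSequence | str,
    usage: CodonUsageTable = SC_CODON_USAGE,
    seed: int = 0,
) -> CodingSequence:
    """Build a synonymous allele maximally divergent from ``reference``.

    For each codon, candidate output codons are the synonymous codons with
    the minimum count of position-wise base matches to the reference codon.
    One candidate is drawn with probability proportional to its codon-usage
    weight (uniformly if all candidate weights are zero).  A single seeded
    generator is consumed left-to-right along the sequence, so the output is
    reproducible and a draw at codon i affects only codons ≥ i.
    """
    if not isinstance(reference, CodingSequence):
        reference = CodingSequence(reference)
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for idx, codon in enumerate(reference.codons(), start=1):
        aa = CODON_TO_AA[codon]
        if not usage.covers(aa):
            raise ValueError(f"amino acid {aa!r} (codon {idx}) absent from usage table")
        candidates = min_sharing_codons(codon)
        if len(candidates) == 1:
            out.append(candidates[0])
            continue
        w = np.array([usage.weight(c) for c in candidates], dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(candidates))
        out.append(candidates[rng.choice(len(candidates), p=w / w.sum())])
    return CodingSequence("".join(out))


def pairwise_identity(a: CodingSequence | str, b: CodingSequence | str) -> float:
    """Position-wise fraction of identical bases between equal-length sequences."""
    sa = a.seq if isinstance(a, CodingSequence) else a
    sb = b.seq if isinstance(b, CodingSequence) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    if not sa:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(sa, sb)) / len(sa)
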