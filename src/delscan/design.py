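"""Deletion enumeration and repair-template oligo library design.

The experimental design places two synonymous copies of the target gene in
tandem around a synthetic Cas9 target site and a counter-selectable marker.
A single constant gRNA cuts between the copies; a pooled library of repair
templates, each joining a prefix of the first copy to a suffix of the second,
programs every possible contiguous in-frame deletion (and, optionally,
deletion-free "clean chimera" junctions).  This module enumerates deletions,
builds the 2-arm oligos, and checks the constant gRNA spacer for uniqueness
against a genome by brute-force PAM-adjacent Hamming scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import reverse_complement

from .recode import CodingSequence, translate

__all__ = [
    "DualConstruct",
    "DeletionSpec",
    "RepairTemplate",
    "OligoLibrary",
    "enumerate_deletions",
    "build_repair_template",
    "build_clean_chimera",
    "build_library",
    "grna_min_mismatch",
    "NO_TARGET_SITES",
]

DEFAULT_ARM_LEN = 100
DEFAULT_PRIMER5 = "GGTCTCACACCGTGC"  # 15-nt constant priming sites flanking
DEFAULT_PRIMER3 = "GCGGTGTGAGACCAG"  # the oligo; any constant 15-mers work


@dataclass(frozen=True)
class DeletionSpec:
    """A contiguous in-frame deletion, inclusive 1-based codon interval [m, n]."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.n):
            raise ValueError(f"invalid deletion interval [{self.m}, {self.n}]")

    @property
    def id(self) -> str:
        return f"del_{self.m}_{self.n}"

    def __len__(self) -> int:
        return self.n - self.m + 1


@dataclass
class DualConstruct:
    """The tandem dual-allele locus: promoter, copy 1, cut cassette, copy 2, flank.

    ``cassette`` sits between the copies and must contain exactly one
    occurrence of ``spacer`` followed by an NGG PAM; repair with any template
    removes it (and with it the marker and the Cas9 target site).
    Both alleles carry their own stop codon.
    """

    promoter: str
    allele_up: CodingSequence
    cassette: str
    allele_down: CodingSequence
    terminator_flank: str
    spacer: str

    def __post_init__(self) -> None:
        if isinstance(self.allele_up, str):
            self.allele_up = CodingSequence(self.allele_up)
        if isinstance(self.allele_down, str):
            self.allele_down = CodingSequence(self.allele_down)
        if translate(self.allele_up) != translate(self.allele_down):
            raise ValueError("alleles do not encode the same protein")
        if len(self.spacer) != 20:
            raise ValueError(f"spacer must be 20 nt, got {len(self.spacer)}")
        hits = _find_spacer_pam(self.cassette, self.spacer)
        if hits != 1:
            raise ValueError(
                f"cassette must contain the spacer+NGG site exactly once, found {hits}"
            )

    @property
    def protein(self) -> str:
        return translate(self.allele_up).rstrip("*")

    @property
    def n_codons(self) -> int:
        """Residue count (the trailing stop codon is not included)."""
        return len(self.protein)

    @property
    def full_locus(self) -> str:
        return (
            self.promoter
            + self.allele_up.seq
            + self.cassette
            + self.allele_down.seq
            + self.terminator_flank
        )


def _find_spacer_pam(seq: str, spacer: str) -> int:
    count = 0
    start = 0
    while True:
        i = seq.find(spacer, start)
        if i < 0:
            return count
        pam = seq[i + 20 : i + 23]
        if len(pam) == 3 and pam[1:] == "GG":
            count += 1
        start = i + 1


@dataclass
class RepairTemplate:
    """One oligo: primer5 + left arm + right arm + primer3.

    The left arm is the ``arm_len`` nt ending at the last base of codon m-1 of
    the first allele (extending into the promoter if needed); the right arm is
    the ``arm_len`` nt starting at the first base of codon n+1 of the second
    allele (extending into the terminator flank).  ``deletion`` is None for a
    clean-chimera (no-deletion) template, in which case ``junction`` gives the
    codon after which the copies are joined.
    """

    deletion: DeletionSpec | None
    left_arm: str
    right_arm: str
    primer5: str
    primer3: str
    junction: int | None = None

    @property
    def full_seq(self) -> str:
        return self.primer5 + self.left_arm + self.right_arm + self.primer3

    @property
    def id(self) -> str:
        if self.deletion is not None:
            return self.deletion.id
        return f"chimera_{self.junction}"


def enumerate_deletions(
    protein_length: int, include_termini: bool = False
) -> list[DeletionSpec]:
    """All contiguous in-frame deletions as inclusive codon intervals, (m, n)-ordered.

    ``protein_length`` counts residues (the stop codon is position
    ``protein_length + 1``).  With ``include_termini=False`` (the analyzed
    set), the start and stop codons are not deletable, leaving codons
    2..protein_length; with ``include_termini=True``, codons
    1..protein_length+1 are all deletable.  The count is k(k+1)/2 for k
    deletable codons.
    """
    if include_termini:
        lo, hi = 1, protein_length + 1
    else:
        lo, hi = 2, protein_length
    if hi < lo:
        raise ValueError(
            f"protein of {protein_length} codons leaves no deletable range"
        )
    return [
        DeletionSpec(m, n) for m in range(lo, hi + 1) for n in range(m, hi + 1)
    ]


def _left_arm(construct: DualConstruct, end_codon: int, arm_len: int) -> str:
    """arm_len nt ending at the last base of ``end_codon`` of the first allele."""
    context = construct.promoter + construct.allele_up.seq[: 3 * end_codon]
    if len(context) < arm_len:
        raise ValueError(
            f"left arm needs {arm_len} nt but only {len(context)} available "
            f"(promoter too short)"
        )
    return context[-arm_len:]


def _right_arm(construct: DualConstruct, start_codon: int, arm_len: int) -> str:
    """arm_len nt starting at the first base of ``start_codon`` of the second allele."""
    context = (
        construct.allele_down.seq[3 * (start_codon - 1) :] + construct.terminator_flank
    )
    if len(context) < arm_len:
        raise ValueError(
            f"right arm needs {arm_len} nt but only {len(context)} available "
            f"(terminator flank too short)"
        )
    return context[:arm_len]


def build_repair_template(
    construct: DualConstruct,
    deletion: DeletionSpec,
    arm_len: int = DEFAULT_ARM_LEN,
    primer5: str = DEFAULT_PRIMER5,
    primer3: str = DEFAULT_PRIMER3,
) -> RepairTemplate:
    """The oligo programming deletion of codons m..n."""
    if deletion.n > construct.n_codons + 1:
        raise ValueError(
            f"deletion end {deletion.n} beyond stop codon {construct.n_codons + 1}"
        )
    return RepairTemplate(
        deletion=deletion,
        left_arm=_left_arm(construct, deletion.m - 1, arm_len),
        right_arm=_right_arm(construct, deletion.n + 1, arm_len),
        primer5=primer5,
        primer3=primer3,
    )


def build_clean_chimera(
    construct: DualConstruct,
    junction: int,
    arm_len: int = DEFAULT_ARM_LEN,
    primer5: str = DEFAULT_PRIMER5,
    primer3: str = DEFAULT_PRIMER3,
) -> RepairTemplate:
    """A no-deletion template joining copy 1 through codon j to copy 2 from j+1."""
    if not (1 <= junction <= construct.n_codons):
        raise ValueError(f"junction {junction} outside 1..{construct.n_codons}")
    return RepairTemplate(
        deletion=None,
        left_arm=_left_arm(construct, junction, arm_len),
        right_arm=_right_arm(construct, junction + 1, arm_len),
        primer5=primer5,
        primer3=primer3,
        junction=junction,
    )


@dataclass
class OligoLibrary:
    """The designed oligo pool plus its manifest and any sequence collisions."""

    templates: list[RepairTemplate]
    collisions: list[tuple[str, str]] = field(default_factory=list)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for t in self.templates:
            rows.append(
                {
                    "id": t.id,
                    "m": t.deletion.m if t.deletion else pd.NA,
                    "n": t.deletion.n if t.deletion else pd.NA,
                    "length": len(t.full_seq),
                    "sequence": t.full_seq,
                }
            )
        return pd.DataFrame(rows, columns=["id", "m", "n", "length", "sequence"])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.templates:
                fh.write(f">{t.id}\n{t.full_seq}\n")


def build_library(
    construct: DualConstruct,
    deletions: list[DeletionSpec] | None = None,
    arm_len: int = DEFAULT_ARM_LEN,
    primer5: str = DEFAULT_PRIMER5,
    primer3: str = DEFAULT_PRIMER3,
    include_clean_chimeras: bool = False,
) -> OligoLibrary:
    """One template per deletion (plus optional deduplicated chimera set).

    Distinct deletions whose oligos collide to the same sequence (possible
    only with internal repeats) are all kept and reported in
    ``OligoLibrary.collisions``; clean-chimera templates are deduplicated by
    sequence, as equal-sequence chimeras program the identical repair.
    """
    if deletions is None:
        deletions = enumerate_deletions(construct.n_codons)
    templates = [
        build_repair_template(construct, d, arm_len, primer5, primer3)
        for d in deletions
    ]
    seen: dict[str, str] = {}
    collisions: list[tuple[str, str]] = []
    for t in templates:
        if t.full_seq in seen:
            collisions.append((seen[t.full_seq], t.id))
        else:
            seen[t.full_seq] = t.id
    if include_clean_chimeras:
        for j in range(1, construct.n_codons + 1):
            t = build_clean_chimera(construct, j, arm_len, primer5, primer3)
            if t.full_seq not in seen:
                seen[t.full_seq] = t.id
                templates.append(t)
    return OligoLibrary(templates=templates, collisions=collisions)


def load_construct(config_path) -> DualConstruct:
    """Build a DualConstruct from a YAML/JSON config naming FASTA records.

    Expected keys: ``fasta`` (path, relative to the config file) and
    ``records`` mapping each of promoter, allele_up, cassette, allele_down,
    terminator_flank to a record id in that FASTA, plus ``spacer`` (20-nt
    string).
    """
    import yaml
    from pathlib import Path
    from Bio import SeqIO

    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("fasta", "records", "spacer"):
        if key not in cfg:
            raise ValueError(f"construct config missing key {key!r}")
    fasta = config_path.parent / cfg["fasta"]
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    parts = {}
    for part in ("promoter", "allele_up", "cassette", "allele_down", "terminator_flank"):
        rec_id = cfg["records"].get(part)
        if rec_id is None or rec_id not in seqs:
            raise ValueError(f"construct config: no FASTA record for {part!r}")
        parts[part] = seqs[rec_id]
    return DualConstruct(
        promoter=parts["promoter"],
        allele_up=CodingSequence(parts["allele_up"]),
        cassette=parts["cassette"],
        allele_down=CodingSequence(parts["allele_down"]),
        terminator_flank=parts["terminator_flank"],
        spacer=str(cfg["spacer"]).upper(),
    )


def save_construct(construct: DualConstruct, outdir, stem: str = "construct"):
    """Write a construct as FASTA + YAML config; returns the config path."""
    import yaml
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{stem}.fa"
    parts = {
        "promoter": construct.promoter,
        "allele_up": construct.allele_up.seq,
        "cassette": construct.cassette,
        "allele_down": construct.allele_down.seq,
        "terminator_flank": construct.terminator_flank,
    }
    with open(fasta, "w") as fh:
        for name, seq in parts.items():
            fh.write(f">{name}\n{seq}\n")
    config = outdir / f"{stem}.yaml"
    with open(config, "w") as fh:
        yaml.safe_dump(
            {
                "fasta": fasta.name,
                "records": {k: k for k in parts},
                "spacer": construct.spacer,
            },
            fh,
        )
    return config


NO_TARGET_SITES = None  # sentinel returned when the genome has no PAM sites


def grna_min_mismatch(
    spacer: str,
    genome: str | list[str],
    pam: str = "NGG",
    exclude_perfect: bool = False,
) -> int | None:
    """Minimum Hamming distance from ``spacer`` to any PAM-adjacent 20-mer.

    Both strands of every genome sequence are scanned for 20-mers lying
    immediately 5' of a PAM (default NGG; the PAM must match exactly and is
    not counted).  Returns ``NO_TARGET_SITES`` (None) when no PAM-adjacent
    site exists.  With ``exclude_perfect`` the on-target 0-mismatch site is
    ignored, so the return value measures off-target uniqueness when the
    construct itself is part of the genome.
    """
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    seqs = [genome] if isinstance(genome, str) else list(genome)
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("empty genome")
    pam_tail = pam[1:]  # leading N matches anything
    k = len(pam)
    best: int | None = None
    for seq in seqs:
        for strand in (seq.upper(), reverse_complement(seq.upper())):
            for i in range(len(strand) - 20 - k + 1):
                if strand[i + 21 : i + 20 + k] != pam_tail:
                    continue
                d = sum(a != b for a, b in zip(spacer, strand[i : i + 20]))
                if exclude_perfect and d == 0:
                    continue
                if best is None or d < best:
                    best = d
                    if best == 0:
                        return 0
    return best
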