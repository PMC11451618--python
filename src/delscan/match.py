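"""Exact-match read counting for deletion-scan amplicons.

Sequencing reads (pre-merged read pairs) are assigned to deletion alleles by
perfect sequence matching only: constant anchor sequences bounding the
variable region are located in each read, and the intervening core must
equal an expected allele core exactly.  Anchored extraction makes the
matching robust to the variable-length prefixes (staggered primers, random
barcodes) that pooled amplicon libraries carry for flow-cell diversity;
any read with even a single substitution in the core is left unmatched, as
are NHEJ products and escapers.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.Seq import reverse_complement

from .design import DeletionSpec, DualConstruct

__all__ = [
    "AlleleIndex",
    "CountsTable",
    "PARENTAL_ID",
    "IndexCollisionError",
    "build_allele_index",
    "count_reads",
    "read_fastq",
]

logger = logging.getLogger(__name__)

PARENTAL_ID = "parental"  # the unedited dual-allele locus, reported separately


class IndexCollisionError(ValueError):
    """Two distinct deletion ids map to the same expected core sequence."""


@dataclass
class AlleleIndex:
    """Expected core sequence -> deletion id, with the bounding anchors.

    ``kind`` is "genomic" (post-repair chimeric single-gene allele) or
    "plasmid" (the repair-template oligo itself).
    """

    kind: str
    anchor5: str
    anchor3: str
    cores: dict[str, str]  # core sequence -> deletion id
    meta: dict[str, tuple[int, int]] = field(default_factory=dict)  # id -> (m, n)

    def __len__(self) -> int:
        return len(self.cores)


def _genomic_core(construct: DualConstruct, m: int, n: int) -> str:
    """The repaired locus between promoter and flank: copy-1 prefix + copy-2 suffix."""
    return construct.allele_up.seq[: 3 * (m - 1)] + construct.allele_down.seq[3 * n :]


def build_allele_index(
    construct: DualConstruct,
    deletions: Iterable[DeletionSpec],
    kind: str = "genomic",
    anchor5: str | None = None,
    anchor3: str | None = None,
    anchor_len: int = 20,
    include_parental: bool = True,
) -> AlleleIndex:
    """Index of expected amplicon cores for exact read assignment.

    For the genomic amplicon the default anchors are the ``anchor_len`` nt of
    promoter and terminator flank abutting the gene; the core for deletion
    [m, n] is the chimeric allele with codons m..n removed, which translates
    to the wild-type protein minus residues m..n.  For the plasmid amplicon
    anchors must be the constant oligo primers and cores are the arm pairs.
    Core collisions abort index construction with both ids named.
    """
    if kind not in ("genomic", "plasmid"):
        raise ValueError(f"unknown amplicon kind {kind!r}")
    if kind == "genomic":
        if anchor5 is None:
            anchor5 = construct.promoter[-anchor_len:]
        if anchor3 is None:
            anchor3 = construct.terminator_flank[:anchor_len]
    elif anchor5 is None or anchor3 is None:
        raise ValueError("plasmid index requires explicit primer anchors")

    from .design import build_repair_template  # local to avoid cycle at import

    cores: dict[str, str] = {}
    meta: dict[str, tuple[int, int]] = {}
    for d in deletions:
        if kind == "genomic":
            core = _genomic_core(construct, d.m, d.n)
        else:
            t = build_repair_template(construct, d)
            core = t.left_arm + t.right_arm
        if core in cores:
            raise IndexCollisionError(
                f"deletions {cores[core]} and {d.id} share the same "
                f"{kind} core sequence"
            )
        cores[core] = d.id
        meta[d.id] = (d.m, d.n)
    if kind == "genomic" and include_parental:
        parental = (
            construct.allele_up.seq + construct.cassette + construct.allele_down.seq
        )
        if parental not in cores:
            cores[parental] = PARENTAL_ID
    for core in cores:
        amplicon = anchor5 + core + anchor3
        if amplicon.count(anchor5) != 1 or amplicon.count(anchor3) != 1:
            raise ValueError(
                f"anchors are not unique in the expected amplicon for "
                f"{cores[core]}; choose longer or different anchors"
            )
    return AlleleIndex(kind=kind, anchor5=anchor5, anchor3=anchor3, cores=cores, meta=meta)


@dataclass
class CountsTable:
    """Per-allele read counts per library, with unmatched/skipped bookkeeping."""

    counts: pd.DataFrame  # index: deletion ids; columns: library names
    unmatched: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)
    meta: dict[str, tuple[int, int]] = field(default_factory=dict)

    def library_total(self, library: str) -> int:
        return int(self.counts[library].sum())

    def add_column(self, library: str, column: pd.Series, unmatched: int, skipped: int) -> None:
        self.counts[library] = column.reindex(self.counts.index, fill_value=0).astype(int)
        self.unmatched[library] = unmatched
        self.skipped[library] = skipped

    @classmethod
    def empty(cls, index: AlleleIndex) -> "CountsTable":
        ids = sorted(index.cores.values())
        return cls(
            counts=pd.DataFrame(index=pd.Index(ids, name="deletion_id")),
            meta=dict(index.meta),
        )

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        df = self.counts.copy()
        df.insert(0, "m", [self.meta.get(i, (pd.NA, pd.NA))[0] for i in df.index])
        df.insert(1, "n", [self.meta.get(i, (pd.NA, pd.NA))[1] for i in df.index])
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for lib in self.counts.columns:
                fh.write(
                    f"# library {lib}: unmatched={self.unmatched.get(lib, 0)} "
                    f"skipped={self.skipped.get(lib, 0)}\n"
                )
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountsTable":
        unmatched: dict[str, int] = {}
        skipped: dict[str, int] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            body_start += 1
            if line.startswith("# library "):
                fields = line[len("# library ") :].strip().split(": ")
                lib = fields[0]
                for kv in fields[1].split():
                    k, v = kv.split("=")
                    (unmatched if k == "unmatched" else skipped)[lib] = int(v)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
        meta = {
            i: (int(r["m"]), int(r["n"]))
            for i, r in df.iterrows()
            if pd.notna(r["m"])
        }
        counts = df.drop(columns=["m", "n"]).astype(int)
        return cls(counts=counts, unmatched=unmatched, skipped=skipped, meta=meta)


def read_fastq(path_or_handle) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from FASTQ, silently dropping malformed records.

    A record is four lines: ``@name``, sequence, ``+``, quality with the same
    length as the sequence.  :func:`count_reads` uses the same reader but
    additionally tallies the dropped records.  Transparent gzip support by
    file suffix.
    """
    records, handle = _fastq_records(path_or_handle)
    try:
        for name, seq in records:
            if seq is not None:
                yield name, seq
    finally:
        if handle is not None:
            handle.close()


def _fastq_iter(handle) -> Iterator[tuple[str | None, str | None]]:
    """Yield (name, seq) or (None, None) for each malformed 4-line block."""
    while True:
        header = handle.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header:
            continue
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        ok = (
            header.startswith("@")
            and plus.startswith("+")
            and len(qual) == len(seq)
            and bool(seq)
        )
        if ok:
            yield header[1:].split()[0], seq.upper()
        else:
            yield None, None


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path_or_handle):
    if hasattr(path_or_handle, "readline"):
        return _fastq_iter(path_or_handle), None
    handle = _open_maybe_gzip(path_or_handle)
    return _fastq_iter(handle), handle


def count_reads(
    reads, index: AlleleIndex
) -> tuple[pd.Series, int, int]:
    """Count perfectly matching reads against an allele index.

    ``reads`` may be a FASTQ path (optionally .gz), an open handle, or an
    iterable of sequence strings.  A read is assigned iff anchor5 and anchor3
    are found (in forward or reverse-complement orientation) and the
    intervening core equals an indexed core exactly.  Returns
    ``(counts, unmatched, skipped)``; the counts Series covers every indexed
    id, so ``counts.sum() + unmatched + skipped`` equals the total reads.
    """
    counts: dict[str, int] = {aid: 0 for aid in index.cores.values()}
    unmatched = 0
    skipped = 0
    a5, a3 = index.anchor5, index.anchor3
    handle = None
    if isinstance(reads, (str, Path)) or hasattr(reads, "readline"):
        records, handle = _fastq_records(reads)
        seq_iter = records
    else:
        seq_iter = ((None, s.upper()) for s in reads)
    try:
        for name, seq in seq_iter:
            if seq is None:
                skipped += 1
                continue
            core = _extract_core(seq, a5, a3)
            if core is None:
                core = _extract_core(reverse_complement(seq), a5, a3)
            aid = index.cores.get(core) if core is not None else None
            if aid is None:
                unmatched += 1
            else:
                counts[aid] += 1
    finally:
        if handle is not None:
            handle.close()
    if skipped:
        logger.info("count_reads: skipped %d malformed FASTQ records", skipped)
    return pd.Series(counts, dtype=int), unmatched, skipped


def _extract_core(seq: str, anchor5: str, anchor3: str) -> str | None:
    i = seq.find(anchor5)
    if i < 0:
        return None
    j = seq.find(anchor3, i + len(anchor5))
    if j < 0:
        return None
    return seq[i + len(anchor5) : j]
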