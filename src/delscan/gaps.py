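"""Homolog alignment gap patterns and their overlay on the dispensability map.

Natural homologs of the scanned protein that lack residues relative to the
reference are evolution's own deletion scan.  Given a multiple sequence
alignment containing the reference, this module maps each homolog's gap
columns (gap in homolog, residue in reference) to ungapped reference
coordinates, merges them into maximal intervals, groups identical interval
lists into unique patterns, and asks whether each gap interval falls in a
region the functional scan called dispensable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GapPattern",
    "read_alignment",
    "extract_gap_patterns",
    "overlay_with_scores",
]


@dataclass
class GapPattern:
    """One homolog's deletions relative to the reference.

    ``intervals`` are sorted, non-overlapping 1-based residue intervals of
    the ungapped reference where the homolog has gaps; ``insertions`` lists
    (reference position, length) pairs for homolog residues falling in
    reference-gap columns (position 0 = before residue 1).  ``pattern_id``
    groups homologs with identical interval lists.
    """

    homolog_id: str
    intervals: list[tuple[int, int]]
    insertions: list[tuple[int, int]] = field(default_factory=list)
    pattern_id: int | None = None


def read_alignment(path) -> dict[str, str]:
    """Aligned FASTA -> ordered {id: aligned sequence}; checks equal lengths."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences in alignment {path}")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    return records


def extract_gap_patterns(
    alignment: dict[str, str] | str,
    reference_id: str,
    exclude_terminal: bool = False,
) -> list[GapPattern]:
    """Gap patterns of every homolog relative to the reference row.

    Columns where the homolog has '-' and the reference a residue become
    reference-coordinate deletions, merged into maximal intervals; columns
    where the reference has '-' are recorded as insertions.  Homologs with
    no gap intervals are omitted.  With ``exclude_terminal``, intervals that
    belong to a homolog's leading or trailing gap run (typically incomplete
    sequences, not genuine deletions) are dropped.
    """
    if not isinstance(alignment, dict):
        alignment = read_alignment(alignment)
    if reference_id not in alignment:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    ref_row = alignment[reference_id]
    # reference coordinate of each alignment column (0 before first residue)
    ref_pos = []
    pos = 0
    for c in ref_row:
        if c != "-":
            pos += 1
        ref_pos.append(pos)

    patterns: list[GapPattern] = []
    for hid, row in alignment.items():
        if hid == reference_id:
            continue
        lead = len(row) - len(row.lstrip("-"))
        trail_start = len(row.rstrip("-"))
        intervals: list[tuple[int, int]] = []
        insertions: dict[int, int] = {}
        cur: list[int] | None = None
        for col, (hc, rc) in enumerate(zip(row, ref_row)):
            deleted = hc == "-" and rc != "-"
            if deleted and exclude_terminal and (col < lead or col >= trail_start):
                deleted = False
            if deleted:
                p = ref_pos[col]
                if cur is not None and p == cur[1] + 1:
                    cur[1] = p
                else:
                    if cur is not None:
                        intervals.append((cur[0], cur[1]))
                    cur = [p, p]
            else:
                if cur is not None:
                    intervals.append((cur[0], cur[1]))
                    cur = None
                if rc == "-" and hc != "-":
                    insertions[ref_pos[col]] = insertions.get(ref_pos[col], 0) + 1
        if cur is not None:
            intervals.append((cur[0], cur[1]))
        if intervals:
            patterns.append(
                GapPattern(
                    homolog_id=hid,
                    intervals=intervals,
                    insertions=sorted(insertions.items()),
                )
            )
    # identical interval lists share a pattern id, numbered by first appearance
    seen: dict[tuple, int] = {}
    for p in patterns:
        key = tuple(p.intervals)
        if key not in seen:
            seen[key] = len(seen) + 1
        p.pattern_id = seen[key]
    return patterns


def overlay_with_scores(
    patterns: list[GapPattern],
    scores_long: pd.DataFrame,
    dispensability_threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify each homolog gap interval against the deletion-scan scores.

    An interval [a, b] is "dispensable" if the deletion cell (m=a, n=b)
    scores above the threshold; when that exact cell is missing, the
    best-scoring scored cell within the interval's triangle stands in.
    Intervals whose triangle holds no scored cell are classified "unscored".
    """
    rows = []
    for p in patterns:
        for a, b in p.intervals:
            exact = scores_long[
                (scores_long["m"] == a) & (scores_long["n"] == b)
            ]["score"]
            if not exact.empty and pd.notna(exact.iloc[0]):
                score = float(exact.iloc[0])
                basis = "exact"
            else:
                tri = scores_long[
                    (scores_long["m"] >= a)
                    & (scores_long["n"] <= b)
                    & scores_long["score"].notna()
                ]["score"]
                if tri.empty:
                    rows.append(
                        {
                            "homolog": p.homolog_id,
                            "pattern_id": p.pattern_id,
                            "interval_start": a,
                            "interval_end": b,
                            "score": float("nan"),
                            "basis": "none",
                            "classification": "unscored",
                        }
                    )
                    continue
                score = float(tri.max())
                basis = "best_in_triangle"
            rows.append(
                {
                    "homolog": p.homolog_id,
                    "pattern_id": p.pattern_id,
                    "interval_start": a,
                    "interval_end": b,
                    "score": score,
                    "basis": basis,
                    "classification": (
                        "dispensable"
                        if score > dispensability_threshold
                        else "not_dispensable"
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "homolog",
            "pattern_id",
            "interval_start",
            "interval_end",
            "score",
            "basis",
            "classification",
        ],
    )
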