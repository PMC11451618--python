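"""Functional scoring of deletion alleles from pooled selection counts.

Each deletion allele's functional score in a replicate is the ratio of its
read frequency under selection (CRISPR-ON: galactose, Cas9 plus the lethal
constant gRNA induced) to its frequency without selection (CRISPR-OFF:
glucose).  A high ratio means cells carrying the deletion survived the
lethal cut, i.e. the deleted protein still inhibits Cas9.  Alleles with
fewer than ``min_glucose_reads`` reads in the unselected library are treated
as unobserved in that replicate.  Replicates are merged with the median when
all replicates observed an allele (robust to escaper outliers), the minimum
of the observed values otherwise, and a missing cell when none did.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .match import CountsTable, PARENTAL_ID

__all__ = [
    "ScoreMatrix",
    "normalize_counts",
    "enrichment",
    "merge_replicates",
    "merge_replicates_mean",
    "score_replicates",
    "export_matrix",
    "plot_heatmap",
]

DEFAULT_MIN_GLUCOSE_READS = 5


def normalize_counts(column: pd.Series) -> pd.Series:
    """Per-allele read frequencies: count / total assigned reads in the library.

    The denominator is the total of allele-assigned reads only; unmatched
    reads (escapers, NHEJ products) are excluded because their fraction
    differs systematically between selected and unselected conditions.
    """
    total = column.sum()
    if total <= 0:
        raise ValueError("zero-total library cannot be normalized")
    return column / total


def enrichment(
    galactose_counts: pd.Series,
    glucose_counts: pd.Series,
    min_glucose_reads: int = DEFAULT_MIN_GLUCOSE_READS,
) -> pd.Series:
    """Per-deletion enrichment e(d) = gal frequency / glu frequency, NaN if unobserved.

    An allele is observed in a replicate only if its unselected (glucose)
    library holds at least ``min_glucose_reads`` reads; below that the score
    is NaN regardless of the selected count.  A zero selected count gives
    e = 0 (complete depletion) — no pseudocounts.
    """
    galactose_counts, glucose_counts = galactose_counts.align(
        glucose_counts, join="outer", fill_value=0
    )
    gal_freq = normalize_counts(galactose_counts)
    glu_freq = normalize_counts(glucose_counts)
    observed = glucose_counts >= min_glucose_reads
    e = pd.Series(np.nan, index=gal_freq.index, dtype=float)
    e[observed] = gal_freq[observed] / glu_freq[observed]
    return e


def merge_replicates(replicate_scores: pd.DataFrame) -> pd.Series:
    """Median across replicates when all observed, else minimum of the observed.

    Per allele: all replicates observed -> median; some but not all observed
    (e.g. two of three) -> the lowest observed value; none -> NaN.  Taking
    the lower value when a replicate is missing is conservative against
    escaper-driven inflation.  Permutation-invariant in the replicates.
    """
    n_obs = replicate_scores.notna().sum(axis=1)
    merged = replicate_scores.min(axis=1)
    full = n_obs == replicate_scores.shape[1]
    merged[full] = replicate_scores[full].median(axis=1)
    merged[n_obs == 0] = np.nan
    return merged


def merge_replicates_mean(replicate_scores: pd.DataFrame) -> pd.Series:
    """Mean of the observed replicate values (NaN when none observed)."""
    return replicate_scores.mean(axis=1)


@dataclass
class ScoreMatrix:
    """Per-replicate and merged deletion scores with codon coordinates."""

    replicates: pd.DataFrame  # index: deletion ids; one column per replicate
    merged: pd.Series
    meta: dict[str, tuple[int, int]] = field(default_factory=dict)

    def long(self, values: pd.Series | None = None) -> pd.DataFrame:
        """Long-format (m, n, score) table over deletion cells; NaN = missing."""
        values = self.merged if values is None else values
        rows = []
        for aid, score in values.items():
            if aid not in self.meta:
                continue
            m, n = self.meta[aid]
            rows.append({"m": m, "n": n, "score": score})
        return (
            pd.DataFrame(rows, columns=["m", "n", "score"])
            .sort_values(["m", "n"])
            .reset_index(drop=True)
        )


def score_replicates(
    counts: CountsTable,
    replicates: list[str] | None = None,
    on_condition: str = "galactose",
    off_condition: str = "glucose",
    min_glucose_reads: int = DEFAULT_MIN_GLUCOSE_READS,
    merge: str = "median",
) -> ScoreMatrix:
    """Score every replicate from a counts table with ``rep_condition`` columns.

    Library columns must be named ``{replicate}_{condition}``.  The parental
    (unedited locus) category is excluded from scoring but its reads still
    count toward library totals via prior assignment — here totals are over
    deletion alleles only, so it is dropped before normalization.
    """
    cols = list(counts.counts.columns)
    if replicates is None:
        replicates = sorted(
            {c.rsplit("_", 1)[0] for c in cols if c.endswith("_" + off_condition)}
        )
    table = counts.counts.drop(index=[PARENTAL_ID], errors="ignore")
    rep_scores = {}
    for rep in replicates:
        gal, glu = f"{rep}_{on_condition}", f"{rep}_{off_condition}"
        if gal not in cols or glu not in cols:
            raise ValueError(f"missing libraries for replicate {rep!r}")
        rep_scores[rep] = enrichment(table[gal], table[glu], min_glucose_reads)
    replicate_df = pd.DataFrame(rep_scores)
    if merge == "median":
        merged = merge_replicates(replicate_df)
    elif merge == "mean":
        merged = merge_replicates_mean(replicate_df)
    else:
        raise ValueError(f"unknown merge rule {merge!r}")
    meta = {k: v for k, v in counts.meta.items() if k in replicate_df.index}
    return ScoreMatrix(replicates=replicate_df, merged=merged, meta=meta)


def export_matrix(scores: ScoreMatrix, path=None, header_comment: str | None = None) -> pd.DataFrame:
    """Long-format table (m, n, per-replicate scores, merged); NaN rows kept.

    Missing cells — alleles observed in no replicate — are emitted with an
    empty score so the triangular map's blank pixels stay explicit.
    """
    df = scores.long()
    for rep in scores.replicates.columns:
        rep_long = scores.long(scores.replicates[rep])
        df[rep] = rep_long["score"].to_numpy()
    if path is not None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)
    return df


def plot_heatmap(scores: ScoreMatrix, path, vmax: float | None = None) -> None:
    """Triangular deletion-start x deletion-end heatmap of merged scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    long = scores.long()
    if long.empty:
        raise ValueError("no scored cells to plot")
    m_max = int(long["n"].max())
    grid = np.full((m_max + 1, m_max + 1), np.nan)
    for _, row in long.iterrows():
        grid[int(row["m"]), int(row["n"])] = row["score"]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid, origin="lower", cmap="viridis", vmax=vmax)
    ax.set_xlabel("deletion end codon n")
    ax.set_ylabel("deletion start codon m")
    fig.colorbar(im, ax=ax, label="CRISPR-ON / CRISPR-OFF enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
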