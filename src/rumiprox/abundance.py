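"""KO abundance data model: read resolution, normalization, filtering, I/O.

The feature unit is the KEGG Orthologue (KO, ``K#####``). Reads are
assigned to a KO only when all of their best alignment hits agree on a
single KO; ambiguous reads are dropped. Per-animal counts are normalized
to relative abundances (closure: each animal row sums to 1), and genes
are filtered by prevalence (absent from too many animals) and mean
relative abundance before any modelling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"^K\d{5}$")


@dataclass
class AbundanceMatrix:
    """Animals x KO relative abundances.

    ``values`` is a DataFrame with animal ids as the index and KO ids as
    columns; after :func:`normalize` every row sums to 1.
    """

    values: pd.DataFrame
    counts: pd.DataFrame | None = None  # raw counts, if known

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].tolist()
            raise ValueError(f"duplicate KO ids: {dup}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundances")
        odd = [c for c in cols if not KO_PATTERN.match(str(c))]
        if odd:
            logger.warning("%d gene ids do not match K#####: %s ...", len(odd), odd[:5])

    @property
    def animals(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_sums(self) -> np.ndarray:
        return self.values.to_numpy().sum(axis=1)


@dataclass
class ReadHitTable:
    """Per-read best-hit KO lists (ties at the best alignment quality)."""

    hits: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for read, kos in self.hits.items():
            if not kos:
                raise ValueError(f"read {read!r} has an empty hit list")


def resolve_ko_counts(table: ReadHitTable) -> tuple[dict[str, int], int]:
    """Count reads per KO, keeping only unambiguous assignments.

    A read contributes one count to a KO iff the set of distinct KOs
    among its best hits has size one; otherwise it is ignored. Returns
    ``(counts, n_ignored)``; counts + ignored always equals input reads.
    """
    counts: dict[str, int] = {}
    ignored = 0
    for read, kos in table.hits.items():
        unique = set(kos)
        if len(unique) == 1:
            ko = next(iter(unique))
            counts[ko] = counts.get(ko, 0) + 1
        else:
            ignored += 1
    if ignored:
        logger.info("%d ambiguous reads ignored", ignored)
    return counts, ignored


def normalize(counts: pd.DataFrame) -> AbundanceMatrix:
    """Convert per-animal KO counts to relative abundances (row closure)."""
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"animals with zero assigned reads: {list(zero.index)}")
    rel = counts.div(totals, axis=0)
    return AbundanceMatrix(values=rel, counts=counts)


def filter_genes(
    matrix: AbundanceMatrix,
    max_absent: int = 2,
    min_mean: float = 1e-5,
    filter_mode: str = "either",
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Prevalence / mean-abundance gene filter.

    A gene fails the prevalence rule when it is absent (exactly zero) from
    more than ``max_absent`` animals, and the abundance rule when its mean
    relative abundance is below ``min_mean`` (0.001% = 1e-5 as a fraction).
    With ``filter_mode="either"`` (default) a gene is removed when it fails
    either rule — i.e. it must pass both to be retained; with
    ``"conjunctive"`` it is removed only when it fails both.

    Returns the filtered matrix and a removal log naming the rule(s) each
    removed gene failed. Idempotent: filtering a filtered matrix is a no-op.
    """
    if filter_mode not in ("either", "conjunctive"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    vals = matrix.values
    n_absent = (vals == 0).sum(axis=0)
    means = vals.mean(axis=0)
    fail_prev = n_absent > max_absent
    fail_mean = means < min_mean
    removed_mask = (fail_prev | fail_mean) if filter_mode == "either" else (fail_prev & fail_mean)
    log = pd.DataFrame({
        "ko": vals.columns[removed_mask],
        "n_absent": n_absent[removed_mask].to_numpy(),
        "mean_abundance": means[removed_mask].to_numpy(),
        "failed_prevalence": fail_prev[removed_mask].to_numpy(),
        "failed_mean": fail_mean[removed_mask].to_numpy(),
    })
    kept = vals.loc[:, ~removed_mask]
    logger.info("filter_genes: %d -> %d genes (%d removed)",
                vals.shape[1], kept.shape[1], int(removed_mask.sum()))
    counts = None if matrix.counts is None else matrix.counts.loc[:, ~removed_mask]
    return AbundanceMatrix(values=kept, counts=counts), log


def read_abundance(path) -> AbundanceMatrix:
    """Read the abundance TSV (header ``animal_id<TAB>K...``; fractions)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = pd.Index(header)
    if dup.duplicated().any():
        raise ValueError(f"duplicate KO columns: {dup[dup.duplicated()].tolist()}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance value: {exc}") from exc
    if table.isna().any().any():
        rows, cols = np.where(table.isna())
        r, c = table.index[rows[0]], table.columns[cols[0]]
        raise ValueError(f"missing cell at animal {r!r}, gene {c!r}")
    if table.index.duplicated().any():
        raise ValueError(f"duplicate animal ids: {table.index[table.index.duplicated()].tolist()}")
    return AbundanceMatrix(values=table)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    """Write the abundance TSV, round-tripping at 12 significant digits."""
    matrix.values.to_csv(path, sep="\t", index_label="animal_id",
                         float_format="%.12g")


def read_annotation(path) -> pd.DataFrame:
    """KO annotation TSV: ko<TAB>gene<TAB>description<TAB>pathways."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    need = {"ko", "gene"}
    if not need <= set(ann.columns):
        raise ValueError(f"annotation file needs columns {sorted(need)}")
    if ann["ko"].duplicated().any():
        raise ValueError("duplicate KO ids in annotation")
    return ann
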