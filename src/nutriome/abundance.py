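"""Genus-level abundance tables: reading, validation, depth normalization.

The table is the substrate of every microbiome stage: one row per sample,
one column per genus, values either sequencing counts or relative
abundances on the simplex.  Downstream feature scoring always works on
relative abundances; alpha-diversity estimators (Chao1) need counts, so
both modes are first-class and conversions are explicit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenusAbundanceTable",
    "AbundanceParseError",
    "read_abundance_table",
    "write_abundance_table",
    "normalize_to_min_depth",
    "to_relative",
]

_RELATIVE_ROW_TOL = 1e-6


class AbundanceParseError(ValueError):
    """Raised when an abundance table fails structural validation."""


@dataclass
class GenusAbundanceTable:
    """Samples x genera abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with genus names as columns.
        All entries must be non-negative.
    mode:
        ``"counts"`` (non-negative integers, sequencing depth = row sum)
        or ``"relative"`` (rows sum to 1 within ``1e-6``).
    phylum_of:
        Optional genus -> phylum map, needed only for phylum-ratio
        features.
    """

    data: pd.DataFrame
    mode: str = "counts"
    phylum_of: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise AbundanceParseError(f"duplicate sample ids: {dupes}")
        if not self.data.columns.is_unique:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise AbundanceParseError(
                f"duplicate genus columns (merge them first): {dupes}"
            )
        values = self.data.to_numpy(dtype=float)
        if values.size and np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise AbundanceParseError(
                f"missing value at sample {self.data.index[r]!r}, "
                f"genus {self.data.columns[c]!r}"
            )
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise AbundanceParseError(
                f"negative abundance {values[r, c]} at sample "
                f"{self.data.index[r]!r}, genus {self.data.columns[c]!r}"
            )
        if self.mode == "relative" and len(self.data):
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _RELATIVE_ROW_TOL
            if bad.any():
                sid = self.data.index[np.argmax(bad)]
                raise AbundanceParseError(
                    f"relative-mode row {sid!r} sums to {sums[np.argmax(bad)]:.8f}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genus_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def depths(self) -> pd.Series:
        """Row sums (sequencing depth in counts mode)."""
        return self.data.sum(axis=1)

    def copy(self) -> "GenusAbundanceTable":
        return replace(self, data=self.data.copy())


def read_abundance_table(
    path, mode: str = "counts", phylum_of: dict[str, str] | None = None
) -> GenusAbundanceTable:
    """Read a TSV abundance table (first column ``sample_id``).

    Duplicate genus columns are merged by summation with a logged warning;
    negative or missing cells raise :class:`AbundanceParseError` naming
    the offending coordinates.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise AbundanceParseError(f"cannot parse {path}: {exc}") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise AbundanceParseError(f"non-numeric cell in {path}: {exc}") from exc
    # pandas mangles duplicate headers (X, X.1, ...); restore the originals
    # so duplicates can be merged by name
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) == df.shape[1]:
        df.columns = header
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        logger.warning("merging duplicate genus columns by summation: %s", dupes)
        df = df.T.groupby(level=0, sort=False).sum().T
    df.index = df.index.astype(str)
    df.index.name = None  # "sample_id" is a serialization detail, not data
    return GenusAbundanceTable(data=df, mode=mode, phylum_of=phylum_of)


def write_abundance_table(table: GenusAbundanceTable, path) -> None:
    """Write the table as TSV with the index labelled ``sample_id``."""
    table.data.rename_axis("sample_id").to_csv(path, sep="\t")


def _largest_remainder_round(row: np.ndarray, target: int, genus_names) -> np.ndarray:
    """Round ``row`` (non-negative reals summing ~ target) to integers
    summing exactly to ``target``; remainder ties break by genus name."""
    floors = np.floor(row).astype(int)
    short = target - int(floors.sum())
    if short == 0:
        return floors
    remainders = row - floors
    # sort by (-remainder, genus name): biggest remainders first,
    # lexicographic genus order as the deterministic tie-break
    order = sorted(range(len(row)), key=lambda j: (-remainders[j], str(genus_names[j])))
    out = floors.copy()
    for j in order[:short]:
        out[j] += 1
    return out


def normalize_to_min_depth(
    table: GenusAbundanceTable,
    method: str = "subsample",
    seed: int | np.random.Generator | None = None,
) -> GenusAbundanceTable:
    """Normalize every sample to the depth of the shallowest sample.

    ``subsample`` rarefies: draws reads without replacement down to the
    minimum row sum (multivariate hypergeometric), the standard practice
    for amplicon count tables.  ``rescale`` multiplies each row by
    ``min_depth / depth`` and rounds with largest-remainder correction so
    row sums match the minimum depth exactly.
    """
    if table.mode != "counts":
        raise ValueError("depth normalization requires a counts-mode table")
    if method not in ("subsample", "rescale"):
        raise ValueError(f"unknown method {method!r}")
    depths = table.depths().to_numpy()
    if (depths <= 0).any():
        zero = [s for s, d in zip(table.sample_ids, depths) if d <= 0]
        raise ValueError(f"zero-depth samples cannot be normalized: {zero}")
    min_depth = int(round(depths.min()))
    counts = table.data.to_numpy()
    int_counts = np.rint(counts).astype(np.int64)
    if method == "subsample":
        if not np.allclose(counts, int_counts):
            raise ValueError("subsampling requires integer counts")
        rng = np.random.default_rng(seed)
        out = np.empty_like(int_counts)
        for i in range(len(int_counts)):
            out[i] = rng.multivariate_hypergeometric(int_counts[i], min_depth)
    else:
        out = np.empty_like(int_counts)
        for i in range(len(counts)):
            scaled = counts[i] * (min_depth / depths[i])
            out[i] = _largest_remainder_round(scaled, min_depth, table.genus_names)
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    logger.info("normalized %d samples to depth %d (%s)", len(df), min_depth, method)
    return GenusAbundanceTable(data=df, mode="counts", phylum_of=table.phylum_of)


def to_relative(table: GenusAbundanceTable) -> GenusAbundanceTable:
    """Convert to relative abundances (rows on the unit simplex).

    Idempotent: applying it to a relative-mode table returns an equal
    table.  A zero-sum row has no defined composition and raises.
    """
    sums = table.depths()
    if (sums <= 0).any():
        zero = list(sums.index[sums <= 0])
        raise ValueError(f"zero-sum rows have no relative composition: {zero}")
    df = table.data.div(sums, axis=0)
    return GenusAbundanceTable(data=df, mode="relative", phylum_of=table.phylum_of)
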