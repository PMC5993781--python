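"""Library-size normalization and abundance summaries.

Common scaling multiplies every library by (smallest library size / its own
size) and rounds to the nearest integer (half away from zero), reproducing
the expectation of infinitely repeated rarefaction without discarding reads
at random. Downstream summaries work on row-normalized relative abundances.
Shannon diversity is reported in nats.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # counts are non-negative, so half-away-from-zero == half-up
    return np.floor(x + 0.5)


def common_scale(counts: pd.DataFrame, reference_size: int | None = None) -> pd.DataFrame:
    """Scale every library to a common reference size.

    Each count c in a library of total size L becomes round(c * S / L) where
    S is ``reference_size`` or, by default, the smallest library size in the
    table. The minimum-size library is returned unchanged.
    """
    sums = counts.sum(axis=1)
    zero = sums == 0
    if zero.any():
        raise ValueError(f"zero-sum libraries: {sorted(counts.index[zero])[:10]}")
    min_size = int(sums.min())
    if reference_size is None:
        reference_size = min_size
    elif reference_size > min_size:
        raise ValueError(
            f"reference_size {reference_size} exceeds smallest library size {min_size}"
        )
    scaled = _round_half_away(
        counts.to_numpy(dtype=float) * (reference_size / sums.to_numpy()[:, None])
    )
    logger.info("common scaling to reference library size S=%d", reference_size)
    out = pd.DataFrame(
        scaled.astype(np.int64), index=counts.index, columns=counts.columns
    )
    out.attrs["reference_size"] = reference_size
    return out


def to_relative(counts: pd.DataFrame, level: str = "otu") -> pd.DataFrame:
    """Row-normalize a count (or abundance) table to fractions summing to 1."""
    sums = counts.sum(axis=1)
    zero = sums == 0
    if zero.any():
        raise ValueError(f"zero-sum rows: {sorted(counts.index[zero])[:10]}")
    rel = counts.div(sums, axis=0).astype(float)
    rel.attrs["level"] = level
    return rel


def aggregate_by_rank(
    rel: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum feature columns within a taxonomic rank; row sums are preserved.

    "unclassified" is kept as a column of its own.
    """
    if rank not in ("phylum", "genus"):
        raise ValueError(f"unsupported rank {rank!r}; expected 'phylum' or 'genus'")
    missing = sorted(set(rel.columns) - set(taxonomy.index))
    if missing:
        raise ValueError(f"features without taxonomy entries: {missing[:10]}")
    labels = taxonomy.loc[list(rel.columns), rank].fillna("unclassified")
    out = rel.T.groupby(labels.to_numpy()).sum().T
    out = out[sorted(out.columns)]
    out.attrs["level"] = rank
    return out


def top_n_features(rel: pd.DataFrame, n: int) -> list[str]:
    """Features ranked by grand total relative abundance, descending.

    Ties are broken lexicographically by feature id (ascending).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = rel.sum(axis=0)
    order = sorted(rel.columns, key=lambda f: (-totals[f], f))
    return order[: min(n, len(order))]


def prevalence_spectrum(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Number of OTUs present in exactly k infants, for k = 1..n_infants.

    An OTU is present in an infant iff it has count > 0 in at least one of
    that infant's samples; OTUs absent everywhere contribute nowhere.
    Presence is assessed on the table passed in (by convention the unscaled
    counts, since scaling can erase singletons).
    """
    infants = meta.loc[counts.index, "infant_id"]
    if len(infants) == 0:
        raise ValueError("no samples")
    present = (counts > 0).groupby(infants.to_numpy()).any()
    k = present.sum(axis=0)  # infants per OTU
    n_infants = present.shape[0]
    spectrum = pd.Series(0, index=pd.RangeIndex(1, n_infants + 1, name="n_infants"))
    observed = k[k > 0].value_counts()
    spectrum.loc[observed.index] = observed
    return spectrum


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample observed OTU count and Shannon entropy (natural log)."""
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("zero-sum rows")
    p = counts.to_numpy(dtype=float) / sums.to_numpy()[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {
            "observed_otus": (counts > 0).sum(axis=1).to_numpy(),
            "shannon": -plogp.sum(axis=1),
        },
        index=counts.index,
    )
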