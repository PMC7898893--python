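"""Filtering, scaling and pooling of eDNA per-allele read counts.

The water-sample pipeline runs in a fixed order: drop alleles under a
minimum absolute read depth per sample, scale each (sample, locus) to 100
reads so frequency filters act uniformly across sequencing depths, remove
sub-threshold alleles per sample, pool replicate samples per unit
(mesocosm or field site), and finally either read off allele frequencies
or apply a sensitivity threshold and build a mixture profile.  Scaled
counts stay fractional throughout -- rounding at 100 reads would erase
sub-1% alleles before the frequency filter could act on them -- and the
low-frequency filter removes rows without renormalising; frequencies are
recomputed from surviving counts when they are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mixture import MixtureProfile

__all__ = [
    "ThresholdScheme",
    "COUNT_COLUMNS",
    "validate_counts",
    "min_read_filter",
    "scale_to_100",
    "low_freq_filter",
    "pool_replicates",
    "edna_allele_freqs",
    "variable_threshold",
    "threshold_filter",
    "to_mixture_profile",
    "freqs_to_dict",
    "freqs_to_frame",
    "edna_pipeline",
]

log = logging.getLogger(__name__)

COUNT_COLUMNS = ["sample", "locus", "allele", "reads"]


@dataclass(frozen=True)
class ThresholdScheme:
    """A read-frequency filtering scheme: one fixed cutoff, or richness-variable.

    The variable scheme interpolates log-linearly between ``t_max`` at
    ``r_min`` alleles per locus and ``t_min`` at ``r_max``: rich loci carry
    true low-frequency alleles, so their cutoff relaxes from 0.1 down to
    0.001 as allelic richness rises.
    """

    kind: str = "fixed"  # "fixed" | "variable"
    t: float = 0.01
    t_max: float = 0.1
    t_min: float = 0.001
    r_min: int = 2
    r_max: int = 21

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "variable"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "fixed" and not (0.0 < self.t < 1.0):
            raise ValueError("fixed threshold must lie in (0, 1)")
        if not (0.0 < self.t_min <= self.t_max < 1.0):
            raise ValueError("require 0 < t_min <= t_max < 1")
        if self.r_min >= self.r_max:
            raise ValueError("require r_min < r_max")

    @property
    def label(self) -> str:
        return f"fixed_{self.t:g}" if self.kind == "fixed" else "variable"


def validate_counts(table: pd.DataFrame, value: str = "reads") -> pd.DataFrame:
    cols = ["sample", "locus", "allele", value]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if (table[value] < 0).any():
        raise ValueError(f"negative {value} in count table")
    if table.duplicated(["sample", "locus", "allele"]).any():
        raise ValueError("duplicate (sample, locus, allele) rows")
    return table[cols]


def min_read_filter(table: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Drop alleles with fewer than ``min_reads`` reads within each sample."""
    table = validate_counts(table)
    kept = table[table["reads"] >= min_reads].reset_index(drop=True)
    log.info("min_read_filter(%d): %d -> %d rows", min_reads, len(table), len(kept))
    return kept


def scale_to_100(table: pd.DataFrame) -> pd.DataFrame:
    """Scale reads within each (sample, locus) to total 100, keeping fractions."""
    table = validate_counts(table)
    table = table[table["reads"] > 0].copy()
    totals = table.groupby(["sample", "locus"])["reads"].transform("sum")
    table["scaled_reads"] = 100.0 * table["reads"] / totals
    return table.drop(columns="reads").reset_index(drop=True)


def low_freq_filter(scaled: pd.DataFrame, min_freq: float = 0.01) -> pd.DataFrame:
    """Remove alleles below ``min_freq`` within-locus frequency per sample.

    Surviving scaled counts are left as-is (no renormalisation).
    """
    scaled = validate_counts(scaled, "scaled_reads")
    totals = scaled.groupby(["sample", "locus"])["scaled_reads"].transform("sum")
    freq = scaled["scaled_reads"] / totals
    kept = scaled[freq >= min_freq].reset_index(drop=True)
    log.info("low_freq_filter(%g): %d -> %d rows", min_freq, len(scaled), len(kept))
    return kept


def pool_replicates(
    scaled: pd.DataFrame, unit_of: Mapping[str, str]
) -> pd.DataFrame:
    """Sum scaled reads across replicate samples of the same unit.

    ``unit_of`` maps sample id -> unit id (e.g. both water samples of a
    mesocosm to the mesocosm).  Loci present in only some replicates
    contribute from those replicates alone (union semantics).
    """
    scaled = validate_counts(scaled, "scaled_reads")
    unknown = set(scaled["sample"]) - set(unit_of)
    if unknown:
        raise ValueError(f"samples without a unit assignment: {sorted(unknown)}")
    out = scaled.copy()
    out["sample"] = out["sample"].map(unit_of)
    out = (
        out.groupby(["sample", "locus", "allele"], as_index=False)["scaled_reads"]
        .sum()
    )
    return out


def edna_allele_freqs(pooled: pd.DataFrame) -> pd.DataFrame:
    """Read-frequency allele frequencies per locus from pooled scaled counts.

    Counts are summed across units first, so the result is one population
    frequency table (columns locus, allele, freq; sums to 1 per locus).
    """
    pooled = validate_counts(pooled, "scaled_reads")
    by_locus = (
        pooled.groupby(["locus", "allele"], as_index=False)["scaled_reads"].sum()
    )
    by_locus = by_locus[by_locus["scaled_reads"] > 0]
    totals = by_locus.groupby("locus")["scaled_reads"].transform("sum")
    by_locus["freq"] = by_locus["scaled_reads"] / totals
    return by_locus.drop(columns="scaled_reads").reset_index(drop=True)


def variable_threshold(richness: int, scheme: ThresholdScheme) -> float:
    """Richness-dependent cutoff: log-linear from t_max at r_min to t_min at r_max."""
    if richness < 1:
        raise ValueError("allelic richness must be >= 1")
    frac = (richness - scheme.r_min) / (scheme.r_max - scheme.r_min)
    frac = min(1.0, max(0.0, frac))
    return 10.0 ** (
        np.log10(scheme.t_max)
        + (np.log10(scheme.t_min) - np.log10(scheme.t_max)) * frac
    )


def threshold_filter(
    pooled: pd.DataFrame,
    scheme: ThresholdScheme,
    richness: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Remove alleles under the scheme's within-locus frequency cutoff per sample."""
    pooled = validate_counts(pooled, "scaled_reads")
    if scheme.kind == "variable":
        if richness is None:
            raise ValueError("variable scheme requires per-locus allelic richness")
        cutoff = pooled["locus"].map(
            lambda loc: variable_threshold(int(richness[loc]), scheme)
        )
    else:
        cutoff = scheme.t
    totals = pooled.groupby(["sample", "locus"])["scaled_reads"].transform("sum")
    freq = pooled["scaled_reads"] / totals
    kept = pooled[freq >= cutoff].reset_index(drop=True)
    log.info(
        "threshold_filter(%s): %d -> %d rows", scheme.label, len(pooled), len(kept)
    )
    return kept


def to_mixture_profile(
    filtered: pd.DataFrame,
    pop: Mapping[str, Mapping[str, float]] | None = None,
    sample: str | None = None,
    source: str = "eDNA",
) -> tuple[MixtureProfile, int]:
    """Observed allele sets per locus for one unit, restricted to ``pop``.

    Returns the profile and the count of observed alleles dropped because
    they carry no population frequency.
    """
    filtered = validate_counts(filtered, "scaled_reads")
    if sample is not None:
        filtered = filtered[filtered["sample"] == sample]
    elif filtered["sample"].nunique() > 1:
        raise ValueError("multiple units present; pass sample=")
    loci: dict[str, frozenset] = {}
    dropped = 0
    for locus, grp in filtered.groupby("locus"):
        alleles = set(grp["allele"])
        if pop is not None:
            known = set(pop.get(locus, {}))
            dropped += len(alleles - known)
            alleles &= known
        if alleles:
            loci[str(locus)] = frozenset(alleles)
    return MixtureProfile(loci=loci, source=source), dropped


def freqs_to_dict(freqs: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Long-format frequency table (locus, allele, freq) -> nested dict."""
    out: dict[str, dict[str, float]] = {}
    for locus, grp in freqs.groupby("locus"):
        out[str(locus)] = dict(zip(grp["allele"], grp["freq"].astype(float)))
    return out


def freqs_to_frame(freqs: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    rows = [
        {"locus": locus, "allele": allele, "freq": f}
        for locus, d in freqs.items()
        for allele, f in d.items()
    ]
    return pd.DataFrame(rows, columns=["locus", "allele", "freq"])


def edna_pipeline(
    table: pd.DataFrame,
    unit_of: Mapping[str, str],
    *,
    min_reads: int = 10,
    min_freq: float = 0.01,
) -> pd.DataFrame:
    """Standard per-sample filtering then pooling: the shared front half.

    min_read_filter -> scale_to_100 -> low_freq_filter -> pool_replicates.
    Downstream callers either estimate frequencies or threshold-filter and
    build mixture profiles from the returned pooled scaled counts.
    """
    return pool_replicates(
        low_freq_filter(scale_to_100(min_read_filter(table, min_reads)), min_freq),
        unit_of,
    )
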