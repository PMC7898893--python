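"""Agreement statistics between eDNA- and tissue-derived allele frequencies,
sample ordination, and the bootstrap simulated-mixture experiment.

Frequency tables are aligned on the union of alleles per locus (an allele
absent from one source pairs with frequency 0) before correlating, so
non-detection counts against agreement rather than being silently ignored.
Ordination follows the usual population-genetic recipe: centre and scale
each allele-frequency column, take principal components, and measure
pairwise Euclidean distances over *all* axes (an orthogonal transform, so
the distances equal those on the scaled data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .edna import ThresholdScheme, threshold_filter, to_mixture_profile
from .mixture import estimate_contributors

__all__ = [
    "FrequencyComparison",
    "SampleOrdination",
    "align_and_correlate",
    "pca_samples",
    "bootstrap_mixture_experiment",
    "bias_summary",
]


@dataclass
class FrequencyComparison:
    aligned: pd.DataFrame           # locus, allele, freq1, freq2
    overall_r: float
    per_locus_r: pd.DataFrame       # locus, n_alleles, r


@dataclass
class SampleOrdination:
    samples: list
    scores: np.ndarray              # samples x axes (all axes kept)
    explained_variance_ratio: np.ndarray
    distances: pd.DataFrame         # symmetric, zero diagonal
    dropped_columns: int = 0


def _align(
    f1: Mapping[str, Mapping[str, float]], f2: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    rows = []
    for locus in sorted(set(f1) | set(f2)):
        a1, a2 = f1.get(locus, {}), f2.get(locus, {})
        for allele in sorted(set(a1) | set(a2)):
            rows.append(
                {
                    "locus": locus,
                    "allele": allele,
                    "freq1": float(a1.get(allele, 0.0)),
                    "freq2": float(a2.get(allele, 0.0)),
                }
            )
    return pd.DataFrame(rows, columns=["locus", "allele", "freq1", "freq2"])


def align_and_correlate(
    f1: Mapping[str, Mapping[str, float]],
    f2: Mapping[str, Mapping[str, float]],
    min_locus_alleles: int = 3,
) -> FrequencyComparison:
    """Pearson correlation of two allele-frequency tables, overall and per locus.

    Per-locus r is reported only for loci whose allele union has at least
    ``min_locus_alleles`` entries (two-allele loci always give r = +/-1 and
    carry no information about agreement).  Zero-variance vectors yield NaN.
    """
    aligned = _align(f1, f2)
    if len(aligned) < 2:
        raise ValueError("need at least two aligned allele entries")

    def _r(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            return float("nan")
        return float(sps.pearsonr(a, b).statistic)

    overall = _r(aligned["freq1"].to_numpy(), aligned["freq2"].to_numpy())
    per_locus = []
    for locus, grp in aligned.groupby("locus"):
        if len(grp) < min_locus_alleles:
            continue
        per_locus.append(
            {
                "locus": locus,
                "n_alleles": len(grp),
                "r": _r(grp["freq1"].to_numpy(), grp["freq2"].to_numpy()),
            }
        )
    return FrequencyComparison(
        aligned=aligned,
        overall_r=overall,
        per_locus_r=pd.DataFrame(per_locus, columns=["locus", "n_alleles", "r"]),
    )


def pca_samples(freq_matrix: pd.DataFrame) -> SampleOrdination:
    """PCA of a samples x alleles frequency matrix (centred, unit-scaled).

    Zero-variance columns are dropped (they cannot be scaled) and counted.
    All principal axes are retained; the distance matrix is Euclidean over
    the full score space.
    """
    if len(freq_matrix) < 2:
        raise ValueError("need at least two samples")
    X = freq_matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if keep.sum() < 2:
        raise ValueError("fewer than two columns with variance")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(Xs.shape[0] - 1, Xs.shape[1]))
    scores = pca.fit_transform(Xs)
    samples = list(freq_matrix.index)
    dist = pd.DataFrame(
        squareform(pdist(scores)), index=samples, columns=samples
    )
    return SampleOrdination(
        samples=samples,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        distances=dist,
        dropped_columns=dropped,
    )


def bootstrap_mixture_experiment(
    mesocosm_counts: pd.DataFrame,
    unit_sizes: Mapping[str, int],
    pop: Mapping[str, Mapping[str, float]],
    schemes: Sequence[ThresholdScheme],
    *,
    richness: Mapping[str, int] | None = None,
    n_reps: int = 1000,
    draw_range: tuple[int, int] = (2, 12),
    x_grid: Sequence[int] = range(1, 101),
    seed: int = 0,
) -> pd.DataFrame:
    """Contributor estimates for random combinations of mesocosm read pools.

    Each replicate draws a uniform number of mesocosms in ``draw_range``
    without replacement, sums their pooled scaled read counts, filters under
    every scheme, and estimates the contributor count; the truth is the
    total fish across the drawn units.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    units = sorted(unit_sizes)
    lo, hi = draw_range
    if hi > len(units):
        raise ValueError(f"draw size {hi} exceeds {len(units)} available mesocosms")
    by_unit = {
        u: grp.drop(columns="sample")
        for u, grp in mesocosm_counts.groupby("sample")
    }
    missing = set(units) - set(by_unit)
    if missing:
        raise ValueError(f"no read counts for units {sorted(missing)}")
    rows = []
    for rep in range(n_reps):
        size = int(rng.integers(lo, hi + 1))
        drawn = list(rng.choice(units, size=size, replace=False))
        truth = int(sum(unit_sizes[u] for u in drawn))
        mix = (
            pd.concat([by_unit[u] for u in drawn], ignore_index=True)
            .groupby(["locus", "allele"], as_index=False)["scaled_reads"]
            .sum()
        )
        mix.insert(0, "sample", "mix")
        for scheme in schemes:
            filtered = threshold_filter(mix, scheme, richness)
            profile, dropped = to_mixture_profile(filtered, pop)
            est = estimate_contributors(profile, pop, x_grid, true_x=truth)
            rows.append(
                {
                    "replicate": rep,
                    "n_mesocosms": size,
                    "mesocosms": ",".join(sorted(drawn)),
                    "true_x": truth,
                    "scheme": scheme.label,
                    "x_hat": est.x_hat,
                    "bias": est.bias,
                    "boundary": est.boundary,
                    "dropped_alleles": dropped,
                }
            )
    return pd.DataFrame(rows)


def bias_summary(
    results: pd.DataFrame, by: Sequence[str] = ("scheme", "true_x")
) -> pd.DataFrame:
    """Mean and spread of estimation bias grouped by scheme and truth."""
    if results.empty:
        raise ValueError("empty result table")
    out = (
        results.groupby(list(by))["bias"]
        .agg(mean_bias="mean", sd_bias="std", n="size")
        .reset_index()
    )
    return out
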