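"""Diploid microsatellite genotype calling, locus QC and tissue allele frequencies.

Calls follow simple depth rules: the top allele by read count is always
carried; a second allele is accepted only if it holds at least 20% of the
locus reads for that individual and at least 10 reads; an individual with
under 10 reads on its top allele is missing at the locus.  Loci are
screened against Hardy-Weinberg expectations and flagged for exclusion
when they show a significant deviation together with heterozygote excess,
the signature of co-amplifying paralogues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiploidGenotype",
    "LocusQCReport",
    "call_genotype",
    "genotype_matrix",
    "hwe_test",
    "pop_allele_freqs",
    "genotypes_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiploidGenotype:
    individual: str
    locus: str
    alleles: tuple | None  # sorted pair, or None when missing

    @property
    def missing(self) -> bool:
        return self.alleles is None

    @property
    def heterozygous(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]


@dataclass
class LocusQCReport:
    locus: str
    n_individuals: int = 0
    hwe_statistic: float = float("nan")
    hwe_p: float = float("nan")
    het_observed: float = float("nan")
    het_expected: float = float("nan")
    excluded: bool = False
    reason: str = ""


def call_genotype(
    counts: Mapping[str, int],
    *,
    min_depth: int = 10,
    het_fraction: float = 0.2,
    individual: str = "",
    locus: str = "",
) -> DiploidGenotype:
    """Call one individual at one locus from per-allele read counts.

    The heterozygote fraction is measured against the individual's total
    reads at the locus.  Exact top-count ties break lexicographically by
    allele id (and are logged); the call is missing when the top allele has
    fewer than ``min_depth`` reads.
    """
    counts = {a: int(c) for a, c in counts.items() if c > 0}
    if not counts:
        return DiploidGenotype(individual, locus, None)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_allele, top_reads = ranked[0]
    if len(ranked) > 1 and ranked[1][1] == top_reads:
        log.info(
            "top-allele tie at %s/%s between %r and %r; keeping %r",
            individual, locus, top_allele, ranked[1][0], top_allele,
        )
    if top_reads < min_depth:
        return DiploidGenotype(individual, locus, None)
    total = sum(counts.values())
    if len(ranked) > 1:
        second_allele, second_reads = ranked[1]
        if second_reads >= het_fraction * total and second_reads >= min_depth:
            return DiploidGenotype(
                individual, locus, tuple(sorted((top_allele, second_allele)))
            )
    return DiploidGenotype(individual, locus, (top_allele, top_allele))


def genotype_matrix(
    tissue_counts: pd.DataFrame,
    loci: Iterable[str],
    *,
    min_depth: int = 10,
    het_fraction: float = 0.2,
) -> tuple[list[DiploidGenotype], pd.DataFrame]:
    """Call every individual at every panel locus; report per-individual missingness.

    ``tissue_counts`` is a long table (sample, locus, allele, reads) where
    sample is the individual id.  One call is produced per individual x
    locus; loci with no reads for an individual come back missing.
    """
    loci = list(loci)
    grouped = {
        (str(s), str(l)): dict(zip(grp["allele"], grp["reads"]))
        for (s, l), grp in tissue_counts.groupby(["sample", "locus"])
    }
    individuals = sorted(tissue_counts["sample"].astype(str).unique())
    calls = []
    miss_rows = []
    for ind in individuals:
        n_missing = 0
        for locus in loci:
            g = call_genotype(
                grouped.get((ind, locus), {}),
                min_depth=min_depth,
                het_fraction=het_fraction,
                individual=ind,
                locus=locus,
            )
            calls.append(g)
            n_missing += g.missing
        miss_rows.append(
            {"individual": ind, "n_loci": len(loci), "n_missing": n_missing}
        )
    return calls, pd.DataFrame(miss_rows)


def _genotype_counts(genotypes: Iterable[DiploidGenotype]) -> dict[tuple, int]:
    counts: dict[tuple, int] = {}
    for g in genotypes:
        if not g.missing:
            counts[g.alleles] = counts.get(g.alleles, 0) + 1
    return counts


def hwe_test(
    genotypes: Iterable[DiploidGenotype],
    *,
    alpha: float = 0.05,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> LocusQCReport:
    """Chi-square goodness of fit of genotype counts against HWE expectations.

    Allele frequencies are estimated from the genotypes themselves; expected
    genotype counts are ``N p_i^2`` and ``2 N p_i p_j``.  Degrees of freedom
    are ``G - k`` for ``G`` possible genotypes over ``k`` alleles.  With
    ``n_permutations > 0`` the p-value is instead the Monte-Carlo proportion
    of gene-copy shuffles with a statistic at least as large.  The locus is
    flagged for exclusion only when the deviation is significant *and*
    observed heterozygosity exceeds expectation (heterozygote excess); a
    heterozygote deficit alone is reported but not flagged.
    """
    genotypes = list(genotypes)
    locus = genotypes[0].locus if genotypes else ""
    obs = _genotype_counts(genotypes)
    n = sum(obs.values())
    report = LocusQCReport(locus=locus, n_individuals=n)
    copies: list = []
    for pair, c in obs.items():
        copies.extend(list(pair) * c)
    alleles = sorted(set(copies))
    if len(alleles) < 2:
        report.reason = "monomorphic: test skipped"
        return report
    if n < 5:
        report.reason = "fewer than 5 individuals: test skipped"
        return report
    freqs = {a: copies.count(a) / len(copies) for a in alleles}
    het_obs = sum(c for pair, c in obs.items() if pair[0] != pair[1]) / n
    het_exp = 1.0 - sum(p * p for p in freqs.values())

    def chi2_stat(gcounts: Mapping[tuple, int]) -> float:
        stat = 0.0
        for pair in combinations_with_replacement(alleles, 2):
            pair = tuple(sorted(pair))
            p, q = freqs[pair[0]], freqs[pair[1]]
            expected = n * (p * p if pair[0] == pair[1] else 2 * p * q)
            if expected > 0:
                stat += (gcounts.get(pair, 0) - expected) ** 2 / expected
        return stat

    statistic = chi2_stat(obs)
    k = len(alleles)
    dof = k * (k + 1) // 2 - k
    if n_permutations > 0:
        rng = rng if rng is not None else np.random.default_rng()
        copies_arr = np.array(copies)
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(copies_arr)
            perm = {}
            for i in range(0, len(copies_arr), 2):
                pair = tuple(sorted(copies_arr[i : i + 2]))
                perm[pair] = perm.get(pair, 0) + 1
            hits += chi2_stat(perm) >= statistic - 1e-12
        p_value = (hits + 1) / (n_permutations + 1)
    else:
        p_value = float(stats.chi2.sf(statistic, dof))
    report.hwe_statistic = statistic
    report.hwe_p = p_value
    report.het_observed = het_obs
    report.het_expected = het_exp
    if p_value < alpha and het_obs > het_exp:
        report.excluded = True
        report.reason = (
            f"HWE deviation (p={p_value:.3g}) with heterozygote excess "
            f"({het_obs:.3f} > {het_exp:.3f})"
        )
    elif p_value < alpha:
        report.reason = f"HWE deviation (p={p_value:.3g}) with heterozygote deficit"
    return report


def pop_allele_freqs(
    genotypes: Iterable[DiploidGenotype],
) -> dict[str, dict[str, float]]:
    """Allele frequencies per locus over 2N gene copies, missing calls excluded."""
    copies: dict[str, dict[str, int]] = {}
    for g in genotypes:
        if g.missing:
            continue
        d = copies.setdefault(g.locus, {})
        for a in g.alleles:
            d[a] = d.get(a, 0) + 1
    out: dict[str, dict[str, float]] = {}
    for locus, d in copies.items():
        total = sum(d.values())
        out[locus] = {a: c / total for a, c in sorted(d.items())}
    return out


def genotypes_to_frame(genotypes: Iterable[DiploidGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        a1, a2 = (None, None) if g.missing else g.alleles
        rows.append(
            {"individual": g.individual, "locus": g.locus, "allele1": a1, "allele2": a2}
        )
    return pd.DataFrame(rows, columns=["individual", "locus", "allele1", "allele2"])
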