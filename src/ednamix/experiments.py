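"""End-to-end orchestration of the three computational experiments.

``prepare_study`` turns a simulated (or loaded) study into the analysis
inputs every experiment shares: called genotypes, locus QC, tissue-based
and eDNA-read-based population allele frequencies, pooled per-mesocosm
scaled read counts and per-locus allelic richness.  On top of that sit

* the mesocosm experiment -- contributor estimates per mesocosm from
  tissue-derived and eDNA-derived allele sets under every filtering
  scheme and both frequency sources, with a bias table;
* the bootstrap experiment -- contributor estimates for random
  combinations of mesocosm read pools (2-12 units per draw);
* the field experiment -- per-replicate estimates at low read depth under
  tissue-reference and eDNA-combined frequencies, plus the frequency
  agreement between the pooled eDNA sample and the genotyped reference.

Tissue-based and eDNA-read-based frequency sources are labelled
explicitly in every output row; nothing is silently mixed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .edna import (
    ThresholdScheme,
    edna_allele_freqs,
    edna_pipeline,
    freqs_to_dict,
    threshold_filter,
    to_mixture_profile,
)
from .genotyping import genotype_matrix, hwe_test, pop_allele_freqs
from .mixture import MixtureProfile, estimate_contributors
from .simulate import SimulationConfig, SyntheticTruth, simulate_study
from .stats import align_and_correlate, bias_summary, bootstrap_mixture_experiment

__all__ = [
    "RunConfig",
    "StudyData",
    "default_schemes",
    "prepare_study",
    "tissue_profile",
    "run_mesocosm_experiment",
    "run_bootstrap_experiment",
    "run_field_experiment",
    "run_study",
    "write_manifest",
]


def default_schemes() -> list[ThresholdScheme]:
    """The four filtering schemes under study: three fixed cutoffs + variable."""
    return [
        ThresholdScheme("fixed", t=0.001),
        ThresholdScheme("fixed", t=0.01),
        ThresholdScheme("fixed", t=0.1),
        ThresholdScheme("variable"),
    ]


@dataclass(frozen=True)
class RunConfig:
    """One experiment run: simulation settings, schemes, grid, output location."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    x_max: int = 100
    n_bootstrap: int = 1000
    alpha: float = 0.05
    apply_locus_qc: bool = True
    outdir: str | None = None
    seed: int = 0

    @property
    def x_grid(self) -> range:
        return range(1, self.x_max + 1)


@dataclass
class StudyData:
    """Shared analysis inputs derived from one study's read counts."""

    truth: SyntheticTruth
    called_genotypes: list
    missingness: pd.DataFrame
    qc: pd.DataFrame
    excluded_loci: list
    tissue_freqs: dict      # from the mesocosm individuals' called genotypes
    tissue_freqs_all: dict  # from all genotyped individuals (mesocosm + field)
    edna_freqs: dict        # read frequencies combined across all mesocosm eDNA
    pooled: pd.DataFrame    # per-mesocosm pooled scaled counts
    richness: dict          # per-locus allele counts in the tissue reference


def prepare_study(truth: SyntheticTruth, cfg: RunConfig) -> StudyData:
    """Genotype the tissue reads, QC the loci, and build both frequency sources."""
    loci = truth.sim_panel.loci
    calls, missingness = genotype_matrix(truth.tissue_counts, loci)
    by_locus: dict[str, list] = {}
    for g in calls:
        by_locus.setdefault(g.locus, []).append(g)
    qc_rows, excluded = [], []
    for locus in loci:
        rep = hwe_test(by_locus.get(locus, []), alpha=cfg.alpha)
        qc_rows.append(vars(rep))
        if rep.excluded:
            excluded.append(locus)
    if cfg.apply_locus_qc and excluded:
        calls = [g for g in calls if g.locus not in excluded]
    mesocosm_inds = {i for members in truth.mesocosms.values() for i in members}
    meso_calls = [g for g in calls if g.individual in mesocosm_inds]
    tissue_freqs = pop_allele_freqs(meso_calls)
    tissue_freqs_all = pop_allele_freqs(calls)
    pooled = edna_pipeline(truth.edna_counts, truth.edna_unit_of)
    if cfg.apply_locus_qc and excluded:
        pooled = pooled[~pooled["locus"].isin(excluded)].reset_index(drop=True)
    edna_freqs = freqs_to_dict(edna_allele_freqs(pooled))
    richness = {locus: len(d) for locus, d in tissue_freqs.items()}
    return StudyData(
        truth=truth, called_genotypes=calls, missingness=missingness,
        qc=pd.DataFrame(qc_rows), excluded_loci=excluded,
        tissue_freqs=tissue_freqs, tissue_freqs_all=tissue_freqs_all,
        edna_freqs=edna_freqs, pooled=pooled, richness=richness,
    )


def tissue_profile(
    genotypes, members: Sequence[str], source: str = "tissue-pooled"
) -> MixtureProfile:
    """Union of the member individuals' called alleles, per locus."""
    wanted = set(members)
    loci: dict[str, set] = {}
    for g in genotypes:
        if g.individual in wanted and not g.missing:
            loci.setdefault(g.locus, set()).update(g.alleles)
    return MixtureProfile(
        loci={k: frozenset(v) for k, v in loci.items()}, source=source
    )


def run_mesocosm_experiment(
    study: StudyData,
    cfg: RunConfig,
    schemes: Sequence[ThresholdScheme] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mesocosm contributor estimates and the resulting bias table.

    Tissue-derived allele sets (pooled member genotypes) are estimated once
    per frequency source; eDNA-derived allele sets are estimated under every
    filtering scheme x frequency source.
    """
    schemes = default_schemes() if schemes is None else schemes
    sources = {"tissue-genotypes": study.tissue_freqs,
               "edna-reads": study.edna_freqs}
    rows = []
    for unit, members in study.truth.mesocosms.items():
        truth_x = len(members)
        tprof = tissue_profile(study.called_genotypes, members)
        for src, pop in sources.items():
            est = estimate_contributors(tprof, pop, cfg.x_grid, true_x=truth_x)
            rows.append(
                {"mesocosm": unit, "true_x": truth_x, "profile": "tissue",
                 "scheme": "none", "freq_source": src, "x_hat": est.x_hat,
                 "bias": est.bias, "boundary": est.boundary,
                 "dropped_alleles": est.n_dropped_alleles}
            )
        unit_counts = study.pooled[study.pooled["sample"] == unit]
        for scheme in schemes:
            filtered = threshold_filter(unit_counts, scheme, study.richness)
            for src, pop in sources.items():
                profile, dropped = to_mixture_profile(filtered, pop, sample=unit)
                est = estimate_contributors(profile, pop, cfg.x_grid,
                                            true_x=truth_x)
                rows.append(
                    {"mesocosm": unit, "true_x": truth_x, "profile": "eDNA",
                     "scheme": scheme.label, "freq_source": src,
                     "x_hat": est.x_hat, "bias": est.bias,
                     "boundary": est.boundary, "dropped_alleles": dropped}
                )
    estimates = pd.DataFrame(rows)
    bias = bias_summary(estimates, by=["profile", "scheme", "freq_source",
                                       "true_x"])
    return estimates, bias


def run_bootstrap_experiment(
    study: StudyData,
    cfg: RunConfig,
    schemes: Sequence[ThresholdScheme] | None = None,
    freq_source: str = "tissue-genotypes",
) -> pd.DataFrame:
    """Bootstrap mixtures of 2-12 mesocosm read pools under each scheme."""
    schemes = default_schemes() if schemes is None else schemes
    pop = (study.tissue_freqs if freq_source == "tissue-genotypes"
           else study.edna_freqs)
    unit_sizes = {u: len(m) for u, m in study.truth.mesocosms.items()}
    results = bootstrap_mixture_experiment(
        study.pooled, unit_sizes, pop, schemes,
        richness=study.richness, n_reps=cfg.n_bootstrap,
        x_grid=cfg.x_grid, seed=cfg.seed,
    )
    results.insert(0, "freq_source", freq_source)
    return results


def run_field_experiment(
    study: StudyData, cfg: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Per-replicate field estimates under both frequency sources.

    Field water samples run through the standard per-sample filters; each
    replicate yields one estimate against the full genotyped reference
    (tissue frequencies from all individuals) and one against frequencies
    combined across the three replicates.  Returns the estimate table and a
    summary with the pooled-vs-reference frequency correlation.
    """
    counts = study.truth.field_counts
    if counts is None or counts.empty:
        raise ValueError("study has no field read counts")
    samples = sorted(counts["sample"].unique())
    per_sample = edna_pipeline(counts, {s: s for s in samples})
    pooled = edna_pipeline(counts, {s: "field" for s in samples})
    field_freqs = freqs_to_dict(edna_allele_freqs(pooled))
    sources = {"tissue-genotypes": study.tissue_freqs_all,
               "edna-reads": field_freqs}
    rows = []
    for sample in samples:
        for src, pop in sources.items():
            profile, dropped = to_mixture_profile(per_sample, pop, sample=sample)
            est = estimate_contributors(profile, pop, cfg.x_grid)
            rows.append(
                {"sample": sample, "freq_source": src, "x_hat": est.x_hat,
                 "boundary": est.boundary, "dropped_alleles": dropped}
            )
    comparison = align_and_correlate(field_freqs, study.tissue_freqs_all)
    summary = {
        "pooled_vs_reference_r": comparison.overall_r,
        "n_true_contributors": study.truth.config.field_n_contributors,
    }
    return pd.DataFrame(rows), summary


def write_manifest(outdir, cfg: RunConfig, extra: Mapping | None = None) -> Path:
    """Record config, seed and versions so a run can be reproduced exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "x_max": cfg.x_max,
        "n_bootstrap": cfg.n_bootstrap,
        "apply_locus_qc": cfg.apply_locus_qc,
        "simulation": vars(cfg.sim),
        **(dict(extra) if extra else {}),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def run_study(cfg: RunConfig) -> StudyData:
    """Simulate a study under ``cfg`` and prepare the shared analysis inputs."""
    truth = simulate_study(cfg.sim, np.random.default_rng(cfg.seed))
    return prepare_study(truth, cfg)
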