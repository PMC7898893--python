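"""Ground-truthed simulation of a microsatellite eDNA study.

Emulates the structure of a mesocosm + field experiment on a panmictic
fish population: a panel of 28 tetranucleotide microsatellite loci with
2-21 alleles each (mean ~9.4), 58 mesocosm fish plus 15 field fish
genotyped in Hardy-Weinberg proportions, twelve mesocosms stocked at
densities 1/3/5/10 (one mis-stocked 11-fish tank), duplicate water
samples per mesocosm and triplicate low-depth field samples.  Read counts
carry the artifacts that make the downstream filtering questions real:
unequal per-individual DNA contributions (Dirichlet weights), PCR stutter
(reads displaced to the one-repeat-shorter allele), substitution errors
(reads displaced onto a small set of recurrent false-allele variants), and
allelic dropout inflated for low-weight contributors.

Every operation is a pure function of its inputs and the supplied
generator, so a seed reproduces the full study bit-for-bit.  Error-free
settings round-trip exactly through read processing and genotyping.

Allele naming: true alleles are ``{locus}_aNN``; stutter products falling
below the locus's allele universe are ``{locus}_sHK`` and substitution
variants ``{parent}~eJ`` -- both recognisably artifactual and absent from
population frequency tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyping import DiploidGenotype
from .reads import LocusDef, LocusPanel, merge_pairs, AmpliconRead, revcomp

__all__ = [
    "SimulationConfig",
    "SimPanel",
    "SyntheticTruth",
    "gen_panel",
    "gen_population",
    "draw_genotypes",
    "gen_mesocosms",
    "gen_tissue_reads",
    "gen_edna_reads",
    "emit_fastq",
    "simulate_study",
]

_BASES = "ACGT"
MESOCOSM_DESIGN = {
    "1a": 1, "1b": 1, "1c": 1,
    "3a": 3, "3b": 3, "3c": 3,
    "5a": 5, "5b": 5, "5c": 5,
    "10a": 10, "10b": 10, "10c": 11,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator; defaults mirror the emulated design."""

    n_loci: int = 28
    richness_min: int = 2
    richness_max: int = 21
    richness_mean: float = 9.4
    dirichlet_alpha: float = 1.0
    n_mesocosm_individuals: int = 58
    n_field_individuals: int = 15
    field_n_contributors: int = 20
    edna_replicates: int = 2
    field_replicates: int = 3
    tissue_depth: int = 45_534
    edna_depth: int = 37_151
    field_depth: int = 4_305
    contribution_concentration: float = 1.0
    substitution_prob: float = 0.005
    stutter_prob: float = 0.05
    dropout_prob: float = 0.05
    amplification_bias_beta: float = 30.0
    read_len: int = 150
    primer_len: int = 20
    flank_len: int = 40
    repeat_min: int = 8
    repeat_max: int = 20
    seed: int = 0

    def errorfree(self) -> "SimulationConfig":
        return replace(
            self, substitution_prob=0.0, stutter_prob=0.0, dropout_prob=0.0
        )


@dataclass
class SimPanel:
    """A locus panel plus the simulator's full sequence/artifact bookkeeping."""

    panel: LocusPanel
    sequences: dict          # (locus, allele id) -> amplicon sequence (incl. artifacts)
    repeat_of: dict          # (locus, true allele id) -> (haplotype, repeat count)
    stutter_target: dict     # (locus, true allele id) -> allele id one repeat shorter
    error_variants: dict     # (locus, true allele id) -> tuple of variant allele ids
    locus_weights: np.ndarray  # relative amplification share per locus

    @property
    def loci(self) -> list[str]:
        return list(self.panel.loci)

    def allele_universe(self, locus: str) -> list[str]:
        return sorted(self.panel.loci[locus].alleles)

    def richness(self) -> dict[str, int]:
        return {loc: len(d.alleles) for loc, d in self.panel.loci.items()}


@dataclass
class SyntheticTruth:
    """Everything needed to score any downstream stage against ground truth."""

    config: SimulationConfig
    sim_panel: SimPanel
    pop_freqs: dict
    genotypes: list
    mesocosms: dict          # unit -> list of individual ids
    contribution_weights: dict  # unit -> {individual: weight}
    tissue_counts: pd.DataFrame
    edna_counts: pd.DataFrame       # mesocosm water samples (2 per unit)
    edna_unit_of: dict              # water sample id -> mesocosm id
    field_counts: pd.DataFrame | None = None
    field_genotypes: list = field(default_factory=list)

    def genotypes_of(self, individuals: Sequence[str]) -> list:
        wanted = set(individuals)
        return [g for g in self.genotypes if g.individual in wanted]


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _draw_richness(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    # shifted binomial: support [min, max], mean = configured mean
    span = cfg.richness_max - cfg.richness_min
    p = (cfg.richness_mean - cfg.richness_min) / span
    return int(cfg.richness_min + rng.binomial(span, p))


def _build_locus(
    locus: str, richness: int, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[LocusDef, dict, dict, dict, dict]:
    """One locus: alleles differ in tetranucleotide repeat count and, when the
    repeat range alone cannot host the richness, a flank SNP haplotype."""
    n_counts = cfg.repeat_max - cfg.repeat_min + 1
    for _attempt in range(50):
        fwd = _rand_seq(rng, cfg.primer_len)
        rev = _rand_seq(rng, cfg.primer_len)
        left = _rand_seq(rng, cfg.flank_len)
        right = _rand_seq(rng, cfg.flank_len)
        motif = _rand_seq(rng, 4)
        if len(set(motif)) == 1:  # homopolymer motifs alias under shift
            continue
        # allele layout: (haplotype, repeat count)
        n_b = max(0, richness - n_counts)
        k0_a = int(rng.integers(cfg.repeat_min,
                                cfg.repeat_max - min(richness, n_counts) + 2))
        layout = [("A", k0_a + i) for i in range(min(richness, n_counts))]
        if n_b:
            k0_b = int(rng.integers(cfg.repeat_min, cfg.repeat_max - n_b + 2))
            layout += [("B", k0_b + i) for i in range(n_b)]
        snp_pos = cfg.flank_len // 2
        right_b = None
        if n_b:
            alt = _BASES[(_BASES.index(right[snp_pos]) + 2) % 4]
            right_b = right[:snp_pos] + alt + right[snp_pos + 1 :]

        def amplicon(hap: str, k: int) -> str:
            flank = right if hap == "A" else right_b
            return fwd + left + motif * k + flank + revcomp(rev)

        layout.sort()
        alleles = {f"{locus}_a{i:02d}": amplicon(h, k)
                   for i, (h, k) in enumerate(layout)}
        repeat_of = {aid: hk for aid, hk in zip(alleles, layout)}
        by_hk = {hk: aid for aid, hk in repeat_of.items()}

        sequences = dict(alleles)
        stutter_target, error_variants = {}, {}
        for aid, (hap, k) in repeat_of.items():
            tgt = by_hk.get((hap, k - 1))
            if tgt is None:
                tgt = f"{locus}_s{hap}{k - 1}"
                sequences[tgt] = amplicon(hap, k - 1)
            stutter_target[aid] = tgt
            variants = []
            for j in range(3):
                pos = cfg.primer_len + 5 + 2 * j  # inside the left flank
                seq = alleles[aid]
                sub = _BASES[(_BASES.index(seq[pos]) + 1 + j) % 4]
                vid = f"{aid}~e{j}"
                sequences[vid] = seq[:pos] + sub + seq[pos + 1 :]
                variants.append(vid)
            error_variants[aid] = tuple(variants)

        # self-check: every catalogued sequence must round-trip through an
        # error-free merge of its read pair and keep distinct identities
        if len(set(sequences.values())) != len(sequences):
            continue
        ok = True
        for seq in sequences.values():
            f = AmpliconRead("f", seq[: cfg.read_len], (38,) * min(cfg.read_len, len(seq)))
            r_seq = revcomp(seq)[: cfg.read_len]
            r = AmpliconRead("r", r_seq, (38,) * len(r_seq))
            merged = merge_pairs(f, r)
            if merged is None or merged.bases != seq:
                ok = False
                break
        if not ok:
            continue
        most_common = next(iter(alleles.values()))
        ldef = LocusDef(
            locus=locus, fwd_primer=fwd, rev_primer=rev,
            reference_prefix=most_common[:40], motif=motif, alleles=alleles,
        )
        seqs = {(locus, aid): s for aid, s in sequences.items()}
        return (
            ldef,
            seqs,
            {(locus, a): hk for a, hk in repeat_of.items()},
            {(locus, a): t for a, t in stutter_target.items()},
            {(locus, a): v for a, v in error_variants.items()},
        )
    raise RuntimeError(f"could not construct a self-consistent locus {locus}")


def gen_panel(cfg: SimulationConfig, rng: np.random.Generator) -> SimPanel:
    """Generate the locus panel with allele catalogues and artifact maps."""
    loci, seqs, repeat_of, stutter, errvar = {}, {}, {}, {}, {}
    primers_seen: set[str] = set()
    for i in range(cfg.n_loci):
        locus = f"L{i + 1:02d}"
        while True:
            richness = _draw_richness(cfg, rng)
            ldef, s, r, st, ev = _build_locus(locus, richness, cfg, rng)
            if ldef.fwd_primer not in primers_seen:
                break
        primers_seen.add(ldef.fwd_primer)
        loci[locus] = ldef
        seqs.update(s)
        repeat_of.update(r)
        stutter.update(st)
        errvar.update(ev)
    weights = rng.dirichlet(np.full(cfg.n_loci, 50.0))
    return SimPanel(
        panel=LocusPanel(loci), sequences=seqs, repeat_of=repeat_of,
        stutter_target=stutter, error_variants=errvar, locus_weights=weights,
    )


def draw_genotypes(
    pop: Mapping[str, Mapping[str, float]],
    n_individuals: int,
    rng: np.random.Generator,
    prefix: str = "ind",
) -> list:
    """Draw diploid genotypes in HWE: two gene copies iid from each locus's p."""
    genotypes = []
    for i in range(n_individuals):
        ind = f"{prefix}{i + 1:03d}"
        for locus, fr in pop.items():
            alleles = list(fr)
            pair = rng.choice(alleles, size=2, p=list(fr.values()))
            genotypes.append(DiploidGenotype(ind, locus, tuple(sorted(pair))))
    return genotypes


def gen_population(
    sim_panel: SimPanel,
    n_individuals: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    prefix: str = "ind",
) -> tuple[dict, list]:
    """Population allele frequencies (symmetric Dirichlet) and HWE genotypes."""
    pop: dict[str, dict[str, float]] = {}
    for locus in sim_panel.loci:
        alleles = sim_panel.allele_universe(locus)
        freqs = rng.dirichlet(np.full(len(alleles), cfg.dirichlet_alpha))
        pop[locus] = dict(zip(alleles, freqs))
    return pop, draw_genotypes(pop, n_individuals, rng, prefix)


def gen_mesocosms(
    individuals: Sequence[str],
    cfg: SimulationConfig,
    design: Mapping[str, int] = MESOCOSM_DESIGN,
) -> dict[str, list[str]]:
    """Assign individuals to mesocosm units (3x1, 3x3, 3x5, 2x10 and one of 11)."""
    need = sum(design.values())
    if len(individuals) < need:
        raise ValueError(f"{need} individuals required, got {len(individuals)}")
    out, cursor = {}, 0
    for unit, n in design.items():
        out[unit] = list(individuals[cursor : cursor + n])
        cursor += n
    return out


def _inject_errors(
    counts: dict[str, int],
    locus: str,
    sim_panel: SimPanel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Move reads of true alleles onto stutter products and error variants."""
    out = dict(counts)
    for allele, c in counts.items():
        if c <= 0 or (locus, allele) not in sim_panel.repeat_of:
            continue
        moved = 0
        if cfg.stutter_prob > 0:
            stut = rng.binomial(c, cfg.stutter_prob)
            if stut:
                tgt = sim_panel.stutter_target[(locus, allele)]
                out[tgt] = out.get(tgt, 0) + stut
                moved += stut
        if cfg.substitution_prob > 0:
            err = rng.binomial(c - moved, cfg.substitution_prob)
            if err:
                variants = sim_panel.error_variants[(locus, allele)]
                split = rng.multinomial(err, [1 / len(variants)] * len(variants))
                for vid, e in zip(variants, split):
                    if e:
                        out[vid] = out.get(vid, 0) + int(e)
                moved += err
        out[allele] = c - moved
    return {a: c for a, c in out.items() if c > 0}


def _locus_depths(
    total: int, sim_panel: SimPanel, rng: np.random.Generator
) -> dict[str, int]:
    draws = rng.multinomial(total, sim_panel.locus_weights)
    return dict(zip(sim_panel.loci, (int(d) for d in draws)))


def gen_tissue_reads(
    genotypes: Sequence[DiploidGenotype],
    sim_panel: SimPanel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Tissue amplicon read counts for genotyped individuals.

    Reads split between a heterozygote's two alleles as Binomial(depth, b)
    with a mild per-individual-per-locus amplification bias
    b ~ Beta(beta, beta); stutter and substitution artifacts follow.
    """
    rows = []
    by_ind: dict[str, list[DiploidGenotype]] = {}
    for g in genotypes:
        by_ind.setdefault(g.individual, []).append(g)
    for ind in sorted(by_ind):
        depths = _locus_depths(cfg.tissue_depth, sim_panel, rng)
        for g in by_ind[ind]:
            if g.missing:
                continue
            depth = depths[g.locus]
            if depth == 0:
                continue
            a1, a2 = g.alleles
            if a1 == a2:
                counts = {a1: depth}
            else:
                b = rng.beta(cfg.amplification_bias_beta, cfg.amplification_bias_beta)
                n1 = int(rng.binomial(depth, b))
                counts = {a1: n1, a2: depth - n1}
            counts = _inject_errors(counts, g.locus, sim_panel, cfg, rng)
            for allele, c in sorted(counts.items()):
                rows.append(
                    {"sample": ind, "locus": g.locus, "allele": allele, "reads": c}
                )
    return pd.DataFrame(rows, columns=["sample", "locus", "allele", "reads"])


def gen_edna_reads(
    member_genotypes: Sequence[DiploidGenotype],
    sim_panel: SimPanel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    *,
    depth: int | None = None,
    n_replicates: int | None = None,
    sample_prefix: str = "w",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replicate water-sample read counts for one unit's members.

    Per-individual shedding weights ~ Dirichlet(concentration) persist across
    replicates; expected allele proportions at a locus are the weight-blended
    genotype dosages.  Counts are multinomial at the sample's per-locus
    depth, then thinned by allelic dropout (probability inflated for alleles
    carried only by low-weight contributors) and decorated with stutter and
    substitution artifacts.
    """
    depth = cfg.edna_depth if depth is None else depth
    n_replicates = cfg.edna_replicates if n_replicates is None else n_replicates
    members = sorted({g.individual for g in member_genotypes})
    if not members:
        raise ValueError("at least one member genotype required")
    w = rng.dirichlet(np.full(len(members), cfg.contribution_concentration))
    weights = dict(zip(members, w))
    dosage: dict[str, dict[str, float]] = {}
    carriers_w: dict[str, dict[str, float]] = {}
    for g in member_genotypes:
        if g.missing:
            continue
        d = dosage.setdefault(g.locus, {})
        cw = carriers_w.setdefault(g.locus, {})
        for a in g.alleles:
            d[a] = d.get(a, 0.0) + weights[g.individual] * 0.5
            cw[a] = max(cw.get(a, 0.0), weights[g.individual])
    rows = []
    for rep in range(n_replicates):
        sample = f"{sample_prefix}{rep + 1}"
        depths = _locus_depths(depth, sim_panel, rng)
        for locus, d in dosage.items():
            ldepth = depths[locus]
            if ldepth == 0 or not d:
                continue
            alleles = sorted(d)
            props = np.array([d[a] for a in alleles])
            props = props / props.sum()
            counts = dict(zip(alleles, rng.multinomial(ldepth, props)))
            if cfg.dropout_prob > 0:
                for a in alleles:
                    rel = carriers_w[locus][a] * len(members)
                    p_drop = min(0.9, cfg.dropout_prob / max(rel, 1e-6))
                    if rng.random() < p_drop:
                        counts[a] = 0
            counts = {a: int(c) for a, c in counts.items() if c > 0}
            counts = _inject_errors(counts, locus, sim_panel, cfg, rng)
            for allele, c in sorted(counts.items()):
                rows.append(
                    {"sample": sample, "locus": locus, "allele": allele, "reads": c}
                )
    return (
        pd.DataFrame(rows, columns=["sample", "locus", "allele", "reads"]),
        weights,
    )


def emit_fastq(
    counts: pd.DataFrame,
    sim_panel: SimPanel,
    outdir,
    cfg: SimulationConfig,
    *,
    quality: int = 38,
) -> dict[str, tuple[Path, Path]]:
    """Write paired FASTQ per sample for every counted read; returns file map.

    Each read pair covers its allele's amplicon from both ends (forward and
    reverse-complement), overlapping well past the merge minimum.  With the
    default flat high quality the files round-trip exactly through
    ``fastq_to_counts``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qchar = chr(quality + 33)
    paths: dict[str, tuple[Path, Path]] = {}
    for sample, grp in counts.groupby("sample"):
        r1 = outdir / f"{sample}_R1.fastq"
        r2 = outdir / f"{sample}_R2.fastq"
        with open(r1, "w") as f1, open(r2, "w") as f2:
            i = 0
            for _, row in grp.iterrows():
                key = (row["locus"], row["allele"])
                if key not in sim_panel.sequences:
                    raise KeyError(f"no sequence catalogued for {key}")
                seq = sim_panel.sequences[key]
                if len(seq) < cfg.read_len // 2:
                    raise ValueError(f"allele sequence too short for reads: {key}")
                fwd = seq[: cfg.read_len]
                rev = revcomp(seq)[: cfg.read_len]
                for _ in range(int(row["reads"])):
                    i += 1
                    rid = f"{sample}.{i}"
                    f1.write(f"@{rid}/1\n{fwd}\n+\n{qchar * len(fwd)}\n")
                    f2.write(f"@{rid}/2\n{rev}\n+\n{qchar * len(rev)}\n")
        paths[str(sample)] = (r1, r2)
    return paths


def simulate_study(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticTruth:
    """Run the full generative model: panel, population, mesocosms, reads."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sim_panel = gen_panel(cfg, rng)
    n_total = cfg.n_mesocosm_individuals + cfg.n_field_individuals
    pop, genotypes = gen_population(sim_panel, n_total, cfg, rng)
    individuals = sorted({g.individual for g in genotypes})
    mesocosm_inds = individuals[: cfg.n_mesocosm_individuals]
    mesocosms = gen_mesocosms(mesocosm_inds, cfg)
    tissue = gen_tissue_reads(genotypes, sim_panel, cfg, rng)
    edna_frames, unit_of, weights = [], {}, {}
    for unit, members in mesocosms.items():
        mg = [g for g in genotypes if g.individual in set(members)]
        df, w = gen_edna_reads(
            mg, sim_panel, cfg, rng, sample_prefix=f"{unit}_w"
        )
        edna_frames.append(df)
        weights[unit] = w
        for rep in range(cfg.edna_replicates):
            unit_of[f"{unit}_w{rep + 1}"] = unit
    edna = pd.concat(edna_frames, ignore_index=True)
    field_counts = None
    field_genotypes: list = []
    if cfg.field_n_contributors > 0:
        field_genotypes = draw_genotypes(
            pop, cfg.field_n_contributors, rng, prefix="fieldfish"
        )
        field_counts, wf = gen_edna_reads(
            field_genotypes, sim_panel, cfg, rng,
            depth=cfg.field_depth, n_replicates=cfg.field_replicates,
            sample_prefix="field_w",
        )
        weights["field"] = wf
    return SyntheticTruth(
        config=cfg, sim_panel=sim_panel, pop_freqs=pop, genotypes=genotypes,
        mesocosms=mesocosms, contribution_weights=weights,
        tissue_counts=tissue, edna_counts=edna, edna_unit_of=unit_of,
        field_counts=field_counts, field_genotypes=field_genotypes,
    )
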