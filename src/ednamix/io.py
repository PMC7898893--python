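"""CSV/JSON interchange for the pipeline's tables.

Long-format CSVs throughout: read counts (sample, locus, allele, reads),
scaled counts (sample, locus, allele, scaled_reads), allele frequencies
(locus, allele, freq), genotypes (individual, locus, allele1, allele2 with
empty cells for missing), mixture profiles (locus, allele).  Contributor
estimates are written as a likelihood-profile CSV (x, loglik) plus a JSON
summary.  Panels serialise to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .edna import freqs_to_dict, freqs_to_frame, validate_counts
from .genotyping import DiploidGenotype, genotypes_to_frame
from .mixture import ContributorEstimate, MixtureProfile
from .reads import LocusDef, LocusPanel

__all__ = [
    "read_counts", "write_counts",
    "read_freqs", "write_freqs",
    "read_genotypes", "write_genotypes",
    "read_profile", "write_profile",
    "write_estimate",
    "read_panel", "write_panel",
]


def read_counts(path, value: str = "reads") -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample": str, "locus": str, "allele": str})
    return validate_counts(df, value)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_freqs(path) -> dict:
    df = pd.read_csv(path, dtype={"locus": str, "allele": str})
    return freqs_to_dict(df)


def write_freqs(freqs, path) -> None:
    if not isinstance(freqs, pd.DataFrame):
        freqs = freqs_to_frame(freqs)
    freqs.to_csv(path, index=False)


def read_genotypes(path) -> list[DiploidGenotype]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for row in df.itertuples(index=False):
        missing = pd.isna(row.allele1) or pd.isna(row.allele2)
        alleles = None if missing else tuple(sorted((row.allele1, row.allele2)))
        out.append(DiploidGenotype(row.individual, row.locus, alleles))
    return out


def write_genotypes(genotypes: Iterable[DiploidGenotype], path) -> None:
    genotypes_to_frame(genotypes).to_csv(path, index=False)


def read_profile(path, source: str = "eDNA") -> MixtureProfile:
    df = pd.read_csv(path, dtype=str)
    loci: dict[str, set] = {}
    for row in df.itertuples(index=False):
        loci.setdefault(row.locus, set()).add(row.allele)
    return MixtureProfile(
        loci={k: frozenset(v) for k, v in loci.items()}, source=source
    )


def write_profile(profile: MixtureProfile, path) -> None:
    rows = [
        {"locus": locus, "allele": allele}
        for locus, alleles in sorted(profile.loci.items())
        for allele in sorted(alleles)
    ]
    pd.DataFrame(rows, columns=["locus", "allele"]).to_csv(path, index=False)


def write_estimate(est: ContributorEstimate, csv_path, json_path) -> None:
    pd.DataFrame(
        {"x": est.x_grid, "loglik": np.where(np.isfinite(est.loglik),
                                             est.loglik, -np.inf)}
    ).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(est.summary(), fh, indent=2)


def write_panel(panel: LocusPanel, path) -> None:
    payload = {
        loc: {
            "fwd_primer": d.fwd_primer,
            "rev_primer": d.rev_primer,
            "reference_prefix": d.reference_prefix,
            "motif": d.motif,
            "alleles": dict(d.alleles),
        }
        for loc, d in panel.loci.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_panel(path) -> LocusPanel:
    payload = json.loads(Path(path).read_text())
    return LocusPanel(
        {loc: LocusDef(locus=loc, **spec) for loc, spec in payload.items()}
    )
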