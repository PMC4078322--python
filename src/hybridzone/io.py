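"""File formats: Structure-style genotypes, site tables, FASTA, phenotypes.

The genotype dialect is the de-facto Structure convention: one row per
individual, an id column, a population column, then two columns per locus
holding integer allele labels, with ``-9`` marking missing data. A header row
names each locus twice.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import GenotypeTable, MISSING, TransectSites, validate_phenotypes


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    path = Path(path)
    header = ["id", "pop"] + [name for locus in table.loci for name in (locus, locus)]
    lines = ["\t".join(header)]
    flat = table.calls.reshape(table.n_individuals, -1)
    for i, ind in enumerate(table.individuals):
        lines.append("\t".join([ind, str(table.populations[i]),
                                *map(str, flat[i])]))
    path.write_text("\n".join(lines) + "\n")


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read the Structure-style dialect written by :func:`write_genotypes`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 4 or (len(header) - 2) % 2 != 0:
        raise ValueError(f"{path}: line 1: header must be id, pop, then locus pairs")
    loci = header[2::2]
    if header[3::2] != loci:
        raise ValueError(f"{path}: line 1: locus names must appear twice in order")
    n_cols = len(header)
    individuals, populations, rows = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(f"{path}: line {lineno}: expected {n_cols} columns, "
                             f"got {len(fields)}")
        individuals.append(fields[0])
        populations.append(fields[1])
        try:
            rows.append([int(v) for v in fields[2:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-integer allele call "
                             f"({exc})") from None
    calls = np.asarray(rows, dtype=np.int64).reshape(len(rows), len(loci), 2)
    bad = (calls < 0) & (calls != MISSING)
    if bad.any():
        raise ValueError(f"{path}: unknown missing code "
                         f"{int(calls[bad][0])} (only -9 is recognised)")
    # a half-missing pair is normalised to fully missing
    half = (calls == MISSING).any(axis=2) & ~(calls == MISSING).all(axis=2)
    if half.any():
        calls[half] = MISSING
    return GenotypeTable(individuals=individuals, populations=np.array(populations),
                         loci=loci, calls=calls)


def write_sites(sites: TransectSites, path: str | Path) -> None:
    sites.to_frame().to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> TransectSites:
    return TransectSites.from_frame(pd.read_csv(path, sep="\t"))


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(table).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(config, path: str | Path) -> None:
    """Serialise a ZoneConfig truth sidecar as JSON."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
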