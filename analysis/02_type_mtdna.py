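#!/usr/bin/env python
"""Type every amplicon coastal/interior by in-silico restriction digest.

Reads results/zone/amplicons.fasta, scores each sequence by band count
(two bands = coastal, one = interior) and tabulates interior-haplotype
frequencies per transect site.
"""

from pathlib import Path

from hybridzone import io as hio
from hybridzone.rflp import DEFAULT_MOTIF, site_haplotype_counts, type_fasta

ZONE = Path(__file__).resolve().parent.parent / "results" / "zone"


def main() -> None:
    sequences = hio.read_fasta(ZONE / "amplicons.fasta")
    genotypes = hio.read_genotypes(ZONE / "genotypes.str")

    calls = type_fasta(sequences, motif=DEFAULT_MOTIF)
    calls.to_csv(ZONE / "mtdna_calls.tsv", sep="\t", index=False)
    site_order = {ind: pop for ind, pop in
                  zip(genotypes.individuals, genotypes.populations)}
    counts = site_haplotype_counts(
        calls["call"], [site_order[i] for i in calls["individual"]])
    counts.to_csv(ZONE / "mtdna_site_counts.tsv", sep="\t", index=False)

    n_int = int((calls["call"] == "interior").sum())
    print(f"typed {len(calls)} amplicons with motif {DEFAULT_MOTIF}: "
          f"{n_int} interior, {len(calls) - n_int} coastal")
    print(counts.to_string(index=False))


if __name__ == "__main__":
    main()
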