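"""Hotspot-motif classification and mutation-spectrum analysis.

AID deaminates C preferentially in 5'WRC trinucleotide contexts (the
mutated C is the 3' base; W = A/T, R = A/G) and avoids 5'SYC contexts
(S = C/G, Y = C/T).  The strand-symmetric 4-mer WGCW ("overlapping
hot", e.g. AGCT) carries a WRC hot motif on each strand of the duplex.

Spectra are per-C-site mutation rates (supermutant families / covered
families) and mutation frequencies (% of all mutations on the strand),
annotated with motif class and region (FW/CDR).  The module also maps
RNA transcript 3' ends back onto the template for pause-site profiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .caller import MutationTable
from .replicates import two_sample_t
from .sequences import ReferencePair

W = set("AT")
R = set("AG")
S = set("CG")
Y = set("CT")


@dataclass
class MotifClass:
    label: str  # hot | cold | other
    edge: bool = False  # True when < 2 upstream bases exist


def classify_site_motif(strand_seq: str, pos: int) -> MotifClass:
    """Motif class of the C at 1-based ``pos`` on a strand read 5'->3'.

    Hot iff the two 5' neighbours match W,R (5'WRC); cold iff they match
    S,Y (5'SYC); otherwise other.  A C with fewer than two upstream
    bases cannot be classified and is returned as other with the edge
    flag set.
    """
    if strand_seq[pos - 1] != "C":
        raise ValueError(f"base at position {pos} is {strand_seq[pos - 1]!r}, not C")
    if pos < 3:
        return MotifClass("other", edge=True)
    b2, b1 = strand_seq[pos - 3], strand_seq[pos - 2]
    if b2 in W and b1 in R:
        return MotifClass("hot")
    if b2 in S and b1 in Y:
        return MotifClass("cold")
    return MotifClass("other")


def find_overlapping_hot(nts_seq: str, pos: int) -> bool:
    """True iff the duplex position sits in a WGCW overlapping hot motif.

    ``pos`` is 1-based on the NTS.  For a C at ``pos`` the 4-mer tested
    is ``pos-2 .. pos+1`` (C in the third slot); for a G it is
    ``pos-1 .. pos+2`` (G in the second slot).  WGCW is its own reverse
    complement, so the test is strand-symmetric.
    """
    base = nts_seq[pos - 1]
    if base == "C":
        lo = pos - 3
    elif base == "G":
        lo = pos - 2
    else:
        return False
    if lo < 0 or lo + 4 > len(nts_seq):
        return False
    a, g, c, w = nts_seq[lo:lo + 4]
    return a in W and g == "G" and c == "C" and w in W


@dataclass
class SpectrumTable:
    """Per-C-site mutation spectrum for one strand library."""

    strand: str
    total_mutations: int
    table: pd.DataFrame  # coord, pos, strand, motif, overlapping_hot, region, rate, freq_pct, ...

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def per_site_spectrum(table: MutationTable, ref: ReferencePair,
                      alt_base: str = "T") -> SpectrumTable:
    """Annotate each C site with motif class, region, rate and frequency %.

    Rate follows the per-site definition (scored C->T supermutant
    families divided by all covered families at that site); frequency is
    the percentage of the strand's total mutations found at the site, so
    frequencies sum to 100 whenever any mutation was scored.
    """
    strand = table.strand
    seq = ref.strand_seq(strand)
    nts = ref.nts_seq
    df = table.table
    rows = []
    for _, r in df[df["ref"] == "C"].iterrows():
        pos = int(r["pos"])
        coord = ref.duplex_coord(strand, pos)
        nts_pos = coord - ref.coord_offset + 1
        mc = classify_site_motif(seq, pos)
        num = int(r[f"n_{alt_base}"])
        den = int(r["denominator"])
        rows.append({
            "coord": coord, "pos": pos, "strand": strand,
            "motif": mc.label, "edge": mc.edge,
            "overlapping_hot": mc.label == "hot" and find_overlapping_hot(nts, nts_pos),
            "region": ref.region_of(coord),
            "numerator": num, "denominator": den,
            "rate": num / den if den else np.nan,
        })
    out = pd.DataFrame(rows).sort_values("coord").reset_index(drop=True)
    total = int(out["numerator"].sum()) if len(out) else 0
    out["freq_pct"] = 100.0 * out["numerator"] / total if total > 0 else 0.0
    return SpectrumTable(strand=strand, total_mutations=total, table=out)


def region_distribution(spectrum: SpectrumTable,
                        exclude_coords=()) -> pd.DataFrame:
    """Percent of mutations per region; sums to 100 with 'unassigned'.

    ``exclude_coords`` removes sites from both the regional numerators
    and the total (used e.g. to mask the run of six consecutive TS Cs
    adjacent to the strong pause site).
    """
    df = spectrum.table
    if exclude_coords:
        df = df[~df["coord"].isin(set(exclude_coords))]
    total = df["numerator"].sum()
    grp = df.groupby("region")["numerator"].sum()
    out = grp.reset_index().rename(columns={"numerator": "mutations"})
    out["percent"] = 100.0 * out["mutations"] / total if total > 0 else 0.0
    return out


def spectrum_correlation(spec_a, spec_b, value: str = "rate") -> float:
    """Pearson r between two spectra at shared C-site coordinates."""
    a = spec_a.table if isinstance(spec_a, SpectrumTable) else spec_a
    b = spec_b.table if isinstance(spec_b, SpectrumTable) else spec_b
    merged = a.merge(b, on="coord", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need at least 3 shared sites for a correlation")
    r, _ = stats.pearsonr(merged[f"{value}_a"], merged[f"{value}_b"])
    return float(r)


def duplex_projection(spec_nts: SpectrumTable, spec_ts: SpectrumTable) -> pd.DataFrame:
    """Project both strands onto NTS coordinates as C/G rows.

    Published B-cell spectra report mutations per NTS position; a
    mutation at a G on the NTS corresponds to a C->T event on the TS.
    Frequencies are re-normalised over the combined mutation total.
    """
    frames = []
    for spec, base in ((spec_nts, "C"), (spec_ts, "G")):
        t = spec.table[["coord", "motif", "overlapping_hot", "region",
                        "numerator", "denominator", "rate"]].copy()
        t["duplex_base"] = base
        frames.append(t)
    out = pd.concat(frames).sort_values("coord").reset_index(drop=True)
    total = out["numerator"].sum()
    out["freq_pct"] = 100.0 * out["numerator"] / total if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# transcript 3'-end profiling


def count_transcript_ends(transcripts, ref: ReferencePair, k: int = 12):
    """Map transcript 3' ends to template coordinates by unique k-mer anchor.

    The nascent RNA has the NTS sequence (U for T).  Each transcript's
    terminal ``k``-mer is matched exactly against the NTS; a unique hit
    ending at duplex coordinate ``c`` places the polymerase 3' end at
    ``c``.  Ambiguous or absent anchors count as unmapped, as do
    transcripts shorter than ``k`` (AID-mutated templates can produce
    unmapped transcripts; they are logged, not guessed at).

    Returns ``(counts, unmapped)`` with ``counts`` a Series indexed by
    duplex coordinate.
    """
    nts = ref.nts_seq
    counts: dict[int, int] = {}
    unmapped = 0
    for t in transcripts:
        t = str(t).upper().replace("U", "T")
        if len(t) < k:
            unmapped += 1
            continue
        anchor = t[-k:]
        hits = []
        start = nts.find(anchor)
        while start != -1:
            hits.append(start)
            start = nts.find(anchor, start + 1)
        if len(hits) != 1:
            unmapped += 1
            continue
        coord = ref.coord_offset + hits[0] + k - 1
        counts[coord] = counts.get(coord, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    series.index.name = "coord"
    return series, unmapped


def compare_region_end_density(end_counts: pd.Series, ref: ReferencePair,
                               region_a: str, region_b: str):
    """Compare mean per-site 3'-end counts between two regions.

    Every template coordinate in a region contributes a count (zero if
    no transcript ended there); the two per-site samples are compared
    with a pooled two-tailed t-test.  Returns
    ``(mean_a, mean_b, p, degenerate)``; a zero pooled variance with
    unequal means is flagged degenerate and reported as p = 0.0
    (below the machine floor).
    """
    samples = []
    for name in (region_a, region_b):
        if name not in ref.regions:
            raise ValueError(f"unknown region {name!r}")
        start, end = ref.regions[name]
        if end - start + 1 < 2:
            raise ValueError(f"region {name!r} has fewer than 2 sites")
        samples.append(np.array([end_counts.get(c, 0) for c in range(start, end + 1)], dtype=float))
    a, b = samples
    res = two_sample_t(a, b)
    return float(a.mean()), float(b.mean()), res.p, res.degenerate
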