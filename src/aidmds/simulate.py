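"""Synthetic barcoded amplicon libraries with processive deamination.

Real libraries of this design are rarely available for method
development, so this module generates ground-truthed stand-ins: a
~203-nt two-strand amplicon with planted
hot (5'WRC), cold (5'SYC), "other" and overlapping (WGCW) motifs; clone
sets mutated by a processive deamination model; and UID-barcoded paired
FASTQ read families with PCR and sequencing errors.

Deamination is generated as Poisson-many enzyme engagements per clone,
each scanning a geometric-length tract from a uniform anchor and
deaminating every C in the tract with a motif-class acceptance
probability.  This engagement-tract construction yields a near-
exponential between-site mutation correlation whose length is
controlled by a single knob (``tract_mean``), matching the observed
behaviour of processive scanning within a stalled transcription bubble.

Everything is driven by a seeded :class:`numpy.random.Generator`; equal
seeds give byte-identical FASTQ and truth-table output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import DEFAULT_REGIONS, ReferencePair, revcomp
from .spectrum import classify_site_motif

# Plant k-mers on an A/T-only background: every C/G in the reference
# comes from a plant, so motif counts are exact by construction.
#   TAC  -> one hot C on the planted strand, no G (no opposite-strand C)
#   GTC  -> one cold C (G,T = S,Y); its G creates one "other" C on the
#           opposite strand
#   ATC  -> one "other" C, no G
#   AGCT -> WGCW: one hot C on each strand (its own reverse complement)
PLANT_KMERS = {"hot": "TAC", "cold": "GTC", "other": "ATC", "wgcw": "AGCT"}
_PLANT_GAP = 2  # >=2 background W bases between plants keep classes independent


@dataclass
class DeaminationModel:
    """Motif-dependent processive deamination of C on one strand.

    Parameters
    ----------
    p_hot, p_other, p_cold:
        Per-site deamination acceptance probabilities for each motif
        class while a tract covers the site (must satisfy
        ``p_cold <= p_other <= p_hot``).
    burst_rate:
        Poisson mean number of enzyme engagements per clone.
    tract_mean:
        Mean tract length in nt (geometric, support >= 1).
    strand_mode:
        'NTS', 'TS', or 'both' (each clone assigned a strand at random).
    """

    p_hot: float = 0.30
    p_other: float = 0.10
    p_cold: float = 0.015
    burst_rate: float = 1.0
    tract_mean: float = 15.0
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        if not 0 <= self.p_cold <= self.p_other <= self.p_hot <= 1:
            raise ValueError("need 0 <= p_cold <= p_other <= p_hot <= 1")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1")
        if self.strand_mode not in ("NTS", "TS", "both"):
            raise ValueError("strand_mode must be NTS, TS or both")


@dataclass
class SequencingModel:
    """UID barcoding, family-size, error and quality model.

    ``family_size`` is either ``("fixed", n)`` or ``("poisson", mean)``;
    zero-size families are legal (the clone is simply never observed).
    PCR errors hit the template copy once per family before
    amplification; sequencing errors hit each read independently.
    Qualities are two-component: ``quality_high`` with probability
    ``high_fraction``, else ``quality_low`` -- enough to exercise the
    >=Q30 gates of the caller.
    """

    uid_length: int = 24
    family_size: tuple = ("poisson", 6.0)
    seq_error_rate: float = 1e-3
    pcr_error_rate: float = 1e-4
    quality_high: int = 37
    quality_low: int = 12
    high_fraction: float = 0.98
    read_length: int = 150

    def __post_init__(self) -> None:
        if self.uid_length < 1:
            raise ValueError("uid_length must be >= 1")
        for p in (self.seq_error_rate, self.pcr_error_rate, self.high_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def draw_family_size(self, rng: np.random.Generator) -> int:
        kind, value = self.family_size
        if kind == "fixed":
            return int(value)
        if kind == "poisson":
            return int(rng.poisson(value))
        raise ValueError(f"unknown family size distribution {kind!r}")


@dataclass
class Clone:
    clone_id: int
    strand: str
    mutations: dict[int, tuple[str, str]]  # local pos -> (ref, alt)


@dataclass
class CloneSet:
    ref: ReferencePair
    clones: list[Clone] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        """One row per true mutation: clone_id, strand, pos, coord, ref, alt."""
        rows = []
        for c in self.clones:
            for pos in sorted(c.mutations):
                ref_b, alt_b = c.mutations[pos]
                rows.append((c.clone_id, c.strand, pos,
                             self.ref.duplex_coord(c.strand, pos), ref_b, alt_b))
        return pd.DataFrame(rows, columns=["clone_id", "strand", "pos", "coord", "ref", "alt"])


class MotifPlanError(ValueError):
    """A motif plan cannot be realised within its region."""


def generate_reference(length: int = 203,
                       motif_plan: dict[str, dict[str, int]] | None = None,
                       seed: int = 0,
                       name: str = "synthetic_igv",
                       coord_offset: int = 1,
                       regions: dict[str, tuple[int, int]] | None = None) -> ReferencePair:
    """Build a two-strand reference with exactly the planted motif counts.

    ``motif_plan`` maps region name -> ``{"hot": n, "cold": n,
    "other": n, "wgcw": n}``.  The background is A/T only, so planted
    k-mers are the sole source of C/G and the requested counts are met
    exactly; plants are placed at random non-adjacent offsets within
    their region.  Raises :class:`MotifPlanError` (naming the region)
    when a plan cannot fit.
    """
    if length < 60:
        raise ValueError("length must be >= 60")
    rng = np.random.default_rng(seed)
    if regions is None:
        regions = {k: v for k, v in DEFAULT_REGIONS.items()
                   if v[1] <= coord_offset + length - 1}
    if motif_plan is None:
        motif_plan = default_motif_plan(regions)

    seq = rng.choice(list("AT"), size=length)
    for rname, counts in motif_plan.items():
        if rname not in regions:
            raise MotifPlanError(f"motif plan names unknown region {rname!r}")
        start, end = regions[rname]
        lo = start - coord_offset          # 0-based slice bounds
        hi = end - coord_offset + 1
        kmers = []
        for cls in ("wgcw", "hot", "cold", "other"):
            kmers += [PLANT_KMERS[cls]] * int(counts.get(cls, 0))
        if not kmers:
            continue
        rng.shuffle(kmers)
        footprint = sum(len(k) + _PLANT_GAP for k in kmers)
        if footprint > hi - lo:
            raise MotifPlanError(
                f"motif plan infeasible in region {rname!r}: needs {footprint} nt, "
                f"region has {hi - lo}")
        # distribute the slack randomly between plants
        slack = (hi - lo) - footprint
        cuts = np.sort(rng.integers(0, slack + 1, size=len(kmers)))
        pos = lo
        for k, extra in zip(kmers, np.concatenate([[cuts[0]], np.diff(cuts)]) if kmers else []):
            pos += int(extra) + _PLANT_GAP
            seq[pos:pos + len(k)] = list(k)
            pos += len(k)
    ref = ReferencePair(name=name, nts_seq="".join(seq), coord_offset=coord_offset,
                        regions=regions)
    _verify_plan(ref, motif_plan)
    return ref


def default_motif_plan(regions: dict[str, tuple[int, int]]) -> dict[str, dict[str, int]]:
    """A plan echoing the IGHV3-23*01 motif layout: hot-motif-rich CDRs
    (with WGCW overlapping sites), sparse FWs, and a C run-capable FW1.
    """
    plan = {
        "scaffold_bubble": {"hot": 1, "cold": 1},
        "FW1": {"hot": 1, "cold": 2, "other": 2},
        "CDR1": {"wgcw": 2, "hot": 3, "cold": 1, "other": 1},
        "FW2": {"hot": 2, "cold": 3, "other": 2},
        "CDR2": {"wgcw": 1, "hot": 3, "cold": 1, "other": 1},
        "FW3": {"hot": 2, "cold": 2, "other": 1},
    }
    return {k: v for k, v in plan.items() if k in regions}


def count_motifs(ref: ReferencePair) -> dict[str, int]:
    """Count motif-classified C sites over both strands of the duplex."""
    out = {"hot": 0, "cold": 0, "other": 0, "wgcw": 0}
    for strand in ("NTS", "TS"):
        seq = ref.strand_seq(strand)
        for pos in ref.c_positions(strand):
            out[classify_site_motif(seq, pos).label] += 1
    for i in range(1, len(ref) - 2):
        window = ref.nts_seq[i - 1:i + 3]
        if window[0] in "AT" and window[1] == "G" and window[2] == "C" and window[3] in "AT":
            out["wgcw"] += 1
    return out


def _verify_plan(ref: ReferencePair, motif_plan: dict[str, dict[str, int]]) -> None:
    want = {"hot": 0, "cold": 0, "other": 0, "wgcw": 0}
    for counts in motif_plan.values():
        for cls in want:
            want[cls] += int(counts.get(cls, 0))
    got = count_motifs(ref)
    # each WGCW contributes a hot C on both strands; each cold plant's G
    # yields one "other" C on the opposite strand
    expect = {
        "wgcw": want["wgcw"],
        "hot": want["hot"] + 2 * want["wgcw"],
        "cold": want["cold"],
        "other": want["other"] + want["cold"],
    }
    if got != expect:
        raise MotifPlanError(f"planted motif verification failed: expected {expect}, got {got}")


# ---------------------------------------------------------------------------
# clone mutation simulation


def site_acceptance(ref: ReferencePair, strand: str, model: DeaminationModel) -> dict[int, float]:
    """Per-C-site acceptance probability (local pos -> p) on a strand."""
    seq = ref.strand_seq(strand)
    probs = {}
    for pos in ref.c_positions(strand):
        label = classify_site_motif(seq, pos).label
        probs[pos] = {"hot": model.p_hot, "cold": model.p_cold, "other": model.p_other}[label]
    return probs


def simulate_clone_mutations(ref: ReferencePair, model: DeaminationModel,
                             n_clones: int, seed: int = 0) -> CloneSet:
    """Simulate processive C->T deamination on ``n_clones`` templates.

    Per clone: draw Poisson(``burst_rate``) engagements; each engagement
    anchors uniformly on the strand, extends a geometric tract of mean
    ``tract_mean`` in a random direction, and deaminates every C it
    covers with that site's motif-class probability.  Sites hit more
    than once stay mutated.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(ref)
    acceptance = {s: site_acceptance(ref, s, model) for s in ("NTS", "TS")}
    clones = []
    for cid in range(n_clones):
        if model.strand_mode == "both":
            strand = "NTS" if rng.random() < 0.5 else "TS"
        else:
            strand = model.strand_mode
        probs = acceptance[strand]
        muts: dict[int, tuple[str, str]] = {}
        for _ in range(rng.poisson(model.burst_rate)):
            anchor = int(rng.integers(1, L + 1))
            tract = int(rng.geometric(1.0 / model.tract_mean))
            if rng.random() < 0.5:
                lo, hi = anchor, min(L, anchor + tract - 1)
            else:
                lo, hi = max(1, anchor - tract + 1), anchor
            for pos, p in probs.items():
                if lo <= pos <= hi and rng.random() < p:
                    muts[pos] = ("C", "T")
        clones.append(Clone(clone_id=cid, strand=strand, mutations=muts))
    return CloneSet(ref=ref, clones=clones)


# ---------------------------------------------------------------------------
# read emission


_PHRED = {q: chr(q + 33) for q in range(0, 94)}


def _mutate_bases(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with a uniform different base at ``rate``."""
    if rate <= 0:
        return seq
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return seq


def emit_read_families(clones: CloneSet, model: SequencingModel, seed: int = 0,
                       r1_path=None, r2_path=None, truth_path=None):
    """Emit paired-end FASTQ read families plus the ground-truth table.

    Per clone: append a unique random UID of ``uid_length`` at the 3'
    end of the mutated insert, draw the family size, apply PCR errors
    once to the family template, then per-read sequencing errors and
    the two-component quality model.  R1 is the fragment 5' prefix and
    R2 the reverse-complemented 3' suffix, overlapping so their merge
    covers the whole fragment.

    Returns ``(records, truth)``: records grouped per strand as
    ``{strand: (r1_records, r2_records)}`` with each record a
    ``(name, seq, qual_string)`` triple, and the truth DataFrame.  When
    paths are given, FASTQ/TSV files are written (R1/R2 interleave both
    strands' libraries in clone order; callers split by strand via the
    record names).
    """
    rng = np.random.default_rng(seed)
    ref = clones.ref
    lib: dict[str, tuple[list, list]] = {"NTS": ([], []), "TS": ([], [])}
    seen_uids: set[str] = set()
    uid_collisions = 0
    for clone in clones.clones:
        uid = "".join(rng.choice(list("ACGT"), size=model.uid_length))
        if uid in seen_uids:
            uid_collisions += 1
        seen_uids.add(uid)
        insert = list(ref.strand_seq(clone.strand))
        for pos, (_, alt) in clone.mutations.items():
            insert[pos - 1] = alt
        fragment = np.array(insert + list(uid))
        n_reads = model.draw_family_size(rng)
        fragment = _mutate_bases(fragment.copy(), model.pcr_error_rate, rng)
        n = fragment.size
        r1_len = min(model.read_length, n)
        r2_len = min(model.read_length, n)
        for k in range(n_reads):
            read = _mutate_bases(fragment.copy(), model.seq_error_rate, rng)
            qual = np.where(rng.random(n) < model.high_fraction,
                            model.quality_high, model.quality_low)
            name = f"clone{clone.clone_id}:{clone.strand}:{k}"
            r1 = "".join(read[:r1_len])
            q1 = "".join(_PHRED[q] for q in qual[:r1_len])
            r2 = revcomp("".join(read[n - r2_len:]))
            q2 = "".join(_PHRED[q] for q in qual[n - r2_len:][::-1])
            lib[clone.strand][0].append((name, r1, q1))
            lib[clone.strand][1].append((name, r2, q2))
    truth = clones.truth_table()
    if r1_path is not None:
        write_fastq(r1_path, lib["NTS"][0] + lib["TS"][0])
    if r2_path is not None:
        write_fastq(r2_path, lib["NTS"][1] + lib["TS"][1])
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return lib, truth, {"uid_collisions": uid_collisions}


def write_fastq(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
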