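"""Maximum-depth-sequencing (MDS) consensus mutation caller.

Reads carry a random UID barcode at their 3' end; all reads sharing a
UID derive from one original template molecule ("clone").  Calling a
mutation only when nearly every read in a UID family agrees on the same
non-reference base suppresses PCR and sequencing errors, whose chance of
recurring identically across >=3 independent reads is negligible.

Rules implemented (defaults in parentheses):

* UID = terminal ``uid_length`` (24) bases of the merged read; rejected
  if any UID base has Phred quality < ``min_qual`` (30).
* A read qualifies if it has the reference length (ungapped register)
  and fewer than ``max_mismatch + 1`` (20) mismatches to the reference.
* Families need at least ``family_min`` (3) reads.
* At a site, the family denominator requires >= ``family_min`` reads
  with site quality >= ``min_qual``; a *supermutant* is called when
  >= ``consensus`` (95%) of those reads share the same non-reference
  base.  Mixed ("ambiguous") families count in the denominator only.
* Per-site mutation rate = supermutant families / covered families.
"""

from __future__ import annotations

import collections
import gzip
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from Bio import SeqIO

from .sequences import ReferencePair, revcomp

BASES = "ACGT"


class Reject(Enum):
    TOO_SHORT = "too_short"
    UID_QUALITY = "uid_quality"
    LENGTH_MISMATCH = "length_mismatch"
    TOO_MANY_MISMATCHES = "too_many_mismatches"


@dataclass
class QualifiedRead:
    uid: str
    insert: str
    qualities: np.ndarray  # per-base Phred, len == len(insert)
    mismatch_count: int


@dataclass
class ReadFamily:
    uid: str
    members: list[QualifiedRead]

    def __len__(self) -> int:
        return len(self.members)


class Verdict(Enum):
    NO_COVERAGE = "no_coverage"
    REFERENCE_CALL = "reference_call"
    SUPERMUTANT = "supermutant"
    AMBIGUOUS = "ambiguous"


@dataclass
class SiteVerdict:
    verdict: Verdict
    alt: str | None = None  # set iff verdict is SUPERMUTANT

    def __post_init__(self) -> None:
        if self.verdict is Verdict.SUPERMUTANT and self.alt not in set(BASES):
            raise ValueError("supermutant verdict requires a single alt base")


@dataclass
class MutationTable:
    """Per-site numerator/denominator counts for one strand library.

    ``table`` columns: pos (1-based local), ref, denominator, one
    numerator column per alt base (A/C/G/T; the ref-base column is 0),
    rate (total supermutant families / denominator).
    """

    strand: str
    table: pd.DataFrame

    def aggregate_rate(self, ref_base: str = "C", alt_base: str = "T") -> float:
        return aggregate_rate(self, ref_base=ref_base, alt_base=alt_base)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "strand", self.strand)
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "MutationTable":
        df = pd.read_csv(path, sep="\t")
        strand = str(df["strand"].iloc[0]) if len(df) else "NTS"
        return cls(strand=strand, table=df.drop(columns=["strand"]))


# ---------------------------------------------------------------------------
# read-level operations


def merge_pair(r1_seq: str, r1_qual, r2_seq: str, r2_qual, fragment_length: int):
    """Merge an overlapping read pair into one full-length fragment.

    R1 covers the fragment 5' end, R2 the 3' end (reverse-complemented).
    In the overlap the base with the higher quality wins (tie -> R1).
    Returns ``(seq, qual)`` or ``None`` if the pair cannot span the
    fragment.
    """
    r1_qual = np.asarray(r1_qual, dtype=int)
    r2_qual = np.asarray(r2_qual, dtype=int)
    if len(r1_seq) + len(r2_seq) < fragment_length:
        return None
    seq = np.full(fragment_length, "N", dtype="<U1")
    qual = np.zeros(fragment_length, dtype=int)
    n1 = min(len(r1_seq), fragment_length)
    seq[:n1] = list(r1_seq[:n1])
    qual[:n1] = r1_qual[:n1]
    r2_fwd = revcomp(r2_seq)
    r2_q = r2_qual[::-1]
    n2 = min(len(r2_fwd), fragment_length)
    start = fragment_length - n2
    r2_arr = np.array(list(r2_fwd[-n2:] if n2 < len(r2_fwd) else r2_fwd), dtype="<U1")
    take = (r2_q[-n2:] if n2 < len(r2_q) else r2_q) > qual[start:]
    take |= seq[start:] == "N"
    seq[start:][take] = r2_arr[take]
    qual[start:][take] = (r2_q[-n2:] if n2 < len(r2_q) else r2_q)[take]
    return "".join(seq), qual


def parse_uid(raw_seq: str, raw_qual, uid_length: int = 24, min_uid_qual: int = 30):
    """Split a raw (merged) read into (uid, insert, insert qualities).

    The UID is the terminal ``uid_length`` bases at the 3' end.  Returns
    a :class:`Reject` reason if the read is too short to contain any
    insert, or if any UID base falls below the quality threshold.
    """
    raw_qual = np.asarray(raw_qual, dtype=int)
    if len(raw_seq) < uid_length + 1:
        return Reject.TOO_SHORT
    uid = raw_seq[-uid_length:]
    if np.any(raw_qual[-uid_length:] < min_uid_qual):
        return Reject.UID_QUALITY
    return uid, raw_seq[:-uid_length], raw_qual[:-uid_length]


def qualify_read(uid: str, insert: str, qualities, reference: str, max_mismatch: int = 19):
    """Positional (ungapped) comparison to the reference.

    Amplicon design guarantees register, so any length deviation is
    treated as indel-containing and rejected.  A read passes with at
    most ``max_mismatch`` mismatches (i.e. fewer than 20 by default).
    """
    if len(insert) != len(reference):
        return Reject.LENGTH_MISMATCH
    mm = sum(a != b for a, b in zip(insert, reference))
    if mm > max_mismatch:
        return Reject.TOO_MANY_MISMATCHES
    return QualifiedRead(uid=uid, insert=insert, qualities=np.asarray(qualities, dtype=int),
                         mismatch_count=mm)


def build_families(reads, family_min: int = 3, log: dict | None = None) -> list[ReadFamily]:
    """Group qualified reads by exact UID match; drop small families."""
    groups: dict[str, list[QualifiedRead]] = collections.defaultdict(list)
    for read in reads:
        groups[read.uid].append(read)
    families = []
    dropped = 0
    for uid in sorted(groups):
        members = groups[uid]
        if len(members) >= family_min:
            families.append(ReadFamily(uid=uid, members=members))
        else:
            dropped += 1
    if log is not None:
        log["uid_groups"] = len(groups)
        log["families_kept"] = len(families)
        log["families_below_min"] = dropped
    return families


# ---------------------------------------------------------------------------
# family/site-level calling


def call_family_site(family: ReadFamily, pos: int, ref_base: str,
                     min_qual: int = 30, family_min: int = 3,
                     consensus: float = 0.95) -> SiteVerdict:
    """Apply the supermutant rule at one site (1-based ``pos``).

    Qualifying reads are family members whose quality at the site is at
    least ``min_qual``.  With fewer than ``family_min`` qualifying reads
    the family does not cover the site.  A supermutant needs a fraction
    >= ``consensus`` of qualifying reads to share one non-reference
    base; a reference call needs the same consensus on the reference
    base; anything else is ambiguous (denominator only).
    """
    if not 1 <= pos <= len(family.members[0].insert):
        raise ValueError(f"site {pos} outside reference")
    i = pos - 1
    bases = [m.insert[i] for m in family.members if m.qualities[i] >= min_qual]
    if len(bases) < family_min:
        return SiteVerdict(Verdict.NO_COVERAGE)
    counts = collections.Counter(bases)
    # tiny epsilon so the exact ">=95%" boundary (e.g. 19/20) is robust
    # to floating-point representation of the consensus fraction
    need = consensus * len(bases) - 1e-9
    best, best_n = max(counts.items(), key=lambda kv: (kv[1], kv[0] == ref_base))
    # two distinct bases can both reach the threshold only if consensus <= 0.5;
    # such ties are treated as ambiguous
    if best_n >= need and sum(n >= need for n in counts.values()) == 1:
        if best == ref_base:
            return SiteVerdict(Verdict.REFERENCE_CALL)
        if best in BASES:
            return SiteVerdict(Verdict.SUPERMUTANT, alt=best)
    return SiteVerdict(Verdict.AMBIGUOUS)


def _family_verdicts(fam: ReadFamily, min_qual: int, family_min: int, consensus: float):
    """Vectorised per-site verdicts for one family.

    Returns ``(covered, alt_idx)``: a boolean site mask of denominator
    coverage and an int array holding the supermutant alt-base index
    (0..3 into ``BASES``) or -1 where no supermutant is called.
    Equivalent site-by-site to :func:`call_family_site` except for the
    reference/ambiguous distinction, which the tabulation never needs.
    """
    seqs = np.array([list(m.insert) for m in fam.members])
    quals = np.stack([m.qualities for m in fam.members])
    ok = quals >= min_qual
    n_ok = ok.sum(axis=0)
    covered = n_ok >= family_min
    counts = np.stack([((seqs == b) & ok).sum(axis=0) for b in BASES])
    need = consensus * n_ok - 1e-9
    reach = counts >= np.maximum(need, 1e-9)
    single = reach.sum(axis=0) == 1
    alt_idx = np.where(single, reach.argmax(axis=0), -1)
    alt_idx = np.where(covered, alt_idx, -1)
    return covered, alt_idx


def tabulate_mutations(families, reference: str, strand: str = "NTS",
                       min_qual: int = 30, family_min: int = 3,
                       consensus: float = 0.95) -> MutationTable:
    """Per-site numerator/denominator counts over all families.

    Vectorised over sites within each family; equivalent site-by-site to
    :func:`call_family_site`.
    """
    L = len(reference)
    ref_idx = np.array([BASES.index(b) if b in BASES else -1 for b in reference])
    denom = np.zeros(L, dtype=np.int64)
    numer = np.zeros((4, L), dtype=np.int64)  # alt base x site

    for fam in families:
        if not fam.members:
            continue
        covered, alt_idx = _family_verdicts(fam, min_qual, family_min, consensus)
        denom += covered
        for bi in range(4):
            numer[bi] += (alt_idx == bi) & (ref_idx != bi)
    cols = {"pos": np.arange(1, L + 1), "ref": list(reference), "denominator": denom}
    for bi, b in enumerate(BASES):
        cols[f"n_{b}"] = numer[bi]
    total_mut = numer.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(denom > 0, total_mut / np.maximum(denom, 1), np.nan)
    cols["rate"] = rate
    return MutationTable(strand=strand, table=pd.DataFrame(cols))


def aggregate_rate(table: MutationTable, ref_base: str = "C", alt_base: str = "T") -> float:
    """Library-wide rate: sum of numerators over sum of denominators.

    Default filters to C sites and C->T calls, the headline statistic
    (total C->T supermutants / total sequenced C templates).  Raises if
    no site passes the filter or the total denominator is zero.
    """
    df = table.table
    sel = df[df["ref"] == ref_base]
    if sel.empty:
        raise ValueError(f"no {ref_base} sites in table")
    den = int(sel["denominator"].sum())
    if den == 0:
        raise ValueError("total denominator is zero; rate undefined")
    num = int(sel[f"n_{alt_base}"].sum())
    return num / den


# ---------------------------------------------------------------------------
# clone-level calls (input to the processivity analysis)


def clone_calls(families, reference: str, strand: str = "NTS",
                min_qual: int = 30, family_min: int = 3,
                consensus: float = 0.95) -> pd.DataFrame:
    """One row per supermutant call: uid, strand, pos, ref, alt.

    Families with no supermutant still matter for per-clone statistics;
    they are retrievable as UIDs absent from the result but present in
    ``families``.
    """
    ref_idx = np.array([BASES.index(b) if b in BASES else -1 for b in reference])
    rows = []
    for fam in families:
        if not fam.members:
            continue
        _, alt_idx = _family_verdicts(fam, min_qual, family_min, consensus)
        for pos in np.nonzero((alt_idx >= 0) & (alt_idx != ref_idx))[0]:
            rows.append((fam.uid, strand, int(pos) + 1, reference[pos], BASES[alt_idx[pos]]))
    return pd.DataFrame(rows, columns=["uid", "strand", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# FASTQ-level pipeline


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path):
    """Yield ``(id, seq, qual array)`` from a (possibly gzipped) FASTQ."""
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq), np.array(rec.letter_annotations["phred_quality"], dtype=int)


@dataclass
class CallResult:
    table: MutationTable
    clones: pd.DataFrame
    families: list[ReadFamily] = field(repr=False, default_factory=list)
    log: dict = field(default_factory=dict)


def call_library(r1_path, r2_path, ref: ReferencePair, strand: str,
                 uid_length: int = 24, min_qual: int = 30, family_min: int = 3,
                 max_mismatch: int = 19, consensus: float = 0.95) -> CallResult:
    """Run the full caller on a paired-end FASTQ library for one strand."""
    reference = ref.strand_seq(strand)
    fragment_length = len(reference) + uid_length
    log: dict = collections.Counter()
    qualified = []
    for (id1, s1, q1), (id2, s2, q2) in zip(read_fastq(r1_path), read_fastq(r2_path)):
        log["pairs_in"] += 1
        merged = merge_pair(s1, q1, s2, q2, fragment_length)
        if merged is None:
            log["rejected_unmergeable"] += 1
            continue
        parsed = parse_uid(*merged, uid_length=uid_length, min_uid_qual=min_qual)
        if isinstance(parsed, Reject):
            log[f"rejected_{parsed.value}"] += 1
            continue
        uid, insert, iq = parsed
        read = qualify_read(uid, insert, iq, reference, max_mismatch=max_mismatch)
        if isinstance(read, Reject):
            log[f"rejected_{read.value}"] += 1
            continue
        qualified.append(read)
    log = dict(log)
    families = build_families(qualified, family_min=family_min, log=log)
    table = tabulate_mutations(families, reference, strand=strand, min_qual=min_qual,
                               family_min=family_min, consensus=consensus)
    clones = clone_calls(families, reference, strand=strand, min_qual=min_qual,
                         family_min=family_min, consensus=consensus)
    return CallResult(table=table, clones=clones, families=families, log=log)
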