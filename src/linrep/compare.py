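"""Anchor-based comparison of two near-identical replicons.

Compares a reference replicon *a* against a derived replicon *b* (e.g. a
parental plasmid against the plasmid of a descendant strain) in four steps:

1. :func:`find_anchors` -- k-mers unique in both sequences, matched forward
   and reverse-complement and merged into maximal exact matches (the dots of
   a dot plot);
2. :func:`chain_blocks` -- collinear anchors chained into synteny blocks
   with a per-block identity from gapped alignment of the inter-anchor gaps;
3. :func:`classify_events` -- block gaps and order changes classified into
   insertion / deletion / inversion / translocation / duplication events;
4. :func:`call_snps` + :func:`classify_snp_effect` -- within-block alignment
   columns turned into substitution and short-indel calls, with a
   coding-effect classification against a feature annotation.

All reported coordinates are 1-based inclusive; internal work is 0-based
half-open.  The size boundary between a "short indel" (reported as a SNP
call) and a rearrangement event is 50 bp by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import __version__
from .io import FeatureRecord, reverse_complement

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "RearrangementEvent",
    "SnpCall",
    "find_anchors",
    "chain_blocks",
    "classify_events",
    "call_snps",
    "classify_snp_effect",
    "export_dotplot",
    "INDEL_EVENT_BOUNDARY",
]

FORWARD = "forward"
REVERSE = "reverse"

#: indels below this size are SNP calls; at or above it, rearrangement events
INDEL_EVENT_BOUNDARY = 50


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match between the two sequences (0-based starts).

    For a reverse anchor, ``seq_a[pos_a:pos_a+length]`` equals the reverse
    complement of ``seq_b[pos_b:pos_b+length]``; ``pos_b`` is always the
    leftmost coordinate of the matched segment on *b*'s forward strand.
    """

    pos_a: int
    pos_b: int
    length: int
    orientation: str

    @property
    def end_a(self) -> int:
        return self.pos_a + self.length

    @property
    def end_b(self) -> int:
        return self.pos_b + self.length


@dataclass(frozen=True)
class SyntenyBlock:
    """A collinear aligned region (0-based half-open intervals)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str
    identity: float

    @property
    def a_span(self) -> int:
        return self.a_end - self.a_start

    @property
    def b_span(self) -> int:
        return self.b_end - self.b_start


@dataclass(frozen=True)
class RearrangementEvent:
    """A classified structural difference, reported in 1-based coordinates.

    ``a_locus`` is a point on the reference; for insertions ``b_interval[0]``
    is the 1-based coordinate on the derived sequence of the first inserted
    base (the convention in which insertion positions are usually printed).
    """

    type: str  # insertion | deletion | inversion | translocation | duplication
    a_locus: int
    b_interval: tuple[int, int]
    length: int


@dataclass(frozen=True)
class SnpCall:
    """A substitution or short indel (1-based positions; '-' marks the empty side)."""

    pos_a: int
    pos_b: int
    ref_base: str
    alt_base: str
    effect: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")

    @property
    def is_indel(self) -> bool:
        return "-" in (self.ref_base, self.alt_base) or len(self.ref_base) != len(self.alt_base)


# ---------------------------------------------------------------------------
# anchors


def _kmer_census(seq: str, k: int) -> tuple[dict[str, int], dict[str, int]]:
    """First position and occurrence count (capped at 2) of each k-mer."""
    first: dict[str, int] = {}
    count: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k]
        c = count.get(kmer, 0)
        if c == 0:
            first[kmer] = i
            count[kmer] = 1
        elif c == 1:
            count[kmer] = 2
    return first, count


def find_anchors(seq_a: str, seq_b: str, k: int = 21) -> list[Anchor]:
    """Maximal exact matches built from k-mers unique in both sequences.

    Uniqueness is double-stranded: a k-mer whose reverse complement also
    occurs is not unique.  k = 21 is effectively unique in a ~300-kb plasmid
    even at 70% GC; repeated regions (transposase cassettes) simply
    contribute no anchors and surface later as unaligned gaps.
    """
    if k > len(seq_a) or k > len(seq_b):
        raise ValueError(f"k={k} exceeds a sequence length")
    first_a, count_a = _kmer_census(seq_a, k)
    first_b, count_b = _kmer_census(seq_b, k)

    fwd: list[tuple[int, int]] = []
    rev: list[tuple[int, int]] = []
    for kmer, pa in first_a.items():
        if "N" in kmer:
            continue
        rc = reverse_complement(kmer)
        ca = count_a[kmer] + (count_a.get(rc, 0) if rc != kmer else 0)
        if ca != 1:
            continue
        cb_f = count_b.get(kmer, 0)
        cb_r = count_b.get(rc, 0) if rc != kmer else 0
        if cb_f + cb_r != 1:
            continue
        if cb_f:
            fwd.append((pa, first_b[kmer]))
        else:
            rev.append((pa, first_b[rc]))

    anchors: list[Anchor] = []
    # Forward runs share a diagonal (pb - pa) and advance one base at a time.
    fwd.sort(key=lambda m: (m[1] - m[0], m[0]))
    i = 0
    while i < len(fwd):
        j = i
        while (
            j + 1 < len(fwd)
            and fwd[j + 1][1] - fwd[j + 1][0] == fwd[i][1] - fwd[i][0]
            and fwd[j + 1][0] == fwd[j][0] + 1
        ):
            j += 1
        run = j - i + 1
        anchors.append(Anchor(fwd[i][0], fwd[i][1], run + k - 1, FORWARD))
        i = j + 1
    # Reverse runs share an anti-diagonal (pb + pa); pb decreases as pa grows.
    rev.sort(key=lambda m: (m[0] + m[1], m[0]))
    i = 0
    while i < len(rev):
        j = i
        while (
            j + 1 < len(rev)
            and rev[j + 1][0] + rev[j + 1][1] == rev[i][0] + rev[i][1]
            and rev[j + 1][0] == rev[j][0] + 1
        ):
            j += 1
        run = j - i + 1
        pa0, pb0 = rev[i]
        anchors.append(Anchor(pa0, pb0 - (run - 1), run + k - 1, REVERSE))
        i = j + 1
    anchors.sort(key=lambda a: a.pos_a)
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _edit_distance(x: str, y: str) -> int:
    if not x:
        return len(y)
    if not y:
        return len(x)
    return edlib.align(x, y, mode="NW", task="distance")["editDistance"]


def chain_blocks(
    anchors: Sequence[Anchor],
    seq_a: str,
    seq_b: str,
    max_gap: int = 5000,
    min_block: int = 500,
    indel_cap: int = INDEL_EVENT_BOUNDARY,
) -> list[SyntenyBlock]:
    """Chain collinear same-orientation anchors into synteny blocks.

    Links allow gaps up to *max_gap* on either sequence but a gap-length
    difference of at most *indel_cap*: any indel at or above the SNP/event
    size boundary breaks the chain, so it surfaces as a gap between blocks
    for :func:`classify_events` instead of hiding inside one.  Chains are
    extracted greedily by best total anchored length; blocks shorter than
    *min_block* on the reference are dropped.  Identity comes from gapped
    (edlib) alignment of the inter-anchor gaps.
    """
    remaining = sorted(anchors, key=lambda a: a.pos_a)
    # Anchors big enough that a link must never jump over them: if one sits
    # inside a link's gap, the true structure has a block boundary there.
    blockers = [a for a in anchors if a.length >= indel_cap]

    def _blocked(lo_a: int, hi_a: int, lo_b: int, hi_b: int, ai, aj) -> bool:
        for x in blockers:
            if x is ai or x is aj:
                continue
            if lo_a <= x.pos_a and x.end_a <= hi_a:
                return True
            if lo_b <= x.pos_b and x.end_b <= hi_b:
                return True
        return False

    blocks: list[SyntenyBlock] = []
    while remaining:
        n = len(remaining)
        score = [a.length for a in remaining]
        back = [-1] * n
        for j in range(n):
            aj = remaining[j]
            for i in range(j):
                ai = remaining[i]
                if ai.orientation != aj.orientation:
                    continue
                ga = aj.pos_a - ai.end_a
                if aj.orientation == FORWARD:
                    gb = aj.pos_b - ai.end_b
                    b_lo, b_hi = ai.end_b, aj.pos_b
                else:
                    gb = ai.pos_b - aj.end_b
                    b_lo, b_hi = aj.end_b, ai.pos_b
                if not (-indel_cap <= ga <= max_gap and -indel_cap <= gb <= max_gap):
                    continue
                if abs(ga - gb) > indel_cap:
                    continue
                if (ga >= indel_cap or gb >= indel_cap) and _blocked(
                    ai.end_a, aj.pos_a, b_lo, b_hi, ai, aj
                ):
                    continue
                # A long anchor-free gap equal on both sides could still be
                # a replaced region: only link across it if the gap
                # sequences actually align (unrelated 70%-GC sequence sits
                # near 48% divergence; genuine SNP clusters are a few %).
                if min(ga, gb) > 20:
                    gap_a = seq_a[ai.end_a: aj.pos_a]
                    if aj.orientation == FORWARD:
                        gap_b = seq_b[ai.end_b: aj.pos_b]
                    else:
                        gap_b = reverse_complement(seq_b[aj.end_b: ai.pos_b])
                    if _edit_distance(gap_b, gap_a) > 0.3 * max(ga, gb):
                        continue
                cand = score[i] + aj.length
                if cand > score[j]:
                    score[j] = cand
                    back[j] = i
        best = int(np.argmax(score))
        chain_idx = []
        i = best
        while i != -1:
            chain_idx.append(i)
            i = back[i]
        chain_idx.reverse()
        chain = [remaining[i] for i in chain_idx]
        used = set(chain_idx)
        remaining = [a for i, a in enumerate(remaining) if i not in used]

        a_start, a_end = chain[0].pos_a, chain[-1].end_a
        if chain[0].orientation == FORWARD:
            b_start, b_end = chain[0].pos_b, chain[-1].end_b
        else:
            b_start, b_end = chain[-1].pos_b, chain[0].end_b
        if a_end - a_start < min_block:
            continue

        edits = 0
        for prev, nxt in zip(chain, chain[1:]):
            gap_a = seq_a[prev.end_a: nxt.pos_a]
            if prev.orientation == FORWARD:
                gap_b = seq_b[prev.end_b: nxt.pos_b]
            else:
                gap_b = reverse_complement(seq_b[nxt.end_b: prev.pos_b])
            edits += _edit_distance(gap_b, gap_a)
        span = max(a_end - a_start, b_end - b_start)
        identity = 1.0 - edits / span if span else 1.0
        blocks.append(
            SyntenyBlock(a_start, a_end, b_start, b_end, chain[0].orientation, identity)
        )
    blocks.sort(key=lambda b: b.a_start)
    return blocks


# ---------------------------------------------------------------------------
# event classification


_SLOP = 50  # bp of boundary ambiguity tolerated between adjacent blocks


def _weighted_lis(blocks: list[SyntenyBlock]) -> set[int]:
    """Indices of the maximum-a-span chain of mutually compatible blocks.

    Compatibility requires near-disjoint, increasing intervals on *both*
    sequences (up to boundary slop), so an off-place or duplicated block
    cannot ride the backbone merely because its start coordinate fits.
    """
    n = len(blocks)
    best = [b.a_span for b in blocks]
    back = [-1] * n
    for j in range(n):
        for i in range(j):
            compatible = (
                blocks[j].b_start >= blocks[i].b_end - _SLOP
                and blocks[j].a_start >= blocks[i].a_end - _SLOP
            )
            if compatible and best[i] + blocks[j].a_span > best[j]:
                best[j] = best[i] + blocks[j].a_span
                back[j] = i
    if not n:
        return set()
    i = int(np.argmax(best))
    keep = set()
    while i != -1:
        keep.add(i)
        i = back[i]
    return keep


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> int:
    return max(0, min(x[1], y[1]) - max(x[0], y[0]))


def classify_events(
    blocks: Sequence[SyntenyBlock],
    seq_a: str,
    seq_b: str,
    min_event: int = INDEL_EVENT_BOUNDARY,
    dup_max_divergence: float = 0.1,
) -> list[RearrangementEvent]:
    """Classify differences between two block decompositions into events.

    The collinear backbone is the maximum-weight run of blocks increasing in
    both sequences.  Blocks off the backbone are translocations (or
    duplications, when their reference interval is already covered by a
    backbone block).  Reverse-orientation backbone blocks are inversions.
    Backbone gaps present only on the derived sequence are insertions --
    unless the inserted sequence aligns to the reference, which makes the
    event a duplication -- and gaps only on the reference are deletions.
    Gap material explained by a translocated block is not double-reported.
    """
    blocks = sorted(blocks, key=lambda b: b.a_start)
    events: list[RearrangementEvent] = []
    backbone_idx = _weighted_lis(list(blocks))
    backbone = [b for i, b in enumerate(blocks) if i in backbone_idx]
    off = [b for i, b in enumerate(blocks) if i not in backbone_idx]

    for b in backbone:
        if b.orientation == REVERSE:
            events.append(
                RearrangementEvent(
                    "inversion", b.a_start + 1, (b.b_start + 1, b.b_end), b.a_span
                )
            )

    placed: list[tuple[SyntenyBlock, str]] = []
    for t in off:
        dup = any(
            _overlap((t.a_start, t.a_end), (b.a_start, b.a_end)) >= 0.5 * t.a_span
            for b in backbone
        )
        kind = "duplication" if dup else "translocation"
        events.append(
            RearrangementEvent(kind, t.a_start + 1, (t.b_start + 1, t.b_end), t.a_span)
        )
        placed.append((t, kind))

    # Sentinel-bounded walk over backbone adjacencies.
    la, lb = len(seq_a), len(seq_b)
    bounds = (
        [(0, 0)]
        + [(b.a_end, b.b_end) for b in backbone]
    )
    nexts = [(b.a_start, b.b_start) for b in backbone] + [(la, lb)]
    for (pa, pb), (na, nb) in zip(bounds, nexts):
        ga = na - pa
        gb = nb - pb
        # Adjacent blocks may overlap by a few bases where the event
        # boundary is ambiguous; clamp those, skip genuine conflicts.
        if ga < -_SLOP or gb < -_SLOP:
            continue
        ga = max(ga, 0)
        gb = max(gb, 0)
        for t, kind in placed:
            if _overlap((t.b_start, t.b_end), (pb, nb)) >= 0.5 * t.b_span:
                gb -= t.b_span
            if kind == "translocation" and _overlap((t.a_start, t.a_end), (pa, na)) >= 0.5 * t.a_span:
                ga -= t.a_span
        diff = gb - ga
        if diff >= min_event:
            ins_seq = seq_b[pb:nb]
            event_type = "insertion"
            a_locus = pa  # 1-based last reference base before the insertion
            b_first = pb + 1  # 1-based first inserted base on the derived seq
            if ga > 0:
                # Unaligned reference residue flanks the insertion (e.g. the
                # event sits closer to a sequence end than one anchor k-mer);
                # align the gaps to localize the inserted run at base level.
                off = _largest_indel_run(seq_a[pa:na], seq_b[pb:nb], "D")
                if off is not None:
                    a_locus = pa + off[0]
                    b_first = pb + off[1] + 1
            # Reclassification as duplication needs enough sequence to be
            # specific; very short inserts match the reference by chance.
            if 50 <= len(ins_seq) <= 500_000:
                hit = edlib.align(ins_seq, seq_a, mode="HW", task="locations")
                if hit["editDistance"] >= 0 and hit["editDistance"] <= dup_max_divergence * len(ins_seq):
                    event_type = "duplication"
                    a_locus = hit["locations"][0][0] + 1
            events.append(
                RearrangementEvent(
                    event_type, a_locus, (b_first, b_first + diff - 1), diff
                )
            )
        elif -diff >= min_event:
            a_first = pa + 1  # 1-based first deleted base
            b_point = pb
            if gb > 0:
                off = _largest_indel_run(seq_a[pa:na], seq_b[pb:nb], "I")
                if off is not None:
                    a_first = pa + off[0] + 1
                    b_point = pb + off[1]
            events.append(
                RearrangementEvent("deletion", a_first, (b_point, b_point), -diff)
            )
    events.sort(key=lambda e: e.a_locus)
    return events


# ---------------------------------------------------------------------------
# SNP calling


def _largest_indel_run(gap_a: str, gap_b: str, want_op: str) -> tuple[int, int] | None:
    """Offsets (in gap_a, gap_b) of the longest run of *want_op* in their alignment.

    With query = gap_a and target = gap_b: ``'D'`` runs are bases present
    only in *gap_b* (an insertion), ``'I'`` runs bases only in *gap_a* (a
    deletion).
    """
    if not gap_a or not gap_b:
        return None
    res = edlib.align(gap_a, gap_b, mode="NW", task="path")
    ai = bi = 0
    best: tuple[int, tuple[int, int]] | None = None
    for n, op in _parse_cigar(res["cigar"]):
        if op == want_op and (best is None or n > best[0]):
            best = (n, (ai, bi))
        if op in ("=", "X", "M"):
            ai += n
            bi += n
        elif op == "I":  # consumes the query (gap_a)
            ai += n
        elif op == "D":  # consumes the target (gap_b)
            bi += n
    return best[1] if best else None


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def call_snps(
    blocks: Sequence[SyntenyBlock],
    seq_a: str,
    seq_b: str,
    max_indel: int = INDEL_EVENT_BOUNDARY,
    min_identity: float = 0.9,
) -> list[SnpCall]:
    """Substitutions and short indels inside near-identical forward blocks.

    Each qualifying block is globally aligned with edlib and the alignment
    columns walked: mismatches become substitution calls, indel runs shorter
    than *max_indel* become indel calls (longer ones belong to
    :func:`classify_events` and are skipped here).  Reverse-orientation
    blocks are not scanned: in the near-identity regime the toolkit targets,
    point mutations sit in the collinear backbone.
    """
    calls: list[SnpCall] = []
    for blk in blocks:
        if blk.orientation != FORWARD or blk.identity < min_identity:
            continue
        sub_a = seq_a[blk.a_start: blk.a_end]
        sub_b = seq_b[blk.b_start: blk.b_end]
        res = edlib.align(sub_b, sub_a, mode="NW", task="path")
        ai = bi = 0
        for n, op in _parse_cigar(res["cigar"]):
            if op == "=":
                ai += n
                bi += n
            elif op in ("X", "M"):
                for t in range(n):
                    ra, rb = sub_a[ai + t], sub_b[bi + t]
                    if ra != rb:
                        calls.append(
                            SnpCall(
                                pos_a=blk.a_start + ai + t + 1,
                                pos_b=blk.b_start + bi + t + 1,
                                ref_base=ra,
                                alt_base=rb,
                            )
                        )
                ai += n
                bi += n
            elif op == "I":  # present in b, absent in a
                if n < max_indel:
                    # left-align within repeat context (canonical position)
                    a0, b0 = ai, bi
                    while (
                        a0 > 0
                        and b0 > 0
                        and sub_b[b0 - 1] == sub_b[b0 + n - 1]
                        and sub_a[a0 - 1] == sub_b[b0 - 1]
                    ):
                        a0 -= 1
                        b0 -= 1
                    calls.append(
                        SnpCall(
                            pos_a=blk.a_start + a0,
                            pos_b=blk.b_start + b0 + 1,
                            ref_base="-",
                            alt_base=sub_b[b0: b0 + n],
                        )
                    )
                bi += n
            elif op == "D":  # present in a, absent in b
                if n < max_indel:
                    a0, b0 = ai, bi
                    while (
                        a0 > 0
                        and b0 > 0
                        and sub_a[a0 - 1] == sub_a[a0 + n - 1]
                        and sub_b[b0 - 1] == sub_a[a0 - 1]
                    ):
                        a0 -= 1
                        b0 -= 1
                    calls.append(
                        SnpCall(
                            pos_a=blk.a_start + a0 + 1,
                            pos_b=blk.b_start + b0,
                            ref_base=sub_a[a0: a0 + n],
                            alt_base="-",
                        )
                    )
                ai += n
            else:  # pragma: no cover - unknown op
                raise ValueError(f"unexpected CIGAR op {op!r}")
    calls.sort(key=lambda c: c.pos_a)
    return calls


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def classify_snp_effect(
    call: SnpCall,
    features: Sequence[FeatureRecord],
    seq_a: str,
) -> str:
    """Coding effect of a SNP call against the reference annotation.

    Uses the standard bacterial genetic code (translation table 11),
    strand-aware.  Substitutions: synonymous / missense / nonsense.  Indels
    in a CDS: frameshift when the net length change is not a multiple of 3,
    otherwise in-frame.  No overlapping CDS: intergenic.
    """
    cds = next(
        (
            f
            for f in features
            if f.kind == "CDS" and f.start <= call.pos_a <= f.end
        ),
        None,
    )
    if cds is None:
        return "intergenic"
    if call.is_indel:
        len_ref = 0 if call.ref_base == "-" else len(call.ref_base)
        len_alt = 0 if call.alt_base == "-" else len(call.alt_base)
        return "frameshift" if abs(len_ref - len_alt) % 3 else "indel_inframe"

    s0, e0 = cds.interval0()
    if (e0 - s0) % 3:
        warnings.warn(
            f"CDS [{cds.start},{cds.end}] length not divisible by 3; "
            "using annotated frame start",
            stacklevel=2,
        )
    p0 = call.pos_a - 1
    if cds.strand == "+":
        off = p0 - s0
        alt = call.alt_base
        coding = seq_a[s0:e0]
    else:
        off = (e0 - 1) - p0
        alt = _COMPLEMENT[call.alt_base]
        coding = reverse_complement(seq_a[s0:e0])
    codon_i = off // 3
    within = off % 3
    codon = coding[3 * codon_i: 3 * codon_i + 3]
    if len(codon) < 3:
        warnings.warn(
            f"substitution at {call.pos_a} falls in an incomplete terminal codon",
            stacklevel=2,
        )
        return "missense"
    mutated = codon[:within] + alt + codon[within + 1:]
    aa_ref = str(Seq(codon).translate(table=11))
    aa_alt = str(Seq(mutated).translate(table=11))
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


# ---------------------------------------------------------------------------
# dot plot export


def export_dotplot(anchors: Sequence[Anchor], out: str | Path) -> pd.DataFrame:
    """Write anchors as a dot-plot coordinate table (1-based starts, TSV)."""
    df = pd.DataFrame(
        [
            {
                "pos_a": a.pos_a + 1,
                "pos_b": a.pos_b + 1,
                "length": a.length,
                "orientation": a.orientation,
            }
            for a in anchors
        ],
        columns=["pos_a", "pos_b", "length", "orientation"],
    )
    with open(out, "w") as fh:
        fh.write(f"# linrep {__version__}; dot plot anchors\n")
        df.to_csv(fh, sep="\t", index=False)
    return df
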