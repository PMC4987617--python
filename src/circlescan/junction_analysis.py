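"""Arrangement enumeration, spanning-read classification, junction calling
and depth profiling.

The central question for a repeat-bearing circular genome is which molecular
arrangement the reads support.  For every repeat pair there are two reference
configurations (a read spans one copy plus unique flank on both sides) and
exactly two recombinant configurations produced by a single crossover
between the copies:

* **direct, same chromosome** — the intervening segment is excised into a
  subgenomic circle and the remainder recloses; the two product circle
  lengths sum to the parent length;
* **inverted, same chromosome** — the intervening segment is inverted in
  place (both repeat copies retained);
* **between chromosomes** — the two circles fuse into one of length
  ``L1 + L2``.

A long read is informative when it covers an entire repeat copy plus at
least ``min_anchor`` bases of unique flank on both sides; the flank identity
then reveals the arrangement.  Junctions are represented as unordered pairs
of breakends ``(chrom, pos, orient)`` where orient ``+`` means the joined
segment lies at coordinates <= pos and ``-`` means it extends from pos
upward; this makes the representation independent of read strand.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import CircInterval, GenomeSet, wrap_pos
from .repeat_finder import DIRECT, INVERTED, RepeatPair

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentSegment",
    "ReadPath",
    "Breakend",
    "JunctionSignature",
    "JunctionCall",
    "ArrangementSupport",
    "ReadClassification",
    "DepthProfile",
    "load_alignments",
    "enumerate_arrangements",
    "classify_read",
    "count_support",
    "call_breakpoint_junctions",
    "junction_presence_matrix",
    "depth_profile",
    "write_junction_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned piece of a read.

    ``read_start``/``read_end`` are 1-based inclusive positions on the read
    in its original orientation (as sequenced), regardless of which strand
    the segment aligned to.
    """

    read_id: str
    read_start: int
    read_end: int
    ref: CircInterval
    strand: str
    is_supplementary: bool = False
    left_clip: int = 0
    right_clip: int = 0

    def __post_init__(self) -> None:
        if self.read_start > self.read_end:
            raise ValueError(f"{self.read_id}: read_start > read_end")


@dataclass
class ReadPath:
    """Ordered alignment segments of one read, sorted by read_start."""

    read_id: str
    segments: list[AlignmentSegment]

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.read_start)
        for s in self.segments:
            if s.read_id != self.read_id:
                raise ValueError("segments from different reads in one path")


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a junction: the joined segment lies at <= pos (orient '+')
    or >= pos (orient '-')."""

    chrom: str
    pos: int
    orient: str


@dataclass(frozen=True)
class JunctionSignature:
    """A junction between two reference loci, in canonical breakend order.

    ``kind`` is ``reference`` (the assembly's own adjacency across a repeat
    copy), ``recombinant`` (predicted from a repeat pair) or ``novel``.
    """

    kind: str
    breakends: tuple[Breakend, Breakend]
    name: str = ""
    product_length: int | None = None
    inverted_segment_length: int | None = None

    def __post_init__(self) -> None:
        be = tuple(sorted(self.breakends))
        object.__setattr__(self, "breakends", be)

    @property
    def description(self) -> str:
        """Human-readable rendering, loci rounded to 0.1 kb."""

        def kb(pos: int) -> str:
            v = f"{pos / 1000:.1f}"
            return v[:-2] if v.endswith(".0") else v

        a, b = self.breakends
        second = f"{b.chrom} " if b.chrom != a.chrom else ""
        return f"{kb(a.pos)} Kb ({a.orient}) join {second}{kb(b.pos)} Kb ({b.orient})"


@dataclass
class JunctionCall:
    """A clustered breakpoint junction with its read support."""

    signature: JunctionSignature
    support: int
    read_ids: list[str] = field(default_factory=list)


@dataclass
class ReadClassification:
    """Outcome of evaluating one read against one repeat pair."""

    category: str  # ref_copy1 | ref_copy2 | ref_both | recombinant | uninformative
    junction: JunctionSignature | None = None


@dataclass
class ArrangementSupport:
    """Per-repeat-pair read counts for reference vs recombinant junctions.

    ``count_ref_copy1``/``count_ref_copy2`` include reads that span both
    copies (such reads count once per copy); the disjoint counters preserve
    the partition over evaluated reads.
    """

    pair: RepeatPair
    signatures: list[JunctionSignature]
    count_ref_copy1_only: int = 0
    count_ref_copy2_only: int = 0
    count_ref_both: int = 0
    recombinant_counts: dict[str, int] = field(default_factory=dict)
    uninformative_count: int = 0
    n_evaluated: int = 0

    @property
    def count_ref_copy1(self) -> int:
        return self.count_ref_copy1_only + self.count_ref_both

    @property
    def count_ref_copy2(self) -> int:
        return self.count_ref_copy2_only + self.count_ref_both

    @property
    def count_recombinant(self) -> int:
        return sum(self.recombinant_counts.values())

    @property
    def count_reference(self) -> int:
        return self.count_ref_copy1_only + self.count_ref_copy2_only + self.count_ref_both

    @property
    def low_evidence(self) -> bool:
        return self.count_reference == 0 and self.count_recombinant == 0

    @property
    def verdict(self) -> str:
        if self.count_recombinant == 0:
            return "reference-only"
        if self.count_reference == 0:
            return "recombinant-only"
        return "mixed"


@dataclass
class DepthProfile:
    """Per-window depth with genome-wide summary and low-depth flags."""

    window: int
    per_window: dict[str, np.ndarray]
    per_base: dict[str, np.ndarray]
    median: float
    mean: float
    low_intervals: list[CircInterval]
    low_fraction: float
    min_span: int


# ---------------------------------------------------------------------------
# alignment loading
# ---------------------------------------------------------------------------


def _paths_from_segments(segments: Iterable[AlignmentSegment]) -> list[ReadPath]:
    grouped: dict[str, list[AlignmentSegment]] = {}
    for seg in segments:
        grouped.setdefault(seg.read_id, []).append(seg)
    return [ReadPath(rid, segs) for rid, segs in grouped.items()]


def load_alignments(
    path: str,
    genome: GenomeSet | None = None,
    fmt: str | None = None,
) -> list[ReadPath]:
    """Read SAM or PAF alignments into one :class:`ReadPath` per read.

    Primary and supplementary records are kept, secondary and unmapped
    records are dropped (with a logged count).  Format is inferred from the
    file extension unless given.
    """
    if fmt is None:
        fmt = "paf" if path.endswith(".paf") else "sam"
    if fmt == "sam":
        segments, dropped = _load_sam(path, genome)
    elif fmt == "paf":
        segments, dropped = _load_paf(path, genome)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if dropped:
        logger.info("dropped %d unmapped/secondary records from %s", dropped, path)
    return _paths_from_segments(segments)


def _load_sam(path: str, genome: GenomeSet | None):
    import pysam

    segments: list[AlignmentSegment] = []
    dropped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                dropped += 1
                continue
            if genome is not None and rec.reference_name not in genome:
                raise ValueError(
                    f"alignment to unknown reference {rec.reference_name!r}"
                )
            cig = rec.cigartuples or []
            left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            qlen = rec.infer_read_length()
            if qlen is None:
                raise ValueError(f"{rec.query_name}: cannot infer read length")
            aligned = qlen - left - right
            if rec.is_reverse:
                read_start, read_end = right + 1, qlen - left
                lclip, rclip = right, left
            else:
                read_start, read_end = left + 1, qlen - right
                lclip, rclip = left, right
            strand = "-" if rec.is_reverse else "+"
            segments.append(
                AlignmentSegment(
                    read_id=rec.query_name,
                    read_start=read_start,
                    read_end=read_end,
                    ref=CircInterval(
                        rec.reference_name,
                        rec.reference_start + 1,
                        rec.reference_end,
                        strand,
                    ),
                    strand=strand,
                    is_supplementary=rec.is_supplementary,
                    left_clip=lclip,
                    right_clip=rclip,
                )
            )
    return segments, dropped


def _load_paf(path: str, genome: GenomeSet | None):
    segments: list[AlignmentSegment] = []
    dropped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"malformed PAF line: {line[:80]!r}")
            qname, qlen, qstart, qend, strand, tname = f[0], int(f[1]), int(f[2]), int(f[3]), f[4], f[5]
            tstart, tend = int(f[7]), int(f[8])
            if tname == "*":
                dropped += 1
                continue
            if genome is not None and tname not in genome:
                raise ValueError(f"alignment to unknown reference {tname!r}")
            tags = dict(t.split(":", 2)[::2] for t in f[12:] if ":" in t)
            if tags.get("tp") == "S":  # secondary
                dropped += 1
                continue
            segments.append(
                AlignmentSegment(
                    read_id=qname,
                    read_start=qstart + 1,
                    read_end=qend,
                    ref=CircInterval(tname, tstart + 1, tend, strand),
                    strand=strand,
                    is_supplementary=False,
                    left_clip=qstart,
                    right_clip=qlen - qend,
                )
            )
    return segments, dropped


# ---------------------------------------------------------------------------
# arrangement enumeration
# ---------------------------------------------------------------------------


def _circ_dist(a: int, b: int, L: int) -> int:
    d = (a - b) % L
    return min(d, L - d)


def _copy_span(iv: CircInterval, L: int) -> int:
    return (iv.end - iv.start) % L + 1


def _overlaps(a: CircInterval, b: CircInterval, L: int) -> bool:
    la, lb = _copy_span(a, L), _copy_span(b, L)
    off = (b.start - a.start) % L
    if off < la:
        return True
    off2 = (a.start - b.start) % L
    return off2 < lb


def enumerate_arrangements(
    pair: RepeatPair, genome: GenomeSet
) -> list[JunctionSignature]:
    """Reference and recombinant junction signatures for one repeat pair.

    Returns two reference signatures (a spanning read across each copy) and
    exactly two recombinant signatures for the single-crossover product
    appropriate to the pair's geometry (excision / inversion / fusion).
    Overlapping copies are degenerate and raise ``ValueError``.
    """
    c1, c2 = pair.copy1, pair.copy2
    if pair.is_intra and _overlaps(c1, c2, genome[c1.chrom_id].length):
        raise ValueError(f"degenerate repeat pair with overlapping copies: {pair}")
    ref_order = [(c1, genome[c1.chrom_id]), (c2, genome[c2.chrom_id])]
    # recombinant geometry is derived from the canonical copy order so that
    # relabeling copy1/copy2 yields identical signatures
    c1, c2 = sorted((c1, c2), key=lambda c: (c.chrom_id, c.start))
    A, B = genome[c1.chrom_id], genome[c2.chrom_id]
    L1, L2 = A.length, B.length
    s1, e1, s2, e2 = c1.start, c1.end, c2.start, c2.end
    sigs: list[JunctionSignature] = []
    for idx, (c, chrom) in enumerate(ref_order, start=1):
        sigs.append(
            JunctionSignature(
                kind="reference",
                breakends=(
                    Breakend(c.chrom_id, wrap_pos(c.start - 1, chrom.length), "+"),
                    Breakend(c.chrom_id, wrap_pos(c.end + 1, chrom.length), "-"),
                ),
                name=f"ref_copy{idx}",
            )
        )
    if pair.is_intra and pair.orientation == DIRECT:
        ch = c1.chrom_id
        len_excised = (s2 - s1) % L1  # spans s1 .. s2-1
        len_remainder = L1 - len_excised
        sigs.append(
            JunctionSignature(
                kind="recombinant",
                breakends=(
                    Breakend(ch, wrap_pos(s2 - 1, L1), "+"),
                    Breakend(ch, s1, "-"),
                ),
                name="excision_circle",
                product_length=len_excised,
            )
        )
        sigs.append(
            JunctionSignature(
                kind="recombinant",
                breakends=(
                    Breakend(ch, wrap_pos(s1 - 1, L1), "+"),
                    Breakend(ch, s2, "-"),
                ),
                name="remainder_circle",
                product_length=len_remainder,
            )
        )
    elif pair.is_intra and pair.orientation == INVERTED:
        ch = c1.chrom_id
        seg_len = (s2 - e1 - 1) % L1
        sigs.append(
            JunctionSignature(
                kind="recombinant",
                breakends=(
                    Breakend(ch, e1, "+"),
                    Breakend(ch, wrap_pos(s2 - 1, L1), "+"),
                ),
                name="inversion_left",
                product_length=L1,
                inverted_segment_length=seg_len,
            )
        )
        sigs.append(
            JunctionSignature(
                kind="recombinant",
                breakends=(
                    Breakend(ch, wrap_pos(e1 + 1, L1), "-"),
                    Breakend(ch, s2, "-"),
                ),
                name="inversion_right",
                product_length=L1,
                inverted_segment_length=seg_len,
            )
        )
    else:  # inter-chromosomal fusion
        ch1, ch2 = c1.chrom_id, c2.chrom_id
        fused = L1 + L2
        if pair.orientation == DIRECT:
            sigs.append(
                JunctionSignature(
                    kind="recombinant",
                    breakends=(
                        Breakend(ch1, e1, "+"),
                        Breakend(ch2, wrap_pos(e2 + 1, L2), "-"),
                    ),
                    name="fusion_left",
                    product_length=fused,
                )
            )
            sigs.append(
                JunctionSignature(
                    kind="recombinant",
                    breakends=(
                        Breakend(ch2, e2, "+"),
                        Breakend(ch1, wrap_pos(e1 + 1, L1), "-"),
                    ),
                    name="fusion_right",
                    product_length=fused,
                )
            )
        else:  # inverted fusion: the second circle is traversed minus
            sigs.append(
                JunctionSignature(
                    kind="recombinant",
                    breakends=(
                        Breakend(ch1, e1, "+"),
                        Breakend(ch2, wrap_pos(s2 - 1, L2), "+"),
                    ),
                    name="fusion_left",
                    product_length=fused,
                )
            )
            sigs.append(
                JunctionSignature(
                    kind="recombinant",
                    breakends=(
                        Breakend(ch2, s2, "-"),
                        Breakend(ch1, wrap_pos(e1 + 1, L1), "-"),
                    ),
                    name="fusion_right",
                    product_length=fused,
                )
            )
    return sigs


# ---------------------------------------------------------------------------
# colinear block merging
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    chrom: str
    strand: str
    first: int  # reference position of the first read base (read order)
    last: int  # reference position of the last read base
    read_start: int
    read_end: int

    def lo(self) -> int:
        return self.first if self.strand == "+" else self.last

    def span(self, L: int, circular: bool) -> int:
        if self.strand == "+":
            d = self.last - self.first
        else:
            d = self.first - self.last
        return (d % L if circular else d) + 1


def _merge_blocks(path: ReadPath, genome: GenomeSet, tol: int) -> list[_Block]:
    blocks: list[_Block] = []
    for seg in path.segments:
        first = seg.ref.start if seg.strand == "+" else seg.ref.end
        last = seg.ref.end if seg.strand == "+" else seg.ref.start
        b = _Block(seg.ref.chrom_id, seg.strand, first, last, seg.read_start, seg.read_end)
        if blocks:
            a = blocks[-1]
            chrom = genome[a.chrom]
            L = chrom.length
            gap = b.read_start - a.read_end - 1
            if (
                a.chrom == b.chrom
                and a.strand == b.strand
                and abs(gap) <= tol
            ):
                expect = (
                    wrap_pos(a.last + 1, L) if a.strand == "+" else wrap_pos(a.last - 1, L)
                )
                if chrom.is_circular:
                    cont = _circ_dist(b.first, expect, L) <= tol
                else:
                    cont = abs(b.first - expect) <= tol
                if cont:
                    a.last = b.last
                    a.read_end = max(a.read_end, b.read_end)
                    continue
        blocks.append(b)
    return blocks


def _block_covers(b: _Block, iv: CircInterval, genome: GenomeSet) -> bool:
    chrom = genome[b.chrom]
    if iv.chrom_id != b.chrom:
        return False
    L = chrom.length
    blen = b.span(L, chrom.is_circular)
    ivlen = _copy_span(iv, L) if chrom.is_circular else iv.end - iv.start + 1
    if chrom.is_circular:
        off = (iv.start - b.lo()) % L
    else:
        off = iv.start - b.lo()
        if off < 0:
            return False
    return off + ivlen <= blen


def _block_overlap_len(b: _Block, iv: CircInterval, genome: GenomeSet) -> int:
    """Number of reference bases the block shares with the interval."""
    chrom = genome[b.chrom]
    if iv.chrom_id != b.chrom:
        return 0
    L = chrom.length
    blen = b.span(L, chrom.is_circular)
    ivlen = _copy_span(iv, L) if chrom.is_circular else iv.end - iv.start + 1

    def arcs(start: int, length: int) -> list[tuple[int, int]]:
        if not chrom.is_circular:
            return [(start, start + length - 1)]
        end = start + length - 1
        if end <= L:
            return [(start, end)]
        return [(start, L), (1, end - L)]

    total = 0
    for s1, e1 in arcs(b.lo(), blen):
        for s2, e2 in arcs(iv.start, ivlen):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def _junction_of(a: _Block, b: _Block) -> tuple[Breakend, Breakend]:
    side1 = Breakend(a.chrom, a.last, "+" if a.strand == "+" else "-")
    side2 = Breakend(b.chrom, b.first, "-" if b.strand == "+" else "+")
    be = tuple(sorted((side1, side2)))
    return be  # type: ignore[return-value]


def _one_breakend_match(cand: Breakend, ref: Breakend, genome: GenomeSet, tol: int) -> bool:
    if cand.chrom != ref.chrom or cand.orient != ref.orient:
        return False
    chrom = genome[cand.chrom]
    L = chrom.length
    d = _circ_dist(cand.pos, ref.pos, L) if chrom.is_circular else abs(cand.pos - ref.pos)
    return d <= tol


def _breakends_match(
    be: tuple[Breakend, Breakend],
    sig: JunctionSignature,
    genome: GenomeSet,
    tol: int,
) -> bool:
    r1, r2 = sig.breakends
    return (
        _one_breakend_match(be[0], r1, genome, tol)
        and _one_breakend_match(be[1], r2, genome, tol)
    ) or (
        _one_breakend_match(be[0], r2, genome, tol)
        and _one_breakend_match(be[1], r1, genome, tol)
    )


# ---------------------------------------------------------------------------
# read classification and support counting
# ---------------------------------------------------------------------------


def classify_read(
    path: ReadPath,
    pair: RepeatPair,
    genome: GenomeSet,
    min_anchor: int = 200,
    breakpoint_tol: int = 50,
) -> ReadClassification:
    """Classify one read against one repeat pair.

    ``ref_copy1``/``ref_copy2`` (or ``ref_both``): a colinear chain covers an
    entire copy plus >= ``min_anchor`` bases of unique flank on both sides.
    ``recombinant``: consecutive chain blocks form a junction matching one of
    the pair's recombinant signatures within ``breakpoint_tol`` at both
    breakends, with >= ``min_anchor`` aligned bases outside both repeat
    copies on each side.  Conflicting evidence resolves to uninformative.
    Defaults: 200 b anchors exceed typical short repeats while staying far
    below long-read lengths; 50 b tolerance absorbs alignment end jitter.
    """
    if min_anchor < 1 or breakpoint_tol < 0:
        raise ValueError("min_anchor >= 1 and breakpoint_tol >= 0 required")
    try:
        sigs = enumerate_arrangements(pair, genome)
    except ValueError:
        return ReadClassification("uninformative")
    recomb = [s for s in sigs if s.kind == "recombinant"]
    blocks = _merge_blocks(path, genome, max(breakpoint_tol, 1))

    ref_hits = []
    for idx, copy in enumerate((pair.copy1, pair.copy2), start=1):
        chrom = genome[copy.chrom_id]
        L = chrom.length
        clen = _copy_span(copy, L)
        if clen + 2 * min_anchor > L:
            continue  # cannot be informative: no unique flank exists
        ext = CircInterval(
            copy.chrom_id,
            wrap_pos(copy.start - min_anchor, L),
            wrap_pos(copy.end + min_anchor, L),
            "+",
        )
        if any(_block_covers(b, ext, genome) for b in blocks):
            ref_hits.append(idx)

    # A read may legitimately cross both junctions of one recombinant product
    # (e.g. it spans a short inverted segment entirely); it still counts once,
    # under the first junction it crosses in read order.
    recomb_hit: JunctionSignature | None = None
    for a, b in zip(blocks, blocks[1:]):
        if recomb_hit is not None:
            break
        if abs(b.read_start - a.read_end - 1) > max(breakpoint_tol, 1):
            continue
        be = _junction_of(a, b)
        for sig in recomb:
            if _breakends_match(be, sig, genome, breakpoint_tol):
                unique_a = a.span(genome[a.chrom].length, genome[a.chrom].is_circular)
                unique_b = b.span(genome[b.chrom].length, genome[b.chrom].is_circular)
                for copy in (pair.copy1, pair.copy2):
                    unique_a -= _block_overlap_len(a, copy, genome)
                    unique_b -= _block_overlap_len(b, copy, genome)
                if unique_a >= min_anchor and unique_b >= min_anchor:
                    recomb_hit = sig
                    break

    if ref_hits and recomb_hit is not None:
        return ReadClassification("uninformative")
    if recomb_hit is not None:
        return ReadClassification("recombinant", recomb_hit)
    if len(ref_hits) == 2:
        return ReadClassification("ref_both")
    if ref_hits == [1]:
        return ReadClassification("ref_copy1")
    if ref_hits == [2]:
        return ReadClassification("ref_copy2")
    return ReadClassification("uninformative")


def count_support(
    paths: Sequence[ReadPath],
    pairs: Sequence[RepeatPair],
    genome: GenomeSet,
    min_anchor: int = 200,
    breakpoint_tol: int = 50,
) -> list[ArrangementSupport]:
    """Aggregate :func:`classify_read` over all reads for each repeat pair.

    Every evaluated read lands in exactly one of the disjoint counters
    (ref copy1 only, ref copy2 only, ref both, one recombinant junction,
    uninformative); pairs with zero evidence report ``reference-only`` with
    the ``low_evidence`` flag raised.
    """
    out = []
    for pair in pairs:
        try:
            sigs = enumerate_arrangements(pair, genome)
        except ValueError:
            sigs = []
        sup = ArrangementSupport(pair=pair, signatures=sigs)
        sup.recombinant_counts = {
            s.name: 0 for s in sigs if s.kind == "recombinant"
        }
        for path in paths:
            cls = classify_read(path, pair, genome, min_anchor, breakpoint_tol)
            sup.n_evaluated += 1
            if cls.category == "ref_copy1":
                sup.count_ref_copy1_only += 1
            elif cls.category == "ref_copy2":
                sup.count_ref_copy2_only += 1
            elif cls.category == "ref_both":
                sup.count_ref_both += 1
            elif cls.category == "recombinant":
                sup.recombinant_counts[cls.junction.name] = (
                    sup.recombinant_counts.get(cls.junction.name, 0) + 1
                )
            else:
                sup.uninformative_count += 1
        if sup.low_evidence:
            logger.warning(
                "no informative reads for repeat pair %s:%d/%s:%d",
                pair.copy1.chrom_id,
                pair.copy1.start,
                pair.copy2.chrom_id,
                pair.copy2.start,
            )
        out.append(sup)
    return out


# ---------------------------------------------------------------------------
# breakpoint junction calling
# ---------------------------------------------------------------------------


def call_breakpoint_junctions(
    paths: Sequence[ReadPath],
    genome: GenomeSet,
    min_clip: int = 100,
    cluster_window: int = 100,
    min_reads: int = 3,
    repeat_pairs: Sequence[RepeatPair] | None = None,
) -> list[JunctionCall]:
    """Call junctions from split alignments.

    Consecutive blocks of a read whose read coordinates abut (gap <=
    ``cluster_window``) but whose reference loci are discontinuous define
    candidate junctions; candidates are clustered within ``cluster_window``
    on both breakends and clusters with >= ``min_reads`` are reported.
    Junctions explained by a known repeat pair's recombinant arrangement are
    annotated ``recombinant``, others ``novel``.  Blocks shorter than
    ``min_clip`` are ignored as alignment noise.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    known: list[tuple[JunctionSignature, RepeatPair]] = []
    for p in repeat_pairs or ():
        try:
            for sig in enumerate_arrangements(p, genome):
                if sig.kind == "recombinant":
                    known.append((sig, p))
        except ValueError:
            continue

    candidates: list[tuple[tuple[Breakend, Breakend], str]] = []
    for path in paths:
        blocks = _merge_blocks(path, genome, max(cluster_window, 1))
        blocks = [
            b
            for b in blocks
            if b.span(genome[b.chrom].length, genome[b.chrom].is_circular) >= min_clip
        ]
        for a, b in zip(blocks, blocks[1:]):
            if abs(b.read_start - a.read_end - 1) > cluster_window:
                continue
            candidates.append((_junction_of(a, b), path.read_id))

    groups: defaultdict[tuple, list[tuple[tuple[Breakend, Breakend], str]]] = defaultdict(list)
    for be, rid in candidates:
        key = (be[0].chrom, be[0].orient, be[1].chrom, be[1].orient)
        groups[key].append((be, rid))

    calls: list[JunctionCall] = []
    for key, items in groups.items():
        items.sort(key=lambda x: (x[0][0].pos, x[0][1].pos))
        cluster: list[tuple[tuple[Breakend, Breakend], str]] = []

        def _flush() -> None:
            if len({rid for _, rid in cluster}) >= min_reads:
                pos1 = int(round(np.median([be[0].pos for be, _ in cluster])))
                pos2 = int(round(np.median([be[1].pos for be, _ in cluster])))
                be0 = cluster[0][0]
                sig = JunctionSignature(
                    kind="novel",
                    breakends=(
                        Breakend(be0[0].chrom, pos1, be0[0].orient),
                        Breakend(be0[1].chrom, pos2, be0[1].orient),
                    ),
                    name="novel",
                )
                for ksig, kp in known:
                    if _breakends_match(sig.breakends, ksig, genome, cluster_window):
                        sig = dataclasses.replace(
                            sig,
                            kind="recombinant",
                            name=f"{ksig.name}@{kp.copy1.chrom_id}:{kp.copy1.start}",
                        )
                        break
                calls.append(
                    JunctionCall(sig, len({rid for _, rid in cluster}), sorted({rid for _, rid in cluster}))
                )

        for be, rid in items:
            if cluster and (
                abs(be[0].pos - cluster[-1][0][0].pos) > cluster_window
                or abs(be[1].pos - cluster[-1][0][1].pos) > cluster_window
            ):
                _flush()
                cluster = []
            cluster.append((be, rid))
        if cluster:
            _flush()
    calls.sort(key=lambda c: (c.signature.breakends[0].chrom, c.signature.breakends[0].pos))
    return calls


def junction_presence_matrix(
    calls_by_sample: Mapping[str, Sequence[JunctionCall]],
    genome: GenomeSet,
    cluster_window: int = 100,
) -> pd.DataFrame:
    """Merge per-sample junction calls into a presence (1/0) matrix.

    Junctions from different samples are considered the same event when both
    breakends agree within ``cluster_window``.
    """
    merged: list[tuple[JunctionSignature, dict[str, int]]] = []
    for sample, calls in calls_by_sample.items():
        for call in calls:
            for sig, presence in merged:
                if _breakends_match(call.signature.breakends, sig, genome, cluster_window):
                    presence[sample] = 1
                    break
            else:
                merged.append((call.signature, {sample: 1}))
    samples = list(calls_by_sample)
    rows = []
    for sig, presence in merged:
        row = {"junction": sig.description, "kind": sig.kind}
        for s in samples:
            row[s] = presence.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["junction", "kind", *samples])


def write_junction_table(
    calls: Sequence[JunctionCall],
    path: str,
    presence: pd.DataFrame | None = None,
) -> None:
    rows = []
    for c in calls:
        a, b = c.signature.breakends
        rows.append(
            {
                "chromA": a.chrom,
                "posA": a.pos,
                "strandA": a.orient,
                "chromB": b.chrom,
                "posB": b.pos,
                "strandB": b.orient,
                "support": c.support,
                "annotation": c.signature.name,
                "description": c.signature.description,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chromA",
            "posA",
            "strandA",
            "chromB",
            "posB",
            "strandB",
            "support",
            "annotation",
            "description",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    if presence is not None:
        presence.to_csv(path + ".presence.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


def depth_profile(
    paths: Sequence[ReadPath],
    genome: GenomeSet,
    window: int = 100,
    low_frac: float = 0.1,
    min_span: int = 1000,
) -> DepthProfile:
    """Wrap-aware per-base coverage, summarized per window.

    Median and mean are computed over the concatenated per-base series of
    all chromosomes.  Maximal runs of bases with depth below
    ``low_frac x genome mean`` spanning >= ``min_span`` are flagged (the
    signature of non-organellar DNA stitched into an assembly).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    per_base = {c.id: np.zeros(c.length, dtype=np.int32) for c in genome}
    for path in paths:
        for seg in path.segments:
            arr = per_base[seg.ref.chrom_id]
            L = len(arr)
            s, e = seg.ref.start, seg.ref.end
            if s <= e:
                arr[s - 1 : e] += 1
            else:  # origin wrap
                arr[s - 1 :] += 1
                arr[:e] += 1
    allbases = np.concatenate(list(per_base.values())) if per_base else np.array([0])
    mean = float(allbases.mean())
    median = float(np.median(allbases))
    per_window = {}
    for cid, arr in per_base.items():
        n = len(arr)
        nwin = (n + window - 1) // window
        padded = np.zeros(nwin * window, dtype=float)
        padded[:n] = arr
        counts = np.full(nwin, window, dtype=float)
        if n % window:
            counts[-1] = n % window
        per_window[cid] = padded.reshape(nwin, window).sum(axis=1) / counts

    thresh = low_frac * mean
    low: list[CircInterval] = []
    for cid, arr in per_base.items():
        flags = arr < thresh
        if not flags.any():
            continue
        if flags.all():
            low.append(CircInterval(cid, 1, len(arr), "+"))
            continue
        # runs, wrap-aware: merge a run touching the end with one at the start
        edges = np.flatnonzero(np.diff(flags.astype(np.int8)))
        starts = [0] if flags[0] else []
        starts += [int(e) + 1 for e in edges if flags[int(e) + 1]]
        ends = [int(e) for e in edges if flags[int(e)]]
        if flags[-1]:
            ends.append(len(arr) - 1)
        runs = list(zip(starts, ends))
        L = len(arr)
        if genome[cid].is_circular and runs and runs[0][0] == 0 and runs[-1][1] == L - 1 and len(runs) > 1:
            first, last = runs[0], runs.pop()
            runs[0] = (last[0], first[1])  # wrap-around run, start > end
        for s0, e0 in runs:
            span = (e0 - s0 + 1) if s0 <= e0 else (L - s0) + e0 + 1
            if span >= min_span:
                low.append(CircInterval(cid, s0 + 1, e0 + 1, "+"))
    return DepthProfile(window, per_window, per_base, median, mean, low, low_frac, min_span)
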