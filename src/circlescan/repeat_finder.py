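"""Exact maximal direct and inverted repeat detection on circular genomes.

Repeated sequence is the substrate for intramolecular recombination in plant
mitochondria: two copies of a direct repeat can excise the intervening
segment into a subgenomic circle, two inverted copies can invert it, and a
repeat shared between chromosomes can fuse two circles.  The census of
repeats by location (within chromosome 1, within chromosome 2, shared) and
by size therefore frames the whole recombination analysis.

The finder reports *maximal exact* repeat pairs of length >= ``min_len``: a
pair that cannot be extended by one base on either side and still match.
Circularity is handled by doubling each circular sequence before the search
and mapping hits back modulo the chromosome length.  Matching is seeded with
``min_len``-mers; a seed pair is only extended when it is left-maximal (the
characters immediately to the left differ), which yields each maximal match
exactly once.  ``N`` never matches, including against itself.

Repeats with more than two copies are reported as all canonical pairs; the
census counts pairs.
"""

from __future__ import annotations

import bisect
import dataclasses
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .genome_model import (
    CircInterval,
    CircularSequence,
    GenomeSet,
    interval_length,
    reverse_complement,
)

__all__ = [
    "RepeatPair",
    "RepeatCensus",
    "find_maximal_repeats",
    "classify_repeats",
    "repeat_mask",
    "MaskIndex",
    "write_repeat_table",
    "read_repeat_table",
    "verify_repeat_pair",
    "INTER_CHROMOSOMAL",
]

DIRECT = "direct"
INVERTED = "inverted"
INTER_CHROMOSOMAL = "inter-chromosomal"


@dataclass(frozen=True)
class RepeatPair:
    """Two same-length intervals whose sequences match (direct) or are
    reverse complements of one another (inverted).

    ``copy1`` sorts lexicographically before ``copy2`` by (chrom_id, start)
    so pairs are canonical; ``copy1`` always carries strand ``+`` and
    ``copy2`` carries ``-`` for inverted pairs.
    """

    copy1: CircInterval
    copy2: CircInterval
    orientation: str
    repeat_length: int
    location_class: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECT, INVERTED):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.copy1.chrom_id, self.copy1.start) == (
            self.copy2.chrom_id,
            self.copy2.start,
        ):
            raise ValueError("repeat copies must be distinct loci")

    @property
    def is_intra(self) -> bool:
        return self.copy1.chrom_id == self.copy2.chrom_id


def verify_repeat_pair(pair: RepeatPair, genome: GenomeSet) -> bool:
    """Check the sequence relationship a RepeatPair claims (test support)."""
    from .genome_model import extract

    s1 = extract(dataclasses.replace(pair.copy1, strand="+"), genome)
    s2 = extract(dataclasses.replace(pair.copy2, strand="+"), genome)
    if len(s1) != pair.repeat_length or len(s2) != pair.repeat_length:
        return False
    return s1 == s2 if pair.orientation == DIRECT else s1 == reverse_complement(s2)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def _left_char(D: str, i: int, circular: bool) -> str | None:
    if i == 0 and not circular:
        return None
    return D[i - 1]  # i == 0 on a doubled circle indexes the last residue


def _extend_right(Da: str, ia: int, Db: str, ib: int, k: int, cap: int) -> int:
    m = k
    la, lb = len(Da), len(Db)
    while m < cap:
        pa, pb = ia + m, ib + m
        if pa >= la or pb >= lb:
            break
        ca = Da[pa]
        if ca != Db[pb] or ca == "N":
            break
        m += 1
    return m


def _fwd_interval(chrom: CircularSequence, i: int, m: int, strand: str) -> CircInterval:
    L = chrom.length
    if chrom.is_circular:
        end = (i + m - 1) % L + 1
    else:
        end = i + m
    return CircInterval(chrom.id, i + 1, end, strand)


def _rc_interval(chrom: CircularSequence, q: int, m: int) -> CircInterval:
    """Map a hit in the reverse-complemented (doubled) string to forward
    coordinates, minus strand."""
    L = chrom.length
    f0 = (L - (q % L) - m) % L if chrom.is_circular else L - q - m
    if chrom.is_circular:
        end = (f0 + m - 1) % L + 1
    else:
        end = f0 + m
    return CircInterval(chrom.id, f0 + 1, end, "-")


def _interval_key(iv: CircInterval) -> tuple[str, int]:
    return (iv.chrom_id, iv.start)


def _canonical_pair(
    iv1: CircInterval, iv2: CircInterval, orientation: str, m: int
) -> RepeatPair:
    a, b = iv1, iv2
    if _interval_key(b) < _interval_key(a):
        a, b = b, a
    a = dataclasses.replace(a, strand="+")
    b = dataclasses.replace(b, strand="-" if orientation == INVERTED else "+")
    return RepeatPair(a, b, orientation, m)


def find_maximal_repeats(
    genome: GenomeSet,
    min_len: int = 30,
    orientations: Iterable[str] = (DIRECT, INVERTED),
) -> list[RepeatPair]:
    """All maximal exact repeat pairs of length >= ``min_len``.

    Within and between chromosomes, wrap-aware on circles, in the requested
    orientations.  Inverted hits whose two copies are the same palindromic
    locus are excluded, and pairs contained in another reported pair on both
    copies are dropped.  Default ``min_len`` is 30 bases, the lower edge of
    the conventional size census.
    """
    orientations = set(orientations)
    bad = orientations - {DIRECT, INVERTED}
    if bad:
        raise ValueError(f"unknown orientations {sorted(bad)}")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    chroms = list(genome)
    if not chroms:
        raise ValueError("empty genome")
    if min_len > max(c.length for c in chroms):
        return []

    k = min_len
    doubled: dict[str, str] = {}
    doubled_rc: dict[str, str] = {}
    index: defaultdict[str, list[tuple[str, int, str]]] = defaultdict(list)

    want_inverted = INVERTED in orientations
    for c in chroms:
        S = c.residues
        D = S + S if c.is_circular else S
        doubled[c.id] = D
        n = c.length if c.is_circular else max(c.length - k + 1, 0)
        for i in range(n):
            km = D[i : i + k]
            if len(km) == k and "N" not in km:
                index[km].append((c.id, i, "f"))
        if want_inverted:
            R = reverse_complement(S)
            Dr = R + R if c.is_circular else R
            doubled_rc[c.id] = Dr
            for i in range(n):
                km = Dr[i : i + k]
                if len(km) == k and "N" not in km:
                    index[km].append((c.id, i, "r"))

    want_direct = DIRECT in orientations
    seen: set[tuple] = set()
    pairs: list[RepeatPair] = []
    by_id = {c.id: c for c in chroms}

    for occ in index.values():
        if len(occ) < 2:
            continue
        for (ca, ia, ta), (cb, ib, tb) in combinations(occ, 2):
            if ta == "r" and tb == "r":
                continue  # mirror of the forward/forward case
            if ta == "r":  # keep forward first
                (ca, ia, ta), (cb, ib, tb) = (cb, ib, tb), (ca, ia, ta)
            inverted = tb == "r"
            if inverted and not want_inverted:
                continue
            if not inverted and not want_direct:
                continue
            A, B = by_id[ca], by_id[cb]
            Da = doubled[ca]
            Db = doubled_rc[cb] if inverted else doubled[cb]
            la = _left_char(Da, ia, A.is_circular)
            lb = _left_char(Db, ib, B.is_circular)
            if la is not None and lb is not None and la == lb and la != "N":
                continue  # not left-maximal; this match is found at its start
            cap_a = A.length if A.is_circular else len(Da) - ia
            cap_b = B.length if B.is_circular else len(Db) - ib
            m = _extend_right(Da, ia, Db, ib, k, min(cap_a, cap_b))
            iv1 = _fwd_interval(A, i=ia, m=m, strand="+")
            iv2 = (
                _rc_interval(B, q=ib, m=m)
                if inverted
                else _fwd_interval(B, i=ib, m=m, strand="+")
            )
            if inverted and ca == cb and iv1.start == iv2.start and iv1.end == iv2.end:
                continue  # palindromic locus matching itself
            if not inverted and ca == cb and iv1.start == iv2.start:
                continue  # same locus (circular self-image)
            pair = _canonical_pair(iv1, iv2, INVERTED if inverted else DIRECT, m)
            key = (
                pair.copy1.chrom_id,
                pair.copy1.start,
                pair.copy2.chrom_id,
                pair.copy2.start,
                pair.orientation,
                m,
            )
            if key not in seen:
                seen.add(key)
                pairs.append(pair)

    return _drop_contained(pairs, genome)


def _contains(outer: CircInterval, inner: CircInterval, L: int, circular: bool) -> bool:
    if outer.chrom_id != inner.chrom_id:
        return False
    len_o = (outer.end - outer.start) % L + 1 if circular else outer.end - outer.start + 1
    len_i = (inner.end - inner.start) % L + 1 if circular else inner.end - inner.start + 1
    if circular:
        off = (inner.start - outer.start) % L
    else:
        off = inner.start - outer.start
        if off < 0:
            return False
    return off + len_i <= len_o


def _drop_contained(pairs: list[RepeatPair], genome: GenomeSet) -> list[RepeatPair]:
    out: list[RepeatPair] = []
    for p in pairs:
        Lp1 = genome[p.copy1.chrom_id].length
        Lp2 = genome[p.copy2.chrom_id].length
        c1 = genome[p.copy1.chrom_id].is_circular
        c2 = genome[p.copy2.chrom_id].is_circular
        contained = False
        for q in pairs:
            if q is p or q.orientation != p.orientation:
                continue
            if q.repeat_length < p.repeat_length:
                continue
            if (
                _contains(q.copy1, p.copy1, Lp1, c1)
                and _contains(q.copy2, p.copy2, Lp2, c2)
            ) or (
                _contains(q.copy1, p.copy2, Lp2, c2)
                and _contains(q.copy2, p.copy1, Lp1, c1)
            ):
                if (q.copy1, q.copy2, q.repeat_length) != (
                    p.copy1,
                    p.copy2,
                    p.repeat_length,
                ):
                    contained = True
                    break
        if not contained:
            out.append(p)
    return sorted(
        out,
        key=lambda p: (
            p.copy1.chrom_id,
            p.copy1.start,
            p.copy2.chrom_id,
            p.copy2.start,
            p.orientation,
        ),
    )


# ---------------------------------------------------------------------------
# census and mask
# ---------------------------------------------------------------------------


@dataclass
class RepeatCensus:
    """Counts of repeat pairs by location class and size bin."""

    total: int
    by_class: dict[str, int]
    by_bin: dict[str, int]
    bin_fractions: dict[str, float]
    pairs: list[RepeatPair] = dataclasses.field(default_factory=list)


def _bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


def classify_repeats(
    pairs: Sequence[RepeatPair],
    genome: GenomeSet,
    bins: Sequence[tuple[int, int | None]] = ((30, 80), (81, 360), (361, None)),
) -> RepeatCensus:
    """Assign each pair one location class and one size bin.

    Location is ``inter-chromosomal`` when the copies sit on different
    chromosomes, else ``intra-<chrom>``.  Default size bins follow the
    conventional census: 30-80 bp, 81-360 bp, >360 bp; lengths below the
    first edge fall into the first bin.
    """
    by_class: dict[str, int] = {}
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    by_bin = {lab: 0 for lab in labels}
    classified: list[RepeatPair] = []
    for p in pairs:
        if p.copy1.chrom_id not in genome or p.copy2.chrom_id not in genome:
            raise KeyError(f"repeat pair references unknown chromosome: {p}")
        loc = (
            f"intra-{p.copy1.chrom_id}"
            if p.is_intra
            else INTER_CHROMOSOMAL
        )
        by_class[loc] = by_class.get(loc, 0) + 1
        placed = False
        for (lo, hi), lab in zip(bins, labels):
            if (p.repeat_length <= hi if hi is not None else True) and (
                p.repeat_length >= lo or lab == labels[0]
            ):
                by_bin[lab] += 1
                placed = True
                break
        if not placed:  # pragma: no cover - bins always cover with open tail
            by_bin[labels[-1]] += 1
        classified.append(dataclasses.replace(p, location_class=loc))
    total = len(classified)
    fracs = {lab: (n / total if total else 0.0) for lab, n in by_bin.items()}
    return RepeatCensus(total, by_class, by_bin, fracs, classified)


def repeat_mask(
    pairs: Sequence[RepeatPair],
    extra_masks: Sequence[CircInterval] = (),
    genome: GenomeSet | None = None,
) -> list[CircInterval]:
    """Merged, sorted, non-overlapping union of repeat copies and extra masks.

    Origin-wrapping intervals are split at the origin (which needs
    ``genome``); abutting intervals merge.  Strand is discarded.
    """
    per_chrom: defaultdict[str, list[tuple[int, int]]] = defaultdict(list)

    def _add(iv: CircInterval) -> None:
        if iv.wraps:
            if genome is None:
                raise ValueError("genome required for wrap-around mask intervals")
            L = genome[iv.chrom_id].length
            per_chrom[iv.chrom_id].append((iv.start, L))
            per_chrom[iv.chrom_id].append((1, iv.end))
        else:
            per_chrom[iv.chrom_id].append((iv.start, iv.end))

    for p in pairs:
        _add(p.copy1)
        _add(p.copy2)
    for iv in extra_masks:
        _add(iv)

    out: list[CircInterval] = []
    for chrom in sorted(per_chrom):
        merged: list[list[int]] = []
        for s, e in sorted(per_chrom[chrom]):
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend(CircInterval(chrom, s, e, "+") for s, e in merged)
    return out


class MaskIndex:
    """Fast point-in-mask queries over a merged mask."""

    def __init__(self, mask: Sequence[CircInterval]) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in mask:
            self._starts.setdefault(iv.chrom_id, []).append(iv.start)
            self._ends.setdefault(iv.chrom_id, []).append(iv.end)
        for chrom in self._starts:
            order = sorted(range(len(self._starts[chrom])), key=self._starts[chrom].__getitem__)
            self._starts[chrom] = [self._starts[chrom][i] for i in order]
            self._ends[chrom] = [self._ends[chrom][i] for i in order]

    def __contains__(self, loc: tuple[str, int]) -> bool:
        chrom, pos = loc
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos <= self._ends[chrom][i]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_TABLE_COLS = [
    "chrom1",
    "start1",
    "end1",
    "strand1",
    "chrom2",
    "start2",
    "end2",
    "strand2",
    "orientation",
    "length",
    "class",
]


def write_repeat_table(pairs: Sequence[RepeatPair], path: str) -> None:
    rows = [
        {
            "chrom1": p.copy1.chrom_id,
            "start1": p.copy1.start,
            "end1": p.copy1.end,
            "strand1": p.copy1.strand,
            "chrom2": p.copy2.chrom_id,
            "start2": p.copy2.start,
            "end2": p.copy2.end,
            "strand2": p.copy2.strand,
            "orientation": p.orientation,
            "length": p.repeat_length,
            "class": p.location_class or "",
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, sep="\t", index=False)


def read_repeat_table(path: str) -> list[RepeatPair]:
    df = pd.read_csv(path, sep="\t", comment="#")
    pairs = []
    for _, row in df.iterrows():
        loc = row["class"]
        loc = None if pd.isna(loc) or not str(loc).strip() else str(loc)
        pairs.append(
            RepeatPair(
                CircInterval(str(row.chrom1), int(row.start1), int(row.end1), str(row.strand1)),
                CircInterval(str(row.chrom2), int(row.start2), int(row.end2), str(row.strand2)),
                str(row.orientation),
                int(row.length),
                loc,
            )
        )
    return pairs
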