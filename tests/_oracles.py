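"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package's search: repeats are
found by enumerating all start-position pairs and extending character by
character, and mask coverage by a per-base boolean array.
"""

from __future__ import annotations

from circlescan.genome_model import reverse_complement


def _char(S: str, i: int, circular: bool) -> str | None:
    L = len(S)
    if circular:
        return S[i % L]
    if 0 <= i < L:
        return S[i]
    return None


def _extend(SA: str, cA: bool, i: int, SB: str, cB: bool, j: int, cap: int) -> int:
    m = 0
    while m < cap:
        a = _char(SA, i + m, cA)
        b = _char(SB, j + m, cB)
        if a is None or b is None or a != b or a == "N":
            break
        m += 1
    return m


def _interval(L: int, circular: bool, start0: int, m: int) -> tuple[int, int]:
    if circular:
        return start0 % L + 1, (start0 + m - 1) % L + 1
    return start0 + 1, start0 + m


def _canonical(id1, iv1, id2, iv2, orientation, m):
    (a_id, a_iv), (b_id, b_iv) = sorted(((id1, iv1), (id2, iv2)), key=lambda x: (x[0], x[1][0]))
    return (a_id, a_iv[0], a_iv[1], b_id, b_iv[0], b_iv[1], orientation, m)


def brute_force_repeats(
    seqs: dict[str, tuple[str, bool]],
    min_len: int,
    orientations=("direct", "inverted"),
) -> set[tuple]:
    """All maximal exact repeat pairs by exhaustive pair extension.

    ``seqs`` maps id -> (sequence, is_circular).  Returns canonical keys
    (chrom1, start1, end1, chrom2, start2, end2, orientation, length).
    """
    found: set[tuple] = set()
    items = list(seqs.items())
    for x in range(len(items)):
        for y in range(x, len(items)):
            idA, (SA, cA) = items[x]
            idB, (SB, cB) = items[y]
            LA, LB = len(SA), len(SB)
            cap = min(LA, LB)
            if "direct" in orientations:
                for i in range(LA):
                    for j in range(LB):
                        if idA == idB and i == j:
                            continue
                        if idA == idB and j < i:
                            continue
                        la, lb = _char(SA, i - 1, cA), _char(SB, j - 1, cB)
                        if la is not None and lb is not None and la == lb and la != "N":
                            continue
                        m = _extend(SA, cA, i, SB, cB, j, cap)
                        if m >= min_len:
                            iv1 = _interval(LA, cA, i, m)
                            iv2 = _interval(LB, cB, j, m)
                            found.add(_canonical(idA, iv1, idB, iv2, "direct", m))
            if "inverted" in orientations:
                TB = reverse_complement(SB)
                for i in range(LA):
                    for j in range(LB):
                        la, lb = _char(SA, i - 1, cA), _char(TB, j - 1, cB)
                        if la is not None and lb is not None and la == lb and la != "N":
                            continue
                        m = _extend(SA, cA, i, TB, cB, j, cap)
                        if m < min_len:
                            continue
                        iv1 = _interval(LA, cA, i, m)
                        # map the revcomp hit back to forward coordinates
                        if cB:
                            f0 = (LB - (j % LB) - m) % LB
                        else:
                            f0 = LB - j - m
                        iv2 = _interval(LB, cB, f0, m)
                        if idA == idB and iv1 == iv2:
                            continue  # palindromic locus
                        found.add(_canonical(idA, iv1, idB, iv2, "inverted", m))
    return _drop_contained_keys(found, seqs)


def _covers(seqs, chrom, outer, inner) -> bool:
    S, circular = seqs[chrom]
    L = len(S)

    def span(iv):
        return (iv[1] - iv[0]) % L + 1 if circular else iv[1] - iv[0] + 1

    off = (inner[0] - outer[0]) % L if circular else inner[0] - outer[0]
    if off < 0:
        return False
    return off + span(inner) <= span(outer)


def _drop_contained_keys(found: set[tuple], seqs) -> set[tuple]:
    out = set()
    for k in found:
        c1, s1, e1, c2, s2, e2, orient, m = k
        contained = False
        for q in found:
            if q == k or q[6] != orient or q[7] < m:
                continue
            qc1, qs1, qe1, qc2, qs2, qe2 = q[:6]
            if (
                qc1 == c1
                and qc2 == c2
                and _covers(seqs, c1, (qs1, qe1), (s1, e1))
                and _covers(seqs, c2, (qs2, qe2), (s2, e2))
            ) or (
                qc1 == c2
                and qc2 == c1
                and _covers(seqs, c2, (qs1, qe1), (s2, e2))
                and _covers(seqs, c1, (qs2, qe2), (s1, e1))
            ):
                contained = True
                break
        if not contained:
            out.add(k)
    return out


def pair_keys(pairs) -> set[tuple]:
    """Canonical keys for RepeatPair objects, matching the oracle's keys."""
    return {
        (
            p.copy1.chrom_id,
            p.copy1.start,
            p.copy1.end,
            p.copy2.chrom_id,
            p.copy2.start,
            p.copy2.end,
            p.orientation,
            p.repeat_length,
        )
        for p in pairs
    }


def brute_force_mask(seqs_len: dict[str, int], intervals) -> dict[str, list[bool]]:
    """Per-base boolean coverage of mask intervals (1-based positions)."""
    cov = {c: [False] * (L + 1) for c, L in seqs_len.items()}
    for iv in intervals:
        L = seqs_len[iv.chrom_id]
        if iv.start <= iv.end:
            rng = range(iv.start, iv.end + 1)
        else:
            rng = list(range(iv.start, L + 1)) + list(range(1, iv.end + 1))
        for p in rng:
            cov[iv.chrom_id][p] = True
    return cov
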