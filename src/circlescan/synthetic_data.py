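"""Synthetic two-circle genomes, molecule populations, long reads and
multi-sample variant matrices, with full truth tracking.

The generator emulates the structure of a two-chromosome plant mitochondrial
genome: a large circle (~300 kb) carrying a long direct repeat (~15 kb) and
an inverted repeat pair (~4 kb), a smaller circle (~145 kb), and many short
repeats (30-360 bp) within and between the chromosomes, with most short
repeats in the 30-80 bp range.  Molecule populations optionally include the
recombinant isoforms each repeat pair could mediate (excision products,
inversion isoforms, fused circles) at configurable fractions; long reads are
drawn from the molecules with a truncated log-normal length distribution
(size-selected 12-50 kb by default) and independent per-base substitution /
insertion / deletion errors; truth SAM records the intended alignment of
every read against the reference chromosomes, including the split segments
of reads crossing recombinant junctions.

Everything is a pure function of (config, seed): identical inputs give
byte-identical FASTA/FASTQ/SAM/VCF output.  All defaults shrink together
(:meth:`SimConfig.small`) without changing any contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    CircInterval,
    CircularSequence,
    GenomeSet,
    extract,
    wrap_pos,
    write_fasta,
)
from .junction_analysis import (
    AlignmentSegment,
    JunctionSignature,
    ReadPath,
    enumerate_arrangements,
)
from .repeat_finder import DIRECT, INVERTED, RepeatPair, _canonical_pair

__all__ = [
    "RepeatSpec",
    "ReadModel",
    "SampleModel",
    "SimConfig",
    "Molecule",
    "TruthSet",
    "default_repeat_specs",
    "simulate_genome",
    "simulate_molecules",
    "simulate_long_reads",
    "simulate_variant_matrix",
    "load_sim_config",
    "save_sim_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RepeatSpec:
    """One planted repeat pair.

    ``chrom1``/``chrom2`` are chromosome indices (``chrom2`` defaults to
    ``chrom1``); ``positions`` optionally pins the two copy start positions,
    otherwise placement is random and non-overlapping.
    ``recombinant_fraction`` is the fraction of that chromosome's molecules
    carrying the recombinant arrangement this pair mediates.
    """

    length: int
    orientation: str
    chrom1: int = 0
    chrom2: int | None = None
    positions: tuple[int, int] | None = None
    recombinant_fraction: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECT, INVERTED):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0 <= self.recombinant_fraction <= 1:
            raise ValueError("recombinant_fraction must be in [0, 1]")


@dataclass
class ReadModel:
    """Long-read model: truncated log-normal lengths, independent errors.

    Defaults mirror size-selected corrected long reads: 12-50 kb envelope
    with the mode near 15 kb, ~14x depth, and 0.5% substitution, insertion
    and deletion rates each (post-correction error levels).
    """

    min_length: int = 12_000
    max_length: int = 50_000
    mode_length: int = 15_000
    sigma: float = 0.45
    depth: float = 14.0
    sub_rate: float = 0.005
    ins_rate: float = 0.005
    del_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must be in [0, 1)")


@dataclass
class SampleModel:
    """Multi-sample variant model.

    Eight samples by default; sharing-level probabilities follow the
    empirical shape of cross-cultivar organelle variant sharing (monotone
    decreasing, most variants private or shared by few samples); two samples
    carry a high (10%) homozygous fraction and the rest 1%.
    """

    n_samples: int = 8
    n_variants: int = 2243
    sharing_probs: tuple[float, ...] | None = None
    carrier_sets: Sequence[Sequence[int]] | None = None
    homozygous_fractions: tuple[float, ...] = (
        0.10,
        0.10,
        0.01,
        0.01,
        0.01,
        0.01,
        0.01,
        0.01,
    )
    site_depth: float = 50.0
    error_rate: float = 0.005
    snp_fraction: float = 2060 / 2243

    def __post_init__(self) -> None:
        if self.sharing_probs is None:
            base = (823, 774, 259, 140, 92, 63, 43, 33)
            w = base[: self.n_samples]
            w = w + (1,) * (self.n_samples - len(w))
            total = sum(w)
            self.sharing_probs = tuple(x / total for x in w)
        if len(self.homozygous_fractions) != self.n_samples:
            raise ValueError("one homozygous fraction per sample required")

    @property
    def sample_names(self) -> list[str]:
        return [f"sample_{i + 1}" for i in range(self.n_samples)]


def default_repeat_specs() -> list[RepeatSpec]:
    """The default planted-repeat layout.

    Two large pairs on chromosome 1 (15 kb direct, 4 kb inverted) plus 109
    short pairs partitioned 45 within chromosome 1, 11 within chromosome 2
    and 53 shared between them; 97 of the shorts fall in 30-80 bp and 12 in
    81-296 bp, so ~87% of all pairs sit in the 30-80 bp bin.
    """
    specs = [
        RepeatSpec(15_000, DIRECT, 0, name="large_direct"),
        RepeatSpec(4_000, INVERTED, 0, name="large_inverted"),
    ]
    classes = [(0, None)] * 45 + [(1, None)] * 11 + [(0, 1)] * 53
    for i, (c1, c2) in enumerate(classes):
        if i % 9 == 8:
            length = 81 + (i * 37) % 216  # 81..296
        else:
            length = 30 + (i * 23) % 51  # 30..80
        specs.append(
            RepeatSpec(length, DIRECT, c1, c2, name=f"short_{i:03d}")
        )
    return specs


@dataclass
class SimConfig:
    """Complete simulation configuration; seed fixes every random choice."""

    chrom_lengths: tuple[int, ...] = (300_000, 145_000)
    chrom_names: tuple[str, ...] = ("chromosome_1", "chromosome_2")
    repeats: list[RepeatSpec] = field(default_factory=default_repeat_specs)
    read_model: ReadModel = field(default_factory=ReadModel)
    sample_model: SampleModel = field(default_factory=SampleModel)
    placement_margin: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) != len(self.chrom_names):
            raise ValueError("chrom_lengths and chrom_names must align")

    @classmethod
    def small(
        cls,
        seed: int = 0,
        direct_fraction: float = 0.0,
        inversion_fraction: float = 0.0,
        fusion_fraction: float = 0.0,
        depth: float = 12.0,
        sub_rate: float = 0.005,
        ins_rate: float = 0.005,
        del_rate: float = 0.005,
        n_shorts: int = 6,
    ) -> "SimConfig":
        """A scaled-down configuration (30 kb + 15 kb circles, 1.5 kb direct
        and 0.4 kb inverted pair, 1.2-5 kb reads) for fast experiments."""
        specs = [
            RepeatSpec(1500, DIRECT, 0, recombinant_fraction=direct_fraction, name="large_direct"),
            RepeatSpec(400, INVERTED, 0, recombinant_fraction=inversion_fraction, name="large_inverted"),
            RepeatSpec(300, DIRECT, 0, 1, recombinant_fraction=fusion_fraction, name="shared_large"),
        ]
        for i in range(n_shorts):
            specs.append(
                RepeatSpec(
                    35 + 11 * i,
                    DIRECT if i % 2 == 0 else INVERTED,
                    i % 2,
                    None if i < n_shorts // 2 else (i + 1) % 2,
                    name=f"short_{i}",
                )
            )
        return cls(
            chrom_lengths=(30_000, 15_000),
            chrom_names=("chromosome_1", "chromosome_2"),
            repeats=specs,
            read_model=ReadModel(
                min_length=1200,
                max_length=5000,
                mode_length=2500,
                sigma=0.4,
                depth=depth,
                sub_rate=sub_rate,
                ins_rate=ins_rate,
                del_rate=del_rate,
            ),
            placement_margin=250,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """A labeled circular molecule, described as an ordered traversal of
    reference blocks ``(chrom_id, start, length, strand)``."""

    name: str
    blocks: list[tuple[str, int, int, str]]
    weight: float
    label: str

    @property
    def length(self) -> int:
        return sum(b[2] for b in self.blocks)


@dataclass
class TruthSet:
    """Ground truth for one simulation."""

    repeat_pairs: list[RepeatPair]
    pairs_by_name: dict[str, RepeatPair]
    molecules: list[Molecule] = field(default_factory=list)
    read_molecule: dict[str, str] = field(default_factory=dict)
    junctions: dict[str, list[JunctionSignature]] = field(default_factory=dict)
    variant_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def _place(
    rng: np.random.Generator,
    L: int,
    length: int,
    reserved: list[tuple[int, int]],
    margin: int,
    max_tries: int = 2000,
) -> int:
    hi = L - length - margin
    if hi <= margin + 1:
        raise ValueError(f"repeat of {length} b cannot fit on a {L} b chromosome")
    for _ in range(max_tries):
        s = int(rng.integers(margin + 1, hi + 1))
        e = s + length - 1
        if all(e + margin < rs or s - margin > re for rs, re in reserved):
            reserved.append((s, e))
            return s
    raise ValueError("repeats cannot be placed without overlap")


def simulate_genome(cfg: SimConfig) -> tuple[GenomeSet, TruthSet]:
    """Random circular chromosomes with repeats planted by copying.

    Background bases are i.i.d. uniform; each repeat pair copies its first
    (source) interval into the second location, reverse-complemented for
    inverted pairs.  Returns the genome and a truth set holding every
    planted pair in canonical form.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    arrays = [
        _BASES[rng.integers(0, 4, size=L)].copy() for L in cfg.chrom_lengths
    ]
    reserved: list[list[tuple[int, int]]] = [[] for _ in cfg.chrom_lengths]
    placements: list[tuple[RepeatSpec, int, int, int, int]] = []
    for spec in cfg.repeats:
        c1 = spec.chrom1
        c2 = spec.chrom2 if spec.chrom2 is not None else spec.chrom1
        if spec.positions is not None:
            p1, p2 = spec.positions
            reserved[c1].append((p1, p1 + spec.length - 1))
            reserved[c2].append((p2, p2 + spec.length - 1))
        else:
            p1 = _place(rng, cfg.chrom_lengths[c1], spec.length, reserved[c1], cfg.placement_margin)
            p2 = _place(rng, cfg.chrom_lengths[c2], spec.length, reserved[c2], cfg.placement_margin)
        placements.append((spec, c1, p1, c2, p2))

    pairs: list[RepeatPair] = []
    by_name: dict[str, RepeatPair] = {}

    def _force_diff(arr: np.ndarray, idx: int, forbidden: int) -> None:
        # make the planted copy non-extendable at this flank base
        if arr[idx] == forbidden:
            alts = [b for b in _BASES if b != forbidden]
            arr[idx] = alts[idx % 3]

    for spec, c1, p1, c2, p2 in placements:
        content = arrays[c1][p1 - 1 : p1 - 1 + spec.length]
        a1, a2 = arrays[c1], arrays[c2]
        L1n, L2n = len(a1), len(a2)
        left1, right1 = a1[(p1 - 2) % L1n], a1[(p1 - 1 + spec.length) % L1n]
        lo2, hi2 = (p2 - 2) % L2n, (p2 - 1 + spec.length) % L2n
        if spec.orientation == INVERTED:
            arrays[c2][p2 - 1 : p2 - 1 + spec.length] = _revcomp_arr(content)
            _force_diff(a2, hi2, _COMP[left1])
            _force_diff(a2, lo2, _COMP[right1])
        else:
            arrays[c2][p2 - 1 : p2 - 1 + spec.length] = content
            _force_diff(a2, lo2, left1)
            _force_diff(a2, hi2, right1)
        iv1 = CircInterval(cfg.chrom_names[c1], p1, p1 + spec.length - 1, "+")
        iv2 = CircInterval(cfg.chrom_names[c2], p2, p2 + spec.length - 1, "+")
        pair = _canonical_pair(iv1, iv2, spec.orientation, spec.length)
        pairs.append(pair)
        by_name[spec.name or f"pair_{len(by_name)}"] = pair

    genome = GenomeSet(
        CircularSequence(name, arr.tobytes().decode(), True)
        for name, arr in zip(cfg.chrom_names, arrays)
    )
    return genome, TruthSet(repeat_pairs=pairs, pairs_by_name=by_name)


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------


def simulate_molecules(
    genome: GenomeSet, truth: TruthSet, cfg: SimConfig
) -> list[Molecule]:
    """Molecule population: master circles plus configured recombinants.

    Direct intra-chromosomal recombination yields the excision pair (two
    circles whose lengths sum to the parent), inverted yields the inversion
    isoform, and inter-chromosomal yields the fused circle.  Each product
    carries the pair's recombinant fraction as its weight; master-circle
    weights are reduced accordingly.
    """
    master_weight = {c.id: 1.0 for c in genome}
    products: list[Molecule] = []
    truth.junctions = {}
    for spec in cfg.repeats:
        f = spec.recombinant_fraction
        if f <= 0:
            continue
        pair = truth.pairs_by_name[spec.name]
        sigs = [
            s for s in enumerate_arrangements(pair, genome) if s.kind == "recombinant"
        ]
        c1, c2 = pair.copy1, pair.copy2
        s1, e1, s2, e2 = c1.start, c1.end, c2.start, c2.end
        if pair.is_intra and pair.orientation == DIRECT:
            ch = c1.chrom_id
            L = genome[ch].length
            len_a = (s2 - s1) % L
            mol_a = Molecule(f"{spec.name}_excised", [(ch, s1, len_a, "+")], f, "excision")
            mol_b = Molecule(f"{spec.name}_remainder", [(ch, s2, L - len_a, "+")], f, "remainder")
            master_weight[ch] -= f
            products += [mol_a, mol_b]
            truth.junctions[mol_a.name] = [s for s in sigs if s.name == "excision_circle"]
            truth.junctions[mol_b.name] = [s for s in sigs if s.name == "remainder_circle"]
        elif pair.is_intra and pair.orientation == INVERTED:
            ch = c1.chrom_id
            L = genome[ch].length
            mol = Molecule(
                f"{spec.name}_inverted",
                [
                    (ch, 1, e1, "+"),
                    (ch, s2 - 1, s2 - 1 - e1, "-"),
                    (ch, s2, L - s2 + 1, "+"),
                ],
                f,
                "inversion",
            )
            master_weight[ch] -= f
            products.append(mol)
            truth.junctions[mol.name] = sigs
        else:
            ch1, ch2 = c1.chrom_id, c2.chrom_id
            L1, L2 = genome[ch1].length, genome[ch2].length
            if c2.strand == "+":
                blocks = [
                    (ch1, 1, e1, "+"),
                    (ch2, wrap_pos(e2 + 1, L2), L2, "+"),
                    (ch1, e1 + 1, L1 - e1, "+"),
                ]
            else:
                blocks = [
                    (ch1, 1, e1, "+"),
                    (ch2, wrap_pos(s2 - 1, L2), L2, "-"),
                    (ch1, wrap_pos(e1 + 1, L1), L1 - e1, "+"),
                ]
            mol = Molecule(f"{spec.name}_fused", blocks, f, "fusion")
            master_weight[ch1] -= f
            master_weight[ch2] -= f
            products.append(mol)
            truth.junctions[mol.name] = sigs
    for ch, w in master_weight.items():
        if w < 0:
            raise ValueError(f"recombinant fractions on {ch} exceed 1")
    molecules = [
        Molecule(f"{c.id}_master", [(c.id, 1, c.length, "+")], master_weight[c.id], "master")
        for c in genome
    ] + products
    for mol in molecules:
        assert mol.length >= 1
    truth.molecules = molecules
    return molecules


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _project(
    molecule: Molecule, genome: GenomeSet, start: int, length: int
) -> list[tuple[str, int, int, str]]:
    """Project a molecule interval onto reference segments.

    Returns traversal pieces ``(chrom, lo, hi, strand)`` in read order,
    split at chromosome origins; a ``-`` piece is traversed high-to-low.
    """
    M = molecule.length
    spans: list[tuple[int, int]] = []
    end = start + length - 1
    if end <= M:
        spans.append((start, end))
    else:
        spans.append((start, M))
        spans.append((1, end - M))
    pieces: list[tuple[str, int, int, str]] = []
    offsets = []
    o = 0
    for b in molecule.blocks:
        offsets.append(o)
        o += b[2]
    for u, v in spans:
        for (chrom, bstart, blen, bstrand), o0 in zip(molecule.blocks, offsets):
            lo_m, hi_m = max(u, o0 + 1), min(v, o0 + blen)
            if lo_m > hi_m:
                continue
            L = genome[chrom].length
            ou = lo_m - (o0 + 1)
            span = hi_m - lo_m + 1
            if bstrand == "+":
                ref = wrap_pos(bstart + ou, L)
                while span > 0:
                    chunk = min(span, L - ref + 1)
                    pieces.append((chrom, ref, ref + chunk - 1, "+"))
                    ref = 1
                    span -= chunk
            else:
                ref = wrap_pos(bstart - ou, L)
                while span > 0:
                    chunk = min(span, ref)
                    pieces.append((chrom, ref - chunk + 1, ref, "-"))
                    ref = L
                    span -= chunk
    return pieces


_ALT_SUB = {b: [c for c in b"ACGT" if c != b] for b in b"ACGT"}


def _mutate(
    seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float
) -> tuple[str, list[tuple[int, int]]]:
    """Apply independent per-base errors; return (new_seq, cigar ops).

    Ops use SAM codes (0=M, 1=I, 2=D); substitutions stay M.  Insertions are
    emitted after the base they follow.
    """
    n = len(seq)
    if n == 0:
        return "", []
    if sub == 0 and ins == 0 and dele == 0:
        return seq, [(0, n)]
    r = rng.random(n)
    is_del = r < dele
    is_sub = (~is_del) & (r < dele + sub)
    is_ins = rng.random(n) < ins
    events = np.flatnonzero(is_del | is_sub | is_ins)
    if events.size == 0:
        return seq, [(0, n)]
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = bytearray()
    ops: list[list[int]] = []

    def _op(code: int, ln: int) -> None:
        if ln <= 0:
            return
        if ops and ops[-1][0] == code:
            ops[-1][1] += ln
        else:
            ops.append([code, ln])

    prev = 0
    for i in map(int, events):
        _op(0, i - prev)
        out += seq[prev:i].encode()
        if is_del[i]:
            _op(2, 1)
        else:
            if is_sub[i]:
                alts = _ALT_SUB.get(raw[i], list(b"ACGT"))
                out.append(alts[int(rng.integers(0, len(alts)))])
            else:
                out.append(raw[i])
            _op(0, 1)
            if is_ins[i]:
                out.append(int(_BASES[int(rng.integers(0, 4))]))
                _op(1, 1)
        prev = i + 1
    _op(0, n - prev)
    out += seq[prev:].encode()
    return out.decode(), [tuple(o) for o in ops]


def _draw_length(rng: np.random.Generator, model: ReadModel, cap: int) -> int:
    mu = np.log(model.mode_length) + model.sigma**2
    for _ in range(100):
        x = rng.lognormal(mu, model.sigma)
        if model.min_length <= x <= model.max_length:
            break
    else:
        x = float(np.clip(x, model.min_length, model.max_length))
    return max(1, min(int(x), cap))


def simulate_long_reads(
    molecules: Sequence[Molecule],
    genome: GenomeSet,
    cfg: SimConfig,
    fastq_path: str | None = None,
    sam_path: str | None = None,
    rng: np.random.Generator | None = None,
    truth: TruthSet | None = None,
) -> list[ReadPath]:
    """Draw reads from the molecule population until target depth.

    Start positions are uniform on each circular molecule, strand uniform,
    molecule choice proportional to weight x length.  Returns the truth
    alignment paths (identical to what loading the truth SAM yields) and
    optionally writes FASTQ and truth SAM.
    """
    model = cfg.read_model
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    weights = np.array([max(m.weight, 0.0) * m.length for m in molecules], float)
    if weights.sum() <= 0:
        raise ValueError("no molecule has positive weight")
    probs = weights / weights.sum()
    target = model.depth * genome.total_length

    paths: list[ReadPath] = []
    fastq_rows: list[tuple[str, str]] = []
    sam_rows: list[tuple] = []  # (rid, idx, chrom, lo, strand, ops, rs, re, readlen)
    read_molecule: dict[str, str] = {}
    nbases = 0
    i = 0
    while nbases < target:
        mi = int(rng.choice(len(molecules), p=probs))
        mol = molecules[mi]
        ln = _draw_length(rng, model, mol.length)
        start = int(rng.integers(1, mol.length + 1))
        rstrand = "+" if rng.random() < 0.5 else "-"
        rid = f"r{i:06d}"
        pieces = _project(mol, genome, start, ln)
        if rstrand == "-":
            pieces = [
                (ch, lo, hi, "-" if st == "+" else "+")
                for ch, lo, hi, st in reversed(pieces)
            ]
        segs: list[AlignmentSegment] = []
        read_seq = []
        cum = 0
        piece_records = []
        for ch, lo, hi, st in pieces:
            true_seq = extract(CircInterval(ch, lo, hi, st), genome)
            eseq, ops = _mutate(true_seq, rng, model.sub_rate, model.ins_rate, model.del_rate)
            if not eseq:
                continue
            rs, re = cum + 1, cum + len(eseq)
            cum = re
            read_seq.append(eseq)
            piece_records.append((ch, lo, hi, st, ops, rs, re))
        if not piece_records:
            continue
        full = "".join(read_seq)
        for j, (ch, lo, hi, st, ops, rs, re) in enumerate(piece_records):
            segs.append(
                AlignmentSegment(
                    read_id=rid,
                    read_start=rs,
                    read_end=re,
                    ref=CircInterval(ch, lo, hi, st),
                    strand=st,
                    is_supplementary=j > 0,
                    left_clip=rs - 1,
                    right_clip=len(full) - re,
                )
            )
            sam_rows.append((rid, j, ch, lo, st, ops, rs, re, full))
        paths.append(ReadPath(rid, segs))
        fastq_rows.append((rid, full))
        read_molecule[rid] = mol.name
        nbases += ln
        i += 1

    if truth is not None:
        truth.read_molecule = read_molecule
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for rid, seq in fastq_rows:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    if sam_path is not None:
        _write_truth_sam(sam_rows, genome, sam_path)
    return paths


def _write_truth_sam(sam_rows, genome: GenomeSet, path: str) -> None:
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c.id, "LN": c.length} for c in genome],
        }
    )
    from .genome_model import reverse_complement

    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rid, j, ch, lo, st, ops, rs, re, full in sam_rows:
            a = pysam.AlignedSegment(header)
            a.query_name = rid
            a.flag = (16 if st == "-" else 0) | (2048 if j > 0 else 0)
            a.reference_id = header.get_tid(ch)
            a.reference_start = lo - 1
            a.mapping_quality = 60
            n = len(full)
            if st == "-":
                stored = reverse_complement(full)
                lead, trail = n - re, rs - 1
                cig = list(reversed(ops))
            else:
                stored = full
                lead, trail = rs - 1, n - re
                cig = list(ops)
            tuples = []
            if lead:
                tuples.append((4, lead))
            tuples += [tuple(o) for o in cig]
            if trail:
                tuples.append((4, trail))
            a.cigartuples = tuples
            a.query_sequence = stored
            a.query_qualities = pysam.qualitystring_to_array("I" * n)
            fh.write(a)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def simulate_variant_matrix(
    cfg: SimConfig,
    genome: GenomeSet,
    avoid: Sequence[CircInterval] | None = None,
    vcf_path: str | None = None,
    rng: np.random.Generator | None = None,
):
    """Multi-sample small variants with planted sharing/zygosity structure.

    Carrier sets are drawn per sharing-level probability (or taken from
    explicit ``carrier_sets``); carriers are homozygous-like with their
    sample's planted probability (alt fraction ~1), otherwise mixed (~0.5);
    non-carriers see only error-level alternate reads.  Returns
    (records, truth) where truth is a DataFrame of states
    (0 absent, 1 mixed, 2 homozygous-like) per sample.
    """
    from .repeat_finder import MaskIndex
    from .variant_summary import VariantRecord, variant_class_of

    model = cfg.sample_model
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 3])
    samples = model.sample_names
    chroms = list(genome)
    lens = np.array([c.length for c in chroms], float)
    cprobs = lens / lens.sum()
    mask = MaskIndex(avoid or [])
    taken: set[tuple[str, int]] = set()

    n = model.n_variants if model.carrier_sets is None else len(model.carrier_sets)
    records = []
    truth_rows = []
    for vi in range(n):
        for _ in range(1000):
            ci = int(rng.choice(len(chroms), p=cprobs))
            chrom = chroms[ci]
            pos = int(rng.integers(1, chrom.length))  # < L so indels fit
            if (chrom.id, pos) not in taken and (chrom.id, pos) not in mask:
                break
        else:
            raise ValueError("could not place variant outside mask")
        taken.add((chrom.id, pos))
        ref_base = chrom.residues[pos - 1]
        if ref_base == "N":
            ref_base = "A"
        if rng.random() < model.snp_fraction:
            alts = [b for b in "ACGT" if b != ref_base]
            ref, alt = ref_base, alts[int(rng.integers(0, 3))]
        else:
            extra = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + extra
            else:
                ref, alt = ref_base + chrom.residues[pos], ref_base
                if ref == alt:
                    ref = ref_base + extra if extra != chrom.residues[pos] else ref_base + "A"
        if model.carrier_sets is not None:
            carriers = set(model.carrier_sets[vi])
        else:
            k = 1 + int(rng.choice(model.n_samples, p=model.sharing_probs))
            carriers = set(map(int, rng.choice(model.n_samples, size=k, replace=False)))
        depths = {}
        states = []
        for si, sample in enumerate(samples):
            d = int(rng.poisson(model.site_depth))
            if si in carriers:
                homo = rng.random() < model.homozygous_fractions[si]
                if homo:
                    a = d - int(rng.binomial(d, model.error_rate))
                    state = 2
                else:
                    a = int(rng.binomial(d, 0.5))
                    state = 1
            else:
                a = int(rng.binomial(d, model.error_rate))
                state = 0
            depths[sample] = (d - a, a)
            states.append(state)
        records.append(
            VariantRecord(
                chrom=chrom.id,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                variant_class=variant_class_of(ref, alt),
                allele_depths=depths,
            )
        )
        truth_rows.append({"chrom": chrom.id, "pos": pos, **dict(zip(samples, states))})

    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    if vcf_path is not None:
        _write_vcf(records, samples, genome, vcf_path)
    return records, truth


def _write_vcf(records, samples, genome: GenomeSet, path: str) -> None:
    import pysam

    header = pysam.VariantHeader()
    for c in genome:
        header.contigs.add(c.id, length=c.length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as fh:
        for rec in records:
            r = fh.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref_allele, rec.alt_allele),
            )
            for s in samples:
                ref_n, alt_n = rec.allele_depths[s]
                d = ref_n + alt_n
                frac = alt_n / d if d else 0.0
                if alt_n == 0 or frac < 0.05:
                    gt = (0, 0)
                elif frac >= 0.9:
                    gt = (1, 1)
                else:
                    gt = (0, 1)
                r.samples[s]["GT"] = gt
                r.samples[s]["AD"] = (ref_n, alt_n)
            fh.write(r)


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------


def save_sim_config(cfg: SimConfig, path: str) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def load_sim_config(path: str) -> SimConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["repeats"] = [RepeatSpec(**r) for r in raw.get("repeats", [])]
    if "read_model" in raw:
        raw["read_model"] = ReadModel(**raw["read_model"])
    if "sample_model" in raw:
        sm = dict(raw["sample_model"])
        if sm.get("sharing_probs") is not None:
            sm["sharing_probs"] = tuple(sm["sharing_probs"])
        if sm.get("homozygous_fractions") is not None:
            sm["homozygous_fractions"] = tuple(sm["homozygous_fractions"])
        raw["sample_model"] = SampleModel(**sm)
    raw["chrom_lengths"] = tuple(raw["chrom_lengths"])
    raw["chrom_names"] = tuple(raw["chrom_names"])
    return SimConfig(**raw)
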