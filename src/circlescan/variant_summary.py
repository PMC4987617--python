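"""Small-variant post-processing: presence calls, masking and sharing.

Organelle variant calls from short-read mapping are dominated by two
artefacts: sequencing error (handled by requiring the minor allele to reach
a minimum proportion of reads per sample, 10% by default) and mismapping
within repeats and chloroplast-derived segments (handled by excluding
variants inside a repeat/chloroplast mask).  What remains is summarized as a
per-sample presence/zygosity matrix, a cross-sample sharing histogram, and a
per-sample homozygous fraction — variants whose alternate allele dominates a
sample's reads, the organelle analogue of a homozygous genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import CircInterval
from .repeat_finder import MaskIndex

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "SampleCall",
    "SharingHistogram",
    "load_variants",
    "call_presence",
    "apply_masks",
    "sharing_histogram",
    "summarize_variants",
]

SNP = "SNP"
INDEL = "InDel"

ABSENT = "absent"
MIXED = "mixed"
HOMOZYGOUS = "homozygous-like"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic small variant with per-sample allele depths."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    allele_depths: Mapping[str, tuple[int, int]]  # sample -> (ref, alt)

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")
        expected = SNP if len(self.ref_allele) == 1 and len(self.alt_allele) == 1 else INDEL
        if self.variant_class != expected:
            raise ValueError(
                f"{self.chrom}:{self.pos}: class {self.variant_class} inconsistent with alleles"
            )
        for sample, (r, a) in self.allele_depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"{self.chrom}:{self.pos}: negative depth for {sample}")


@dataclass(frozen=True)
class SampleCall:
    state: str  # absent | mixed | homozygous-like
    alt_fraction: float


def variant_class_of(ref: str, alt: str) -> str:
    return SNP if len(ref) == 1 and len(alt) == 1 else INDEL


def load_variants(path: str) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF with per-sample AD fields; multiallelic sites are split.

    Returns the records and the sample order.  Missing allele-depth data
    raises ``ValueError``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"{v.CHROM}:{v.POS}: missing AD (allele depth) field")
        for ai, alt in enumerate(v.ALT):
            depths = {}
            for si, sample in enumerate(samples):
                r = int(ad[si][0])
                a = int(ad[si][ai + 1])
                depths[sample] = (max(r, 0), max(a, 0))  # missing (-1) -> 0
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref_allele=v.REF,
                    alt_allele=alt,
                    variant_class=variant_class_of(v.REF, alt),
                    allele_depths=depths,
                )
            )
    return records, samples


def call_presence(
    rec: VariantRecord,
    min_minor_prop: float = 0.10,
    homo_threshold: float = 0.9,
) -> dict[str, SampleCall]:
    """Per-sample presence/zygosity under the minor-allele-proportion rule.

    With depth ``d = ref + alt``: absent when ``alt == 0``, ``d == 0`` or
    ``alt/d < min_minor_prop``; homozygous-like when ``alt/d >=
    homo_threshold``; mixed otherwise.  The default 0.9 homozygous cutoff is
    a conventional threshold for organelle homoplasmy-style calls.
    """
    if not 0 < min_minor_prop < 0.5:
        raise ValueError("min_minor_prop must be in (0, 0.5)")
    if not 0.5 <= homo_threshold <= 1:
        raise ValueError("homo_threshold must be in [0.5, 1]")
    calls = {}
    for sample, (r, a) in rec.allele_depths.items():
        d = r + a
        if d == 0 or a == 0:
            calls[sample] = SampleCall(ABSENT, 0.0)
            continue
        frac = a / d
        if frac < min_minor_prop:
            calls[sample] = SampleCall(ABSENT, frac)
        elif frac >= homo_threshold:
            calls[sample] = SampleCall(HOMOZYGOUS, frac)
        else:
            calls[sample] = SampleCall(MIXED, frac)
    return calls


def apply_masks(
    records: Sequence[VariantRecord],
    mask: Sequence[CircInterval],
) -> tuple[list[VariantRecord], int]:
    """Remove variants whose position lies inside any mask interval."""
    idx = MaskIndex(mask)
    kept = [r for r in records if (r.chrom, r.pos) not in idx]
    removed = len(records) - len(kept)
    if removed:
        logger.info("masked out %d of %d variants", removed, len(records))
    return kept, removed


@dataclass
class SharingHistogram:
    """Cross-sample sharing counts plus per-sample homozygous fractions."""

    counts: dict[int, int]
    total: int
    shared_1_to_5: int
    shared_6_plus: int
    homozygous_fraction: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: Mapping[int, int]) -> "SharingHistogram":
        counts = {int(k): int(v) for k, v in counts.items() if v}
        total = sum(counts.values())
        low = sum(v for k, v in counts.items() if 1 <= k <= 5)
        high = sum(v for k, v in counts.items() if k >= 6)
        return cls(dict(sorted(counts.items())), total, low, high)


def sharing_histogram(
    records: Sequence[VariantRecord],
    calls: Sequence[Mapping[str, SampleCall]],
) -> SharingHistogram:
    """Histogram of how many samples carry each variant.

    A sample carries a variant when its call state is not absent.  Variants
    with zero carriers are dropped (the histogram starts at one sample).
    The per-sample homozygous fraction is homozygous-like calls over present
    calls for that sample.
    """
    if len(records) != len(calls):
        raise ValueError("records and calls must align")
    counts: dict[int, int] = {}
    present: dict[str, int] = {}
    homo: dict[str, int] = {}
    for rec, call in zip(records, calls):
        carriers = [s for s, c in call.items() if c.state != ABSENT]
        if not carriers:
            continue
        counts[len(carriers)] = counts.get(len(carriers), 0) + 1
        for s in carriers:
            present[s] = present.get(s, 0) + 1
            if call[s].state == HOMOZYGOUS:
                homo[s] = homo.get(s, 0) + 1
    hist = SharingHistogram.from_counts(counts)
    hist.homozygous_fraction = {
        s: homo.get(s, 0) / n for s, n in sorted(present.items())
    }
    return hist


def summarize_variants(
    records: Sequence[VariantRecord],
    min_minor_prop: float = 0.10,
    homo_threshold: float = 0.9,
    mask: Sequence[CircInterval] | None = None,
    site_filter: bool = False,
) -> tuple[SharingHistogram, list[dict[str, SampleCall]], int]:
    """Mask, call presence and build the sharing histogram in one pass.

    ``site_filter=True`` applies an alternative reading of the minor-allele
    rule: a site failing the proportion threshold in every sample is dropped
    entirely, and any sample with alternate reads at a kept site counts as a
    carrier.  The default treats the rule as a per-sample presence filter.
    """
    kept = list(records)
    removed = 0
    if mask:
        kept, removed = apply_masks(kept, mask)
    calls = [call_presence(r, min_minor_prop, homo_threshold) for r in kept]
    if site_filter:
        filtered_records, filtered_calls = [], []
        for rec, call in zip(kept, calls):
            if all(c.state == ABSENT for c in call.values()):
                continue
            permissive = {}
            for sample, (r, a) in rec.allele_depths.items():
                d = r + a
                if d == 0 or a == 0:
                    permissive[sample] = SampleCall(ABSENT, 0.0)
                else:
                    frac = a / d
                    state = HOMOZYGOUS if frac >= homo_threshold else MIXED
                    permissive[sample] = SampleCall(state, frac)
            filtered_records.append(rec)
            filtered_calls.append(permissive)
        kept, calls = filtered_records, filtered_calls
    return sharing_histogram(kept, calls), calls, removed


def write_histogram(hist: SharingHistogram, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("n_samples\tvariant_count\n")
        for k, v in sorted(hist.counts.items()):
            fh.write(f"{k}\t{v}\n")
        fh.write(f"# total\t{hist.total}\n")
        fh.write(f"# shared_1_to_5\t{hist.shared_1_to_5}\n")
        fh.write(f"# shared_6_plus\t{hist.shared_6_plus}\n")


def write_sample_summary(hist: SharingHistogram, path: str) -> None:
    df = pd.DataFrame(
        {
            "sample": list(hist.homozygous_fraction),
            "homozygous_fraction": list(hist.homozygous_fraction.values()),
        }
    )
    df.to_csv(path, sep="\t", index=False)
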