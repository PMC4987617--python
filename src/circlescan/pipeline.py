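"""End-to-end orchestration: repeats -> read support -> junctions -> depth
-> variant summary, with a parameter-stamped report."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .genome_model import CircInterval, GenomeSet, read_fasta, write_bed
from .junction_analysis import (
    ArrangementSupport,
    DepthProfile,
    JunctionCall,
    call_breakpoint_junctions,
    count_support,
    depth_profile,
    load_alignments,
    write_junction_table,
)
from .repeat_finder import (
    RepeatCensus,
    classify_repeats,
    find_maximal_repeats,
    repeat_mask,
    write_repeat_table,
)
from .variant_summary import (
    SharingHistogram,
    load_variants,
    summarize_variants,
    write_histogram,
    write_sample_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and stage parameters for one pipeline run."""

    fasta: str
    alignments: str | None = None
    vcf: str | None = None
    extra_mask_bed: str | None = None
    outdir: str = "circlescan_out"
    # repeat stage
    min_repeat_len: int = 30
    orientations: tuple[str, ...] = ("direct", "inverted")
    # read classification
    min_anchor: int = 200
    breakpoint_tol: int = 50
    support_min_repeat_len: int = 500
    # junction calling
    min_clip: int = 100
    cluster_window: int = 100
    min_junction_reads: int = 3
    # depth
    depth_window: int = 100
    low_depth_fraction: float = 0.1
    low_depth_min_span: int = 1000
    # variants
    min_minor_prop: float = 0.10
    homo_threshold: float = 0.9


@dataclass
class RunResult:
    census: RepeatCensus
    mask: list[CircInterval]
    support: list[ArrangementSupport] = field(default_factory=list)
    junctions: list[JunctionCall] = field(default_factory=list)
    depth: DepthProfile | None = None
    histogram: SharingHistogram | None = None
    masked_variants: int = 0
    report: str = ""


def _read_bed(path: str) -> list[CircInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5].strip() if len(f) > 5 else "+"
            out.append(CircInterval(f[0], int(f[1]) + 1, int(f[2]), strand))
    return out


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute every configured stage and write tables plus a report.

    The alignment and variant stages are optional; skipped stages are marked
    "not run" in the report.  All outputs are pure functions of the inputs
    and parameters.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(cfg.fasta)

    pairs = find_maximal_repeats(genome, cfg.min_repeat_len, cfg.orientations)
    census = classify_repeats(pairs, genome)
    extra = _read_bed(cfg.extra_mask_bed) if cfg.extra_mask_bed else []
    mask = repeat_mask(census.pairs, extra, genome)
    write_repeat_table(census.pairs, str(out / "repeats.tsv"))
    write_bed(mask, str(out / "mask.bed"), genome, name="mask")

    result = RunResult(census=census, mask=mask)

    paths = None
    if cfg.alignments:
        paths = load_alignments(cfg.alignments, genome)
        big = [p for p in census.pairs if p.repeat_length >= cfg.support_min_repeat_len]
        result.support = count_support(
            paths, big, genome, cfg.min_anchor, cfg.breakpoint_tol
        )
        result.junctions = call_breakpoint_junctions(
            paths,
            genome,
            cfg.min_clip,
            cfg.cluster_window,
            cfg.min_junction_reads,
            repeat_pairs=census.pairs,
        )
        write_junction_table(result.junctions, str(out / "junctions.tsv"))
        result.depth = depth_profile(
            paths,
            genome,
            cfg.depth_window,
            cfg.low_depth_fraction,
            cfg.low_depth_min_span,
        )
        _write_support_table(result.support, str(out / "support.tsv"))
        _write_depth_table(result.depth, str(out / "depth.tsv"))

    if cfg.vcf:
        records, _samples = load_variants(cfg.vcf)
        hist, _calls, removed = summarize_variants(
            records, cfg.min_minor_prop, cfg.homo_threshold, mask=mask
        )
        result.histogram = hist
        result.masked_variants = removed
        write_histogram(hist, str(out / "variant_sharing.tsv"))
        write_sample_summary(hist, str(out / "variant_samples.tsv"))

    result.report = _render_report(cfg, result)
    (out / "report.txt").write_text(result.report)
    return result


def _write_support_table(support: Sequence[ArrangementSupport], path: str) -> None:
    rows = []
    for s in support:
        rows.append(
            {
                "chrom1": s.pair.copy1.chrom_id,
                "start1": s.pair.copy1.start,
                "chrom2": s.pair.copy2.chrom_id,
                "start2": s.pair.copy2.start,
                "orientation": s.pair.orientation,
                "length": s.pair.repeat_length,
                "ref_copy1": s.count_ref_copy1,
                "ref_copy2": s.count_ref_copy2,
                "ref_both": s.count_ref_both,
                "recombinant": s.count_recombinant,
                "uninformative": s.uninformative_count,
                "verdict": s.verdict,
                "low_evidence": int(s.low_evidence),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_depth_table(depth: DepthProfile, path: str) -> None:
    rows = []
    for chrom, vals in depth.per_window.items():
        for wi, v in enumerate(vals):
            rows.append({"chrom": chrom, "window_start": wi * depth.window + 1, "depth": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")


def _render_report(cfg: RunConfig, r: RunResult) -> str:
    lines = [
        f"# circlescan v{__version__} pipeline report",
        "## parameters",
    ]
    for k, v in dataclasses.asdict(cfg).items():
        lines.append(f"  {k} = {v}")
    lines.append("")
    lines.append("## repeat census")
    lines.append(f"  total pairs: {r.census.total}")
    for cls, n in sorted(r.census.by_class.items()):
        lines.append(f"  {cls}: {n}")
    for lab, n in r.census.by_bin.items():
        frac = r.census.bin_fractions[lab]
        lines.append(f"  size {lab} bp: {n} ({frac:.0%})")
    lines.append("")
    if r.support:
        lines.append("## arrangement support (repeat pairs >= "
                     f"{cfg.support_min_repeat_len} bp)")
        for s in r.support:
            p = s.pair
            lines.append(
                f"  {p.copy1.chrom_id}:{p.copy1.start}-{p.copy1.end} / "
                f"{p.copy2.chrom_id}:{p.copy2.start}-{p.copy2.end} "
                f"({p.orientation}, {p.repeat_length} bp): "
                f"ref {s.count_ref_copy1}+{s.count_ref_copy2} "
                f"(both {s.count_ref_both}), recombinant {s.count_recombinant}, "
                f"verdict {s.verdict}"
                + (" [low evidence]" if s.low_evidence else "")
            )
        lines.append("")
        lines.append("## breakpoint junctions")
        if r.junctions:
            for c in r.junctions:
                lines.append(
                    f"  {c.signature.description} (support {c.support}, {c.signature.kind})"
                )
        else:
            lines.append("  none called")
        lines.append("")
        lines.append("## depth")
        lines.append(f"  median {r.depth.median:.0f}, mean {r.depth.mean:.1f}")
        if r.depth.low_intervals:
            for iv in r.depth.low_intervals:
                lines.append(
                    f"  low-depth (<{r.depth.low_fraction:.0%} of mean): "
                    f"{iv.chrom_id}:{iv.start}-{iv.end}"
                )
        else:
            lines.append("  no low-depth intervals flagged")
    else:
        lines.append("## arrangement support / junctions / depth: not run (no alignments)")
    lines.append("")
    if r.histogram is not None:
        h = r.histogram
        lines.append("## variant sharing")
        lines.append(f"  masked out: {r.masked_variants}")
        lines.append(f"  total variants: {h.total}")
        lines.append(f"  shared by 1-5 samples: {h.shared_1_to_5}")
        lines.append(f"  shared by >=6 samples: {h.shared_6_plus}")
        for s, f in h.homozygous_fraction.items():
            lines.append(f"  {s}: homozygous fraction {f:.3f}")
    else:
        lines.append("## variant summary: not run (no VCF)")
    lines.append("")
    return "\n".join(lines)
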