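"""Output writers: VCF/BCF, gVCF with non-variant blocks, and pileup text.

The gVCF writer merges runs of adjacent invariable sites into block records
(END + per-sample MIN_DP) keyed by configurable per-sample depth ranges, with
a symbolic non-reference aggregate allele (``<NON_REF>`` in the GATK dialect,
``<*>`` in the BCFtools dialect).  The pileup dialect writes explicit bases —
uppercase for forward-strand reads, lowercase for reverse — rather than the
``.``/``,`` ref-matching shorthand.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import pysam

from .likelihoods import NONREF_SYMBOLS
from .pipeline import SiteResult
from .truth import TruthCohort

logger = logging.getLogger("glsim")

_MODES = {"v": "w", "z": "wz", "b": "wb", "u": "wb0"}

__all__ = [
    "GvcfBlock",
    "write_vcf",
    "write_gvcf",
    "write_pileup",
    "read_record_stream",
    "expand_gvcf",
]


def _build_header(
    cohort: TruthCohort, command: str | None, gvcf: bool
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in cohort.contig_lengths.items():
        if length is None:
            header.contigs.add(contig)
        else:
            header.contigs.add(contig, length=length)
    header.info.add("QS", "R", "Float", "Normalized per-allele sum of base quality scores")
    header.info.add("I16", 16, "Float", "Auxiliary mpileup tag: strand-stratified ref/non-ref counts and sums/squared-sums of base qualities, mapping qualities, and tail distances")
    if gvcf:
        header.info.add("END", 1, "Integer", "End position of non-variant block (inclusive)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Per-allele read depth")
    header.formats.add("GL", "G", "Float", "Log10-scaled genotype likelihoods")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    if gvcf:
        header.formats.add("MIN_DP", 1, "Integer", "Minimum per-sample depth in block")
    if command is not None:
        header.add_line(f"##glsim_command={command}")
    for name in cohort.sample_names:
        header.add_sample(name)
    return header


def _pad(values, target: int) -> list:
    # pysam writes None as the VCF missing value "."
    return list(values) + [None] * (target - len(values))


def _fill_sample(fmt, gt, depth, ad, gl, pl, gq, n_alleles: int) -> None:
    n_geno = n_alleles * (n_alleles + 1) // 2
    fmt["GT"] = gt
    fmt.phased = False
    fmt["DP"] = depth
    fmt["AD"] = _pad([int(x) for x in ad], n_alleles)
    fmt["GL"] = _pad([float(x) for x in gl], n_geno)
    fmt["PL"] = _pad([int(x) for x in pl], n_geno)
    fmt["GQ"] = gq


def _write_site_record(out, res: SiteResult, cohort: TruthCohort) -> None:
    # a lone REF needs a dummy "." ALT (reads back as alts=None); array
    # fields then pad to the 2-allele layout with missing values
    alleles = res.alleles if len(res.alleles) > 1 else (res.alleles[0], ".")
    rec = out.new_record(
        contig=res.site.contig,
        start=res.site.pos - 1,
        stop=res.site.pos,
        alleles=alleles,
    )
    if res.annotation.qs is not None:
        rec.info["QS"] = _pad(res.annotation.qs, len(alleles))
    rec.info["I16"] = res.annotation.i16
    for i, name in enumerate(cohort.sample_names):
        depth = res.depths[i]
        gt = res.site.genotypes[i]
        out_gt = gt if (gt is not None and depth > 0) else (None, None)
        _fill_sample(
            rec.samples[name], out_gt, depth, res.ads[i],
            res.gls[i].values, res.pls[i], res.gqs[i], len(alleles),
        )
    out.write(rec)


def write_vcf(
    results: list[SiteResult],
    cohort: TruthCohort,
    path: str,
    mode: str = "v",
    command: str | None = None,
) -> None:
    """Write per-site records as VCF (``v``), bgzip VCF (``z``), BCF (``b``),
    or uncompressed BCF (``u``)."""
    if mode not in _MODES:
        raise ValueError(f"unknown output mode {mode!r}; use one of {sorted(_MODES)}")
    header = _build_header(cohort, command, gvcf=False)
    with pysam.VariantFile(path, _MODES[mode], header=header) as out:
        for res in results:
            _write_site_record(out, res, cohort)


@dataclass
class GvcfBlock:
    """A run of adjacent invariable sites compressed into one record."""

    contig: str
    start: int
    end: int
    ref: str
    key: tuple  # per-sample (depth-bin, has-coverage) signature
    sites: list[SiteResult]

    def min_dps(self) -> list[int]:
        return [
            min(res.depths[i] for res in self.sites)
            for i in range(len(self.sites[0].depths))
        ]


def _depth_key(depths: list[int], breakpoints: tuple[int, ...]) -> tuple:
    # zero-coverage status is part of the key so ./. vs 0/0 stays exact
    return tuple((bisect_right(breakpoints, d), d > 0) for d in depths)


def _flush_block(out, block: GvcfBlock, cohort: TruthCohort, nonref: str) -> None:
    rec = out.new_record(
        contig=block.contig,
        start=block.start - 1,
        stop=block.end,
        alleles=(block.ref, nonref),
    )
    min_dps = block.min_dps()
    for i, name in enumerate(cohort.sample_names):
        # representative GL/PL/GQ come from this sample's minimum-depth site
        rep = min(block.sites, key=lambda r: r.depths[i])
        gt = (0, 0) if min_dps[i] > 0 else (None, None)
        _fill_sample(
            rec.samples[name], gt, block.sites[0].depths[i], rep.ads[i],
            rep.gls[i].values, rep.pls[i], rep.gqs[i], 2,
        )
        rec.samples[name]["MIN_DP"] = min_dps[i]
    out.write(rec)


def write_gvcf(
    results: list[SiteResult],
    cohort: TruthCohort,
    path: str,
    dp_breakpoints: tuple[int, ...] = (1,),
    mode: str = "v",
    command: str | None = None,
) -> None:
    """Write a gVCF: variant sites as ordinary records, invariable runs as
    non-variant blocks.

    ``dp_breakpoints`` are increasing depth thresholds defining the blocking
    ranges (e.g. ``(5, 10)`` gives [0,5), [5,10), [10,inf)); adjacent
    invariable sites merge only while every sample stays in the same range
    and keeps its zero/nonzero coverage status.  Results must have been
    scored with a symbolic non-reference allele.
    """
    if not results:
        raise ValueError("no results to write")
    if results[0].alleles[-1] not in NONREF_SYMBOLS:
        raise ValueError(
            "gVCF output requires scoring with a non-reference aggregate "
            f"allele (one of {NONREF_SYMBOLS})"
        )
    bp = tuple(dp_breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])) or any(b < 1 for b in bp):
        raise ValueError("dp breakpoints must be strictly increasing and >= 1")
    nonref = results[0].alleles[-1]
    header = _build_header(cohort, command, gvcf=True)
    with pysam.VariantFile(path, _MODES[mode], header=header) as out:
        block: GvcfBlock | None = None
        for res in results:
            if res.site.is_variant:
                if block is not None:
                    _flush_block(out, block, cohort, nonref)
                    block = None
                _write_site_record(out, res, cohort)
                continue
            key = _depth_key(res.depths, bp)
            if (
                block is not None
                and res.site.contig == block.contig
                and res.site.pos == block.end + 1
                and key == block.key
            ):
                block.end = res.site.pos
                block.sites.append(res)
            else:
                if block is not None:
                    _flush_block(out, block, cohort, nonref)
                block = GvcfBlock(
                    res.site.contig, res.site.pos, res.site.pos,
                    res.site.ref_allele, key, [res],
                )
        if block is not None:
            _flush_block(out, block, cohort, nonref)


def write_pileup(
    results: list[SiteResult], cohort: TruthCohort, path: str
) -> None:
    """Write samtools-style pileup text.

    Per site: contig, position, reference base, then per sample a depth
    column, a base string (uppercase forward / lowercase reverse), and a
    Phred+33 quality string.  Qualities above 93 clamp to the printable
    ASCII bound with a warning; depth 0 writes ``0\\t*\\t*``.
    """
    clamped = False
    with open(path, "w") as fh:
        for res in results:
            cols = [res.site.contig, str(res.site.pos), res.site.ref_allele]
            for stack in res.reads.observations:
                if not stack:
                    cols += ["0", "*", "*"]
                    continue
                bases = "".join(
                    o.base if o.strand == 0 else o.base.lower() for o in stack
                )
                quals = []
                for o in stack:
                    q = o.reported_quality
                    if q > 93:
                        clamped = True
                        q = 93
                    quals.append(chr(q + 33))
                cols += [str(len(stack)), bases, "".join(quals)]
            fh.write("\t".join(cols) + "\n")
    if clamped:
        logger.warning("pileup: qualities above 93 clamped to the ASCII bound")


def read_record_stream(path: str) -> list[tuple]:
    """Read a VCF into comparable tuples: (contig, pos, ref, alts, GTs).

    Symbolic non-reference alleles are dropped from the ALT set so plain-VCF
    and gVCF streams compare directly.
    """
    out = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = tuple(
                a for a in (rec.alts or ()) if a not in NONREF_SYMBOLS
            )
            gts = tuple(rec.samples[s].get("GT") for s in samples)
            out.append((rec.chrom, rec.pos, rec.ref, alts, gts))
    return out


def expand_gvcf(path: str) -> list[tuple]:
    """Expand gVCF blocks back to a per-site record stream.

    Block records replicate their GT pattern across every covered position;
    the result has the same tuple shape as :func:`read_record_stream`.
    """
    out = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = tuple(
                a for a in (rec.alts or ()) if a not in NONREF_SYMBOLS
            )
            gts = tuple(rec.samples[s].get("GT") for s in samples)
            end = rec.stop  # pysam surfaces INFO/END as the record stop
            if not alts and end > rec.pos:
                for pos in range(rec.pos, end + 1):
                    out.append((rec.chrom, pos, rec.ref, alts, gts))
            else:
                out.append((rec.chrom, rec.pos, rec.ref, alts, gts))
    return out
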