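"""Truth-genotype input: read VCF/BCF truth sets and generate synthetic ones.

A truth set is the ground-truth diploid genotypes the read simulator samples
alleles from.  It can come from any VCF/BCF with GT — including tree-sequence
exports from msprime or SLiM, whose synthetic ``0``/``1`` alleles are remapped
to concrete bases — or from the built-in Bernoulli generator, so the whole
pipeline is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pysam

BASES = ("A", "C", "G", "T")

# msprime/SLiM tree-sequence exports use REF=0/ALT=1 placeholder alleles.
DEFAULT_REMAP = {"0": "A", "1": "C"}

__all__ = [
    "TruthSite",
    "TruthCohort",
    "UnsupportedPloidyError",
    "AlleleRemapError",
    "MissingGenotypeError",
    "read_truth_vcf",
    "write_truth_vcf",
    "generate_truth",
    "explode_invariable",
    "DEFAULT_REMAP",
]


class UnsupportedPloidyError(ValueError):
    """GT field is not diploid."""


class AlleleRemapError(ValueError):
    """An allele is not A/C/G/T and no remap entry covers it."""


class MissingGenotypeError(ValueError):
    """A sample has a missing GT and skipping is not enabled."""


@dataclass(frozen=True)
class TruthSite:
    """One site's true alleles and per-sample diploid genotypes.

    ``genotypes[i]`` is the ordered pair of allele indices for sample ``i``
    (unphased semantics; ``None`` marks a missing genotype, which downstream
    simulation treats as depth 0).  ``alt_alleles`` is empty for invariable
    sites.
    """

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: tuple[tuple[int, int] | None, ...]

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES:
            raise ValueError(f"ref allele {self.ref_allele!r} is not a single base")
        alleles = (self.ref_allele, *self.alt_alleles)
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"alleles not distinct at {self.contig}:{self.pos}")
        for a in self.alt_alleles:
            if a not in BASES:
                raise ValueError(f"alt allele {a!r} is not a single base")
        n_alleles = len(alleles)
        for gt in self.genotypes:
            if gt is None:
                continue
            if max(gt) >= n_alleles or min(gt) < 0:
                raise ValueError(
                    f"genotype index out of range at {self.contig}:{self.pos}"
                )

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)

    @property
    def is_variant(self) -> bool:
        return len(self.alt_alleles) > 0


@dataclass
class TruthCohort:
    """An ordered stream of truth sites plus sample and contig metadata."""

    sample_names: list[str]
    contig_lengths: dict[str, int | None]
    sites: list[TruthSite] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def validate(self) -> None:
        prev: dict[str, int] = {}
        for site in self.sites:
            if len(site.genotypes) != self.n_samples:
                raise ValueError(f"sample count mismatch at {site.contig}:{site.pos}")
            if site.contig in prev and site.pos <= prev[site.contig]:
                raise ValueError(
                    f"positions not strictly increasing at {site.contig}:{site.pos}"
                )
            length = self.contig_lengths.get(site.contig)
            if length is not None and site.pos > length:
                raise ValueError(
                    f"position {site.pos} exceeds contig length {length}"
                )
            prev[site.contig] = site.pos


def _remap_allele(allele: str, base_remap: dict[str, str] | None) -> str:
    if base_remap and allele in base_remap:
        return base_remap[allele]
    if allele in BASES:
        return allele
    raise AlleleRemapError(
        f"allele {allele!r} is not A/C/G/T and has no remap entry"
    )


def read_truth_vcf(
    path: str,
    base_remap: dict[str, str] | None = None,
    skip_missing: bool = False,
) -> TruthCohort:
    """Read truth genotypes from a VCF/BCF file.

    Parameters
    ----------
    path:
        VCF/BCF file (plain, bgzipped, or binary); GT must be present.
    base_remap:
        Optional map from placeholder alleles (e.g. ``"0"``/``"1"`` in
        tree-sequence exports) to concrete bases.  Alleles already in
        {A,C,G,T} pass through.
    skip_missing:
        If True a missing GT becomes ``None`` (the sample gets no reads at
        that site); otherwise it raises :class:`MissingGenotypeError`.
    """
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        contig_lengths: dict[str, int | None] = {
            name: (ctg.length or None) for name, ctg in vf.header.contigs.items()
        }
        sites: list[TruthSite] = []
        for rec in vf:
            ref = _remap_allele(rec.ref, base_remap)
            alts = tuple(
                _remap_allele(a, base_remap) for a in (rec.alts or ())
            )
            genotypes: list[tuple[int, int] | None] = []
            for name in samples:
                gt = rec.samples[name].get("GT")
                if gt is None or all(a is None for a in gt):
                    if skip_missing:
                        genotypes.append(None)
                        continue
                    raise MissingGenotypeError(
                        f"missing GT for {name} at {rec.chrom}:{rec.pos}"
                    )
                if len(gt) != 2 or any(a is None for a in gt):
                    raise UnsupportedPloidyError(
                        f"non-diploid GT {gt} for {name} at {rec.chrom}:{rec.pos}"
                    )
                genotypes.append((int(gt[0]), int(gt[1])))
            sites.append(
                TruthSite(rec.chrom, rec.pos, ref, alts, tuple(genotypes))
            )
    cohort = TruthCohort(samples, contig_lengths, sites)
    cohort.validate()
    return cohort


def write_truth_vcf(cohort: TruthCohort, path: str) -> None:
    """Write a cohort back out as a minimal sites+GT VCF (round-trip aid)."""
    header = pysam.VariantHeader()
    for contig, length in cohort.contig_lengths.items():
        if length is None:
            header.contigs.add(contig)
        else:
            header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for name in cohort.sample_names:
        header.add_sample(name)
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in cohort.sites:
            rec = out.new_record(
                contig=site.contig,
                start=site.pos - 1,
                stop=site.pos,
                alleles=site.alleles if site.is_variant else (site.ref_allele,),
            )
            for i, name in enumerate(cohort.sample_names):
                gt = site.genotypes[i]
                rec.samples[name]["GT"] = gt if gt is not None else (None, None)
                rec.samples[name].phased = False
            out.write(rec)


FreqSpec = float | Callable[[np.random.Generator], float]


def generate_truth(
    n_samples: int,
    contig_length: int,
    n_variant_sites: int,
    allele_freq_sampler: FreqSpec = 0.5,
    seed: int = 0,
    contig: str = "chrSim",
    ref_allele: str = "A",
    alt_allele: str = "C",
) -> TruthCohort:
    """Generate a synthetic biallelic truth cohort.

    Positions are ``n_variant_sites`` distinct sorted coordinates on a single
    contig; each sample's genotype is two independent Bernoulli(f) allele
    draws, where ``f`` is either the fixed ``allele_freq_sampler`` float or a
    fresh draw from the given callable per site.  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_variant_sites > contig_length:
        raise ValueError("n_variant_sites must not exceed contig_length")
    if isinstance(allele_freq_sampler, (int, float)):
        f = float(allele_freq_sampler)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele frequency {f} outside [0,1]")
        freq_fn: Callable[[np.random.Generator], float] = lambda _rng: f
    elif callable(allele_freq_sampler):
        freq_fn = allele_freq_sampler
    else:
        raise ValueError(
            "allele_freq_sampler must be a frequency in [0,1] or a callable"
        )

    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(contig_length, size=n_variant_sites, replace=False) + 1
    )
    sites = []
    for pos in positions:
        f = freq_fn(rng)
        draws = rng.random((n_samples, 2)) < f
        genotypes = tuple((int(a), int(b)) for a, b in draws)
        sites.append(
            TruthSite(contig, int(pos), ref_allele, (alt_allele,), genotypes)
        )
    cohort = TruthCohort(
        [f"sample{i}" for i in range(n_samples)], {contig: contig_length}, sites
    )
    cohort.validate()
    return cohort


def explode_invariable(
    cohort: TruthCohort, ref_base: str = "A",
    reference: dict[str, Sequence[str]] | None = None,
) -> TruthCohort:
    """Fill every position of every contig with a site.

    Positions absent from the input become invariable sites: no ALT alleles,
    all genotypes homozygous reference.  The invariable reference base is the
    fixed ``ref_base`` (genotype-likelihood math is base-symmetric, so the
    choice is cosmetic but deterministic) unless a per-contig ``reference``
    sequence lookup is supplied.  Idempotent.
    """
    hom_ref = tuple((0, 0) for _ in cohort.sample_names)
    by_contig: dict[str, dict[int, TruthSite]] = {}
    for site in cohort.sites:
        by_contig.setdefault(site.contig, {})[site.pos] = site
    unknown = set(by_contig) - set(cohort.contig_lengths)
    if unknown:
        raise ValueError(f"sites on contigs without a length: {sorted(unknown)}")
    out_sites: list[TruthSite] = []
    for contig, length in cohort.contig_lengths.items():
        if length is None:
            raise ValueError(
                f"cannot explode contig {contig!r}: length unknown"
            )
        existing = by_contig.get(contig, {})
        seq = reference.get(contig) if reference else None
        for pos in range(1, length + 1):
            if pos in existing:
                out_sites.append(existing[pos])
            else:
                base = seq[pos - 1].upper() if seq is not None else ref_base
                out_sites.append(TruthSite(contig, pos, base, (), hom_ref))
    out = TruthCohort(cohort.sample_names, dict(cohort.contig_lengths), out_sites)
    out.validate()
    return out
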