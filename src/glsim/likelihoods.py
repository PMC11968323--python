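"""Genotype likelihoods and site annotations.

Two canonical GL models are implemented:

* McKenna (GATK lineage): read errors are independent.  For genotype
  {A1, A2} the per-read term is ``(1/2)P(b|A1) + (1/2)P(b|A2)`` with
  ``P(b|A) = 1 - e`` if ``b == A`` else ``e/3``, and reads multiply.
* Li (MAQ/SAMtools/BCFtools lineage): errors of reads reporting the same
  base are *not* independent.  Within each observed-base group, qualities
  (capped at the model's internal cap) are ranked in decreasing order and the
  rank-r quality is down-weighted to ``lambda**r * q`` before entering the
  same per-read product, so stacks of duplicate errors stop accumulating
  evidence geometrically instead of linearly.

Both return log10 likelihood vectors over the VCF-ordered diploid genotypes
of the site's allele set, max-rescaled so the best genotype is 0.  The
quality-to-probability conversion uses the *reported* (possibly binned)
quality — the discretization-bias channel this simulator exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reads import BaseObservation

# Error probabilities entering the GL models are clipped here so a quality-0
# read never produces log10(0) for a matching homozygote.
MAX_MODEL_ERROR = 0.75

NONREF_SYMBOLS = ("<NON_REF>", "<*>")

__all__ = [
    "GLVector",
    "LiModelConfig",
    "SiteAnnotation",
    "genotype_order",
    "gl_mckenna",
    "gl_li",
    "to_pl_gq",
    "annotate_site",
]


def genotype_order(n_alleles: int) -> list[tuple[int, int]]:
    """Diploid genotypes in VCF ordering: (j,k) at index k(k+1)/2 + j, j<=k."""
    return [(j, k) for k in range(n_alleles) for j in range(k + 1)]


@dataclass
class GLVector:
    """Per-sample log10 genotype likelihoods, max-rescaled to 0.

    ``alleles`` may include a trailing symbolic non-reference allele
    (``<NON_REF>``/``<*>``) that matches no read base.
    """

    values: np.ndarray
    alleles: tuple[str, ...]
    no_data: bool = False

    def __post_init__(self) -> None:
        g = len(self.alleles)
        if len(self.values) != g * (g + 1) // 2:
            raise ValueError("GL vector length does not match allele count")

    @property
    def genotypes(self) -> list[tuple[int, int]]:
        return genotype_order(len(self.alleles))

    def best_index(self) -> int:
        return int(np.argmax(self.values))


@dataclass
class LiModelConfig:
    """Dependent-error model constants.

    dependency_coefficient (lambda) in (0,1] geometrically down-weights
    ranked same-base qualities; at 1 the model reduces to independent errors
    up to the internal quality cap (default 37).
    """

    dependency_coefficient: float = 0.85
    quality_cap: int = 37

    def __post_init__(self) -> None:
        if not 0.0 < self.dependency_coefficient <= 1.0:
            raise ValueError("dependency coefficient must be in (0,1]")


def _per_read_errors(quals: np.ndarray) -> np.ndarray:
    e = np.power(10.0, -quals / 10.0)
    return np.minimum(e, MAX_MODEL_ERROR)


def _gl_from_quals(
    bases: list[str], quals: np.ndarray, alleles: tuple[str, ...]
) -> np.ndarray:
    """Shared likelihood kernel: independent per-read terms at given quals."""
    e = _per_read_errors(quals)
    # match[a, j] = P(read j base | allele a)
    match = np.empty((len(alleles), len(bases)))
    for ai, allele in enumerate(alleles):
        hit = np.fromiter((b == allele for b in bases), dtype=bool, count=len(bases))
        match[ai] = np.where(hit, 1.0 - e, e / 3.0)
    out = np.empty(len(alleles) * (len(alleles) + 1) // 2)
    for gi, (j, k) in enumerate(genotype_order(len(alleles))):
        out[gi] = np.sum(np.log10(0.5 * match[j] + 0.5 * match[k]))
    return out


def _finish(raw: np.ndarray, alleles: tuple[str, ...], no_data: bool) -> GLVector:
    return GLVector(values=raw - raw.max(), alleles=alleles, no_data=no_data)


def gl_mckenna(
    obs: list[BaseObservation], alleles: tuple[str, ...]
) -> GLVector:
    """Independent-error (GATK-style) genotype likelihoods."""
    g = len(alleles)
    if not obs:
        return _finish(np.zeros(g * (g + 1) // 2), alleles, no_data=True)
    quals = np.array([o.reported_quality for o in obs], dtype=float)
    raw = _gl_from_quals([o.base for o in obs], quals, alleles)
    return _finish(raw, alleles, no_data=False)


def gl_li(
    obs: list[BaseObservation],
    alleles: tuple[str, ...],
    cfg: LiModelConfig | None = None,
) -> GLVector:
    """Dependent-error (SAMtools/BCFtools-style) genotype likelihoods.

    Reads are grouped by observed base; within a group, qualities capped at
    ``cfg.quality_cap`` are sorted in decreasing order and the rank-r value is
    scaled by ``lambda**r``.  The adjusted qualities then enter the same
    independent kernel, making repeated identical base calls carry
    geometrically less weight than under the McKenna model.  A single read is
    unadjusted, and lambda = 1 reduces to the independent model up to capping.
    """
    if cfg is None:
        cfg = LiModelConfig()
    g = len(alleles)
    if not obs:
        return _finish(np.zeros(g * (g + 1) // 2), alleles, no_data=True)
    lam = cfg.dependency_coefficient
    bases = [o.base for o in obs]
    quals = np.minimum(
        np.array([o.reported_quality for o in obs], dtype=float), cfg.quality_cap
    )
    adjusted = np.empty_like(quals)
    for base in set(bases):
        idx = [j for j, b in enumerate(bases) if b == base]
        grp = np.sort(quals[idx])[::-1]
        weights = np.power(lam, np.arange(len(idx)))
        order = sorted(idx, key=lambda j: -quals[j])
        adjusted[order] = grp * weights
    raw = _gl_from_quals(bases, adjusted, alleles)
    return _finish(raw, alleles, no_data=False)


def to_pl_gq(gl: GLVector, gq_cap: int = 99) -> tuple[np.ndarray, int]:
    """Phred-scale the GL vector and derive genotype quality.

    PL = round(-10 * GL) (half-away-from-zero; best genotype 0); GQ is the
    gap between the smallest and second-smallest PL, capped at ``gq_cap``.
    A flat (single-genotype or no-data) vector has GQ 0.
    """
    pl = np.floor(-10.0 * gl.values + 0.5).astype(int)
    if len(pl) < 2:
        return pl, 0
    best, second = np.partition(pl, 1)[:2]
    return pl, int(min(second - best, gq_cap))


@dataclass
class SiteAnnotation:
    """Aggregate base-quality (QS) and mpileup I16 annotations for one site.

    ``qs`` holds per-allele fractions of the summed reported base qualities
    (REF first), or None when no read supports any listed allele.  ``i16`` is
    the 16-value mpileup layout: strand-stratified ref/non-ref read counts,
    then sums and squared sums of base qualities, mapping qualities, and tail
    distances for ref and non-ref reads.
    """

    qs: tuple[float, ...] | None
    i16: tuple[float, ...]


def annotate_site(
    all_obs: list[list[BaseObservation]], alleles: tuple[str, ...]
) -> SiteAnnotation:
    """Compute QS and I16 over all samples' read stacks at one site."""
    ref = alleles[0]
    qsum = {a: 0.0 for a in alleles}
    i16 = np.zeros(16)
    for stack in all_obs:
        for o in stack:
            if o.base in qsum:
                qsum[o.base] += o.reported_quality
            is_ref = o.base == ref
            if is_ref:
                i16[0 if o.strand == 0 else 1] += 1
                i16[4] += o.reported_quality
                i16[5] += o.reported_quality**2
                i16[8] += o.mapping_quality
                i16[9] += o.mapping_quality**2
                i16[12] += o.tail_distance
                i16[13] += o.tail_distance**2
            else:
                i16[2 if o.strand == 0 else 3] += 1
                i16[6] += o.reported_quality
                i16[7] += o.reported_quality**2
                i16[10] += o.mapping_quality
                i16[11] += o.mapping_quality**2
                i16[14] += o.tail_distance
                i16[15] += o.tail_distance**2
    total = sum(qsum.values())
    qs = (
        tuple(qsum[a] / total for a in alleles) if total > 0 else None
    )
    return SiteAnnotation(qs=qs, i16=tuple(float(x) for x in i16))
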