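"""End-to-end orchestration: truth sites -> read stacks -> GLs -> records.

Read simulation is separated from likelihood computation so that one seeded
read set can be re-scored under different GL models or allele-set policies
(plain VCF vs gVCF with a symbolic non-reference allele) and every output
dialect carries identical base/quality content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ErrorModelConfig
from .likelihoods import (
    GLVector,
    LiModelConfig,
    SiteAnnotation,
    annotate_site,
    gl_li,
    gl_mckenna,
    to_pl_gq,
)
from .reads import ReadSimConfig, SiteReadData, simulate_site
from .truth import BASES, TruthCohort, TruthSite

__all__ = ["SiteResult", "simulate_reads", "score_reads", "simulate_cohort"]


@dataclass
class SiteResult:
    """Everything known about one site after simulation and scoring."""

    site: TruthSite
    reads: SiteReadData
    alleles: tuple[str, ...]  # REF first; may end with a symbolic non-ref
    gls: list[GLVector]
    pls: list[np.ndarray]
    gqs: list[int]
    ads: list[tuple[int, ...]]  # per-sample read counts per allele
    annotation: SiteAnnotation

    @property
    def depths(self) -> list[int]:
        return self.reads.depths


def simulate_reads(
    cohort: TruthCohort,
    err_cfg: ErrorModelConfig,
    read_cfg: ReadSimConfig,
    seed: int | np.random.Generator,
) -> list[SiteReadData]:
    """Simulate read stacks for every site; deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [simulate_site(site, err_cfg, read_cfg, rng) for site in cohort.sites]


def _site_alleles(
    site: TruthSite, all_bases: bool, nonref_symbol: str | None
) -> tuple[str, ...]:
    if all_bases:
        alleles: tuple[str, ...] = (
            site.ref_allele,
            *(b for b in BASES if b != site.ref_allele),
        )
    else:
        alleles = site.alleles
    if nonref_symbol is not None:
        alleles = (*alleles, nonref_symbol)
    return alleles


def score_reads(
    cohort: TruthCohort,
    reads: list[SiteReadData],
    gl_model: str = "mckenna",
    li_cfg: LiModelConfig | None = None,
    all_bases: bool = False,
    nonref_symbol: str | None = None,
) -> list[SiteResult]:
    """Compute GL/PL/GQ/AD and site annotations for pre-simulated reads.

    ``gl_model`` is "li" (dependent errors, flag value 1) or "mckenna"
    (independent errors, flag value 2).  ``all_bases`` scores the full
    10-genotype vector over {A,C,G,T}; ``nonref_symbol`` appends a symbolic
    allele that matches no base (the gVCF non-reference aggregate).
    """
    if gl_model not in ("mckenna", "li"):
        raise ValueError(f"unknown GL model {gl_model!r}; use 'mckenna' or 'li'")
    results = []
    for site, site_reads in zip(cohort.sites, reads):
        alleles = _site_alleles(site, all_bases, nonref_symbol)
        gls, pls, gqs, ads = [], [], [], []
        for stack in site_reads.observations:
            if gl_model == "li":
                gl = gl_li(stack, alleles, li_cfg)
            else:
                gl = gl_mckenna(stack, alleles)
            pl, gq = to_pl_gq(gl)
            concrete = [a for a in alleles if a in BASES]
            counts = {a: 0 for a in concrete}
            other = 0
            for o in stack:
                if o.base in counts:
                    counts[o.base] += 1
                else:
                    other += 1
            ad = tuple(counts[a] for a in concrete)
            if nonref_symbol is not None:
                ad = (*ad, other)
            gls.append(gl)
            pls.append(pl)
            gqs.append(gq)
            ads.append(ad)
        annotation = annotate_site(site_reads.observations, alleles)
        results.append(
            SiteResult(site, site_reads, alleles, gls, pls, gqs, ads, annotation)
        )
    return results


def simulate_cohort(
    cohort: TruthCohort,
    err_cfg: ErrorModelConfig,
    read_cfg: ReadSimConfig,
    seed: int | np.random.Generator,
    gl_model: str = "mckenna",
    li_cfg: LiModelConfig | None = None,
    all_bases: bool = False,
    nonref_symbol: str | None = None,
) -> list[SiteResult]:
    """One-call convenience: simulate reads then score them."""
    reads = simulate_reads(cohort, err_cfg, read_cfg, seed)
    return score_reads(
        cohort, reads, gl_model=gl_model, li_cfg=li_cfg,
        all_bases=all_bases, nonref_symbol=nonref_symbol,
    )
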