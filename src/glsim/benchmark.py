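"""Genotype-calling benchmark: naive ML caller, GQ sweeps, error/call rates.

The naive caller picks the genotype with the highest likelihood, with no
allele-frequency prior.  For a GQ threshold t, a (site, sample) unit counts
as called when it has data and GQ >= t; call rate is called units over all
simulated units, and error rate is wrongly called genotypes over called
units (heterozygote identity is unordered).  Sweeping t traces the
call-rate/error-rate curve; the area under that curve summarizes a setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ErrorModelConfig
from .likelihoods import GLVector, LiModelConfig
from .pipeline import SiteResult, score_reads, simulate_reads
from .reads import ReadSimConfig
from .truth import TruthCohort, generate_truth

DEFAULT_GQ_THRESHOLDS = tuple(range(0, 100))
HIGHLIGHT_GQ = 20  # conventional minimum reporting threshold

__all__ = [
    "CallRecord",
    "naive_call",
    "collect_calls",
    "external_calls",
    "sweep_metrics",
    "curve_auc",
    "run_benchmark",
]


@dataclass(frozen=True)
class CallRecord:
    """One (site, sample) calling outcome against truth."""

    truth: tuple[int, int] | None
    call: tuple[int, int] | None  # unordered allele-index pair; None = no data
    gq: int
    tie: bool


def naive_call(gl: GLVector) -> tuple[tuple[int, int] | None, bool]:
    """Pick the maximum-likelihood genotype.

    Returns (genotype, tie_flag); genotype is None for a no-data/flat vector.
    A partial tie resolves to the first genotype in VCF order and sets the
    flag.
    """
    if gl.no_data or bool(np.all(gl.values == 0.0)):
        return None, False
    best = int(np.argmax(gl.values))
    tie = int(np.sum(gl.values == gl.values[best])) > 1
    return gl.genotypes[best], tie


def collect_calls(results: Iterable[SiteResult]) -> list[CallRecord]:
    """Run the naive caller over every (site, sample) unit."""
    records = []
    for res in results:
        for i, gt in enumerate(res.site.genotypes):
            call, tie = naive_call(res.gls[i])
            truth = tuple(sorted(gt)) if gt is not None else None
            call_s = tuple(sorted(call)) if call is not None else None
            records.append(CallRecord(truth, call_s, res.gqs[i], tie))
    return records


def external_calls(path: str, cohort: TruthCohort) -> list[CallRecord]:
    """Parse a downstream caller's VCF output into scorable call records.

    The hook for external genotype callers (e.g. the BCFtools multiallelic
    caller run on a BCF this package emitted): their algorithm is not
    implemented here, only their output is consumed.  Records are matched to
    the truth cohort by (contig, position); GQ defaults to 0 when the caller
    did not emit it.
    """
    import pysam

    truth_by_pos = {
        (s.contig, s.pos): s for s in cohort.sites
    }
    records = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if samples != cohort.sample_names:
            raise ValueError("sample names do not match the truth cohort")
        for rec in vf:
            site = truth_by_pos.get((rec.chrom, rec.pos))
            if site is None:
                continue
            # map the caller's allele strings back onto truth indices
            index_of = {a: i for i, a in enumerate(site.alleles)}
            called_alleles = (rec.ref, *(rec.alts or ()))
            for i, name in enumerate(samples):
                fmt = rec.samples[name]
                gt = fmt.get("GT")
                truth = site.genotypes[i]
                truth_s = tuple(sorted(truth)) if truth is not None else None
                if gt is None or any(a is None for a in gt):
                    records.append(CallRecord(truth_s, None, 0, False))
                    continue
                try:
                    call = tuple(
                        sorted(index_of[called_alleles[a]] for a in gt)
                    )
                except KeyError:
                    call = None  # caller introduced an allele truth lacks
                gq = fmt.get("GQ")
                records.append(
                    CallRecord(truth_s, call, int(gq or 0), False)
                )
    return records


def sweep_metrics(
    calls: Sequence[CallRecord],
    gq_thresholds: Sequence[int] = DEFAULT_GQ_THRESHOLDS,
    **stratifiers,
) -> pd.DataFrame:
    """Tabulate call rate and error rate at each GQ threshold.

    One row per threshold: n_total, n_calls, n_errors, call_rate
    (= n_calls / n_total), error_rate (= n_errors / n_calls; NaN with an
    ``undefined_error_rate`` flag when nothing is called).  Extra keyword
    stratifiers (depth, variance, gl_model, replicate, ...) are copied into
    every row.
    """
    n_total = len(calls)
    gqs = np.array([c.gq for c in calls])
    has_call = np.array([c.call is not None for c in calls])
    wrong = np.array(
        [c.call is not None and c.call != c.truth for c in calls]
    )
    rows = []
    for t in gq_thresholds:
        passing = has_call & (gqs >= t)
        n_calls = int(passing.sum())
        n_errors = int((wrong & passing).sum())
        rows.append(
            {
                **stratifiers,
                "threshold": t,
                "n_total": n_total,
                "n_calls": n_calls,
                "n_errors": n_errors,
                "call_rate": n_calls / n_total if n_total else 0.0,
                "error_rate": n_errors / n_calls if n_calls else np.nan,
                "undefined_error_rate": n_calls == 0,
            }
        )
    return pd.DataFrame(rows)


def curve_auc(df: pd.DataFrame) -> float:
    """Trapezoid area under the (call_rate, error_rate) curve.

    Points are sorted by call rate; undefined-error-rate points are dropped.
    """
    pts = df.loc[~df["undefined_error_rate"], ["call_rate", "error_rate"]]
    pts = pts.sort_values("call_rate")
    if len(pts) < 2:
        return float("nan")
    return float(
        np.trapezoid(pts["error_rate"].to_numpy(), pts["call_rate"].to_numpy())
    )


def run_benchmark(
    depths: Sequence[float] = (0.1, 0.5, 1, 2, 10, 20, 100),
    variances: Sequence[float] = (0.0, 1e-5),
    gl_models: Sequence[str] = ("li", "mckenna"),
    n_replicates: int = 1,
    n_samples: int = 2,
    n_sites: int = 1000,
    mean_error: float = 0.002,
    contig_length: int | None = None,
    allele_freq: float = 0.5,
    gq_thresholds: Sequence[int] = DEFAULT_GQ_THRESHOLDS,
    li_cfg: LiModelConfig | None = None,
    platform_bins=None,
    qs_cap: int = 60,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end grid benchmark: simulate, call, sweep, summarize.

    For each replicate one truth cohort is generated and shared across the
    whole depth/variance grid; both GL models score the *same* simulated
    reads within a grid cell.  Returns (metrics, auc): the per-threshold
    metrics table and one AUC row per (replicate, depth, variance, model)
    curve.
    """
    if contig_length is None:
        contig_length = 10 * n_sites
    ss = np.random.SeedSequence(seed)
    truth_seeds = ss.spawn(n_replicates)
    metrics_frames = []
    auc_rows = []
    for rep in range(n_replicates):
        cohort = generate_truth(
            n_samples=n_samples,
            contig_length=contig_length,
            n_variant_sites=n_sites,
            allele_freq_sampler=allele_freq,
            seed=truth_seeds[rep],
        )
        cell_seeds = truth_seeds[rep].spawn(len(depths) * len(variances))
        cell = 0
        for depth in depths:
            read_cfg = ReadSimConfig(mean_depth=float(depth))
            for variance in variances:
                err_cfg = ErrorModelConfig(
                    mean_error=mean_error,
                    beta_variance=variance,
                    qs_cap=qs_cap,
                    platform_bins=platform_bins,
                )
                rng = np.random.default_rng(cell_seeds[cell])
                cell += 1
                reads = simulate_reads(cohort, err_cfg, read_cfg, rng)
                for model in gl_models:
                    results = score_reads(
                        cohort, reads, gl_model=model, li_cfg=li_cfg
                    )
                    calls = collect_calls(results)
                    df = sweep_metrics(
                        calls,
                        gq_thresholds,
                        replicate=rep,
                        depth=depth,
                        variance=variance,
                        gl_model=model,
                    )
                    metrics_frames.append(df)
                    auc_rows.append(
                        {
                            "replicate": rep,
                            "depth": depth,
                            "variance": variance,
                            "gl_model": model,
                            "auc": curve_auc(df),
                        }
                    )
    metrics = pd.concat(metrics_frames, ignore_index=True)
    return metrics, pd.DataFrame(auc_rows)
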