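# Methods

## Simulation model

For each site and sample, read depth is `Poisson(μ)` with a single fixed
mean `μ` (`--depth`, default 20). Each read draws one of the two alleles of
the true diploid genotype with probability ½ — no allelic-bias parameter,
matching the assumption baked into both likelihood models. A true per-read
error probability `ε` corrupts the base to one of the three other bases
uniformly (so error terms appear as `ε/3` in the likelihoods).

`ε` is either exact (`v = 0`: every read carries the configured mean error
`e`, and the Beta sampler is never touched) or drawn from `Beta(α, β)` with
shapes set by the method of moments: `κ = e(1−e)/v − 1`, `α = eκ`,
`β = (1−e)κ`. This is feasible iff `0 < v < e(1−e)`; infeasible requests
raise rather than clamp. The benchmark settings are `e = 0.002` and
`v ∈ {0, 1e-5}` (giving `α ≈ 0.3972`, `β ≈ 198.2028`).

The reported quality is `round(−10·log₁₀ ε)` (half-away-from-zero, stated so
outputs are bit-reproducible), clamped to `[0, qs_cap]` with `qs_cap = 60`
by default to bound the transform for vanishingly small Beta draws.
Platform binning optionally maps the quality to a bin representative; the
built-in `novaseq` preset is the four-bin RTA3-style table
[0–2]→2, [3–14]→12, [15–30]→23, [31–cap]→37, fully overridable via
`--platform custom:<file>`. Representatives must lie inside their own bin so
binning is idempotent. Strand is a fair coin, tail distance uniform on
[1, 50], mapping quality a constant 60 (all configurable); these marginals
feed only the `I16` annotation.

The central design invariant: bases are corrupted with the **true** `ε`,
while the GL engine sees only the **reported** quality. With binning or
`v > 0`, the two diverge — that divergence is the quantity of interest, and
a test asserts it (reported qualities collapse onto bin representatives
while the realized error frequency tracks the Beta mean).

## Genotype likelihood models

Both models convert reported quality to `e = 10^(−q/10)` and evaluate, per
genotype `{A₁, A₂}`, `Σⱼ log₁₀(½P(bⱼ|A₁) + ½P(bⱼ|A₂))` with `P(b|A) = 1−e`
if `b = A` else `e/3`, max-rescaled so the best genotype is 0. `e` is
clipped at 0.75 inside the models so a quality-0 read never produces
`log₁₀(0)` for a matching homozygote.

The McKenna (independent-error, GATK lineage) model uses the per-read
qualities as-is. The Li (dependent-error, MAQ/SAMtools lineage) model first
caps qualities at an internal cap (default 37), groups reads by observed
base, sorts each group's qualities in decreasing order, and scales the
rank-r quality by `λʳ` (dependency coefficient `λ = 0.85` by default,
`--gl1-lambda`/`--gl1-qcap`). Stacked identical base calls therefore
accumulate evidence sub-linearly rather than linearly. Two model-independent
reductions anchor the implementation: a single read yields the same genotype
ranking as the independent model, and `λ = 1` reproduces it exactly within
the cap. `--gl 1` selects Li, `--gl 2` McKenna.

PL is `round(−10·GL)` (best 0); GQ is the gap between the two smallest PLs,
capped at 99. `QS` is the per-allele fraction of summed reported base
quality over all samples (alleles outside the site's allele set are
excluded; undefined and omitted when no read supports a listed allele).
`I16` follows the mpileup layout: strand-stratified ref/non-ref counts, then
sums and squared sums of base qualities, mapping qualities, and tail
distances, ref before non-ref.

By default GLs are reported over REF plus the site's true ALT alleles —
deterministic output and exact file round trips; `--all-bases` scores the
full 10-genotype vector over {A,C,G,T}. For invariable sites the default
vector is the single REF/REF genotype; the gVCF path carries the
informative REF-vs-aggregate comparison instead.

## Output formats

VCF/BCF writing goes through pysam/htslib (modes `v`, `z`, `b`, `u`).
Headers carry contigs, field definitions, and a deterministic command-line
provenance line (no timestamps), so identically seeded runs are
byte-identical — asserted by a test over VCF, gVCF, and pileup.

gVCF blocking: invariable sites merge into a block while every sample stays
in the same depth range (breakpoints from `--gvcf-dps`, default `1`, i.e.
zero vs nonzero coverage) *and* keeps its zero/nonzero coverage status; the
extra status key guarantees `./.` versus `0/0` is exactly recoverable from
the block. Variant sites always break blocks. A block record carries
`END`, per-sample `MIN_DP`, and representative GL/PL/GQ taken from that
sample's minimum-depth site; the aggregate allele is `<NON_REF>` (GATK
dialect) or `<*>` (BCFtools dialect), modeled in the likelihood as an
allele matching no read base (`P = e/3`). Depth-based blocking was chosen
over GQ-based blocking because depth is the simulator's native quantity.

Because a block stores summaries, per-site DP/GL inside a block are not
recoverable by construction; the normative round-trip property is that
expanding blocks reproduces the per-site stream of (contig, position, REF,
ALT set, per-sample GT) exactly, plus `MIN_DP` equals the minimum of the
per-site depths. Both are tested against the all-sites VCF of the same
simulation.

Pileup records explicit bases (uppercase forward / lowercase reverse — not
the `.`/`,` reference shorthand, since records carry concrete bases),
Phred+33 qualities clamped at 93, and `0 * *` for empty columns.

## Benchmark harness

The naive caller takes the argmax genotype of the GL vector; exact ties
resolve to the first genotype in VCF order and are flagged; a fully flat
vector (no data) is a no-call. Heterozygote identity is unordered. For a GQ
threshold `t`, call rate = called units / all simulated units and error
rate = wrong calls / called units; a zero-call cell reports error rate as
undefined (NaN with a flag), never 0. The sweep default is t = 0..99 step 1
with 20 as the conventional reporting threshold. Each
(depth × variance × model × replicate) curve is summarized by the trapezoid
area under (call rate, error rate), points sorted by call rate — the AUC
construction is a documented choice of this package.

Within a grid cell both GL models score the *same* simulated reads, so model
comparisons are paired. Per-replicate truth cohorts and per-cell read
simulations take their seeds from a spawned `SeedSequence` tree, making the
whole grid reproducible from one integer.

## Synthetic truth generator

`generate_truth` places biallelic A/C sites at distinct uniform positions
and draws each genotype as two Bernoulli(f) allele copies (default
f = 0.5; a callable gives per-site frequencies). It emulates the shape of a
cohort VCF — not linkage, a site-frequency spectrum, population structure,
or mutation-model detail. Benchmarks on it therefore measure the
calling/likelihood machinery under known error and depth settings; they do
not certify performance on real, structured variation. Tree-sequence VCFs
(REF=0/ALT=1) are supported through the default `{0→A, 1→C}` remap, and
invariable positions are filled deterministically with reference base `A`
(the GL math is base-symmetric, so the choice is cosmetic but
reproducible) unless a reference sequence is supplied.

## Problem sizes and numerical choices

The shipped tests run the trend benchmark at 2 samples × 10⁴ sites and
depths {1, 20}, the Monte-Carlo calibration checks at 10⁵–10⁶ draws (4-SE
tolerances on means, 10 % on the Beta variance), the GL-oracle comparison on
10³ random stacks at 1e-10 log₁₀ tolerance, and file round trips on a 10 kb
contig — sizes chosen so the full suite completes in under a minute while
keeping Monte-Carlo tolerances meaningful. Missing GTs are an error by
default (`--skip-missing` converts them to zero-depth samples). Depth-0
samples emit `./.` with DP 0 rather than being dropped.

## Known limitations

No read-length/fragment structure, paired ends, correlated or locally
varying depth, position-in-read or context-dependent error profiles, indel
errors or likelihoods, BAQ, or mapping-bias modeling. The external
multiallelic caller is supported only as a consumer of the emitted BCF, not
reimplemented. Multiallelic truth sites are accepted throughout, but the
benchmark grid as shipped is biallelic.
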