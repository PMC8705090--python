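# Methods

## isomiR model and classification

A mature-arm reference is a hairpin (precursor) sequence with up to two
arms located by 0-based half-open coordinates; arm sequences are stored as
RNA and validated as exact substrings of their precursor on every load.
A read is explained as

    read = precursor[p : p + L] + tail

where the templated block starts within `max_offset` (default 5 nt) of an
arm's 5′ start, its end lies within `max_offset` of the arm's 3′ end, and
the tail holds at most `max_tail` (default 3) non-templated nucleotides.
The templated block is *maximal*: it is extended as far as the precursor
agrees with the read, so the first tail base never re-matches the hairpin
(except when the match reaches the precursor's end). This is what makes
"non-templated" well defined — without maximality, a templated extension
and a tail of the same letter would be interchangeable. Internal
mismatches are not allowed; edited/SNP (polymorphic) variants are out of
scope. Read length is restricted to 16–28 nt, bracketing the 19–25 nt
range of mature miRs with room for trimmed and tailed variants.

End offsets are `offset5 = p − arm_start` (positive = 5′-trimmed) and
`offset3 = (p + L + |tail|) − arm_end` (positive = longer, tail included),
so read length always equals `arm length − offset5 + offset3`. The
category follows from the fields: a non-empty tail is `nontemplate`
regardless of offsets; otherwise zero/zero is `refseq` and the offset
pattern selects `iso5`, `iso3`, or `iso5_3`. Canonical names are the
parent arm name unadorned (refseq), `{parent}_t_{o5}_{o3}`, or
`{parent}_nont_{o5}_{o3}_{tail}`, with explicit `+`/`-` signs and a bare
`0`; `parse_name` inverts `name_call` exactly (property-tested over the
full field grid).

When several (arm, start) explanations fit, the winner is chosen by:
longest templated match, then smallest `|offset5| + |offset3|`, then
shortest tail, then lexicographically smallest parent name, then the
(offset5, offset3, tail) tuple as a final component that makes the order
total (two exact interpretations of the same read on one arm can tie on
all four leading keys when the arm has local repeat structure). Reads are
counted once, never fractionally. The walking implementation is checked
against a brute-force enumeration oracle on randomized instances.

The seed is defined as nucleotides 2–8 (1-based) of the mature sequence;
a variant's seed is shifted exactly when `offset5 != 0`. Type-distribution
summaries count *distinct features* per category, not reads, because the
question they answer is about the variant repertoire.

## Differential expression

Counts are normalized with median-of-ratios size factors (geometric-mean
pseudo-reference over features positive in all samples, factors scaled to
geometric mean 1). For a two-group contrast, each feature with total
count ≥ 10 in the contrast samples is tested; lower-count features are
flagged `filtered` and excluded rather than tested.

The noise model is NB with `var = μ + α μ²`. Per feature, α is estimated
by a bias-corrected method of moments within each group
(`α̂ = (v − m̂)/(m̂² − v/n)`, undefined estimates dropped), df-weighted
across the two groups, and then squeezed toward a robust across-feature
mean (per-feature estimates clipped at their 99th percentile before
averaging) with a fixed prior weight of 16 residual degrees of freedom:

    α_moderated = (df·α̂ + 16·ᾱ) / (df + 16),   floored at 1e-8.

The moderation is the package's calibration device: with ~6 samples per
group a purely per-feature variance estimate makes the Wald statistic
t-like with ~10 df, which inflates nominal 5% type-I error to ~8% under a
normal reference. Borrowing ~16 df of strength across features (the same
reasoning behind dispersion shrinkage in the standard NB DE tools)
restores calibration; the prior weight was fixed from that degrees-of-
freedom argument. Measured null type-I error at n = 6/group is ≈ 0.05.

The effect estimate is `log2fc = log2(m_test / m_ref)` of normalized group
means, with a 0.5 pseudo-count added to both means only when one of them
is zero — this keeps fold changes finite while preserving exact scale
invariance (rescaling any single library leaves every log2fc of
positive-mean features unchanged). The standard error comes from the
delta method, `Var(m̂_g) = μ Σ 1/s_j / n² + α μ²/n` per group, and the
Wald statistic `log2fc/se` is referred to the standard normal, two-sided.
Benjamini–Hochberg adjusted p-values are reported for convenience, but DE
calling uses raw `p < α` (default 0.05) together with `|log2fc| ≥ lfc_min`
(0 for small-RNA features, 1 for genes). Samples are treated as
independent groups; within-subject pairing across time points is not
modeled.

## Pairing and circuit assembly

Target predictions carry 0–100 confidence scores and are kept at
score ≥ 80 (inclusive). A DE regulator uses its own prediction rows when
it has any; a 3′-only variant (`offset5 == 0`) whose seed equals its
parent's inherits the parent's rows otherwise; 5′-shifted variants never
inherit, since their seed — and hence target spectrum — differs. Each
(regulator, gene) with both sides DE forms one pair, classed *negative*
when the fold-change signs oppose and *positive* otherwise (a zero product
cannot normally occur because DE calling excludes zero fold changes; a
defensive rule classes it positive and logs a warning). "Correlation"
here is fold-change sign opposition, not a correlation coefficient.

Multi-targeted transcripts are genes reached by ≥ 2 distinct regulators
among negative pairs, counting a reference miR and its variants
separately. TF regulations are recorded at miR-family level (arm label
stripped) and, because all variants of an arm are transcribed from the
same gene, expand to every DE member of the family; only
literature-curated records are used by default. The circuit graph has
typed nodes (TF / mir_family / gene) and edges (tf_regulates_mir /
mir_targets_gene); variant features collapse into family nodes labeled by
parent arm with their multiplicity recorded, and only negative pairs are
wired (positive pairs are reported but carry no repression reading). Every
edge maps back to an input relation.

## Synthetic data

The generator emulates the study design the pipeline expects: two or more
groups (reference first) with 6 samples each, random hairpins (arm
lengths 19–25 nt, 4–8 nt flanks) where the base directly 3′ of every arm
is drawn from {G, C} so the default A/U tails are never accidentally
templated. Per arm, isoform composition follows a fixed profile —
40% reference, 40% templated end-variants, 20% adenine-heavy tails
(A/2A/3A/U/AU) — and every candidate isoform is verified by classifying
its realized sequence; ambiguous isoforms (for example a tail that
re-matches the hairpin after a 3′ trim) are dropped and the profile
renormalized, which guarantees the truth table is an exact oracle for
quantification. Copy numbers are NB(mean, α) with per-arm mean 300 split
across isoforms, dispersion 0.1, and planted log2 fold changes of ±2.5 on
half the arms (balanced up/down); with dispersion 0 counts are
`round(mean)` and quantification must reproduce the truth table exactly.
Planted effect sizes are strong by design: the recovery criterion asks
whether true anti-correlated pairs *survive the pipeline*, not whether
the test is powered at marginal effects (calibration is tested
separately). Gene counts (mean 500) carry planted fold changes opposite
in sign to their planted regulator's, target rows at score ≥ 85 for
planted pairs, sub-threshold decoys (score < 80), high-score rows onto
null genes, and a literature-curated TF motif
(regulator↑ → TF_a↓, TF_a → family_b, family_b↓ → TF_b↑) for end-to-end
circuit checks.

What the generator does not emulate: sequencing errors and quality-score
variation, adapter remnants, genomic multi-mapping outside the reference,
within-woman pairing of samples, and realistic across-feature dispersion
trends. Passing the synthetic benchmarks therefore demonstrates
correctness of the classification/quantification/pairing logic and
calibration of the test under the stated NB model — not robustness to
alignment artifacts or biological confounding in real libraries.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere (dominant genomics
  convention); DNA input is converted to RNA on load.
- Simulation panel sizes in the test suite (e.g. 20 replicates × 100
  planted + 400 null features for fold-change recovery, 2000 features for
  null calibration, 10,000 random instances for oracle agreement) were
  chosen to make the Monte-Carlo error small relative to the asserted
  bounds while keeping the default test run fast.
- Recovery of a planted log2fc of 2 is summarised per replicate by the
  panel-mean estimate: a single feature's estimate at n = 6/group and
  dispersion 0.1 has a sampling sd of ≈ 0.27 — no estimator can pin a
  single feature within ±0.3 with 95% confidence at that design — while
  the panel mean concentrates as 1/√(panel size).
- Simulated DE panels plant effects in both directions over a null
  majority; one-directional planting would bias median-of-ratios
  normalization itself (composition bias), which is a well-known property
  of ratio-based normalizers rather than of the estimator under test.
- Deterministic outputs throughout: mandatory seeds in the generator,
  lexicographically sorted rows in every written table, and a total
  tie-break order in the classifier; re-running the CLI pipeline on
  unchanged inputs reproduces byte-identical TSVs.

## Known limitations

- The NB Wald surrogate is not numerically equivalent to DESeq2 (no
  trended dispersion prior, no LFC shrinkage, no outlier replacement);
  it asserts the same model family and calibrated statistical behavior.
- Raw p-values drive DE calling (with BH values reported), so feature-set
  sizes scale with the number of features tested.
- Fractional handling of genuinely multi-mapping reads is intentionally
  not implemented; the deterministic tie-break assigns each read once.
- TF-regulation expansion assumes all family variants share promoters;
  variant-specific transcriptional control is not representable.
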