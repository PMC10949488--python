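# Methods

## The scoring procedure

Every contig is scored by summing rule contributions. A *subrule* is a
predicate over the merged feature table (comparisons and and/or
combinations over named features) paired with a signed contribution:
±0.5 for low-confidence evidence, ±1 for confident evidence, and −3 for
a highly confident non-viral signal. Any comparison that touches an
absent feature (the tool did not report that contig) evaluates false, so
missing output can never satisfy a condition; only the explicit `absent`
operator matches missingness. The condition language deliberately has no
NOT operator — negation is written as `== false` or `absent` clauses —
because a NOT over the "absent is false" semantics would turn missing
data into vacuous truths.

Single-tool rules (`vs2`, `vb`, `vs`, `dvf`) combine their subrules with
`max_positive`: one tool contributes its single best confidence level
and cannot stack with itself. The tuning rules (`tna`, `tnv`) combine
with `sum`: independent pieces of cross-tool evidence accumulate, which
is what lets tuning removal drive a confidently non-viral contig to a
strongly negative score (its three subrules can reach −4.5 together)
while tuning addition alone can push a well-supported virus past the
threshold (up to +2.5). The viral threshold is **inclusive**: score ≥ 1
is viral.

### Default subrule set

The shipped cutoffs follow the tool developers' published
recommendations and are reconstructions — users with their own validated
cutoffs should override them via the YAML config (`--rules`):

| rule | condition | score |
|---|---|---|
| vs2 | VirSorter2 score ≥ 0.9 | +1 |
| vs2 | 0.5 ≤ score < 0.9 | +0.5 |
| vs2 | hallmark ≥ 1 and score ≥ 0.5 | +1 |
| vb | VIBRANT quality high/medium | +1 |
| vb | quality low | +0.5 |
| vs | VirSorter category 1–2 | +1 |
| vs | category 3 | +0.5 |
| dvf | DeepVirFinder score ≥ 0.9, p < 0.05 | +1 |
| dvf | 0.7 ≤ score < 0.9, p < 0.05 | +0.5 |
| tna | CheckV quality complete/high/medium or completeness ≥ 50 | +1 |
| tna | Kaiju superkingdom = Viruses | +0.5 |
| tna | VirSorter2 hallmark ≥ 2 | +1 |
| tnv | Kaiju classified non-viral and CheckV viral genes = 0 | −3 |
| tnv | CheckV host genes ≥ 2 and viral genes ≤ 1 | −1 |
| tnv | no VirSorter2/VIBRANT/VirSorter signal at all | −0.5 |

VirSorter prophage categories 4–6 are disabled by default because the
benchmark's positive class excludes proviruses. The tnv host-gene
condition is stated in the config as
`host_genes ≥ 2 and viral_genes ≤ 1`, which is the exact reduction of
"host genes at least twice max(viral genes, 1)" under the viral-genes ≤ 1
constraint. Whether a real pipeline caps a single tool at its best
subrule or sums within a tool is an open design point; `max_positive`
was chosen so that one tool cannot out-vote the rest by matching several
of its own subrules, and it is switchable per rule in the config.

Disabling `include_low_confidence` removes every ±0.5 subrule before
evaluation; scores can then only change by multiples of 0.5. This
supports auditing the common assumption that several low-confidence
calls add up to a confident one.

## Parsing and merging

Each dialect parser is pinned to the column layout of the tool's
standard output file; unknown extra columns are ignored with a warning
(tools add columns across versions), missing required columns are hard
errors naming the column, and duplicate contig ids within one file are
rejected. Kaiju's file has no header and one is tolerated if present.

Contig ids are normalized at parse time with a configurable regex list
(default strips `||…` suffixes, `-circular`, `_fragment_N`), since
several tools decorate contig names and cross-tool joins fail otherwise.
How any particular published pipeline reconciled ids is generally
undocumented; the default list covers the decorations these tool
versions are known to emit, and the `score` command hard-fails when the
join across tools is empty (the signature of a normalization failure).

Merging takes the outer union of contig ids. *Absent is not zero*: a
contig CheckV never saw has `cv_viral_genes = NaN`, not 0, and the two
are never conflated. Exceptions with a meaningful default: VIBRANT
quality (`none` — VIBRANT only lists contigs it considers phage, so
absence from its list *is* the negative call) and Kaiju classification
status (`False`). `kj_is_viral` is derived as: first lineage token
equals "Viruses" case-insensitively; unclassified contigs leave it
undefined. Sequence lengths come from the FASTA when given, else from
any tool that reports them, FASTA winning conflicts with a warning.

## Mock metagenomes

The generator samples contigs with replacement from per-class pools at
the default composition 68% bacteria, 10% archaea, 10% virus, 5%
plasmid, 5% protist, 2% fungi — the mix reported for cellular-enriched
aquatic metagenomes — with 8,000 contigs per replicate and five
replicates (the point where between-replicate variability plateaus).
Class counts are apportioned by largest remainder, so the target
fractions are hit exactly up to rounding (at n=8,000 the default mix is
exact: 5440/800/800/400/400/160); a multinomial mode is available when
sampling variability in the composition itself is wanted.

Pool sequences are trimmed to strictly below 2,100 kb (the
DeepVirFinder input cap; the largest known phage genome, ~735 kb, is far
below it, so trimming is not expected to affect biology) and filtered to
strictly above 3 kb (tool accuracy degrades below 3 kb). Trimming keeps
the sequence prefix; whether an upstream pipeline would trim from the
start, end, or split is unspecified, and the prefix choice is arbitrary
but deterministic. A fragmenter cuts one uniform 3–5 kb piece per parent
(uniform start; length capped at the parent) to emulate short-contig
assemblies; fragments-per-parent is 1 because nothing more is implied by
the use case and more fragments would correlate replicates.

Bundled pools are uniform-random ACGT sequences (configurable GC,
default lengths 3.2–8 kb, 50 per class). They carry **no biological
signal**; they exist so the scoring/benchmarking stack runs without
downloads. Real per-class FASTA pools drop in via `--pool class=path`.

## Simulated tool outputs

The simulator fakes tool *output files*, not biology. Per tool, each
contig is dropped with probability `dropout`; otherwise a virus gets a
positive signal with probability `sensitivity` and a non-virus with
`1 − specificity`; a positive is demoted to the low-confidence tier with
probability `low_confidence_rate`. Feature values are then drawn
uniformly from the region satisfying the corresponding default subrule
(e.g., a confident VirSorter2 positive draws score ~ U[0.9, 1.0] and
2–10 hallmark genes), negatives from the region satisfying none. Draw
ranges are kept clear of tier boundaries after output rounding (e.g.,
negative CheckV completeness is drawn below 49.8 so one-decimal rounding
cannot reach the ≥ 50 cutoff). CheckV/Kaiju negatives look distinctly
cellular (host genes ≥ 2, zero viral genes, cellular lineage), which is
the pattern tuning removal keys on. For VIBRANT and VirSorter —
whose real outputs only list phage calls — negatives and dropouts are
both absent rows; their `dropout` parameter is therefore only
distinguishable from lost sensitivity in expectation, not per contig.

Tools err independently by default; `shared_detectability` draws one
latent uniform per contig used by every tool's positive-signal
comparison, producing strongly correlated hits (the "easy virus" effect)
without changing any marginal rate.

Closed forms used in tests: a confident-only single-tool ruleset has
expected recall `sensitivity × (1 − dropout)`; with perfect tools every
ruleset containing a confident positive rule attains MCC = 1 end to end.
Passing these shows the plumbing (dialects → parsing → merging → scoring
→ metrics) is correct and the error-rate parameters propagate as
specified. It does **not** show the default cutoffs are optimal for real
data: the simulator plants values inside the very regions the subrules
test, so benchmark rankings on simulated bundles reflect the configured
error profiles, never the intrinsic quality of real tools.

## Metrics and grouping

Precision, recall, and MCC are computed from exact confusion counts.
Zero-denominator conventions: precision with no positive calls is 0, and
MCC with any zero factor in its denominator is 0 — the standard choice
that keeps degenerate rulesets (e.g., tuning removal alone, which can
never reach +1) finite and rankable. A replicate with zero true viruses
is flagged degenerate and excluded from grouping.

"High" groups per metric are found by ranking rulesets on the unweighted
mean across replicates and testing each against the top ruleset with a
paired one-sided Wilcoxon signed-rank ("is this ruleset lower?"),
Benjamini–Hochberg adjustment across rulesets, alpha 0.05. The top
ruleset is always in its own group; ties with all-zero paired
differences are treated as p = 1. Note the Wilcoxon floor: with five
replicates the smallest attainable one-sided p is 1/32 ≈ 0.031, and
after BH adjustment few comparisons clear alpha, so grouping at the
default replicate count is intentionally permissive; a paired t-test is
selectable (`--test ttest`) when replicates are few and
normality is palatable. With a single replicate the grouping degrades to
rank only, with a warning.

Ruleset overlap is Jaccard similarity of viral-call sets; two rulesets
that both call nothing viral are defined to overlap perfectly (1.0),
logged when triggered. The summary statistics (fraction of pairs above
0.5; count of rulesets ≥ 0.9 similar to another) follow the common
reporting scheme for such matrices.

## Problem sizes in the shipped tests

The test suite exercises the stack at 80–2,000 contigs and 1–4
replicates, and the composition check at the full n = 8,000; these sizes
put every code path and every statistical check (binomial 99% CIs,
chi-squared goodness of fit at alpha 0.001 over 50 replicates) on firm
ground while keeping the suite fast. Parameter-recovery tolerances are
the binomial intervals themselves — not tuned bands.

## Known limitations

- The default cutoffs are reconstructions of developer recommendations,
  not a validated transcription of any published pipeline's exact
  values; treat them as a starting point and override per study.
- Simulated fixtures satisfy the *default* subrule regions; a custom
  config with tighter thresholds needs regenerated fixtures.
- The simulators model tool behavior at the call level only — no gene
  content, ORF calling, or sequence-level signal; conclusions about real
  tools require real tool runs.
- Proviruses are out of scope: the positive class is free viral
  sequences, and VirSorter's prophage categories are off by default.
- The statistical grouping's power at five replicates is limited by the
  Wilcoxon floor (see above); this is a property of the design, not a
  bug.
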