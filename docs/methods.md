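# Methods

`tadmil` predicts which somatic non-coding structural variants (SVs) are
pathogenic through regulatory-domain disruption. The model rests on one
biological premise: genes and regulatory elements interact mostly within a
topologically associating domain (TAD) or an intra-TAD CTCF loop, so an SV
whose breakpoints cross a domain boundary rewires which enhancers, super
enhancers and eQTLs a gene can contact. Pathogenicity is learned, not
asserted: pairs of (SV, gene) are labeled by patient-matched expression
outliers and classified from the regulatory elements the gene gained or
lost.

## Coordinate and overlap conventions

All internal coordinates are 0-based, half-open (BED native); VCF input
(1-based) is converted on read. "Overlap" always means at least one shared
basepair between half-open intervals. Chromosome names are compared after
stripping an optional `chr` prefix. These conventions are global: every
overlap decision in the pipeline (rewiring, feature encoding, mutation
filters) uses the same 1 bp rule.

## Derivative-domain rewiring

Only SVs whose breakpoints both lie inside domains and whose span (or
junction, for translocations) crosses at least one boundary are considered.
Per SV type:

- **Deletion** `[s, e)`: the domains flanking the deletion fuse. Genes on one
  side gain the elements on the other side; genes and elements overlapped by
  the deleted span are not counted at all, so deletions produce only gains.
- **Tandem duplication**: the copy is inserted immediately 3' of the original
  span (the dominant somatic configuration; the insertion site is otherwise
  unobservable from a single junction). The duplicated copy re-inserts the
  disrupted boundary, creating a new domain that joins the duplicated tail of
  the right endpoint domain with the duplicated head of the left endpoint
  domain; genes and elements overlapped by the duplication on opposite sides
  of the boundary meet there. Pairs that already shared a domain are not
  counted as gains.
- **Inversion** `[s, e)`: domain intervals stay fixed while the inverted
  sequence is reflected in place (`p -> s + e - 1 - p`). Membership of gene
  and element fragments in the two endpoint domains is re-evaluated after
  reflection; a gene gains elements it newly shares an endpoint domain with
  and loses those it no longer shares one with.
- **Translocation**: each breakpoint orientation states which side of its
  domain is retained (`+` = 5' side). The two retained segments join into one
  derivative domain; retained genes gain the other segment's elements and
  lose the elements of their own domain's lost segment, unless both still
  meet in a domain the translocation leaves untouched.

SVs spanning more than two boundaries are modeled through their endpoint
domains only; interior domains are ignored. This matches the per-basepair
derivative-genome enumerator used as the test oracle everywhere except at
degenerate breakpoints placed exactly on a boundary coordinate, which the
generator never produces.

Pairs are then filtered: a gene carrying any coding disruption in that
patient — a moderate/high-impact SNV in the gene body, a copy number below
1.7 or above 2.3, or overlap by any SV span — is excluded, except that a
duplication or inversion may overlap the very gene it pairs with (the
disruption there is the point, not a confounder). For translocations the
"span" is the two breakpoint loci.

## Instance features

Each gained or lost element becomes a fixed-length instance vector:
gain/loss indicators; binary >= 1 bp overlap with four histone marks, eight
chromHMM states (the legacy nine-state set with the enhancer state is
available via `chromhmm_state_set="svmil1"`), DNase, RNA Pol II, CTCF, TFBS
and CpG islands; peak-intensity strengths for the marks that carry signal;
a one-hot of the element kind; and the total number of elements the SV
disrupts (`instance_count`). eQTL records are filtered at p <= 0.05
(configurable down to genome-wide 5e-8), and eQTL/histone/TFBS tracks are
binned on a 1 kb grid with max-signal aggregation (max is robust to peak
fragmentation; the aggregation rule is ours, the bin width is not).
Missing tissue tracks can be substituted from a configured fallback
epigenome (each substitution is logged). Features are min-max normalized to
[0, 1] using training-fold statistics only; apply-set values are clipped. A variance filter
(`log(variance) < -10`) is available to prune uninformative features; the
default 29-feature schema is already the post-selection set.

## Labels and class balance

A pair is positive when the patient's expression of the gene is an outlier
against a reference panel of patients with no disruption of that gene (no
coding SNV/CNV/SV and no non-coding SV pairing): `z > 1.5` or `z < -1.5`,
strict, with the sample (n-1) standard deviation. Genes need at least 5
reference patients (below that, z is unstable) and a non-zero reference sd.
Negatives are subsampled per SV type to the number of positives; when
negatives are already the minority nothing is upsampled.

## MILES embedding and classification

A bag's embedding coordinate against reference instance `j` is the L1
distance between the bag's mean instance vector and `j` ("absolute
distance" read literally as summed per-feature absolute differences; L2 is
available). Reference instances are all instances of the training bags. A
random forest (100 trees, sqrt features per split, fixed seed) is trained on
the embedded bags, one model per SV type; bags are capped at 700 per type by
class-preserving subsampling before CV.

Evaluation is leave-one-patient-out: all bags of one patient form the test
fold, and both the normalization statistics and the embedding reference are
rebuilt from the training patients in every fold, so nothing from the
held-out patient leaks into the model. Each fold also scores the held-out
patient's full labeled bag set (not only the class-balanced subset): AUC is
reported on the balanced predictions, while the operating point — the
threshold maximizing recall subject to precision >= 0.5, ties resolved to
higher precision then lower threshold — is selected on the full pooled
predictions. On balanced predictions alone the precision floor equals the
base rate and the threshold degenerates to the minimum score; scoring every
pair of a new patient is also the clinical use the CV emulates.

## Downstream statistics

- **Instance enrichment**: the 100 reference instances with the highest
  forest importance are compared per feature against 100 instances drawn from
  bags predicted non-pathogenic (classifier probability < 0.5 — the
  recall-optimized calling threshold can sit at the minimum score and leave
  no negative calls), using a two-sample t-test and a standardized mean
  difference capped at ±10, Bonferroni-corrected over the tested features
  (times the number of cohorts when several are analyzed). `instance_count`
  is reported descriptively but not tested: it is constant within a bag, so
  an instance-level t-test on it is pseudo-replication, and top-importance
  sets systematically over-represent SVs that contribute many reference
  columns. More broadly, importance-selected instance sets are only
  calibrated against a feature-homogeneous background: with heterogeneous
  instances the selection correlates with features regardless of labels, so
  the package's null checks use signal-free cohorts.
- **Driver potential**: per candidate gene, the cohort count of
  moderate/high-impact coding SNVs is compared against 10,000 random gene
  sets of the same size drawn from the (catalog-filtered) universe. The
  descriptive statistic is `(count - mean(set means)) / sd(set means)`; the
  default p-value is the empirical tail probability of the count against the
  individual gene counts pooled from the sampled sets, Bonferroni-corrected
  across candidates. The classical one-sample t-test of the set-mean
  distribution against a single gene's count (`mode="set_mean_t"`) is
  retained but is strongly anti-conservative: the standard error of 10,000
  set means is near zero, so any gene with one SNV over a sparse null is
  declared significant.
- **Regulatory swaps**: per swap, the signed AUC differences to the original
  run are summed across SV types (signed rather than absolute, so direction
  is meaningful), standardized over all swaps of the tissue (mean 0, sd 1 by
  construction), and quantized at |z| = 1 and 2.

## Synthetic data generator

The generator emulates the study conditions without any external data: 4
chromosomes x 2 Mb tiled by 20 abutting 100-kb domains; 25% of domains are
"active", allocated in adjacent pairs, and are three-fold denser in genes
and elements (enhancer clusters and super-enhancer regions are gene- and
element-rich); ~90% of active enhancers/super-enhancers carry high-signal
h3k27ac and DNase peaks — these marked elements are the pathogenic
signature. A 40-patient cohort receives 2 SVs per type per patient; a
planted 30% of SVs cross active-active boundaries, the rest cross
inactive-inactive boundaries. Every gene pairing with a planted SV and
gaining a marked element is shifted up by 4 noise-sd units of expression
(down when it only loses marked elements); everything else is
Normal(baseline, 1). Sparse random SNVs (3/patient) and CNV events
(2/patient) exercise the coding filters. The truth table is derived from the
pairs the rewiring stage itself produces, so it is a subset of them by
construction.

What the generator does not emulate: breakpoint hotspots and SV size
distributions, nested/complex SVs, count-based expression noise (values are
continuous, as the pipeline consumes normalized expression), correlated
epigenomic tracks, genes spanning domain boundaries as a common case, and
domain gaps (domains abut). Passing tests therefore demonstrate the
pipeline's internal correctness and its ability to recover a planted
regulatory signal under realistic label noise — not performance on real
tumor genomes.

Because the positive-label rule keeps ~13.4% of background pairs as
expression-outlier noise (2 x P(Z > 1.5); slightly more in practice since
reference-panel standard deviations are estimated from ~20 patients, giving
t-like tails), per-SV-type AUC under these conditions sits around 0.90-0.96
with a seed-to-seed spread of ~0.015; the recovery checks pool
leave-one-patient-out predictions over two replicate cohorts to estimate it
stably. Null AUCs from pooled cross-validation are expected slightly below
0.5: with shuffled labels on a small cohort, each fold's training class
ratio anti-correlates with the held-out labels, the usual pessimistic bias
of pooled CV under the null.

## Problem sizes and determinism

The test suite and the acceptance script use: two 40-patient planted
cohorts (~320 SVs, ~2,500 pairs each) for recovery; a 24-patient signal-free
cohort for null calibration (10-20 label shufflings); 200+ random toy
genomes (<= 10 kb) for the rewiring oracle; 1,000-draw nulls for the driver
test. All randomness flows through seeded `numpy.random.default_rng`
generators; pairs, labels and CV predictions are written in a fixed sort
order, so identical configurations and seeds reproduce outputs byte for
byte.

## Known limitations

- Breakpoints placed exactly on a boundary coordinate have undefined
  derivative geometry (treated as interior of the right-hand domain).
- The duplication model assumes a tandem copy; dispersed duplications are
  modeled as if tandem.
- Reciprocal translocation products are not modeled; only the derivative
  joining the two retained segments generates pairs.
- The MILES mean-instance embedding dilutes single discriminative instances
  in large bags.
- The enrichment statistic inherits the selection bias of importance-ranked
  instance sets discussed above.
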