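# tadmil

**Multiple-instance learning for non-coding structural variants that disrupt
regulatory domains.**

Most somatic structural variants (SVs) in tumor genomes never touch an exon,
yet some of them are drivers: by breaking the boundary of a topologically
associating domain (TAD) or an intra-TAD CTCF loop, an SV can put a gene in
contact with enhancers it was insulated from (enhancer hijacking) or strip
away the elements that sustained its expression. `tadmil` identifies the
genes plausibly disrupted this way and classifies each (SV, gene) pair as
pathogenic or not, for cohorts with matched whole-genome and expression
data. It is aimed at computational cancer-genomics groups prioritizing
non-coding SVs in WGS cohorts.

## The model

1. **Derivative-domain rewiring.** For every SV whose breakpoints start and
   end inside domains and cross at least one boundary, the derivative
   domains are reconstructed per SV type (fusion for deletions, a new domain
   between the original and re-inserted boundary for tandem duplications,
   in-place reflection for inversions, an orientation-aware join of retained
   segments for translocations). Genes that gain or lose at least one
   regulatory element — an eQTL, enhancer or super enhancer, with >= 1 bp
   overlap deciding membership — form SV–gene pairs. Genes carrying coding
   mutations (moderate/high-impact SNV, copy number outside [1.7, 2.3], or
   any SV overlapping the gene body) are excluded, except the pairing
   duplication/inversion itself.

2. **MIL formulation.** Each pair is a *bag*; each gained/lost element is an
   *instance* described by a 29-feature vector (gain/loss, histone marks,
   chromHMM states, TF-binding profiles, CpG, peak strengths, element kind,
   instance count), min–max normalized to [0, 1]. Bags are labeled from
   patient-matched expression: positive iff the z-score against all patients
   without any disruption of the gene satisfies |z| > 1.5.

3. **MILES embedding + random forest.** Bags map into a bag-to-instance
   similarity space — entry (i, j) is the L1 distance between bag i's mean
   instance and training instance j — and a per-SV-type random forest is
   trained on it. Performance is estimated by leave-one-patient-out CV with
   fold-local normalization and embedding references (no leakage), and the
   operating point maximizes recall at precision >= 0.5 on the pooled
   predictions.

4. **Downstream statistics**: feature enrichment of the most important
   instances, a driver-potential permutation test against random gene sets,
   and z-scored AUC differences under regulatory-track swaps between
   tissues.

No external or controlled-access data is required: `tadmil.simulate`
generates complete synthetic genomes and cohorts with planted pathogenic
structure, and every claim in the test suite is made against those or
against brute-force oracles.

## Worked example

```bash
python examples/02_simulate_and_classify.py
```

```
64 SVs -> 210 SV-gene pairs, 123 planted pathogenic pairs
DEL: LOPO AUC=0.946 operating_point=0.056 planted-truth recall=1.00
DUP: LOPO AUC=0.921 operating_point=0.015 planted-truth recall=1.00
```

A 16-patient cohort with two deletions and two duplications per patient
yields 210 SV–gene pairs, 123 of them planted as pathogenic (expression
shifted by 4 sd in the carrier). The leave-one-patient-out AUC in the low
0.9s reflects the irreducible ~13% of background pairs that are expression
outliers by chance; the recall of 1.00 means every planted pair is called
pathogenic at the selected operating point. `examples/01_*.py` walks
through the rewiring rules on a hand-built locus, and `examples/03_*.py`
runs the three downstream statistics.

The same pipeline is scriptable from the shell: `tadmil simulate` writes a
dataset as standard BED/VCF/TSV files, `tadmil pair` exports SV–gene pairs,
`tadmil cv` runs the full cross-validated study (pass `--domains` with a
CTCF-loop BED to run in loop-domain mode), and `tadmil predict` scores a
dataset with a saved model bundle.

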