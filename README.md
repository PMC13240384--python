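# pgtm — embryo-as-proband PGT-M haplotyping and low-pass CNV calling

Preimplantation genetic testing for monogenic disease (PGT-M) normally
phases the parental haplotypes around a pathogenic variant using an
affected relative.  When no such relative exists — a de novo variant, a
deceased parent, an uninformative pedigree — an embryo whose mutation
status is confirmed by direct testing (Sanger sequencing or Gap-PCR) can
itself serve as the proband.  `pgtm` implements this workflow end to end
for embryologists and clinical bioinformaticians:

* **Phasing** — selects informative heterozygous SNPs within ±5 Mb of the
  variant, labels each carrier parent's mutant-linked (M) and normal (N)
  haplotypes through the proband embryo, and decodes every sibling
  embryo's inherited haplotypes by exact Viterbi over a 4-state HMM whose
  transitions are Haldane recombination fractions from a genetic map,
  r = (1 − e^(−2d))/2, and whose emissions model allele dropout (ADO)
  and genotype error.
* **Diagnosis** — reads the decoded path at the variant locus
  (flanking-marker consensus), reconciles it with the direct mutation
  test, and reports the more severe call with explanatory flags on any
  disagreement.  Non-disomic embryos (trisomy, monosomy, triploidy) are
  caught by a ploidy gate and excluded from haplotype diagnosis.
* **CNV calling** — 400-kb/200-kb sliding-window read depth from low-pass
  WGA sequencing, LOESS GC correction, log2 ratios and Z-scores against a
  reference panel with sex adjustment, circular binary segmentation (CBS)
  with a permutation test, and reporting rules: |log2| > 0.25 events that
  are whole-chromosome, whole-arm, or ≥ 4 Mb (≥ 20 bins); intermediate
  "mosaic" states when ≥ 10 Mb with an estimated aberrant-cell level
  above 30% (level = 2(2^L − 1) for gains, 2(1 − 2^L) for losses).
* **Simulation** — families with Poisson crossovers on the cM scale,
  shared-likelihood genotype observation, and GC-biased negative-binomial
  depth, so every stage is testable without patient data.

See `docs/methods.md` for the full model description and assumptions.

## Worked example

Simulate the packaged three-family dataset (a both-carrier ~19.3-kb
α-globin-cluster deletion family, and two de novo dominant frameshift
families) and run the full pipeline on the written files:

```sh
pgtm simulate --scenario cohort --out demo/
pgtm run --in demo/ --out report/ --seed 3
cat report/summary.tsv
```

which prints (exit code 2 flags that one embryo has a diagnostic failure):

```
embryo_id  cnv_flag  direct_call  proband_id  haplotype_call  final_status  flags
E1-1       abnormal  wild_type    E1-2        wild_type       wild_type     -
E1-2       abnormal  carrier      E1-2        carrier         carrier       -
E1-3       normal    wild_type    E1-2        wild_type       wild_type     -
E1-4       abnormal  wild_type    E1-2        failure         wild_type     ploidy_failure
E2-1       abnormal  wild_type    E2-4        wild_type       wild_type     -
E2-2       abnormal  wild_type    E2-4        wild_type       wild_type     -
E2-3       normal    wild_type    E2-4        wild_type       wild_type     -
E2-4       normal    carrier      E2-4        carrier         carrier       -
E3-1       abnormal  wild_type    E3-2        wild_type       wild_type     low_margin
E3-2       abnormal  carrier      E3-2        carrier         carrier       -
```

Reading the rows: `E1-2` is the family-1 proband — a carrier of the
paternal deletion by both Gap-PCR-style direct testing and haplotype
analysis.  `E1-3` inherited both parents' normal haplotypes and is
deletion-free with a normal CNV screen.  `E1-4` is a triploid: its direct
test is negative but haplotype construction fails (`ploidy_failure`), so
only the direct result stands, and the embryo is CNV-flagged.  The
`abnormal` CNV flags on the other embryos come from a whole-chromosome
trisomy called by the depth module (`report/<embryo>.segments.tsv` has
the segment table; `report/E1.phase.tsv` the per-marker M/N phase;
`report/<embryo>.path.tsv` the decoded inheritance vectors).

The same stages are available programmatically:

```python
from pgtm import RunConfig, FamilyInputs, run_family
from pgtm.simulate import make_cohort_fixture

bundle = make_cohort_fixture()[0]
result = run_family(FamilyInputs(
    family_id=bundle.family_id, variant=bundle.variant,
    genotypes=bundle.genotypes, gmap=bundle.gmap,
    direct_tests=bundle.direct_tests, embryo_ids=bundle.embryo_ids,
    depth_profiles=bundle.depth_profiles, panel=bundle.panel,
    arms=bundle.arms), RunConfig(seed=1))
for d in result.diagnoses:
    print(d.embryo_id, d.final_status, sorted(d.flags))
```

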