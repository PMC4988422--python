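# triohap

Trio-based multiplex mini-haplotyping of the PAH (phenylalanine
hydroxylase) locus: dye mobility-shift correction for capillary
electrophoresis (CE) fragment sizes, allele calling against STR/VNTR
reference ladders, dye-variability statistics, and Mendelian trio
phasing for indirect genetic diagnosis of phenylketonuria (PKU).

## The problem

PKU diagnosis and carrier screening can be done *indirectly*: the PAH
locus shows strong linkage disequilibrium, so a mini-haplotype built
from an intragenic tetranucleotide STR (alleles 226–254 bp in 4-bp
steps), an optional Xmn1 RFLP, and a downstream 30-bp VNTR (alleles
334–514 bp) tags the pathogenic chromosome in a family without
sequencing the causal variant. Typing all three members of a trio in
**one** CE injection — child amplified with FAM, father with HEX,
mother with TAMRA — cuts cost and lets alleles be compared directly
within a family.

The catch is the **dye shift**: each fluorophore retards its fragment
differently (TAMRA least, FAM/HEX by ≈2.1–2.5 bp), and the shift
depends on fragment length. Uncorrected, the same allele sizes
differently in each trio member, which on a 4-bp ladder is enough to
miscall genotypes and wreck a linkage-based diagnosis.

## The method

For each dye $d$ and reference allele size $R$ (the fragment length
expected from the reference genome), the mean shift over many runs
defines a correction coefficient $c_d(R) = \overline{x - R}$, where $x$
is the observed size. A degree-6 polynomial $f_d(x)$ fitted by least
squares to the points $(R + c_d(R),\, c_d(R))$ maps any observed size to
its correction, and corrected sizes are $x - f_d(x)$. Corrected sizes
are binned to the nearest ladder rung within a tolerance (1.5 bp STR,
5 bp VNTR), genotypes are checked for Mendelian consistency, phased
into paternal/maternal mini-haplotypes, and an affected proband's two
haplotypes — both at-risk by definition — are traced into a sibling,
fetus or embryo to predict affected / carrier / unaffected status.

Shift variability decomposes into a run effect shared by all dyes in an
injection (SD $\sigma_{\text{run}}$) plus per-dye peak noise (SD
$\sigma_\varepsilon$). Because the run effect cancels across co-injected
dyes, correction drives the *inter-dye* SD (spread across the three
dyes within one injection) below every *intra-dye* SD (spread of one
dye across injections) — the property that makes within-family
comparisons unusually precise. The bundled calibration (12 alleles ×
3 dyes, measured across 100 family trios) ships with the package, and a
synthetic-data module simulates Mendelian trios and sized peaks under
exactly this error model so that every stage is testable end to end.

## Worked example

Simulate 100 trios under the bundled calibration, then correct, call,
analyse and phase:

```sh
triohap simulate --families 100 --seed 42 --out peaks.tsv --truth truth.tsv
triohap correct  --peaks peaks.tsv --truth truth.tsv --out corrected.tsv \
                 --model-out models.json --table-out coefficients.tsv
triohap call     --corrected corrected.tsv --out genotypes.tsv
triohap stats    --corrected corrected.tsv --out variability.tsv \
                 --correlations correlations.tsv
triohap phase    --genotypes genotypes.tsv --out haplotypes.tsv
```

which prints

```
wrote 1075 peaks for 100 trios to peaks.tsv
FAM: degree 6, n=12, R^2=0.984, SE=0.037
HEX: degree 6, n=12, R^2=0.975, SE=0.043
TAMRA: degree 6, n=12, R^2=0.994, SE=0.035
called 100 trios to genotypes.tsv
Friedman |shift| across dyes: raw chi2=186.25 p=3.61e-41 (106 blocks); corrected chi2=1.75 p=0.416
phased 88/100 families fully (0 with Mendelian violations) to haplotypes.tsv
```

Reading the output: the per-dye polynomial fits explain 97–99 % of the
variation of the correction coefficient with observed size; the
Friedman test shows the three dyes differ enormously in raw shift
(p ≈ 10⁻⁴¹) and indistinguishably after correction (p = 0.42); and 88 of
100 families phase completely (the rest contain an uninformative
marker, e.g. all three members sharing one heterozygous genotype —
flagged, never guessed). The recovered coefficient table
(`coefficients.tsv`) reproduces the calibration means — e.g. FAM at
226 bp: −2.254 recovered vs −2.26 calibrated — and `correlations.tsv`
shows the characteristic sign pattern: shift vs size correlates
negatively below 300 bp for every dye (r ≈ −0.62 to −0.68) and
positively for FAM and HEX in the 300–600 bp VNTR range.

A sibling or fetus is then diagnosed indirectly with
`triohap diagnose --genotypes genotypes.tsv --family F0001
--relative relative.tsv --out call.tsv`.

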