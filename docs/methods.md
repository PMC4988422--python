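# Methods

## Setting

One capillary injection per family carries the PCR products of all
three trio members, each labeled with its own fluorophore (child FAM,
father HEX, mother TAMRA), for two repeat-length markers at the PAH
locus: a tetranucleotide STR (reference alleles 226, 230, …, 254 bp)
and a 30-bp VNTR (334, 454, 484, 514 bp). The two markers occupy
disjoint size ranges, so the three dyes suffice for a whole trio.
Allele identity throughout is the reference allele size in bp; ladder
validation enforces strictly increasing rungs whose spacings are
positive multiples of the repeat unit, and the VNTR ladder is
deliberately allowed to be non-uniform (its spacings are 120/30/30 bp).

## Dye-shift correction

The shift of a peak is observed size minus reference size. Averaging
shifts per (dye, reference allele) gives the correction-coefficient
table; the bundled calibration contains these means for 12 alleles ×
3 dyes measured across 100 trios. For correction at arbitrary observed
sizes, a degree-6 polynomial f(x) is fitted per dye by ordinary least
squares to the points (x = R + c, y = c) — the abscissa is the observed
size *implied* by each cell, since that is the quantity available at
correction time. STR and VNTR cells are pooled into one model per dye
(one equation per dye is the natural scope of the calibration), fitted
unweighted.

Numerical form matters here: a degree-6 power-basis polynomial over
x ≈ 220–515 bp is catastrophically ill-conditioned, and its printed
3-significant-digit coefficients are not evaluable (round-off in the
leading terms exceeds the function value by orders of magnitude). The
fit therefore uses `numpy.polynomial.Polynomial.fit`, which maps x onto
[−1, 1] before solving; models are serialised in that stable basis, and
raw power-basis coefficients are exported for display only.

Diagnostics: R² = 1 − SSE/SST, and a residual standard error
SE = √(SSE/(n − degree − 1)), reported as undefined when the fit
interpolates (zero residual df). This SE convention is a package
choice; externally quoted SEs for comparable fits do not always state
their denominator and should be compared qualitatively. On the bundled
table the fits give R² of 0.981 (FAM), 0.971 (HEX) and 0.994 (TAMRA).

Corrected size = observed − f(observed). Outside the fitted x-range,
f is held at its endpoint value and the peak is flagged
(`extrapolated`); a degree-6 polynomial must never be trusted beyond
its data.

Reference assignment for shift measurement has two paths. With known
genotypes (simulation, or families validated by parental comparison),
peaks are rank-matched to the member's true alleles within each
(family, member, marker) group — necessary because a ≈2.3-bp shift can
move a peak closer to the *adjacent* 4-bp rung than to its own. Without
truth, the nearest rung to (observed − prior mean shift for that dye)
is used, and peaks farther than half the minimum rung spacing are left
unassigned rather than force-matched.

## Noise model and its calibration

The generator's measurement model is

    observed = R + mu_dye(R) + runEffect + eps

with `runEffect ~ N(0, sigma_run²)` drawn once per injection and shared
by all dyes, and `eps ~ N(0, sigma_eps_dye²)` per peak. This
decomposition is an assumption, not a measured fact: it is the minimal
structure that reproduces the signature of co-electrophoresed trio
data, namely an after-correction inter-dye SD far below every intra-dye
SD (the shared run effect cancels within an injection but accumulates
across injections). Whether the real cross-dye correlation arises
entirely from shared injection conditions is not established; no
further structure is guessed.

Calibration inverts published variability numbers through the c4
factor, c4(n) = E[sample SD of n N(0,1) draws]; c4(3) = √π/2 ≈ 0.8862.
From an after-correction inter-dye SD `s_inter` and per-dye intra SDs
`s_d`:

    sigma_eps     = s_inter / c4(3)
    sigma_run_dye = sqrt(max(0, s_d² − sigma_eps²))   (clamped with a warning)

with the single panel `sigma_run` taken as the mean over dyes. From the
bundled 226-bp row (intra 0.103/0.132/0.070, inter-after 0.05) this
gives sigma_eps = 0.0564 bp and sigma_run = 0.0823 bp. Under these
defaults the simulated FAM intra-dye SD is ≈0.100 bp — slightly below
the calibrating 0.103 because a single shared run-effect magnitude
replaces three per-dye values; the discrepancy is within the
uncertainty of the source numbers.

Between tabulated alleles, mu is piecewise-linearly interpolated;
beyond the table it is held at the nearest endpoint and the peak
flagged, avoiding polynomial extrapolation blow-up. The TAMRA intra-SD
at 254 bp is undetermined in the source table; where a value is needed
the generator borrows the mean of the other STR rungs' TAMRA SDs.

## Synthetic genetics

Founder haplotypes are drawn i.i.d. per marker from allele-frequency
vectors (defaults: uniform over the ladder rungs — a neutral choice
made once for testability, not an estimate of any population), with a
pathogenic-risk flag carried at a configurable founder frequency
(default 0.25 for simulations that exercise diagnosis, chosen so that
affected probands are common enough to test against). Children receive
one uniformly chosen haplotype from each parent; no recombination,
mutation, stutter, dropout or null alleles are simulated. Affected
status is recessive: affected iff both inherited haplotypes carry the
flag. RNG substreams are keyed by (seed, family index), making output
independent of generation order.

The generator emulates: Mendelian trio structure, dye-specific mean
shifts, shared-injection correlation, homozygote single peaks. It does
not emulate: PCR stutter, allelic dropout, pull-up, peak-height
asymmetry, population structure or real PAH allele frequencies. Tests
passing on this generator therefore validate the arithmetic and logic
of the pipeline, not its robustness to those real-data artifacts —
dropout in particular is only *flagged* downstream (a single-peak
homozygote is never trusted silently).

## Allele calling

Corrected sizes bin to the nearest rung within a tolerance of 1.5 bp
(STR) and 5 bp (VNTR) — under half the minimum spacing, with a wide
guard band given post-correction residual SDs ≤ 0.11 bp. Exact ties
are no-calls with a flag; a wrong call is worse than a missing one.
Per member and marker: two called peaks → heterozygote; one →
homozygote flagged `single_peak` (dropout indistinguishable); zero or
more than two → marker failed. A run whose dye labels contradict the
panel's member→dye assignment is rejected outright.

## Variability statistics

Sample SDs use the n−1 denominator throughout (the convention for the
3-dye blocks is consequential: sample vs population SD differ by
×1.22, so cross-source comparisons are qualitative). Intra-dye SD
pools shifts per (dye, R) across runs; inter-dye SD is computed within
each qualifying run (≥2 dyes sharing an allele) and averaged over
runs, before correction on raw shifts and after correction on
(corrected − R) residuals. The Friedman test uses (run, R) pairs as
blocks and dyes as treatments on |shift|, with average-rank ties and
the closed-form χ² statistic on k−1 df (no tie-correction denominator;
scipy's tie-corrected variant serves as a cross-check on tie-free
data). Pearson correlations of (R, shift) are reported separately for
the sub-300-bp STR range and the 300–600-bp VNTR range, with two-sided
p-values; the significance threshold is α = 0.01. Exact correlation
magnitudes from any particular dataset are not reproducible from the
calibration means alone — only the sign pattern (negative below
300 bp for all dyes, positive above for FAM and HEX) is asserted.

## Phasing and indirect diagnosis

Phasing enumerates, per marker, both partitions of the child's
genotype into (paternal, maternal) and keeps those consistent with the
parents; a unique survivor resolves the marker, multiple survivors
mark it ambiguous (the classic all-three-identical-heterozygote case),
none is a Mendelian violation that refuses phasing for the family.
Resolved origins assemble into two mini-haplotypes; the Xmn1 RFLP slot
is carried untyped so the haplotype keeps its three-marker shape. No
recombination between STR and VNTR is assumed within a family (the
locus spans ~100 kb in high LD); conflicting marker origins are
surfaced as warnings, never resolved probabilistically.

Indirect diagnosis designates both haplotypes transmitted to an
affected proband as at-risk, reconstructs each parent's untransmitted
haplotype from the remaining alleles, and traces which the relative
inherited, marker by marker (a parent homozygous at a marker is
uninformative there; a call resting on a subset of markers is flagged
`partial`). Inherited at-risk count 2/1/0 → affected/carrier/
unaffected; any untraceable or conflicting transmission →
indeterminate. A parent recorded as affected contributes risk through
either haplotype, no tracing needed. On simulated families this logic
makes no wrong definitive call — by construction of the no-recombination
generator, which is exactly the assumption a real-data user must be
willing to make within a ~100-kb LD block.

## Problem sizes and numerical choices

Simulation-based tests use 100–2,000 families (10,000 for the phasing
and noise-recovery checks), sizes at which Monte-Carlo error is
comfortably inside the asserted tolerances (e.g. the mean cross-dye SD
over 10,000 runs has standard error ≈0.0003 bp against a ±0.005
tolerance). The noise-free correction round trip is bounded by the
polynomial fit residuals themselves: ≤0.07 bp for the bundled
piecewise-linear calibration shifts, <0.05 bp for genuinely smooth
shift functions. Peak observations are deterministic given the root
seed; same seed → bit-identical tables.

## Known limitations

- The correction is only as good as the calibration table; alleles
  outside 226–514 bp are corrected by endpoint extrapolation and
  flagged.
- The error model omits stutter, dropout and pull-up; real
  electropherograms need peak QC upstream of this package (input is
  already-sized peaks, not traces).
- Indirect diagnosis is within-family only; no population haplotype
  frequencies or direct variant interpretation are provided.
- The Friedman block layout and the SD denominator are package
  conventions chosen where the field reports statistics without
  stating them; both are documented above.
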