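# Methods

This note documents the models implemented in `cenrec`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would want to know.

## Fluctuation analysis

**Model.** Mutant counts from parallel cultures follow the Luria–Delbrück
distribution in the Lea–Coulson formulation, parameterized by m, the expected
number of events per culture. The pmf is evaluated with the Ma–Sandri–Sarkar
recursion (p₀ = e^(−m); p_k = (m/k) Σ_{j=0}^{k−1} p_j/(k−j+1)), which assumes
deterministic exponential growth of mutant clones, no differential fitness,
and no phenotypic lag. The per-division rate is m̂/(N_t − N₀): divisions per
culture are taken as the net cell increase, which for N_t ≫ N₀ is
indistinguishable from N_t. Defaults N₀ = 10³ and N_t = 2×10⁸ make expected
counts realistic (m ≈ 2) at a rate of 10⁻⁸/division; culture sizes are always
user-settable because they are experiment-specific.

**Estimation.** m̂ maximizes the summed log-pmf by bounded one-dimensional
optimization with bracket expansion; the m = 0 boundary (all-zero counts) is
returned exactly. Confidence limits are profile-likelihood bounds at the
χ²₁(0.95)/2 = 1.9207 drop, found by bisection on each side of m̂ and clipped
at 0 below; this mirrors the standard likelihood-ratio interval used by
fluctuation-analysis software. Counts above 10⁴ are right-censored into a
tail bin contributing a log-survival term, bounding the O(k²) recursion cost
without discarding jackpot cultures. The recursion kernel is numba-compiled
when numba is importable, with an identical pure-numpy fallback.

**Partial plating.** With plating fraction e < 1 counts are binomially
thinned; the thinned pmf is obtained by composing the Lea–Coulson probability
generating function with z → 1 − e(1 − z) and inverting the series by FFT on
a circle of radius r < 1 (r^n = 10⁻⁹), which keeps the aliased tail below
~10⁻⁹ while amplifying roundoff less than 20-fold. At e = 1 this agrees with
the direct recursion to ~10⁻⁸.

**Pooling.** Replicate experiments are pooled on the rate scale by
maximizing the summed log-likelihood with per-experiment m_i = ρ(N_t,i −
N₀,i); whether the original analyses pooled by likelihood or averaged rates
is not documented, so pooling is likelihood-based and the choice is flagged
here. A secondary-screen correction (the fraction of selected colonies
confirmed as true events) is applied by default as deterministic scaling of
m̂ — the expected-value correction — with stochastic binomial thinning of the
raw counts available behind a flag.

**Sectored colonies.** Acentric-chromosome loss is estimated from
half-sectored colonies under the model that a colony with similar-sized
marker-plus/marker-minus sectors reflects a loss at the first post-plating
division, so the rate per division is the sectored fraction; a Wilson score
interval is attached and the point estimate is also reported to two
significant figures, the precision at which such rates are quoted.

## Centromere breakpoint mapping

Coordinates are 1-based inclusive columns of the given pairwise alignment.
Informative sites are columns where both parents carry different non-gap
bases; columns with a gap in either parent are tracked separately and never
used for breakpoint logic, because the mapping rests on the substitution
SNPs only. A recombinant sequence is genotyped per site as W/Y/N; a single
W→Y transition in the construct's orientation yields a simple-recombinant
call with an exclusive breakpoint interval (the exchange lies strictly
between the flanking SNPs). N sites are skipped for switch counting but
widen the interval to the nearest called sites — conservative reporting
rather than imputation. A single switch *against* the declared construct
orientation cannot arise from the expected recombinant product and is
reported as ambiguous. Identity-tract search includes the two terminal runs;
ties go to the smallest start.

The canonical 117-bp fixture honors the published geometry — informative
sites at columns 11, 13, 24, 68, 70, 81 and 101 (hence a longest identity
tract of 43 bp between 24 and 68), CDEI/CDEII/CDEIII spans with an AT-rich
CDEII, and the functionally critical CDEIII C at column 106 — but its
remaining bases are synthetic, because the true sequences are published only
as a figure. Every test conclusion therefore concerns the geometry, not the
actual bases.

## Isolate classification

Each chromosome III copy is reduced to (left-arm allele, centromere PCR
state, right-arm allele). Coupling is parental-W for (leu2, MATalpha),
parental-Y for (LEU2, MATa), crossed otherwise; an isolate in classes 1–4 is
CO iff any haplotype is crossed. Trisomes (class 5) are never assigned CO/NCO
status. The canonical single-chromosome configurations A–E and K–P fix the
distal couplings as the unique assignment under which this coupling rule
reproduces every tabulated CO/NCO call (verified exhaustively in the test
suite); the original letter definitions live in unavailable supplementary
material, so only their printed properties are treated as ground truth, and
`proximal_tag` exists to disambiguate configurations the three markers
cannot. Reciprocal pairs are identified by subclass membership {1F, 2C, 3B}
rather than a coupling predicate: a predicate on distal couplings alone
provably selects 2H along with 1F/2C/3B, so the printed set is authoritative.
A "simple NCO" is computed structurally — one unrearranged parental
chromosome plus an RCU chromosome carrying the *other* parent's phase, the
SDSA expectation — which distinguishes it from NCO patterns requiring
sister-chromatid co-segregation. Mechanism labels are annotations only:
reciprocal pairs → DSBR, other crossovers → {DSBR, BIR}, plain non-crossover
conversions → SDSA.

Class 4 admits RU as well as RCU monosomes for generality, although the
reference roster contains only RCU monosomes. The Fisher exact test is
two-sided via `scipy.stats.fisher_exact`, cross-checked in the tests against
full hypergeometric enumeration.

## Coverage, copy number, LOH

NSC divides each allele's read count by the genome-wide mean of per-SNP
total (both-parent) coverage, so one chromosome copy has expectation 0.5 and
the mean total NSC is exactly 1 by construction. The normalizer is global —
per-chromosome normalization would mask aneuploidy — with the caveat that a
large copy-number event shifts the baseline of every other site; whether the
normalizer is a per-site mean or ratio of totals is ambiguous in prose, and
the per-site mean is used (they coincide for complete tables).

Copy states are called per parent by a centered sliding median (default
k = 11 SNPs, shrunk at chromosome edges) divided by 0.5 and rounded, placing
decision boundaries at 0.25, 0.75, 1.25, … — symmetric about the per-copy
expectation. Because the two parental medians cross their thresholds
independently, a genuine copy-number step can leave a 1–2 SNP transitional
run in a half-switched state at its edge; interior runs of at most k//2 SNPs
whose state interpolates between two differing flanks are therefore
re-assigned by a local least-squares changepoint fit of the *raw* NSC
against the flanking copy expectations. Runs between identical flanks are
never touched, so genuine short events cannot be erased by the refinement;
events shorter than about half the window remain below the caller's
resolution. Maximal runs of non-(1,1) states become tracts (terminal iff
they reach the chromosome's first or last SNP, boundaries at the outermost
SNPs of the run); runs of fewer than 2 SNPs are discarded as noise.
Tract length is the bp span between the outermost converted SNPs, excluding
heterozygous-insertion content by construction, and a tract is unidirectional
iff it lies entirely on one side of the centromere midpoint, patchy iff its
donor parent switches internally. Whole-chromosome ploidy uses the mean
total NSC with cuts at 0.75/1.25/1.75. None of the smoothing/thresholding
machinery is described in the original prose; the windowed-median scheme and
its refinements are this package's design.

## Synthetic data

The generators state a world and keep it fixed:

- **Fluctuation counts**: events per culture ~ Poisson(rate·(N_t − N₀));
  each event's clone size is min(N_t, ⌊1/u⌋), u ~ Uniform(0,1] — the
  deterministic-growth descendant construction. This simulator shares no
  code with the MSS recursion, so their χ² agreement in the tests is a
  genuine cross-validation of both. A generation-by-generation branching
  simulator (stochastic clone growth) is out of scope.
- **Centromere pairs and recombinants**: sequences differing exactly at
  requested columns; simple recombinants splice the parents at a column;
  patchy recombinants switch parents at listed columns; the acentric
  recombinant is the perfect fusion of the reporter intron halves.
- **Rosters**: instantiated from subclass counts (default: the 22-subclass
  composition totalling 100 isolates) and shuffled by seed. The roster
  follows the tabulated 9 monosomes even though the accompanying prose says
  10; the table is taken as authoritative and the discrepancy is noted, not
  resolved.
- **Coverage**: 3-chromosome genome (230/315/577 kb, the 315-kb chromosome-
  III analog with its centromere at 114 kb), SNPs every 400 bp, depth 50×,
  negative-binomial noise with variance = 2 × mean (dispersion 1 = Poisson,
  0 = noiseless limit). Planted events set per-segment or whole-chromosome
  copy numbers and are recorded as ground truth. Not emulated: read-level
  errors, mappability variation, Ty/structural variants beyond copy-number
  segments, meiotic recombination. A green planted-event test therefore
  establishes the caller's statistical behavior under this noise model, not
  robustness to alignment artifacts.

All generators are byte-reproducible from (config, seed), and every ground
truth is sufficient to score the corresponding downstream call.

## Known limitations

- The original raw culture counts and per-isolate tract tables are not
  published, so rates and tract statistics are validated by parameter
  recovery at the published magnitudes, not by re-analysis of the original
  data.
- The MSS likelihood ignores post-plating growth differences and phenotypic
  lag; rates from assays violating these assumptions will be biased.
- Global NSC normalization shifts baselines when a substantial fraction of
  the genome changes copy number; with the default three-chromosome model a
  whole-chromosome event moves other chromosomes' totals by up to ~10%.
- The subclass letters encode the printed marker properties, not the
  original supplementary definitions; configurations outside the canonical
  table classify by class rules but receive no subclass label.
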