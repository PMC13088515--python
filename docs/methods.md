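# Methods

## The homozygosity-deficit model

A fully penetrant recessive lethal removes homozygous conceptions before
they can be genotyped. For a haplotype with population frequency $q$ among
$2N$ chromosomes of $N$ genotyped animals, Hardy–Weinberg equilibrium
predicts $E = N q^2$ homozygotes; a lethal linked in strong LD with the
haplotype drives the observed count $O$ toward zero. The scan treats each
window haplotype as one test of
$H_0: O \sim \mathrm{Binomial}(N, q^2)$ against the lower tail,
$p = P(X \le O)$. Only the lower tail is tested: an excess of homozygotes
is not a lethality signal and is not reported.

Assumptions: random mating with respect to the haplotype (violated by
deliberate carrier avoidance, which deflates $O$ for known disorders — the
test is then conservative in its biological interpretation but still a
correct deficit detector), complete and phased genotypes, and $q$ estimated
from the same sample used for the test. $q$ is the sample haplotype count
over $2N$; when only the heterozygous-carrier fraction $c$ is available,
$q$ is recovered as the minor root of $c = 2q(1-q)$.

### Multiple testing and windows

Windows of 1 Mb and 2 Mb slide by half their size per chromosome (starting
at the first marker position; half-open intervals; windows with fewer than
two markers are dropped). The two sizes trade haplotype specificity against
LD coverage; overlapping significant windows are interpreted as one
underlying region and merged (overlap or exact adjacency on the same
chromosome). The Bonferroni denominator $m$ is the number of haplotypes
actually tested — those passing the frequency ($q > 0.005$) and ceiling
($O \le 30$) filters — pooled across both window sizes; $p_{adj} =
\min(1, m\,p)$, significance at $p_{adj} < 0.05$. The frequency filter
guards against phasing-error haplotypes and powerless rare strings; the
ceiling keeps the test set focused on candidate deficits. Filter order is
immaterial to the result set; both are applied.

### QC filters

The pre-phasing quality control mirrors standard chip QC: animals with call
rate ≤ 70% are removed first; then markers with MAF ≤ 1%, call rate ≤ 90%
or Hardy–Weinberg exact-test $p < 10^{-8}$. The HWE exact test is the
conditional-on-allele-counts enumeration (sum of genotype-table
probabilities no larger than the observed one), implemented directly and
verified in the test suite against an exact integer-combinatorics oracle;
no installed Python package exposes this primitive.

## Fertility phenotypes

Three phenotypes are computed from raw mating and foal-registration
records:

* **insemination success** — matings of the same sire–dam pair within 10
  days of the previous retained mating are collapsed into one insemination
  event (transitive chains, event keeps its first date); an event succeeds
  iff a foal (dead or alive) of the same dam is born 300–400 days later.
  A foal is attributed to the latest event of its dam in that window;
  orphan foals (event unregistered) enter foal-level phenotypes only.
* **stillbirth rate** — foals flagged dead at birth or with death date
  equal to the birth date, over all foals.
* **juvenile mortality** — death within 365 days of birth (day-0 deaths
  included, so stillbirths are counted here too), over all foals.

Mating categories per region: *risk1* = carrier sire × genotyped carrier
dam; *risk2* = carrier sire × ungenotyped dam whose sire (maternal
grandsire) is a carrier — a genotyped non-carrier dam is excluded even if
her sire is a carrier, and a genotyped carrier dam contributes to risk1
only; *non-risk* = genotyped non-carrier sire with the same two dam groups.
"Carrier" always means heterozygous or homozygous; "non-carrier" requires a
genotyped call — unknown never counts as non-carrier. Matings with
unknown-status sires are excluded from every contrast and counted in the
log. Sire-level groups (all matings of carrier vs non-carrier sires) are
labelled independently. Group contrasts use the pooled two-proportion
z-test (two-tailed; zero pooled variance returns $p = 1$ by convention) and
are reported as relative differences
$\Delta_{rel} = (r_{ref} - r_{cmp})/r_{ref} \times 100\%$, rates to one
decimal.

Under full embryonic lethality one quarter of carrier×carrier conceptions
die, so risk1 insemination success is expected 25% below the non-risk
reference, and across all matings of a carrier sire the expected reduction
is $0.25 \times$ (population carrier frequency).

## The synthetic population

The generator emulates the statistical structure the analysis relies on,
not equine biology in detail:

* **Pedigree** — discrete cohorts ~5 years apart; parents drawn from all
  living animals aged 3–20 years at conception; the top
  `popular_sire_fraction` (default 10%) of eligible sires receive a fixed
  70% share of matings. Baseline (non-genetic) stillbirth (3%) and
  juvenile mortality (4%) are drawn at pedigree time so dead animals are
  never parents.
* **Gene drop** — uniformly spaced diallelic markers (default 480 over
  24 Mb, one per 50 kb, chip density); neutral founder allele frequencies
  Uniform(0.05, 0.95) so the QC filters have work to do; one crossover per
  chromosome per meiosis at a uniform position (the simplest model that
  preserves Mb-scale LD blocks). The lethal haplotype is the all-alternate
  string over a centred 1.5-Mb region, planted on founder chromosomes at
  frequency `q_lethal` (default 0.07, carrier frequency ~13% — the scale
  of drift-borne lethals in closed studbooks). The causal variant is an
  off-chip locus at the region centre riding on the same chromosome;
  `causal_ld_breakage` (default 2%) of founder lethal-haplotype
  chromosomes lack it, which is what produces the haplotype-homozygous but
  variant-heterozygous recombinants the discordance check flags. Founder
  draws are conditioned on not being causal-homozygous whenever a lethal
  penetrance stage is active, because a homozygous founder would not have
  survived to breed.
* **Penetrance** — homozygous conceptions die in utero (`embryonic`), are
  born dead (`stillbirth`), die within the first year (`juvenile`), or
  survive (`none`). Animals removed by lethality cannot parent; their
  already-scheduled conceptions are cascade-removed. Genotyped animals are
  the survivors, matching how registration-time sampling misses animals
  that die first.
* **Matings** — each realized conception is one insemination event;
  preceding failures are geometric with per-cycle success
  `baseline_insemination_success` (default 0.65, the ~65% per-cycle
  pregnancy rate reported for horses), placed one 21-day estrus cycle
  apart. A failed event spawns a duplicate re-mating record 1–10 days
  later with probability `remating_prob`; re-inseminations within one
  cycle share the event's conception outcome rather than getting an
  independent chance — with independent per-record success, the collapsed
  risk1 contrast would converge below the theoretical 25% (re-mating would
  rescue failures), contradicting the model the contrast estimates. Each
  mating row is registered with probability `registration_completeness`
  (default 0.9); foal registration is complete, so unregistered successes
  leave orphan foals, as in real studbooks.
* **Dates** — integer day offsets (rendered from a 2000-01-01 epoch in
  CSV); gestation fixed at 340 days, a horse-typical constant.

What the generator does **not** emulate: realistic recombination maps, the
X chromosome, seasonality and mare age effects, selection on breeding-goal
traits, heterozygote advantage, and non-uniform registration bias
(incompleteness is uniform, so simulated rates are unbiased; real
registration preferentially omits failures). Passing tests therefore
demonstrate the correctness of the statistical machinery under the stated
model, not robustness to these real-data features.

## Variant prioritization

For each deficient region, sequenced sires are split by carrier status and
variants within 4 Mb of the region boundaries are kept when every
sequenced carrier is heterozygous (a missing call fails conservatively; at
most one homozygous-alternate sire is tolerated anywhere, allowing one
genotyping error) and at most three sequenced non-carriers carry the
allele (either het or hom-alt; hom-alt non-carriers also count toward the
homozygote allowance). Fewer than two sequenced carriers leaves a region
explicitly unprocessed. Survivors are tiered: loss-of-function classes
(frameshift, stop gained/lost, start lost, splice donor/acceptor, inframe
indel) and SVs overlapping ≥ 1 bp of an exon rank first, then missense
with SIFT ≤ 0.05; a missense variant without a SIFT annotation falls to
"other" with a warning rather than being silently promoted. Within a tier,
variants with a known database homozygote or a non-conserved site are
demoted; ties break on genomic coordinate, so output is deterministic and
independent of input order. SIFT/CADD/conservation/database evidence are
consumed as annotations, never computed.

## Numerical and design notes

* Exact binomial tail via `scipy.stats.binom.cdf`, clamped to (0, 1]; the
  test suite verifies agreement with a direct term-by-term summation
  oracle to 1e-12 relative error up to N = 10,000.
* Coordinates are 1-based marker positions; all intervals half-open
  [start, end). Expected homozygote counts are reported rounded in tables,
  exact internally.
* Two-proportion z-test delegates to `statsmodels`; rank-sum comparisons
  use `scipy.stats.mannwhitneyu` with the exact method for tie-free groups
  of ≤ 25.
* One global seed expands into independent per-stage streams
  (`np.random.default_rng([stage, seed])`), so identical seeds give
  byte-identical outputs and stages can be re-run in isolation.
* Study sizes used by the replicated validation experiments
  (`hapdeficit.studies`): the power experiment uses a shallow
  three-generation pedigree (1,700 founders + 2 × 1,700 offspring,
  N ≈ 4,850 genotyped, q = 0.07, complete LD) so the realized haplotype
  frequency is not eroded by deep-pedigree drift — expected homozygotes
  ≈ 24, giving essentially certain detection; the neutral type-I
  experiment uses 1,000-animal populations over a 10-Mb genome; the risk1
  contrast uses 10,000–20,000 matings per group, where the Monte-Carlo
  95% interval around the 25% reduction is about ±1–2 percentage points.

## Known limitations

* The scan requires complete phased input; phasing and imputation are out
  of scope, and missing genotypes are a hard error rather than being
  imputed.
* Bonferroni over tested haplotypes is conservative when windows overlap
  (the same chromosome strings recur in adjacent windows).
* Carrier status from a haplotype is not fully reliable in the presence of
  recombination with the causal variant; the discordance report quantifies
  this but the mating contrasts still use haplotype-based status.
* With very small regions or sparse maps the planted haplotype may span
  < 2 markers in a window size and escape a size class entirely.
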