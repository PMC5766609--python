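# Methods

## Doped-library statistics

The design table treats each clone's mutation count as
Binomial(*m*, 1 − *p*<sub>wt</sub>) over the *m* randomized positions,
with substituted residues uniform over the *a* allowed alternatives
(default *a* = 18: the 20 standard amino acids minus the wild type and
minus Cys, which is excluded throughout to avoid unpaired thiols on
phage). Class diversities C(m,k)·a^k are exact integers; expected clone
counts n_k = N·f_k stay real-valued before any division so duplication
ratios (n_k/U_k) are exact — rounding them first visibly corrupts the
k = 1 duplication figure.

Coverage uses the Poisson occupancy estimate c = 1 − exp(−n/D); the exact
occupancy expectation 1 − (1 − 1/D)^n is provided (`exact_coverage`) and
used as the oracle in tests. The two differ by at most ≈ 0.184/D (attained
near n ≈ D), so they agree within 0.01 for D ≥ 19 and are
indistinguishable at the design point.

Display convention: percentages to two decimals, printing 100.00% once
1 − c < 5×10⁻⁵; counts to three significant figures; average duplication
prints `<<1` once coverage < 1% (duplication negligible although the
estimator's value is mathematically ≥ 1). The totals row of the
*displayed* table sums the rounded row values so the printed rows and
printed total remain arithmetically consistent; the engine's totals keep
full precision (the two unique-clone totals are 4.55×10⁷ vs 4.5446×10⁷).

## Window layout

The default layout divides the 29-residue backbone into four consecutive
7-residue windows (1–7, 8–14, 15–21, 22–28), each augmented with the
shared C-terminal positions {27, 28}, plus an N-terminal-extension
library randomizing {−2, −1, 1, 2, 3, 4, 5, 27, 28}. After deduplication
the fourth window has 7 randomized positions rather than 9; the true
historical window boundaries are not recoverable from available
descriptions (observed clones also substitute position 29), so the layout
is a configurable `WindowLayout` and clones whose substitutions fit no
window are *flagged* inconsistent, never reassigned or rejected.

## Oligo design and site probability

Randomized positions are exact trimer-codon mixtures: the wild-type codon
at weight *p*<sub>wt</sub>, each alternative at (1 − *p*<sub>wt</sub>)/a;
extension slots, which have no wild type, are uniform over the 19 non-Cys
residues. One codon encodes each residue within a mixture and stop codons
are rejected.

Because positions are independent (true for mixed-trimer synthesis), the
probability that a random library member contains ≥ 1 occurrence of ≥ 1
recognition sequence is computed exactly: an Aho–Corasick DFA is built
over the recognition sequences with matching redirected to an absorbing
hit state, and the state *distribution* is propagated codon-wise through
the spec — a transfer-matrix pass linear in sequence length. Scanning is
single-strand by default since NcoI (CCATGG) and NotI (GCGGCCGC) are
palindromic; a flag adds the reverse-complement patterns for
non-palindromic enzymes.

The optimizer is deterministic coordinate descent over positions, swept
5'→3' until no change, with lexicographic tie-breaking on codon order.
The hit probability is linear in each mixture entry, so given the forward
state distribution and the backward hit probability around a position the
per-residue codon choice is exactly optimal conditional on the rest.
Constant (non-randomized) codons of the insert are part of the synthesis
design and are optimized by default as well — this matters in practice:
with constant codons frozen, a CC-ending constant codon ahead of a doped
Met can pin the NcoI probability near 2% regardless of mixture choices.
All five default sub-library specs reach site probability 0 (< the 0.13%
design bound). An exhaustive-search optimizer over all assignments is
available for toy problems and validates the descent. Candidate codons
default to all sense codons per residue, initialized at the highest-usage
human codon; the historical trimer-block catalogue is unpublished, so the
bound is treated as achievable-by-optimization, not tied to specific
published codons.

Duplex assembly models primer extension: the longest 3'-complementary
overlap (≥ `min_overlap`, default 6 nt) anneals and both strands are
extended; digestion checks report all top-strand occurrences (0-based)
and call a fragment clonable when NcoI and NotI each occur exactly once,
NcoI 5' of NotI.

## Selection simulator

The simulator is stated plumbing, not an inference target: it generates
ground-truth data so the analysis stages can be tested; no parameter is
fitted to experimental data, and pool-activity magnitudes from real
campaigns are figure-only and never targeted numerically.

Latent potency model: the parent anchors at EC50 0.05 nM on GCGR and
200 nM on GLP1R (log10 nM: −1.30 / +2.30) — a potent glucagon agonist
with weak cross-reactivity. Each (position, residue) substitution draws
one Normal(0, 1) effect per receptor on log10 EC50, derived from a
counter-based RNG keyed by (seed, position, residue) so identical
mutations act identically across variants and across pools; effects add.
A Bernoulli(0.10) flag per mutation marks it binder-only: selection sees
its binding strength, but activity readouts give zero signal —
sufficient to reproduce binder-not-activator clones at screening and the
qualitative decline of pool activity over late rounds when the
binder-only burden is high.

Panning round: capture is logistic in binding strength
b = −log10 EC50[nM] with midpoint 1 nM and width 0.5; captured phage
survive the washes with probability 0.5, uncaptured with 0.01; a 10⁻⁴
additive carryover floors survival; survivors are multinomially resampled
to the amplification target (no growth bias; a bias hook is the
parameter). Depletion on naïve cells is modeled as the variant-uniform
factor 1 − depletion_efficiency × nonspecific_binding (defaults 0.9 ×
0.1) because the generative model carries no per-variant stickiness
trait; it rescales survival without changing composition and is kept as
an explicit hook. Four rounds by default; scheme 1 alternates
GCGR→GLP1R→GCGR→GLP1R, scheme 2 the inverse; zero rounds returns the
initial sample.

Simulated problem sizes: tests and examples sample 2×10⁴–10⁶ clones and
amplify to 2×10⁴–2×10⁵ — large enough for 3-standard-error agreement with
closed-form expectations while keeping the suite fast. The simulator
emulates the doped sampling distribution, additive potency genetics and
multinomial bottlenecks of a campaign; it does **not** emulate phage
growth-rate bias, display-valency effects, cell-number fluctuations or
sequencing error, so passing tests certify the analysis code, not
wet-lab predictions.

## Screening and pharmacology conventions

Peptide positions are 1-based on the parent (glucagon numbering H1…T29);
a peptide longer than the parent by e ≤ 2 residues is read as an
N-terminal extension with labels −e…−1 (no internal gaps are considered —
inputs are translated clone sequences, not noisy reads). Mutation calling
and re-application are exact inverses, property-tested including
extensions, and all 35 packaged sequences round-trip.

EC50 ratios are GCGR/GLP1R per the source table's column (its narrative
sometimes says GLP1R/GCGR; both directions are reported in summaries).
Censored measurements (">20", ">200" nM) carry only their bound, are
never imputed, and exceed every finite threshold. Thresholds are
inclusive; the balance window [0.5, 1.5] is endpoint-inclusive (a printed
ratio of exactly 1.50 is balanced). Classification uses printed means and
ignores standard deviations.

Known fixture inconsistencies, reported rather than patched: printed
ratios of rows 7, 8, 28 and 35 differ in the last digit from
recomputation (they evidently derive from unrounded means), so tests
assert exact printed-precision agreement for the other 25 uncensored rows
and one-ulp agreement for all 29; the "8 peptides ≤ 30 pM on each
receptor" headline recounts to 7 from printed means (one row prints
0.031 nM), so that count is reported, not asserted; and the
engineered-analogue table prints its parent 16 with an R18A reading
absent from the main table — the fixture preserves each table as printed
and the engineering transformation (S2 → D-Ser; Y10 → K carrying the
γGlu-γGlu-C16 palmitoyl PK modifier) maps each printed parent to its
printed analogue exactly. DPP-IV liability is called when residue 2 is
L-configured Ser/Ala/Pro on a free N-terminus; D-Ser2 clears it.

The 4PL dose-response model (`DoseResponse(doses, responses).fit()`)
estimates (bottom, top, log10 EC50, hill) by Levenberg–Marquardt least
squares, parameterizing EC50 in log-space; flat responses, optimizer
failure and EC50 estimates more than a decade outside the tested dose
range are flagged `converged=False` instead of raising. On noise-free
4PL data it recovers EC50 within 1%; with 5% log-normal noise the median
relative error over 100 replicates stays under 10%.

## Determinism

All randomness flows through explicit integer seeds via NumPy
`SeedSequence` spawning (library sampling, per-mutation effects, each
panning round, readout noise). Identical config + seed reruns are
byte-identical, and run manifests record version, config hash and seeds.
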