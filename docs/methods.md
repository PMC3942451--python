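# Methods

This note documents the models and numerical choices behind `fgakit`, the
defaults that matter, what the simulators do and do not emulate, and the
known limitations.

## Reference database and k-mer index

All specificity is judged against a single database holding target CDS
(grouped into gene families) plus background sequences. Every sequence is
indexed by exact k-mer on both strands (default **k = 12**). The choice of
12 guarantees that any shared exact stretch of ≥ 20 bases — the
sequence-specific rejection threshold — contains at least one shared
12-mer, so no stretch violation can be missed by seeding. Coordinates are
0-based half-open; reverse-strand postings store the window's start on the
forward strand. k-mers containing N are never indexed, and N never matches
any base anywhere in the package. Ambiguity codes other than N are
rejected at read time; nucleotide input is case-folded with U→T.

The database persists as plain text (`sequences.fasta`, `families.tsv`,
`meta.json`); the k-mer index is rebuilt on load, which at the scales this
package addresses costs well under a second and avoids a versioned binary
format.

## Family recruitment

Candidate family members are scored with an ungapped position-specific
log-odds profile built from a seed alignment, not a full profile HMM.
Column log-odds in bits:

    s_c(a) = log2( (n_c(a) + τ·q(a)) / (n_c + τ) / q(a) )

with total pseudocount **τ = 1** per column and uniform background
q(a) = 1/20. Columns with gap fraction above `gap_col_max` (default 0.5)
are dropped. A query scores the maximum over ungapped placements; ties go
to the leftmost placement. The default recruitment threshold is 0.6 × the
minimum self-score of the seed rows. This scorer is deliberately simple —
recruitment is a commodity step — and results from a real HMMER3 search
can be imported instead from `--domtblout` output (best domain per
family/sequence pair, pass/fail on the independent E-value). The computed
and imported scores live on different scales and are never compared.

## Specificity metrics

* **Best identity**: exhaustive ungapped scan of every probe-length window
  on both strands of the subject; the denominator is always the probe
  length, so identity is comparable across subjects. Leftmost best window
  wins ties.
* **Continuous stretch**: exact longest common substring, computed by
  binary search over the shared-length predicate with substring hashing
  (the predicate is monotone). Substrings containing N are excluded.
* **Duplex ΔG°37**: for an aligned probe/window pair, the sum of unified
  nearest-neighbor stack energies over adjacent positions where *both*
  positions are Watson–Crick matched, plus a per-terminal initiation
  penalty when the corresponding window terminal is matched. Mismatch
  positions contribute nothing: no mismatch stacks, loops, bulges, or
  dangling ends. The per-subject statistic is the minimum over all
  same-length windows on both strands. This is an intentionally
  conservative, exactly checkable approximation of a full duplex model;
  its virtue is that a brute-force window scan reproduces it bit for bit.
* **Melting temperature**: perfect-duplex assumption,
  Tm = ΔH/(ΔS + R ln(Cт/4)) − 273.15 + 16.6·log10([Na+]), with total
  strand concentration 1 µM and 1 M monovalent salt by default. Agrees
  with an independent published-parameter NN calculator to < 0.5 °C.
* **Self structure**: longest self-complementary run
  (LCS of the probe vs its own reverse complement) and longest
  homopolymer run.

The thermodynamic table shipped in `fgakit/data/nn_unified_dna.tsv` is the
unified oligonucleotide ΔH/ΔS/ΔG°37 set; a step and its reverse complement
share one value, and the packaged loader asserts that symmetry.

## Probe design

Defaults: probe length **50** (40–70 supported), GC 30–70%, Tm 60–95 °C
(consistent with the 1 µM / 1 M salt Tm model above), self-complementary
run ≤ 12, homopolymer ≤ 6. Probes are forward-strand, within-CDS windows.

Classification per candidate:

1. Covered targets = same-family CDS matching at ≥ 96% identity, ≥ 35-base
   stretch and ≤ −60 kcal/mol. The source CDS contains the probe verbatim
   and is always covered — this guards AT-rich probes whose *perfect*
   duplex is weaker than the group ΔG threshold from being orphaned.
2. Everything else (other families, background, non-covered siblings) is a
   non-target; the worst cases (max identity, max stretch, min ΔG) are
   taken independently, so the three extremes may come from different
   sequences.
3. Exactly 1 covered + all non-target worst cases within identity ≤ 90%,
   stretch ≤ 20, ΔG ≥ −35 → sequence-specific; ≥ 2 covered under the same
   non-target condition → group-specific; otherwise rejected.

At database scale, candidate cross-hybridization partners are found by
k-mer seeding and each seeded subject is then scanned exhaustively. A
subject sharing no 12-mer with the probe is reported at identity 0 /
stretch < 12 / ΔG 0: by the seed-length argument it cannot violate the
stretch threshold, and similarity that low is far inside the other two
thresholds, so classification is unaffected. The pairwise functions,
called directly, are always exhaustive. One consequence worth knowing:
siblings in the 90–96% identity band are too similar to pass the
non-target screen and not similar enough to be covered, so probes in such
regions are correctly rejected — conserved families yield group probes,
diverged families yield sequence-specific probes, and the band in between
yields few probes, which is the intended conservative behavior.

Selection takes up to `per_target` probes per covered CDS, greedily in
lexicographic quality order (lowest worst non-target identity, then
shortest worst stretch, then highest worst ΔG, then lower offset), subject
to a minimum spacing of probe_length/2 between chosen offsets on the same
target. Control designs: CORS spots are n identical copies of one fixed
50-mer; negative-control candidates are windows of supplied negative
sources that pass the physicochemical filters and stay *below* the
sequence-specific identity threshold against every target (an error is
raised only if none survive); degenerate positive-control oligos expand
IUPAC codes to all concrete variants.

## Preprocessing

QC removes a probe/sample measurement when replicate-spot CV > 0.8, SNR
< 2, or raw intensity < 1000 ("less than" is strict: exactly 1000
survives). Control probes are exempt from the intensity filter, since CORS
levels are set by spike-in concentration, not biology. The intensity
cutoff is applied to raw scanner units, before normalization (the
threshold is meaningful on that scale); this order is configurable. When
replicate-spot data are supplied instead of precomputed columns, CV =
sd/mean across replicate spots and SNR = (mean signal − mean local
background)/sd(local background).

CORS normalization multiplies each sample by (mean CORS total across
samples)/(that sample's CORS total); afterwards all CORS totals equal the
reference exactly (to machine precision). Removed measurements are masked
zeros and are treated as true zeros downstream — an abundance
interpretation, appropriate for Bray–Curtis.

Detection: a probe is detected in a group when present (unmasked, > 0) in
≥ 3 of that group's samples (configurable), and detected overall when
detected in ≥ 1 group. Both the per-group table and per-sample detected
counts are emitted because summary figures can be phrased either way.

Family aggregation sums surviving normalized intensities per family and
conserves total signal exactly.

## Community statistics

* **Bray–Curtis** d = Σ|x−y| / Σ(x+y) on sample columns; a pair of
  all-zero samples gets d = 0 with a warning.
* **ANOSIM** uses mid-ranks for ties; R = (r̄_B − r̄_W)/(M/2), M = N(N−1)/2.
  R is invariant under strictly monotone transforms of the distances.
* **adonis/PERMANOVA** (one-way): SS_T = Σd²/N, SS_W = Σ_g Σ_{i<j∈g} d²/n_g,
  F = (SS_A/(a−1))/(SS_W/(N−a)), R² = SS_A/SS_T. SS_W = 0 yields an
  infinite-F sentinel with a warning.
* **MRPP**: δ = Σ_g (n_g/N)·mean within-group distance; A = 1 − δ/E(δ),
  where E(δ) under label permutation equals the mean of all pairwise
  distances exactly (the group weights sum to one), so no Monte Carlo
  estimate of the expectation is needed. Small δ is extreme, so p counts
  permuted δ ≤ observed.
* **p-values**: Monte Carlo p = (1 + #extreme)/(1 + n_perm), default
  n_perm = 999, seed required for reproducibility. When the number of
  distinct label arrangements is ≤ 10,000 the tests switch automatically
  to full enumeration and report the exact fraction.
* **Ordination**: CA by SVD of the chi-square standardized matrix
  (algebraically identical to reciprocal averaging); sample scores are
  column principal coordinates, axes ordered by eigenvalue, sign fixed so
  each axis's first non-zero score is positive. DCA detrends axes ≥ 2 by
  segment-wise centering against axis 1 (default 26 segments); nonlinear
  rescaling is not applied.
* **Response ratio**: RR = ln(x̄_t/x̄_c); SE² = s_t²/(n_t·x̄_t²) +
  s_c²/(n_c·x̄_c²) with sample (ddof = 1) variances; CI uses the normal
  quantile (1.959964 at 95%), not Student's t — documented because at
  small n this costs roughly a point of coverage. A zero group mean makes
  RR undefined and is reported as such, never as ±inf.
* **Array-vs-NGS**: pooled mode averages each profile over its samples
  and correlates the family vectors (Pearson, t-transform p); per-family
  mode correlates across shared samples per family and counts significant
  families at α. The detection floor is the minimum NGS relative abundance
  among families with non-zero array signal.

## Simulators

`simulate_sequences` draws one random ancestor per family and mutates each
member independently at per-site rate m chosen so that the *expected
pairwise* identity between members equals the request: two members agree
at a site with probability (1−m)² + m²/3, giving
m = ¾(1 − √(1 − 4(1−p)/3)). Background decoys are ancestor-free random
sequences GC-matched to the targets. Every mutation site is recorded in
the truth file.

`simulate_experiment` models intensity(probe, sample) = family abundance ×
probe affinity × LogNormal(1, cv) + Normal(background, sd), floored at 0.
Affinity decreases linearly from 1 to 0.5 with the rank of the probe's
perfect-duplex ΔG (most stable first). Family base abundances are
lognormal (median 20,000 signal units, σ = 0.5) unless overridden; fold
changes multiply abundances in every non-control group. CORS probes sit at
a fixed level with 5% noise; measurements drop out independently at rate
0.02. Defaults: 12 samples per group (two groups), noise CV 0.2,
background 200 ± 50. The sequence and experiment generators use separate
RNG streams derived from (seed, 0) and (seed, 1), so one probe set can be
reused across many experiment replicates, and identical seeds give
byte-identical outputs.

What the simulator does **not** emulate: spatial slide artifacts, dye
chemistry, probe-specific cross-hybridization bleed-through (probes only
ever see their own family's abundance), saturation, and correlated noise
between neighboring spots. Passing tests therefore demonstrate the
correctness and calibration of the computations under a clean signal
model, not robustness to every artifact of real scans.

## Verification scale and calibration checks

The shipped checks run at desk scale, sized to keep the whole suite in a
few minutes: specificity oracles on 1,000 random 50-mer/≤1-kb pairs;
exhaustive-enumeration agreement on all tested layouts with N ≤ 6; type-I
error of ANOSIM/adonis/MRPP over 1,000 simulated null experiments
(12 + 12 samples, 99 permutations per test — under exchangeability the
p-value convention makes the nominal level exactly 0.05); response-ratio
CI coverage over 1,000 replicates at n = 30 per group with lognormal
σ = 0.2 and true fold change 4 (a regime where the delta-method normal CI
is expected to be near-nominal; empirical coverage runs ≈ 94%); and the
design partition on two 5-member families at 98% identity plus 100
decoys. MRPP is additionally cross-checked against `vegan::mrpp` and
ANOSIM/PERMANOVA statistics against scikit-bio's implementations.

## Known limitations

* The ΔG model ignores mismatch stacking and loop penalties, so it
  understates the stability of near-matched duplexes with isolated
  mismatches; thresholds are calibrated for this conservative scale.
* The profile scorer is ungapped; indel-rich families should be recruited
  via an external HMMER run and the domtblout importer.
* Reverse-strand and CDS-boundary-spanning probes are not designed
  (forward-strand, within-CDS windows only).
* DCA implements detrending only; the nonlinear axis rescaling of classic
  implementations is intentionally omitted.
* At database scale, non-targets sharing no 12-mer with a probe are
  reported with zeroed worst-case statistics rather than exact small
  values; only reported magnitudes below the seed-detectable regime are
  affected, never classification.
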