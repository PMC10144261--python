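# Methods

This note documents the models and procedures implemented in `svatk`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used at
boundaries.

## Mass arithmetic

Residue masses are standard monoisotopic chain masses (free amino acid
minus water), embedded as six-decimal constants so results cannot drift
with external tables; water (18.010565 Da) is stored once and added per
peptide. A substitution's shift is Δ = m(obs) − m(wt), which is
antisymmetric by construction. Isobaric lookup is an exhaustive scan over
every ordered pair of distinct configured residues plus every registered
modification, returned in deterministic order (ascending |Δ_query − Δ|,
then alphabetical); with 21 configured symbols this is a few hundred
comparisons and needs no indexing.

Methylnorleucine (Mnl), an Ile-position misincorporation product seen in
recombinant antibodies, is modeled as Ile/Leu + CH₂ (+14.01565 Da) and
shipped as a default non-canonical symbol; its exact chemistry is
configurable. Heavy-isotope modifications obey
Δ_heavy = Δ_light + n(¹³C) × 1.0033548 Da. The default heavy
carboxymethyl label carries two ¹³C (+60.0122 Da): the reagent's label
count is a configuration choice, and two atoms already clear the
+58.0055 Da substitution isobar by ~400× the 0.005 Da matching tolerance.

## Digestion

Cleavage sites are inter-residue positions (cut after residue *i*,
1-based); C-side enzymes cut after a member residue, N-side enzymes before
one, and trypsin suppresses cuts before proline by default (the standard
search-engine convention; configurable). Asp-N cleaves N-terminal to D
only, per sequencing-grade convention. Protein termini always count as
specific termini.

Fully specific peptides are spans between cleavage boundaries with at most
`max_missed_cleavages` internal sites (trypsin and Asp-N default 2;
thermolysin unlimited) and length within bounds (default 1–50 residues;
thermolysin capped at 40 to bound the combinatorics of a cutter with ~40%
site density while keeping every practically observable peptide).
Semi-specific enumeration adds every sub-peptide of a fully specific
peptide that retains exactly one specific terminus; this is equivalent to
filtering all substrings by the semi-specific predicate, which is how the
test oracle checks it. Peptide sets are deduplicated by span and sorted,
so enumeration order cannot leak into results.

## PSM schema and validation

All modules consume one CSV schema (one row per PSM: location, charge,
observed/theoretical m/z, precursor ppm, score, engine, retention time,
XIC area, modifications, optional variant call named `{wt}{pos}{obs}_{chain}`).
Engine scores are opaque dimensionless numbers — the toolkit ingests, never
recomputes, search results. On read, the stated precursor ppm is recomputed
from the m/z pair and must agree to 1e-3 ppm; floats are serialized with
shortest round-trip repr so write∘read is byte-stable and read∘write is
field-identical.

Two config profiles are built in. `high_res` (default): score cutoff 225,
MS1 tolerance 2.0 ppm, MS2 5.0 ppm, XIC window 10 ppm, quantification
limit 0.2%. `legacy` (ion-trap MS2): cutoff 15, ±8 ppm precursor, 0.8 Da
fragment tolerance. The cutoff of 225 is the calibration outcome the
score-sweep machinery reproduces: it is the largest round cutoff that
still retains every 0.2% variant in the spiked fixture, whereas 250 loses
three of seven.

## Triage semantics

Rules annotate; nothing is deleted. A PSM is `false_positive` iff at least
one rule or gate triggers, and its comment names every triggered rule
exactly once (the comment is parseable back to the rule set).

- **R1 (semi-tryptic, K/R uninvolved).** Scoped to trypsin PSMs whose span
  classifies as semi-specific. "Involved" is formalized as: wildtype or
  observed residue is K/R, or the variant position immediately flanks the
  nonspecific terminus (position s−1 or s for a nonspecific N-terminus at
  s; e or e+1 for a nonspecific C-terminus at e). Those are exactly the
  cases where a substitution can create or destroy a tryptic site and
  legitimately explain the semi-tryptic observation.
- **R2 (terminal residue).** The call's Δ is matched against every
  canonical residue mass within 0.005 Da (comfortably above 2 ppm
  precursor error at peptide masses, far below the 0.036 Da minimum
  spacing between distinct residue masses); the matched residue must occur
  within 2 residues of either terminus of the observed peptide. Both the
  window and tolerance are configurable. Only additions (positive Δ) are
  considered by default; a flag extends the rule to residue-loss shifts.
- **R3 (below quantification limit).** Strictly below the limit triggers;
  a level at the limit is kept (the assay requirement is to detect
  variants at ≥ the limit). A 1e-9 guard keeps levels sitting exactly at
  the limit from flipping on float rounding.
- **R4 (orthogonal redundancy).** A non-trypsin variant PSM triggers when
  the same variant site (protein, position, observed) has at least one
  trypsin PSM scoring at or above the cutoff — one confident tryptic
  identification being the minimal defensible meaning of "well covered".
  Trypsin PSMs never trigger R4.
- **Gates.** Score strictly below the cutoff (score ≥ cutoff counts as
  detected) and |precursor ppm| strictly above the MS1 tolerance.

Retained-count monotonicity in the score cutoff holds on generator output
and ordinary data; it is not guaranteed against adversarial inputs where
raising the cutoff both disqualifies a tryptic witness (un-flagging an R4
duplicate) and leaves the duplicate above the cutoff.

## Quantitation

Relative quantitation is the variant's share of the peptide pool,
100·A_v/(A_v + A_wt) — for sub-percent variants numerically
indistinguishable from the variant:wildtype ratio, but a single convention
must be fixed and the pool share is the one that reads a 0.5% spike as
0.5%. Areas are summed across charge states and enzymes before ratioing
(ratio of sums, not mean of ratios). The wildtype partner is the
unmodified PSM with the identical span and enzyme when present, else the
shortest fully specific covering peptide; a variant with no covering
wildtype is reported with a missing-wildtype flag rather than dropped.
Reports print one decimal; full precision is kept internally.

## Acquisition model

The simulator is phenomenological, built to make one bias auditable rather
than to model trap physics. Species elute as Gaussians in ion flux. Per
MS1 scan at total flux R: nominal fill time t_nom = min(t_max, AGC/R)
(defaults 120 ms, 4×10⁵); the space-charge proxy is κ × fill-fraction with
κ = 5 ppm at full fill, so the aggressive 0.75 ppm threshold gates
essentially the whole elution of an abundant peptide while a 100 ppm
threshold never fires; in DDA mode, when the proxy exceeds the threshold
the actual fill time is divided by the gating factor G (default 10 — the
bias mechanism does not depend on G, which only raises variance).
Detected ions are Poisson(flux × t_act); reported intensity is N/t_act,
which is unbiased — the under-quantitation is carried entirely by the
dominant-gain parameter γ (default 2.0): species holding ≥ 30% of the
detected ions in a gated scan report γ × N/t_act, reflecting the observed
~twofold inflation of abundant-ion signal under gating. Why the real
instrument exhibits the bias only in DDA acquisition is not asserted; the
model simply scopes gating to DDA mode.

XICs are trapezoidal integrals of reported intensity over MS1 scan times
(area, not apex, because sparse MS1 sampling is exactly what degrades
XIC peaks); quantitation requires ≥ 3 scans with signal per species. The
guaranteed scans-per-peak count for a ±2σ window at duty-cycle cadence c
is ⌊4σ/c⌋, and a design check warns below 8, the accepted floor for robust
peak areas. With gating off the estimator is unbiased (verified over 50
seeds per level at a 3σ band — a 2σ band falsely flags ~5% of unbiased
runs); with gating on and γ ∈ [1.6, 2.0], a 0.5% spike reads 0.25–0.32%,
matching the observed direction and magnitude of the bias.

Default scenario sizes: 60 s runs, σ = 2 s peaks, 0.25 s MS1 scans
(240 scans, ~32 per peak), apex flux 10⁶ ions/s total for unbiased runs
and 10⁷ for gated runs (the higher flux drives the trap to full fill so
the gated fraction of the peak, and hence the bias, is stable). These
sizes give sub-percent relative Poisson error on the minor species while
keeping a full simulation under a millisecond.

## Synthetic projects

The generator emulates the spike-study design used to calibrate the score
cutoff: two chains (HC 450, LC 214 residues) sampled at ~10% K/R density
with small residues enriched; wildtype PSMs for every 0-missed tryptic
peptide (areas lognormal around 10⁶, scores uniform 260–420, precursor
errors N(0, 0.5 ppm) clipped to ±1.5); then, at distinct protein
positions on distinct full-tryptic slots:

- **7 true SVs** at 0.2% with two charge-state PSMs each; three sites draw
  both scores in [226, 249) and four in [260, 420), so the fixture's best
  scores are ≥ 225 with exactly three in [225, 250).
- **20 semi-tryptic plants** (R1): one-residue N-terminal truncations with
  a substitution ≥ 2 residues from the nonspecific junction.
- **10 terminal-residue plants** (R2): substitutions whose Δ sits within
  0.004 Da of a residue mass present in the peptide's two-residue terminal
  window (in practice G→N, G→Q, A→Q).
- **10 below-limit plants** (R3): levels uniform in [0.05, 0.15]%.
- **10 orthogonal duplicates** (R4): Asp-N/thermolysin PSMs at the true SV
  sites, scores in [226, 248] so they can never carry a site past a 250
  cutoff on their own.
- Optional high-ppm decoys (3–7 ppm) for high-res vs legacy comparisons.

Substitutions for true SVs and R1/R3 plants are drawn from "safe" pairs —
non-K/R, |Δ| > 0.02 Da, and not within 0.007 Da of any residue mass — so
no plant can trip a rule other than its own class. Variant XIC areas are
set from the paired wildtype area so the planted level is recovered
exactly by the quant convention. Everything derives from one seeded
generator with sorted iteration, so equal seeds give byte-identical
files.

What the generator does **not** emulate: chimeric spectra, retention-time
structure, charge-state-dependent ionization, isotope envelopes,
missed-cleavage area redistribution, score/level correlation, or real
search-engine score distributions. Passing tests therefore demonstrate the
correctness of the triage/quant logic under the stated study design, not
the false-positive rates to expect on real peptide maps.

## Numerical conventions and limitations

Boundary semantics: score ≥ cutoff is detected; level ≥ limit is
quantifiable; |ppm| ≤ tolerance passes. Percent reductions round half-up
to integer percent. Report rendering and CSV output are byte-deterministic
for fixed inputs (no timestamps).

Known limitations: no FDR estimation or spectrum re-scoring; no reading of
vendor raw files or mzML (the PSM CSV is the ingestion boundary); the
acquisition model is not a space-charge/coalescence simulation; Table-style
comparisons of real biotherapeutic runs require real data and are out of
scope — the toolkit reproduces the arithmetic and the decision logic, and
the simulator reproduces the acquisition bias mechanism.
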