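# Methods

This note documents the models behind `scrkit`, the defaults that matter, the
assumptions built into the synthetic-data generators, and the places where a
genuinely open design choice was made.

## Codon/anticodon algebra

Degenerate codons use the 15 standard IUPAC nucleotide symbols; expansion is
the per-symbol cross product, so its cardinality is the product of symbol-set
sizes. Translation uses the standard genetic code (64 codons, 3 stops).
Codons are held in the DNA alphabet, anticodons in RNA; both alphabets are
accepted on input. Anticodon→codon readout is the reverse complement read as
mRNA 5′→3′.

Wobble decoding implements the classical rules for an unmodified anticodon
position 34 pairing codon position 3: G34→{C,U}, U34→{A,G}, C34→{G},
A34→{U}. Modified-nucleoside rules (e.g. inosine) are deliberately out of
scope; the ruleset argument exists so they could be added without changing
the interface.

Amino-acid diversity of a degenerate codon **excludes stop codons by
default**. This matches the convention used when quoting the expressed
diversity of a library position (NHH expands to 36 codons encoding 15 amino
acids plus the TAA stop, and is quoted as 15); a flag includes stops for
users who need the raw partition.

## Library accounting

A library spec is an ordered list of positions, each either a codon position
(three IUPAC symbols, parent amino acid) or a nucleotide position (one
symbol, parent base). DNA-level diversity is the product of codon/nucleotide
counts; expressed-level diversity replaces codon counts by distinct
amino-acid counts. Totals are exact integers; the two-significant-figure
scientific presentation is a formatting layer. A fixed position (degeneracy
of size 1) is representable and contributes a factor of 1.

Parent-inclusion checks report, per position, whether any codon in the
expansion encodes the stated parent. An unreachable parent raises a warning
but is never "fixed": a selected clone carrying a residue its position's
degeneracy cannot encode is a real observation (spontaneous mutation or
record error) that the analyst must see, not something software should
resolve.

Clone sampling is uniform over *codons*, not amino acids, reflecting
transformation of a degenerate-oligo library: two-codon amino acids are
twice as likely as one-codon ones.

Coverage is occupancy — the expected fraction of distinct variants present
among `T` uniform transformant draws, `1 − (1 − 1/D)^T`, computed stably via
`expm1`/`log1p`; the Poisson form `1 − e^{−T/D}` agrees to ~1e−9 relative at
library scales. Fold-coverage (`T/D`) is not what a unique-transformant count
measures, so it is not reported.

## Reassignment efficiency

The screen's statistic is a two-point calibration: per replicate,
`E = 100 (S − S_0)/(S_100 − S_0)`. It is affine-invariant, so instrument
background and gain cancel; no separate blank subtraction is performed (the
0% reference absorbs background). References are averaged within the plate
before normalization; replicate statistics are mean ± sample SD (ddof = 1)
across biological replicates. Estimates are never clipped to [0, 100]; an
out-of-range mean is flagged instead.

The signal `S` is the time-averaged OD-corrected fluorescence: the pointwise
ratio F/OD integrated by the trapezoid rule over a window and divided by the
window span. The window defaults to 0–240 min from the start of the recorded
series (i.e. it treats time zero as induction); both endpoints are
configurable since plate protocols differ on whether recording starts at
inoculation or induction. Averaging the ratio rather than the endpoint value
makes the statistic robust to growth-profile differences between systems —
the stated purpose of OD-correcting over a multi-hour window.

The lysate variant applies the identical normalization to fluorescence per
protein amount (gel-quantified), with a `brightness_correction` factor that
rescales the 100% reference when the test chromophore differs photophysically
from the reference chromophore (an azide-substituted fluorophore has roughly
10% apparent brightness). With a correction of 1 the two statistics are the
same function. Gel-quantification uncertainty enters through the per-protein
ratio; to first order a relative protein error of δ adds δ·E to the
efficiency error, and the replicate SD is assumed to absorb it (no separate
propagation term is reported).

The detection limit defaults to 0.2% and the comparison is strict (`<`);
boundary equality counts as detectable.

## Multi-site incorporation

Incorporation at each of `n` target codons is modeled as an independent
Bernoulli event with probability `p` (the single-site efficiency). The fully
substituted yield is `p^n` — at `p = 0.5`, `n = 3` it is 12.5% — and the
species mixture over the number of substituted sites is binomial. Site-to-site
correlation (codon context, mRNA structure) is real but unquantified here;
the binomial is the stated headline model, not a mechanistic claim.

## Growth fitness

"Instantaneous doubling time" is the maximum specific growth rate: a window
of fixed width slides over ln(OD), each window gets an ordinary
least-squares line, and `t_d = ln 2 / max slope`. OD is floored at 0.005
before the log so blank-level noise cannot dominate; the floor and window are
configurable.

The default window is **9 points**. This was set by a prospective variance
analysis rather than convention: with multiplicative OD noise of CV 0.02 and
10-minute sampling, a 5-point window has a per-window slope standard error of
≈3.6% of a 40-min-doubling slope, and taking the *maximum* over many windows
turns that into recovery errors of up to ~10%; a 9-point window (≈80 min,
one to two doublings) brings worst-case recovery under 4% in the same
regime while remaining well inside a typical exponential phase. On noiseless
exponentials any window width ≥ 3 is exact, and the estimate is invariant to
OD rescaling.

Relative system fitness is `100 · t_ref/t_test` (control over test): a
slower test system scores below 100%, a faster one above. The exact value is
retained; presentation rounds to the nearest integer. Error bars on doubling
times are SDs across replicate curves, not single-fit standard errors.

Carrying capacity is the maximum of the moving-median-smoothed OD series
(default 5-point kernel); the median filter exists solely to reject isolated
spikes.

## Intact-mass species assignment

Average masses are used throughout because deconvoluted intact-protein
masses at ~8 kDa are average-mass centroids (a monoisotopic table is
available). Canonical residue masses come from standard elemental
compositions; the noncanonical residues are compositional:
pAzF = Phe + N₃ − H and pAmF (the reduced amine) = Phe + NH₂ − H, giving
+32 and +6 Da at an arginine site, versus +7 Da for tyrosine. The default
"methyl" modification is the average CH₂ mass, 14.027 Da, treated purely as
a mass offset (no site assignment).

Species enumeration crosses site options with all modification subsets and
deduplicates hypotheses within 0.1 Da. Peak assignment matches each peak to
the nearest hypothesis within a tolerance (default 1.5 Da; ties to the lower
mass). Because the tyrosine (+7) and amine (+6) species differ by only 1 Da,
both can fall within tolerance of one peak: the assignment is then flagged
ambiguous and a warning is emitted — mass alone cannot separate them, which
is exactly why ±ncAA control samples are needed, and the package never
infers the azide-vs-amine reduction state. Relative species abundance from
summed assigned intensities is labeled semi-quantitative (equal electrospray
response is assumed). The reporter's base mass is user-supplied, not
computed, because a full construct sequence is often unavailable; when one
is available `protein_average_mass` computes it.

A `pick_peaks` step (local maxima above 5% of the base peak) reduces a
gridded profile spectrum to centroids before assignment.

## FACS campaign simulation

Each round: (1) screen `N` cells as a multinomial draw from current variant
frequencies; (2) give each cell a lognormal fluorescence whose **median** is
its variant's efficiency on the 100%-reference scale (identity brightness
map — the screen's core linearity assumption) with CV 0.3, a typical
single-cell GFP spread; (3) retain the brightest `⌊qN⌋` cells; (4) renormalize
and amplify the retained census by a fixed factor (default 25, matching the
regrowth of the original transformant pool; configurable since later-round
amplification is usually unrecorded). Gating on sampled cells, not the
analytic distribution, preserves founder effects at realistic scales (10⁷
screened from ~10⁹). Growth-rate differences between variants during
amplification are out of scope — compose with `growth_fitness` if needed.
A gate that retains zero cells raises a campaign-collapse error.

`sample_clones` draws single clones (with replacement) from the post-sort
frequencies and reports the fraction exceeding a reference efficiency,
mirroring plate-and-pick clone analysis.

Scenario files for the CLI list explicit variants (id, efficiency,
abundance). Deriving a population from a library spec plus an
efficiency-assignment rule was considered and left out: no measured
efficiency landscape anchors such a rule, and users who have one can compose
`library_design.sample_clone` with it in a few lines.

## Synthetic data: what it does and does not emulate

* **Growth**: logistic OD with multiplicative lognormal read noise
  (CV 0.02), initial OD 0.01, doubling time 40 min, carrying capacity 1.2,
  read every 10 min for 10 h. No lag-phase stochasticity, no diauxie, no
  evaporation drift.
* **Screen**: OD from the same logistic; fluorescence per OD is
  `s0 + E (s100 − s0)` — linear in the true efficiency `E`, which is
  precisely the assumption the two-reference normalization requires, so
  round-trip tests certify the estimator *given* linearity, not the
  linearity itself. Noise: per-timepoint instrument CV 0.05 on each channel
  and a per-well lognormal expression factor of CV 0.03 (biological
  replicate scatter). Twelve test wells and twelve wells per reference
  system, the replication level at which the screen's published-style
  SDs (~1–5 percentage points) arise naturally. No maturation kinetics,
  no plate-edge effects, no medium autofluorescence drift.
* **Spectrum**: sum of Gaussians (σ = 1 Da) at the species masses on a
  0.5 Da grid with additive Gaussian baseline noise (1% of base peak),
  clipped at zero. Deconvolution artifacts (satellite peaks, adducts) are
  not modeled.

Every generator is a pure function of its config (which contains the seed):
same config, byte-identical output.

## Numerical choices

* Coverage via `expm1`/`log1p` for `D ≫ 1`.
* Sample SD with ddof = 1; a single replicate reports SD 0.
* Doubling-time slopes below 1e−12 /min are treated as non-growth (pure
  rounding noise on a flat curve would otherwise produce absurd positive
  slopes).
* Peak-assignment ties (equidistant hypotheses) go to the lower mass,
  deterministically.
* Degenerate-codon expansions and all set outputs are sorted for stable
  serialization.

## Known limitations

* The binomial incorporation model ignores codon-context correlation, and
  measured efficiencies are reporter- and position-dependent; numbers from
  different reporters should not be compared as absolutes.
* The FACS model has no instrument optics (spillover, doublets, gate
  placement error) and identity brightness mapping; enrichment factors are
  relative, not predictive of sorter throughput.
* Mass-based abundance is semi-quantitative; the Tyr/pAmF 1-Da ambiguity is
  surfaced, never resolved.
* The screen statistic assumes the reporter is far from saturation; strongly
  nonlinear fluorophore maturation would bias all systems together but is
  not modeled.
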