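# Methods

This note documents the models, parameter choices, and numerical conventions
behind `diaforge`, and what the simulator does and does not emulate.

## Mass arithmetic and digestion

Peptide and fragment m/z use standard monoisotopic residue masses (from
pyteomics), proton 1.007276 Da and water 18.010565 Da. Precursors:
(Σ residues + mods + water + z·1.007276)/z; y-ions carry the water, b-ions do
not; modification deltas apply only to residues a fragment covers. Stored
precursor m/z must agree with the recomputed value to 1e-4 Th or validation
fails. Digestion is tryptic — cleave C-terminal of K/R except before P — with
up to two missed cleavages enumerated; a peptide's stored missed-cleavage
count must equal the value derived from its sequence.

## Transition selection and decoys

For each (peptide, charge) the top 5 library-spectrum peaks are kept that
match a theoretical y/b fragment within ±0.035 Th (greedy smallest-|Δm/z|
matching, each peak and each theoretical fragment used at most once), with
series ordinal in [3, n−1], fragment charge 1–2, and m/z outside ±5 Th of the
precursor (half the 10 Th isolation width). Intensity ties break toward lower
fragment m/z, then y before b. Decoys are per-peptide shuffles of the
non-C-terminal residues (tryptic character and precursor mass preserved),
reshuffled on collision with any target up to 20 times, then a deterministic
+8 rotation; fragment m/z are recomputed from the shuffled sequence while
library intensities are copied from the target so the decoy intensity
distribution matches.

## Filter cascade

Steps 1–4 are static rules (allowed PTMs = Met-oxidation and
Cys-carbamidomethylation only; repeated or protein-shared peptides removed;
≥4 transitions per precursor; no missed cleavages). Step 5 removes a peptide
only when its best peak group's dotp is below 0.8 in *every* training sample
(strictly below: 0.80 survives). The dotp consulted is that of the most
intense candidate peak group, not the maximum dotp over candidates — a faint
baseline bump has a deceptively high square-root-transformed cosine, so
taking the maximum would defeat the filter. Step 6 requires ≥2 peptides per
protein. Step 7 codifies manual curation, aggregating per population:

1. a transition is dropped if, in ≥ half the samples of any population, its
   trace has an off-target maximum (inside the ±3 min window, outside the
   peak boundaries) exceeding its on-target apex;
2. a precursor is dropped if undetected (best apex S/N < 3 against the
   median absolute smoothed intensity in the window) in ≥ half the samples of
   any population — "clearly discernable" is not numeric in manual practice,
   so S/N ≥ 3 is the operationalization;
3. a precursor is dropped if, within a population, the median FWHM of the
   wider half of samples exceeds 2× the median of the narrower half;
4. a precursor is dropped if more than one transition is rule-1-flagged in
   the same sample, in ≥ half the samples of any population.

The ≥ half-of-one-population aggregation for rules 1 and 4 mirrors rule 2's
stated criterion; per-sample aggregation was the open alternative. After
rule application the ≥4-transition and ≥2-peptide constraints are re-applied,
since transition removal can re-violate them. All censuses are recorded per
step and are non-increasing by construction.

## Extraction, calibration, peak detection

Isolation windows: step = width − 2·edge_overlap, n = ceil(range/step); the
"0.5 m/z overlap" convention is read as 0.5 Th shared per edge, which is the
reading that reproduces 75 windows over 390–1065 m/z at 10 Th width.
Precursors assign to the window with the nearest center (ties to the lower
index). XIC extraction sums all peaks within ±0.035 Th per time point (the
library-matching tolerance reused; no separate extraction tolerance is
defined). iRT calibration is ordinary least squares on (iRT, RT) of the 16
standards with up to two rounds of 3σ outlier rejection; an exact fit
(residual SD < 1e-9 min) stops rejection immediately. Peak groups are local
maxima of the Savitzky–Golay-smoothed (window 7, order 2) summed trace
within ±3 min of the predicted RT; boundaries sit at the flanking minima or
the 1%-of-apex crossing, whichever is nearer; per-transition areas are
trapezoidal over the boundaries; FWHM is interpolated at the half-maximum
crossings. At most 10 candidates per (precursor, sample) are scored.

## Scoring and q-values

Five subscores per candidate: dotp (cosine of square-root-transformed library
vs observed intensity vectors), coelution (mean pairwise Pearson correlation
of transition traces within the boundaries; constant traces contribute 0;
a single transition scores 1), absolute RT deviation, log10(1 + total area),
and apex S/N. Training is semi-supervised: iteration 0 ranks by dotp; each of
3 iterations takes targets at q < 0.15 as positives and all decoys as
negatives, fits a pooled-covariance linear discriminant with ridge 1e-6 on
standardized features, and rescores; the weight vector is normalized and
oriented toward targets. One global model is fitted per run set (stable at
small sample counts; per-file models were the alternative). q-values use
target–decoy counting: FDR(s) = (1 + #decoys ≥ s)·(N_t/N_d)/max(1,
#targets ≥ s), minimized over thresholds ≤ s and clipped to [0, 1]. The +1
pseudo-count makes the estimator conservative — with N targets the smallest
attainable q is 1/N, so a q ≤ 0.005 working point needs at least 200
accepted targets. Quantitation takes the best-scoring peak group per
(precursor, sample) at q ≤ 0.005.

## Quantitation and inference

Transition areas enter as log2(1 + area); per-sample medians are equalized by
shifting each column to the grand median of column medians (within-sample
contrasts untouched; post-condition exact). Protein summarization is Tukey's
median polish per protein (rows = transitions, columns = samples), with
missing peaks imputed as zero intensity before the log transform — a
documented simplification of censored-value handling. The sweep arithmetic
and the residual-sum stopping rule mirror R's `stats::medpolish` exactly
(row sweep first; the median of the opposite margin's effects moves into the
overall term after each sweep; stop when the sum of absolute residuals is
stable to a relative 1e-6 or after 10 sweeps by default), because on
even-sized matrices the sweeps can cycle without per-sweep changes reaching
zero; the implementation agrees with the R reference to 1e-6 on random small
matrices. Protein abundance per sample = overall + column effect.

Differential testing is a fixed-effects linear model per protein — log2
abundance on a one-vs-rest population indicator, plus additive
sampling-batch terms in combined analyses — with a two-sided t-test on the
group coefficient and BH correction across proteins within a comparison.
With one summarized measurement per biological replicate this coincides with
the mixed-model formulation. All proteins share the design matrix, so the
fit is a single linear solve; it is verified against a reference OLS
implementation in the tests. Significance calls combine adjusted p < 0.05
with a fold-change floor: 2.0 for separate-batch comparisons (n = 6 per
population), 1.45 for the combined comparison (n = 24).

The power formula is the classical two-sample normal approximation
Δlog2 = (z_{1−α/2} + z_{power})·√(2σ²/n), with σ the log2-scale SD implied by
the anticipated CV (σ = √ln(1 + CV²)/ln 2) and α the FDR level. It implies
FC(4n) = √FC(n); calibrating σ so FC(6) = 2.0 (power 0.8, α = 0.01) gives
FC(24) = √2 ≈ 1.414, within 3% of the 1.45 produced by the FDR-anticipating
variant used in dedicated proteomics power tools — agreement, not equality,
is the design claim.

## Reproducibility statistics

Per (protein, population, batch) the one-vs-rest log2FC and adjusted p define
"significant" as adj_p < α and |FC| ≥ threshold. A false positive in a focal
batch is a significant protein whose FC in *any* other batch lies beyond the
reciprocal threshold in the opposite direction (FC ≥ 2 here, ≤ 0.5
elsewhere). A false negative exceeds the FC threshold in the consensus
direction (sign of the mean log2FC across batches) but misses significance.
A population's signature is the set of proteins significant in the same
direction in *every* batch. Volcano tables carry the standard class labels
(significant at 0.01 / at 0.05 only / not significant; elevated vs reduced)
with fold changes clipped to ±4 in plot coordinates and flagged.

## Simulator

The generator emulates the study design the statistics are built for: 4
populations × 6 biological replicates × 4 sampling batches (96 samples), 200
proteins with 2–3 peptides each, 10% of proteins per population carrying a
±1.5 log2 fold change (disjoint sets across populations). Protein base
abundances are log-normal (log2 mean 14, SD 1.5 across proteins); replicate
variation uses a 30% biological CV, with ~15% multiplicative technical noise
per precursor × sample and 5% per transition, for a total CV near the ~35%
implied by calibrating the power formula to FC 2.0 at n = 6. Peptides get
iRT ~ U(0, 100), log-normal ionization responses (ln-SD 0.3) and Dirichlet(1)
fragment profiles over 5 y-ion transitions. Each sample has a linear iRT→RT
map (slope U(0.7, 1.3), intercept U(0, 20) min) plus 0.1 min RT jitter per
peptide; peaks are Gaussian with log-normal FWHM around 0.3 min (ln-SD 0.25)
on a 0.1-min grid spanning ±4 min; the baseline is Poisson with mean 15
counts. Interferences (rate 0.03 per target precursor × sample) add a
half-amplitude Gaussian 1–2.5 min off-apex on one transition and are recorded
in a registry; 5% of target peptides are designated signal-free (baseline
only), as are all decoys. Sixteen iRT standards are spiked bright into every
sample. Observed fragment m/z jitter is uniform within ±8 ppm. Everything
derives from one seed via independent child streams, so outputs are
bit-reproducible.

Deliberate simplifications: Gaussian peaks (no tailing), centroid-free
trace-level rendering (no raw-spectrum synthesis; the XIC extractor is
exercised on small explicit spectra tables instead), no isotope envelopes,
no charge-state interference, uniform residue usage in random proteins (with
K/R every 6–15 residues so digestion is productive). Tests passing on this
simulator show the pipeline's logic and calibration are correct under its
assumptions; they do not certify behavior on real chromatography artifacts
(tailing, drift, co-eluting isobars beyond the injected interference model).

The planted-violation cascade fixture (~21 proteins) builds one entry per
filter rule — disallowed PTM, shared and repeated peptides, 3-transition
precursor, missed cleavage, inverted fragment profile (dotp ≈ 0.59),
single-peptide protein, interfered transitions (3× apex), an undetectable
precursor, 4×-widened peaks in half of one population, and a 4-transition
precursor that loses one to interference — and its expected final census is
computed from the plant registry itself (which entries were built to
survive), independently of the filter implementation.

## Problem sizes

The bundled validation experiments use: 1000 target peptides (200
signal-free) + 1000 decoys × 2 samples × 10 seeds for FDR calibration; the
full 200-protein, 96-sample design for the end-to-end run; 500-protein
matrix-level simulations for inference calibration; 50 random ≤6×8 matrices
for the median-polish cross-check; 100 seeded fits for iRT recovery. These
sizes were chosen as the smallest designs at which the quantities being
checked (an FDP bound, a recovery rate, a type-I error rate) are estimated
with comfortable margin relative to their thresholds.

## Known limitations

- Missing peaks as zeros biases low-abundance proteins downward relative to
  censored-likelihood summarization; acceptable here because comparisons are
  within-protein across samples.
- The decoy q-value floor of 1/N makes very small target sets unable to
  reach stringent cutoffs; this is the intended conservatism of the
  pseudo-count.
- Peak boundaries and smoothing are a concrete, documented stand-in for
  proprietary peak pickers; equivalence with any particular vendor tool is
  not claimed.
- The CLI serializes chromatograms as TSV only; at very large scale a binary
  container would be preferable.
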