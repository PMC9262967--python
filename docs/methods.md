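# Methods

## Mass model

All masses are monoisotopic and derived from an embedded isotope table
(CODATA/AME values, ≥6 decimal places); no literature decimal is used as
a runtime constant. Peptide neutral mass is the sum of residue
compositions plus water plus modification deltas; m/z at charge *z* is
(M + z·1.00727646688)/z; cation m/z (oxonium, TMT reporters) subtracts
one electron mass from the neutral-atom composition.

The three deglycosylation remnant signatures are computed, not stored:
HexNAc-Fuc = mass(C8H13NO5) + mass(C6H10O4) = 349.1373 Da, HexNAc =
203.0794 Da, deamidation = mass(Asp) − mass(Asn) = 0.98402 Da. The
deamidation delta cannot be a non-negative elemental composition (it
removes NH and adds O), so `Modification` carries a plain mass delta
with an optional composition. A deamidated asparagine is exactly
isobaric with aspartate; site localization therefore relies on fragment
ions, and the search treats the two identically when they produce
identical fragment ladders (deterministic tie-break, see below).

The TMT 10-plex label is fixed at C8 13C4 H20 N 15N O2 (229.162932 Da);
reporter cations are C8H16N+ with the channel-specific 13C/15N
substitutions, which reproduces the 6.32 mDa N/C channel spacing from
the isotope table.

Reference oxonium ions are the HexNAc fragment series C6H8NO2+,
C7H8NO2+, C8H12NO4+ and C8H14NO5+ (m/z 126.0550, 138.0550, 186.0761,
204.0866). Published tables sometimes print the third ion as 186.066
and the intact HexNAc oxonium as 204.0966; both disagree with the
elemental composition, so matching always uses the computed values with
the fragment ppm tolerance. One further ion (HexNAc-Fuc, C14H24NO9+,
m/z 350.14) is tabulated for reference but not used for validation.

## Digestion and sequons

Lys-C + trypsin sequential digestion is modeled as trypsin specificity
(cleave after K/R, not before P) since Lys-C sites are a subset of
tryptic sites. Peptides are fully specific, ≤2 missed cleavages, length
6–50 by default. Protein N-terminal methionine is not clipped and I/L
are kept distinct. The KP/RP suppression default is a package decision:
search engines differ on it, and it is exposed as a flag.

Sequons are N-X-S/T with X ≠ P. When a sequon's +1/+2 context extends
past a peptide's C-terminus it is resolved against the parent protein,
so C-terminal asparagines are classified correctly. All reported
positions are 1-based protein coordinates.

Modification forms are enumerated combinatorially with static
carbamidomethyl-C and dynamic oxidation-M plus the three remnant
signatures, at most 3 dynamic mods per peptide (the budget is a package
decision; it bounds the form count while covering the observed
multi-site peptides). Remnant mods are only placed on sequon
asparagines — a deliberate constraint that mirrors the biological
attachment rule and keeps the search space tractable.

## Spectrum conditioning and triage

Conditioning is: (1) denoise by a relative-intensity floor (default
0.5% of the base peak — the published workflow's denoising algorithm is
unspecified, so a deterministic, config-exposed rule was chosen);
(2) square-root intensity transform; (3) top-100 peak selection on the
transformed intensities. Oxonium triage asks whether the HexNAc oxonium
(m/z ≈ 204.087) is within tolerance of one of the 10 most abundant
peaks ranked by *original* intensity. Validation scans the whole
spectrum for any of the four HexNAc-series ions at the fragment
tolerance (no dedicated tolerance is published for these ions).

## Search and scoring

A sorted array of every theoretical b/y fragment m/z (charges 1–2, plus
HexNAc and — for CF remnants — HexNAc-Fuc neutral-loss companions) maps
each peak to candidate peptide forms in O(log n). Forms with ≥6 fragment
hits among the top-100 peaks are re-scored against the full spectrum:
Morpheus score = matched fragment count + matched share of total
(sqrt-transformed) intensity, counting a fragment as matched if its
monoisotopic or +1/+2 isotope companion (spacing 1.00335483/z) hits a
peak. The best form wins; ties break by higher intensity fraction, then
lexicographically smaller sequence — fully deterministic and
order-independent.

The precursor-minus-peptide mass gap is interpreted at the precursor
tolerance (10 ppm): ≈0 means a fully deglycosylated or remnant-only
peptide; a match in the glycan composition database (default
combinatorial HexNAc 2–7, Hex 3–12, Fuc 0–4, NeuAc 0–4) records an
intact-glycopeptide assignment; anything else invalidates the PSM.
PSMs must also cover >10% of total spectrum intensity (strict).

An optional precursor-isotope filter scores the cosine similarity
between an observed MS1 envelope and an averagine-Poisson model
(λ ≈ 4.75·10⁻⁴·M, from averagine's 0.0444 carbons/Da × 1.07% ¹³C);
without envelope input the filter passes, and the threshold default is
permissive because no published value exists.

Decoys are reversed proteins sharing all digestion/modification rules.
q(s) = min over thresholds s′ ≤ s of #decoy(≥s′)/#target(≥s′), computed
over tie groups, monotone by construction; targets with q < 0.01 are
retained. When a decoy database was searched but no decoy PSM survives
the candidate filters, the empirical FDP is 0/t = 0 and all q-values
are 0.

## Site calling

A remnant PSM yields a glycosite call only if: the modified asparagine
is a sequon re-checked against the protein; CF/HexNAc PSMs carry ≥1
validation oxonium ion in their spectrum (evidence is per spectrum and
supports all remnant sites of a multi-sequon PSM); and the peptide does
not carry HexNAc-Fuc and HexNAc simultaneously (excluded wholesale —
potential in-source fucose loss makes the classes indistinguishable).
CF together with deamidation on different sequons is a legitimate
multi-site product and yields both calls. Unique sites are keyed by
(accession, position); peptides shared between proteins produce one
call per protein flagged as shared evidence, since no protein-inference
rule is published for shared glycopeptides.

Flank analysis extracts ±10 residues around each unique CF site;
per-position frequencies are relative to observed (non-gap) residues,
so terminal truncation does not distort them; the center position is N
with frequency 1 by construction.

## Quantification

Reporter intensities are the nearest peak within tolerance of each
computed reporter m/z, summed over a site's supporting spectra.
Normalization divides by the pooled reference channel per row, takes
log2, and median-centers each channel (idempotent; medians are exactly
0 afterwards). Rows quantified in ≤75% of non-reference channels are
dropped (strict inequality). The unpaired test is Welch's two-sided t
on log2 values (the published description says only "two-sided t test";
the equal-variance variant is available behind a switch) with BH
adjustment; the paired test is a two-sided paired t on per-pair log2
differences, all-zero differences giving p = 1 by convention. Effect
size is the difference of group medians on the log2 scale; direction
flags require FDR < 0.01 and |FC| ≥ 1.5 (unpaired) or p < 0.05 and
FC > 1.5 (paired) — the boundary is inclusive for the "≥" phrasing and
strict for ">". No missing-value imputation is performed; untested rows
are reported as such. Median centering removes any effect shared by all
rows, so fold changes are interpretable only when regulated sites are a
minority — the recovery tests plant effects on ≤20% of rows.

CV is 100·sd/mean (sample sd), undefined below two values.

## Synthetic data generator

The generator emulates the post-laboratory statistical structure the
pipeline assumes: proteins are i.i.d. uniform over the 20 residues
(~150–400 aa) with sequons planted by triplet substitution (Poisson
mean 2 per protein, ≥4 residues apart so two sequons can share a
tryptic peptide); each observable site draws a remnant class from the
enzyme-specificity mixture (CF 0.50, deamidated 0.40, HexNAc 0.10);
spectra contain the form's full charge-1 b/y ladder with neutral-loss
companions (log-normal intensities, σ = 0.6), each validation oxonium
ion with probability 0.95 (the triage ion emitted hot so it ranks in
the top 10), TMT reporter peaks with planted ±1 log2 tumor effects
(15% up, 5% down, channel noise σ = 0.25 log2, reference = mean of
sample channels emulating a pooled reference), and 30 uniform noise
peaks at ~1% intensity scale; 2 spectra per site; 100 additional
unmodified-peptide spectra; 50% entrapment proteins present in the
FASTA but never generating spectra. The drawn CF+HexNAc combination on
one peptide is redrawn (those products are excluded by the pipeline
anyway); a config switch can force it for testing the exclusion rule.
One RNG stream keyed by the seed drives protein/site assignment, with
per-spectrum substreams keyed by (seed, spectrum index); identical
seeds give byte-identical FASTA/MGF output.

What the generator does **not** model: real proteome sequence
composition and homology, chromatography and co-isolation, charge-state
envelopes beyond a mass-based 2/3 choice, isotope patterns beyond +1/+2
companions, TMT isotope impurity, and missingness mechanisms other than
reporter absence. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical assumptions, not
performance on real tissue data.

## Problem sizes and numerical choices

The full-scale verification study uses 200 target proteins (+50%
entrapment, reversed decoys on top) and ~640 spectra — large enough for
stable sensitivity/FDR estimates while keeping a complete run in
minutes on one CPU. Tolerance comparisons are two-sided ppm windows;
all sorting uses stable algorithms and all tie-breaks are total orders,
so results are independent of spectrum and peptide enumeration order
and of thread count (the engine is single-threaded by design).

## Known limitations

- Remnant mode is the primary path; intact-glycopeptide (mass-gap) mode
  shares the scoring machinery but has no neutral-loss model for full
  glycans beyond the composition lookup.
- Deamidation calls are genuinely ambiguous against genomic aspartate
  and spontaneous deamidation; the pipeline reports them as a class
  rather than resolving the ambiguity.
- The mzML reader supports centroided MS2 with 32/64-bit float,
  optionally zlib-compressed peak arrays only; vendor formats and
  profile data are out of scope.
- Protein-level rollup uses a simple peptide-count threshold; no
  parsimony inference.
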