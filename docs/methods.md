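# Methods

## Model of the measurement

An amino-acid analyzer reports the relative abundance of free amino acids in
a protein hydrolysate. Three facts of hydrolysis chemistry shape everything
downstream:

* **Deamidation pooling.** Gln deamidates to Glu and Asn to Asp during acid
  hydrolysis, so Q/E are quantified together as **Glx** and N/D as **Asx**.
  Pooled quantitation is safe because the members of each pair have nearly
  equal masses (Gln 146.15 vs Glu 147.13 g/mol from elemental composition).
* **Tryptophan.** 6 M HCl hydrolysis destroys Trp (recovery 0); 4 N
  methanesulfonic acid (MSA) preserves it (recovery 1).
* **Relative quantitation.** The detector (ninhydrin) reports relative
  channel content; measured tables are therefore renormalized on read, with
  the raw column sum kept as metadata so either reading of an unnormalized
  chromatogram is preserved.

A `HydrolysisScheme` is the pair (residue→channel map, per-residue recovery
ρ ∈ [0,1]). Three named schemes exist: `intact` (identity, all ρ = 1, for
sequence work), `hcl` and `msa` (pooled channels; ρ_W = 0 and 1
respectively). Cysteine recovery defaults to 1 under both hydrolysate
schemes but is configurable (`recovery_overrides={"C": …}`), since acid
hydrolysis degrades Cys in practice and the appropriate correction is
instrument-specific.

The composition of a protein is the mole fraction of each channel,

    f_c = Σ_{r: map(r)=c} n_r ρ_r / Σ_r n_r ρ_r ,

i.e. recovery is applied **before** normalization and the result
renormalized — the model of an analyzer that reports relative content of the
channels it can see. Mixtures weight each component's counts by chain-molar
amount (`molar_chain`) or by mass divided by polymer chain mass (`mass`).
Compositions are count-based throughout ("percentage of amino-acid
numbers"); mass-based weighting enters only through mixture weights.

Ambiguity codes: B feeds the Asx channel and Z the Glx channel (they are
exactly the pooled pairs), U counts as Cys, X is dropped from counts and
from the length denominator with a warning. B/Z are errors under `intact`,
where no pooled channel exists to receive them.

Free amino-acid masses are computed from elemental formulas with IUPAC 2021
standard atomic weights (C 12.011, H 1.008, N 14.007, O 15.999, S 32.06,
Se 78.971); chain mass is the sum of residue masses plus one water.

## Enrichment calling and ranking

Fold change is the per-channel ratio case/control after replacing control
fractions below ε by ε (default ε = 1e-4, logged when used, so an empty
control channel cannot yield an infinite ratio). The default calling rule —
the single channel with the strictly greatest fold change, provided it
exceeds 1 — encodes the expected signature of a deposit built from one
residue class: that channel rises while every other channel is diluted. A
`threshold` mode (all channels with fold change ≥ cutoff) covers
dipeptide-repeat-like deposits that enrich two channels at once.

Ranking scores every candidate by its fraction of the target channel under
the measurement's scheme; ties share the smaller rank and are ordered by id,
so output is deterministic and permutation-invariant. Candidates with no
recoverable residues are excluded with a warning.

Profile similarity reports two metrics on purpose — Pearson r of channel
fractions and the base-2 Jensen–Shannon divergence (in [0,1], 0 iff equal) —
because a visual "the profiles look alike" claim has no single canonical
statistic; neither is privileged in any pass/fail logic. Pearson is reported
as missing for constant vectors.

The mixture fraction is the argmin over f ∈ [0,1] of the Euclidean distance
between the measured vector and f·candidate + (1−f)·background (bounded
scalar minimisation, xatol 1e-7, endpoints checked). The objective is convex
in f, so the optimum is unique whenever candidate ≠ background; the
degenerate case is flagged instead of fitted. The residual is reported so a
poor two-component fit is visible.

## LCR / CBR scanning

Two sliding-window scans, both 0-based half-open, both deterministic:

* **Low complexity** (SEG-like two-threshold scheme): windows with Shannon
  entropy ≤ k_trigger seed segments; a maximal run of consecutive windows
  with entropy ≤ k_extend containing at least one trigger window becomes a
  segment spanning first window start to last window end. Segment score is
  the minimum window entropy.
* **Residue bias**: for a queried residue set with background mass p₀, each
  window of length w with observed count k gets the exact binomial upper
  tail P(X ≥ k), X ~ Binomial(w, p₀); windows at or below p_threshold form
  segments as above (single threshold). Score is −log10 of the smallest
  tail, computed through the log survival function to survive underflow.

Segments closer than merge_gap are merged (idempotent; scores keep the most
extreme value, residue sets are unioned). Coverage is union length over
sequence length and refuses overlapping input — merging is upstream.

Defaults: window 25, k_trigger 2.2 bits, k_extend 2.5 bits, p_threshold
1e-6, merge_gap 10, uniform 1/20 background (an average SwissProt frequency
table is provided as an alternative). A 25-residue window resolves the
50–100-residue quasi-repeat domains typical of deposit proteins; 2.2 bits
admits windows dominated by ~4–5 residue types; 1e-6 on a 25-window demands
roughly ≥ 9 hits of a residue set with p₀ = 0.1, i.e. a strong local bias.
Per-window tails are diagnostics, not hypothesis tests: windows overlap and
no multiple-testing correction is applied.

## Synthetic experiments

The generator emulates the case/control design the pipeline assumes:

* **Background proteome**: n (default 50) proteins, lengths lognormal with
  log-mean 5.8 and log-sd 0.45 (median ≈ 330 residues, a realistic
  proteome-wide distribution), residues i.i.d. from SwissProt-average
  frequencies.
* **Spike**: a random 50-residue head plus a tandem repeat of a 20-mer unit
  that is 50% Ser / 30% Gly (a glycine/serine-rich quasi-repeat of the kind
  deposit proteins carry), 30 units by default (≈ 650 residues).
* **Mixtures**: control = equal-molar background; case = background at
  1 − w plus the spike at chain-molar weight w (default 0.4). Because the
  spike is longer than the average background chain, its residue-level
  fraction is higher (≈ 0.55 at defaults); that value is computed at
  generation time and stored as ground truth, since it is what the
  mixture-fraction fit estimates.
* **Detector noise**: per-channel multiplicative lognormal with mean 1 and
  CV 0.03 (default), followed by renormalization — keeps fractions positive
  and mimics relative-quantitation error. One seeded numpy Generator is
  threaded through all draws; no global state.

What the generator does **not** model: LC–MS/MS identification noise beyond
plain background proteins, chromatographic peak shapes, and non-protein
material in real fractions (lipofuscin and other autofluorescent debris).
Passing the recovery tests therefore shows the inference chain is sound
under its own assumptions, not that real fractions are free of confounding
background.

## Pipeline

`run_pipeline` chains enrich → rank → similarity → CBR scan → fraction for
the top target channel (`all_targets` analyses every called channel). The
bias scan for the top candidate queries the residues feeding the target
channel. The mixture background is the equal-weight mixture of the remaining
candidates. Reports are JSON with a config echo, package version and sha256
input checksums, and contain no timestamps, so identical inputs produce
byte-identical reports. Exit codes: 0 success, 3 no channel called, 4 input
error. Human-readable TSVs use 1-based closed coordinates; everything
internal is 0-based half-open.

## Numerical and design choices

* Composition vectors validate non-negativity and Σf = 1 to 1e-9 at
  construction; every vector carries its scheme tag and operations refuse
  mixed-scheme input.
* The enrichment example sizes are small enough that all suite-level
  simulations (including the 100-seed recovery study) run in seconds.
* The positive-control construct is a packaged FASTA labelled as a synthetic
  reconstruction (huntingtin exon-1 head + polyQ tract + proline-rich tail
  fused to EGFP); `construct_nhtt_egfp(n)` edits only the tract, so any two
  lengths share all non-tract sequence. The 190Q/21Q pooled-Glx ratio it
  yields under `hcl` is 2.68.
* The hydrolysate channel order (Asx, Thr, Ser, Glx, Pro, Gly, Ala, Cys,
  Val, Met, Ile, Leu, Tyr, Phe, His, Lys, Arg, Trp) follows analyzer elution
  and is fixed for stable tables and plots.

## Known limitations

* Single measurements per fraction are assumed (no replicate-level
  statistics across chromatograms).
* One candidate is fitted at a time; no simultaneous multi-candidate
  deconvolution.
* No disorder prediction or tandem-repeat period inference — the scans
  annotate composition only.
* The accession-based checks against the real 19-protein candidate list
  need a one-time UniProt fetch (`scripts/fetch_table1.py`); the library
  itself performs no network access.
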