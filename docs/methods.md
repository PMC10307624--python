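# Methods

`phosphokin` implements a phosphoproteomics inference chain for
ligand-stimulation experiments: phosphosite-group quantification and
differential statistics, collapse to one fold change per site,
cross-species phosphosite position transfer by global alignment,
kinase-activity inference via a substrate-set z statistic, and
interaction-network / enrichment assembly. A synthetic-data generator with
recorded ground truth stands in for deposited mass-spectrometry data and
drives all calibration studies.

## Quantification model

Peptide observations carry a protein accession, the set of phosphorylated
S/T/Y positions, a run label (condition x timepoint x replicate), and a
log2 intensity. Peptides with an identical (protein, phosphosite-set) form
one *phosphorylation site group* — set equality, not overlap, so
`{S15}` and `{S15, T20}` are distinct groups. Within a run, a group's
peptides are **summed on the linear scale** and re-logged. The aggregation
operator was a genuinely open choice (sum, mean, or a model fit would all
be defensible); summing preserves total ion signal and is the package's
documented assumption.

Runs are **equal-median normalized**: each run is shifted additively on
the log2 scale so its median equals the grand median (median of
pre-normalization run medians). Any common target constant cancels in fold
changes; the grand-median choice makes normalization idempotent. The
post-condition (equal medians) holds to 1e-9 and is tested.

Each stimulation condition is contrasted against its **time-matched
unstimulated control**. The per-site statistic is a two-sided two-sample
*t* test; the **Welch (unequal-variance)** form is the default because it
is the robust choice at n = 2–3 replicates; the classical pooled form can
be obtained by comparison against `scipy.stats.ttest_ind` if needed.
Degenerate inputs: when both groups have (numerically) zero variance and
equal means, p = 1; otherwise a variance floor of 1e-8 keeps the statistic
defined. Sites observed on only one side of a contrast get log2FC = ±inf
and an undefined p. Benjamini–Hochberg correction is applied **within each
contrast** over the defined p values, mirroring per-timepoint testing.

Per (site, contrast), multiple records (several site groups containing the
site) are collapsed by the **lowest-p rule**: infinite fold changes are
discarded, then the record with minimal p wins; ties break by larger |FC|
and then lexicographic site-group key for determinism. Proteins "changed in
phosphorylation state" are those with at least one site under the FDR
threshold (default 0.05) in at least one timepoint of a ligand.

## Ortholog position transfer

Source-species sites are converted to target-species coordinates by
Needleman–Wunsch global alignment of each designated ortholog pair. The
aligner is `Bio.Align.PairwiseAligner` with **BLOSUM62, gap open −10, gap
extend −0.5** (affine; end gaps penalized). The original analysis used an
R aligner's unnamed "default parameters"; this standard protein scheme is
the package's substitute and is exposed in configuration, so mapped
positions can differ from the original at alignment-ambiguous edge cases.
When tracebacks tie, the aligner's first traceback is taken, which is
deterministic for fixed inputs. A site whose alignment column holds a
target gap is unalignable and dropped (with a logged count); a site landing
on a different or non-S/T/Y target residue is retained but flagged
`residue_conserved = False` by default (a switch drops such sites) so the
substrate sets are not silently shrunk. Coordinates are 1-based throughout.

Correctness is checked two ways: scores must equal an exhaustive
enumeration of all global alignments for short random pairs (the
enumeration scores gap runs independently of the aligner), and transferred
positions must match the synthetic generator's exact edit-script ground
truth on mutated ortholog pairs.

## Kinase activity

For kinase K with m >= 2 measured substrate sites in a contrast,

    z = (M − u) / se,   se = sd / sqrt(m),   p = 2 (1 − Φ(|z|))

where M is the mean collapsed log2FC over K's measured substrate sites and
(u, sd) are the mean and sample SD (ddof 1) of **all** finite site fold
changes in the contrast. Reading "in terms of standard error ... against
the overall distribution" as the background-SD form is the standard
substrate-enrichment (KSEA) convention; the substrate-set SD is available
behind `use_substrate_sd`. Substrates are not excluded from the background
(the background is the overall distribution); kinases with fewer than two
measured substrates are omitted, never zero-filled. A multiply-
phosphorylated site group contributes once per kinase even when several of
its positions are annotated substrates. Significance is flagged on the raw
two-tailed p at alpha = 0.05, matching the unadjusted z-test cutoff
convention for activity displays; a BH-adjusted column is emitted
alongside. Differential regulation between two ligands is displayed as the
per-timepoint z difference.

The statistic inherits location and scale invariance from its form, and
the background (u, sd) is computed after the ortholog step in the pipeline
so substrates and background share one coordinate space.

## Network and enrichment

Changed phosphoproteins form the core node set; edges come from a
combined-score association table and are kept when score **> 0.4
(strictly)**. Isolated core proteins remain as nodes because they carry
phosphorylation states. Up to ten expansion nodes are added, ranked by the
sum of their above-threshold edge scores to the current nodes (ties
lexicographic) — a re-specification of "functionally related" nodes that
an external database service would rank internally. Each node carries one
state per timepoint: the signed log2FC of its largest-|FC| significant
site, or absent.

Enrichment is the upper-tail hypergeometric test P(X >= k) with BH
correction, filtered at FDR < 0.05. The universe defaults to proteins with
at least one quantified phosphosite (the detected background, the standard
guard against detection bias), not a whole annotation. Redundant terms are
pruned greedily by ascending FDR, dropping any term whose **Jaccard
similarity** of overlap gene sets with a kept term is >= 0.5; the original
tool's redundancy metric is unspecified, so Jaccard is the package's
stated substitution.

## Synthetic data generator

The generator emulates the study design: two stimulation ligands x two
timepoints x time-matched unstimulated controls, n = 2–3 replicates
(default 3; n >= 2 is enforced). Protein sequences are random over the 20
amino acids with S/T enriched ~2.5-fold and Y ~1.5-fold so phosphosites
exist; orthologs derive from single-residue substitutions (rate 0.05) and
single-residue indels (rate 0.02) with the exact position map recorded
(longer gaps arise only from adjacent indels, keeping the truth exact).
Site-group log2 intensities are Normal(mu, noise_sd) per replicate with mu
~ Uniform(18, 28) and noise_sd = 0.3 by default — the intensity
distribution of real data is unknown, and the normal-on-log2 model is an
explicit assumption. Planted kinase activity adds a fixed log2FC (default
1.5) to all substrate sites of an active kinase in its active conditions.
Per-run additive offsets (SD 0.7) make normalization non-trivial; each
measurement is dropped independently with probability 0.1, which exercises
the infinite-FC path; ~20% of sites get a second peptide with the same
site set and ~25% of adjacent site pairs also appear as doubly-
phosphorylated peptides, exercising grouping. One master seed feeds
fixed-offset child generators per stage, so tables are byte-identical
across reruns.

What the generator does **not** emulate: peptide detectability and
intensity-dependent missingness, correlated noise between sites of one
protein, ragged phosphosite localization uncertainty, and real
kinase-substrate annotation structure. Passing calibration here shows the
statistics behave as designed under the stated model, not that real
spectra would yield the same site lists.

## Reference validation studies

- **Alignment oracle** — 500 random pairs, lengths <= 6: aligner score
  must equal the exhaustive-enumeration optimum on every pair.
- **Transfer recovery** — 40 proteins (length 200–400) mutated at
  substitution 0.05 / indel 0.02: >= 95% of surviving S/T/Y sites must map
  to the true position (observed ~99.6%).
- **Null calibration** — 200 simulations with no planted shifts, each 120
  proteins / ~540 sites / 50 kinases x 10 disjoint substrates, one
  contrast per simulation (the z statistic is per-contrast, so one
  contrast loses no generality and keeps the study fast): fraction of
  kinases at p < 0.05 must lie in [0.03, 0.07], and pooled z values must
  pass a Kolmogorov–Smirnov test against N(0, 1) at the 1% level. The
  slight conservatism expected from substrates being part of the
  background (variance factor 1 − m/n) is within the window.
- **Planted recovery** — 100 simulations with 5 of 50 kinases shifted by
  1.5 at noise 0.3, n = 3: the planted kinases must occupy the top-5 |z|
  ranks in >= 95% of simulations.

These sizes are the package's reference conditions and are used unchanged
by both the test suite and `scripts/acceptance.py`.

## Known limitations

- The per-site t test at n = 2–3 has limited power; with the default demo
  size (40 proteins) few sites clear the site-level FDR, so demo networks
  are small. Kinase-level inference pools substrates and is well powered
  at the same settings.
- Protein accessions may not contain underscores (they delimit the
  canonical site-group key).
- Ortholog *pairing* is an input; the package does not detect orthologs,
  convert identifier namespaces, or query any live service.
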