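# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic-study generator does and does
not emulate, and the numerical and design choices made where the
procedure left room.

## The comparison design

The unit of analysis is a *clade*: one or more fully heterotrophic
species compared against ≥ 2 photosynthetic (autotroph) references from
the same lineage, mirroring the mycoheterotroph study design of a pair
of *Epipogium* species against three photosynthetic orchids and
*Hypopitys monotropa* against photosynthetic Ericales. All group
statistics are heterotroph × autotroph pairwise comparisons aggregated
within the clade; nothing is ever pooled across clades.

## Filtering cascade

Defaults (`FilterConfig`): minimum mean coverage 3 reads/position
(inclusive — a transcript at exactly 3.0 is kept), minimum CDS length
30 aa, contamination e-value cutoff 10⁻⁵, plant clade "Streptophyta".

* **Major isoform**: per gene, the isoform with the most mapped reads;
  ties break to the lexicographically smallest transcript id, making
  the selection order-invariant.
* **ORF model**: an ORF is a maximal stop-free codon run in any of the
  six frames; 5′-partial runs (frame start to first stop) are allowed.
  An ORF qualifies by length (≥ 30 aa) or by carrying a supplied domain
  hit — a sub-minimum ORF rescued by a domain hit is accepted and
  counted in the filtering report (`sub_min_cds_rescued`), since domain
  evidence is the stronger signal. The longest qualifying ORF wins;
  exact ties break deterministically (+ strand, then lower frame, then
  smaller start). Coordinates are 1-based inclusive on the forward
  transcript; minus-strand ORFs keep transcript coordinates with a
  strand flag. `five_prime_complete` means the run starts with ATG and
  either an in-frame stop precedes it or ≥ 3 nt of transcript lie
  upstream; only such proteins are meaningful inputs for transit-peptide
  prediction. Codons containing N never count as stops. Hexamer coding
  potential is deliberately out of scope.
* **Contamination**: decided solely by the single best hit (highest bit
  score) among hits at e ≤ 10⁻⁵; lineage containing the plant clade →
  plant. No hits → plant (absence of evidence is not treated as
  contamination). A bit-score tie including a plant hit → plant,
  consistent with that retention bias.
* **RBH orthology**: a query whose top bit score is tied has no unique
  best and yields no pair — "1–1" requires uniqueness on both sides.

## Group-wise GO enrichment

Direct annotations are closed under is_a ancestry before counting, so a
gene annotated "photosystem I" also counts for "plastid" and every
other ancestor. Genes encoded in the plastid or mitochondrial genome
are removed first (their loss reflects organelle-genome reduction, not
nuclear gene content); `n_total` is the number of remaining genes with
≥ 1 term.

Per term and per heterotroph × autotroph pair, a two-sided Fisher exact
test compares (genes with term, genes without) between the two species.
A term × pair test is skipped only when the count is zero in *both*
species of the pair; zero in one species is precisely the signal of a
total loss and remains testable. The Fisher p is computed by the
point-probability method — the sum of hypergeometric probabilities of
all tables with the observed margins not exceeding the observed table's
probability, with a 1 × 10⁻⁷ relative tie tolerance, matching the
convention of mainstream statistical software. It is implemented with
log-gamma arithmetic in-package because the FDR validation runs
hundreds of simulated studies (≈ 10⁵ tests) where per-call overhead
dominates; equivalence with exact enumeration and with an independent
library implementation is enforced by tests.

**Group aggregation.** Each pair has a direction, sign(heterotroph
fraction − autotroph fraction); equal fractions are compatible with
either. If the non-zero directions agree, p_group = min(1, n_pairs ·
max p) — a Bonferroni bound on the hypothesis that *every* pair
deviates, which is the claim a group-level "underrepresented" call
makes. Conflicting directions give direction `mixed` and p_group = 1.
The alternative n_pairs · min p rule is available
(`EnrichmentConfig.group_rule="min"`) but not default: it tests "at
least one pair deviates", a weaker claim that is vulnerable to a single
aberrant assembly.

**FDR.** Benjamini–Yekutieli (via statsmodels) once per clade across
all tested terms. BY rather than Benjamini–Hochberg because propagated
GO counts are strongly positively dependent (every gene counted for a
term is counted for all its ancestors); BY is valid under arbitrary
dependence at the cost of the c(m) = Σ1/k inflation. Significance:
q ≤ α, default α = 0.05.

**Effect size.** Median over pairs of (heterotroph fraction / autotroph
fraction). Pairs with both counts zero are skipped; autotroph fraction
zero against a positive heterotroph count gives +∞; with an even number
of pairs the median is the midpoint of the central two and is reported
as +∞ when either central element is infinite (no finite midpoint
exists). Terms with no eligible pair are excluded with an explicit
error. Counts in the output table are propagated counts, consistent
with what the tests consume.

## Loss parallelism

Core set: genes flagged as having a reference-proteome 1–1 ortholog and
present in every autotroph, removing assembly-quality and
lineage-specific artifacts from the denominator. The overlap
percentage uses the *larger* loss set as denominator; this is the
convention under which the published expected values ("~16 %") are
internally consistent across all three species pairs
(100·min(|A|,|B|)/N gives 16.7, 15.2 and 15.2 for the printed counts),
and it is configurable (`denominator="min"`). Shared-loss counts
reconstructed from a printed percentage are rounded to the nearest
integer.

The upper tail P(X ≥ k), X ~ Hypergeometric(N, K, n), is summed in log
space from log-gamma point masses; the log₁₀ p is reported alongside p
and remains accurate (checked against exact rational arithmetic) far
below the double-precision underflow horizon. Absence here means "not
recovered from the transcriptome assembly", which overstates genomic
loss for weakly expressed genes; the pairwise report carries that
caveat as a footnote rather than modelling it.

## Organelle targeting

A classA (TargetP-style) call is accepted at reliability class ≤ 4; a
classB (DualPred-style) call is dual at score ≥ 0.5. Reconciliation per
variant: accepted plastid/mitochondrion + dual → **dual**
(non-contradictory, the dual score subsumes the single-organelle
signal); accepted call + agreeing single call → that compartment (a
classB "other" is compatible with classA "secretory", since the dual
predictor has no secretory class); accepted call + disagreeing
non-dual classB → contradictory; rejected classA + any organellar
classB support → **contradictory** (one-tool-only evidence is reported,
not accepted — `TargetingConfig.accept_single_tool=True` relaxes this);
otherwise none.

Truncation emulates alternative downstream translation starts: the
suffix from the first Met at 1-based position ≥ 26 ("after the first 25
residues"), retaining that Met as initiator. Across variants (full,
truncated, isoforms) the per-protein verdict takes the precedence dual
> plastid > mitochondrion > secretory > contradictory > none — dual
ranked first because it implies plastid import capability; the
precedence order across variants is this package's choice (the
procedure it mirrors did not need one), and the supporting variant is
recorded so conflicts stay visible.

Substitute nomination for plastome-lost ribosomal genes: proteins
hitting the lost gene's family HMM at e ≤ 10⁻⁵, minus the 1–1 orthologs
of the plastid gene itself; verdict plastid/dual ⇒ import-capable,
contradictory ⇒ single-tool. Families without a lost-gene mapping are
skipped.

## Selection shifts

statistic = max(0, 2(lnL_free − lnL_constrained)) against χ²(df); df is
the parameter-count difference, defaulting to 1 (two-ratio vs one-ratio
branch models differ by one dN/dS). A free likelihood below the
constrained one beyond 1 × 10⁻⁶ triggers a warning and clamping —
an optimizer artifact, not evidence. p-values are floored at 10⁻³⁰⁰
and Bonferroni-multiplied by m (default: number of genes tested; m is
a config input because the relevant gene family can define a smaller
m, e.g. the five chlorophyll-pathway genes). Significant genes with
heterotroph dN/dS above (below) the autotroph value are classified
relaxed (intensified). Fits with dS > 0.5 are flagged as
saturation-suspect, not corrected.

## The synthetic-study generator

All stages draw from per-stage child streams of a single integer seed
(`numpy.random.SeedSequence` with CRC32 stage keys), so identical
configs give byte-identical outputs file by file.

* **Ontology**: a rooted random is_a DAG (default 150 terms, depth 5,
  1–2 parents per term); eight deepest leaves are flagged
  photosynthesis-like. Planted terms are structurally ordinary.
* **Annotation**: 15 % of genes form a photosynthesis module carrying
  1–2 planted terms plus 1–2 background terms; the rest carry 1–4
  background terms. This mirrors real GO structure, where
  photosynthesis categories are large (tens to hundreds of member
  genes); at the default 2000 genes it gives planted terms ≈ 40–80
  members, enough for the Fisher tests to resolve a 0.9-vs-0.1 loss
  differential at this scaled-down study size. Under the no-signal null
  (equal loss probabilities) loss indicators are i.i.d. across genes
  and species, so every term — planted or not — is null and the FDR
  check is valid; term *sizes* are not exchangeable between module and
  background.
* **Losses**: autotrophs keep everything; heterotrophs lose
  planted-module genes with probability 0.9 and others with 0.1. With
  probability c = 0.6 a gene's loss indicator is drawn once and shared
  by all heterotrophs, otherwise independently per species — a single
  parameter controlling exactly the excess overlap the hypergeometric
  test detects.
* **Transcripts**: 1 + Poisson(0.7) isoforms per retained gene;
  negative-binomial read counts (mean 200, dispersion 0.5) and
  log-normal coverage (μ = 2, σ = 1 on the log scale) — heavy-tailed
  like real RNA-seq, though the exact laws are a modelling choice, not
  an estimate. Each gene gets one planted CDS (ATG + 38–198 non-stop
  codons + stop) shared across species, with random UTRs; FPKM is
  computed from reads and transcript length per species.
  Contaminants are added so they form 20 % of transcripts, with best
  hits drawn from a small fixed toy taxonomy of fungal and bacterial
  lineages versus Streptophyta.
* **Hit tables**: taxonomy best hits match the planted origin, flipped
  with probability `hit_noise`; directional reference-proteome hits are
  wired so true pairs are unique mutual bests except a
  `rbh_corruption` fraction whose forward best is redirected.
* **Targeting**: signals drawn per protein (dual 5 %, plastid 15 %,
  mitochondrion 10 %, secretory 5 %); classA reliability classes from
  the fixed mixture (0.4, 0.3, 0.2, 0.1) over classes 1–4, classB
  scores uniform on the matching side of 0.5. `targeting_noise`
  replaces a prediction's signal with a random one.
* **Branch fits**: null genes get ΔlnL ~ χ²(1)/2 (the LRT null);
  planted relaxed genes a large ΔlnL with elevated heterotroph dN/dS.

What the generator does **not** emulate: real sequence evolution,
read-level errors, expression-dependent detectability of genes (absence
is exact, not coverage-driven), assembly fragmentation and chimerism,
annotation-transfer errors, database-version effects, and the real GO's
multiple namespaces and regulates-edges. Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated
under the assumed generative structure — not that the original study's
specific term counts (which depend on unpublished assemblies and
database versions) are recovered.

## Problem sizes

The validation suite runs the enrichment at the design scale it
validates (2000 genes, 2 × 3 species, 150 terms) over 50 seeds for
planted-signal recovery and 200 seeds for the null FDR check; exact
oracle sweeps cover every 2 × 2 table with margins ≤ 12 and every
hypergeometric configuration with N ≤ 60. The acceptance script uses 25
and 50 seeds for its two simulation summaries and a 400-gene noise-free
study for filtering/orthology recovery; these sizes were chosen as the
package's own validation budget and are stated here so they can be
scaled up deliberately.
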