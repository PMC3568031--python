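# Methods

## Problem and model

`trionovo` operationalizes the discovery design for a sporadic disorder
assumed to arise from dominant de novo point mutations: if unrelated
probands share a phenotype, their causal variants should be (i) absent from
polymorphism databases, (ii) protein-altering or splice-disrupting,
(iii) in genes expressed in the affected tissue, (iv) recurrent across
probands at the variant or gene level, (v) absent from both parents and
from unaffected controls, and (vi) technically real. The pipeline is the
composition of those predicates, with counts reported at every boundary so
a cohort's attrition profile is always auditable.

There is no fitted statistical model: every stage is a deterministic
predicate over discrete records, which is why the package exposes pipeline
functions and report objects rather than estimator classes. Variant
identity is the 4-tuple (chromosome, 1-based position, ref, alt);
annotations (gene, consequence, protein change) are attributes. One
annotation is kept per variant; when a source supplies several, the most
severe by the fixed order of the closed consequence vocabulary
(missense, synonymous, splice_acceptor, splice_donor, frameshift_indel,
inframe_indel, other) is retained. That order is a convention of the
closed vocabulary, not a biological severity claim; it only matters for
multi-annotated inputs, which the packaged data never contain.

## Known-variant matching semantics

The novelty filter supports two modes. `allele_aware` (default) declares a
query known only when a database record matches chromosome, position, ref
and alt. `position_only` matches on coordinate alone and is retained
deliberately: it reproduces the documented failure in which a novel
substitution is discarded because a different allele at the same site is
registered (ATP1A3 D801N vs the registered D801Y at chr19:42474557). For
any input and database, position-only survivors are a subset of
allele-aware survivors, and the difference is exactly the set of variants
sharing a registered coordinate without a registered allele — both are
property-tested. `gene_refocus` is the corresponding rescue: it re-runs
the consequence filter over all variants of one gene in the
pre-novelty-filter data, which the pipeline retains for this purpose.
Indels pass the same filters as SNVs, are matched exactly (no
left-normalization at this scale) and are counted separately in reports.

## Recurrence and prevalence

Gene-level sharing counts distinct probands carrying any qualifying
variant of the gene, so a gene hit by four different substitutions in four
probands ranks alongside one variant shared by four. The default threshold
of 4 carriers is half of an eight-trio cohort — the smallest sharing worth
pursuing in this design — and is a parameter. Prevalence is reported as a
raw fraction plus an integer percent rounded half-up (19/82 → 23%).

## Trio classification and exclusion

`classify_trio` is exhaustive over the finite genotype/availability space
and verified against a brute-force enumeration of all 192 usable
combinations. Absent genotype records at a listed site mean homozygous
reference (cohort-table convention); an explicitly uncalled genotype is
`missing` and propagates to `unknown_parent`. A carrier parent dominates
(inherited even if the other parent is unavailable); both parents observed
reference means de novo. Exclusion removes a candidate that fails
confirmation, has ≥ 1 control carrier, or is inherited in every carrier
trio; one genuine de novo observation retains the candidate, and a
candidate with only `unknown_parent` statuses survives flagged
`unvalidated`. Parental mosaicism, non-paternity and genotype error are
not modelled; wet-lab confirmation is abstracted as an oracle that must
hold an entry for every queried call (a missing entry raises rather than
silently passing).

## Substitution distance and conservation

The physicochemical distance combines side-chain composition, polarity and
molecular volume: `D = ρ·[α(Δc)² + β(Δp)² + γ(Δv)²]^{1/2}` with α = 1.833,
β = 0.1018, γ = 0.000399 and ρ normalizing the mean over the 190 unordered
residue pairs to 100. Two surfaces exist deliberately. The canonical
published integer table (`GRANTHAM_MATRIX`) is what the field's annotation
tools share, and is the default for scoring; `GranthamModel` recomputes
from the properties. Recomputation reproduces 149/190 printed entries
exactly and all but one within a single unit of print rounding; the
printed Trp/Asp value (181) cannot be regenerated from the printed
properties (recomputation gives 191) and is treated as the historical
table's internal anomaly. Tests pin both surfaces: spot-checked published
integers exactly, and the ±1 agreement across all 190 pairs with the
anomaly asserted as such. Scores are computed in full precision and
reported as integers.

A trained impact classifier (e.g. PolyPhen-2) is intentionally not part of
the package; the impact stage is distance + conservation, with ranking
kept ordinal — no pathogenic/benign cutoff is asserted, since none is
defensible at this scale. Externally computed scores can ride along as
attributes.

Conservation anchors on the human reference row of an aligned orthologue
block: the fraction of non-gap homolog rows matching the human residue at
the queried column. The human row is excluded from the denominator, gap
rows are excluded, and a column with no informative homolog rows is a
degenerate-input error rather than 0 or 1. Orthologue alignments of real
genes are not packaged (they are not reproducible from printed figures);
the loader accepts any aligned FASTA, and test alignments are synthetic.

## The packaged study cohort

`fixture_paper_cohort()` transcribes the ten-patient AHC cohort: carriers
per the variant table (G755C I-1; E815K II-1/III-1/IV-1 plus the extension
patients IX-1/X-1; C927Y V-1; D801N VI-1/VII-1/VIII-1), the D801Y database
record at the D801N coordinate, the six-carrier CNTN4 call that fails
confirmation, the four inherited SYNE1 variants with 2/2/2/0 control
carriers, trios with IX-1's parents unavailable, and the clinical feature
table (respiratory abnormality, status epilepticus, epilepsy, regression,
headache, effective drug; "unknown" is legal). The published sources
disagree on which of two patients carries G755C vs E815K; the fixture
follows the variant and clinical tables, which agree with each other, and
every aggregate count (5/3/1/1 carriers) is identical under either
reading. ATP1A3 coordinates are the published chr19 positions; CNTN4 and
SYNE1 positions are synthetic placeholders on the correct chromosomes
(flagged in the module), since the study prints none. The fifteen
registered SYNE1 background variants are arranged so a SYNE1 refocus
yields 19 distinct non-synonymous keys with per-sample counts
10/10/8/10/9/8/10/9 — the study states both totals but not the overlap
pattern relating them, so the overlap is synthetic by construction.
Load-time checks assert the carrier counts.

## Simulator

`simulate_cohort` emits a labelled cohort per `SimParams`. Defaults are
the package's study conditions: 8 trios, Poisson(5000) variants per
proband, fraction chain 0.80 known → 0.40 NS/SS of novel → 0.25
brain-expressed of NS/SS, one planted de novo missense variant shared by
5 probands, artifact rate 0.02, 96 controls. The chain centres the
brain-expressed NS/SS count per proband on 100, inside the 77–129
per-patient band a comparable exome cohort shows after the same filters;
5,000 variants per proband is the desk-scale stand-in for the ~200k of a
real exome, preserving the cascade's selectivity profile at test speed.
Backgrounds are single-carrier and inherited (one parent het); registered
backgrounds may appear in controls (2% per control). Beyond the
backgrounds the simulator always plants one shared inherited decoy gene
(distinct inherited variants in min(4, n_trios) probands, two control
carriers on one) and, when artifact_rate > 0, one shared
confirmation-failing variant — the two exclusion paths the validation
stage must exercise. Truth labels record each variant's class, intended
carriers and intended trio classification at generation time, so pipeline
output is compared against intent, not re-derivation. Positions are drawn
uniquely from a synthetic 22-chromosome space; gene symbols from synthetic
pools with a flagged brain-expressed subset. All randomness flows from the
seed; identical seeds give byte-identical output files.

What the simulator does **not** emulate: read-level error processes,
allele-frequency structure, linkage, mutation-rate heterogeneity,
multi-allelic sites, parental mosaicism. Passing the recovery suite
therefore shows the *logic* is sound under the stated generative
assumptions, not that the pipeline is robust to real-data artefacts beyond
the modelled confirmation failures.

## Numerical and degenerate-input choices

Percent rounding is half-up (Decimal, not banker's). Ranking sorts by
(confirmed de novo carriers, total carriers, conservation, distance)
descending with stable genomic-coordinate tie-breaks; missing scores rank
below any present score. Variants with no gene symbol fail the expression
filter (fail-closed). Cohort unique totals count distinct keys/genes once
across samples, because per-sample sums double-count shared variants; both
are derivable from the report. An empty gene set, empty control cohort,
zero-size cohort prevalence, missing proband genotype and fully-gapped
conservation columns are errors, not defaults.

## Verification problem sizes

The test suite runs the unit and property layers on a 400-variant/proband
cohort and the end-to-end recovery suite on 20 seeds at the full default
scale (8 × ~5,000 variants, one planted variant, decoys present),
asserting exact recovery — the planted set and nothing else — on every
seed, plus the position-collision miss/refocus-rescue pair on three seeds.
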