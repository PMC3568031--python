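# trionovo

De novo variant prioritization for small trio-exome cohorts with a sporadic,
presumed-dominant phenotype.

Given per-patient variant tables, a pedigree, a known-polymorphism database,
an expression gene set, control genotypes and an orthogonal confirmation
table, `trionovo` runs the discovery logic a rare-disease exome study uses:

1. **Filter cascade** — exclude registered variants (novelty filter), keep
   protein-altering and splice-site consequences (NS/SS), keep genes in the
   expression set (e.g. brain-expressed genes for a neurological phenotype).
2. **Recurrence** — flag variants shared across unrelated probands and genes
   hit in ≥ *k* probands (default *k* = 4), even by different substitutions.
3. **Validation** — classify each candidate in its trio
   (`de_novo` / `inherited_*` / `unknown_parent`), screen the control
   cohort, and apply the confirmation oracle (the stand-in for Sanger
   re-sequencing). A candidate is excluded if it fails confirmation, is
   carried by any control, or is inherited in *every* carrier trio.
4. **Impact scoring** — physicochemical substitution distance
   (`D = ρ·[α·Δc² + β·Δp² + γ·Δv²]^{1/2}`, scaled so the mean over the 190
   residue pairs is 100) plus cross-species conservation of the substituted
   residue from an aligned orthologue block.

The package makes the known-variant **matching semantics** explicit, because
it is a real failure mode: with `position_only` matching, a novel variant is
wrongly discarded whenever a *different* allele is registered at the same
coordinate. The canonical example is ATP1A3 D801N (chr19:42474557 G>A),
which a position-only novelty filter removes because the rapid-onset
dystonia-parkinsonism allele D801Y (G>T) occupies the same position. The
default mode is `allele_aware`; `gene_refocus` re-examines all variants of a
flagged gene in the *pre-filter* data and recovers such losses.

Two data sources ship with the package: a transcription of the ten-patient
alternating-hemiplegia-of-childhood (AHC) cohort in which four de novo
ATP1A3 mutations (G755C, E815K, D801N, C927Y) were found, and a seeded
simulator that emits truth-labelled trio cohorts (planted shared de novo
variants, inherited decoys, confirmation-failing artifacts) for end-to-end
verification.

## Worked example

```python
import trionovo as t

fx = t.fixture_paper_cohort()                 # the ten-patient AHC cohort
rep = t.run_analysis(fx.exome_cohort(),       # 8 exome trios
                     fx.trios, fx.genotypes, fx.known_db,
                     fx.gene_set, fx.controls, fx.oracle)

# extend with the two Sanger-genotyped patients (IX-1, X-1)
extra = {s: {v.key: fx.genotypes.get(s, v.key) for v in fx.atp1a3.values()}
         for s in fx.extension_patients}
ext = t.extend_cohort(rep, extra)
for label, (carriers, cohort, frac, pct) in ext.prevalences.items():
    print(f"{label}: {carriers} of {cohort} patients ({pct}%)")
```

prints

```
E815K: 5 of 10 patients (50%)
D801N: 3 of 10 patients (30%)
C927Y: 1 of 10 patients (10%)
G755C: 1 of 10 patients (10%)
```

i.e. the four ATP1A3 mutations survive every exclusion (the shared CNTN4
call fails confirmation; the four SYNE1 variants are carried by controls or
inherited from healthy parents), and E815K is the recurrent mutation, in
half the cohort. Each candidate carries its per-carrier trio status — for
E815K: de novo in II-1, III-1, IV-1, X-1 and `unknown_parent` in IX-1,
whose parents declined testing — its substitution distance (E→K = 56) and,
when an alignment is supplied, the conservation of the substituted residue.

The same run from the shell:

```sh
trionovo fixture --out-dir demo/
trionovo run --config demo/config.yaml      # paths to the files written above
```

```
cohort of 8; 4 surviving candidates
  E815K: 3 of 8 patients (38%)
  ...
```

Other subcommands: `simulate` (truth-labelled synthetic cohorts), `cascade`,
`recur` (recurrence + `--refocus GENE`), `validate`, `score`, `extend`.

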