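# Methods

This note documents the model behind `comphet`, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish about behaviour on real data.

## Data model and coordinate conventions

All coordinates are 1-based inclusive (VCF convention); no 0-based
representation is exposed anywhere. Contig names are normalized on input to
the bare dialect (`1`..`22`, `X`, `Y`, `MT`) by stripping a leading `chr`;
the input dialect is detected and restored on output, so mixed-style trios
(a common artifact of mixing GRCh37- and GRCh38-aligned files) merge
cleanly. INFO values are carried as opaque strings: unknown keys survive a
read→write round trip byte-for-byte, and the model-level round-trip
`read ∘ write ∘ read = read` is tested field-for-field. Of the per-sample
FORMAT fields only `GT` is modelled: every downstream operation consumes
genotypes alone, and merged multi-sample records have no well-defined
reconciliation for other keys. gVCF reference blocks (`<NON_REF>` alt with
an `END` key) cover `pos..END` inclusive.

Genotypes are ordered allele-index pairs with a phase flag; `.` parses to a
missing allele, and half-missing genotypes such as `./1` are preserved
exactly. **Phase convention:** in a phased genotype `a|b`, `a` is the
paternal and `b` the maternal haplotype, globally. Some fixed convention is
required for trans-configuration detection, and transmitted-first ordering
is also applied to parental genotypes when phasing forces them.

## Trio preparation

Harmonization keys on `(contig, position)` only — not on alleles — so that
allele conflicts surface at merge time as multiallelic records rather than
silently dropping sites. A parental gVCF block overlapping a retained child
site certifies homozygous reference there and is collapsed to an explicit
`0/0` genotype using the child's alleles.

Merging produces one record per child record occurrence; alternate alleles
from different members are unioned in child-first order and each member's
genotype indices are remapped into the union. REF disagreement at an
identical locus is an error, not a silent multiallelic.

Site hygiene removes, with one logged reason each, in precedence order:

* `multiallelic` — more than one alternate allele after merging;
* `duplicate` — *all* records sharing a position are removed (no tie-break
  rule is defensible without allele-level duplicate semantics, and removal
  is the conservative choice for downstream phasing);
* `parents_missing` — both parents fully missing (`./.`). Half-missing
  parental genotypes count as non-missing: the rule exists to protect
  phasing, and a half-called parent still constrains transmission.

In single-sample mode the parent-dependent rule is a no-op; the others
apply unchanged.

## Mendelian phasing

At a biallelic site the child receives one allele from each parent.
The classifier enumerates every ordered pair (paternal transmission,
maternal transmission) consistent with the trio's genotypes, treating each
missing allele — in any member — as a wildcard rather than imputing it
(panel-based imputation is out of scope, and a wildcard is the weakest
assumption that keeps such sites usable):

* exactly one consistent pair → **phased**; the all-reference and
  all-alternate "trivial" cases fall out here naturally;
* more than one → **ambiguous** (canonically: child and both parents all
  heterozygous). Ambiguous sites are retained, flagged via the `PSTAT`
  INFO key, and excluded from CH pairing — without phase, a trans
  configuration is unverifiable, and a silent mis-phase would corrupt CH
  calls. The flag is also the seam where a statistical phaser could be
  plugged in;
* zero consistent pairs with both parents explicitly `0/0` and a
  single-alt child → **potential de novo**, retained unphased. Removing
  these as Mendelian errors would make de novo identification vacuously
  empty, so the single clean de novo pattern is carved out;
* zero consistent pairs otherwise → **Mendelian error**, removed.

A child with a half-missing genotype is never phased (the uncalled allele
cannot be assigned to a haplotype); it is classed ambiguous when any
transmission is consistent, error otherwise.

REF/ALT congruence repair runs **before** the Mendelian check: phasing
tools are known to emit records with REF and ALT switched relative to the
reference genome, and a switched-but-consistent site would otherwise be
falsely removed as an error. Repair compares the record's REF with the
reference sequence at its locus; on mismatch, if the single ALT matches
instead, REF/ALT are swapped and every genotype index inverted (phase order
preserved); if neither matches the site is removed as `incongruent`.
Repair is idempotent.

The classifier is verified exhaustively against an independent brute-force
oracle that expands every wildcard substitution — all 27 fully-called trio
genotype combinations plus every combination involving missing or
half-missing alleles (216 total).

## Normalization

A variant representation is normalized when it is left-aligned and
parsimonious. The algorithm: (a) while every allele ends with the same
base, truncate it; if an allele empties, prepend the reference base at
`pos − 1` and decrement `pos`; (b) while every allele starts with the same
base and all alleles have length ≥ 2, trim the first base and increment
`pos`. Multiallelic sites are normalized jointly (the shared-base
conditions quantify over the whole allele set) so the operation is
reusable standalone, although the pipeline has removed multiallelics
before this stage. Left extension required at position 1 raises rather
than emitting a non-left-alignable representation: real contigs provide
context, and fixtures must too.

Correctness is checked three ways: an exhaustive oracle that enumerates
every candidate `(pos, ref, alt)` producing the identical alternate
haplotype and keeps the shortest, left-most one; idempotence and
haplotype-preservation properties on random repeat-rich contigs; and
cross-validation against `bcftools norm` on a deterministic batch.

## Annotation store and identification

The store ingests SnpEff-style `ANN` entries (pipe-delimited, standard
field positions, `MODERATE` mapped to `MED`), yielding one entry per
(record, gene) — a variant overlapping *k* genes participates in each gene
independently. Per gene, impact is the most severe entry
(HIGH > MED > LOW > MODIFIER, order-invariant with a lexicographic
tie-break on the term) and a variant is exonic iff any of its terms is in
a configurable coding-change set. MAF and CADD come from configurable INFO
keys (defaults `MAF`, `CADD`) because annotation pipelines differ in which
population-frequency field they populate.

Filters are conjunctive — `MAF ≤ maf_max` (default 0.01), `CADD ≥
cadd_min` (default 15), exonic when required, impact in {HIGH, MED} — and
**fail closed**: a missing MAF or CADD fails the filter, since an unknown
frequency cannot certify rarity. CH pairing requires both members phased
heterozygous with alternate alleles on opposite haplotypes; all qualifying
pairs in a gene are reported (per-pair granularity is collapsible to
per-gene, not vice versa). Hom-alt requires `1/1`/`1|1`; an optional
strict-recessive mode additionally requires both parents to carry an
alternate allele. De novo requires both parents *explicitly* `0/0` — a
missing parent cannot certify allele absence.

GDI annotation left-joins per-gene Gene Damage Index scores and gene
lengths by case-insensitive symbol; scores ≤ 13.84 (configurable) classify
as "likely" to harbour disease-causing damage. A small excerpt of
published GDI scores ships with the package for reference lookups.

## Synthetic fixtures

The simulator emulates a small exome-like trio study: two contigs with
tandem-repeat tracts (default 25 % of bases) so left-alignment is
exercised, 24 genes × 4 sites by default, and per-gene planted categories
covering trans CH pairs, cis pairs, hom-alt, de novo, Mendelian errors,
all-het ambiguous sites, multiallelics, duplicated positions,
both-parents-missing sites, denormalized indels, and filter-failing
variants (high MAF, low CADD, non-exonic, low impact). Passing variants
draw MAF from [1e-4, 5e-3] and CADD from [16, 35] — comfortably inside the
default thresholds, as befits planted positives — and failing ones from
clearly outside. The child file uses `chr`-prefixed contigs while the
parents use bare names, exercising dialect harmonization. In VCF mode
parental hom-ref calls are explicit `0/0` records (a sites-only VCF cannot
distinguish hom-ref from missing); in gVCF mode they are `<NON_REF>`
coverage blocks with holes at planted no-coverage sites. Everything is
generated from one seeded RNG; identical specs produce byte-identical
files.

What passing these fixtures does **not** show: behaviour under genotyping
error and low-confidence calls, linkage structure, overlapping or
multi-gene transcripts, structural variants, or the statistical phasing of
ambiguous sites — real data contains all of these, and candidate lists
from this toolkit remain candidates for orthogonal confirmation.

## Numerical and scale choices

The test suite and acceptance script run at deliberately small scales —
216 trio genotype combinations (exhaustive), 1,000 random normalization
variants on 50 bp contigs, a 24-gene trio (~100 sites) for end-to-end
recovery, and a 5 × 5 threshold grid for monotonicity — chosen so the full
cycle completes in seconds while every code path and planted category is
still exercised. All randomness is seeded; the acceptance script derives
every stream from its `--seed` argument. Report row order is
deterministic (gene, then position), QUAL values are serialized as
integers when integral, and floating-point INFO values are written with
fixed precision so outputs are byte-reproducible.
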