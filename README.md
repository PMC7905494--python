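# comphet

Trio-aware identification of **compound-heterozygous (CH)**,
**homozygous-alternate** and **de novo** candidate variants from VCF/gVCF
call sets.

A compound-heterozygous genotype arises when a person carries two different
heterozygous variants in the same gene, one inherited from each parent —
together they can disable both copies of the gene even though neither
variant is homozygous. Detecting them from short-read sequencing requires
*phasing*: deciding which alternate allele sits on the paternal and which on
the maternal haplotype. Given a sequenced child–father–mother trio, most
sites can be phased purely by Mendelian transmission logic; this package
implements that logic end to end, together with all the file preparation a
trio analysis needs, and is aimed at rare-disease and missing-heritability
studies that start from per-member VCF or gVCF files.

## What it does

The pipeline runs these stages (each also invokable on its own):

1. **Harmonize** — restrict parental records to the child's variant
   positions; drop the child's gVCF non-variant blocks; collapse parental
   coverage blocks over child sites to explicit `0/0` genotypes.
2. **Merge** — combine the three single-sample files into one multi-sample
   record set, re-indexing alternate alleles into a shared allele list.
3. **Site hygiene** — remove multiallelic sites, duplicated positions, and
   sites where both parents are fully missing (`./.`); every removal is
   logged with a reason.
4. **Phase** — per chromosome, classify each site by enumerating the
   (paternal, maternal) transmissions consistent with the trio genotypes:

   | consistent transmissions | outcome |
   |---|---|
   | exactly one | phased, written `paternal\|maternal` |
   | several | ambiguous (e.g. all three members `0/1`); left unphased |
   | none, parents both `0/0`, child single-alt | potential de novo; retained |
   | none otherwise | Mendelian error; removed |

   REF/ALT congruence with the reference genome is repaired first (a swap
   inverts every genotype index while preserving phase order).
5. **Normalize** — left-align and trim every variant to its left-most,
   most parsimonious representation against the reference.
6. **Store** — ingest SnpEff-style `ANN` annotations plus MAF and CADD
   INFO keys into a gene-indexed in-memory store.
7. **Identify** — apply the conjunctive filters
   `MAF <= 0.01`, `CADD >= 15`, exonic, impact in {HIGH, MED}
   (all configurable), then report trans-configured CH pairs (`1|0` with
   `0|1` in one gene), homozygous-alternate sites (`1/1`), and de novo
   sites (child het, both parents explicitly `0/0`).
8. **GDI** — join per-gene Gene Damage Index scores and gene lengths;
   genes scoring `<= 13.84` are classified as more likely to harbour
   disease-causing damage.

Statistical panel-based phasing of ambiguous sites (SHAPEIT2/Eagle2/Beagle
style) is deliberately out of scope; ambiguous sites are flagged and never
enter CH pairing. See `docs/methods.md` for the full model description and
design choices.

## Worked example

The package ships a deterministic trio simulator, so a complete run needs
no external data:

```bash
comphet simulate --seed 7 -o fx/
comphet run \
  --vcf-child fx/child.vcf --vcf-father fx/father.vcf --vcf-mother fx/mother.vcf \
  --ped fx/trio.ped --fasta fx/ref.fa \
  --gdi-table fx/gdi.tsv --length-table fx/gene_lengths.tsv \
  --maf 0.01 --cadd 15 -o out/
```

prints

```
INFO comphet.identify: compound-het pairing skipped 5 unphased/ambiguous heterozygotes
ch: 2 candidate(s)
denovo: 2 candidate(s)
homalt: 2 candidate(s)
```

and `out/ch.tsv` contains (abridged):

```
gene     chrom  pos   ref  alt  child_gt  father_gt  mother_gt  maf       cadd   ... inheritance  gdi_score  damage_class  pair_id
GENE001  1      81    G    T    1|0       1|1        0|0        0.004938  22.06  ... paternal     2.69       likely        0
GENE001  1      130   C    G    0|1       0|0        1|1        0.004362  23.43  ... maternal     2.69       likely        0
GENE019  2      1521  C    A    1|0       1|1        0|0        0.002948  31.8   ... paternal     11.01      likely        1
GENE019  2      1570  T    C    0|1       0|0        1|1        0.004856  29.42  ... maternal     11.01      likely        1
```

Each `pair_id` groups the two variants of one CH pair: the child is
heterozygous at both positions, the alternate alleles lie on opposite
haplotypes (`1|0` paternal-alt, `0|1` maternal-alt), both members pass the
rarity (MAF) and deleteriousness (CADD) filters, and the gene's GDI score
is joined with its damage classification. The simulator's `fx/truth.tsv`
lists every planted site, so the run is fully checkable: the two reported
genes are exactly the planted trans pairs that pass filters, and the
`denovo`/`homalt` reports likewise recover exactly the planted sites.

The same `run` command works on real data: per-member VCF or gVCF files
(`--mode gvcf`), a 6-column PED, an indexed FASTA, and a SnpEff-annotated
child VCF carrying `ANN`, `MAF` and `CADD` INFO keys (key names
configurable). Every stage writes its intermediate VCF, a removal/site log,
and `manifest.json` recording all thresholds and flags.

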