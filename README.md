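# markerforge

Genome-wide design of **InDel**, **CAPS** and tagged amplicon-**SNP** PCR
markers from multi-sample VCF genotyping data.

Marker-assisted selection and genetic mapping need many cheap, reliable
PCR assays that distinguish two groups of samples — typically two parent
cultivars or two pools of lines. Resequencing makes the raw material (a
multi-sample VCF against a reference assembly) easy to obtain, but turning
thousands of variant calls into *validated* primer pairs is the hard part:
each candidate locus must be genotyped consistently within each group,
the primers must avoid nearby segregating variants and low-coverage
regions, they must not amplify anywhere else in the genome, and they must
not fold into hairpins or dimers. markerforge automates the whole chain.

## What it designs

| Marker type | Scored by | Discriminating event |
|---|---|---|
| InDel | product length on a gel | insertion/deletion of 3–50 bp (configurable) |
| CAPS | restriction digest pattern | a variant that creates/destroys an enzyme site |
| SNP | amplicon sequencing | any single-base difference; primers get CS1/CS2 adapter tags |

## Method

For each VCF site, samples are split into two groups fixed for distinct
alleles — either groups the user names, or exhaustively by allele
(auto-group): group *i* holds every sample homozygous for allele *i*;
heterozygous or missing samples join no group. The *target sequence* is
the variant ±20 bp, realized once per group allele. InDel candidates
need an allele length difference inside the configured window; CAPS
candidates need an enzyme (IUPAC-degenerate motif, matched on both
strands) with ≥1 recognition site in exactly one allele's realized
target; SNP candidates need two distinct single-base alleles.

The *template* extends the target by 500 bp on each side. Excluded
regions are annotated for: nearby variants segregating among the grouped
samples (±1 bp guard), runs of pooled read depth below `--min-depth`, and
— for CAPS — everything beyond a second recognition site of the marker's
enzyme, so the amplicon digests exactly once. The design engine then
enumerates primer pairs flanking the target (nearest-neighbor
thermodynamic T_m, length/GC/homopolymer constraints, penalty-ranked with
a minimum 3′-end distance between returned pairs). Every candidate is
screened genome-wide for *facing* binding-site pairs within 10 kb
(3′-anchored matching: exact 15-mer seed at the 3′ end, ≤2 mismatches
elsewhere) and for hairpin/self-dimer/cross-dimer structure — on the full
synthesized oligo, tags included. Failed primers become excluded regions
and design repeats until a specific, structure-clean pair emerges or the
engine is exhausted. Amplicon size satisfies
`product = right-primer 3′ end − left-primer 5′ end + 1`.

For multiplex amplicon panels, `markerforge panel` keeps amplicons inside
a GC window (default 40–60%) and size window (default 150–175 bp) and
thins markers to ≥2 Mb spacing per contig.

## Worked example

Everything runs from synthetic inputs — no downloads:

```sh
markerforge fixtures make --out demo --seed 7 --profile caps
# fixture 'caps' with 10 loci -> demo
markerforge run --vcf demo/variants.vcf --ref demo/reference.fasta \
    --depth demo/depth.tsv --marker-type caps --min-depth 5 \
    --enzyme-names EcoRI --out demo/report.tsv
# designed 7 markers (7 screened in) -> demo/report.tsv
```

The fixture plants ten candidate loci, seven of which are genuinely
CAPS-recoverable (an EcoRI site destroyed by the alternate allele); the
other three are decoys (site cut in both alleles, or no site). The run
reports exactly the seven, e.g.:

```text
marker_id              pos    left_primer           right_primer          tm_left  tm_right  product_size  enzyme  digested_allele  fragments_a  fragments_b
chr1_68004_CAPS_EcoRI  68004  TGACCGGGGCCGGTAATTGA  AATCGCAGCTCTCGCAGTGC  59.72    59.94     152           EcoRI   A                97,55        152
chr1_74504_CAPS_EcoRI  74504  GGGGACCGACTGGGTCGTTA  GCGAGACGTGAGCACTCGTC  59.44    59.68     161           EcoRI   A                93,68        161
```

Reading the first row: a 152-bp product amplified with the given primers
(T_m ≈ 60 °C each) digests into 97 + 55 bp fragments when the template
carries the group-A allele and stays a single 152-bp band for group B —
a co-dominant gel assay. A `report.summary.json` sidecar records the
stage counters and the full configuration.

## Layout

- `markerforge.io_layer` — FASTA/VCF/depth readers, TSV report writer
- `markerforge.grouping` — user-specified and exhaustive auto grouping
- `markerforge.marker_screen` — InDel/CAPS/SNP screens, IUPAC site scanner
- `markerforge.template_builder` — template extension, masking, CAPS trim
- `markerforge.design_loop` — design engine, specificity, structure, redesign
- `markerforge.panel_tools` — panel GC/size filter, spacing, fragment sizes
- `markerforge.fixtures` — seeded synthetic genomes/VCFs with truth tables
- `markerforge.pipeline` / `markerforge.cli` — the `markerforge` command

See `docs/methods.md` for the model, parameter defaults and limitations.
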