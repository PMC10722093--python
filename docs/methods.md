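# Methods

## Problem and model

markerforge converts multi-sample variant calls into validated PCR
assays. The underlying model of a "good marker" has four parts:

1. **Fixed, distinct alleles.** A marker is only interpretable if every
   assayed sample carries a known allele, so grouping demands
   homozygosity. Auto-group mode forms one candidate group pair per
   unordered allele pair (i, j) with at least one homozygote each —
   bounding the enumeration at C(n_alleles, 2) rather than all sample
   set-partitions. Heterozygous and missing samples are excluded from
   auto groups; in user-specified mode they veto the site, because the
   user explicitly claimed those samples for the assay.
2. **A scorable event.** InDel: allele length difference within a
   user window (a [min, max] window subsumes an exact size as min=max).
   CAPS: an enzyme whose recognition motif occurs in exactly one group
   allele's realized target (variant ±20 bp). Because the two realized
   targets share both flanks by construction, any differential site is
   attributable to the variant itself. SNP: two distinct single-base
   group alleles (decided on the grouped allele pair, not ref/alt).
3. **A bindable neighborhood.** Primers must sit on sequence that is
   identical in all assayed material and actually present in the
   sequencing data — hence masking of segregating nearby variants and
   low-depth runs (below).
4. **A specific, well-behaved pair.** No second facing binding-site
   combination within 10 kb anywhere in the genome, and no
   hairpin/dimer structure in the synthesized oligos.

## Coordinates

All internal coordinates are 0-based half-open; conversion to and from
the 1-based conventions of VCF and the depth-TSV dialect happens only at
the io boundary. Report positions are 1-based to match the input VCF.

## Template construction and masking

The target is the variant ±20 bp; the template extends it by 500 bp per
side, clipped (and flagged) at contig edges. Exclusion reasons:

- `variant`: a nearby VCF site that is not monomorphic across the union
  of the two grouped sample sets, masked over its reference span ±1 bp.
  Heterozygous or missing genotypes count as polymorphic (conservative).
  Sites segregating only in unselected samples do not mask: primers need
  only bind identically in the assayed material.
- `low_depth`: maximal runs of pooled depth < `min_depth` (active only
  when a depth source is given; `min_depth 0` disables). Depth from
  multi-sample alignments is pooled as a per-position sum of streamed
  alignment coverage; the TSV dialect carries pre-pooled values. Pooling
  is conservative for the purpose of "regions the caller could not see".
- `rejected_primer`: footprints of pairs that failed specificity or
  structure in earlier design rounds.
- CAPS templates are additionally *trimmed*: the digested-allele-realized
  template is scanned and the template edge moves past the nearest extra
  recognition site on each side, removing the extra site itself — the
  only reading that guarantees a unique cut site. If two sites fall
  inside the untrimmable ±20 bp target window the candidate is rejected.

Exclusion lists are kept merged, sorted and disjoint (overlaps merge,
reasons join with `+`), which makes masking idempotent.

## Restriction-site engine

Recognition motifs are IUPAC-degenerate strings (≥4 bp). A position
matches if the motif matches the forward strand or if the motif's
reverse complement matches (equivalently, the motif on the bottom
strand); palindromic motifs report once per position. `N` in the
*sequence* never matches — an unknown base cannot confirm a site. The
default table ships 21 common 6- and 4-cutters with top-strand cut
offsets; users supply their own via `--enzymes` (TSV: name, site,
offset). Digestion fragments are predicted by cutting at
`site_start + cut_offset` for every match; fragment lengths always sum
to the product length.

## Design engine

The engine is authored in this package and operates on the masked
template:

- **Candidates.** Left primers end at or before the target start, right
  primers begin at or after the target end; footprints avoid every
  excluded base; length 18–25 nt (optimum 20); GC 20–80%; homopolymer
  runs ≤5; T_m 57–63 °C (optimum 60) from the nearest-neighbor
  thermodynamic model (SantaLucia parameters, 50 mM monovalent salt, via
  Biopython's melting-temperature module). Product size must contain the
  whole target and lie in `[product_min, product_max]` (default
  150–200 bp), with `product = right 3′ end − left 5′ end + 1`.
- **Ranking.** Pair penalty = Σ per-primer (|T_m − T_opt| + |len −
  len_opt|) + 0.5·|ΔT_m between mates|. Returned pairs obey a minimum
  3′-end distance (default 2 bp) on at least one side versus every
  earlier-returned pair, so a single unfortunate neighborhood cannot
  monopolize the candidate list; up to 100 pairs are returned.
- **Specificity.** Binding sites of each primer are found genome-wide on
  both strands by a 3′-anchored rule mirroring extension chemistry: the
  3′-terminal 15-mer must match exactly, and at most 2 mismatches are
  allowed over the remainder. Two sites on opposite strands whose 3′
  ends point toward each other with implied product
  `minus-site 3′ coordinate − plus-site 5′ coordinate + 1` in (0, 10 kb]
  predict an off-target amplicon; the combination overlapping the
  template's own genomic interval is the intended locus and is ignored.
  The 15-mer/2-mismatch rule is an explicit, deterministic stand-in for
  a heuristic local-alignment search; its parameters are part of the
  package's contract and are checked against an exhaustive string-scan
  oracle in the test suite.
- **Structure.** Measured in contiguous complementary-run units on the
  full synthesized oligos (adapter tags included, since tags can pair
  like any sequence): fail on a self- or cross-dimer duplex run ≥8 bp, a
  3′-anchored duplex run ≥5 bp, or a hairpin stem ≥6 bp closable with a
  loop ≥3 nt. These thresholds reproduce the canonical judgments
  (poly-A vs poly-T fails; typical random 20-mers pass; a 10-bp inverted
  repeat with a 4-nt loop fails) while staying cheap enough to screen
  every candidate.
- **Redesign.** Each round evaluates the ranked list in order; the first
  pair passing both checks wins. When a whole round fails, all rejected
  footprints join the exclusions (`rejected_primer`) and the engine
  re-runs, up to `max_iterations` (default 10) rounds. Exclusion mass is
  monotone non-decreasing across rounds, which, with the iteration cap,
  guarantees termination; exhaustion is recorded with the last failure
  reason.

In SNP mode the CS1 (`ACACTGACGACATGGTTCTACA`) and CS2
(`TACGGTAGCAGAGACTTGGTCT`) adapter tags — or any user-supplied pair —
are prepended before the structure check, and tag bases never count
toward genomic footprints or binding.

## Synthetic data

The fixture generator emulates exactly the features the pipeline
consumes, with all randomness flowing from one seed:

- i.i.d. random genomes at a chosen GC (default 0.50, 200 kb for the
  main profile) with optional exact duplication blocks;
- planted loci every 6.5 kb: per marker type, seven recoverable loci and
  three decoys (InDel: length outside the 3–50 bp window, monomorphic;
  CAPS: motif cut in both alleles, no motif; SNP: a 1.3-kb zero-depth
  hole over the locus, monomorphic, all-heterozygous). CAPS loci stamp
  the EcoRI motif into the reference and break it with the alternate
  allele; every locus window is scrubbed and repaired until the realized
  allele windows carry exactly the promised site counts, so the truth
  table follows from construction for every seed. CAPS-recoverable loci
  are scrubbed over the whole template span, since a unique cut site
  there is part of what "recoverable" promises;
- a uniform depth-30 track with zero-depth holes;
- an off-target profile that copies the left and right primer
  neighborhoods of one SNP locus to a second location, a configurable
  separation apart, so the implied off-target product tracks the
  separation across the 10-kb boundary.

What this does *not* emulate: real base-composition structure (isochores,
repeats, homopolymer-rich regions), alignment artifacts, genotyping
error, or linked variant clusters. Passing tests therefore demonstrate
the pipeline's logic and contracts, not wet-lab success rates on real
genomes — marker validation rates in the field depend on VCF quality and
polymorphisms absent from the input.

## Problem sizes and determinism

The bundled analyses run on a 200-kb single-contig genome with 30
planted loci (plus 40-kb off-target genomes), sizes chosen so the entire
suite and the reproduction script each complete in well under a minute
on one CPU while exercising every code path, including multi-round
redesign. Identical seed and configuration give byte-identical reports;
the engine itself is fully deterministic, so no engine seed is needed.

## Known limitations

- dCAPS (mismatch-engineered sites), methylation-sensitive digestion and
  double digests are out of scope; one enzyme per CAPS marker.
- The specificity rule is near-exact matching; diverged paralogs with >2
  mismatches outside the seed, or seed-breaking indels, are invisible to
  it (as they largely are to short-seed alignment searches).
- Nearby homozygous-alt sites in the grouped samples are masked rather
  than realized into the template; primers are designed on the
  reference-realized sequence.
- Cross-marker dimer screening of a pooled multiplex panel is not
  performed; the panel tools filter per-amplicon properties only.
- Structure checks use run-length heuristics, not a full thermodynamic
  fold; borderline oligos that a ΔG model would flag can pass.
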