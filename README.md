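# delscan

Discovery and characterization of large radiation-induced deletions in
polyploid wheat from exome-capture read depth — plus the downstream analyses
that turn deletion lines into a phenotype: dominant PCR-marker genotyping,
F2 segregation statistics, and starch-granule morphometry.

It is written for geneticists working with irradiated mutant populations of
bread wheat (or any polyploid with a reference assembly), where large
deletions are screened by PCR markers, mapped by capture sequencing against
a wild-type line, and combined across subgenomes by crossing.

## The method

**Deletion discovery.** Exome-capture depth is probe-dependent, so raw
coverage is uninformative; the pipeline counts retained alignments (MAPQ ≥
30, proper pairs) in 1 Mb bins and normalizes twice:

    value(bin) = (n_mut / N_mut) / (n_wt / N_wt)

where *n* is the bin count and *N* the line's total retained reads. Shared
per-bin capture efficiency cancels in the ratio. A large deletion is a run
of at least 4 adjacent bins with value ≤ 0.1, and it is considered finished
only once at least 4 adjacent bins rise above 0.1 (shorter interior high
runs are absorbed); bins with zero wild-type coverage are masked and
neutral. Coordinates on split "parts" pseudomolecules are lifted to full
chromosomes (part-2 bins shift by part-1's length, so they sit off the 1 Mb
grid). Calls shared between independent mutants are flagged as likely
background-vs-reference polymorphisms, and bin-resolution borders can be
refined to the first/last gene model whose own normalized coverage is ≤ 0.1,
with the nearest covered genes reported as flanks. Gene content of
homoeologous deletions is intersected through a homoeologue map.

**Genotyping and segregation.** Dominant PCR markers (absent or faint
product → putative deletion) are interpreted against an ordered marker
panel into deletion-extent classes; a multiplex marker with per-genome
products identifies double mutants. For two unlinked deletion loci in an
F2, the homozygous double mutant expectation is (1/4)² = 1/16; observed
proportions are tested by chi-square goodness of fit with an exact binomial
tail for the focal class.

**Granule morphometry.** Micrographs are binarized (Otsu), touching
granules split by a distance-transform watershed, and particle areas
measured twice: all particles ≥ 0.785 µm² (granules > 1 µm diameter) and
those within 0.785–78.5 µm² (the 1–10 µm small class). The percentage of
small granules per image, averaged over images, summarizes the size
distribution; swelling power is swollen-pellet weight / dry weight.

A synthetic-data module generates every input — paired coverage with shared
lognormal capture efficiency and Poisson noise, gene models with
homoeologue maps, marker screens, and granule micrographs — each with a
truth table, so the whole pipeline is testable without downloads.

## Worked example

```bash
python examples/deletion_scan.py
```

```
Line A1: 4 large deletions (planted: 4)
line_id chrom     start       end  size_bp  n_low_bins method flags
     A1 Chr1B 182000000 190000000  8000000           8    bin
     A1 Chr4A 576555092 600555092 24000000          24    bin
     A1 Chr5D 422000000 440000000 18000000          18    bin
     A1 Chr6A 262000000 274000000 12000000          12    bin
...
Line D4: 6 large deletions (planted: 6)
```

Each row is a contiguous low-coverage block; the simulated line A1 carries
its four known deletions (note the Chr4A boundaries off the 1 Mb grid —
the part-1/part-2 lift offset), and the caller recovers all of them at
exact bin boundaries. `examples/genotype_screen.py`,
`examples/segregation_test.py` and `examples/granule_sizes.py` walk the
marker, segregation and imaging stages the same way, and the `delscan` CLI
(`delscan simulate`, `delscan run`, `delscan granules`, ...) exposes the
same functions on files.

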