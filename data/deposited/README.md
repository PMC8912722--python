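# Deposited field genotypes (not bundled)

The deterministic checks in `tests/test_acceptance.py::test_deposited_genotype_statistics`
run against the archived EST-SSR genotypes of the two maple species, which are
distributed by their public repositories (Mendeley Data and Dryad) and are not
redistributed here.

To run those checks, place two files in this directory:

- `genotypes.gen` — a GenePop file combining both species: title line, one
  locus name per line (17 loci), populations separated by `POP` lines,
  3-digit allele coding, `000000` for missing genotypes.
- `meta.csv` — columns `population,species,latitude,longitude,altitude`, one
  row per population block of the GenePop file, in the same order (population
  labels `pop1`, `pop2`, ... matching the reader's block numbering, or edit
  the labels consistently in both files).

Everything else in the test suite runs on synthetic data and does not need
these files.
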