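# mabckit

A toolkit for marker-assisted backcross (MABC) breeding computations:

- **InDel marker-panel design** from a two-parent variant table: genotype
  quality (GQ > 30) filtering, 30–50 bp length-difference screening,
  120–150 bp flank extraction, tandem-repeat exclusion, a 55–60 % flank
  G/C window, a reference-divergence envelope, and greedy thinning to an
  ~20 cM evenly spaced panel on a genetic map.
- **Background-recovery scoring**: per-individual recovery rate
  `Rg = (2·#RR + #RD) / (2·I) × 100` (which reduces to the band-count
  form `(I+S)/(2I) × 100` in a clean backcross), strict threshold
  selection, progeny-based homozygosity testing, the 1:1 segregation
  chi-square test, and `2^−ΔΔCt` relative expression.
- **A forward-in-time breeding simulator**: ancestry-segment genomes on a
  genetic map, Poisson/Haldane meiosis (no interference), backcrossing,
  selfing, foreground (transgene-carrier) selection, marker genotyping,
  and a whole-scheme driver (F1 → BC1 → BC2 → two selfings).
- **Synthetic data**: a 10-chromosome maize-like map (~2100 cM), founder
  genomes differing at simulated InDel sites, and backcross populations —
  so everything is testable offline.

## CLI

```sh
mabckit synth --out syn/ --seed 1 --n-sites 600 --bp-per-cm 100
mabckit design-panel --vcf syn/sites.vcf --ref syn/reference.fasta \
    --genome syn/recurrent.fasta --map syn/map.tsv --spacing 20 \
    --out-prefix panel/panel
mabckit score --genotypes genotypes.csv --min-rg 80 --out reports.tsv
mabckit segtest --pos 111 --neg 113
mabckit ddct --ct-target 22 --ct-reference 25
mabckit simulate --config scheme.toml --seed 42 --out summary.json
```

Genotype CSVs have individuals as rows and markers as columns with cells
`RR`/`RD`/`DD`/`NA`. Maps are TSVs with `chrom`, `length_cM` and optional
`length_bp`/`markers_cM` columns. Panels are written as TSV plus BED
(0-based half-open flank windows). Every file-writing command drops a
`manifest.json` recording the invocation, seed and config digest.

## Layout

```
src/mabckit/
  genmap.py          genetic-map coordinate system (cM, bp interpolation)
  marker_design.py   screening cascade + spaced panel selection
  scoring.py         Rg, selection, chi-square, homozygosity, 2^-ddCt
  breeding_sim.py    meiosis, backcross/self, foreground selection, scheme
  synthetic_data.py  maps, founder genomes, candidate sites, populations
  datasets.py        bundled published per-plant recovery tables
  io_cli/            VCF/FASTA/TSV/CSV/BED io, manifests, click CLI
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
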