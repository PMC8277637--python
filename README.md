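# polypat

SNP-based paternity assignment in polycross field designs, estimation of the
degree of cross-fertilization (C) and paternal outcrossing success (P) of the
component genotypes, and an exact inbreeding-dynamics engine for the
generations of synthetic cultivars.

The package targets the setting of a partially allogamous crop grown as a
polycross of eight genotypes (8 blocks x 8 plants per genotype, 512 plants),
where ~12 seeds per plant are genotyped at a handful of biallelic SNPs and
each seed's pollen donor is identified from the marker calls. Because field
accessions of this kind are typically not public, a synthetic-data generator
with known mating parameters drives all analyses and tests.

## Modules

| module | what it does |
| --- | --- |
| `polypat.panel` | SNP panels of candidate parents; minimal and validation distinguishing marker sets (exact enumeration); TSV I/O |
| `polypat.simulate` | polycross layouts, mating events with genotype-specific cross-flower rates / donor weights / compatibility, Mendelian offspring calls with missing/error noise, ground-truth tables |
| `polypat.paternity` | maternal-allele attribution, mismatch-tolerant father matching (0/1/2 ignored markers, union-uniqueness rule), resample-or-omit handling, batch summaries |
| `polypat.estimation` | C and P binomial datasets, the 1/8 intra-genotype imputation, binomial-logit GLMs (IRLS), sequential analysis of deviance, equal-weight LS means, Bonferroni contrasts, compact letter displays, overdispersion checks, Pearson C-P correlation |
| `polypat.syngen` | founder-class engine for Syn-n generations (exact joint founder-origin matrices), idealized F recursion and its (1-C)/(1+C) equilibrium, equal-P and single-donor scenarios with recessive/dominant zero-pollen inheritance |
| `polypat.cli` | `polypat` command orchestrating simulate -> assign -> estimate -> syngen |

## CLI

```sh
# full pipeline on the default 8x8x8 polycross
polypat all --seed 1 --out runs/demo

# custom run from a flat key = value config
polypat all --config run.cfg --out runs/custom
```

Config keys use dotted namespaces (`design.n_blocks`, `mating.cross_flower_rate`,
`noise.error_rate`, `sampling.seeds_per_plant`, `syngen.scenario`, `seed`, ...);
per-genotype parameters may be comma lists aligned with `design.genotypes`.
Outputs are TSV files (truth, calls, assignments, C/P datasets, deviance
tables, LS-mean estimates with letters, syngen trajectory) plus `run_meta.txt`
recording the seed and config hash. Reruns with the same config and seed are
byte-identical. Exit codes: 0 ok, 2 config error, 3 data error.

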