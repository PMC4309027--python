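# phosphoid

Phosphopeptide identification from CID LC-MS/MS spectra.

The pipeline builds a target/decoy/composite peptide database from a
protein FASTA file by in silico tryptic digestion with variable
phosphorylation of serine/threonine (+79.966 Da) and fixed
carbamidomethylation of cysteine (+57.021 Da); prescreens dta spectra by
the characteristic H3PO4 (97.977 Da) precursor neutral-loss signal;
identifies phosphopeptide sequences and phosphosites by expanding all
positional phospho-isomers of precursor-mass-matched candidates and
scoring matched b/y fragments (with water, ammonia and phosphoric-acid
losses) through a sigmoid weight of normalized peak intensity; and
validates target hits against the per-spectrum decoy score distribution
with a Bonferroni-corrected critical value.

## Modules

| module | contents |
|---|---|
| `phosphoid.chem` | monoisotopic constants, residue masses, peptide mass |
| `phosphoid.peptide_db` | FASTA parsing, digestion, mod-state enumeration, composite DB |
| `phosphoid.spectra` | dta reading/merging, charge filter, normalization, bin denoising, neutral-loss check |
| `phosphoid.search` | phosphosite isomer enumeration, theoretical b/y spectra, sigmoid match scoring |
| `phosphoid.stats` | Bonferroni alpha, empirical / Gumbel-tail decoy p-values, significance filter |
| `phosphoid.evaluation` | confusion counts, the six detection indexes, sequence/site checks |
| `phosphoid.synthetic` | ground-truthed synthetic spectrum generator + bundled FASTA |
| `phosphoid.cli` | `phosphoid` command-line interface |

## CLI

```sh
# 1. build the composite database from a FASTA file
phosphoid build-db --fasta proteins.fasta --out db.tsv

# 2. generate a ground-truthed synthetic dataset (optional)
phosphoid simulate --out-dir spectra/ --n-phospho 50 --n-nonphospho 50 --seed 1

# 3. merge single-spectrum dta files (optional; identify also reads a directory)
phosphoid merge --spectra-dir spectra/ --out merged.txt

# 4. identify: charge filter -> normalize -> denoise -> neutral-loss check
#    -> isomer search -> decoy significance
phosphoid identify --db db.tsv --spectra merged.txt --out-dir run/ \
    --nl-threshold 30

# 5. score against ground truth
phosphoid evaluate --summary run/summary.tsv --truth spectra/truth.tsv \
    --mode all_hits
```

All parameters (protease, missed cleavages, dta precursor convention,
tolerances, neutral-loss threshold, `alpha_whole`, p-value mode, ...) can
be placed in a flat `key = value` config file passed via `--config`;
command-line flags override file values. Exit codes: 0 success, 1 input
error, 2 config error.

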