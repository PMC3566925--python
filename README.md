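# dtrflp

Digital T-RFLP profiling of 16S rRNA amplicon reads, electropherogram
drift correction by cross-correlation, and phylotype annotation of
terminal restriction fragments.

## What problem this solves

T-RFLP (terminal restriction fragment length polymorphism) is a fast,
cheap, highly reproducible community fingerprinting method: amplify the
16S rRNA gene pool with a fluorescently labeled forward primer, digest
with a restriction enzyme, and size the labeled terminal fragments
(T-RFs) by capillary electrophoresis. Its weakness is that a peak at,
say, 214 bp carries no taxonomy.

Amplicon sequencing of the *same* DNA extract supplies the missing link.
Each read starts at the labeled primer end, so the distance from the
read start to the first recognition site predicts the fragment that read
would produce — a digital T-RF. `dtrflp`:

* filters and denoises the reads (mean PHRED ≥ 20, 300–500 bp, greedy
  97%-identity clustering with abundance-weighted medoid centroids);
* maps cluster centroids against a taxonomy-annotated reference FASTA by
  exhaustive affine-gap Smith–Waterman (default threshold 150 on the
  unit-match score scale);
* digests centroids in silico (HaeIII by default; AluI, MspI, HhaI,
  RsaI, TaqI and user-defined enzymes supported) into a digital
  fingerprint of (size bp, relative abundance %) peaks;
* aligns digital to experimental fingerprints with a cosine-normalized
  cross-correlation over integer lags,

      c(l) = Σ_j d[j]·e[j+l] / (‖d‖·‖e‖),

  estimating the electrophoretic drift (typically −4…−6 bp) as the
  optimal lag, shifting the digital profile, and matching peaks within
  ±1 bp;
* annotates every digital T-RF with ranked phylotype contributions
  (taxonomy, read counts, percent contribution, alignment scores,
  accession);
* computes richness and Shannon H′ (natural log) and screens enzyme
  panels by fragment density over the 0–500 bp domain.

A synthetic-data module generates a toy reference database, error-bearing
reads (substitutions + homopolymer run-length errors) with known
community composition, and a matching drifted electropherogram CSV, so
the whole pipeline runs without any download. See `docs/methods.md` for
the model details and design choices.

## Worked example

Generate a synthetic sample and run the standard procedure:

```sh
dtrflp synth --n-taxa 5 --reads 80 --drift 5 --seed 31 --out-dir demo/in
dtrflp run --reads demo/in/reads.fastq --db demo/in/reference.fasta \
    --etrflp demo/in/etrflp.csv --out-dir demo/out --sample-id demo
```

The run prints its manifest; the interesting numbers (from an actual
run) are:

```
"counts": {
  ...
  "clusters": 5,
  "optimal_lag_bp": -5,
  "max_cross_correlation": 1.0,
  "applied_shift_bp": -5,
  "etrfs_affiliated_pct": 100.0,
  "richness": 5,
  "shannon_h": 1.283
}
```

Read this as: the 80 reads collapsed into 5 denoised clusters (one per
taxon); the cross-correlation between the digital and the experimental
fingerprint peaked at a lag of −5 bp — exactly the drift injected by the
generator — with coefficient 1.0; after shifting the digital profile by
−5 bp, every experimental peak found a digital partner within ±1 bp; the
shifted fingerprint has 5 peaks with Shannon H′ = 1.28. The per-peak
taxonomy lives in `demo/out/demo_peak_annotations.csv`, e.g.:

```
etrf_bp,dtrf_bp,dtrf_shifted_bp,counts,relative_contribution_pct,phylogenetic_affiliation,...
77,82,77,34,100.0,P:SyntheticPhylum_1;...;S:SyntheticSpecies_1,...
```

Python API equivalent:

```python
from dtrflp import (quality_filter, denoise_cluster, map_clusters,
                    digest_dataset, build_profile, correlate_profiles,
                    ENZYMES, read_sequences, read_reference_db, read_etrflp)

reads = read_sequences("demo/in/reads.fastq", "fastq")
kept, stats = quality_filter(reads)
clusters = denoise_cluster(kept)
hits, unmapped, mstats = map_clusters(clusters, read_reference_db("demo/in/reference.fasta"))
digest = digest_dataset(clusters, hits, ENZYMES["HaeIII"])
dprofile = build_profile(digest.trfs, "demo")
xcorr = correlate_profiles(dprofile, read_etrflp("demo/in/etrflp.csv"))
print(xcorr.optimal_lag, xcorr.max_coefficient)   # -5 0.9999999999999999
```

Other subcommands: `dtrflp screen-enzymes` (rank a panel of enzymes on
one dataset), `dtrflp compare` (align two existing fingerprint CSVs
without sequence processing).

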