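# Methods

## The problem

Terminal restriction fragment length polymorphism (T-RFLP) fingerprints a
microbial community by PCR-amplifying the 16S rRNA gene pool with a
fluorescently labeled forward primer, digesting the amplicons with a
restriction endonuclease, and sizing the labeled terminal fragments
(T-RFs) on a capillary sequencer. The resulting electropherogram — a list
of (fragment size in bp, relative abundance) peaks — is cheap and highly
reproducible, but a peak by itself says nothing about which organisms
produced it.

Amplicon sequencing of the same DNA extract closes that gap. Every read
starts at the labeled primer end, so the distance from the read start to
the first recognition site of the same enzyme predicts the fragment that
read would have produced in the capillary — a *digital* T-RF. Aggregating
digital fragments over all reads gives a digital T-RFLP (dT-RFLP) profile
directly comparable to the experimental (eT-RFLP) one, and the reads
behind each digital fragment carry taxonomy via a reference-database
search. `dtrflp` implements this workflow end to end.

## Pipeline stages

1. **Quality control** (`preprocess`). Optional primer trimming (IUPAC
   ambiguity codes honoured, one mismatch allowed by default), then a
   length window of 300–500 bp and a mean-PHRED threshold of 20
   (`P_error = 10^(-Q/10)`, so Q20 is a 1% error rate). Reads shorter
   than the window would distort fragment proportions; the thresholds are
   the field's conventional defaults and are user-settable.

2. **Denoising** (`preprocess.denoise_cluster`). Pyrosequencing-style
   errors — above all homopolymer run-length miscalls — scatter reads of
   one template into many variants, each potentially shifting the digital
   fragment by ±1 bp and inflating apparent richness. The denoiser
   dereplicates exact duplicates, orders groups by descending abundance
   (ties broken lexicographically, so no seed is needed), and greedily
   assigns each group to the first cluster representative within 97%
   pairwise identity, founding a new cluster otherwise. Pairwise identity
   is matches / alignment columns of an end-free global alignment
   (match +1, mismatch −1, gap −1), with internal gaps counted as columns
   — homopolymer indels must depress identity — and free terminal
   overhangs excluded, since reads of one template legitimately differ in
   3' length. The denominator is floored at the shorter sequence length
   so a short accidental overlap between unrelated sequences cannot score
   as high identity. After assignment, each cluster's representative is
   re-elected as the count-weighted medoid of its distinct member
   sequences (capped at the 12 most abundant for cost): the medoid is the
   variant the other members agree with, which keeps an arbitrary indel
   variant from defining the whole cluster's fragment size. Cluster read
   counts are preserved as abundance weights; singletons survive as
   size-1 clusters, so every read lands in exactly one cluster.

3. **Reference mapping** (`mapping`). Each cluster representative is
   aligned against every record of a taxonomy-annotated reference FASTA
   with an exact affine-gap Smith–Waterman search (match +1, mismatch −3,
   gap open −5, gap extend −2; a k-long gap costs open + (k−1)·extend).
   At unit match reward a perfect full-length ~450 bp read scores ~450,
   which sets the scale for the default acceptance threshold of 150
   (typical user range 100–250). Both orientations are tried and the
   better one wins. Scores divided by query length allow comparison
   across read lengths. Sub-threshold clusters go to an unmapped list and
   leave the pipeline. The search is exhaustive rather than heuristic:
   at desk scale (10²–10⁴ references) exactness is affordable and easy
   to verify against a naive dynamic-programming oracle.

4. **In-silico digestion** (`digestion`). The enzyme registry is
   data-driven (name, IUPAC recognition site, cut offset on the labeled
   strand) and ships the common panel: HaeIII GG^CC, AluI AG^CT, MspI
   C^CGG, HhaI GCG^C, RsaI GT^AC, TaqI T^CGA. A fragment size is the
   index of the first site occurrence plus the cut offset plus a
   configurable `origin_offset` (default 0; set it to the trimmed primer
   length to restore primer-inclusive sizes). Ambiguous bases in a read
   never match a site — an uncertain base call must not create a
   fragment. Site-free representatives are discarded and counted.
   Fragments are grouped by integer size, weighted by cluster read
   counts, and normalized to percent abundances.

5. **Profile comparison** (`comparison`). Capillary electrophoresis
   systematically sizes fragments a few bp short of their sequence length
   (drift of roughly 4–6 bp). Both profiles are binned to 1-bp vectors
   over 50–500 bp (the electropherogram window; sub-50 bp digital
   fragments are cut and the rest renormalized) and cross-correlated
   over integer lags in ±20 bp:

       c(l) = Σ_j d[j]·e[j+l] / (‖d‖·‖e‖)

   The cosine normalization uses global norms, not per-overlap norms, so
   coefficients are comparable across lags and bounded by 1, and a
   noiseless pure translation scores exactly 1 at the true lag. The optimal lag
   (ties: smallest magnitude, then negative) is the shift *added* to
   digital sizes — drift appears as a negative lag. A single global
   shift is applied rather than per-fragment models, whose reported
   standard deviation exceeds 1 bp; the user can override the shift
   manually. Shifted and experimental peaks are then matched greedily by
   nearest size within a ±1 bp tolerance (each peak used once, ties to
   the smaller digital size), and a mirror table/plot (experimental up,
   digital down, display clipped at 5% with true values annotated)
   supports visual inspection.

6. **Annotation** (`annotation`). For each digital fragment the
   contributing clusters are grouped by best-hit accession (distinct
   accessions of one species stay distinct), ranked by read count, and
   expressed as percentages of the fragment total rounded to one decimal
   (scores to three). When experimental data are absent the pipeline
   runs in no-eT-RFLP mode: no sub-50 bp cut, no shift, no experimental
   sizes. `taxon_trf_table` inverts the view: all fragment sizes carrying
   one taxon, with the predominant size flagged — reads with indels ahead
   of the cut site make one phylotype appear at several sizes.

7. **Metrics and enzyme screening** (`metrics`). Richness is the number
   of distinct fragments; Shannon's H′ = −Σ p ln p uses natural log (the
   ecology convention, consistent with H′ ≈ 2.5 at ~42 fragments).
   Density reports count distinct fragments per 50-bp class over 0–500 bp
   (half-open classes, the last closed) with a cumulative curve ending at
   the richness. `screen_enzymes` digests one processed dataset with a
   whole panel and ranks enzymes by richness and H′ — the screening mode
   for designing a fingerprinting protocol before any electropherogram
   exists.

## Synthetic data generator (`synth`)

The generator produces all three pipeline inputs with a known ground
truth, so every stage is testable without downloads.

* **Reference database**: per taxon a random sequence (default 480 bp)
  carrying exactly one recognition site at a pinned position, giving
  known, distinct fragment sizes. Default positions are spaced over
  80–280 bp so that every read of the default length range reaches its
  site; taxonomies are rank-complete synthetic strings (P:/C:/O:/F:/G:/S:).
* **Reads**: 5'-anchored reference prefixes with lengths uniform on
  300–450 bp, substitutions at 0.5% per base and ±1 homopolymer
  run-length errors at 1% per run of ≥3 bp — the plausible error profile
  of 454-era amplicon data, with the homopolymer mode dominant. Clean
  bases get Q40, edited bases Q10. A read counts toward the expected
  profile only if its error-free template contains the site.
* **Experimental profile**: the expected digital profile with all sizes
  shifted down by the injected drift (default 5 bp) and peaks below a
  detection floor removed, then renormalized — the electropherogram the
  lab method would deliver.

Everything is deterministic given the seed.

What the generator does *not* emulate: chimeras, primer-bias, flowgram
noise structure, per-fragment drift dependence on purine content or
secondary structure, and pseudo-T-RFs from undigested single-stranded
amplicons. Tests passing on synthetic data therefore demonstrate the
pipeline's arithmetic and its drift-alignment behavior, not robustness
to every artifact of real electropherograms.

## Numerical and design choices

* Fragment sizes are integer bp everywhere (electropherogram bins);
  CSV size rounding is half-up, duplicate sizes after rounding are
  summed with a warning.
* Profile abundances always renormalize to sum 100 after any window cut
  or shift; an all-zero profile is an error, not a silent empty object.
* Alignment traceback ties follow the aligner's deterministic
  enumeration; scores, the quantity the pipeline consumes, are exact.
* Mapping ties between references resolve to the earlier database record
  and are logged; orientation ties prefer the forward strand.
* The digestion origin convention (primer bases included or not) only
  translates the digital profile, and the cross-correlation absorbs any
  constant translation into the lag — so `origin_offset` defaults to 0
  and both conventions remain reachable.
* Test problem sizes: property oracles run on hundreds of short random
  instances; the drift-recovery study uses 100 seeded communities of
  8 taxa × 150 reads on a 0.8-geometric abundance gradient — a
  multi-peak fingerprint regime in which no single error-shifted peak
  can dominate the lag search. The acceptance script uses one 300-read
  community plus 40 drift trials.

## Known limitations

* The denoiser is a sequence-space stand-in with the same 97% identity
  contract as flowgram-space denoisers; it cannot correct errors it
  cannot see in base space.
* Exhaustive Smith–Waterman does not scale to full-size public
  databases; the intended regime is curated, study-scale references.
* Only the best mapping hit is kept; near-ties in taxonomy are not
  reported.
* Double digests, methylation sensitivity, and 3'-labeled fragments are
  out of scope.
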