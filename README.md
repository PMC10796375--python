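# seedviab

**6mer seed viability analysis of RISC-bound small RNAs.**

Small RNAs loaded into the RNA-induced silencing complex (RISC) silence
targets through their *6mer seed*, the hexamer at positions 2–7 of the
guide strand. Seeds rich in G target C-rich seed matches in essential
survival genes and can kill cells (death induced by survival gene
elimination, DISE); each of the 4096 possible seeds has a measured
*viability* — the mean % viability of cells transfected with an
siRNA-like duplex carrying that seed, averaged over three human or three
mouse cell lines. `seedviab` quantifies how the seed-viability
composition of a RISC-bound small-RNA population differs between two
conditions, for researchers analyzing Ago pulldown sequencing (Ago-RP-Seq)
count tables or published differential miRNA lists.

The pipeline:

1. **preprocess** — 3'-adapter trimming, collapsing of unique read
   sequences into a sequence × sample raw count table, rare-read filter
   (default: total count ≥ 6).
2. **annotate** — RNA-type assignment by exact-substring matching against
   ordered reference sets (artificial spikes are removed; mature miRNAs,
   then an "RNAworld" catch-all of other small RNAs); every surviving
   read gets its seed and species-average viability.
3. **normalize** — every sample column scaled to 10⁶ reads.
4. **differential** — per-row two-sided equal-variance Student *t*-test
   between the two groups; rows with p < α (default 0.05, no
   multiple-testing correction) are expressed as delta read counts
   Δ = mean(perturbed) − mean(control).
5. **viability statistics** — each row contributes round(weight/1000)
   copies of its viability to an expanded multiset; on it the package
   computes Tukey box statistics (hinges = quartiles, whiskers ≤ 1.5×IQR),
   Kruskal–Wallis group comparisons, 1%-binned viability curves
   (collapsed on seed × RNA type) and weighted nucleotide-composition
   matrices over seed positions 1–6.

A synthetic-data module generates every input — a complete
toxicity-structured 4096-seed viability table, two-group count tables
with a controlled shift toward low-viability seeds, reference FASTA sets
and FASTQ files — with ground truth for parameter-recovery tests.

## Worked example

```sh
seedviab simulate --outdir demo --seed 7 --shift 0.8 --depth 20000 --n-rows 200
seedviab run --config demo/config.yaml --outdir demo/out --plot
```

The first command materializes a complete synthetic workspace (viability
CSV, per-sample FASTQ, reference FASTA sets, config). The second runs
the full analysis. `demo/out/boxstats_differential.tsv` then contains,
for this seed:

```
group	n	median	q1	q3	whisker_low	whisker_high	n_outliers	kruskal_H	kruskal_p
enriched	193	53.76273333	47.904	55.1321	46.46163333	64.5634	9	282.8333628	1.812041729e-63
depleted	181	93.8191	87.39463333	97.03473333	77.96623333	104.6977333	0	282.8333628	1.812041729e-63
```

Reads enriched in the RISC of the perturbed group carry a median seed
viability of ~54%, versus ~94% for depleted reads (Kruskal–Wallis
p ≈ 2×10⁻⁶³): the perturbed condition shifted RISC loading toward toxic
seeds, which is exactly the effect the simulation injected
(`--shift 0.8`). The companion composition matrices
(`composition_differential_*.tsv`) show the enriched seeds are markedly
G-richer. The same statistics are produced for total (non-differential)
RISC content in `boxstats_total.tsv`, and
`seedviab mirna-list list.csv --config … --outdir …` reanalyzes a
published miRNA list (CSV of name and signed expression change) the same
way.

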