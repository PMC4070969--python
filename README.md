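# trflpkit

Terminal restriction fragment length polymorphism (T-RFLP) analysis for
microbial community fingerprinting, built around the workflow used to
profile arbuscular mycorrhizal fungi (AMF) in rice roots: electropherogram
peak processing, in-silico restriction digestion and phylotype assignment,
diversity statistics with rarefaction, ordination, and factorial group
comparison — plus a synthetic-data generator with known ground truth so the
whole chain is testable end to end.

## Who this is for

Microbial ecologists with size-called fragment peak tables (e.g. GeneMapper
exports) from double-end-labeled amplicons (HEX forward / FAM reverse
primer), a restriction enzyme such as HinfI (`GANTC`, cut `G^ANTC`), and
optionally cloned amplicon sequences to anchor observed terminal fragments
(T-RFs) to taxa.

## The analysis in brief

1. **QC & filtering** — profiles whose strongest peak is outside
   2,000–8,000 rfu are flagged for rerun; peaks below 50 rfu or outside
   50–600 bp are dropped.
2. **Binning** — peaks within a 1.2 bp window are merged into T-RF bins
   labeled by their largest-area member; bins under 1% of total area are
   removed and relative abundances p_i recalculated.
3. **Typing** — predicted forward/reverse T-RFs from sequences are matched
   to observed bins within ~2 bp; distinct RFLP patterns define OTUs.
4. **Diversity** — richness S, Shannon–Weiner H′ = −Σ p_i log₂ p_i (bits),
   evenness E = H′/log₂(S), and exact hypergeometric rarefaction
   E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n)) with 95% bounds.
5. **Ordination** — PCA on binary phylotype incidence; 2-D metric MDS
   (SMACOF stress majorization from a classical-scaling start) on T-RF
   area profiles.
6. **Group comparison** — two-way factorial ANOVA with Tukey–Kramer
   pairwise tests and compact letter display (shared letter ⇔ not
   significantly different at P ≤ 0.05).

See `docs/methods.md` for models, defaults, and numerical choices.

## Worked example

```python
import trflpkit as tk

# a 5-phylotype community with known abundances and HinfI sites
base = tk.fixture_community()
print(base.abundances)            # (0.35, 0.25, 0.18, 0.13, 0.09)

# three replicate electropherograms with realistic noise
profiles = tk.simulate_profiles(base, tk.NoiseModel(), 3, seed=42)
reps = [tk.abundance_filter(tk.bin_peaks(tk.filter_peaks(p)))
        for p in profiles]
consensus = tk.consensus_profile(reps)

# match observed bins to predicted terminal fragments (±2 bp)
assignment = tk.assign_trfs(consensus, base.predicted_trfs(), tolerance=2.0)
est = tk.estimate_abundances(assignment)
print(est.round(3).to_dict())
# {'P01': 0.352, 'P02': 0.255, 'P03': 0.174, 'P04': 0.129, 'P05': 0.089}

stats = tk.shannon(est.to_numpy())
print(round(stats.H_prime, 3), round(stats.E, 3))
# 2.165 0.932
```

The estimated abundances come back within ±0.01 of the ground truth and
H′ within ~0.006 bits of the true 2.171 — the chain of filtering, binning,
replicate averaging, and assignment preserves the community structure it
was designed to measure.

The same steps are available from a shell:

```bash
trflp-kit simulate --n-phylotypes 5 --seed 42 --out-dir demo
trflp-kit process --peaks demo/peaks.csv --consensus --out demo/profiles.tsv
trflp-kit digest --fasta demo/community.fasta --out demo/pred.tsv
trflp-kit diversity --profile demo/profiles.tsv --out demo/stats.tsv
trflp-kit run --out-dir demo-run --seed 42    # full six-stage pipeline
```

`trflp-kit run` simulates the 2×2 factorial field design (cultivation
system × compost amendment, three plots each), processes every plot, and
writes profiles, assignments, diversity tables, rarefaction curves,
ordination coordinates, and the ANOVA table with letter groupings, plus a
manifest recording the configuration and seed.

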