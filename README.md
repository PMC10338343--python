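# piwikit

Quantitative analysis of piRNA-guided target binding and cleavage by
PIWI-clade Argonaute proteins.

PIWI proteins use PIWI-interacting RNAs (piRNAs, 18–35 nt) to slice
complementary transposon transcripts, cutting the phosphodiester bond
between the target nucleotides opposite guide positions g10 and g11.
Unlike AGO-clade proteins, PIWI slicing tolerates mismatches at
essentially any guide position once ~15 or more contiguous nucleotides
pair — a property with direct consequences for how easily transposons
can escape silencing by mutation. `piwikit` provides, as a tested
reusable library, the estimators needed to quantify that behaviour:

- **`piwikit.pairing`** — guide:target duplex representation in g/t
  coordinates, cut-site arithmetic, and nearest-neighbour duplex free
  energy; ΔG⁰ = RT ln(K_d/1 M) conversion.
- **`piwikit.rbns`** — Bind-'n-Seq analysis: assignment of reads to
  non-overlapping site types and joint maximum-likelihood estimation of
  per-site dissociation constants across a six-point piRISC
  concentration series (median of 49 optimizer starts), plus the
  closed-form double-filter binding fit and an energy/affinity
  permutation regression.
- **`piwikit.cns`** — Cleave-'n-Seq analysis: depletion normalization,
  the single-turnover burst-and-steady-state fit
  P(t) = E·[(k₂/(k₂+k₃))²(1 − e^−(k₂+k₃)t) + k₂k₃/(k₂+k₃)·t] with
  k = k₂+k₃ reported as the pre-steady-state cleavage rate, mismatch
  fold-change summaries, and cut-site mapping from sequenced 3' products.
- **`piwikit.invivo`** — degradome (5'-monophosphate) analysis: piRNA
  prefix-group filtering, spike-in absolute quantification, candidate
  3'-cleavage-product identification, and the background-subtracted
  statistic f_cleaved = f_decreased(targeted) − f_decreased(control)
  over 16 control×mutant animal pairings with a 10,000-iteration
  bootstrap CI.
- **`piwikit.logit`** — the 35-feature logistic decision function for
  P(cleaved), fit as a 16×5×5 = 400-model cross-validated ensemble with
  precision–recall evaluation.
- **`piwikit.mutsim`** — transposon-mutagenesis escape simulation:
  synonymous-constrained substitutions under a mutation spectrum and
  counting of cleavage-competent piRNA/siRNA guides.
- **`piwikit.kmers`** — transcript/transposon k-mer sharing fractions.
- **`piwikit.simulate`** — seeded generators producing synthetic inputs
  with known ground truth for every stage.

A thin `pwk` command-line interface wraps the library
(`pwk simulate|rbns|cns|invivo|logit|mutsim|kmer …`).

## Worked example

Generate a small synthetic Cleave-'n-Seq experiment with known rates and
recover them:

```python
import numpy as np
from piwikit import cns, simulate

rng = np.random.default_rng(7)
k_true = 10 ** rng.uniform(-2, 0.5, 5)          # five variants, 0.01-3 /min
counts, manifest = simulate.gen_cns(k_true, depth=100_000, seed=8)
norm = cns.normalize_library(counts, manifest.index[manifest["is_normalizer"]])
p_rel = cns.compute_p_relative(norm)
p_rel = p_rel[~p_rel["variant_id"].str.startswith("norm")]
fits = cns.fit_burst_table(p_rel)
for vid, row in fits.iterrows():
    print(f"{vid}: k = {row.k:.4f} /min (true {manifest.loc[vid,'true_k']:.4f})")
```

prints

```
v0000: k = 0.3709 /min (true 0.3654)
v0001: k = 1.7744 /min (true 1.7500)
v0002: k = 0.8886 /min (true 0.8694)
v0003: k = 0.0356 /min (true 0.0366)
v0004: k = 0.0558 /min (true 0.0563)
```

i.e. each variant's pre-steady-state cleavage rate is recovered within a
few percent from multinomially noisy counts at 10⁵ reads per sample,
after normalizing to the uncleavable (≤7-nt complementarity) variants
that track library recovery.

The same round-trip pattern works for every stage: `simulate.gen_rbns_counts`
→ `rbns.fit_kd_mle`; `simulate.gen_degradome` → `invivo.group_pirnas` →
`invivo.find_candidates` → `invivo.fraction_cleaved`;
`simulate.gen_repertoire` → `mutsim.run_simulations` → `mutsim.decay_rate`.

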