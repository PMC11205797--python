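# patchassembly

Community-assembly analysis for microbial communities living on discrete
habitat patches of different sizes — the kind of bare soil patches that
burrowing mammals (pikas, prairie dogs, zokors) carve out of alpine meadows.
Given an ASV count table, a rooted phylogeny and per-sample metadata (patch
membership, patch area, soil properties), the pipeline asks two questions:

1. **Do microbes follow a species–area relationship?** α-diversity (Shannon,
   richness, Chao1), within-patch β-diversity (Bray–Curtis) and habitat
   heterogeneity are regressed on log10(patch area).
2. **Which ecological processes assemble these communities?** Three
   complementary analyses: Levins' niche-breadth classification of taxa into
   habitat generalists and specialists; the Sloan neutral community model,
   whose migration rate m and fit R² measure how far a community sits from
   pure dispersal–drift expectation; and Stegen-style null-model partitioning
   of sample pairs into five processes from βNTI and RC_bray:

   | βNTI | RC_bray | process |
   |------|---------|---------|
   | > 2  | —       | variable selection |
   | < −2 | —       | homogeneous selection |
   | \|·\| ≤ 2 | > 0.95 | dispersal limitation |
   | \|·\| ≤ 2 | < −0.95 | homogenizing dispersal |
   | \|·\| ≤ 2 | \|·\| ≤ 0.95 | undominated (drift) |

   Thresholded Spearman co-occurrence networks with per-sample subnetwork
   topology (size, connectivity, modularity) regressed on patch area complete
   the picture.

The Sloan model predicts a taxon's occurrence frequency from its mean
relative abundance p: with N reads per sample and migration rate m, local
relative abundance is approximately Beta(N·m·p, N·m·(1−p)), and
f̂ = 1 − BetaCDF(d; N·m·p, N·m·(1−p)) at detection limit d = 1/N. `fit_ncm`
estimates m by bounded least squares; by default it propagates the finite-read
sampling layer exactly (beta-binomial occurrence), which removes the upward
bias of the hard-threshold form on count data (see `docs/methods.md`).

Because studies of this design rarely deposit raw reads, the package includes
a first-class synthetic-community generator with three regimes — neutral,
selection-driven (Brownian trait evolution on a coalescent tree + Gaussian
environmental filtering) and dispersal-limited (area-scaled log-normal pool
divergence) — each with serialized ground truth, used throughout the test
suite.

## Worked example

Run the bundled selection-driven fixture (6 patches of 4–592 m², 51 samples,
200 taxa, 99 null randomizations):

```bash
patchassembly -v run-all --config configs/bacteria_like.yaml --out-dir out/
```

`out/sar_regressions.tsv` (abridged):

| response | slope | r2 | pvalue | direction |
|----------|-------|----|--------|-----------|
| shannon  | −0.610 | 0.77 | 3.9e−17 | negative |
| richness | −40.76 | 0.86 | 3.1e−22 | negative |
| beta_bray_curtis | −0.045 | 0.75 | 0.027 | negative |

Shannon diversity drops by ~0.61 per decade of patch area — the inverse
species–area relationship that environmental selection produces when larger
patches are more nutrient-depleted. `out/assembly_partition.tsv`:

| group | variable_selection | homogeneous_selection | dispersal_limitation | homogenizing_dispersal | undominated |
|-------|-----|-----|------|------|------|
| all | 0.667 | 0.000 | 0.013 | 0.254 | 0.066 |
| between_patch | 0.796 | 0.000 | 0.016 | 0.161 | 0.027 |

Two thirds of all sample pairs are under variable selection (βNTI > 2):
deterministic processes dominate, and they do so through between-patch
environmental contrasts. `out/ncm_fit.tsv` reports the neutral-model fit for
the same data — m = 0.034, R² = 0.69 — a mediocre neutral fit, consistent
with selection-dominated assembly. Running the companion
`configs/fungi_like.yaml` (dispersal-limited regime) instead yields a
*positive* β-diversity–area slope and a stochastic share above 0.9,
reproducing the classic bacteria-versus-fungi contrast in assembly mode.

Each stage is also exposed as a subcommand (`simulate`, `rarefy`,
`diversity`, `niche`, `ncm`, `assembly`, `network`) and as plain library
functions (`patchassembly.fit_ncm`, `patchassembly.assembly_metrics`, ...).

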