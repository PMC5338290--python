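# phytophagnet

Chemically annotated plant–herbivore network analysis.

Herbivorous insects — butterflies in particular — are often strikingly
selective about their host plants. Two competing explanations are the
**feed-on-family** hypothesis (insects track plant taxonomy: hosts cluster
within plant families) and the **feed-on-compound** hypothesis (insects track
plant chemistry: hosts share secondary metabolites, wherever they sit
taxonomically). `phytophagnet` implements the statistics needed to weigh the
two on any bipartite insect–plant interaction dataset annotated with a
plant–compound catalog (e.g. KNApSAcK-style species–metabolite records), and
to screen for the *common specific* compounds — shared by a clade's host
plants and absent elsewhere — that are candidate attractants or repellents.

It is aimed at ecologists and systems biologists with three delimited-text
tables: interactions (`insect`, `plant`), taxonomy per side (`species`,
`genus`, `subfamily`, `family`, `order`), and plant compounds
(`plant`, `compound`).

## Statistics implemented

All significance statements score an observed network measure X against
1,000 degree-preserving randomizations (checkerboard-swap *fixed–fixed*
null model by default; an independent-cell *probabilistic* model with
p<sub>ij</sub> ∝ d<sub>i</sub>d<sub>j</sub> is also provided):
Z<sub>X</sub> = (X<sub>real</sub> − ⟨X<sub>rand</sub>⟩)/SD<sub>rand</sub>.

- **Interaction-frequency Z-scores** — W<sub>ij</sub>, the number of edges
  between insect taxon *i* and plant family *j*; positive Z flags
  attraction, negative Z avoidance.
- **Family-based evenness** (feed-on-family test) — for insect category *i*
  with S<sub>i</sub> hosts, N<sub>ij</sub> of them in plant family *j*:
  E(i) = −Σ<sub>j</sub> (N<sub>ij</sub>/S<sub>i</sub>) ln(N<sub>ij</sub>/S<sub>i</sub>) / ln|m<sub>f</sub>|,
  normalized by the plant families m<sub>f</sub> present in the whole
  network (Pielou-style). Z<sup>E</sup> < 0 ⇒ feeding is more
  family-selective than degree-matched chance.
- **Food-pairing statistic** (feed-on-compound test) —
  N<sub>s</sub>(k): mean |C<sub>a</sub> ∩ C<sub>b</sub>| over unordered
  pairs of butterfly *k*'s hosts, where C<sub>p</sub> is plant *p*'s
  compound set. Z<sup>Ns</sup> > 0 ⇒ hosts share more compounds than
  chance.
- **Compound contribution** χ<sub>i</sub> — observed minus expected mean
  compound overlap between plant *i* and the other hosts of its
  herbivores; positive χ marks plants that pull the network toward
  compound-driven selection. Reported with its Spearman correlation
  against plant degree.
- **Enrichment screen** — per compound, a 2×2 table (clade vs non-clade
  observations × compound present/absent), two-sided Fisher's exact p and
  Cramér's V = √(χ²/n); candidates pass a fixed effect-size-calibrated p
  threshold (default 10⁻⁶), with Benjamini–Hochberg as an opt-in.
- **Ecozone composition similarity** — Pearson r between relative
  family-composition profiles of faunal regions.

A synthetic-data module generates taxonomically structured networks with
planted family preference (λ) and compound attraction (β) plus layered
chemistry (common / family-core / clade-specific / background compounds)
and full ground truth, so the whole pipeline is testable offline.

## Worked example

```sh
phytophagnet simulate --out fixture --seed 3
cat > pipeline.yaml <<EOF
interactions: fixture/interactions.tsv
insect_taxonomy: fixture/insect_taxonomy.tsv
plant_taxonomy: fixture/plant_taxonomy.tsv
compounds: fixture/compounds.tsv
out_dir: out
null_model: {replicates: 1000, seed: 1}
p_threshold: 1.0e-4
EOF
phytophagnet run pipeline.yaml
```

prints (trimmed):

```
raw network: 250 edges, 50 insects, 92 plants
compound-annotated network: 250 edges, 50 insects, 92 plants

feed-on-family:   <E>_real = 0.0787, <E>_null = 0.7152, Z = -28.227
feed-on-compound: <Ns>_real = 6.9180, <Ns>_null = 2.7933, Z = 35.572
chi vs degree: Spearman r = -0.046545315268839364

common-specific candidates per clade:
  Lepifam00: C00000002, C00000003, C00000004, C00000005, C00000006, C00000022, C00000026
  ...
```

Reading: the simulated butterflies' realized host sets are far more
concentrated within plant families than degree-matched chance
(Z<sup>E</sup> ≪ 0, mean evenness 0.08 vs 0.72 expected), and their hosts
share far more compounds than chance (Z<sup>Ns</sup> ≫ 0, ~6.9 shared
compounds per host pair vs ~2.8) — both planted effects recovered. The
candidate lists name the compounds statistically specific to each
butterfly family's host plants; in the simulation these are exactly the
planted clade-specific compounds (plus family-core compounds of the
preferred plant family, which are genuinely host-specific too).

The same `run` command works unchanged on real exports, and the library
surface (`phytophagnet.family_networks`, `phytophagnet.compound_stats`,
`phytophagnet.null_models`) exposes every statistic individually.

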