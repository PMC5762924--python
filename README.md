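# paleotrait

Trait-based analysis of late-Quaternary plant communities from permafrost
environmental DNA (sedaDNA).

Metabarcoding of ancient DNA yields a sample × MOTU read-count table — a
snapshot of past vegetation at each dated permafrost sample. Combining it
with per-taxon mutualist traits (mycorrhizal type AM/ECM/ERM/NM and status
OM/FM/NM, symbiotic N-fixation, pollination mode) plus growth form lets
one ask how the mutualist structure of high-latitude vegetation shifted
across the climatic periods of the last ~50,000 years: pre-LGM (> 25 ka
BP), LGM (25–15 ka BP) and post-LGM (< 15 ka BP). `paleotrait` provides
that entire analysis as a tested, reusable Python library with a CLI, plus
a synthetic-data generator reproducing the study design (216 samples split
145/32/39 over periods, 131 MOTUs, 21 sites) so every procedure can be
validated against known generative truth.

## What it computes

* **Composition** — per-sample community-weighted trait shares
  (read-weighted and MOTU-weighted) and per-period means with stratified
  bootstrap 95% CIs (2.5/97.5 percentiles, resampling within periods).
* **PERMANOVA** — Gower-centred sequential (Type-I) partition of
  Bray–Curtis or Euclidean distances, SS_k = tr(H_k G) − tr(H_{k−1} G),
  pseudo-F by free permutation; pairwise contrasts with a compact letter
  display. Under Euclidean distance and one factor this reduces exactly to
  classical one-way ANOVA.
* **OMI ordination** — each MOTU's niche position is its
  abundance-weighted mean environmental position m_i = Σ_j p_ij z_j in the
  standardized period-indicator space; OMI_i = ‖m_i‖², with the exact
  decomposition inertia = OMI + tolerance + residual tolerance; axes from
  the eigendecomposition of MᵀUM; a Monte-Carlo test of the weighted mean
  OMI; trait-on-niche PERMANOVA model series and Dunn's post-hoc tests.
* **Spatial diagnostics** — Mantel correlograms on db-RDA residual
  distances over great-circle distance classes, multi-scale variance
  decomposition (total = explained + residual + cross term per class), and
  a simulation-based Type-I inflation estimate under a spatial Gaussian
  process.
* **Phylogenetics** — grafting MOTUs onto a backbone supertree at the
  lowest containing taxonomic rank (preserving ultrametricity), and
  phylogenetic GLS with Pagel's λ co-estimated by ML on [0, 1].
* **Sensitivity** — random trait-error injection (1–20% of MOTUs per
  susceptible trait; ERM and N-fixation protected) with composition
  correlation curves and reruns of the most conservative trait-niche model.

## Worked example

```python
from paleotrait.synthetic_data import SimConfig, simulate_dataset
from paleotrait.traits import filter_dataset
from paleotrait.composition import sample_trait_shares, bootstrap_ci
from paleotrait.permanova import bray_curtis, permanova, pairwise_permanova
from paleotrait.omi import omi_analysis, omi_randtest

ds = simulate_dataset(SimConfig(seed=1))          # 216 samples x 131 MOTUs
rm, tt, report = filter_dataset(ds.read_matrix, ds.traits)
st = ds.samples[ds.samples.sample_id.isin(rm.index)]
periods = st.set_index("sample_id")["period"].loc[rm.index]

shares = sample_trait_shares(rm, tt, "myc_type", "reads")
ci = bootstrap_ci(shares, st, B=1000, seed=1)
print(ci.point.round(3))

d = bray_curtis(shares + 1e-12)
res = permanova(d, periods.rename("period"), n_perm=999, seed=1)
print(res.terms.round(4).to_string(index=False))
_, letters = pairwise_permanova(d, periods, n_perm=999, seed=1)
print(letters)

omi = omi_analysis(rm, periods)
_, p, _ = omi_randtest(rm, periods, n_perm=999, seed=1)
print(round(omi.mean_omi, 3), p)
```

Output:

```
             AM    ECM    ERM     NM
pre-LGM   0.728  0.039  0.011  0.222
LGM       0.504  0.086  0.020  0.390
post-LGM  0.288  0.125  0.020  0.566
  name  df     SS  pseudo_F     R2     p
period   2 6.3722  364.5915 0.7739 0.001
{'pre-LGM': 'a', 'LGM': 'b', 'post-LGM': 'c'}
0.554 0.005
```

Read-weighted AM share declines from 73% of reads in the pre-LGM to 29% in
the post-LGM while NM rises — the generator's built-in period shift —
and the mycorrhizal-type composition differs between all three periods
(pairwise letters a/b/c). The mean outlying-mean-index of 0.554 is matched or
exceeded by only 4 of 999 random sample-to-period assignments (p = 0.005),
confirming that period structures MOTU niches.

The same pipeline runs end-to-end from a YAML config:

```bash
paleotrait run-all --config run.yaml --outdir out/   # writes CSVs + manifest.json
paleotrait simulate --seed 1 --outdir data/          # just the synthetic dataset
```

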