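# crpconn

Hierarchical analysis linking peripheral inflammation to brain microstructure
and resting-state functional connectivity — with a synthetic-cohort generator
so that every stage of the pipeline can be exercised, and its statistical
behaviour verified, without access to clinical MRI data.

## The scientific problem

Systemic inflammation, indexed by blood C-reactive protein (CRP, mg/L), is
associated with depression and is known to perturb brain physiology. This
package implements a case–control analysis design for testing whether CRP
relates to (a) regional brain microstructure — quantitative-MT proton density
(PD), a proxy for tissue free-water content — and (b) the resting-state
functional connectome, across three groups: healthy controls, depressed cases
with CRP < 3 mg/L, and depressed cases with CRP > 3 mg/L.

The analysis proceeds hierarchically, from coarse to fine:

1. **Global**: two-sample Kolmogorov–Smirnov tests on whole-brain
   distributions of regional measures and edge weights, per group contrast.
2. **Nodal** (gated on level 1): for each of 376 regions (360 cortical +
   16 subcortical), OLS of the MRI measure on CRP with covariate adjustment
   (default: age and scanning centre), or a covariate-adjusted case–control
   contrast; Benjamini–Hochberg FDR within the 376-test family
   (significant ⇔ q < 0.05).
3. **Edge** (gated likewise): the same regression over all
   n(n−1)/2 = 70,500 edges of the connectome (response: Fisher-z transformed
   Pearson correlation), plus per-seed families of 375 (whole brain) or 187
   (same-hemisphere) edges for subcortical seeds such as the hippocampus.

Connectivity is estimated from band-limited BOLD: regional time series are
band-passed to 0.01–0.1 Hz by summing MODWT (maximal overlap discrete wavelet
transform) details at levels 2–4 (TR = 2.57 s), correlated per pair, and
summarized per node by the **weighted degree** k_i = mean_{j≠i} r_ij — signed,
unthresholded hubness. **Modular degree** averages k over the nodes of one
resting-state module (e.g. the default mode network, DMN).

Where a CRP effect on microstructure and on connectivity co-localise, linear
**causal mediation** asks whether the connectivity effect is direct
(ADE = c′) or mediated through PD (ACME = a·b), from the two-equation system
m = a·x + …, y = b·m + c′·x + …, with case-resampling bootstrap percentile
CIs.

## Worked example

```python
import numpy as np
from crpconn import (CohortConfig, simulate_dataset, functional_connectivity,
                     weighted_degree, run_hierarchy, HierarchyConfig)

ds = simulate_dataset(CohortConfig(), seed=42)   # 46 HC / 50 loCRP / 33 hiCRP
order = ds.subjects["subject_id"]
matrices = {s: functional_connectivity(ds.panels[s]) for s in order}
pd_table = np.stack([ds.qmt[s].pd for s in order], axis=1)
degree_table = np.stack([weighted_degree(matrices[s]).k for s in order], axis=1)

res = run_hierarchy(ds.subjects, pd_table, degree_table, matrices, ds.meta,
                    HierarchyConfig())
```

Output for this seed:

```
KS pd     cases_vs_controls  D=0.088 p=1.10e-01
KS pd     hiCRP_vs_loCRP     D=0.112 p=1.83e-02
PD~CRP significant regions: 25
  top hits: L_ProS, L_p47r, L_v23ab, L_IFSa
degree case-control significant regions: 196
  of which DMN: 70
edge~CRP significant edges: 4
  hits: L_FOP1--L_7Pm, L_RSC--L_v23ab, L_POS1--L_hippocampus, L_10r--L_hippocampus
```

Reading this: the global KS gate opens on the hiCRP-vs-loCRP PD contrast;
the nodal PD~CRP map recovers the generator's injected effect regions
(posterior cingulate/precuneus and frontal areas, 22 positive + 7 negative,
here 25 detected at q < 0.05 with a handful of false positives consistent
with 5% FDR); the case–control degree contrast flags every DMN node (the
injected hubness reduction); and the edge-level scan finds exactly the four
strongly injected edges — three scaling positively with CRP (two within the
DMN midline, one hippocampus–medial-prefrontal) and one negatively.

The same stages are available from the shell:

```bash
crpconn simulate --out sim/ --seed 42 --with-motion
crpconn preprocess --in sim/ --out pre/
crpconn connectome --in pre/ --out conn/ --subjects sim/subjects.tsv
crpconn infer --in conn/ --subjects sim/subjects.tsv --out stats/
crpconn mediate --subjects sim/subjects.tsv --in conn/ \
    --candidates candidates.json --boot 5000 --seed 1 --out mediation.tsv
```

(`infer` expects `matrices/` and `qmt/` under `--in`; paths are plain TSV/NPZ
as documented in `crpconn.io`.)

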