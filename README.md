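# neurometab

Multiomics integration of whole-brain structural MRI with untargeted
cerebrospinal-fluid (CSF) metabolomics, aimed at mapping gray-matter atrophy
in mild cognitive impairment (MCI) onto dysregulated metabolic pathways. The
package implements the full analysis pipeline as a tested, reusable library
with a synthetic-data generator that plants known structure, so every stage
has a parameter-recovery test.

Intended users: imaging-omics methodologists and analysts who want a
transparent, scriptable reimplementation of this three-step integration
design — and a sandbox in which its operating characteristics (calibration,
recovery, replication) can be measured.

## The pipeline

1. **Metabolomics preprocessing.** LC-MS feature tables (m/z, retention
   time, triplicate intensities) are cleaned by the cascade: drop features
   with median within-replicate CV ≥ 0.75; drop samples whose replicate
   Pearson correlation is < 0.7; median-summarize triplicates (≥ 2
   non-missing required); ComBat batch correction (parametric empirical
   Bayes, on log2 values); retain features with < 20% missing in at least
   one diagnosis group and impute the rest with half the feature's minimum;
   log2 transform and quantile normalization.
2. **Voxel selection (PLS-DA + VIP).** Gray-matter probability maps are
   masked at mean probability ≥ 0.3 and flattened to a subject × voxel
   matrix. A 3-fold cross-validated PLS-DA (NIPALS, diagnosis coded ±1)
   selects the component count; voxels are scored by variable importance in
   projection,

       VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),  SS_a = q_a² t_aᵀt_a,

   and selected when VIP ≥ 2 with > 2% mean GM difference. Voxels with
   *higher* GM in cases are binned as artifacts and excluded.
3. **Network integration.** Pairwise Pearson correlations between selected
   voxels and clean metabolites (sparse-PLS association mode available). The
   edge cutoff is the weakest |r| at which every voxel keeps ≥ 1 metabolite
   link (with p < 0.05); communities come from multilevel (Louvain)
   modularity maximization on |r|-weighted edges, with eigenvector
   centrality per node and a per-community voxel/metabolite summary table.
4. **Region annotation.** Community voxels are mapped back to 3D; a
   community is annotated with an atlas region only if its largest
   26-connected component and its majority label both cover ≥ 50% of its
   voxels, else "N/A".
5. **Pathway enrichment (mummichog-style).** Features are annotated to
   compounds by adduct mass rules (M[1+], M+H[1+], M+Na[1+]) at 10 ppm,
   collapsed to unique compounds, and tested per pathway with a right-tail
   hypergeometric p plus an empirical permutation p from resampled feature
   lists.
6. **Replication.** A 67/33 diagnosis-stratified split re-runs the
   integration on training subjects with the fixed cutoff; every training
   edge's correlation is recomputed on validation subjects and summarized by
   OLS R², at pair level and per-metabolite averages.

## Worked example

```python
from neurometab import PipelineConfig, run_all
from neurometab.synthetic import SyntheticConfig

cfg = PipelineConfig(seed=1, synthetic=SyntheticConfig(seed=1))
result = run_all(cfg)
print(result.metrics)
```

prints (at seed 1):

```
{'voxel_jaccard': 0.9843, 'community_ari': 1.0,
 'enriched_community': 0, 'planted_pathway_rank': 1,
 'planted_pathway_permutation_p': 0.009901, ...
 'replication_r2_signal': 0.9439, 'replication_r2_all': 0.6793}
```

Reading: of the 14,112 masked voxels the PLS-DA/VIP rule recovers the 750
planted atrophy voxels almost exactly (Jaccard 0.98); Louvain communities
reproduce the planted voxel-metabolite blocks perfectly (ARI 1.0); the
planted pathway ranks first in its community's enrichment at the smallest
achievable permutation p (1/101); and voxel-metabolite links that carry
planted signal replicate far better across the 67/33 split (R² 0.94) than
the full edge set (R² 0.68). The automatic cutoff lands at |r| ≈ 0.29 —
the same regime as the 0.271 threshold used with the original cohort.

The same run is available from the shell:

```bash
neurometab run-all --seed 1 --out results/
neurometab summary --results results/
```

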