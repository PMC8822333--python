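"""Published reference values from the MCI brain/CSF multiomics study.

These constants are the study's printed dataset-level numbers. They are not
reproducible from synthetic data (the cohort is access-restricted), so they
serve as config defaults, consistency checks and worked examples: cohort
sizes, voxel bookkeeping, the community-cluster table, and m/z values of
lab-confirmed metabolites with their neutral monoisotopic masses.
"""

from __future__ import annotations

import pandas as pd

# Cohort
STUDY_N_MCI = 60
STUDY_N_CONTROL = 85
STUDY_N_SUBJECTS = STUDY_N_MCI + STUDY_N_CONTROL

# Voxel bookkeeping (whole-brain gray-matter mask and PLS-DA selection)
STUDY_TOTAL_VOXELS = 247_941
STUDY_SELECTED_VOXELS = 2_424          # VIP >= 2 and >2% mean GM difference
STUDY_ARTIFACT_VOXELS = 49             # higher GM in MCI; excluded
STUDY_RETAINED_VOXELS = 2_375          # lower GM in MCI; integrated

# Metabolomics bookkeeping
STUDY_TOTAL_FEATURES = 13_064
STUDY_CLEAN_FEATURES = 9_804
STUDY_LINKED_METABOLITES = 463
STUDY_CORRELATION_CUTOFF = 0.271       # weakest |r| keeping every voxel linked

# Sensitivity analysis (67/33 stratified split)
STUDY_TRAIN_FRACTION = 0.67
STUDY_SPLIT_COUNTS = {
    "train_cases": 40,
    "train_controls": 57,
    "validation_cases": 20,
    "validation_controls": 28,
}

# Community-cluster table: voxel and (edge-linked) metabolite counts per
# cluster, with the annotated brain region or None for clusters that did not
# map to a contiguous region.
STUDY_CLUSTER_TABLE = pd.DataFrame(
    [
        (1, "Right parietal cortex", 90, 111),
        (2, "Posterior thalamus", 406, 96),
        (3, None, 11, 13),
        (4, "Hippocampus/Parahippocampal gyrus (right)", 209, 68),
        (5, None, 7, 14),
        (6, "Left Hippocampus/Parahippocampal gyrus A", 438, 108),
        (7, "Thalamus", 158, 54),
        (8, "Left Hippocampus/Parahippocampal gyrus B", 617, 107),
        (9, None, 13, 36),
        (10, "Occipital lobe and orbitofrontal cortex", 393, 177),
        (11, None, 32, 31),
        (12, None, 1, 1),
    ],
    columns=["cluster", "region", "n_voxels", "n_metabolites"],
)

# Lab-confirmed metabolites (identification level 1) with printed m/z, the
# ionization adduct, and the neutral monoisotopic mass of the compound.
LAB_CONFIRMED_METABOLITES = pd.DataFrame(
    [
        ("Gamma-aminobutyrate", 104.0706, "M+H[1+]", 103.06333),   # C4H9NO2
        ("Hypoxanthine", 137.0458, "M+H[1+]", 136.03851),          # C5H4N4O
        ("Leucine", 132.1019, "M+H[1+]", 131.09463),               # C6H13NO2
    ],
    columns=["metabolite", "mz", "adduct", "monoisotopic_mass"],
)


def noncontiguous_cluster_sizes() -> list[int]:
    """Voxel counts of the clusters that did not map to a contiguous region."""
    t = STUDY_CLUSTER_TABLE
    return t.loc[t["region"].isna(), "n_voxels"].tolist()
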