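"""Feature schemas and cohort-plan constants.

The structural schema is the 221-feature morphometric vector produced by a
standard Freesurfer ``recon-all`` run: 9 global quantities, 26 subcortical /
corpus-callosum volumes from ``aseg.stats``, and volume, mean thickness and
thickness SD for the 62 cortical regions (31 per hemisphere) of the
Desikan-Killiany-Tourville (DKT) parcellation from the bilateral
``aparc.stats`` files.

The functional schema is a Harvard-Oxford-style list of 110 regional
timeseries labels; pairwise correlations among the retained regions form the
connectivity features.
"""

from __future__ import annotations

# --- structural -----------------------------------------------------------

#: Global quantities: 6 whole-brain volumes reported as '# Measure' lines in
#: aseg.stats, the CSF volume row of aseg.stats, and the per-hemisphere mean
#: cortical thickness from each aparc.stats file.
GLOBAL_MEASURES = (
    "lhCortexVol",
    "rhCortexVol",
    "lhCerebralWhiteMatterVol",
    "rhCerebralWhiteMatterVol",
    "CSF",
    "TotalGrayVol",
    "BrainSegVolNotVent",
    "lh_MeanThickness",
    "rh_MeanThickness",
)

#: Subcortical structures and corpus callosum subdivisions (aseg.stats rows).
SUBCORTICAL_STRUCTURES = (
    "Left-Lateral-Ventricle",
    "Right-Lateral-Ventricle",
    "Left-Thalamus-Proper",
    "Right-Thalamus-Proper",
    "Left-Caudate",
    "Right-Caudate",
    "Left-Putamen",
    "Right-Putamen",
    "Left-Pallidum",
    "Right-Pallidum",
    "Left-Hippocampus",
    "Right-Hippocampus",
    "Left-Amygdala",
    "Right-Amygdala",
    "Left-Accumbens-area",
    "Right-Accumbens-area",
    "Left-VentralDC",
    "Right-VentralDC",
    "3rd-Ventricle",
    "4th-Ventricle",
    "Brain-Stem",
    "CC_Posterior",
    "CC_Mid_Posterior",
    "CC_Central",
    "CC_Mid_Anterior",
    "CC_Anterior",
)

#: The 31 DKT cortical regions per hemisphere.
DKT_REGIONS = (
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "transversetemporal",
    "insula",
)

CORTICAL_MEASURES = ("GrayVol", "ThickAvg", "ThickStd")

HEMIS = ("lh", "rh")


def structural_feature_names() -> list[str]:
    """Ordered names of the 221 structural features.

    Order: 9 globals, 26 subcortical volumes, then per hemisphere and region
    the three cortical measures (volume, mean thickness, thickness SD).
    """
    names = list(GLOBAL_MEASURES) + list(SUBCORTICAL_STRUCTURES)
    for hemi in HEMIS:
        for region in DKT_REGIONS:
            for meas in CORTICAL_MEASURES:
                names.append(f"{hemi}_{region}_{meas}")
    return names


N_STRUCTURAL = 221
assert len(structural_feature_names()) == N_STRUCTURAL

# --- functional -----------------------------------------------------------

N_ATLAS_REGIONS = 110


def atlas_region_ids(n_regions: int = N_ATLAS_REGIONS) -> list[str]:
    """Synthetic Harvard-Oxford-style region labels, left/right interleaved."""
    ids = []
    for i in range(n_regions):
        hemi = "L" if i % 2 == 0 else "R"
        ids.append(f"HO_{hemi}_{i // 2 + 1:03d}")
    return ids


# --- cohort plan ----------------------------------------------------------

#: Per-site (n_ASD, n_TD) counts of the 35-site male 5-40 y multi-site ABIDE
#: I+II sample: 1383 subjects, 680 ASD and 703 TD.
ABIDE_SITE_PLAN: tuple[tuple[str, int, int], ...] = (
    ("BNI_A", 14, 11),
    ("CALTECH", 12, 11),
    ("CMU", 7, 9),
    ("EMC_A", 21, 22),
    ("ETH_A", 10, 22),
    ("GU_A", 37, 26),
    ("IP_A", 13, 8),
    ("IU_A", 8, 9),
    ("KKI", 13, 18),
    ("KKI_A", 30, 62),
    ("LEUVEN_A", 9, 11),
    ("LEUVEN_B", 10, 13),
    ("MAX_MUN", 15, 26),
    ("NYU", 62, 73),
    ("NYU_A", 41, 27),
    ("OHSU", 13, 15),
    ("OHSU_A", 29, 27),
    ("OILH_B", 7, 7),
    ("OLIN", 16, 13),
    ("PITT", 26, 21),
    ("SBL", 10, 12),
    ("SDSU", 10, 13),
    ("SDSU_A", 23, 22),
    ("STANFORD", 15, 14),
    ("TCD_A", 19, 15),
    ("TRINITY", 24, 25),
    ("UCD_A", 12, 8),
    ("UCLA_A", 33, 26),
    ("UCLA_B", 10, 9),
    ("UM_A", 33, 33),
    ("UM_B", 12, 18),
    ("USM", 46, 36),
    ("USM_A", 14, 12),
    ("U_MIA_A", 7, 9),
    ("YALE", 19, 20),
)

assert sum(p[1] for p in ABIDE_SITE_PLAN) == 680
assert sum(p[2] for p in ABIDE_SITE_PLAN) == 703
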