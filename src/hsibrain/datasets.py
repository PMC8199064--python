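"""Published reference tables used for arithmetic cross-checks.

These are printed summary numbers from the intraoperative glioma study this
pipeline re-implements; the underlying images are private, but the printed
tables are usable inputs: the labeled-pixel census of the thirteen captures
and the band-efficiency comparison of published brain-HSI classifiers.
"""

from .classes import ARTERIAL, DURA, HEALTHY, TUMOR, VENOUS

#: labeled-pixel counts per capture and class (thirteen high-grade-glioma
#: captures from twelve patients)
COHORT_CENSUS = {
    "ID18":   {HEALTHY: 648,  TUMOR: 1587, VENOUS: 79,  ARTERIAL: 14,  DURA: 369},
    "ID25":   {HEALTHY: 801,  TUMOR: 206,  VENOUS: 90,  ARTERIAL: 15,  DURA: 94},
    "ID29":   {HEALTHY: 3752, TUMOR: 64,   VENOUS: 98,  ARTERIAL: 11,  DURA: 1599},
    "ID30":   {HEALTHY: 2587, TUMOR: 2737, VENOUS: 487, ARTERIAL: 381, DURA: 1366},
    "ID33":   {HEALTHY: 6671, TUMOR: 973,  VENOUS: 842, ARTERIAL: 35,  DURA: 1443},
    "ID34":   {HEALTHY: 1186, TUMOR: 1464, VENOUS: 181, ARTERIAL: 176, DURA: 780},
    "ID35":   {HEALTHY: 3864, TUMOR: 1389, VENOUS: 837, ARTERIAL: 58,  DURA: 586},
    "ID38":   {HEALTHY: 1740, TUMOR: 487,  VENOUS: 113, ARTERIAL: 191, DURA: 825},
    "ID47C1": {HEALTHY: 174,  TUMOR: 160,  VENOUS: 58,  ARTERIAL: 54,  DURA: 567},
    "ID47C2": {HEALTHY: 715,  TUMOR: 182,  VENOUS: 14,  ARTERIAL: 148, DURA: 129},
    "ID50":   {HEALTHY: 410,  TUMOR: 1282, VENOUS: 712, ARTERIAL: 47,  DURA: 628},
    "ID51":   {HEALTHY: 3888, TUMOR: 2731, VENOUS: 95,  ARTERIAL: 85,  DURA: 525},
    "ID56":   {HEALTHY: 1920, TUMOR: 1967, VENOUS: 75,  ARTERIAL: 37,  DURA: 5922},
}

#: printed labeled-pixel percentages for the same census (two decimals,
#: as published; the published rounding is not perfectly uniform)
COHORT_CENSUS_PERCENT = {
    "ID18":   {HEALTHY: 24.02, TUMOR: 58.84, VENOUS: 2.92,  ARTERIAL: 0.52,  DURA: 13.68},
    "ID25":   {HEALTHY: 66.42, TUMOR: 17.08, VENOUS: 7.46,  ARTERIAL: 1.24,  DURA: 7.79},
    "ID29":   {HEALTHY: 67.92, TUMOR: 1.16,  VENOUS: 1.77,  ARTERIAL: 0.20,  DURA: 28.95},
    "ID30":   {HEALTHY: 34.23, TUMOR: 36.21, VENOUS: 6.44,  ARTERIAL: 5.04,  DURA: 18.07},
    "ID33":   {HEALTHY: 66.95, TUMOR: 9.76,  VENOUS: 8.45,  ARTERIAL: 0.35,  DURA: 14.48},
    "ID34":   {HEALTHY: 31.32, TUMOR: 38.66, VENOUS: 4.78,  ARTERIAL: 4.65,  DURA: 20.60},
    "ID35":   {HEALTHY: 57.38, TUMOR: 20.63, VENOUS: 12.43, ARTERIAL: 0.86,  DURA: 8.70},
    "ID38":   {HEALTHY: 51.85, TUMOR: 14.51, VENOUS: 3.37,  ARTERIAL: 5.69,  DURA: 24.58},
    "ID47C1": {HEALTHY: 17.17, TUMOR: 15.79, VENOUS: 5.73,  ARTERIAL: 5.33,  DURA: 55.97},
    "ID47C2": {HEALTHY: 60.19, TUMOR: 15.32, VENOUS: 1.18,  ARTERIAL: 12.46, DURA: 10.86},
    "ID50":   {HEALTHY: 13.32, TUMOR: 41.64, VENOUS: 23.12, ARTERIAL: 1.53,  DURA: 20.40},
    "ID51":   {HEALTHY: 53.09, TUMOR: 37.29, VENOUS: 1.30,  ARTERIAL: 1.16,  DURA: 7.17},
    "ID56":   {HEALTHY: 19.35, TUMOR: 19.83, VENOUS: 0.76,  ARTERIAL: 0.37,  DURA: 59.69},
}

#: published brain-HSI classification results used for the band-efficiency
#: comparison: (approach, overall accuracy in %, number of spectral bands).
#: The first three rows are the snapshot-camera results this pipeline
#: re-implements (25 bands); the rest are published comparators on
#: higher-band-count systems.
BAND_EFFICIENCY_REFERENCE = [
    ("snapshot SVM", 60.0, 25),
    ("snapshot RF", 53.0, 25),
    ("snapshot 3DCNN", 49.0, 25),
    ("3D-2D CNN", 80.0, 128),
    ("3D-2D CNN + SVM", 75.0, 128),
    ("SVM (128-band)", 76.0, 128),
    ("2D CNN", 72.0, 128),
    ("1D CNN", 78.0, 128),
    ("ANN (826-band)", 96.7, 826),
    ("RF (826-band)", 99.46, 826),
    ("spectral unmixing", 76.0, 128),
]
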