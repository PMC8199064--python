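"""Tissue class codes shared across the package.

Label 0 is reserved for unlabeled background; 1-5 are the five tissue
classes annotated in the intraoperative ground-truth maps.
"""

UNLABELED = 0
HEALTHY = 1
TUMOR = 2
VENOUS = 3
ARTERIAL = 4
DURA = 5

CLASS_IDS = (HEALTHY, TUMOR, VENOUS, ARTERIAL, DURA)
N_CLASSES = len(CLASS_IDS)

CLASS_NAMES = {
    UNLABELED: "unlabeled",
    HEALTHY: "healthy",
    TUMOR: "tumor",
    VENOUS: "venous",
    ARTERIAL: "arterial",
    DURA: "dura",
}

#: classification-map colors: green healthy, red tumor, blue venous,
#: cyan arterial, pink dura; unlabeled background is rendered black.
CLASS_COLORS = {
    UNLABELED: (0, 0, 0),
    HEALTHY: (0, 160, 0),
    TUMOR: (220, 0, 0),
    VENOUS: (0, 0, 220),
    ARTERIAL: (0, 200, 200),
    DURA: (240, 130, 180),
}
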